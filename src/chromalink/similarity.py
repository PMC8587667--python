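"""Pairwise Pearson similarity of fingerprints and its intra/inter partition.

The Pearson product-moment correlation r between two whole pretreated
traces (in data-point index space, no peak table) is the similarity score
throughout. Sample pairs are partitioned by their source labels into
*intra* (same source — "linked" ground truth) and *inter* (different
sources — "unlinked") lists; everything downstream (thresholds, error
rates, ROC, cross-validation) consumes that partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import FingerprintSet
from .errors import DegenerateDataError, PreconditionError

__all__ = [
    "PairwiseCorrelations",
    "pearson_r",
    "correlation_structure",
    "flag_outliers",
    "replicate_repeatability",
    "write_pairs_csv",
    "write_correlation_csv",
    "plot_correlation_map",
]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two equal-length (≥ 3) sequences.

    Raises :class:`DegenerateDataError` if either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise PreconditionError(f"inputs must be equal-length 1-D, got {x.shape} and {y.shape}")
    if len(x) < 3:
        raise PreconditionError(f"need at least 3 points, got {len(x)}")
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(xc @ xc)
    ny = float(yc @ yc)
    if nx <= 0 or ny <= 0:
        raise DegenerateDataError("correlation undefined for constant input")
    return float(np.clip((xc @ yc) / np.sqrt(nx * ny), -1.0, 1.0))


@dataclass
class PairwiseCorrelations:
    """Symmetric correlation matrix plus the intra/inter pair partition.

    ``intra`` and ``inter`` hold ``(i, j, r)`` triples with ``i < j`` row
    indices into ``sample_ids``/``labels``. Built from a labelled set by
    :func:`correlation_structure`, or from bare r-value lists via
    :meth:`from_partitions` when no matrix exists.
    """

    intra: list[tuple[int, int, float]]
    inter: list[tuple[int, int, float]]
    labels: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)
    r_matrix: np.ndarray | None = None

    @property
    def intra_r(self) -> np.ndarray:
        return np.array([r for _, _, r in self.intra])

    @property
    def inter_r(self) -> np.ndarray:
        return np.array([r for _, _, r in self.inter])

    @property
    def n_pairs(self) -> int:
        return len(self.intra) + len(self.inter)

    @classmethod
    def from_partitions(
        cls, intra_r: np.ndarray, inter_r: np.ndarray
    ) -> "PairwiseCorrelations":
        """Wrap pre-computed intra/inter r-values (no matrix, no indices)."""
        return cls(
            intra=[(-1, -1, float(r)) for r in np.asarray(intra_r, dtype=float)],
            inter=[(-1, -1, float(r)) for r in np.asarray(inter_r, dtype=float)],
        )


def correlation_structure(fpset: FingerprintSet) -> PairwiseCorrelations:
    """Full sample×sample Pearson matrix, partitioned by label equality.

    Requires ≥ 2 labelled groups and non-constant traces.
    """
    labels = [str(g) for g in fpset.labels]
    if any(g in ("None", "") for g in labels):
        raise PreconditionError("every sample needs a group label")
    if len(set(labels)) < 2:
        raise PreconditionError("intra/inter analysis needs at least 2 groups")
    matrix = fpset.matrix()
    sd = matrix.std(axis=1)
    flat = np.flatnonzero(sd <= 0)
    if flat.size:
        raise DegenerateDataError(
            f"constant trace(s): {[fpset.sample_ids[i] for i in flat]}"
        )
    c = np.clip(np.corrcoef(matrix), -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    n = len(fpset)
    intra, inter = [], []
    for i in range(n):
        for j in range(i + 1, n):
            triple = (i, j, float(c[i, j]))
            (intra if labels[i] == labels[j] else inter).append(triple)
    return PairwiseCorrelations(intra, inter, labels, list(fpset.sample_ids), c)


def flag_outliers(
    pc: PairwiseCorrelations, group: str, k_mad: float = 3.0, min_drop: float = 0.01
) -> list[str]:
    """Samples of ``group`` whose similarity to their own group is anomalously low.

    For each member, take the median of its correlations to the other
    members; flag members whose median falls below
    (median of those medians) − max(``k_mad`` × MAD, ``min_drop``), with the
    MAD scaled by 1.4826 (consistent robust sigma). The ``min_drop`` floor
    (r units) keeps a tightly-clustered homogeneous group from flagging
    members over practically meaningless spread — a reproducible stand-in
    for the visual colour-map inspection used in practice. Flagging only —
    removal is a separate, explicit step.
    """
    if pc.r_matrix is None:
        raise PreconditionError("outlier flagging needs the full correlation matrix")
    members = [i for i, g in enumerate(pc.labels) if g == group]
    if not members:
        raise LookupError(f"unknown group label {group!r}")
    if len(members) < 4:
        raise PreconditionError(
            f"group {group!r} has {len(members)} members; outlier flagging needs >= 4"
        )
    idx = np.array(members)
    sub = pc.r_matrix[np.ix_(idx, idx)]
    med = np.array(
        [np.median(np.delete(sub[k], k)) for k in range(len(idx))]
    )
    centre = np.median(med)
    mad = 1.4826 * np.median(np.abs(med - centre))
    cutoff = centre - max(k_mad * mad, min_drop)
    return [pc.sample_ids[idx[k]] for k in range(len(idx)) if med[k] < cutoff]


def replicate_repeatability(replicate_set: FingerprintSet) -> float:
    """Mean within-item pairwise r for a set whose group labels identify
    replicate groups (e.g. triplicate extractions of the same sample)."""
    matrix = replicate_set.matrix()
    groups = replicate_set.group_indices()
    rs = []
    for _, members in sorted(groups.items()):
        if len(members) < 2:
            raise PreconditionError("each item needs at least 2 replicates")
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                rs.append(pearson_r(matrix[members[a]], matrix[members[b]]))
    return float(np.mean(rs))


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_pairs_csv(pc: PairwiseCorrelations, path: str | Path) -> None:
    """Intra/inter pair list: i, j, sample ids, groups, kind, r."""
    rows = []
    for kind, pairs in (("intra", pc.intra), ("inter", pc.inter)):
        for i, j, r in pairs:
            rows.append(
                {
                    "i": i,
                    "j": j,
                    "sample_i": pc.sample_ids[i] if pc.sample_ids else "",
                    "sample_j": pc.sample_ids[j] if pc.sample_ids else "",
                    "group_i": pc.labels[i] if pc.labels else "",
                    "group_j": pc.labels[j] if pc.labels else "",
                    "kind": kind,
                    "r": r,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def write_correlation_csv(pc: PairwiseCorrelations, path: str | Path) -> None:
    if pc.r_matrix is None:
        raise PreconditionError("no correlation matrix to write")
    pd.DataFrame(pc.r_matrix, index=pc.sample_ids, columns=pc.sample_ids).to_csv(
        path, float_format="%.12g"
    )


def plot_correlation_map(pc: PairwiseCorrelations, path: str | Path) -> None:
    """Colour-map rendering of the correlation matrix (cosmetic; the CSV
    exports carry the exact values)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if pc.r_matrix is None:
        raise PreconditionError("no correlation matrix to plot")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(pc.r_matrix, vmin=-1, vmax=1, cmap="RdYlBu_r")
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_xlabel("sample index")
    ax.set_ylabel("sample index")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
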