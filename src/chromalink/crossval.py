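"""Cross-validated error rates for a threshold-linkage pipeline.

Two schemes estimate how well thresholds fitted on part of the data
predict held-out correlation values:

* **leave-n-objects-out (LNO)** — the intra and inter r-value lists are
  each partitioned (seeded, uniformly at random) into 20 disjoint folds of
  ~5%; per fold, thresholds are fitted on the remaining 95% of intra
  values and FN/FP evaluated on the held-out fold; the 20 folds together
  cover every r-value exactly once.
* **leave-one-plantation-out (LOPO)** — one source group per fold;
  thresholds come from the intra values of the other groups, the test FN
  set is the held-out group's intra pairs, and the test FP set is every
  inter pair with at least one member in the held-out group.

Overall rates pool the per-fold counts. If the data are exchangeable the
pooled rates match the full-calibration rates up to Monte-Carlo error —
the representativeness check for the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision import ErrorRates, threshold
from .errors import PreconditionError
from .similarity import PairwiseCorrelations

__all__ = ["CVReport", "lno_cv", "lopo_cv", "full_calibration"]


@dataclass
class CVReport:
    """Per-fold thresholds and error counts plus pooled overall rates."""

    scheme: str
    folds: pd.DataFrame
    overall: dict[float, ErrorRates]

    def overall_frame(self) -> pd.DataFrame:
        """Overall FN%/FP% as a one-row-per-level table (report layout)."""
        return pd.DataFrame(
            [
                {"level": lvl, "fn_pct": er.fn_pct, "fp_pct": er.fp_pct}
                for lvl, er in sorted(self.overall.items())
            ]
        )


def _fold_row(
    fold: str | int,
    train_intra: np.ndarray,
    test_intra: np.ndarray,
    test_inter: np.ndarray,
    levels: tuple[float, ...],
    counts: dict[float, list[int]],
) -> dict:
    row: dict = {
        "fold": fold,
        "n_test_intra": len(test_intra),
        "n_test_inter": len(test_inter),
    }
    for level in levels:
        thr = threshold(train_intra, level)
        fn = int(np.sum(test_intra < thr.value))
        fp = int(np.sum(test_inter >= thr.value))
        tag = f"{level:.2f}".split(".")[1]
        row[f"thr_{tag}"] = thr.value
        row[f"fn_{tag}"] = 100.0 * fn / len(test_intra) if len(test_intra) else np.nan
        row[f"fp_{tag}"] = 100.0 * fp / len(test_inter) if len(test_inter) else np.nan
        acc = counts[level]
        acc[0] += fn
        acc[1] += len(test_intra)
        acc[2] += fp
        acc[3] += len(test_inter)
    return row


def _pool(counts: dict[float, list[int]]) -> dict[float, ErrorRates]:
    return {
        level: ErrorRates(100.0 * fn / n_fn, 100.0 * fp / n_fp)
        for level, (fn, n_fn, fp, n_fp) in counts.items()
    }


def lno_cv(
    pc: PairwiseCorrelations,
    seed: int,
    n_folds: int = 20,
    levels: tuple[float, ...] = (0.95, 0.99),
) -> CVReport:
    """Leave-n-objects-out CV over the r-value lists (disjoint folds).

    Requires at least ``n_folds`` intra and inter values so every fold is
    non-empty; fold sizes differ by at most one.
    """
    intra, inter = pc.intra_r, pc.inter_r
    if len(intra) < n_folds or len(inter) < n_folds:
        raise PreconditionError(
            f"need >= {n_folds} intra and inter r-values, got {len(intra)}/{len(inter)}"
        )
    rng = np.random.default_rng(seed)
    intra_folds = np.array_split(rng.permutation(len(intra)), n_folds)
    inter_folds = np.array_split(rng.permutation(len(inter)), n_folds)
    counts = {level: [0, 0, 0, 0] for level in levels}
    rows = []
    for f in range(n_folds):
        test_i = intra[intra_folds[f]]
        train_mask = np.ones(len(intra), dtype=bool)
        train_mask[intra_folds[f]] = False
        rows.append(
            _fold_row(f, intra[train_mask], test_i, inter[inter_folds[f]], levels, counts)
        )
    return CVReport("lno", pd.DataFrame(rows), _pool(counts))


def lopo_cv(
    pc: PairwiseCorrelations,
    levels: tuple[float, ...] = (0.95, 0.99),
) -> CVReport:
    """Leave-one-plantation-out CV: one fold per source group, deterministic.

    Needs a pair partition carrying labels (built from a labelled set) and
    at least 3 groups.
    """
    if not pc.labels:
        raise PreconditionError("LOPO needs group labels on the pair partition")
    groups = sorted(set(pc.labels))
    if len(groups) < 3:
        raise PreconditionError(f"LOPO needs >= 3 groups, got {len(groups)}")
    intra_groups = np.array([pc.labels[i] for i, _, _ in pc.intra])
    intra = pc.intra_r
    inter = pc.inter_r
    counts = {level: [0, 0, 0, 0] for level in levels}
    rows = []
    for g in groups:
        test_mask = intra_groups == g
        train_intra = intra[~test_mask]
        test_intra = intra[test_mask]
        touch = np.array(
            [pc.labels[i] == g or pc.labels[j] == g for i, j, _ in pc.inter]
        )
        rows.append(_fold_row(g, train_intra, test_intra, inter[touch], levels, counts))
    return CVReport("lopo", pd.DataFrame(rows), _pool(counts))


def full_calibration(
    pc: PairwiseCorrelations, levels: tuple[float, ...] = (0.95, 0.99)
) -> dict[float, ErrorRates]:
    """Error rates with thresholds fitted on the entire dataset — the
    reference row the CV schemes are compared against."""
    from .decision import error_rates

    return {level: error_rates(pc, threshold(pc.intra_r, level)) for level in levels}
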