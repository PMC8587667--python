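"""Linkage thresholds, FN/FP error rates, ROC/AUC, and the pretreatment sweep.

A "linked" decision threshold comes from the intra-source correlation
distribution, assumed Gaussian: value = r̄ − z·s_r with z = 1.96 (95% CL)
or 2.576 (99% CL), where r̄ and s_r are the mean and (n−1) standard
deviation of the pooled intra-source r-values. By construction the
expected false-negative rate is ≈ 5% / 1%; the false-positive rate — the
fraction of unlinked pairs at or above the threshold — measures how well
sources are discriminated and is the quantity a forensic workflow tries to
minimize. A pair exactly at the threshold counts as linked (conservative
toward FP).

ROC curves sweep the threshold over all observed r-values; the trapezoidal
AUC equals the rank statistic P(r_intra > r_inter) + ½·P(equal). Its 95%
confidence interval is a stratified bootstrap (intra and inter resampled
separately), seeded for reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dataio import FingerprintSet
from .errors import ParameterError, PreconditionError
from .pretreat import METHODS, PretreatSpec, apply
from .similarity import PairwiseCorrelations, correlation_structure

__all__ = [
    "Z_VALUES",
    "LinkageThreshold",
    "ErrorRates",
    "ROCCurve",
    "threshold",
    "error_rates",
    "rank_auc",
    "roc",
    "evaluate_pretreatments",
]

#: standard-normal quantiles for the two confidence levels used
Z_VALUES = {0.95: 1.96, 0.99: 2.576}


@dataclass(frozen=True)
class LinkageThreshold:
    """r̄ − z·s_r confidence-limit threshold on the intra-source r distribution."""

    level: float
    z: float
    r_bar: float
    s_r: float
    value: float


@dataclass(frozen=True)
class ErrorRates:
    """Percent of linked pairs below the threshold (FN) and of unlinked
    pairs at/above it (FP)."""

    fn_pct: float
    fp_pct: float


@dataclass
class ROCCurve:
    """Sensitivity vs false-positive-rate points, AUC, and bootstrap CI."""

    points: np.ndarray  # shape (k, 2): (fp_rate, sensitivity), sorted
    auc: float
    ci: tuple[float, float] | None = None


def threshold(intra_r: np.ndarray, level: float = 0.95) -> LinkageThreshold:
    """Confidence-limit linkage threshold from pooled intra-source r-values."""
    if level not in Z_VALUES:
        raise ParameterError(f"level must be one of {sorted(Z_VALUES)}, got {level}")
    intra_r = np.asarray(intra_r, dtype=float)
    if len(intra_r) < 3:
        raise PreconditionError(f"need at least 3 intra r-values, got {len(intra_r)}")
    z = Z_VALUES[level]
    r_bar = float(intra_r.mean())
    s_r = float(intra_r.std(ddof=1))
    return LinkageThreshold(level, z, r_bar, s_r, r_bar - z * s_r)


def error_rates(pc: PairwiseCorrelations, thr: LinkageThreshold) -> ErrorRates:
    """FN% over intra pairs and FP% over inter pairs at the given threshold."""
    intra, inter = pc.intra_r, pc.inter_r
    if len(intra) == 0 or len(inter) == 0:
        raise PreconditionError("both intra and inter partitions must be non-empty")
    fn = 100.0 * float(np.mean(intra < thr.value))
    fp = 100.0 * float(np.mean(inter >= thr.value))
    return ErrorRates(fn, fp)


def rank_auc(intra_r: np.ndarray, inter_r: np.ndarray) -> float:
    """AUC as the rank statistic P(r_intra > r_inter) + ½ P(equal),
    computed via midranks in O(n log n)."""
    intra_r = np.asarray(intra_r, dtype=float)
    inter_r = np.asarray(inter_r, dtype=float)
    n1, n0 = len(intra_r), len(inter_r)
    ranks = rankdata(np.concatenate([intra_r, inter_r]))
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc(
    pc: PairwiseCorrelations,
    n_boot: int = 2000,
    seed: int = 0,
) -> ROCCurve:
    """ROC curve over all observed r-values, trapezoidal AUC, bootstrap CI.

    ``n_boot = 0`` skips the CI. The stratified bootstrap resamples intra
    and inter r-values independently with replacement and recomputes the
    (rank-statistic) AUC; the CI is the 2.5/97.5 percentile interval.
    """
    intra, inter = pc.intra_r, pc.inter_r
    if len(intra) == 0 or len(inter) == 0:
        raise PreconditionError("both intra and inter partitions must be non-empty")
    scores = np.concatenate([intra, inter])
    y = np.concatenate([np.ones(len(intra)), np.zeros(len(inter))])
    fpr, tpr, _ = _sk_roc_curve(y, scores)
    auc_value = float(_trapezoid_auc(fpr, tpr))
    points = np.column_stack([fpr, tpr])
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bi = intra[rng.integers(0, len(intra), len(intra))]
            bj = inter[rng.integers(0, len(inter), len(inter))]
            boots[b] = rank_auc(bi, bj)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        ci = (float(lo), float(hi))
    return ROCCurve(points, auc_value, ci)


def evaluate_pretreatments(
    fpset: FingerprintSet,
    methods: list[PretreatSpec] | None = None,
    levels: tuple[float, ...] = (0.95, 0.99),
    n_boot: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the full comparison sweep over pretreatments on an aligned set.

    For each method: pretreat → pairwise correlations → thresholds at each
    confidence level → FN%/FP% → AUC. Returns one row per method with
    columns ``thr_<level>``, ``fn_<level>``, ``fp_<level>``, ``auc`` (and CI
    bounds when ``n_boot > 0``), plus ``rank_fp95`` ranking methods by FP%
    at the 95% level, ascending (rank 1 = most discriminating).
    """
    if methods is None:
        methods = [PretreatSpec(m) for m in METHODS]
    rows = []
    index = []
    for spec in methods:
        try:
            treated = apply(spec, fpset)
            pc = correlation_structure(treated)
            row: dict[str, float] = {}
            for level in levels:
                thr = threshold(pc.intra_r, level)
                er = error_rates(pc, thr)
                tag = f"{level:.2f}".split(".")[1]
                row[f"thr_{tag}"] = thr.value
                row[f"fn_{tag}"] = er.fn_pct
                row[f"fp_{tag}"] = er.fp_pct
            curve = roc(pc, n_boot=n_boot, seed=seed)
            row["auc"] = curve.auc
            if curve.ci is not None:
                row["auc_ci_low"], row["auc_ci_high"] = curve.ci
        except Exception as exc:
            raise RuntimeError(f"pretreatment {spec.method!r} failed: {exc}") from exc
        rows.append(row)
        index.append(spec.method)
    table = pd.DataFrame(rows, index=pd.Index(index, name="method"))
    if "fp_95" in table.columns:
        table["rank_fp95"] = table["fp_95"].rank(method="min").astype(int)
    return table
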