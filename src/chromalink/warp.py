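"""Correlation-Optimized Warping (COW) and warping-parameter optimization.

COW corrects run-to-run retention-time drift by piecewise-linearly
stretching/compressing a sample trace onto a reference (target) trace.
Both traces are cut into segments of nominal length SL (segment length,
data points); each sample-segment end point may move by at most ±SS (slack
size) relative to the nominal position. Dynamic programming chooses the
node placement maximizing the summed Pearson correlation between each
linearly-interpolated warped sample segment and the corresponding target
segment — a global optimum over all admissible node placements.

Two strategies pick (SL, SS) for a whole dataset:

* :func:`acow_optimize` — automated search: coarse grid over the SL/SS
  ranges followed by a discrete-coordinate descent, objective = mean
  correlation of the warped samples to the reference;
* :func:`doe_optimize` — a 3² full-factorial design over (SL, SS) with a
  quadratic response model, response = mean intra-group correlation after
  alignment; the best of the nine runs supplies the parameters.

Everything here is deterministic; ties break toward the lowest index /
first-evaluated candidate.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .dataio import FingerprintSet
from .errors import ParameterError, PreconditionError

__all__ = [
    "WarpingParams",
    "WarpResult",
    "DoEResult",
    "DOE_DESIGNS",
    "select_reference",
    "cow_pair",
    "cow_set",
    "alignment_objective",
    "acow_optimize",
    "doe_optimize",
    "fit_quadratic_response",
    "doe_levels",
]

_EPS = 1e-12

#: the two preset (SL, SS) search ranges the pipeline exposes
DOE_DESIGNS: dict[int, tuple[tuple[int, int], tuple[int, int]]] = {
    1: ((15, 100), (1, 10)),
    2: ((25, 200), (1, 10)),
}


@dataclass(frozen=True)
class WarpingParams:
    """A segment-length / slack-size pair (both in data points)."""

    sl: int
    ss: int

    def __post_init__(self) -> None:
        if self.sl < 3:
            raise ParameterError(f"segment length SL must be >= 3, got {self.sl}")
        if not 1 <= self.ss < self.sl:
            raise ParameterError(
                f"slack SS must satisfy 1 <= SS < SL, got SS={self.ss}, SL={self.sl}"
            )


@dataclass
class WarpResult:
    """A warped dataset plus per-sample alignment quality."""

    aligned: FingerprintSet
    reference_index: int
    params: WarpingParams
    per_sample_r: np.ndarray
    rounds: int


@dataclass
class DoEResult:
    """Outcome of a 3² full-factorial warping-parameter optimization."""

    design_points: list[WarpingParams]  # 9 points, row-major over (SL, SS) levels
    coded_points: np.ndarray            # shape (9, 2), levels in {-1, 0, 1}
    responses: np.ndarray               # mean intra-group r per design point
    coefficients: np.ndarray            # (β0, β1, β2, β11, β22, β12)
    best_params: WarpingParams


# ---------------------------------------------------------------------------
# pairwise COW dynamic program
# ---------------------------------------------------------------------------

def _segment_nodes(length: int, sl: int) -> np.ndarray:
    """Target node indices: N = floor(length/SL) segments, the last absorbing
    the remainder; nodes at 0, SL, 2·SL, …, (N−1)·SL, length−1."""
    n_seg = length // sl
    if n_seg < 2:
        raise PreconditionError(
            f"sequence of {length} points is too short for SL={sl} (need >= 2*SL)"
        )
    return np.append(np.arange(n_seg) * sl, length - 1)


def cow_pair(
    sample: np.ndarray, target: np.ndarray, params: WarpingParams
) -> tuple[np.ndarray, float]:
    """Warp ``sample`` onto ``target``; return (warped trace, benefit).

    The warped trace has the target's length; its end points coincide with
    the sample's. Benefit is the sum over segments of the Pearson
    correlation between the interpolated sample segment and the target
    segment (a zero-variance segment contributes r = 0). The dynamic
    program is exact: the returned node placement maximizes the benefit
    over all placements with per-segment length changes in [−SS, +SS].
    """
    sample = np.asarray(sample, dtype=float)
    target = np.asarray(target, dtype=float)
    sl, ss = params.sl, params.ss
    if len(sample) < 2 * sl or len(target) < 2 * sl:
        raise PreconditionError(
            f"both traces need >= 2*SL = {2 * sl} points "
            f"(got {len(sample)} and {len(target)})"
        )
    nodes_t = _segment_nodes(len(target), sl)
    n_seg = len(nodes_t) - 1
    d = np.diff(nodes_t)                      # target segment step counts
    ls = len(sample)

    lo_inc = np.maximum(d - ss, 1)
    hi_inc = d + ss
    # feasible sample-node ranges from both ends (end points are fixed)
    lo = np.empty(n_seg + 1, dtype=int)
    hi = np.empty(n_seg + 1, dtype=int)
    cum_lo = np.concatenate([[0], np.cumsum(lo_inc)])
    cum_hi = np.concatenate([[0], np.cumsum(hi_inc)])
    tail_lo = cum_lo[-1] - cum_lo
    tail_hi = cum_hi[-1] - cum_hi
    for i in range(n_seg + 1):
        lo[i] = max(cum_lo[i], (ls - 1) - tail_hi[i])
        hi[i] = min(cum_hi[i], (ls - 1) - tail_lo[i])
    if np.any(lo > hi):
        raise PreconditionError(
            "no admissible warping: length difference exceeds total slack"
        )

    best_prev = np.zeros(1)                   # scores over positions lo[0]..hi[0]
    parents: list[np.ndarray] = []
    for i in range(n_seg):
        m = d[i] + 1                          # points in the target segment
        tseg = target[nodes_t[i] : nodes_t[i + 1] + 1]
        tc = tseg - tseg.mean()
        tnorm = math.sqrt(float(tc @ tc))
        n_end = hi[i + 1] - lo[i + 1] + 1
        best_new = np.full(n_end, -np.inf)
        parent_inc = np.zeros(n_end, dtype=int)
        for inc in range(lo_inc[i], hi_inc[i] + 1):
            x0 = max(lo[i], lo[i + 1] - inc)
            x1 = min(hi[i], hi[i + 1] - inc)
            if x0 > x1:
                continue
            xs = np.arange(x0, x1 + 1)
            pos = xs[:, None] + np.linspace(0.0, inc, m)[None, :]
            base = np.minimum(pos.astype(int), ls - 2)
            frac = pos - base
            seg = sample[base] * (1.0 - frac) + sample[base + 1] * frac
            if tnorm <= _EPS:
                r = np.zeros(len(xs))
            else:
                sc = seg - seg.mean(axis=1, keepdims=True)
                sn = np.sqrt((sc * sc).sum(axis=1))
                with np.errstate(invalid="ignore", divide="ignore"):
                    r = (sc @ tc) / (sn * tnorm)
                r[sn <= _EPS] = 0.0
            cand = best_prev[xs - lo[i]] + r
            sl_end = xs + inc - lo[i + 1]
            better = cand > best_new[sl_end]
            best_new[sl_end[better]] = cand[better]
            parent_inc[sl_end[better]] = inc
        best_prev = best_new
        parents.append(parent_inc)

    benefit = float(best_prev[-1])            # single position: ls-1
    # backtrack node placement
    xs_nodes = np.empty(n_seg + 1, dtype=int)
    xs_nodes[-1] = ls - 1
    for i in range(n_seg - 1, -1, -1):
        inc = parents[i][xs_nodes[i + 1] - lo[i + 1]]
        xs_nodes[i] = xs_nodes[i + 1] - inc
    # reconstruct warped trace
    warped = np.empty(len(target))
    for i in range(n_seg):
        m = d[i] + 1
        inc = xs_nodes[i + 1] - xs_nodes[i]
        pos = xs_nodes[i] + np.linspace(0.0, inc, m)
        base = np.minimum(pos.astype(int), ls - 2)
        frac = pos - base
        warped[nodes_t[i] : nodes_t[i + 1] + 1] = (
            sample[base] * (1.0 - frac) + sample[base + 1] * frac
        )
    return warped, benefit


# ---------------------------------------------------------------------------
# dataset-level alignment
# ---------------------------------------------------------------------------

def select_reference(fpset: FingerprintSet) -> int:
    """Index of the sample with the highest mean correlation to all others
    (ties → lowest index) — the automatically chosen warping target."""
    if len(fpset) < 2:
        raise PreconditionError("reference selection needs at least 2 samples")
    matrix = fpset.matrix()
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(matrix)
    c = np.nan_to_num(c, nan=-np.inf)
    np.fill_diagonal(c, 0.0)
    mean_r = c.sum(axis=1) / (len(fpset) - 1)
    return int(np.argmax(mean_r))


def _corr_to_reference(matrix: np.ndarray, ref: int) -> np.ndarray:
    t = matrix[ref] - matrix[ref].mean()
    tn = math.sqrt(float(t @ t))
    out = np.empty(matrix.shape[0])
    for j in range(matrix.shape[0]):
        s = matrix[j] - matrix[j].mean()
        sn = math.sqrt(float(s @ s))
        out[j] = float(s @ t) / (sn * tn) if sn > _EPS and tn > _EPS else 0.0
    out[ref] = 1.0
    return out


def cow_set(
    fpset: FingerprintSet,
    params: WarpingParams,
    rounds: int = 1,
    reference_index: int | None = None,
) -> WarpResult:
    """Warp every sample of a set to an automatically selected reference.

    With ``rounds > 1`` the output of each pass (with a freshly selected
    reference) is the input of the next — repeated alignment of the same
    data. The reference passes through unchanged each round.
    """
    if rounds < 1:
        raise ParameterError(f"rounds must be >= 1, got {rounds}")
    current = fpset
    ref = 0
    for _ in range(rounds):
        ref = select_reference(current) if reference_index is None else reference_index
        matrix = current.matrix()
        target = matrix[ref]
        warped = np.empty_like(matrix)
        for j in range(matrix.shape[0]):
            if j == ref:
                warped[j] = target
            else:
                warped[j], _ = cow_pair(matrix[j], target, params)
        current = current.with_matrix(warped)
    per_sample_r = _corr_to_reference(current.matrix(), ref)
    return WarpResult(current, ref, params, per_sample_r, rounds)


# ---------------------------------------------------------------------------
# parameter optimization: automated search (ACOW)
# ---------------------------------------------------------------------------

def alignment_objective(fpset: FingerprintSet, params: WarpingParams) -> float:
    """Mean correlation of all samples to the reference after one alignment
    pass — the quantity the automated search maximizes."""
    return float(cow_set(fpset, params, rounds=1).per_sample_r.mean())


def _int_levels(lo: int, hi: int, n: int) -> list[int]:
    return sorted(set(int(math.floor(v + 0.5)) for v in np.linspace(lo, hi, n)))


def acow_optimize(
    fpset: FingerprintSet,
    sl_range: tuple[int, int] = (15, 100),
    ss_range: tuple[int, int] = (1, 10),
    grid_points: int | None = None,
) -> WarpingParams:
    """Automated (SL, SS) selection over the given integer ranges.

    A coarse lattice is evaluated first (by default up to 11 levels per
    factor — exhaustive on ranges that narrow, since the objective is
    rugged in SL: segment boundaries interact with peak positions); a
    discrete-coordinate descent (±1 neighbour moves, the discrete analogue
    of a simplex walk) then refines the best lattice point. Deterministic:
    ties keep the first-evaluated candidate, so a plateau (e.g. a
    zero-shift set where every parameter pair scores 1) returns the first
    optimum found.
    """
    sl_lo, sl_hi = sl_range
    ss_lo, ss_hi = ss_range
    if sl_lo > sl_hi or ss_lo > ss_hi or sl_lo < 3 or ss_lo < 1:
        raise ParameterError(f"invalid search ranges SL={sl_range}, SS={ss_range}")
    if grid_points is not None and grid_points < 3:
        raise ParameterError("coarse grid needs at least 3 levels per factor")

    def n_levels(lo: int, hi: int) -> int:
        span = hi - lo + 1
        return min(span, grid_points if grid_points is not None else 11)

    cache: dict[tuple[int, int], float] = {}

    def evaluate(sl: int, ss: int) -> float:
        key = (sl, ss)
        if key not in cache:
            cache[key] = alignment_objective(fpset, WarpingParams(sl, ss))
        return cache[key]

    candidates = [
        (sl, ss)
        for sl in _int_levels(sl_lo, sl_hi, n_levels(sl_lo, sl_hi))
        for ss in _int_levels(ss_lo, ss_hi, n_levels(ss_lo, ss_hi))
        if ss < sl
    ]
    if not candidates:
        raise ParameterError("no admissible (SL, SS) pair in the given ranges")
    best = candidates[0]
    best_obj = evaluate(*best)
    for cand in candidates[1:]:
        obj = evaluate(*cand)
        if obj > best_obj:
            best, best_obj = cand, obj

    improved = True
    while improved:
        improved = False
        sl, ss = best
        for nsl, nss in ((sl - 1, ss), (sl + 1, ss), (sl, ss - 1), (sl, ss + 1)):
            if not (sl_lo <= nsl <= sl_hi and ss_lo <= nss <= ss_hi and nss < nsl):
                continue
            obj = evaluate(nsl, nss)
            if obj > best_obj:
                best, best_obj = (nsl, nss), obj
                improved = True
    return WarpingParams(*best)


# ---------------------------------------------------------------------------
# parameter optimization: 3² full-factorial design
# ---------------------------------------------------------------------------

def doe_levels(sl_range: tuple[int, int], ss_range: tuple[int, int]) -> tuple[list[int], list[int]]:
    """Low/centre/high factor levels for the 3² design (centre = half-up
    rounded midpoint, e.g. 15–100 → 58 and 25–200 → 113)."""
    def three(lo: int, hi: int) -> list[int]:
        return [lo, int(math.floor((lo + hi) / 2 + 0.5)), hi]

    return three(*sl_range), three(*ss_range)


def fit_quadratic_response(coded: np.ndarray, responses: np.ndarray) -> np.ndarray:
    """Least-squares fit of y = β0 + β1x1 + β2x2 + β11x1² + β22x2² + β12x1x2
    on coded factor levels. Returns (β0, β1, β2, β11, β22, β12)."""
    coded = np.asarray(coded, dtype=float)
    responses = np.asarray(responses, dtype=float)
    x1, x2 = coded[:, 0], coded[:, 1]
    design = np.column_stack([np.ones_like(x1), x1, x2, x1**2, x2**2, x1 * x2])
    beta, *_ = np.linalg.lstsq(design, responses, rcond=None)
    return beta


def doe_optimize(
    fpset: FingerprintSet,
    design: int = 1,
    rounds: int = 1,
    sl_range: tuple[int, int] | None = None,
    ss_range: tuple[int, int] | None = None,
) -> DoEResult:
    """3² full-factorial optimization of (SL, SS).

    Runs :func:`cow_set` at each of the nine level combinations of the
    chosen design (1: SL 15/58/100, 2: SL 25/113/200; SS 1/6/10 for both);
    the response is the mean of all intra-group correlations after
    alignment. The quadratic response-surface model is fitted for
    reporting; the returned ``best_params`` is the design point with the
    highest response (ties → lowest index).
    """
    from .similarity import correlation_structure  # local import: avoids a cycle

    if any(lbl in (None, "None") for lbl in fpset.labels):
        raise PreconditionError("DoE response needs group labels on every sample")
    if sl_range is None or ss_range is None:
        if design not in DOE_DESIGNS:
            raise ParameterError(f"design must be 1 or 2, got {design}")
        sl_range, ss_range = DOE_DESIGNS[design]
    sl_levels, ss_levels = doe_levels(sl_range, ss_range)

    points: list[WarpingParams] = []
    coded_rows: list[tuple[int, int]] = []
    responses: list[float] = []
    for (ci, slv), (cj, ssv) in itertools.product(
        zip((-1, 0, 1), sl_levels), zip((-1, 0, 1), ss_levels)
    ):
        params = WarpingParams(slv, ssv)
        aligned = cow_set(fpset, params, rounds=rounds).aligned
        responses.append(float(correlation_structure(aligned).intra_r.mean()))
        points.append(params)
        coded_rows.append((ci, cj))
    coded = np.array(coded_rows, dtype=float)
    resp = np.array(responses)
    beta = fit_quadratic_response(coded, resp)
    best = int(np.argmax(resp))
    return DoEResult(points, coded, resp, beta, points[best])
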