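"""Data pretreatments applied to the aligned fingerprint matrix.

Six methods, named as chemometric practice names them:

====================  ======================================================
``cc``                column centring — subtract each column (time-point)
                      mean across samples
``norm_cc``           row scaling (divide each trace by its own standard
                      deviation) followed by column centring
``snv_cc``            standard normal variate (row centre + row scale)
                      followed by column centring
``sqrt``              elementwise square root of the (non-negative) trace
``fourth_root``       elementwise fourth root — compresses a dominant peak
                      10⁴× taller than its neighbours down to 10×
``autoscale``         column centring followed by division by the column
                      standard deviation (zero-variance columns stay 0)
====================  ======================================================

plus region excision (removing the dominant-peak window from every trace)
and ``apply`` which runs excision first, then the named method. Standard
deviations use the n−1 (sample) denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import FingerprintSet
from .errors import DegenerateDataError, ParameterError, PreconditionError

__all__ = [
    "PretreatSpec",
    "METHODS",
    "column_center",
    "row_scale",
    "snv",
    "root_transform",
    "autoscale",
    "excise_region",
    "locate_dominant_window",
    "apply",
]

METHODS = ("none", "cc", "norm_cc", "snv_cc", "sqrt", "fourth_root", "autoscale")


@dataclass(frozen=True)
class PretreatSpec:
    """A named pretreatment, optionally preceded by excision of a half-open
    column window (e.g. the THC peak region)."""

    method: str = "none"
    excise_window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ParameterError(
                f"unknown pretreatment {self.method!r}; choose from {METHODS}"
            )
        if self.excise_window is not None:
            start, stop = self.excise_window
            if start < 0 or stop < start:
                raise ParameterError(
                    f"excise_window must be a valid half-open interval, got {self.excise_window}"
                )


def _require_multiple_samples(fpset: FingerprintSet, op: str) -> None:
    if len(fpset) < 2:
        raise PreconditionError(f"{op} needs at least 2 samples")


def column_center(fpset: FingerprintSet) -> FingerprintSet:
    """Subtract each column's mean: output column means are 0. Idempotent."""
    _require_multiple_samples(fpset, "column centring")
    m = fpset.matrix()
    return fpset.with_matrix(m - m.mean(axis=0, keepdims=True))


def row_scale(fpset: FingerprintSet) -> FingerprintSet:
    """Divide each trace by its own standard deviation (output row sd = 1)."""
    m = fpset.matrix()
    sd = m.std(axis=1, ddof=1)
    flat = np.flatnonzero(sd <= 0)
    if flat.size:
        raise DegenerateDataError(
            f"zero-variance trace(s): {[fpset.sample_ids[i] for i in flat]}"
        )
    return fpset.with_matrix(m / sd[:, None])


def snv(fpset: FingerprintSet) -> FingerprintSet:
    """Standard normal variate: per-trace centre and scale (row mean 0, sd 1)."""
    m = fpset.matrix()
    sd = m.std(axis=1, ddof=1)
    flat = np.flatnonzero(sd <= 0)
    if flat.size:
        raise DegenerateDataError(
            f"zero-variance trace(s): {[fpset.sample_ids[i] for i in flat]}"
        )
    return fpset.with_matrix((m - m.mean(axis=1, keepdims=True)) / sd[:, None])


def root_transform(fpset: FingerprintSet, power: int = 4) -> FingerprintSet:
    """Elementwise ``max(x, 0) ** (1/power)``, power 2 or 4.

    Negative values (possible after upstream arithmetic) are clipped to 0
    before rooting; detector intensities are physically non-negative.
    """
    if power not in (2, 4):
        raise ParameterError(f"power must be 2 or 4, got {power}")
    m = np.clip(fpset.matrix(), 0.0, None)
    return fpset.with_matrix(m ** (1.0 / power))


def autoscale(fpset: FingerprintSet) -> FingerprintSet:
    """Column centre, then divide by column sd; constant columns become 0."""
    _require_multiple_samples(fpset, "auto-scaling")
    m = fpset.matrix()
    centred = m - m.mean(axis=0, keepdims=True)
    sd = m.std(axis=0, ddof=1)
    safe = np.where(sd > 0, sd, 1.0)
    return fpset.with_matrix(centred / safe)


def excise_region(fpset: FingerprintSet, window: tuple[int, int]) -> FingerprintSet:
    """Remove columns in the half-open ``[start, stop)`` window from every
    trace (and from the time axis); column order is preserved."""
    start, stop = window
    if not (0 <= start <= stop <= fpset.n_points):
        raise ParameterError(
            f"excise window {window} out of bounds for {fpset.n_points} points"
        )
    if start == stop:
        return fpset.with_matrix(fpset.matrix())
    keep = np.r_[0:start, stop : fpset.n_points]
    return fpset.with_matrix(fpset.matrix()[:, keep], time=fpset.time[keep])


def locate_dominant_window(fpset: FingerprintSet, half_width: int) -> tuple[int, int]:
    """Helper: window of ``2·half_width + 1`` columns centred on the tallest
    mean-intensity column (clipped to bounds). The dominant-peak window is
    normally supplied explicitly; this is a convenience, never a default."""
    centre = int(np.argmax(fpset.matrix().mean(axis=0)))
    return max(0, centre - half_width), min(fpset.n_points, centre + half_width + 1)


def apply(spec: PretreatSpec, fpset: FingerprintSet) -> FingerprintSet:
    """Apply a pretreatment spec: excision first, then the named chain.

    ``norm_cc`` = row scaling then column centring; ``snv_cc`` = SNV then
    column centring; the rest are single steps; ``none`` is the identity.
    """
    out = fpset
    if spec.excise_window is not None:
        out = excise_region(out, spec.excise_window)
    if spec.method == "none":
        return out
    if spec.method == "cc":
        return column_center(out)
    if spec.method == "norm_cc":
        return column_center(row_scale(out))
    if spec.method == "snv_cc":
        return column_center(snv(out))
    if spec.method == "sqrt":
        return root_transform(out, power=2)
    if spec.method == "fourth_root":
        return root_transform(out, power=4)
    if spec.method == "autoscale":
        return autoscale(out)
    raise ParameterError(f"unknown pretreatment {spec.method!r}")  # pragma: no cover
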