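"""Synthetic chromatographic fingerprints with controlled group structure.

The generator emulates a seizure-comparison study: a set of cultivation
sites (groups), several plants (samples) per site, and one long GC trace per
plant. A chromatogram is modelled as a sum of Gaussian peaks on a constant
baseline with i.i.d. detector noise, clipped at zero:

* peak *positions* (retention) are shared by all groups — compounds elute
  where they elute;
* peak *heights* carry the compositional signal: a shared master pattern,
  perturbed per group (between-source variability, ``inter_sd``) and again
  per sample (within-source variability, ``intra_sd``);
* one designated dominant peak (THC-like) sits at a common position in every
  group with height ``dominant_peak_ratio`` × the median of the other peak
  heights — the masking regime in which every pair of samples correlates
  highly regardless of source until a root transform tames the peak;
* each sample gets a single global retention shift drawn with scale
  ``shift_sd`` (run-to-run drift), applied by linear-interpolation
  resampling of the whole trace.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawn keys, so identical config ⇒ bit-identical dataset, and any one sample
can be regenerated independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .dataio import Fingerprint, FingerprintSet
from .errors import ParameterError

__all__ = ["SynthConfig", "GroupTemplate", "make_group_templates", "generate_dataset", "plant_outliers"]

#: total run time of the emulated GC program, minutes
_RUN_MINUTES = 34.0
#: fractional position of the dominant (THC-like) peak on the trace
_DOMINANT_FRACTION = 0.65


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for one synthetic dataset.

    Defaults emulate the seizure study the pipeline targets: 10 cultivation
    sites × 10 plants, 5231-point traces, a dominant peak 40× the median
    height, and within/between-site variability chosen so the intra- and
    inter-source correlation distributions overlap partially.
    """

    n_groups: int = 10
    samples_per_group: int | tuple[int, ...] = 10
    n_points: int = 5231
    n_peaks: int = 30
    dominant_peak_ratio: float = 40.0
    intra_sd: float = 0.12
    inter_sd: float = 0.35
    shift_sd: float = 3.0
    peak_width_range: tuple[float, float] = (8.0, 30.0)
    baseline_level: float = 2.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 100:
            raise ParameterError(f"n_points must be >= 100, got {self.n_points}")
        if self.n_groups < 2:
            raise ParameterError(f"n_groups must be >= 2, got {self.n_groups}")
        sizes = self.group_sizes
        if len(sizes) != self.n_groups:
            raise ParameterError(
                f"samples_per_group has {len(sizes)} entries for {self.n_groups} groups"
            )
        if min(sizes) < 2:
            raise ParameterError("samples_per_group entries must all be >= 2")
        if self.n_peaks < 2:
            raise ParameterError(f"n_peaks must be >= 2, got {self.n_peaks}")
        for name in ("dominant_peak_ratio", "intra_sd", "inter_sd", "shift_sd", "baseline_level", "noise_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        lo, hi = self.peak_width_range
        if not (0 < lo <= hi):
            raise ParameterError(f"peak_width_range must satisfy 0 < min <= max, got {self.peak_width_range}")

    @property
    def group_sizes(self) -> tuple[int, ...]:
        if isinstance(self.samples_per_group, int):
            return (self.samples_per_group,) * self.n_groups
        return tuple(int(k) for k in self.samples_per_group)


@dataclass(frozen=True)
class GroupTemplate:
    """Peak parameters for one group: rows of (position, height, width) in
    data-point units, with one row marked dominant."""

    peaks: np.ndarray  # shape (n_peaks, 3)
    dominant_index: int

    @property
    def positions(self) -> np.ndarray:
        return self.peaks[:, 0]

    @property
    def heights(self) -> np.ndarray:
        return self.peaks[:, 1]

    @property
    def widths(self) -> np.ndarray:
        return self.peaks[:, 2]


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def make_group_templates(config: SynthConfig) -> list[GroupTemplate]:
    """Draw one master peak set and derive per-group templates.

    The master has ``n_peaks - 1`` minor peaks (log-normal heights, uniform
    positions and widths) plus the dominant peak at a fixed common position.
    Each group's minor heights are the master's perturbed multiplicatively by
    ``exp(inter_sd·z)``; the dominant height is re-pinned to
    ``dominant_peak_ratio`` × median(minor heights) so the ratio is exact per
    group. ``inter_sd = 0`` ⇒ identical templates.
    """
    rng = _rng(config.seed, 0)
    n_minor = config.n_peaks - 1
    lo_w, hi_w = config.peak_width_range
    margin = 0.04 * config.n_points
    positions = rng.uniform(margin, config.n_points - margin, size=n_minor)
    heights = rng.lognormal(mean=math.log(20.0), sigma=0.8, size=n_minor)
    widths = rng.uniform(lo_w, hi_w, size=n_minor)
    dom_pos = _DOMINANT_FRACTION * config.n_points
    dom_width = rng.uniform(lo_w, hi_w)

    templates = []
    for g in range(config.n_groups):
        grng = _rng(config.seed, 1, g)
        h = heights * np.exp(config.inter_sd * grng.standard_normal(n_minor))
        dom_height = config.dominant_peak_ratio * float(np.median(h))
        peaks = np.column_stack(
            [
                np.append(positions, dom_pos),
                np.append(h, dom_height),
                np.append(widths, dom_width),
            ]
        )
        templates.append(GroupTemplate(peaks=peaks, dominant_index=config.n_peaks - 1))
    return templates


def _render(template_peaks: np.ndarray, heights: np.ndarray, n_points: int) -> np.ndarray:
    """Sum of Gaussians on the index grid (noise-free, baseline-free)."""
    grid = np.arange(n_points, dtype=float)
    pos = template_peaks[:, 0][:, None]
    wid = template_peaks[:, 2][:, None]
    return (heights[:, None] * np.exp(-0.5 * ((grid[None, :] - pos) / wid) ** 2)).sum(axis=0)


def generate_dataset(config: SynthConfig) -> FingerprintSet:
    """Generate the full labelled dataset described by ``config``.

    Per sample: group template heights jittered by ``exp(intra_sd·z)``, peaks
    rendered, a global retention shift of scale ``shift_sd`` applied by linear
    interpolation, baseline and Gaussian noise added, intensities clipped ≥ 0.
    """
    templates = make_group_templates(config)
    time = np.linspace(0.0, _RUN_MINUTES, config.n_points)
    grid = np.arange(config.n_points, dtype=float)
    width = len(str(config.n_groups))
    samples = []
    for g, (template, size) in enumerate(zip(templates, config.group_sizes)):
        label = f"site{g + 1:0{max(width, 2)}d}"
        for i in range(size):
            srng = _rng(config.seed, 2, g, i)
            h = template.heights * np.exp(config.intra_sd * srng.standard_normal(config.n_peaks))
            clean = _render(template.peaks, h, config.n_points)
            shift = srng.normal(0.0, config.shift_sd) if config.shift_sd > 0 else 0.0
            if shift != 0.0:
                clean = np.interp(grid - shift, grid, clean)
            noise = (
                srng.normal(0.0, config.noise_sd, config.n_points)
                if config.noise_sd > 0
                else np.zeros(config.n_points)
            )
            y = np.clip(clean + config.baseline_level + noise, 0.0, None)
            samples.append(
                Fingerprint(f"{label}-{i + 1:02d}", time, y, group=label)
            )
    return FingerprintSet(samples)


def plant_outliers(
    dataset: FingerprintSet,
    group: str,
    k: int,
    distortion: float = 0.8,
    seed: int = 0,
) -> FingerprintSet:
    """Return a copy with ``k`` samples of ``group`` compositionally distorted.

    Emulates deviant plants within one site (e.g. a different cultivar):
    each chosen trace is multiplied by a smooth log-normal gain field
    ``exp(distortion · s(t))`` where ``s`` is unit-variance Gaussian noise
    smoothed over a scale larger than a peak width — so different peaks get
    different gains and the sample's intra-group correlation drops.
    ``k = 0`` or ``distortion = 0`` leave the data unchanged.

    Raises
    ------
    LookupError
        Unknown group label.
    ParameterError
        ``k`` not smaller than the group size, or negative inputs.
    """
    groups = dataset.group_indices()
    if group not in groups:
        raise LookupError(f"unknown group label {group!r}; have {sorted(groups)}")
    members = groups[group]
    if not 0 <= k < len(members):
        raise ParameterError(f"k must satisfy 0 <= k < group size ({len(members)}), got {k}")
    if distortion < 0:
        raise ParameterError(f"distortion must be >= 0, got {distortion}")
    matrix = dataset.matrix().copy()
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(members, size=k, replace=False).tolist())
    sigma = max(5.0, dataset.n_points / 100.0)
    for idx in chosen:
        field = gaussian_filter1d(rng.standard_normal(dataset.n_points), sigma)
        sd = field.std()
        if sd > 0:
            field = (field - field.mean()) / sd
        matrix[idx] = matrix[idx] * np.exp(distortion * field)
    return dataset.with_matrix(matrix)
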