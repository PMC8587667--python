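"""Reading, writing and assembling chromatographic fingerprints.

A *fingerprint* is the full intensity-vs-time trace of one chromatographic
run, used untargeted (no peak table). On disk each sample is a two-column
delimited text file (time, intensity) — the form instrument software exports —
and a whole dataset is a single CSV with one row per sample: a ``sample_id``
column, a ``group`` column holding the source (plantation) label, and one
column per time-grid point.

All indexing is 0-based and every index window is half-open ``[start, stop)``.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, PreconditionError

__all__ = [
    "Fingerprint",
    "FingerprintSet",
    "read_chromatogram_text",
    "write_chromatogram_text",
    "assemble_set",
    "read_labels_csv",
    "write_labels_csv",
    "read_matrix_csv",
    "write_matrix_csv",
]

#: number format guaranteeing lossless float64 text round-trips
_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class Fingerprint:
    """One chromatographic trace.

    Parameters
    ----------
    sample_id : str
        Unique identifier, by default the file stem.
    time : ndarray
        Retention time in minutes, strictly increasing.
    intensity : ndarray
        Detector response (arbitrary units), same length as ``time``.
    group : str, optional
        Source label (e.g. plantation id); attached by :func:`assemble_set`.
    channel : str
        Detector tag, ``"fid"`` or ``"ms_tic"``.
    """

    sample_id: str
    time: np.ndarray
    intensity: np.ndarray
    group: str | None = None
    channel: str = "fid"

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if time.ndim != 1 or intensity.ndim != 1:
            raise FormatError(f"{self.sample_id}: time and intensity must be 1-D")
        if len(time) != len(intensity):
            raise FormatError(
                f"{self.sample_id}: time ({len(time)}) and intensity "
                f"({len(intensity)}) lengths differ"
            )
        if len(time) and not np.all(np.diff(time) > 0):
            raise FormatError(f"{self.sample_id}: time axis is not strictly increasing")
        if not np.all(np.isfinite(intensity)):
            raise FormatError(f"{self.sample_id}: non-finite intensity values")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "intensity", intensity)

    @property
    def n_points(self) -> int:
        return len(self.time)


@dataclass
class FingerprintSet:
    """An ordered collection of equal-length fingerprints with source labels."""

    samples: list[Fingerprint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.samples:
            raise PreconditionError("FingerprintSet requires at least one sample")
        lengths = {s.n_points for s in self.samples}
        if len(lengths) != 1:
            raise PreconditionError(
                f"all samples must share one length; got lengths {sorted(lengths)}"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PreconditionError(f"duplicate sample_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def n_points(self) -> int:
        return self.samples[0].n_points

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def labels(self) -> list[str | None]:
        return [s.group for s in self.samples]

    @property
    def time(self) -> np.ndarray:
        return self.samples[0].time

    def matrix(self) -> np.ndarray:
        """Samples × time-points intensity matrix (rows ordered as ``samples``)."""
        return np.vstack([s.intensity for s in self.samples])

    def group_indices(self) -> dict[str, list[int]]:
        """Map each group label to the row indices of its members."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            out.setdefault(str(s.group), []).append(i)
        return out

    def with_matrix(
        self, matrix: np.ndarray, time: np.ndarray | None = None
    ) -> "FingerprintSet":
        """Return a copy with intensities replaced by ``matrix`` rows.

        ``time`` overrides the time axis (required when the number of columns
        changed, e.g. after region excision).
        """
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape[0] != len(self.samples):
            raise PreconditionError(
                f"matrix has {matrix.shape[0]} rows for {len(self.samples)} samples"
            )
        if time is None:
            time = self.time
        return FingerprintSet(
            [
                Fingerprint(s.sample_id, time, matrix[i], s.group, s.channel)
                for i, s in enumerate(self.samples)
            ]
        )

    def subset(self, indices: Iterable[int]) -> "FingerprintSet":
        return FingerprintSet([self.samples[i] for i in indices])


def read_chromatogram_text(
    path: str | Path,
    delimiter: str | None = None,
    header: str = "auto",
    sample_id: str | None = None,
    channel: str = "fid",
) -> Fingerprint:
    """Parse a two-column (time, intensity) instrument text export.

    Parameters
    ----------
    delimiter
        Column separator; ``None`` auto-detects comma vs whitespace per line.
    header
        ``"auto"`` tolerates a single leading non-numeric header line;
        ``"none"`` rejects any non-numeric row.

    Raises
    ------
    FormatError
        On an empty file, a row with the wrong column count, a non-numeric
        value (the message cites the 1-based line number), or a
        non-monotone time axis.
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter) if delimiter else (
                line.split(",") if "," in line else line.split()
            )
            fields = [f.strip() for f in fields if f.strip() != ""]
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, found {len(fields)}"
                )
            try:
                t, v = float(fields[0]), float(fields[1])
            except ValueError:
                if header == "auto" and not times and lineno == 1:
                    continue  # single leading header line
                raise FormatError(
                    f"{path}:{lineno}: non-numeric row {fields!r}"
                ) from None
            times.append(t)
            values.append(v)
    if not times:
        raise FormatError(f"{path}: no data rows")
    return Fingerprint(
        sample_id=sample_id or path.stem,
        time=np.array(times),
        intensity=np.array(values),
        channel=channel,
    )


def write_chromatogram_text(fp: Fingerprint, path: str | Path, delimiter: str = "\t") -> None:
    """Write one fingerprint as two-column delimited text."""
    np.savetxt(
        path,
        np.column_stack([fp.time, fp.intensity]),
        fmt=_FLOAT_FMT,
        delimiter=delimiter,
    )


def assemble_set(
    fingerprints: Iterable[Fingerprint], labels: Mapping[str, str]
) -> FingerprintSet:
    """Attach group labels and build a :class:`FingerprintSet`.

    Samples are ordered by (group, sample_id) so downstream matrices are
    stable regardless of input order.

    Raises
    ------
    LookupError
        If a sample_id has no entry in ``labels``.
    PreconditionError
        If trace lengths differ or a sample_id repeats.
    """
    relabelled = []
    for fp in fingerprints:
        if fp.sample_id not in labels:
            raise LookupError(f"no group label for sample {fp.sample_id!r}")
        relabelled.append(
            Fingerprint(fp.sample_id, fp.time, fp.intensity, str(labels[fp.sample_id]), fp.channel)
        )
    relabelled.sort(key=lambda f: (f.group, f.sample_id))
    return FingerprintSet(relabelled)


def read_labels_csv(path: str | Path) -> dict[str, str]:
    """Read a (sample_id, group) label table."""
    df = pd.read_csv(path, dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return dict(zip(df["sample_id"], df["group"]))


def write_labels_csv(fpset: FingerprintSet, path: str | Path) -> None:
    pd.DataFrame(
        {"sample_id": fpset.sample_ids, "group": fpset.labels}
    ).to_csv(path, index=False)


def write_matrix_csv(fpset: FingerprintSet, path: str | Path) -> None:
    """Write the dataset as one CSV row per sample.

    Columns: ``sample_id``, ``group``, then the time grid (column names are
    the time values). Numeric precision is full float64 round-trip.
    """
    df = pd.DataFrame(fpset.matrix(), columns=[_FLOAT_FMT % t for t in fpset.time])
    df.insert(0, "group", fpset.labels)
    df.insert(0, "sample_id", fpset.sample_ids)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_matrix_csv(path: str | Path, channel: str = "fid") -> FingerprintSet:
    """Read a dataset CSV written by :func:`write_matrix_csv`."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except OSError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    if "group" not in df.columns:
        raise FormatError(f"{path}: missing required column 'group'")
    value_cols = [c for c in df.columns if c not in ("sample_id", "group")]
    if not value_cols:
        raise FormatError(f"{path}: no intensity columns")
    try:
        time = np.array([float(c) for c in value_cols])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric time column header: {exc}") from None
    samples = [
        Fingerprint(
            str(row["sample_id"]),
            time,
            row[value_cols].to_numpy(dtype=float),
            str(row["group"]),
            channel,
        )
        for _, row in df.iterrows()
    ]
    return FingerprintSet(samples)
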