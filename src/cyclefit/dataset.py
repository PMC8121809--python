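"""Containers and plain-text I/O for time-resolved difference spectroscopy data.

A flash-photolysis experiment records absorbance differences ``ΔE(channel, t)``
relative to the unphotolysed ground state: positive bands are photoproduct
absorption, negative bands are depleted educt (ground-state) absorption.
Channels are wavenumbers (cm⁻¹, FTIR) or wavelengths (nm, UV/VIS); delay times
are strictly positive seconds, with the exciting flash at ``t = 0``.

Datasets are stored as a tab-separated matrix: comment lines starting with
``#`` carry ``key=value`` metadata, the first data row holds the delay times,
the first column the channel positions, and cell *(i, j)* holds ΔE.  The axis
is kept in ascending order internally regardless of file order (spectra are
conventionally *plotted* descending in cm⁻¹, but one canonical storage order
keeps the invariants simple).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DatasetFormatError",
    "SpectralDataset",
    "Spectrum",
    "KineticTrace",
    "read_dataset",
    "write_dataset",
    "merge_segments",
    "extract_trace",
    "difference_spectrum_at",
]

MODALITIES = ("FTIR", "UVVIS")


class DatasetFormatError(ValueError):
    """Raised when a dataset file violates the TSV matrix dialect."""


def _as_float_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class SpectralDataset:
    """A ΔE(channel, time) matrix with its axes and acquisition metadata.

    Attributes
    ----------
    axis : channel positions, strictly ascending after construction.
    times : delay times in seconds, strictly increasing, all positive.
    values : ΔE matrix, shape ``(n_channels, n_times)``, dimensionless.
    modality : ``"FTIR"`` or ``"UVVIS"``.
    segment_label : free text, e.g. ``"step-scan"``, ``"rapid-scan"``, ``"merged"``.
    axis_unit : ``"cm-1"`` or ``"nm"``.
    """

    axis: np.ndarray
    times: np.ndarray
    values: np.ndarray
    modality: str = "FTIR"
    segment_label: str = "merged"
    axis_unit: str = "cm-1"

    def __post_init__(self) -> None:
        self.axis = _as_float_vector(self.axis, "axis")
        self.times = _as_float_vector(self.times, "times")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.axis.size, self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"(n_channels={self.axis.size}, n_times={self.times.size})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        d = np.diff(self.axis)
        if self.axis.size > 1 and np.all(d < 0):  # normalize to ascending
            self.axis = self.axis[::-1].copy()
            self.values = self.values[::-1].copy()
        elif self.axis.size > 1 and not np.all(d > 0):
            raise ValueError("axis must be strictly monotonic")
        if np.any(self.times <= 0):
            raise ValueError("all times must be strictly positive (flash at t = 0)")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {self.modality!r}")

    @property
    def n_channels(self) -> int:
        return self.axis.size

    @property
    def n_times(self) -> int:
        return self.times.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpectralDataset):
            return NotImplemented
        return (
            np.array_equal(self.axis, other.axis)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
            and self.modality == other.modality
            and self.segment_label == other.segment_label
            and self.axis_unit == other.axis_unit
        )


@dataclass
class Spectrum:
    """A single difference spectrum: ΔE per channel at one time window."""

    axis: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.axis = _as_float_vector(self.axis, "axis")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.axis.shape:
            raise ValueError("axis and values must have the same length")
        d = np.diff(self.axis)
        if self.axis.size > 1 and np.all(d < 0):
            self.axis = self.axis[::-1].copy()
            self.values = self.values[::-1].copy()
        elif self.axis.size > 1 and not np.all(d > 0):
            raise ValueError("axis must be strictly monotonic")


@dataclass
class KineticTrace:
    """Single-channel time course: ΔE averaged over a spectral window."""

    center: float
    bandwidth: float
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.bandwidth < 0:
            raise ValueError("bandwidth must be >= 0")
        self.times = _as_float_vector(self.times, "times")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.times.shape:
            raise ValueError("times and values must have the same length")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_dataset(path, fmt: str = "tsv") -> SpectralDataset:
    """Read a dataset from the TSV matrix dialect.

    Raises :class:`DatasetFormatError` naming the offending line for ragged
    rows, unparsable numbers, a non-monotonic axis or non-positive times.
    """
    if fmt != "tsv":
        raise ValueError(f"unsupported format {fmt!r} (only 'tsv')")
    meta: dict[str, str] = {}
    header: tuple[int, list[str]] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.lstrip().startswith("#"):
                body = line.lstrip()[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = (lineno, fields)
            else:
                rows.append((lineno, fields))
    if header is None or not rows:
        raise DatasetFormatError(f"{path}: no data rows found")

    def _floats(fields: list[str], lineno: int) -> list[float]:
        out = []
        for col, f in enumerate(fields):
            try:
                out.append(float(f))
            except ValueError:
                raise DatasetFormatError(
                    f"{path}: line {lineno}, column {col + 1}: cannot parse {f!r}"
                ) from None
        return out

    lineno, fields = header
    times = np.array(_floats(fields[1:], lineno))
    if times.size == 0:
        raise DatasetFormatError(f"{path}: line {lineno}: header has no time points")
    if np.any(times <= 0):
        bad = int(np.argmax(times <= 0))
        raise DatasetFormatError(
            f"{path}: line {lineno}: time column {bad + 1} is not positive"
        )
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise DatasetFormatError(f"{path}: line {lineno}: times not strictly increasing")

    axis = np.empty(len(rows))
    values = np.empty((len(rows), times.size))
    for i, (lineno, fields) in enumerate(rows):
        if len(fields) != times.size + 1:
            raise DatasetFormatError(
                f"{path}: line {lineno}: expected {times.size + 1} fields, got {len(fields)}"
            )
        nums = _floats(fields, lineno)
        axis[i] = nums[0]
        values[i] = nums[1:]
    d = np.diff(axis)
    if axis.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        bad = int(np.argmax(~(d > 0) if d[0] > 0 else ~(d < 0)))
        raise DatasetFormatError(
            f"{path}: axis not strictly monotonic near row {bad + 2} "
            f"(channel {axis[bad + 1]:g})"
        )
    if not np.all(np.isfinite(values)):
        raise DatasetFormatError(f"{path}: non-finite ΔE values")
    return SpectralDataset(
        axis=axis,
        times=times,
        values=values,
        modality=meta.get("modality", "FTIR"),
        segment_label=meta.get("segment", "merged"),
        axis_unit=meta.get("axis_unit", "cm-1"),
    )


def write_dataset(dataset: SpectralDataset, path) -> None:
    """Write a dataset in the TSV matrix dialect.

    Values are written with 17 significant digits so that a read/write
    roundtrip is lossless at double precision.
    """
    if dataset.n_channels == 0 or dataset.n_times == 0:
        raise ValueError("refusing to write a dataset with zero channels or times")
    fmt = "%.17g"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# modality={dataset.modality}\n")
        fh.write(f"# segment={dataset.segment_label}\n")
        fh.write(f"# axis_unit={dataset.axis_unit}\n")
        fh.write("channel\t" + "\t".join(fmt % t for t in dataset.times) + "\n")
        for x, row in zip(dataset.axis, dataset.values):
            fh.write(fmt % x + "\t" + "\t".join(fmt % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# segment merging and slicing
# ---------------------------------------------------------------------------

def _combine(axis, t_a, v_a, t_b, v_b, modality, axis_unit) -> SpectralDataset:
    # concatenate two segments; exactly duplicated times are averaged
    t = np.concatenate([t_a, t_b])
    v = np.concatenate([v_a, v_b], axis=1)
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[:, order]
    uniq, inverse = np.unique(t, return_inverse=True)
    acc = np.zeros((uniq.size, v.shape[0]))
    np.add.at(acc, inverse, v.T)
    counts = np.bincount(inverse, minlength=uniq.size)
    merged = (acc / counts[:, None]).T
    return SpectralDataset(
        axis=axis.copy(),
        times=uniq,
        values=merged,
        modality=modality,
        segment_label="merged",
        axis_unit=axis_unit,
    )


def merge_segments(
    early: SpectralDataset,
    late: SpectralDataset,
    overlap_policy: str = "scale_late",
) -> SpectralDataset:
    """Combine a fast (e.g. step-scan) and a slow (e.g. rapid-scan) segment.

    Both segments must share the channel axis.  Under ``"scale_late"`` the late
    segment is multiplied by the scalar ``s = Σxy / Σyy`` (x early, y late over
    the overlapping time window) minimizing the squared difference to the early
    segment before concatenation; the early segment is never modified.  Under
    ``"none"`` the segments are concatenated unchanged.  Exactly duplicated
    time points are averaged in either case.  When the two grids differ inside
    the overlap window, the late segment is interpolated (linearly in log time)
    onto the early grid points for the purpose of computing ``s`` only.
    """
    if early.axis.shape != late.axis.shape or not np.array_equal(early.axis, late.axis):
        raise ValueError("cannot merge: channel axes differ")
    if early.modality != late.modality:
        raise ValueError("cannot merge: modalities differ")
    if overlap_policy not in ("scale_late", "none"):
        raise ValueError(f"unknown overlap policy {overlap_policy!r}")

    late_values = late.values
    if overlap_policy == "scale_late":
        lo, hi = late.times[0], early.times[-1]
        mask = (early.times >= lo) & (early.times <= hi)
        if lo > hi or not np.any(mask):
            raise ValueError(
                "scale_late requested but the segments share no overlapping time window"
            )
        t_overlap = early.times[mask]
        x = early.values[:, mask]
        log_t = np.log(t_overlap)
        log_late = np.log(late.times)
        y = np.vstack([np.interp(log_t, log_late, row) for row in late.values])
        denom = float(np.sum(y * y))
        if denom == 0.0:
            raise ValueError("late segment is identically zero on the overlap window")
        scale = float(np.sum(x * y)) / denom
        late_values = scale * late.values

    return _combine(
        early.axis, early.times, early.values, late.times, late_values,
        early.modality, early.axis_unit,
    )


def _window_mask(grid: np.ndarray, lo: float, hi: float) -> np.ndarray:
    eps = 1e-9 * max(1.0, abs(lo), abs(hi))
    return (grid >= lo - eps) & (grid <= hi + eps)


def extract_trace(dataset: SpectralDataset, center: float, bandwidth: float = 0.0) -> KineticTrace:
    """Time course of ΔE averaged over channels within ``center ± bandwidth/2``."""
    if bandwidth < 0:
        raise ValueError("bandwidth must be >= 0")
    mask = _window_mask(dataset.axis, center - bandwidth / 2, center + bandwidth / 2)
    if not np.any(mask):
        raise ValueError(
            f"no channel within {center:g} ± {bandwidth / 2:g} {dataset.axis_unit}"
        )
    return KineticTrace(
        center=center,
        bandwidth=bandwidth,
        times=dataset.times.copy(),
        values=dataset.values[mask].mean(axis=0),
    )


def difference_spectrum_at(dataset: SpectralDataset, t_lo: float, t_hi: float) -> Spectrum:
    """Per-channel mean ΔE over the closed time window ``[t_lo, t_hi]``."""
    if t_lo > t_hi:
        raise ValueError("t_lo must not exceed t_hi")
    mask = _window_mask(dataset.times, t_lo, t_hi)
    if not np.any(mask):
        raise ValueError(f"no time point within [{t_lo:g}, {t_hi:g}] s")
    return Spectrum(
        axis=dataset.axis.copy(),
        values=dataset.values[:, mask].mean(axis=1),
        label=f"mean over [{t_lo:g}, {t_hi:g}] s",
    )
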