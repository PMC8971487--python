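"""Shared in-memory containers for optical-mapping analysis.

A fluorescence movie is a 3-D stack indexed ``(frame, row, col)``; every
analysis result is either a per-pixel scalar image (:class:`ScalarMap`), a
velocity vector field (:class:`VectorMap`), a spectrum, or a table of
detected beats.  Out-of-mask or unmeasurable pixels carry ``NaN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Polarity of the optical signal.  ANEPPS-family voltage dyes at long
#: emission wavelengths report depolarisation as a *decrease* in
#: fluorescence, hence ``inverted_voltage``; calcium indicators and
#: already-corrected signals are ``upright`` (depolarisation positive).
POLARITIES = ("inverted_voltage", "upright")

MAP_KINDS = ("activation_ms", "apd_ms", "dapd_ms", "ows", "df_hz")


@dataclass
class FluorescenceMovie:
    """A 3-D fluorescence intensity stack with acquisition metadata.

    Parameters
    ----------
    data:
        Array of shape ``(frames, rows, cols)``, arbitrary fluorescence units.
    frame_rate:
        Sampling rate in Hz (samples per second).
    pixel_size:
        Pixel edge length in micrometres.
    polarity:
        ``"inverted_voltage"`` if depolarisation is a fluorescence decrease,
        ``"upright"`` otherwise.
    label:
        Free-text provenance (species, intervention, file of origin).
    """

    data: np.ndarray
    frame_rate: float
    pixel_size: float
    polarity: str = "upright"
    label: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"movie data must be 3-D, got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {self.data.shape}")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def times_ms(self) -> np.ndarray:
        """Frame times in milliseconds from the start of the recording."""
        return np.arange(self.n_frames) * (1000.0 / self.frame_rate)

    def with_data(self, data: np.ndarray, **meta) -> "FluorescenceMovie":
        """Return a copy holding ``data`` and optionally updated metadata."""
        return replace(self, data=data, **meta)


@dataclass
class TissueMask:
    """Boolean image marking analysable pixels (True = tissue)."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.flags.any():
            raise ValueError("mask must contain at least one true pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.flags.sum())


def as_mask(mask, frame_shape: tuple[int, int]) -> np.ndarray:
    """Normalise ``mask`` (TissueMask, ndarray or None) to a boolean image."""
    if mask is None:
        return np.ones(frame_shape, dtype=bool)
    flags = mask.flags if isinstance(mask, TissueMask) else np.asarray(mask, dtype=bool)
    if flags.shape != tuple(frame_shape):
        raise ValueError(
            f"mask shape {flags.shape} does not match frame shape {frame_shape}"
        )
    return flags


@dataclass
class ScalarMap:
    """Per-pixel scalar result image; undefined pixels are NaN.

    ``kind`` identifies the measurement (``activation_ms``, ``apd_ms``,
    ``dapd_ms``, ``ows`` or ``df_hz``) and ``units`` its physical unit.
    """

    values: np.ndarray
    mask: np.ndarray
    kind: str
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.kind not in MAP_KINDS:
            raise ValueError(f"kind must be one of {MAP_KINDS}")
        # defined pixels must lie inside the mask
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def defined(self) -> np.ndarray:
        """Boolean image of pixels with a defined value."""
        return self.mask & np.isfinite(self.values)

    @property
    def defined_values(self) -> np.ndarray:
        return self.values[self.defined]


@dataclass
class VectorMap:
    """Conduction-velocity vector field in image coordinates.

    ``vx`` points along columns (+x right), ``vy`` along rows (+y down);
    both in cm/s.  ``speed`` is the magnitude.  Undefined pixels are NaN.
    """

    vx: np.ndarray
    vy: np.ndarray
    speed: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.vx, self.vy, self.speed, self.mask)}
        if len(shapes) != 1:
            raise ValueError("vx, vy, speed and mask must share one shape")

    @property
    def defined(self) -> np.ndarray:
        return self.mask & np.isfinite(self.speed)


@dataclass
class BeatTable:
    """Detected beats with per-beat cycle lengths and PCL group labels.

    ``beats`` columns: ``peak_frame`` (int), ``cycle_length_ms`` (float,
    NaN for the first beat), ``pcl_group`` (int).
    ``groups`` columns: ``pcl_group``, ``nominal_pcl_ms``, ``beat_count``.
    """

    beats: pd.DataFrame
    groups: pd.DataFrame
    frame_rate: float

    def peaks_of_group(self, group: int) -> np.ndarray:
        sel = self.beats[self.beats.pcl_group == group]
        return sel.peak_frame.to_numpy()

    def nominal_pcl(self, group: int) -> float:
        row = self.groups[self.groups.pcl_group == group]
        if row.empty:
            raise KeyError(f"no PCL group {group}")
        return float(row.nominal_pcl_ms.iloc[0])

    @property
    def group_labels(self) -> list[int]:
        return self.groups.pcl_group.tolist()


@dataclass
class EnsembleBeat:
    """Frame-wise average of aligned beat windows at one PCL."""

    window: np.ndarray          # (frames, rows, cols)
    pre_ms: float
    post_ms: float
    n_averaged: int
    source_pcl: float
    frame_rate: float
    align_frame: int = 0        # index of the alignment point inside window

    def __post_init__(self) -> None:
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")

    @property
    def times_ms(self) -> np.ndarray:
        """Window times in ms relative to the window start."""
        return np.arange(self.window.shape[0]) * (1000.0 / self.frame_rate)


@dataclass
class SpectrumResult:
    """Power spectrum on the zero-padded frequency grid plus the dominant
    frequency (Hz of peak power inside the analysis band; NaN if no power)."""

    frequencies: np.ndarray
    power: np.ndarray
    df: float
    band: tuple[float, float] = (0.5, 50.0)


@dataclass
class SettingsOverrides:
    """Typed key->value overrides parsed from a settings text file, plus the
    keys that were present but not recognised (reported, never dropped)."""

    values: dict = field(default_factory=dict)
    unknown: list = field(default_factory=list)
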