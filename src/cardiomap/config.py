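"""Pipeline configuration, dataset profiles and the settings-key registry.

Defaults follow standard optical-mapping practice for these preparations:
3x3 Gaussian spatial filter (sigma 1.5 px), morphological top-hat baseline
correction (200 ms structuring element for guinea-pig recordings, 100 ms
for mouse), ensemble averaging of the last 10 beats per pacing cycle
length, APD at 80% repolarisation, multi-vector conduction velocity with a
5x5 fitting window, and dominant-frequency analysis over 0.5-50 Hz at
0.05 Hz resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional


@dataclass
class DatasetProfile:
    """Acquisition metadata for one recording configuration."""

    frame_rate: float       # Hz
    pixel_size: float       # micrometres / pixel
    tophat_ms: float        # default baseline-correction kernel, ms
    grid: tuple[int, int]   # typical (rows, cols), informational


#: Acquisition profiles for the three deposited preparations.
PROFILES: dict[str, DatasetProfile] = {
    "mouse_heart": DatasetProfile(1000.0, 156.0, 100.0, (51, 51)),
    "mouse_atria": DatasetProfile(987.0, 71.4, 100.0, (45, 45)),
    "guinea_pig": DatasetProfile(500.0, 320.0, 200.0, (64, 64)),
}


@dataclass
class PipelineConfig:
    """Resolved parameter set driving the whole analysis pipeline."""

    # preprocessing
    gaussian_size: int = 3
    gaussian_sigma: float = 1.5
    tophat_ms: Optional[float] = None     # None -> profile default
    polarity: str = "inverted_voltage"
    mask_method: str = "amplitude_fraction"
    mask_fraction: float = 0.3
    # beat detection / grouping
    min_prominence: float = 0.4
    min_interval_ms: float = 40.0
    pcl_tolerance_ms: float = 5.0
    ensemble_n: int = 10
    # morphology
    apd_level: float = 80.0
    activation_mode: str = "midpoint"
    # conduction
    cv_window: int = 5
    cv_order: str = "plane"
    speed_cap_min: float = 1.0           # cm/s
    speed_cap_max: float = 200.0         # cm/s
    # rhythm
    df_band_low: float = 0.5             # Hz
    df_band_high: float = 50.0           # Hz
    df_resolution: float = 0.05          # Hz
    # acquisition (profile-dependent)
    profile: str = "custom"
    frame_rate: Optional[float] = None   # Hz; required for profile "custom"
    pixel_size: Optional[float] = None   # um; required for profile "custom"
    # file reading
    dim_order: str = "row_col_frame"
    mat_variable: Optional[str] = None
    # reproducibility
    seed: int = 0

    def resolved(self) -> "PipelineConfig":
        """Fill frame_rate / pixel_size / tophat_ms from the profile."""
        cfg = replace(self)
        if cfg.profile != "custom":
            if cfg.profile not in PROFILES:
                raise ValueError(
                    f"unknown profile {cfg.profile!r}; expected one of "
                    f"{sorted(PROFILES)} or 'custom'"
                )
            prof = PROFILES[cfg.profile]
            cfg.frame_rate = cfg.frame_rate or prof.frame_rate
            cfg.pixel_size = cfg.pixel_size or prof.pixel_size
            if cfg.tophat_ms is None:
                cfg.tophat_ms = prof.tophat_ms
        if cfg.frame_rate is None or cfg.pixel_size is None:
            raise ValueError(
                "frame_rate and pixel_size must be set explicitly when "
                "profile is 'custom' (the movie containers do not embed them)"
            )
        if cfg.tophat_ms is None:
            cfg.tophat_ms = 100.0
        return cfg

    def apply_overrides(self, overrides: dict) -> "PipelineConfig":
        return replace(self, **overrides)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes", "on"):
        return True
    if t in ("false", "0", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


#: Registry of settings-file keys -> (config field, parser).  Anything not
#: listed here is reported back as unknown rather than silently dropped.
KEY_REGISTRY: dict[str, tuple[str, callable]] = {
    "gaussian_size": ("gaussian_size", int),
    "gaussian_sigma": ("gaussian_sigma", float),
    "tophat_ms": ("tophat_ms", float),
    "polarity": ("polarity", str),
    "mask_method": ("mask_method", str),
    "mask_fraction": ("mask_fraction", float),
    "min_prominence": ("min_prominence", float),
    "min_interval_ms": ("min_interval_ms", float),
    "pcl_tolerance_ms": ("pcl_tolerance_ms", float),
    "ensemble_n": ("ensemble_n", int),
    "apd_level": ("apd_level", float),
    "activation_mode": ("activation_mode", str),
    "cv_window": ("cv_window", int),
    "cv_order": ("cv_order", str),
    "speed_cap_min": ("speed_cap_min", float),
    "speed_cap_max": ("speed_cap_max", float),
    "df_band_low": ("df_band_low", float),
    "df_band_high": ("df_band_high", float),
    "df_resolution": ("df_resolution", float),
    "profile": ("profile", str),
    "frame_rate": ("frame_rate", float),
    "pixel_size": ("pixel_size", float),
    "dim_order": ("dim_order", str),
    "mat_variable": ("mat_variable", str),
    "seed": ("seed", int),
}
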