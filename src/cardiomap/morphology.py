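"""Per-pixel action-potential morphology: activation time, APD, alternans.

Conventions used throughout (on upstroke-positive single-beat windows):

* baseline = a low-percentile floor (5th percentile) of the trace before
  the upstroke; a pre-upstroke estimate is used because windows may clip
  the previous repolarisation tail, and a percentile rather than the
  strict minimum because the minimum of a noisy segment grows with its
  length and would bias amplitudes (and hence APD crossings) upward;
* activation time = the 50% upstroke crossing ("depolarisation midpoint",
  linearly interpolated) or the instant of maximum upstroke velocity
  (maximum first difference, earliest frame on ties, not interpolated —
  finite differences live on the frame grid);
* APD at level L = time from maximum upstroke velocity to the first
  downward crossing of (1 - L/100) of the amplitude above baseline after
  the peak, crossing linearly interpolated.
"""

from __future__ import annotations

import warnings

import numpy as np

from .beats import beat_windows
from .containers import (
    BeatTable,
    EnsembleBeat,
    FluorescenceMovie,
    ScalarMap,
    TissueMask,
    as_mask,
)


def activation_time(trace: np.ndarray, frame_rate: float,
                    mode: str = "midpoint") -> float:
    """Activation time in ms from the window start; NaN if undefined."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3 or not np.all(np.isfinite(trace)):
        return np.nan
    peak = int(np.argmax(trace))
    if peak == 0:
        return np.nan
    dt_ms = 1000.0 / frame_rate
    if mode == "midpoint":
        base = _baseline(trace, peak)
        amp = trace[peak] - base
        if amp <= 0:
            return np.nan
        level = base + 0.5 * amp
        seg = trace[:peak + 1]
        below = np.nonzero(seg[:-1] <= level)[0]
        cross = below[seg[below + 1] > level]
        if cross.size == 0:
            return np.nan
        i = int(cross[0])  # first upward crossing before the peak
        frac = (level - seg[i]) / (seg[i + 1] - seg[i])
        return (i + frac) * dt_ms
    if mode == "max_dvdt":
        d = np.diff(trace[:peak + 1])
        if d.size == 0 or d.max() <= 0:
            return np.nan
        return _earliest_argmax(d) * dt_ms
    raise ValueError(f"unknown activation mode {mode!r}")


def _earliest_argmax(d: np.ndarray) -> int:
    """First index attaining the maximum, treating values equal to within
    float rounding as tied (a plateau of equal slopes resolves to its
    earliest sample)."""
    tol = 1e-9 * max(abs(float(d.max())), 1e-300)
    return int(np.nonzero(d >= d.max() - tol)[0][0])


def _baseline(trace: np.ndarray, peak: int) -> float:
    """Diastolic floor before the upstroke: 5th percentile of the samples
    up to the maximum-upstroke-velocity instant (falls back to the
    pre-peak minimum when that segment is too short to rank)."""
    d = np.diff(trace[:peak + 1])
    if d.size and d.max() > 0:
        start = _earliest_argmax(d)
        if start + 1 >= 5:
            return float(np.percentile(trace[:start + 1], 5))
    return float(trace[:peak + 1].min())


def apd(trace: np.ndarray, frame_rate: float, level: float = 80.0) -> float:
    """Action potential duration at ``level``% repolarisation, in ms.

    Measured from the instant of maximum upstroke velocity to the first
    downward crossing of the (1 - level/100) amplitude threshold after the
    peak.  NaN when repolarisation never reaches the level in the window.
    """
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100)")
    trace = np.asarray(trace, dtype=float)
    if trace.size < 3 or not np.all(np.isfinite(trace)):
        return np.nan
    peak = int(np.argmax(trace))
    if peak == 0:
        return np.nan
    base = _baseline(trace, peak)
    ampl = trace[peak] - base
    if ampl <= 0:
        return np.nan
    d = np.diff(trace[:peak + 1])
    if d.max() <= 0:
        return np.nan
    start = _earliest_argmax(d)
    target = base + (1.0 - level / 100.0) * ampl
    seg = trace[peak:]
    above = np.nonzero(seg[:-1] >= target)[0]
    cross = above[seg[above + 1] < target]
    if cross.size == 0:
        return np.nan
    j = int(cross[0])
    frac = (seg[j] - target) / (seg[j] - seg[j + 1])
    end = peak + j + frac
    return (end - start) * (1000.0 / frame_rate)


def map_beat(
    ensemble: EnsembleBeat,
    mask: TissueMask | np.ndarray,
    measure: str,
    mode: str = "midpoint",
    level: float = 80.0,
) -> ScalarMap:
    """Apply a morphology measure pixel-wise over an ensemble beat window.

    ``measure`` is ``"activation"`` or ``"apd"``.  Activation maps are
    re-zeroed to the earliest defined pixel, i.e. values are time after
    first activation.
    """
    flags = as_mask(mask, ensemble.window.shape[1:])
    values = np.full(flags.shape, np.nan)
    fr = ensemble.frame_rate
    for r, c in zip(*np.nonzero(flags)):
        trace = ensemble.window[:, r, c]
        if measure == "activation":
            values[r, c] = activation_time(trace, fr, mode=mode)
        elif measure == "apd":
            values[r, c] = apd(trace, fr, level=level)
        else:
            raise ValueError(f"unknown measure {measure!r}")
    if measure == "activation":
        if np.any(np.isfinite(values)):
            values -= np.nanmin(values)
        kind, units = "activation_ms", "ms"
    else:
        kind, units = "apd_ms", "ms"
    n_undef = int(np.sum(~np.isfinite(values[flags])))
    if n_undef > 0.5 * flags.sum():
        warnings.warn(
            f"{measure} undefined at {n_undef}/{int(flags.sum())} in-mask "
            "pixels", stacklevel=2)
    return ScalarMap(values=values, mask=flags, kind=kind, units=units)


def heterogeneity(smap: ScalarMap) -> float:
    """Spatial heterogeneity index: (P95 - P5) / median over defined pixels.

    Dimensionless and scale-invariant; percentiles use linear interpolation
    between order statistics.
    """
    vals = smap.defined_values
    if vals.size < 20:
        raise ValueError(
            f"need >= 20 defined pixels for heterogeneity, got {vals.size}")
    p5, p50, p95 = np.percentile(vals, [5, 50, 95])
    if p50 == 0:
        raise ValueError("heterogeneity undefined: median is zero")
    return float((p95 - p5) / p50)


def alternans_map(
    movie: FluorescenceMovie,
    table: BeatTable,
    group: int,
    mask: TissueMask | np.ndarray,
    level: float = 80.0,
    stat: str = "mean",
    pre_ms: float | None = None,
    post_ms: float | None = None,
) -> ScalarMap:
    """Beat-to-beat APD alternans magnitude map (kind ``dapd_ms``).

    APD is measured on each *single* (non-averaged) beat of the group;
    the pixel value is the mean over consecutive pairs of |APD_i -
    APD_{i-1}| (``stat="last"`` keeps only the final pair).  Pixels where
    any single-beat APD is unmeasurable are undefined.
    """
    if stat not in ("mean", "last"):
        raise ValueError("stat must be 'mean' or 'last'")
    peaks = table.peaks_of_group(group)
    if peaks.size < 2:
        raise ValueError(f"PCL group {group} has fewer than 2 beats")
    windows, _refs, _pre = beat_windows(
        movie, table, group, pre_ms=pre_ms, post_ms=post_ms, mask=mask)
    if windows.shape[0] < 2:
        raise ValueError("fewer than 2 usable beats after window clipping")
    flags = as_mask(mask, movie.frame_shape)
    fr = movie.frame_rate
    values = np.full(flags.shape, np.nan)
    for r, c in zip(*np.nonzero(flags)):
        apds = np.array([apd(w[:, r, c], fr, level=level) for w in windows])
        if np.any(~np.isfinite(apds)):
            continue
        diffs = np.abs(np.diff(apds))
        values[r, c] = diffs[-1] if stat == "last" else diffs.mean()
    return ScalarMap(values=values, mask=flags, kind="dapd_ms", units="ms")
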