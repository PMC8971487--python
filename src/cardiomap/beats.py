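"""Beat detection, pacing-cycle-length grouping and ensemble averaging.

Beats are found on a global (mask-averaged) signal, grouped into pacing
cycle length (PCL) stages by a running-median scan, and the last beats of
each stage are aligned on the global upstroke midpoint and averaged
frame-wise to raise signal-to-noise before morphology measurement.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .containers import BeatTable, EnsembleBeat, FluorescenceMovie, TissueMask, as_mask


def global_signal(movie: FluorescenceMovie,
                  mask: TissueMask | np.ndarray | None = None) -> np.ndarray:
    """Frame-wise mean fluorescence over in-mask pixels."""
    flags = as_mask(mask, movie.frame_shape)
    if not flags.any():
        raise ValueError("mask is empty")
    return movie.data[:, flags].mean(axis=1)


def detect_beats(
    signal: np.ndarray,
    frame_rate: float,
    min_prominence: float = 0.4,
    min_interval_ms: float = 40.0,
) -> np.ndarray:
    """Detect beat peaks in a 1-D signal.

    Local maxima with topographic prominence of at least ``min_prominence``
    times the signal's full amplitude are kept; candidates closer than
    ``min_interval_ms`` are resolved in favour of the more prominent peak.
    Returns strictly increasing peak frame indices (possibly empty).
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size < 3:
        raise ValueError("signal must have at least 3 samples")
    amp = signal.max() - signal.min()
    if amp <= 0:
        return np.array([], dtype=int)
    peaks, props = find_peaks(signal, prominence=min_prominence * amp)
    if peaks.size == 0:
        return peaks
    # greedy spacing enforcement, most prominent first (ties: earliest)
    min_dist = max(1, int(round(min_interval_ms * frame_rate / 1000.0)))
    order = np.lexsort((peaks, -props["prominences"]))
    accepted: list[int] = []
    for idx in order:
        p = peaks[idx]
        if all(abs(p - a) >= min_dist for a in accepted):
            accepted.append(int(p))
    return np.array(sorted(accepted), dtype=int)


def identify_pcls(
    peak_frames: np.ndarray,
    frame_rate: float,
    tolerance_ms: float = 5.0,
    signal: np.ndarray | None = None,
) -> BeatTable:
    """Group beats into pacing-cycle-length stages.

    Successive cycle lengths are scanned in order; a new group starts
    whenever an interval differs from the running median of the current
    group by more than ``tolerance_ms`` (so single ectopic intervals form
    their own groups and adjacent 10-ms ramp stages never merge).  Each
    group's nominal PCL is the median of its member intervals rounded to
    1 ms.  The first beat joins the group of the first interval.

    When ``signal`` is supplied, cycle lengths are measured between the
    interpolated 50% upstroke crossings preceding each peak instead of
    between the raw peak frames: the peak of a broad optical plateau can
    wander by a frame or two under noise, while the upstroke midpoint —
    the package's timing reference throughout — is steep and stable.
    Reported ``peak_frame`` values stay the raw peaks.
    """
    peaks = np.asarray(peak_frames, dtype=int)
    if peaks.size < 2:
        raise ValueError("need at least 2 beats to identify PCLs")
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("peak frames must be strictly increasing")
    if signal is not None:
        lookback = float(np.median(np.diff(peaks))) * 0.8 * 1000.0 / frame_rate
        times = np.array([_upstroke_midpoint_time(signal, int(p), frame_rate,
                                                  lookback)
                          for p in peaks])
        intervals_ms = np.diff(times)
    else:
        intervals_ms = np.diff(peaks) * (1000.0 / frame_rate)

    group_of_interval = np.empty(intervals_ms.size, dtype=int)
    current: list[float] = []
    label = 0
    for i, cl in enumerate(intervals_ms):
        if current and abs(cl - np.median(current)) > tolerance_ms:
            label += 1
            current = []
        current.append(cl)
        group_of_interval[i] = label

    beat_group = np.concatenate([[group_of_interval[0]], group_of_interval])
    cycle = np.concatenate([[np.nan], intervals_ms])
    beats = pd.DataFrame({
        "peak_frame": peaks,
        "cycle_length_ms": cycle,
        "pcl_group": beat_group,
    })
    rows = []
    for g in np.unique(group_of_interval):
        member = intervals_ms[group_of_interval == g]
        rows.append({
            "pcl_group": int(g),
            "nominal_pcl_ms": float(round(float(np.median(member)))),
            "beat_count": int((beat_group == g).sum()),
        })
    groups = pd.DataFrame(rows)
    return BeatTable(beats=beats, groups=groups, frame_rate=frame_rate)


def _upstroke_midpoint_time(signal: np.ndarray, peak: int, frame_rate: float,
                            lookback_ms: float = 100.0) -> float:
    """Interpolated 50% upstroke crossing (ms) preceding ``peak``."""
    start = max(0, peak - int(round(lookback_ms * frame_rate / 1000.0)))
    seg = signal[start:peak + 1]
    base = seg.min()
    level = base + 0.5 * (signal[peak] - base)
    below = np.nonzero(seg[:-1] <= level)[0]
    cross = below[(seg[below + 1] > level)]
    if cross.size == 0:
        return peak * 1000.0 / frame_rate
    i = cross[-1]  # crossing nearest the peak: the beat's own upstroke
    frac = (level - seg[i]) / (seg[i + 1] - seg[i])
    return (start + i + frac) * 1000.0 / frame_rate


def upstroke_midpoint_frame(signal: np.ndarray, peak: int, frame_rate: float,
                            lookback_ms: float = 100.0) -> int:
    """Alignment reference for one beat: the 50% upstroke crossing of the
    global signal before ``peak``, linearly interpolated then snapped to
    the nearest frame."""
    t = _upstroke_midpoint_time(signal, peak, frame_rate, lookback_ms)
    return int(round(t * frame_rate / 1000.0))


def beat_windows(
    movie: FluorescenceMovie,
    table: BeatTable,
    group: int,
    pre_ms: float | None = None,
    post_ms: float | None = None,
    n_last: int | None = None,
    mask: TissueMask | np.ndarray | None = None,
):
    """Extract aligned per-beat sub-movies for one PCL group.

    Windows span ``pre_ms`` before to ``post_ms`` after each beat's global
    upstroke midpoint (defaults: 20% / 90% of the nominal PCL, clamped to
    the recording).  The group's final beat is excluded when its window
    would overlap the next group's first beat (prevents contamination
    across ramp steps).  Returns ``(windows, refs, pre_frames)`` where
    ``windows`` has shape (n_beats, frames, rows, cols).
    """
    fr = movie.frame_rate
    pcl = table.nominal_pcl(group)
    if pre_ms is None:
        pre_ms = 0.2 * pcl
    if post_ms is None:
        post_ms = 0.9 * pcl
    length = int(round((pre_ms + post_ms) * fr / 1000.0)) + 1
    pre_f = int(round(pre_ms * fr / 1000.0))
    post_f = length - 1 - pre_f

    signal = global_signal(movie, mask)
    peaks = table.peaks_of_group(group)
    if peaks.size == 0:
        raise KeyError(f"no beats in PCL group {group}")
    lookback = max(100.0, 0.8 * pcl)  # reach diastole even for slow waves
    refs = np.array([upstroke_midpoint_frame(signal, int(p), fr, lookback)
                     for p in peaks])

    # drop the final beat if its window reaches into the next group
    later = table.beats[table.beats.peak_frame > peaks[-1]]
    if not later.empty and refs[-1] + post_f >= int(later.peak_frame.iloc[0]):
        peaks, refs = peaks[:-1], refs[:-1]

    if n_last is not None:
        peaks, refs = peaks[-n_last:], refs[-n_last:]

    windows, kept_refs = [], []
    for ref in refs:
        lo, hi = ref - pre_f, ref + post_f
        if lo < 0 or hi >= movie.n_frames:
            warnings.warn(
                f"beat window [{lo}, {hi}] exceeds recording bounds; "
                "beat dropped", stacklevel=2)
            continue
        windows.append(movie.data[lo:hi + 1])
        kept_refs.append(int(ref))
    if not windows:
        raise ValueError("no usable beats: all windows exceed the recording")
    return np.stack(windows), np.array(kept_refs), pre_f


def ensemble_average(
    movie: FluorescenceMovie,
    table: BeatTable,
    group: int,
    n_last: int = 10,
    pre_ms: float | None = None,
    post_ms: float | None = None,
    mask: TissueMask | np.ndarray | None = None,
) -> EnsembleBeat:
    """Average the last ``n_last`` aligned beats of a PCL group frame-wise.

    Alignment is on each beat's global-signal upstroke midpoint (sub-sample
    interpolable and robust to plateau noise).  If fewer beats are
    available, all of them are used and ``n_averaged`` records the count.
    """
    pcl = table.nominal_pcl(group)
    if pre_ms is None:
        pre_ms = 0.2 * pcl
    if post_ms is None:
        post_ms = 0.9 * pcl
    windows, _refs, pre_f = beat_windows(
        movie, table, group, pre_ms=pre_ms, post_ms=post_ms,
        n_last=n_last, mask=mask)
    return EnsembleBeat(
        window=windows.mean(axis=0),
        pre_ms=float(pre_ms),
        post_ms=float(post_ms),
        n_averaged=windows.shape[0],
        source_pcl=pcl,
        frame_rate=movie.frame_rate,
        align_frame=pre_f,
    )


def export_beat_table(table: BeatTable, path) -> None:
    """Write the beat table as CSV (peak_frame, cycle_length_ms, pcl_group)."""
    table.beats.to_csv(path, index=False)
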