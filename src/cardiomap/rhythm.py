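"""Temporal-regularity and frequency analyses.

Dominant frequency (DF): the Hann-windowed, zero-padded power spectrum of
a pixel's full trace; DF is the frequency of peak power inside the
analysis band (default 0.5-50 Hz, padded to a 0.05 Hz grid).  During
regular pacing DF maps are spatially uniform at the pacing frequency;
during fibrillation they become elevated and heterogeneous.

Optical wave similarity (OWS): an index in [0, 1] of beat-to-beat
morphological regularity built from pairwise cosine similarities of
amplitude-normalised single-beat traces; 1 for a perfectly repeating
signal, approaching 0 in fibrillation.  Per-beat weights default to
uniform but are injectable.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal.windows import hann

from .beats import beat_windows
from .containers import (
    BeatTable,
    FluorescenceMovie,
    ScalarMap,
    SpectrumResult,
    TissueMask,
    as_mask,
)


def _padded_length(n: int, frame_rate: float, resolution: float) -> int:
    return max(n, int(np.ceil(frame_rate / resolution)))


def dominant_frequency(
    trace: np.ndarray,
    frame_rate: float,
    band: tuple[float, float] = (0.5, 50.0),
    resolution: float = 0.05,
) -> SpectrumResult:
    """Dominant frequency of a 1-D trace.

    The mean-subtracted trace is multiplied by a Hann window of its own
    length, zero-padded so the frequency grid spacing is at most
    ``resolution``, and the magnitude-squared spectrum is computed.  DF is
    the frequency of maximum power restricted to ``band``; exact power
    ties resolve to the lowest frequency, and an all-zero spectrum (flat
    trace) yields NaN.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise ValueError("trace must have at least 2 samples")
    if frame_rate <= 2.0 * band[1]:
        raise ValueError(
            f"band upper edge {band[1]} Hz exceeds Nyquist for frame rate "
            f"{frame_rate} Hz")
    x = (trace - trace.mean()) * hann(trace.size)
    n = _padded_length(trace.size, frame_rate, resolution)
    power = np.abs(np.fft.rfft(x, n)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / frame_rate)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    band_power = power[in_band]
    if band_power.size == 0 or band_power.max() <= 0:
        df = np.nan
    else:
        df = float(freqs[in_band][int(np.argmax(band_power))])
    return SpectrumResult(frequencies=freqs, power=power, df=df, band=band)


def df_map(
    movie: FluorescenceMovie,
    mask: TissueMask | np.ndarray,
    band: tuple[float, float] = (0.5, 50.0),
    resolution: float = 0.05,
    chunk: int = 256,
) -> ScalarMap:
    """Dominant frequency per in-mask pixel on the full (non-ensembled)
    trace, computed in pixel chunks to bound memory."""
    flags = as_mask(mask, movie.frame_shape)
    if movie.frame_rate <= 2.0 * band[1]:
        raise ValueError("band upper edge exceeds Nyquist")
    T = movie.n_frames
    n = _padded_length(T, movie.frame_rate, resolution)
    freqs = np.fft.rfftfreq(n, d=1.0 / movie.frame_rate)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    band_freqs = freqs[in_band]
    win = hann(T)

    traces = movie.data[:, flags]          # (T, n_pixels)
    dfs = np.full(traces.shape[1], np.nan)
    for lo in range(0, traces.shape[1], chunk):
        blk = traces[:, lo:lo + chunk]
        x = (blk - blk.mean(axis=0)) * win[:, None]
        p = np.abs(np.fft.rfft(x, n, axis=0)[in_band]) ** 2
        peak = p.max(axis=0)
        idx = p.argmax(axis=0)
        vals = band_freqs[idx]
        vals[peak <= 0] = np.nan
        dfs[lo:lo + chunk] = vals
    values = np.full(flags.shape, np.nan)
    values[flags] = dfs
    return ScalarMap(values=values, mask=flags, kind="df_hz", units="Hz")


def ows(beat_traces, weights=None) -> float:
    """Optical wave similarity of a sequence of single-beat traces.

    Each trace is amplitude-normalised to [0, 1] (flat beats are dropped);
    all are truncated to the shortest length.  With pairwise cosine
    similarity s(i, j) = <b_i, b_j>/(|b_i||b_j|), OWS is the weighted sum
    over beats of the mean similarity of each beat to all others
    (uniform weights by default), clipped to [0, 1].  NaN when fewer than
    two usable beats remain.
    """
    traces = [np.asarray(t, dtype=float) for t in beat_traces]
    if len(traces) < 2:
        raise ValueError("need at least 2 beat traces")
    length = min(t.size for t in traces)
    normed = []
    for t in traces:
        t = t[:length]
        lo, hi = t.min(), t.max()
        if not hi > lo:
            continue  # flat beat dropped
        normed.append((t - lo) / (hi - lo))
    if len(normed) < 2:
        return np.nan
    B = np.stack(normed)
    norms = np.linalg.norm(B, axis=1)
    S = (B @ B.T) / np.outer(norms, norms)
    n = B.shape[0]
    off = S - np.eye(n) * S.diagonal()
    per_beat = off.sum(axis=1) / (n - 1)
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != n:
            raise ValueError(
                f"weights length {w.size} does not match {n} usable beats")
        w = w / w.sum()
    return float(np.clip(w @ per_beat, 0.0, 1.0))


def ows_map(
    movie: FluorescenceMovie,
    table: BeatTable,
    group: int,
    mask: TissueMask | np.ndarray,
    pre_ms: float | None = None,
    post_ms: float | None = None,
) -> ScalarMap:
    """OWS per in-mask pixel over the single-beat windows of one PCL group.

    Windows are aligned on the global-signal upstroke midpoint (default
    span: 20 ms before to 90% of the PCL after), so each pixel compares
    like-for-like phases of consecutive beats.
    """
    flags = as_mask(mask, movie.frame_shape)
    peaks = table.peaks_of_group(group)
    if peaks.size < 2:
        warnings.warn(f"PCL group {group} has fewer than 2 beats; "
                      "OWS map is undefined", stacklevel=2)
        return ScalarMap(values=np.full(flags.shape, np.nan), mask=flags,
                         kind="ows", units="")
    pcl = table.nominal_pcl(group)
    if pre_ms is None:
        pre_ms = 20.0
    if post_ms is None:
        post_ms = 0.9 * pcl
    windows, _refs, _pre = beat_windows(
        movie, table, group, pre_ms=pre_ms, post_ms=post_ms, mask=flags)
    nb = windows.shape[0]
    if nb < 2:
        warnings.warn("fewer than 2 usable beat windows; OWS map is "
                      "undefined", stacklevel=2)
        return ScalarMap(values=np.full(flags.shape, np.nan), mask=flags,
                         kind="ows", units="")

    W = windows[:, :, flags]               # (beats, frames, pixels)
    lo = W.min(axis=1, keepdims=True)
    amp = W.max(axis=1, keepdims=True) - lo
    with np.errstate(divide="ignore", invalid="ignore"):
        N = np.where(amp > 0, (W - lo) / amp, np.nan)  # flat beats -> NaN
    norms = np.linalg.norm(N, axis=1)      # (beats, pixels)
    sims = []
    for i in range(nb):
        for j in range(i + 1, nb):
            with np.errstate(invalid="ignore"):
                sims.append((N[i] * N[j]).sum(axis=0) / (norms[i] * norms[j]))
    sims = np.stack(sims)                  # (pairs, pixels)
    usable = np.isfinite(N[:, 0, :]).sum(axis=0)   # beats with amplitude
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = np.nanmean(sims, axis=0)
    vals = np.clip(vals, 0.0, 1.0)
    vals[usable < 2] = np.nan
    values = np.full(flags.shape, np.nan)
    values[flags] = vals
    return ScalarMap(values=values, mask=flags, kind="ows", units="")


def export_spectrum(spectrum: SpectrumResult, path) -> None:
    """Write a spectrum as two-column CSV (frequency_hz, power)."""
    lines = ["frequency_hz,power"]
    lines += [f"{f!r},{p!r}" for f, p in
              zip(spectrum.frequencies, spectrum.power)]
    from pathlib import Path
    Path(path).write_text("\n".join(lines) + "\n")
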