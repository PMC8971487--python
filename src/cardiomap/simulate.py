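"""Synthetic fluorescence movies with exact ground truth.

The generator is kinematic, not electrophysiological: a stylised optical
action potential template is launched from each stimulus and propagates as
a planar or radial wavefront at a fixed speed.  Every ground-truth
quantity (activation map, APD80 map, speed field, per-beat PCL, dominant
frequency) is computed in closed form from the parameters; noise and
drift perturb only the movie, never the truth.

Template shape: a raised-cosine upstroke rising 0 -> 1 over
``upstroke_ms`` (unique maximum-slope instant at its centre, which is
also the depolarisation midpoint), followed by a linear repolarisation
whose slope is chosen so the 20%-amplitude downward crossing falls
exactly ``apd80_ms`` after the maximum-slope instant, then rest at 0.
Linear (rather than exponential) repolarisation keeps the APD80 ground
truth closed-form; an exponential tail option exists for realism but
carries no exactness guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import FluorescenceMovie, POLARITIES


@dataclass
class SimulationSpec:
    """Parameters of a paced synthetic recording.

    Defaults emulate a mouse whole-heart acquisition: 51x51 pixels at
    156 um/pixel, 1 kHz sampling, pacing at 110 ms cycle length, APD80
    around 45 ms, planar propagation at 50 cm/s, voltage-dye polarity
    (depolarisation = fluorescence decrease).
    """

    grid: tuple[int, int] = (51, 51)
    pixel_size: float = 156.0             # um / pixel
    frame_rate: float = 1000.0            # Hz
    geometry: str = "planar"              # "planar" | "radial"
    origin: tuple[float, float] | float = 0.0
    # planar: propagation angle in degrees, image convention (0 = +x/cols,
    # angles increase towards +y/down); radial: (row, col) focus pixel
    speed: float = 50.0                   # cm/s
    pcl_schedule: Sequence[tuple[float, int]] = ((110.0, 10),)
    apd80: float = 45.0                   # ms
    alternans_delta: float = 0.0          # ms, even/odd beat APD alternation
    upstroke_ms: float = 5.0              # ms
    noise_sd: float = 0.0                 # fraction of AP amplitude
    drift: tuple[float, float] = (0.0, 1.0)   # (amplitude fraction, period s)
    polarity: str = "inverted_voltage"
    breakthrough_boost: float = 0.0       # >= 0, far-field apparent speed-up
    repolarisation: str = "linear"        # "linear" | "exponential"
    tissue: Optional[np.ndarray] = None   # bool image; None = all pixels active
    start_ms: float = 20.0                # first stimulus time
    tail_fraction: float = 0.3            # recording tail after last beat
    seed: int = 0

    def validate(self) -> None:
        if not self.speed > 0:
            raise ValueError("speed must be > 0")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be > 0")
        if self.geometry not in ("planar", "radial"):
            raise ValueError("geometry must be 'planar' or 'radial'")
        if self.polarity not in POLARITIES:
            raise ValueError(f"polarity must be one of {POLARITIES}")
        if not self.apd80 > self.upstroke_ms / 2.0:
            raise ValueError(
                "apd80 must exceed half the upstroke time (repolarisation "
                "slope would be non-positive)")
        for pcl, _n in self.pcl_schedule:
            if not pcl > self.apd80 + self.upstroke_ms:
                raise ValueError(
                    f"pcl_schedule: PCL {pcl} ms must exceed apd80 + "
                    f"upstroke ({self.apd80 + self.upstroke_ms} ms)")


@dataclass
class GroundTruth:
    """Exact per-pixel truths implied by a :class:`SimulationSpec`."""

    activation_map: np.ndarray            # ms delay after stimulus, per pixel
    apd80_of_beat: np.ndarray             # ms, per beat
    speed_field: np.ndarray               # cm/s apparent speed, per pixel
    pcl_of_beat: np.ndarray               # ms, per beat
    stimulus_times_ms: np.ndarray         # ms, per beat
    df_true: Optional[np.ndarray] = None  # Hz per pixel (None if ambiguous)
    tissue: Optional[np.ndarray] = None


def _template_value(tau_ms: np.ndarray, upstroke_ms: float, apd80_ms: float,
                    repolarisation: str = "linear") -> np.ndarray:
    """Evaluate the AP template at times ``tau_ms`` after stimulus (vectorised).

    Raised-cosine upstroke on [0, U]; maximum slope and 50% level at U/2.
    Linear fall from 1 with duration F = (apd80 - U/2)/0.8 so the
    0.2-amplitude crossing is at U/2 + apd80 exactly.
    """
    U = upstroke_ms
    F = (apd80_ms - U / 2.0) / 0.8
    if F <= 0:
        raise ValueError("infeasible template: apd80 <= upstroke/2")
    tau = np.asarray(tau_ms, dtype=float)
    out = np.zeros_like(tau)
    up = (tau >= 0) & (tau < U)
    out[up] = 0.5 * (1.0 - np.cos(np.pi * tau[up] / U))
    if repolarisation == "linear":
        fall = (tau >= U) & (tau < U + F)
        out[fall] = 1.0 - (tau[fall] - U) / F
    elif repolarisation == "exponential":
        # time constant chosen so the 0.2 crossing matches the linear case
        k = 0.8 * F / np.log(5.0)
        fall = tau >= U
        out[fall] = np.exp(-(tau[fall] - U) / k)
        out[out < 1e-3] = 0.0
    else:
        raise ValueError("repolarisation must be 'linear' or 'exponential'")
    return out


def template_duration_ms(upstroke_ms: float, apd80_ms: float) -> float:
    """Total support of the linear-repolarisation template, in ms."""
    return upstroke_ms + (apd80_ms - upstroke_ms / 2.0) / 0.8


def ap_template(upstroke_ms: float, apd80_ms: float, frame_rate: float,
                duration_ms: float,
                repolarisation: str = "linear") -> np.ndarray:
    """Sample the AP template on the frame grid over ``duration_ms``.

    By construction the measured APD80 (maximum upstroke velocity to 20%
    crossing) equals ``apd80_ms`` within one frame, and the measured
    depolarisation midpoint equals ``upstroke_ms / 2`` within one frame.
    """
    if not duration_ms > upstroke_ms + apd80_ms:
        raise ValueError("duration_ms must exceed upstroke_ms + apd80_ms")
    t = np.arange(int(round(duration_ms * frame_rate / 1000.0))) \
        * (1000.0 / frame_rate)
    return _template_value(t, upstroke_ms, apd80_ms, repolarisation)


def _delay_map(spec: SimulationSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel activation delay (ms) and apparent speed field (cm/s)."""
    rows, cols = spec.grid
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    if spec.geometry == "planar":
        theta = np.radians(float(spec.origin))
        proj = cc * np.cos(theta) + rr * np.sin(theta)
        dist_um = (proj - proj.min()) * spec.pixel_size
    else:
        r0, c0 = spec.origin
        dist_um = np.hypot(rr - r0, cc - c0) * spec.pixel_size
    # 0.1 = (um -> cm) / (s -> ms)
    delay = 0.1 * dist_um / spec.speed
    speed_field = np.full(spec.grid, float(spec.speed))
    if spec.breakthrough_boost > 0:
        # apparent-delay compression growing with distance: a phenomenological
        # stand-in for epicardial breakthrough inflating far-field speed
        L = max(delay.max(), 1e-9)
        b = spec.breakthrough_boost
        delay = (L / b) * np.log1p(b * delay / L)
        speed_field = spec.speed * (1.0 + b * 0.1 * dist_um / spec.speed / L)
    return delay, speed_field


def simulate_paced_movie(spec: SimulationSpec) -> tuple[FluorescenceMovie, GroundTruth]:
    """Render a paced synthetic movie and its exact ground truth.

    Each stimulus in ``pcl_schedule`` launches one template beat that
    reaches pixel p after the geometric delay; with ``alternans_delta``
    the APD80 alternates +delta/2 (even beats) / -delta/2 (odd beats).
    Gaussian noise and sinusoidal drift are added to the fluorescence,
    polarity is applied last, and the result is bit-reproducible from
    ``seed``.
    """
    spec.validate()
    fr = spec.frame_rate
    dt = 1000.0 / fr
    delay, speed_field = _delay_map(spec)

    stim: list[float] = []
    pcls: list[float] = []
    t0 = round(spec.start_ms / dt) * dt
    for pcl, n in spec.pcl_schedule:
        for _ in range(n):
            stim.append(t0)
            pcls.append(pcl)
            t0 += pcl
    stim_arr = np.array(stim)
    pcl_arr = np.array(pcls)
    n_beats = stim_arr.size
    apd_of_beat = spec.apd80 + np.where(np.arange(n_beats) % 2 == 0, 0.5, -0.5) \
        * spec.alternans_delta

    max_delay = float(delay.max())
    for k in range(n_beats - 1):
        dur = template_duration_ms(spec.upstroke_ms, apd_of_beat[k])
        if max_delay + dur > stim_arr[k + 1] - stim_arr[k]:
            raise ValueError(
                f"overlapping beats: activation spread ({max_delay:.1f} ms) "
                f"+ beat duration ({dur:.1f} ms) exceeds PCL "
                f"{stim_arr[k + 1] - stim_arr[k]:.0f} ms")

    last_dur = template_duration_ms(spec.upstroke_ms, apd_of_beat[-1])
    total_ms = stim_arr[-1] + max_delay + last_dur \
        + spec.tail_fraction * pcl_arr[-1]
    n_frames = int(round(total_ms / dt)) + 1
    t = np.arange(n_frames) * dt

    signal = np.zeros((n_frames,) + spec.grid)
    for k in range(n_beats):
        dur = template_duration_ms(spec.upstroke_ms, apd_of_beat[k])
        lo = int(np.floor((stim_arr[k] + delay.min()) / dt))
        hi = min(n_frames, int(np.ceil((stim_arr[k] + max_delay + dur) / dt)) + 1)
        tau = t[lo:hi, None, None] - stim_arr[k] - delay[None, :, :]
        signal[lo:hi] += _template_value(tau, spec.upstroke_ms,
                                         apd_of_beat[k], spec.repolarisation)

    if spec.tissue is not None:
        tissue = np.asarray(spec.tissue, dtype=bool)
        if tissue.shape != spec.grid:
            raise ValueError("tissue mask shape must match grid")
        signal *= tissue[None, :, :]
    else:
        tissue = None

    rng = np.random.default_rng(spec.seed)
    movie_data = signal.copy()
    if spec.noise_sd > 0:
        movie_data = movie_data + rng.normal(0.0, spec.noise_sd,
                                             size=movie_data.shape)
    drift_amp, drift_period = spec.drift
    if drift_amp > 0:
        movie_data = movie_data + drift_amp * np.sin(
            2.0 * np.pi * t[:, None, None] / (1000.0 * drift_period))
    if spec.polarity == "inverted_voltage":
        # voltage dye: bright diastole, depolarisation darkens the pixel
        movie_data = 100.0 - movie_data

    movie = FluorescenceMovie(
        data=movie_data, frame_rate=fr, pixel_size=spec.pixel_size,
        polarity=spec.polarity, label="synthetic paced movie")
    df_true = None
    if len(spec.pcl_schedule) == 1:
        df_true = np.full(spec.grid, 1000.0 / spec.pcl_schedule[0][0])
        if tissue is not None:
            df_true = np.where(tissue, df_true, np.nan)
    truth = GroundTruth(
        activation_map=delay - delay.min(),
        apd80_of_beat=apd_of_beat,
        speed_field=speed_field,
        pcl_of_beat=pcl_arr,
        stimulus_times_ms=stim_arr,
        df_true=df_true,
        tissue=tissue,
    )
    return movie, truth


def spec_to_text(spec: SimulationSpec) -> str:
    """Serialise a SimulationSpec as plain ``key = value`` text."""
    lines = [
        f"grid = {spec.grid[0]},{spec.grid[1]}",
        f"pixel_size = {spec.pixel_size}",
        f"frame_rate = {spec.frame_rate}",
        f"geometry = {spec.geometry}",
        ("origin = " + (f"{spec.origin[0]},{spec.origin[1]}"
                        if spec.geometry == "radial" else f"{spec.origin}")),
        f"speed = {spec.speed}",
        "pcl_schedule = " + ";".join(f"{p}x{n}" for p, n in spec.pcl_schedule),
        f"apd80 = {spec.apd80}",
        f"alternans_delta = {spec.alternans_delta}",
        f"upstroke_ms = {spec.upstroke_ms}",
        f"noise_sd = {spec.noise_sd}",
        f"drift = {spec.drift[0]},{spec.drift[1]}",
        f"polarity = {spec.polarity}",
        f"breakthrough_boost = {spec.breakthrough_boost}",
        f"repolarisation = {spec.repolarisation}",
        f"seed = {spec.seed}",
    ]
    return "\n".join(lines) + "\n"


def spec_from_text(text: str) -> SimulationSpec:
    """Parse ``key = value`` lines (as written by :func:`spec_to_text`)."""
    spec = SimulationSpec()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: cannot parse {raw!r}")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        try:
            if key == "grid":
                r, c = val.split(",")
                spec.grid = (int(r), int(c))
            elif key in ("pixel_size", "frame_rate", "speed", "apd80",
                         "alternans_delta", "upstroke_ms", "noise_sd",
                         "breakthrough_boost", "start_ms", "tail_fraction"):
                setattr(spec, key, float(val))
            elif key == "geometry":
                spec.geometry = val
            elif key == "origin":
                parts = val.split(",")
                spec.origin = (float(parts[0]), float(parts[1])) \
                    if len(parts) == 2 else float(parts[0])
            elif key == "pcl_schedule":
                sched = []
                for item in val.replace(";", ",").split(","):
                    p, _, n = item.partition("x")
                    sched.append((float(p), int(n)))
                spec.pcl_schedule = tuple(sched)
            elif key == "drift":
                a, p = val.split(",")
                spec.drift = (float(a), float(p))
            elif key in ("polarity", "repolarisation"):
                setattr(spec, key, val)
            elif key == "seed":
                spec.seed = int(val)
            else:
                raise ValueError(f"unknown field {key!r}")
        except ValueError as exc:
            raise ValueError(f"line {lineno}, field {key!r}: {exc}") from exc
    spec.validate()
    return spec


def simulate_irregular_movie(
    grid: tuple[int, int],
    frame_rate: float,
    domains: Sequence[tuple[np.ndarray, float]],
    jitter: float = 0.0,
    seed: int = 0,
    duration_s: float = 4.0,
    pixel_size: float = 156.0,
    polarity: str = "upright",
) -> tuple[FluorescenceMovie, GroundTruth]:
    """Movie with spatial domains beating at different rates (VF-like fixture).

    Each domain emits a beat train at its own frequency; ``jitter``
    perturbs inter-beat intervals, per-beat amplitudes and per-beat APDs
    multiplicatively (all ~ fraction of their base values), emulating the
    temporal irregularity of fibrillation.  ``df_true`` per pixel is the
    domain frequency; pixels in no domain stay silent (NaN truth).
    """
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration_s * frame_rate))
    t = np.arange(n_frames) * (1000.0 / frame_rate)
    signal = np.zeros((n_frames,) + tuple(grid))
    df_true = np.full(grid, np.nan)
    claimed = np.zeros(grid, dtype=bool)

    for region, f in domains:
        region = np.asarray(region, dtype=bool)
        if region.shape != tuple(grid):
            raise ValueError("domain region shape must match grid")
        if not 0.5 < f < 50.0:
            raise ValueError(f"domain frequency {f} Hz outside (0.5, 50)")
        if (region & claimed).any():
            raise ValueError("domains overlap")
        claimed |= region
        base = 1000.0 / f                      # ms
        upstroke = min(5.0, 0.25 * base)
        apd_base = 0.5 * base
        trace = np.zeros(n_frames)
        t_k = 10.0
        while t_k < t[-1]:
            amp = max(0.2, 1.0 + jitter * rng.normal())
            apd_k = float(np.clip(apd_base * (1.0 + jitter * rng.normal()),
                                  0.6 * upstroke, 0.8 * base))
            trace += amp * _template_value(t - t_k, upstroke, apd_k)
            step = base * (1.0 + jitter * rng.normal())
            t_k += max(0.3 * base, step)
        signal[:, region] += trace[:, None]
        df_true[region] = f

    if polarity == "inverted_voltage":
        signal = 100.0 - signal
    movie = FluorescenceMovie(
        data=signal, frame_rate=frame_rate, pixel_size=pixel_size,
        polarity=polarity, label="synthetic irregular movie")
    truth = GroundTruth(
        activation_map=np.zeros(grid),
        apd80_of_beat=np.array([]),
        speed_field=np.full(grid, np.nan),
        pcl_of_beat=np.array([]),
        stimulus_times_ms=np.array([]),
        df_true=df_true,
        tissue=claimed,
    )
    return movie, truth
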