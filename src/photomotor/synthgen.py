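"""Synthetic photometry + behavior sessions with exported ground truth.

Every downstream stage of the pipeline gets an oracle from this module: it
fabricates a raw frequency-multiplexed photodetector voltage (Ca2+
transients with fast-rise/exponential-decay kinetics riding on a
double-exponential bleaching drift, a motion artifact shared by both
carriers, white noise), an open-field trajectory whose locomotor bouts are
known exactly, a stimulus train at ~60 s jittered intervals with a
configurable fraction of responding trials and trial-wise habituation, and
grooming/rearing annotations.  The injected components are returned as
:class:`SessionGroundTruth` so recovery can be scored without real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from .behavior import BoutSet, EventTable, TrackingTable
from .demodulation import DEFAULT_CARRIERS, RawPhotometryRecording

__all__ = [
    "TransientKernel",
    "SessionGroundTruth",
    "SessionConfig",
    "SessionBundle",
    "generate_transient_train",
    "superpose_transients",
    "generate_motion_artifact",
    "synthesize_raw_photometry",
    "synthesize_tracking",
    "synthesize_session",
]

#: raw acquisition rate, Hz — a power-of-two division of a common
#: acquisition master clock; comfortably above twice the 531 Hz carrier
RAW_FS = 6103.52


@dataclass(frozen=True)
class TransientKernel:
    """Ca2+ transient shape: difference of exponentials, unit peak.

    Defaults emulate a fast indicator (jGCaMP7f-like): ~25 ms rise and
    ~200 ms decay time constants.  ``amplitude`` scales the normalized
    kernel, so the kernel's maximum equals ``amplitude`` exactly.
    """

    rise_tau: float = 0.025
    decay_tau: float = 0.2
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.rise_tau <= 0 or self.decay_tau <= 0 or self.amplitude <= 0:
            raise ValueError("kernel parameters must be positive")
        if self.decay_tau <= self.rise_tau:
            raise ValueError("decay_tau must exceed rise_tau")

    @property
    def peak_time(self) -> float:
        """Time of the kernel maximum after onset (closed form)."""
        r, d = self.rise_tau, self.decay_tau
        return float(np.log(d / r) * r * d / (d - r))

    @property
    def support(self) -> float:
        """Duration after which the kernel is negligible."""
        return self.peak_time + 8.0 * self.decay_tau

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        r, d = self.rise_tau, self.decay_tau
        peak = np.exp(-self.peak_time / d) - np.exp(-self.peak_time / r)
        h = np.where(t >= 0, np.exp(-t / d) - np.exp(-t / r), 0.0)
        return self.amplitude * h / peak


def superpose_transients(
    event_times: np.ndarray,
    amplitudes: np.ndarray,
    kernel: TransientKernel,
    duration: float,
    fs: float,
) -> np.ndarray:
    """Sum of amplitude-scaled kernels at the given onset times."""
    n = int(round(duration * fs))
    trace = np.zeros(n)
    n_sup = int(np.ceil(kernel.support * fs))
    t = np.arange(n) / fs
    for te, amp in zip(np.asarray(event_times, float), np.asarray(amplitudes, float)):
        i0 = max(0, int(np.ceil(te * fs)))
        i1 = min(n, i0 + n_sup)
        if i0 >= n:
            continue
        trace[i0:i1] += amp * kernel(t[i0:i1] - te) / kernel.amplitude
    return trace


def generate_transient_train(
    rate: float,
    kernel: TransientKernel,
    duration: float,
    fs: float = 100.0,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson transient train; returns (onset times, clean trace)."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_events = rng.poisson(rate * duration)
    times = np.sort(rng.uniform(0.0, duration, n_events))
    trace = superpose_transients(
        times, np.full(times.size, kernel.amplitude), kernel, duration, fs
    )
    return times, trace


def generate_motion_artifact(
    duration: float,
    fs: float,
    sd: float,
    cutoff: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Slow zero-mean artifact: low-passed white noise rescaled to ``sd``."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * fs))
    if sd == 0.0:
        return np.zeros(n)
    sos = sps.butter(2, cutoff, "low", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    x -= x.mean()
    s = x.std()
    return x * (sd / s) if s > 0 else x


@dataclass
class BleachParams:
    """Double-exponential multiplicative decay applied to both LED envelopes."""

    fast_fraction: float = 0.1
    tau_fast: float = 150.0
    tau_slow: float = 6000.0

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return self.fast_fraction * np.exp(-t / self.tau_fast) + (
            1.0 - self.fast_fraction
        ) * np.exp(-t / self.tau_slow)


def synthesize_raw_photometry(
    clean_trace: np.ndarray,
    iso_artifact_trace: np.ndarray,
    fs: float = RAW_FS,
    carriers: dict[str, float] | None = None,
    baseline_ca: float = 1.0,
    baseline_iso: float = 1.0,
    mixing: float = 1.0,
    bleach: BleachParams | None = None,
    noise_sd: float = 0.003,
    seed: int | np.random.Generator = 0,
) -> RawPhotometryRecording:
    """Frequency-multiplex the two envelopes onto one voltage trace.

    The Ca2+ envelope carries baseline + transients + ``mixing`` x artifact;
    the isosbestic envelope carries baseline + artifact.  The shared
    double-exponential bleaching decay scales each baseline (a slow drift
    per envelope, removed downstream by the detrending high-pass); transient
    and artifact amplitudes are left unscaled so injected amplitudes remain
    the ground truth for recovery tests.
    """
    carriers = dict(carriers or DEFAULT_CARRIERS)
    if fs <= 2.0 * max(carriers.values()):
        raise ValueError(
            f"fs = {fs} Hz aliases the {max(carriers.values())} Hz carrier"
        )
    clean = np.asarray(clean_trace, dtype=float)
    art = np.asarray(iso_artifact_trace, dtype=float)
    if clean.shape != art.shape:
        raise ValueError("clean and artifact traces must share a grid")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = clean.size
    t = np.arange(n) / fs
    b = (bleach or BleachParams())(t)
    env_ca = baseline_ca * b + clean + mixing * art
    env_iso = baseline_iso * b + art
    v = env_ca * np.sin(2 * np.pi * carriers["ca"] * t) + env_iso * np.sin(
        2 * np.pi * carriers["iso"] * t
    )
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, n)
    return RawPhotometryRecording(voltage=v, fs=fs, carrier_hz=carriers)


def synthesize_tracking(
    bout_plan: list[tuple[float, float, float]],
    duration: float,
    arena_cm: float = 40.0,
    fps: float = 20.0,
    px_per_cm: float = 10.0,
    baseline_speed: float = 1.0,
    noise_px: float = 0.0,
    speed_threshold: float = 3.0,
    min_bout_duration: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[TrackingTable, BoutSet]:
    """Open-field trajectory whose locomotor bouts are known exactly.

    ``bout_plan`` lists (onset_s, duration_s, speed_cms) triples.  The
    trajectory is built frame by frame from a per-frame speed profile —
    the planned speed inside bouts, a sub-threshold wander elsewhere — with
    smoothly turning headings reflected away from the walls, so the speed
    the downstream pipeline computes from positions is the profile exactly
    (up to the optional pixel noise).  Returned true bouts are what the
    bout detector must find on the noiseless track.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration * fps))
    frame = 1.0 / fps
    if baseline_speed >= speed_threshold:
        raise ValueError("baseline wander speed must stay below the bout threshold")

    profile = np.full(n, baseline_speed)
    spans: list[tuple[int, int]] = []
    for onset, dur, v in sorted(bout_plan):
        if v <= speed_threshold:
            raise ValueError(f"planned bout speed {v} cm/s is not above threshold")
        if dur < min_bout_duration:
            raise ValueError(f"planned bout duration {dur} s is below the minimum")
        f_on = int(round(onset * fps))
        n_fr = int(round(dur * fps))
        if f_on < 1 or f_on + n_fr > n:
            raise ValueError("planned bout extends outside the session")
        if spans and f_on <= spans[-1][1]:
            raise ValueError("planned bouts overlap or touch (need a gap frame)")
        profile[f_on : f_on + n_fr] = v
        spans.append((f_on, f_on + n_fr - 1))

    true_bouts = BoutSet.from_intervals(
        [(a / fps, (b + 1) / fps) for a, b in spans], kind="locomotion", source="detected"
    )

    margin = 2.0
    pos = np.empty((n, 2))
    pos[0] = (arena_cm / 2.0, arena_cm / 2.0)
    heading = rng.uniform(0, 2 * np.pi)
    turn_sd = 0.3  # radians per frame: smooth, curving paths
    lo, hi = margin, arena_cm - margin
    center = np.array([arena_cm / 2.0, arena_cm / 2.0])
    for i in range(1, n):
        step = profile[i] * frame
        heading += rng.normal(0.0, turn_sd)
        nxt = pos[i - 1] + step * np.array([np.cos(heading), np.sin(heading)])
        if not (lo <= nxt[0] <= hi and lo <= nxt[1] <= hi):
            # turn toward the arena center, keeping the step length exact
            d = center - pos[i - 1]
            heading = np.arctan2(d[1], d[0]) + rng.normal(0.0, 0.2)
            nxt = pos[i - 1] + step * np.array([np.cos(heading), np.sin(heading)])
            nxt = np.clip(nxt, lo, hi)
        pos[i] = nxt

    xy_px = pos * px_per_cm
    if noise_px > 0:
        xy_px = xy_px + rng.normal(0.0, noise_px, xy_px.shape)
    side_px = arena_cm * px_per_cm
    corners = np.array([[0, 0], [side_px, 0], [side_px, side_px], [0, side_px]], float)
    tracking = TrackingTable(
        time=np.arange(n) / fps,
        x=xy_px[:, 0],
        y=xy_px[:, 1],
        likelihood=np.full(n, 0.99),
        corners=corners,
        fps=fps,
    )
    return tracking, true_bouts


@dataclass
class SessionGroundTruth:
    """Everything injected into a synthetic session, for recovery scoring."""

    transient_onsets: list[float] = field(default_factory=list)
    transient_times: list[float] = field(default_factory=list)  # peak times
    transient_amplitudes: list[float] = field(default_factory=list)
    true_bouts: BoutSet = field(default_factory=BoutSet)
    true_response_flags: list[bool] = field(default_factory=list)
    mixing_coefficient: float = 1.0
    habituation_decay: list[float] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = {
            "transient_onsets": self.transient_onsets,
            "transient_times": self.transient_times,
            "transient_amplitudes": self.transient_amplitudes,
            "true_bouts": self.true_bouts.table.to_dict(orient="records"),
            "true_response_flags": self.true_response_flags,
            "mixing_coefficient": self.mixing_coefficient,
            "habituation_decay": self.habituation_decay,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SessionGroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        bouts = BoutSet(pd.DataFrame(d["true_bouts"], columns=["onset_s", "offset_s", "kind", "source"]))
        return cls(
            transient_onsets=d["transient_onsets"],
            transient_times=d["transient_times"],
            transient_amplitudes=d["transient_amplitudes"],
            true_bouts=bouts,
            true_response_flags=d["true_response_flags"],
            mixing_coefficient=d["mixing_coefficient"],
            habituation_decay=d["habituation_decay"],
        )


@dataclass
class SessionConfig:
    """Study-condition defaults for one synthetic session.

    The stimulus regime follows the emulated experiment: trains of ~10
    trials at 60.1 s intervals with +/-0.3 s jitter in a 40 x 40 cm arena
    filmed at 20 fps; photometry carriers at 211 / 531 Hz sampled at
    6103.52 Hz.  Noise magnitudes are free parameters of the generator,
    not claims about any particular rig.
    """

    duration_s: float = 600.0
    fs_raw: float = RAW_FS
    fps: float = 20.0
    arena_cm: float = 40.0
    px_per_cm: float = 10.0
    # stimulus train
    n_trials: int = 10
    modality: str = "sound"
    stim_interval_s: float = 60.1
    stim_jitter_s: float = 0.3
    first_stim_s: float = 20.0
    responder_fraction: float = 0.5
    # photometry
    transient_amplitude: float = 0.5
    rise_tau: float = 0.025
    decay_tau: float = 0.2
    evoked_latency_s: float = 0.15
    amplitude_jitter: float = 0.0
    background_rate_hz: float = 0.02
    habituation: tuple[float, float] | None = None  # linear first->last multiplier
    mixing: float = 1.0
    baseline_ca: float = 1.0
    baseline_iso: float = 1.0
    artifact_sd: float = 0.05
    raw_noise_sd: float = 0.003
    # behavior
    n_spontaneous_bouts: int = 6
    spontaneous_speed_range: tuple[float, float] = (5.0, 15.0)
    spontaneous_duration_range: tuple[float, float] = (0.6, 2.0)
    evoked_latency_range: tuple[float, float] = (0.5, 2.5)
    evoked_duration_range: tuple[float, float] = (0.8, 2.0)
    evoked_speed_range: tuple[float, float] = (8.0, 16.0)
    n_grooming: int = 2
    n_rearing: int = 2
    tracking_noise_px: float = 0.0

    @property
    def kernel(self) -> TransientKernel:
        return TransientKernel(self.rise_tau, self.decay_tau, self.transient_amplitude)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["habituation"] = list(self.habituation) if self.habituation else None
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k in (
            "spontaneous_speed_range",
            "spontaneous_duration_range",
            "evoked_latency_range",
            "evoked_duration_range",
            "evoked_speed_range",
            "habituation",
        ):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class SessionBundle:
    """One complete synthetic session plus its ground truth."""

    photometry: RawPhotometryRecording
    tracking: TrackingTable
    events: EventTable
    annotations: BoutSet
    truth: SessionGroundTruth
    config: SessionConfig

    def write(self, outdir) -> None:
        from . import io as pio
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_raw_h5(outdir / "raw.h5", self.photometry)
        self.tracking.to_dlc_csv(outdir / "tracking.csv")
        self.events.to_csv(outdir / "events.csv")
        self.annotations.to_csv(outdir / "annotations.csv")
        self.truth.to_json(outdir / "truth.json")
        self.config.to_yaml(outdir / "config.yaml")


def _place_in_zones(rng, zones, dur, occupied, margin=0.5):
    """Draw an onset inside free zones, avoiding occupied intervals."""
    for _ in range(200):
        lo, hi = zones[rng.integers(len(zones))]
        if hi - lo <= dur:
            continue
        onset = rng.uniform(lo, hi - dur)
        if all(onset + dur + margin <= a or onset >= b + margin for a, b in occupied):
            return onset
    return None


def synthesize_session(config: SessionConfig | None = None, seed: int = 0) -> SessionBundle:
    """Build a full session: photometry, tracking, events, annotations, truth."""
    cfg = config or SessionConfig()
    rng = np.random.default_rng(seed)

    # --- stimulus train ---------------------------------------------------
    onsets = (
        cfg.first_stim_s
        + cfg.stim_interval_s * np.arange(cfg.n_trials)
        + rng.uniform(-cfg.stim_jitter_s, cfg.stim_jitter_s, cfg.n_trials)
    )
    if cfg.n_trials and onsets[-1] + 15.0 > cfg.duration_s:
        raise ValueError(
            f"session of {cfg.duration_s} s too short for {cfg.n_trials} trials "
            f"at {cfg.stim_interval_s} s intervals"
        )
    events = EventTable(
        pd.DataFrame({"onset_s": onsets, "modality": cfg.modality})
    )

    # --- responders & habituation ----------------------------------------
    n_resp = int(round(cfg.responder_fraction * cfg.n_trials))
    responders = np.zeros(cfg.n_trials, dtype=bool)
    responders[rng.choice(cfg.n_trials, n_resp, replace=False)] = True
    if cfg.habituation is not None:
        h0, h1 = cfg.habituation
        hab = np.linspace(h0, h1, cfg.n_trials) if cfg.n_trials > 1 else np.array([h0])
    else:
        hab = np.ones(cfg.n_trials)

    # --- transients -------------------------------------------------------
    kernel = cfg.kernel
    t_onsets = list(onsets + cfg.evoked_latency_s)
    amps = list(cfg.transient_amplitude * hab)
    if cfg.amplitude_jitter > 0:
        amps = [
            max(a * (1.0 + rng.normal(0.0, cfg.amplitude_jitter)), 0.05 * cfg.transient_amplitude)
            for a in amps
        ]
    # background transients, kept clear of every stimulus transient
    n_bg = rng.poisson(cfg.background_rate_hz * cfg.duration_s)
    guard = 1.5
    placed = sorted(t_onsets)
    for _ in range(n_bg):
        for _ in range(50):
            cand = rng.uniform(5.0, cfg.duration_s - kernel.support - 5.0)
            if all(abs(cand - p) > guard for p in placed):
                t_onsets.append(cand)
                amps.append(cfg.transient_amplitude)
                placed.append(cand)
                break
    order = np.argsort(t_onsets)
    t_onsets = list(np.asarray(t_onsets)[order])
    amps = list(np.asarray(amps)[order])

    clean = superpose_transients(t_onsets, amps, kernel, cfg.duration_s, cfg.fs_raw)
    artifact = generate_motion_artifact(
        cfg.duration_s, cfg.fs_raw, cfg.artifact_sd, seed=rng
    )
    raw = synthesize_raw_photometry(
        clean,
        artifact,
        fs=cfg.fs_raw,
        baseline_ca=cfg.baseline_ca,
        baseline_iso=cfg.baseline_iso,
        mixing=cfg.mixing,
        noise_sd=cfg.raw_noise_sd,
        seed=rng,
    )

    # --- behavior plan ----------------------------------------------------
    # evoked bouts start inside the 5 s response window of responder trials
    plan: list[tuple[float, float, float]] = []
    for i in np.flatnonzero(responders):
        lat = rng.uniform(*cfg.evoked_latency_range)
        dur = rng.uniform(*cfg.evoked_duration_range)
        v = rng.uniform(*cfg.evoked_speed_range)
        plan.append((onsets[i] + lat, dur, v))
    # spontaneous bouts live in zones clear of every response window
    zones = _quiet_zones(onsets, cfg.duration_s)
    occupied = [(on, on + d) for on, d, _ in plan]
    for _ in range(cfg.n_spontaneous_bouts):
        dur = rng.uniform(*cfg.spontaneous_duration_range)
        onset = _place_in_zones(rng, zones, dur, occupied)
        if onset is None:
            continue
        v = rng.uniform(*cfg.spontaneous_speed_range)
        plan.append((onset, dur, v))
        occupied.append((onset, onset + dur))

    tracking, true_bouts = synthesize_tracking(
        plan,
        duration=cfg.duration_s,
        arena_cm=cfg.arena_cm,
        fps=cfg.fps,
        px_per_cm=cfg.px_per_cm,
        noise_px=cfg.tracking_noise_px,
        seed=rng,
    )

    # --- annotations (mouse treated as stationary during these) ----------
    ann_rows = []
    for kind, count, dur_rng_ in (
        ("grooming", cfg.n_grooming, (4.0, 9.0)),
        ("rearing", cfg.n_rearing, (2.5, 5.0)),
    ):
        for _ in range(count):
            dur = rng.uniform(*dur_rng_)
            onset = _place_in_zones(rng, zones, dur, occupied, margin=1.0)
            if onset is None:
                continue
            ann_rows.append(
                {"onset_s": onset, "offset_s": onset + dur, "kind": kind, "source": "manual"}
            )
            occupied.append((onset, onset + dur))
    annotations = (
        BoutSet(pd.DataFrame(ann_rows, columns=["onset_s", "offset_s", "kind", "source"]))
        if ann_rows
        else BoutSet()
    )

    truth = SessionGroundTruth(
        transient_onsets=[float(v) for v in t_onsets],
        transient_times=[float(v + kernel.peak_time) for v in t_onsets],
        transient_amplitudes=[float(a) for a in amps],
        true_bouts=true_bouts,
        true_response_flags=[bool(r) for r in responders],
        mixing_coefficient=cfg.mixing,
        habituation_decay=[float(h) for h in hab],
    )
    return SessionBundle(
        photometry=raw,
        tracking=tracking,
        events=events,
        annotations=annotations,
        truth=truth,
        config=cfg,
    )


def synthesize_speed_coupled_session(
    slope: float = 0.1,
    n_bouts: int = 40,
    noise_sd: float = 0.5,
    speed_range: tuple[float, float] = (4.0, 15.0),
    bout_duration: float = 1.5,
    fps: float = 20.0,
    rate: float = 100.0,
    seed: int | np.random.Generator = 0,
):
    """Processed-level session with a programmed linear Z-vs-speed coupling.

    Builds a speed trace of constant-speed locomotor bouts and a Z trace
    equal to ``slope`` x speed plus white noise, for validating the
    speed-binned regression's slope recovery.  Returns
    ``(bouts, signal, speed)``.
    """
    from .behavior import SpeedTrace
    from .signal_processing import ProcessedSignal

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gap = 10.0
    duration = (bout_duration + gap) * n_bouts + gap
    n_frames = int(round(duration * fps))
    speeds = np.zeros(n_frames)
    intervals = []
    n_bout_frames = int(round(bout_duration * fps))
    for k in range(n_bouts):
        onset = gap + (bout_duration + gap) * k
        v = rng.uniform(*speed_range)
        i0 = int(round(onset * fps))
        # plateau extends one frame past the bout offset so the interpolated
        # Z trace is constant across the half-open bout window
        speeds[i0 : i0 + n_bout_frames + 1] = v
        intervals.append((i0 / fps, (i0 + n_bout_frames) / fps))
    speed = SpeedTrace(
        time=np.arange(n_frames) / fps, speed=speeds, fps=fps, scale=0.1
    )
    t = np.arange(int(round(duration * rate))) / rate
    z = slope * np.interp(t, speed.time, speeds)
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, t.size)
    signal = ProcessedSignal(z=z, rate=rate)
    bouts = BoutSet.from_intervals(intervals, kind="locomotion", source="detected")
    return bouts, signal, speed


def _quiet_zones(onsets, duration, pre=2.0, post=7.0, edge=5.0):
    """Intervals clear of every stimulus response window."""
    zones = []
    lo = edge
    for t0 in list(onsets) + [duration + post]:
        hi = t0 - pre
        if hi - lo > 1.0:
            zones.append((lo, min(hi, duration - edge)))
        lo = t0 + post
    return [(a, b) for a, b in zones if b > a + 1.0]
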