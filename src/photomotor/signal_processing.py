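"""Isosbestic correction, Butterworth detrending/smoothing, and Z-scoring.

The two demodulated channels are reduced to one motion-corrected Ca2+
trace: the isosbestic channel (Ca2+-independent, so it carries only motion
and bleaching artifacts) is subtracted from the Ca2+ channel, the
difference is detrended with a 3rd-order 0.0051 Hz high-pass and smoothed
with a 5th-order 2.29 Hz low-pass Butterworth filter, and the result is
normalized per recording as a Z-score, z = (signal - mean) / SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .demodulation import ChannelTrace

__all__ = [
    "FilterSpec",
    "ProcessedSignal",
    "fit_isosbestic",
    "subtract_isosbestic",
    "bandpass_detrend",
    "zscore_trace",
    "process_photometry",
]

#: recordings shorter than this cannot be detrended reliably by the
#: 0.0051 Hz high-pass (its time constant is on the order of 200 s)
MIN_RELIABLE_DURATION_S = 600.0


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth detrend/smooth cascade parameters.

    Defaults are a 3rd-order high-pass at 0.0051 Hz (removes bleaching
    drift) followed by a 5th-order low-pass at 2.29 Hz (removes demodulation
    residue above indicator kinetics).  ``phase_mode='zero_phase'`` applies
    each filter forward-backward so event latencies are not shifted;
    ``'causal'`` applies a single forward pass.
    """

    hp_order: int = 3
    hp_cutoff: float = 0.0051
    lp_order: int = 5
    lp_cutoff: float = 2.29
    phase_mode: str = "zero_phase"

    def __post_init__(self) -> None:
        if self.phase_mode not in ("zero_phase", "causal"):
            raise ValueError(f"unknown phase_mode {self.phase_mode!r}")
        if not 0 < self.hp_cutoff < self.lp_cutoff:
            raise ValueError("need 0 < hp_cutoff < lp_cutoff")


@dataclass
class ProcessedSignal:
    """Per-recording Z-scored Ca2+ trace on a uniform grid.

    The Z statistics (mean, SD with n-1 denominator) are computed over the
    scored span only — settling edges flagged by the demodulator are
    excluded — so ``z[scored_mask]`` has mean 0 and SD 1 to numerical
    precision.
    """

    z: np.ndarray
    rate: float
    t0: float = 0.0
    scored_mask: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.all(np.isfinite(self.z)):
            raise ValueError("processed signal contains non-finite values")
        if self.scored_mask is None:
            self.scored_mask = np.ones(self.z.size, dtype=bool)
        self.scored_mask = np.asarray(self.scored_mask, dtype=bool)

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.z.size) / self.rate


def fit_isosbestic(ca: ChannelTrace, iso: ChannelTrace) -> tuple[float, float]:
    """Least-squares affine fit ``ca ~ a * iso + b`` over the full recording."""
    _check_aligned(ca, iso)
    a, b = np.polyfit(iso.value, ca.value, 1)
    return float(a), float(b)


def subtract_isosbestic(
    ca: ChannelTrace, iso: ChannelTrace, method: str = "fitted"
) -> ChannelTrace:
    """Remove the shared motion/bleaching component using the isosbestic channel.

    ``method='fitted'`` (default) scales the isosbestic trace by an affine
    least-squares fit before subtracting, which is correct whenever the two
    channels have different gains; ``'direct'`` subtracts it unscaled.  A
    zero-variance isosbestic channel under ``fitted`` falls back to
    ``direct`` with a warning.
    """
    _check_aligned(ca, iso)
    if method == "direct":
        out = ca.value - iso.value
    elif method == "fitted":
        if np.ptp(iso.value) == 0.0:
            warnings.warn(
                "isosbestic channel has zero variance; falling back to direct "
                "subtraction",
                stacklevel=2,
            )
            out = ca.value - iso.value
        else:
            a, b = fit_isosbestic(ca, iso)
            out = ca.value - (a * iso.value + b)
    else:
        raise ValueError(f"unknown subtraction method {method!r}")
    return ca.with_value(out)


def bandpass_detrend(trace: ChannelTrace, spec: FilterSpec | None = None) -> ChannelTrace:
    """High-pass then low-pass Butterworth cascade per ``spec``."""
    spec = spec or FilterSpec()
    if spec.lp_cutoff >= trace.rate / 2.0:
        raise ValueError(
            f"low-pass cutoff {spec.lp_cutoff} Hz is not below Nyquist "
            f"({trace.rate / 2.0} Hz)"
        )
    duration = trace.value.size / trace.rate
    if duration < MIN_RELIABLE_DURATION_S:
        warnings.warn(
            f"recording of {duration:.0f} s is short for the {spec.hp_cutoff} Hz "
            "high-pass (time constant ~200 s); detrending may be unreliable",
            stacklevel=2,
        )
    hp = sps.butter(spec.hp_order, spec.hp_cutoff, "high", fs=trace.rate, output="sos")
    lp = sps.butter(spec.lp_order, spec.lp_cutoff, "low", fs=trace.rate, output="sos")
    x = trace.value
    if spec.phase_mode == "zero_phase":
        x = sps.sosfiltfilt(hp, x)
        x = sps.sosfiltfilt(lp, x)
    else:
        x = sps.sosfilt(hp, x)
        x = sps.sosfilt(lp, x)
    return trace.with_value(x)


def zscore_trace(trace: ChannelTrace, provenance: dict | None = None) -> ProcessedSignal:
    """Normalize per recording: z = (x - mean) / SD over the scored span.

    Sample SD (n-1 denominator).  Settling edges flagged by the demodulator
    are excluded from the statistics but still reported (as Z values under
    the scored-span normalization).
    """
    mask = trace.scored_mask
    x = trace.value[mask]
    if x.size < 2:
        raise ValueError("need at least 2 samples within the scored span")
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate signal: zero standard deviation")
    z = (trace.value - mu) / sd
    return ProcessedSignal(
        z=z,
        rate=trace.rate,
        t0=trace.t0,
        scored_mask=mask,
        provenance=dict(provenance or {}, mean=mu, sd=sd),
    )


def process_photometry(
    ca: ChannelTrace,
    iso: ChannelTrace,
    spec: FilterSpec | None = None,
    method: str = "fitted",
) -> ProcessedSignal:
    """Full channel-to-Z pipeline: subtract, detrend/smooth, Z-score."""
    spec = spec or FilterSpec()
    corrected = subtract_isosbestic(ca, iso, method=method)
    filtered = bandpass_detrend(corrected, spec)
    prov = {"subtraction": method, "filter": asdict(spec)}
    return zscore_trace(filtered, provenance=prov)


def _check_aligned(a: ChannelTrace, b: ChannelTrace) -> None:
    if a.value.size != b.value.size:
        raise ValueError("channel traces differ in length")
    if not np.isclose(a.rate, b.rate) or not np.isclose(a.t0, b.t0):
        raise ValueError("channel traces are not on the same time base")
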