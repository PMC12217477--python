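"""Recovery scoring: peak detection and interval/event matching.

Used to compare pipeline output against synthetic ground truth (and by the
round-trip tests): transient peaks found in the processed trace are matched
to injected peak times within a tolerance; detected bout intervals are
scored for precision and recall against the true intervals.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .behavior import BoutSet
from .signal_processing import ProcessedSignal

__all__ = [
    "find_transient_peaks",
    "match_times",
    "score_intervals",
    "measure_filter_cutoffs",
]


def measure_filter_cutoffs(
    spec=None, rate: float = 10.0, n: int = 2**21, seed: int = 0
) -> tuple[float, float]:
    """Empirical -3 dB points of the single-pass detrend/smooth filters.

    White noise is passed once (causally) through the high-pass/low-pass
    cascade; the Welch PSD ratio of output to input estimates |H(f)|^2, and
    Butterworth magnitude curves of the spec's orders are least-squares
    fitted around each nominal corner with the corner frequency free.
    Returns the fitted (hp_cutoff, lp_cutoff) in Hz.
    """
    from dataclasses import replace as _replace

    from scipy.optimize import curve_fit

    from .demodulation import ChannelTrace
    from .signal_processing import FilterSpec, bandpass_detrend

    spec = spec or FilterSpec()
    spec = _replace(spec, phase_mode="causal")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    tr = ChannelTrace(x, rate=rate)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        y = bandpass_detrend(tr, spec).value
    nper = 2**16
    f, pxx = sps.welch(x, fs=rate, nperseg=nper)
    _, pyy = sps.welch(y, fs=rate, nperseg=nper)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = pyy / pxx

    def hp_mag2(freq, fc):
        r = (freq / fc) ** (2 * spec.hp_order)
        return r / (1.0 + r)

    def lp_mag2(freq, fc):
        return 1.0 / (1.0 + (freq / fc) ** (2 * spec.lp_order))

    hp_band = (f > spec.hp_cutoff / 3) & (f < spec.hp_cutoff * 3)
    lp_band = (f > spec.lp_cutoff / 3) & (f < min(spec.lp_cutoff * 1.8, 0.95 * rate / 2))
    hp_fit, _ = curve_fit(hp_mag2, f[hp_band], ratio[hp_band], p0=[spec.hp_cutoff])
    # divide out the fitted high-pass before fitting the low-pass corner
    lp_fit, _ = curve_fit(
        lp_mag2,
        f[lp_band],
        ratio[lp_band] / hp_mag2(f[lp_band], hp_fit[0]),
        p0=[spec.lp_cutoff],
    )
    return float(hp_fit[0]), float(lp_fit[0])


def find_transient_peaks(
    signal: ProcessedSignal,
    min_prominence_mads: float = 5.0,
    min_separation_s: float = 0.3,
) -> np.ndarray:
    """Times of prominent peaks in a Z-scored trace.

    The prominence floor is set robustly: ``min_prominence_mads`` times the
    median absolute deviation of the scored span (scaled to SD units), so
    large transients do not inflate their own detection threshold.
    """
    z = signal.z
    scored = z[signal.scored_mask]
    mad_sd = 1.4826 * np.median(np.abs(scored - np.median(scored)))
    prom = min_prominence_mads * max(mad_sd, 1e-12)
    distance = max(1, int(round(min_separation_s * signal.rate)))
    idx, _ = sps.find_peaks(z, prominence=prom, distance=distance)
    return signal.time[idx]


def match_times(
    detected: np.ndarray, truth: np.ndarray, tolerance: float
) -> tuple[int, np.ndarray]:
    """Greedy one-to-one matching of detected to true times.

    Returns (number of true events matched, per-true-event hit mask)."""
    detected = np.sort(np.asarray(detected, dtype=float))
    truth = np.asarray(truth, dtype=float)
    used = np.zeros(detected.size, dtype=bool)
    hit = np.zeros(truth.size, dtype=bool)
    for k, t in enumerate(truth):
        if detected.size == 0:
            break
        err = np.abs(detected - t)
        err[used] = np.inf
        j = int(np.argmin(err))
        if err[j] <= tolerance:
            used[j] = True
            hit[k] = True
    return int(hit.sum()), hit


def score_intervals(
    detected: BoutSet, truth: BoutSet, tol_s: float = 0.051
) -> dict[str, float]:
    """Precision/recall of detected intervals against true intervals.

    Two intervals match when both endpoints agree within ``tol_s`` (one
    frame period at 20 fps, by default)."""
    det = detected.table[["onset_s", "offset_s"]].to_numpy(dtype=float)
    tru = truth.table[["onset_s", "offset_s"]].to_numpy(dtype=float)
    used = np.zeros(len(det), dtype=bool)
    n_hit = 0
    for a, b in tru:
        for j in range(len(det)):
            if used[j]:
                continue
            if abs(det[j, 0] - a) <= tol_s and abs(det[j, 1] - b) <= tol_s:
                used[j] = True
                n_hit += 1
                break
    precision = n_hit / len(det) if len(det) else float("nan")
    recall = n_hit / len(tru) if len(tru) else float("nan")
    return {
        "n_detected": float(len(det)),
        "n_true": float(len(tru)),
        "n_matched": float(n_hit),
        "precision": precision,
        "recall": recall,
    }
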