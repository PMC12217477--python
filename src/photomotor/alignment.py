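"""Trial and bout alignment of the processed Ca2+ signal.

Stimulus trials are cut into raw-time epochs from -5 s to +10 s around the
(modality-aligned) onset, with locomotor speed averaged into 50 ms bins.
Variable-duration motor events (locomotion, grooming, rearing) are instead
mapped onto normalized time u = (t - onset) / duration, so onset is 0 and
offset is 1, and averaged over the span -0.5..1.5 into fixed bins: 0.002 of
normalized time for the photometry signal, 0.05 for the motor parameter.
Window means (pre/during/post for stimuli; pre/first-half/second-half/post
for motor events) feed the statistics layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import BoutSet, EventTable, SpeedTrace
from .signal_processing import ProcessedSignal

__all__ = [
    "AlignedEpochs",
    "NormalizedEpochs",
    "EpochSummary",
    "extract_stimulus_epochs",
    "extract_normalized_epochs",
    "summarize_epochs",
    "split_by_response",
    "STIMULUS_WINDOW",
    "SPEED_BIN_S",
    "NORMALIZED_SPAN",
    "PHOTOMETRY_BIN_NORM",
    "MOTOR_BIN_NORM",
    "WINDOW_SCHEMES",
]

STIMULUS_WINDOW = (-5.0, 10.0)
SPEED_BIN_S = 0.05
NORMALIZED_SPAN = (-0.5, 1.5)
PHOTOMETRY_BIN_NORM = 0.002
MOTOR_BIN_NORM = 0.05

#: named half-open windows [a, b) for epoch summaries
WINDOW_SCHEMES: dict[str, dict[str, tuple[float, float]]] = {
    "stimulus": {"pre": (-5.0, 0.0), "during": (0.0, 5.0), "post": (5.0, 10.0)},
    "motor": {
        "pre": (-0.5, 0.0),
        "first_half": (0.0, 0.5),
        "second_half": (0.5, 1.0),
        "post": (1.0, 1.5),
    },
}


@dataclass
class AlignedEpochs:
    """Trial x time matrix of Z-scores on a shared relative time axis."""

    matrix: np.ndarray  # trials x samples
    time_axis: np.ndarray  # seconds relative to alignment point
    companion_speed: np.ndarray | None  # trials x 50 ms bins, NaN = empty bin
    speed_bin_centers: np.ndarray | None
    trial_meta: pd.DataFrame
    n_dropped: int = 0
    scheme: str = "stimulus"

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def mean_trace(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


@dataclass
class NormalizedEpochs:
    """Bout x normalized-time-bin matrix; bin edges land exactly on 0 and 1."""

    matrix: np.ndarray  # bouts x 1000 bins, NaN = empty bin
    bin_centers: np.ndarray
    companion: np.ndarray | None  # bouts x 40 motor bins
    companion_centers: np.ndarray | None
    bout_meta: pd.DataFrame
    n_dropped: int = 0
    scheme: str = "motor"

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def mean_trace(self) -> np.ndarray:
        """Cross-bout mean per bin, ignoring empty (missing) bins."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.matrix, axis=0)


@dataclass
class EpochSummary:
    """Per-trial (or per-bout) mean Z in each named window."""

    table: pd.DataFrame  # meta columns + one column per window
    scheme: str
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def window_names(self) -> list[str]:
        return list(self.windows)

    def values(self) -> np.ndarray:
        """Rows x windows matrix of means."""
        return self.table[self.window_names].to_numpy(dtype=float)


def extract_stimulus_epochs(
    signal: ProcessedSignal,
    speed: SpeedTrace | None,
    events: EventTable,
    window: tuple[float, float] = STIMULUS_WINDOW,
    speed_bin: float = SPEED_BIN_S,
) -> AlignedEpochs:
    """Cut raw-time epochs around each (alignment-offset) stimulus onset.

    The Z trace is interpolated onto a common relative axis at the signal
    rate; locomotor speed is averaged into ``speed_bin``-wide bins over the
    same window.  Trials whose window is not fully covered by the recording
    are dropped with a warning.
    """
    lo, hi = window
    axis = np.arange(round((hi - lo) * signal.rate)) / signal.rate + lo
    t_sig = signal.time
    n_bins = int(round((hi - lo) / speed_bin))
    bin_edges = lo + speed_bin * np.arange(n_bins + 1)
    bin_centers = (bin_edges[:-1] + bin_edges[1:]) / 2.0

    rows, speeds, meta = [], [], []
    n_dropped = 0
    aligned = events.aligned_onsets
    for k, (_, ev) in enumerate(events.table.iterrows()):
        t_align = aligned[k]
        if t_align + lo < t_sig[0] or t_align + hi > t_sig[-1]:
            n_dropped += 1
            continue
        rows.append(np.interp(t_align + axis, t_sig, signal.z))
        if speed is not None:
            rel = speed.time - t_align
            sel = (rel >= lo) & (rel < hi) & speed.valid
            # epsilon keeps frames that land on a bin edge (up to float
            # error) in the left-closed bin they belong to
            idx = np.floor((rel[sel] - lo) / speed_bin + 1e-9).astype(int)
            idx = np.clip(idx, 0, n_bins - 1)
            sums = np.bincount(idx, weights=speed.speed[sel], minlength=n_bins)
            cnts = np.bincount(idx, minlength=n_bins)
            with np.errstate(invalid="ignore"):
                speeds.append(sums / cnts)
        meta.append(
            {
                "onset_s": float(ev["onset_s"]),
                "modality": ev["modality"],
                "series_id": ev["series_id"],
                "trial_index": ev["trial_index"],
            }
        )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} trial(s) with incomplete epoch coverage",
            stacklevel=2,
        )
    if not rows:
        raise ValueError("no usable trials: every epoch window falls outside the recording")
    return AlignedEpochs(
        matrix=np.vstack(rows),
        time_axis=axis,
        companion_speed=np.vstack(speeds) if speeds else None,
        speed_bin_centers=bin_centers if speeds else None,
        trial_meta=pd.DataFrame(meta),
        n_dropped=n_dropped,
    )


def extract_normalized_epochs(
    signal: ProcessedSignal,
    motor: SpeedTrace | None,
    bouts: BoutSet,
    span: tuple[float, float] = NORMALIZED_SPAN,
    signal_bin: float = PHOTOMETRY_BIN_NORM,
    motor_bin: float = MOTOR_BIN_NORM,
) -> NormalizedEpochs:
    """Average signal (and motor parameter) onto the normalized-time grid.

    For a bout of duration D a sample at time t has normalized time
    u = (t - onset) / D; samples with u in ``span`` are averaged into fixed
    bins whose edges are anchored on 0 (onset) and 1 (offset).  Empty bins
    are NaN.  Bouts whose absolute window is not fully inside the recording
    are dropped with a warning.
    """
    lo, hi = span
    n_sig = int(round((hi - lo) / signal_bin))
    sig_edges = lo + signal_bin * np.arange(n_sig + 1)
    sig_centers = (sig_edges[:-1] + sig_edges[1:]) / 2.0
    n_mot = int(round((hi - lo) / motor_bin))
    mot_edges = lo + motor_bin * np.arange(n_mot + 1)
    mot_centers = (mot_edges[:-1] + mot_edges[1:]) / 2.0

    t_sig = signal.time
    rows, mot_rows, meta = [], [], []
    n_dropped = 0
    for _, b in bouts.table.iterrows():
        onset, offset = float(b["onset_s"]), float(b["offset_s"])
        dur = offset - onset
        if dur <= 0:
            raise ValueError(f"bout at {onset} s has non-positive duration")
        t_lo, t_hi = onset + lo * dur, onset + hi * dur
        if t_lo < t_sig[0] or t_hi > t_sig[-1]:
            n_dropped += 1
            continue
        rows.append(
            _bin_by_normalized_time(t_sig, signal.z, None, onset, dur, lo, signal_bin, n_sig)
        )
        if motor is not None:
            mot_rows.append(
                _bin_by_normalized_time(
                    motor.time, motor.speed, motor.valid, onset, dur, lo, motor_bin, n_mot
                )
            )
        meta.append(
            {"onset_s": onset, "offset_s": offset, "duration_s": dur, "kind": b["kind"]}
        )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} bout(s) with incomplete normalized-window coverage",
            stacklevel=2,
        )
    if not rows:
        raise ValueError("no usable bouts for normalized-time extraction")
    return NormalizedEpochs(
        matrix=np.vstack(rows),
        bin_centers=sig_centers,
        companion=np.vstack(mot_rows) if mot_rows else None,
        companion_centers=mot_centers if mot_rows else None,
        bout_meta=pd.DataFrame(meta),
        n_dropped=n_dropped,
    )


def _bin_by_normalized_time(t, x, valid, onset, dur, lo, width, n_bins):
    u = (t - onset) / dur
    sel = (u >= lo) & (u < lo + width * n_bins) & np.isfinite(x)
    if valid is not None:
        sel &= valid
    idx = np.floor((u[sel] - lo) / width + 1e-9).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    sums = np.bincount(idx, weights=x[sel], minlength=n_bins)
    cnts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        return sums / cnts


def summarize_epochs(
    epochs: AlignedEpochs | NormalizedEpochs, scheme: str | None = None
) -> EpochSummary:
    """Arithmetic mean of in-window samples per trial/bout.

    Windows are half-open [a, b): shared endpoints are never counted twice.
    A window with no samples yields NaN with a warning.
    """
    if scheme is None:
        scheme = epochs.scheme
    if scheme not in WINDOW_SCHEMES:
        raise ValueError(f"unknown window scheme {scheme!r}")
    windows = WINDOW_SCHEMES[scheme]
    if isinstance(epochs, AlignedEpochs):
        axis = epochs.time_axis
        meta = epochs.trial_meta
    else:
        axis = epochs.bin_centers
        meta = epochs.bout_meta

    out = meta.copy()
    for name, (a, b) in windows.items():
        in_win = (axis >= a) & (axis < b)
        sub = epochs.matrix[:, in_win]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(sub, axis=1) if sub.size else np.full(len(out), np.nan)
        if sub.size == 0 or np.any(np.all(np.isnan(sub), axis=1)):
            warnings.warn(f"window {name!r} has rows with no samples", stacklevel=2)
        out[name] = means
    return EpochSummary(table=out, scheme=scheme, windows=dict(windows))


def split_by_response(
    summary: EpochSummary,
    flags: pd.Series | np.ndarray,
    window: str = "during",
    mouse: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-mouse paired means of the during-window Z: response vs no response.

    ``flags`` holds one boolean per summary row; ``mouse`` groups rows by
    animal (a single animal is assumed when omitted).  Mice lacking either
    responsive or non-responsive trials are excluded, mirroring the rule
    that mice without locomotor trials or without non-locomotor trials do
    not enter the paired comparison.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.size != len(summary.table):
        raise ValueError("one response flag per summary row is required")
    mouse_ids = (
        np.zeros(flags.size, dtype=int) if mouse is None else np.asarray(mouse)
    )
    vals = summary.table[window].to_numpy(dtype=float)
    rows = []
    for m in pd.unique(mouse_ids):
        sel = mouse_ids == m
        r, nr = vals[sel & flags], vals[sel & ~flags]
        if r.size == 0 or nr.size == 0:
            continue
        rows.append(
            {
                "mouse": m,
                "response_mean": float(r.mean()),
                "no_response_mean": float(nr.mean()),
                "n_response": int(r.size),
                "n_no_response": int(nr.size),
            }
        )
    if not rows:
        warnings.warn(
            "no mouse has both responsive and non-responsive trials", stacklevel=2
        )
    return pd.DataFrame(
        rows,
        columns=["mouse", "response_mean", "no_response_mean", "n_response", "n_no_response"],
    )
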