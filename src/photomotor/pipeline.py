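"""End-to-end session analysis: raw voltage + tracking to statistics.

Glues the stages together in the order an experimenter would run them:
demodulate both carriers, isosbestic-correct / detrend / Z-score, QC the
tracking and compute speed, detect locomotor bouts, classify per-trial
locomotor responses, extract stimulus-aligned and bout-aligned epochs, and
summarize window means.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import alignment, behavior, demodulation, signal_processing
from .behavior import BoutSet, EventTable, SpeedTrace, TrackingTable
from .demodulation import RawPhotometryRecording
from .signal_processing import FilterSpec, ProcessedSignal

__all__ = ["SessionResult", "analyze_session"]


@dataclass
class SessionResult:
    """All intermediate and final products of one session's analysis."""

    signal: ProcessedSignal
    speed: SpeedTrace
    qc: behavior.QCResult
    bouts: BoutSet
    response_flags: pd.DataFrame
    response_proportion: float
    stimulus_epochs: alignment.AlignedEpochs | None
    stimulus_summary: alignment.EpochSummary | None
    bout_epochs: alignment.NormalizedEpochs | None
    bout_summary: alignment.EpochSummary | None


def analyze_session(
    raw: RawPhotometryRecording,
    tracking: TrackingTable,
    events: EventTable | None = None,
    annotations: BoutSet | None = None,
    filter_spec: FilterSpec | None = None,
    subtraction: str = "fitted",
    output_rate: float = demodulation.DEFAULT_OUTPUT_RATE,
    arena_side_cm: float = 40.0,
) -> SessionResult:
    """Run the full pipeline on one session."""
    ca, iso = demodulation.demodulate_channels(raw, output_rate=output_rate)
    signal = signal_processing.process_photometry(
        ca, iso, spec=filter_spec, method=subtraction
    )

    scale = behavior.compute_calibration(tracking.corners, arena_side_cm)
    qc = behavior.qc_filter_positions(tracking, scale)
    speed = behavior.compute_speed(tracking, qc.valid, scale)
    bouts = behavior.detect_bouts(speed)

    flags = pd.DataFrame()
    proportion = float("nan")
    stim_epochs = stim_summary = None
    if events is not None and len(events):
        flags, proportion = behavior.classify_stimulus_responses(events, speed)
        stim_epochs = alignment.extract_stimulus_epochs(signal, speed, events)
        stim_summary = alignment.summarize_epochs(stim_epochs, "stimulus")

    bout_epochs = bout_summary = None
    if len(bouts):
        bout_epochs = alignment.extract_normalized_epochs(signal, speed, bouts)
        bout_summary = alignment.summarize_epochs(bout_epochs, "motor")

    return SessionResult(
        signal=signal,
        speed=speed,
        qc=qc,
        bouts=bouts,
        response_flags=flags,
        response_proportion=proportion,
        stimulus_epochs=stim_epochs,
        stimulus_summary=stim_summary,
        bout_epochs=bout_epochs,
        bout_summary=bout_summary,
    )
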