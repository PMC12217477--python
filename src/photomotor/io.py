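"""Readers and writers for the pipeline's on-disk formats.

Raw photometry lives in HDF5 (`/raw/voltage`, `/raw/time`, attrs ``fs`` and
``carrier_hz``); everything downstream is plain CSV with JSON sidecars for
provenance, so intermediate products stay inspectable.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .alignment import AlignedEpochs, EpochSummary, NormalizedEpochs
from .demodulation import ChannelTrace, RawPhotometryRecording
from .signal_processing import ProcessedSignal

__all__ = [
    "write_raw_h5",
    "read_raw_h5",
    "write_demodulated_csv",
    "read_demodulated_csv",
    "write_processed_csv",
    "read_processed_csv",
    "write_epochs_csv",
    "write_summary_csv",
]


def write_raw_h5(path, raw: RawPhotometryRecording) -> None:
    with h5py.File(path, "w") as fh:
        g = fh.create_group("raw")
        g.create_dataset("voltage", data=raw.voltage, compression="gzip")
        g.create_dataset("time", data=raw.time, compression="gzip")
        g.attrs["fs"] = raw.fs
        g.attrs["carrier_names"] = list(raw.carrier_hz.keys())
        g.attrs["carrier_hz"] = [raw.carrier_hz[k] for k in raw.carrier_hz]


def read_raw_h5(path) -> RawPhotometryRecording:
    with h5py.File(path, "r") as fh:
        g = fh["raw"]
        voltage = g["voltage"][:]
        t0 = float(g["time"][0]) if g["time"].shape[0] else 0.0
        names = [
            n.decode() if isinstance(n, bytes) else str(n)
            for n in g.attrs["carrier_names"]
        ]
        carriers = dict(zip(names, [float(v) for v in g.attrs["carrier_hz"]]))
        return RawPhotometryRecording(
            voltage=voltage, fs=float(g.attrs["fs"]), carrier_hz=carriers, t0=t0
        )


def write_demodulated_csv(path, ca: ChannelTrace, iso: ChannelTrace) -> None:
    pd.DataFrame({"time_s": ca.time, "ca": ca.value, "iso": iso.value}).to_csv(
        path, index=False
    )


def read_demodulated_csv(path) -> tuple[ChannelTrace, ChannelTrace]:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    rate = 1.0 / np.median(np.diff(t))
    ca = ChannelTrace(df["ca"].to_numpy(dtype=float), rate=rate, channel="ca", t0=t[0])
    iso = ChannelTrace(df["iso"].to_numpy(dtype=float), rate=rate, channel="iso", t0=t[0])
    return ca, iso


def write_processed_csv(path, sig: ProcessedSignal) -> None:
    """Processed trace plus a ``.provenance.json`` sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"time_s": sig.time, "z": sig.z, "scored": sig.scored_mask}
    ).to_csv(path, index=False)
    side = path.with_suffix(".provenance.json")
    with open(side, "w") as fh:
        json.dump(sig.provenance, fh, indent=1, default=float)


def read_processed_csv(path) -> ProcessedSignal:
    path = Path(path)
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    rate = 1.0 / np.median(np.diff(t))
    prov = {}
    side = path.with_suffix(".provenance.json")
    if side.exists():
        with open(side) as fh:
            prov = json.load(fh)
    mask = df["scored"].to_numpy(dtype=bool) if "scored" in df.columns else None
    return ProcessedSignal(
        z=df["z"].to_numpy(dtype=float), rate=rate, t0=t[0], scored_mask=mask, provenance=prov
    )


def write_epochs_csv(path, epochs: AlignedEpochs | NormalizedEpochs) -> None:
    """Wide matrix (one row per trial/bout, header = bin centers) + sidecar."""
    path = Path(path)
    if isinstance(epochs, AlignedEpochs):
        axis, meta = epochs.time_axis, epochs.trial_meta
    else:
        axis, meta = epochs.bin_centers, epochs.bout_meta
    wide = pd.DataFrame(epochs.matrix, columns=[f"{c:.4f}" for c in axis])
    wide.to_csv(path, index=False)
    side = path.with_suffix(".meta.json")
    with open(side, "w") as fh:
        json.dump(
            {
                "scheme": epochs.scheme,
                "n_dropped": epochs.n_dropped,
                "rows": meta.to_dict(orient="records"),
            },
            fh,
            indent=1,
            default=float,
        )


def write_summary_csv(path, summary: EpochSummary, mouse: str = "m1") -> None:
    """Tidy long format: mouse, row, window, mean_z."""
    long = summary.table.reset_index(names="row").melt(
        id_vars=["row"],
        value_vars=summary.window_names,
        var_name="window",
        value_name="mean_z",
    )
    long.insert(0, "mouse", mouse)
    long.to_csv(path, index=False)
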