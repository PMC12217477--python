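"""Open-field behavior: tracking QC, speed, locomotor bouts, responses.

Pose-tracking tables (body center, tail base, arena corners; 20 fps) are
converted to calibrated speed traces under three quality filters applied in
order — tracking likelihood < 0.8, position outside the arena polygon,
implied step speed above 334 cm/s (the fastest locomotion recorded in
mice).  A locomotor bout is a maximal run of frames with speed strictly
above 3 cm/s lasting at least 0.5 s.  A stimulus trial counts as a
locomotor response when a bout starts within 5 s of stimulus onset.
Manually scored grooming/rearing intervals are ingested from CSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "TrackingTable",
    "SpeedTrace",
    "BoutSet",
    "EventTable",
    "QCResult",
    "compute_calibration",
    "qc_filter_positions",
    "compute_speed",
    "detect_bouts",
    "classify_stimulus_responses",
    "load_annotations",
    "SPEED_THRESHOLD_CMS",
    "MIN_BOUT_DURATION_S",
    "MAX_MOUSE_SPEED_CMS",
    "LIKELIHOOD_MIN",
    "RESPONSE_WINDOW_S",
]

SPEED_THRESHOLD_CMS = 3.0
MIN_BOUT_DURATION_S = 0.5
MAX_MOUSE_SPEED_CMS = 334.0
LIKELIHOOD_MIN = 0.8
RESPONSE_WINDOW_S = 5.0

BOUT_KINDS = ("locomotion", "grooming", "rearing")
MODALITIES = ("sound", "looming", "airpuff")
#: the looming video's exponential disk expansion starts 0.803 s in; trials
#: of that modality are aligned to this offset
LOOMING_ALIGNMENT_OFFSET_S = 0.803

_BODY_PARTS = ("bodycenter", "tailbase", "corner1", "corner2", "corner3", "corner4")


@dataclass
class TrackingTable:
    """Per-frame body positions plus arena-corner coordinates (pixels)."""

    time: np.ndarray
    x: np.ndarray
    y: np.ndarray
    likelihood: np.ndarray
    corners: np.ndarray  # (4, 2) pixel coordinates
    fps: float = 20.0
    tailbase: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        self.corners = np.asarray(self.corners, dtype=float).reshape(4, 2)
        if not (self.time.size == self.x.size == self.y.size == self.likelihood.size):
            raise ValueError("tracking columns differ in length")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        lk = self.likelihood[np.isfinite(self.likelihood)]
        if lk.size and (lk.min() < 0 or lk.max() > 1):
            raise ValueError("likelihoods must lie in [0, 1]")

    def __len__(self) -> int:
        return self.time.size

    @classmethod
    def from_dlc_csv(cls, path, fps: float = 20.0) -> "TrackingTable":
        """Read the 3-header-row pose-tracking CSV dialect.

        Header rows are scorer / bodyparts / coords; each tracked part
        contributes x, y, likelihood columns.  Arena corners are taken as
        the per-part median position (they are static)."""
        df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
        df.columns = ["_".join(c[1:]) for c in df.columns]  # bodypart_coord

        def col(part, coord):
            name = f"{part}_{coord}"
            if name not in df.columns:
                raise ValueError(f"tracking file lacks column {name}")
            return df[name].to_numpy(dtype=float)

        n = len(df)
        corners = np.array(
            [
                [np.median(col(f"corner{i}", "x")), np.median(col(f"corner{i}", "y"))]
                for i in range(1, 5)
            ]
        )
        tail = None
        if "tailbase_x" in df.columns:
            tail = pd.DataFrame(
                {
                    "x": col("tailbase", "x"),
                    "y": col("tailbase", "y"),
                    "likelihood": col("tailbase", "likelihood"),
                }
            )
        return cls(
            time=np.arange(n) / fps,
            x=col("bodycenter", "x"),
            y=col("bodycenter", "y"),
            likelihood=col("bodycenter", "likelihood"),
            corners=corners,
            fps=fps,
            tailbase=tail,
        )

    def to_dlc_csv(self, path, scorer: str = "synthetic") -> None:
        """Write the 3-header-row pose-tracking CSV dialect."""
        n = len(self)
        data: dict[tuple, np.ndarray] = {}
        parts = {
            "bodycenter": (self.x, self.y, self.likelihood),
        }
        if self.tailbase is not None:
            parts["tailbase"] = (
                self.tailbase["x"].to_numpy(),
                self.tailbase["y"].to_numpy(),
                self.tailbase["likelihood"].to_numpy(),
            )
        for i, (cx, cy) in enumerate(self.corners, start=1):
            parts[f"corner{i}"] = (
                np.full(n, cx),
                np.full(n, cy),
                np.ones(n),
            )
        for part, (px, py, pl) in parts.items():
            data[(scorer, part, "x")] = px
            data[(scorer, part, "y")] = py
            data[(scorer, part, "likelihood")] = pl
        out = pd.DataFrame(data)
        out.columns = pd.MultiIndex.from_tuples(
            out.columns, names=["scorer", "bodyparts", "coords"]
        )
        out.to_csv(path, index_label=None)


@dataclass
class SpeedTrace:
    """Frame-wise locomotor speed in cm/s; NaN marks missing frames."""

    time: np.ndarray
    speed: np.ndarray
    fps: float
    scale: float  # cm per pixel

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.time.size != self.speed.size:
            raise ValueError("time and speed differ in length")
        v = self.speed[np.isfinite(self.speed)]
        if v.size and v.min() < 0:
            raise ValueError("speeds must be non-negative")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.speed)

    def __len__(self) -> int:
        return self.time.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "speed_cms": self.speed, "valid": self.valid}
        )


_BOUT_COLUMNS = ["onset_s", "offset_s", "kind", "source"]


@dataclass
class BoutSet:
    """Behavioral intervals (locomotion / grooming / rearing)."""

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_BOUT_COLUMNS)
    )

    def __post_init__(self) -> None:
        df = self.table.reset_index(drop=True)
        missing = [c for c in _BOUT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"bout table lacks columns {missing}")
        bad_kind = set(df["kind"]) - set(BOUT_KINDS)
        if bad_kind:
            raise ValueError(f"unknown bout kind(s) {sorted(bad_kind)}")
        if len(df) and not (df["onset_s"] < df["offset_s"]).all():
            raise ValueError("every bout needs onset < offset")
        for kind, grp in df.groupby("kind"):
            g = grp.sort_values("onset_s")
            if (g["onset_s"].to_numpy()[1:] < g["offset_s"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping {kind} bouts")
        self.table = df.sort_values("onset_s", ignore_index=True)

    @classmethod
    def from_intervals(cls, intervals, kind: str, source: str) -> "BoutSet":
        rows = [
            {"onset_s": float(a), "offset_s": float(b), "kind": kind, "source": source}
            for a, b in intervals
        ]
        return cls(pd.DataFrame(rows, columns=_BOUT_COLUMNS))

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.table[self.table["kind"] == kind].reset_index(drop=True)

    @property
    def durations(self) -> np.ndarray:
        return (self.table["offset_s"] - self.table["onset_s"]).to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class EventTable:
    """Stimulus trials: onset, modality, series and within-series index."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.reset_index(drop=True).copy()
        if "modality" not in df.columns or "onset_s" not in df.columns:
            raise ValueError("event table needs onset_s and modality columns")
        bad = set(df["modality"]) - set(MODALITIES)
        if bad:
            raise ValueError(f"unknown modality {sorted(bad)}")
        if "series_id" not in df.columns:
            df["series_id"] = 1
        if "trial_index" not in df.columns:
            df["trial_index"] = df.groupby("series_id").cumcount() + 1
        if "alignment_offset" not in df.columns:
            df["alignment_offset"] = np.where(
                df["modality"] == "looming", LOOMING_ALIGNMENT_OFFSET_S, 0.0
            )
        on = df["onset_s"].to_numpy(dtype=float)
        if on.size > 1 and np.any(np.diff(on) <= 0):
            raise ValueError("stimulus onsets must be strictly increasing")
        for sid, grp in df.groupby("series_id"):
            idx = grp["trial_index"].to_numpy()
            if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
                raise ValueError(f"trial_index not contiguous in series {sid}")
        self.table = df

    def __len__(self) -> int:
        return len(self.table)

    @property
    def onsets(self) -> np.ndarray:
        return self.table["onset_s"].to_numpy(dtype=float)

    @property
    def aligned_onsets(self) -> np.ndarray:
        """Onsets shifted by the modality alignment offset."""
        return self.onsets + self.table["alignment_offset"].to_numpy(dtype=float)

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compute_calibration(corners: np.ndarray, arena_side_cm: float = 40.0) -> float:
    """cm-per-pixel scale from the four arena corners.

    The corners are ordered around their centroid; the scale is the arena
    side length divided by the mean of the four side lengths in pixels.
    """
    pts = np.asarray(corners, dtype=float).reshape(4, 2)
    centroid = pts.mean(axis=0)
    order = np.argsort(np.arctan2(*(pts - centroid).T[::-1]))
    pts = pts[order]
    sides = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
    if np.any(sides <= 0):
        raise ValueError("degenerate arena quadrilateral (coincident corners)")
    # convexity: consistent turn direction at every vertex
    edges = np.roll(pts, -1, axis=0) - pts
    cross = np.cross(edges, np.roll(edges, -1, axis=0))
    if np.any(cross == 0) or not (np.all(cross > 0) or np.all(cross < 0)):
        raise ValueError("arena corners do not form a convex quadrilateral")
    return float(arena_side_cm / sides.mean())


@dataclass
class QCResult:
    """Validity mask plus per-rule exclusion counts (first rule wins)."""

    valid: np.ndarray
    counts: dict[str, int]

    @property
    def n_retained(self) -> int:
        return int(self.valid.sum())


def qc_filter_positions(
    tracking: TrackingTable,
    scale: float,
    likelihood_min: float = LIKELIHOOD_MIN,
    speed_max: float = MAX_MOUSE_SPEED_CMS,
) -> QCResult:
    """Frame QC in fixed order: likelihood, arena containment, step speed.

    A frame fails if its tracking likelihood is below ``likelihood_min``
    (strict), its position falls outside the convex polygon of the detected
    corners, or the step from the previous valid frame implies a speed
    above ``speed_max`` cm/s.  Each frame is counted against the first rule
    it fails.
    """
    n = len(tracking)
    valid = np.ones(n, dtype=bool)
    counts = {"likelihood": 0, "arena": 0, "speed": 0}

    low = tracking.likelihood < likelihood_min
    counts["likelihood"] = int(low.sum())
    valid &= ~low

    pts = np.asarray(tracking.corners, dtype=float)
    centroid = pts.mean(axis=0)
    order = np.argsort(np.arctan2(*(pts - centroid).T[::-1]))
    poly = shapely.Polygon(pts[order])
    inside = shapely.covers(poly, shapely.points(tracking.x, tracking.y))
    out = valid & ~inside
    counts["arena"] = int(out.sum())
    valid &= inside

    # sequential scan: a frame removed here cannot invalidate its successor
    for i in range(1, n):
        if valid[i] and valid[i - 1]:
            dt = tracking.time[i] - tracking.time[i - 1]
            step = np.hypot(
                tracking.x[i] - tracking.x[i - 1], tracking.y[i] - tracking.y[i - 1]
            )
            if scale * step / dt > speed_max:
                valid[i] = False
                counts["speed"] += 1
    return QCResult(valid=valid, counts=counts)


def compute_speed(
    tracking: TrackingTable, valid_mask: np.ndarray, scale: float
) -> SpeedTrace:
    """Frame-wise speed; defined only where a frame and its predecessor are valid."""
    t = tracking.time
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    valid_mask = np.asarray(valid_mask, dtype=bool)
    n = t.size
    speed = np.full(n, np.nan)
    dx = np.diff(tracking.x)
    dy = np.diff(tracking.y)
    dt = np.diff(t)
    pair_ok = valid_mask[1:] & valid_mask[:-1]
    speed[1:][pair_ok] = scale * np.hypot(dx, dy)[pair_ok] / dt[pair_ok]
    return SpeedTrace(time=t, speed=speed, fps=tracking.fps, scale=scale)


def detect_bouts(
    speed: SpeedTrace,
    threshold: float = SPEED_THRESHOLD_CMS,
    min_duration: float = MIN_BOUT_DURATION_S,
    kind: str = "locomotion",
) -> BoutSet:
    """Maximal supra-threshold runs lasting at least ``min_duration``.

    A run is a sequence of consecutive valid frames with speed strictly
    above ``threshold``; missing frames terminate it.  Each frame stands
    for one frame period, so a run's duration is (t_last - t_first) + 1/fps
    and its offset is t_last + 1/fps.
    """
    frame = 1.0 / speed.fps
    above = np.isfinite(speed.speed) & (speed.speed > threshold)
    intervals = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    # duration compared in whole frame periods so that e.g. ten 50 ms frames
    # make exactly 0.5 s without floating-point shortfall
    min_frames = min_duration * speed.fps - 1e-9
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_frames:
            intervals.append((speed.time[start], speed.time[stop - 1] + frame))
    return BoutSet.from_intervals(intervals, kind=kind, source="detected")


def classify_stimulus_responses(
    events: EventTable,
    speed: SpeedTrace,
    response_window: float = RESPONSE_WINDOW_S,
    threshold: float = SPEED_THRESHOLD_CMS,
    min_duration: float = MIN_BOUT_DURATION_S,
    mode: str = "onset",
) -> tuple[pd.DataFrame, float]:
    """Flag trials with a locomotor response in the post-stimulus window.

    A trial is responsive when a locomotor bout *starts* within
    ``(onset, onset + response_window]`` (``mode='onset'``, default; the
    bout may extend past the window) or, with ``mode='overlap'``, when any
    bout overlaps that window.  Trials whose window extends past the end of
    the recording are dropped with a warning.  Returns the per-trial table
    and the responsive proportion.
    """
    if mode not in ("onset", "overlap"):
        raise ValueError(f"unknown response mode {mode!r}")
    bouts = detect_bouts(speed, threshold=threshold, min_duration=min_duration)
    b_on = bouts.table["onset_s"].to_numpy()
    b_off = bouts.table["offset_s"].to_numpy()
    t_end = speed.time[-1] + 1.0 / speed.fps

    rows = []
    n_dropped = 0
    for _, ev in events.table.iterrows():
        t0 = float(ev["onset_s"])
        if t0 + response_window > t_end:
            n_dropped += 1
            continue
        if mode == "onset":
            hit = np.any((b_on > t0) & (b_on <= t0 + response_window))
        else:
            hit = np.any((b_off > t0) & (b_on <= t0 + response_window))
        rows.append(
            {
                "onset_s": t0,
                "modality": ev["modality"],
                "series_id": ev["series_id"],
                "trial_index": ev["trial_index"],
                "response": bool(hit),
            }
        )
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} trial(s) whose {response_window} s response "
            "window extends past the end of the recording",
            stacklevel=2,
        )
    flags = pd.DataFrame(
        rows, columns=["onset_s", "modality", "series_id", "trial_index", "response"]
    )
    proportion = float(flags["response"].mean()) if len(flags) else float("nan")
    return flags, proportion


def load_annotations(path) -> BoutSet:
    """Read manually scored grooming/rearing intervals from CSV.

    Expects columns onset_s, offset_s, behavior; rows failing validation
    are reported with their line number (header = line 1)."""
    df = pd.read_csv(path)
    if len(df) == 0:
        return BoutSet()
    needed = {"onset_s", "offset_s", "behavior"}
    if not needed.issubset(df.columns):
        raise ValueError(f"annotation file needs columns {sorted(needed)}")
    rows = []
    for i, row in df.iterrows():
        line = i + 2
        kind = str(row["behavior"]).strip().lower()
        if kind not in ("grooming", "rearing"):
            raise ValueError(f"line {line}: unknown behavior label {row['behavior']!r}")
        onset, offset = float(row["onset_s"]), float(row["offset_s"])
        if not offset > onset:
            raise ValueError(f"line {line}: offset {offset} not after onset {onset}")
        rows.append(
            {"onset_s": onset, "offset_s": offset, "kind": kind, "source": "manual"}
        )
    return BoutSet(pd.DataFrame(rows, columns=_BOUT_COLUMNS))
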