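"""Calcium-trace processing: ΔF/F0 normalization, peak detection and activity scores.

A culture is imaged for 45 s every few hours; each neuron contributes one raw
fluorescence trace per session.  The per-session "activity score" of a neuron
is the area under the peaks of its ΔF/F0 trace — a single number summarizing
how active the neuron was during that recording.  Scores assembled across
sessions form the neurons × sessions :class:`ActivityPattern` that every
rhythm statistic consumes.

Conventions (fixed here because the upstream protocol leaves them open):

* F0 is a low percentile of the raw trace (default 10th, linear-interpolation
  percentile), robust to sparse calcium transients.
* A peak is a run of at least ``min_frames`` consecutive frames with
  ΔF/F0 above ``noise_k`` times the robust noise scale of the trace
  (1.4826 × median absolute deviation, the SD-equivalent for Gaussian noise).
* The score integrates ΔF/F0 (clipped below at zero) over each peak segment
  with the trapezoidal rule, dt = 1/sampling_rate; units are ΔF/F0 · seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraceRecording",
    "DffTrace",
    "PeakSegment",
    "ActivityScoreRecord",
    "ActivityPattern",
    "estimate_baseline",
    "compute_dff",
    "detect_peaks",
    "activity_score",
    "assemble_pattern",
    "score_recordings",
    "read_traces_csv",
    "write_scores_csv",
]

MAD_TO_SD = 1.4826  # Gaussian consistency factor for the median absolute deviation


@dataclass
class TraceRecording:
    """One neuron's raw fluorescence recording at one clock time point.

    ``values`` are raw fluorescence in arbitrary units (finite, positive);
    nominal duration is 45 s at ``sampling_rate_hz`` frames per second.
    ``clock_time_h`` is a label in [0, 24); ``session_time_h`` is hours since
    the start of the experiment and orders the sessions.
    """

    neuron_id: str
    session_time_h: float
    clock_time_h: float
    sampling_rate_hz: float
    values: np.ndarray
    duration_s: float = 45.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("trace must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("raw fluorescence must be finite and positive")
        expected = round(self.sampling_rate_hz * self.duration_s)
        if abs(self.values.size - expected) > 1:
            raise ValueError(
                f"trace length {self.values.size} inconsistent with "
                f"{self.sampling_rate_hz} Hz x {self.duration_s} s (expected ~{expected})"
            )


@dataclass
class DffTrace:
    """Baseline-normalized trace: values[i] == (raw[i] - f0) / f0."""

    f0: float
    values: np.ndarray
    sampling_rate_hz: float
    peak_threshold: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class PeakSegment:
    """One peak: inclusive 0-based frame indices and its trapezoidal area (ΔF/F0·s)."""

    start_index: int
    end_index: int
    area: float = 0.0

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("start_index must be <= end_index")


@dataclass(frozen=True)
class ActivityScoreRecord:
    neuron_id: str
    session_time_h: float
    score: float
    n_peaks: int
    clock_time_h: float = float("nan")

    def __post_init__(self) -> None:
        if (self.score == 0) != (self.n_peaks == 0):
            raise ValueError("score must be 0 exactly when n_peaks is 0")


@dataclass
class ActivityPattern:
    """Neurons × sessions matrix of activity scores.

    The design must be complete (every neuron measured at every session);
    the repeated-measures statistics downstream require it.  When
    ``normalized`` is set each row was divided by its median score, so rows
    with positive raw median have median exactly 1.  Rows whose median was 0
    are left as-is and listed in ``zero_median_neurons``.
    """

    neuron_ids: list
    session_times_h: np.ndarray
    scores: np.ndarray
    normalized: bool = False
    clock_times_h: np.ndarray | None = None
    zero_median_neurons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.session_times_h = np.asarray(self.session_times_h, dtype=float)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.neuron_ids), self.session_times_h.size):
            raise ValueError("scores shape must be (n_neurons, n_sessions)")
        if np.any(np.diff(self.session_times_h) <= 0):
            raise ValueError("session_times_h must be strictly increasing")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("pattern contains non-finite scores")

    @property
    def n_neurons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_sessions(self) -> int:
        return self.scores.shape[1]

    def mean_scores(self) -> np.ndarray:
        """Mean score per session over neurons (the 'average firing pattern')."""
        return self.scores.mean(axis=0)


def estimate_baseline(recording: TraceRecording, percentile: float = 10.0) -> float:
    """F0 as a lower percentile of the raw trace.

    Uses numpy's linear-interpolation percentile convention.  ``percentile``
    must lie in (0, 50]; a low value makes F0 robust to sparse transients.
    """
    if not 0 < percentile <= 50:
        raise ValueError("percentile must be in (0, 50]")
    f0 = float(np.percentile(recording.values, percentile, method="linear"))
    if f0 <= 0 or not np.isfinite(f0):
        raise ValueError("baseline estimate must be positive and finite")
    return f0


def compute_dff(recording: TraceRecording, f0: float) -> DffTrace:
    """Elementwise (F - f0)/f0; invariant under a positive gain applied to both."""
    if f0 <= 0 or not np.isfinite(f0):
        raise ValueError("f0 must be positive and finite")
    return DffTrace(
        f0=float(f0),
        values=(recording.values - f0) / f0,
        sampling_rate_hz=recording.sampling_rate_hz,
    )


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean vector as inclusive (start, end) pairs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    return [(int(a), int(b - 1)) for a, b in zip(starts, stops)]


def detect_peaks(dff: DffTrace, noise_k: float = 3.0, min_frames: int = 3) -> list[PeakSegment]:
    """Peaks = maximal runs of >= min_frames frames with ΔF/F0 above the noise floor.

    The threshold is ``noise_k`` × (1.4826 × MAD of the whole ΔF/F0 trace).
    For a silent trace the MAD is dominated by noise, so the threshold sits at
    ``noise_k`` noise SDs; segments are disjoint and sorted by construction.
    The threshold used is stored on ``dff.peak_threshold``.
    """
    x = dff.values
    if not np.all(np.isfinite(x)):
        raise ValueError("ΔF/F0 trace must be finite")
    mad = np.median(np.abs(x - np.median(x)))
    threshold = noise_k * MAD_TO_SD * mad
    dff.peak_threshold = float(threshold)
    dt = 1.0 / dff.sampling_rate_hz
    segments = []
    for start, end in _runs_above(x > threshold):
        if end - start + 1 >= min_frames:
            area = float(np.trapezoid(np.clip(x[start : end + 1], 0.0, None), dx=dt))
            segments.append(PeakSegment(start, end, area))
    return segments


def activity_score(
    dff: DffTrace,
    segments: Sequence[PeakSegment],
    sampling_rate_hz: float | None = None,
    neuron_id: str = "",
    session_time_h: float = float("nan"),
    clock_time_h: float = float("nan"),
) -> ActivityScoreRecord:
    """Sum of trapezoidal areas of ΔF/F0 (clipped at 0) over the peak segments.

    Units: ΔF/F0 × seconds.  Zero segments means score 0.  Degenerate
    segments with zero integral (possible only for single-frame runs, which
    the default ``min_frames=3`` already excludes) do not count as peaks.
    """
    rate = sampling_rate_hz if sampling_rate_hz is not None else dff.sampling_rate_hz
    dt = 1.0 / rate
    n = dff.values.size
    total = 0.0
    prev_end = -1
    for seg in sorted(segments, key=lambda s: s.start_index):
        if seg.start_index <= prev_end:
            raise ValueError("peak segments must be disjoint")
        if seg.end_index >= n:
            raise ValueError("segment extends beyond the trace")
        prev_end = seg.end_index
        total += float(
            np.trapezoid(np.clip(dff.values[seg.start_index : seg.end_index + 1], 0.0, None), dx=dt)
        )
    n_peaks = len(segments) if total > 0 else 0
    return ActivityScoreRecord(
        neuron_id=neuron_id,
        session_time_h=session_time_h,
        score=total if n_peaks else 0.0,
        n_peaks=n_peaks,
        clock_time_h=clock_time_h,
    )


def score_recordings(
    recordings: Sequence[TraceRecording],
    baseline_percentile: float = 10.0,
    noise_k: float = 3.0,
    min_frames: int = 3,
) -> list[ActivityScoreRecord]:
    """Full per-recording pipeline: baseline → ΔF/F0 → peaks → activity score."""
    records = []
    for rec in recordings:
        f0 = estimate_baseline(rec, baseline_percentile)
        dff = compute_dff(rec, f0)
        segments = detect_peaks(dff, noise_k=noise_k, min_frames=min_frames)
        records.append(
            activity_score(
                dff,
                segments,
                neuron_id=rec.neuron_id,
                session_time_h=rec.session_time_h,
                clock_time_h=rec.clock_time_h,
            )
        )
    return records


def assemble_pattern(records: Sequence[ActivityScoreRecord], normalize: bool = False) -> ActivityPattern:
    """Pivot score records into a complete neurons × sessions matrix.

    Every (neuron, session) pair must be present exactly once; otherwise a
    ``ValueError`` lists the offending pairs.  With ``normalize`` each row is
    divided by its median score (rows with median 0 are kept unscaled and
    flagged — they still carry rank information for the Friedman test).
    """
    if not records:
        raise ValueError("no score records given")
    df = pd.DataFrame(
        {
            "neuron_id": [r.neuron_id for r in records],
            "session_time_h": [r.session_time_h for r in records],
            "clock_time_h": [r.clock_time_h for r in records],
            "score": [r.score for r in records],
        }
    )
    dup = df.duplicated(subset=["neuron_id", "session_time_h"])
    if dup.any():
        pairs = df.loc[dup, ["neuron_id", "session_time_h"]].values.tolist()
        raise ValueError(f"duplicated (neuron, session) records: {pairs}")
    wide = df.pivot(index="neuron_id", columns="session_time_h", values="score")
    if wide.isna().any().any():
        rows, cols = np.where(wide.isna().values)
        missing = [(str(wide.index[i]), float(wide.columns[j])) for i, j in zip(rows, cols)]
        raise ValueError(f"incomplete design, missing (neuron, session) cells: {missing}")
    sessions = np.asarray(sorted(wide.columns), dtype=float)
    wide = wide[sorted(wide.columns)]
    scores = wide.values.astype(float)
    clock = (
        df.drop_duplicates("session_time_h")
        .sort_values("session_time_h")["clock_time_h"]
        .to_numpy(dtype=float)
    )
    zero_median: list = []
    if normalize:
        med = np.median(scores, axis=1)
        zero_median = [wide.index[i] for i in np.flatnonzero(med <= 0)]
        safe = np.where(med > 0, med, 1.0)
        scores = scores / safe[:, None]
    return ActivityPattern(
        neuron_ids=list(wide.index),
        session_times_h=sessions,
        scores=scores,
        normalized=normalize,
        clock_times_h=clock,
        zero_median_neurons=zero_median,
    )


def read_traces_csv(path) -> list[TraceRecording]:
    """Read long-format trace CSV: neuron_id, session_time_h, clock_time_h,
    sampling_rate_hz, frame_index, fluorescence."""
    df = pd.read_csv(path)
    required = {
        "neuron_id",
        "session_time_h",
        "clock_time_h",
        "sampling_rate_hz",
        "frame_index",
        "fluorescence",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    recordings = []
    for (nid, t), grp in df.groupby(["neuron_id", "session_time_h"], sort=True):
        grp = grp.sort_values("frame_index")
        recordings.append(
            TraceRecording(
                neuron_id=str(nid),
                session_time_h=float(t),
                clock_time_h=float(grp["clock_time_h"].iloc[0]),
                sampling_rate_hz=float(grp["sampling_rate_hz"].iloc[0]),
                values=grp["fluorescence"].to_numpy(dtype=float),
            )
        )
    return recordings


def write_scores_csv(records: Sequence[ActivityScoreRecord], path) -> None:
    pd.DataFrame(
        {
            "neuron_id": [r.neuron_id for r in records],
            "session_time_h": [r.session_time_h for r in records],
            "clock_time_h": [r.clock_time_h for r in records],
            "score": [r.score for r in records],
            "n_peaks": [r.n_peaks for r in records],
        }
    ).to_csv(path, index=False)
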