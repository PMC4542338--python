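"""Cornering-event detection from collar accelerometer records.

Cornering produces lateral (centripetal) acceleration, which appears on a
collar-mounted tri-axial logger as a departure of the mediolateral
acceleration magnitude from the 1 g gravity baseline.  The processing chain:

1. ``sqrt(heave**2 + sway**2)`` — the vectorial sum of the two lateral
   axes.  Using the magnitude makes the analysis insensitive to collar
   rotation, which arbitrarily redistributes gravity between heave and sway.
2. A 2 s running mean isolates the static (gravity + sustained centripetal)
   component from stride-level dynamics; the residual bounding-gait
   waveform is then attenuated with a second 0.5 s running mean.
3. The departure from 1 g of the doubly smoothed magnitude is scanned for
   peaks above a threshold.  Bounding gait can split one physical turn into
   adjacent ripples, so lower peaks within an exclusion window of a
   retained peak are discarded.
4. Each turn's onset is the last upward crossing of an onset threshold
   before its peak; duration is onset-to-peak.

Running means are centred, with windows shrinking symmetrically at the
record edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "AccelTrace",
    "DetectedTurn",
    "ChaseMetrics",
    "static_lateral",
    "double_smooth",
    "detect_turns",
    "chase_metrics",
    "read_trace_csv",
    "write_trace_csv",
    "write_detections_csv",
]

DEFAULT_RATE = 30.0
STATIC_WINDOW_S = 2.0
SECOND_WINDOW_S = 0.5
DEFAULT_THRESHOLD = 0.1
DEFAULT_ONSET_THRESHOLD = 0.05
DEFAULT_EXCLUSION_S = 0.4


@dataclass
class AccelTrace:
    """One tri-axial accelerometer record.

    Channels are in g: ``surge`` (anteroposterior), ``heave``
    (dorsoventral) and ``sway`` (mediolateral) — though on a rotating
    collar heave and sway are interchangeable and all downstream
    processing treats them symmetrically.  ``truth_turns`` carries
    ground-truth turn-peak times for synthetic traces only.
    """

    surge: np.ndarray
    heave: np.ndarray
    sway: np.ndarray
    sampling_rate: float = DEFAULT_RATE
    start_time: float = 0.0
    truth_turns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.surge = np.asarray(self.surge, dtype=float)
        self.heave = np.asarray(self.heave, dtype=float)
        self.sway = np.asarray(self.sway, dtype=float)
        if not (len(self.surge) == len(self.heave) == len(self.sway)):
            raise ValueError("channel lengths differ")
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if self.truth_turns is not None:
            self.truth_turns = np.asarray(self.truth_turns, dtype=float)

    def __len__(self) -> int:
        return len(self.heave)

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return len(self) / self.sampling_rate


@dataclass(frozen=True)
class DetectedTurn:
    """One detected cornering event.

    ``duration`` is onset-to-peak: the time for lateral g to build from
    the onset threshold to its within-turn maximum.
    """

    onset: float
    peak: float
    peak_departure: float
    duration: float

    def __post_init__(self) -> None:
        if self.peak < self.onset:
            raise ValueError("peak time must be >= onset time")
        if self.duration < 0:
            raise ValueError("duration must be >= 0")


@dataclass(frozen=True)
class ChaseMetrics:
    """Summary metrics of one chase window."""

    n_turns: int
    duration: float
    turn_rate: float
    turn_durations: tuple[float, ...] = field(default_factory=tuple)


def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean with shrinking windows at the edges."""
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def static_lateral(trace: AccelTrace, signed: bool = False) -> np.ndarray:
    """Departure from 1 g of the 2 s-smoothed lateral magnitude.

    Computes ``sqrt(heave**2 + sway**2)``, smooths with a centred 2 s
    running mean and returns the departure from 1 g — absolute by default,
    signed with ``signed=True``.  Same length as the input.
    """
    window = max(1, round(STATIC_WINDOW_S * trace.sampling_rate))
    if len(trace) < window:
        raise ValueError(
            f"trace of {len(trace)} samples is shorter than the "
            f"{STATIC_WINDOW_S} s smoothing window ({window} samples)"
        )
    magnitude = np.hypot(trace.heave, trace.sway)
    smoothed = _running_mean(magnitude, window)
    departure = smoothed - 1.0
    return departure if signed else np.abs(departure)


def double_smooth(series: np.ndarray, rate: float) -> np.ndarray:
    """Second-stage 0.5 s running mean (gait-waveform suppression)."""
    series = np.asarray(series, dtype=float)
    window = max(1, round(SECOND_WINDOW_S * rate))
    if len(series) < window:
        raise ValueError(
            f"series of {len(series)} samples is shorter than the "
            f"{SECOND_WINDOW_S} s window ({window} samples)"
        )
    return _running_mean(series, window)


def detect_turns(
    trace: AccelTrace,
    threshold: float = DEFAULT_THRESHOLD,
    gait_exclusion_window: float = DEFAULT_EXCLUSION_S,
    onset_threshold: float = DEFAULT_ONSET_THRESHOLD,
    signed: bool = False,
) -> list[DetectedTurn]:
    """Detect cornering events in a tri-axial trace.

    Peaks of the doubly smoothed departure-from-1 g series exceeding
    ``threshold`` are candidate turns; any candidate lower than, and
    within ``gait_exclusion_window`` seconds of, a retained peak is
    discarded (gait ripple).  Each turn's onset is the last upward
    crossing of ``onset_threshold`` before its peak, falling back to the
    preceding local minimum when the series never dips that low.
    """
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    rate = trace.sampling_rate
    departure = double_smooth(static_lateral(trace, signed=signed), rate)

    idx, _ = find_peaks(departure, height=threshold)
    if idx.size == 0:
        return []

    # greedy exclusion: keep peaks in descending height, drop lower
    # neighbours inside the exclusion window
    order = idx[np.argsort(departure[idx])[::-1]]
    min_gap = gait_exclusion_window * rate
    kept: list[int] = []
    for i in order:
        if all(abs(i - j) > min_gap for j in kept):
            kept.append(i)
    kept.sort()

    turns = []
    for i in kept:
        below = np.nonzero(departure[:i] < onset_threshold)[0]
        if below.size:
            onset_i = below[-1]
        else:
            # never below the onset threshold before the peak: use the
            # last local minimum (or the record start)
            seg = departure[:i]
            mins = np.nonzero((seg[1:-1] <= seg[:-2]) & (seg[1:-1] <= seg[2:]))[0]
            onset_i = mins[-1] + 1 if mins.size else 0
        t0 = trace.start_time
        turns.append(
            DetectedTurn(
                onset=t0 + onset_i / rate,
                peak=t0 + i / rate,
                peak_departure=float(departure[i]),
                duration=(i - onset_i) / rate,
            )
        )
    return turns


def chase_metrics(turns: list[DetectedTurn], duration: float) -> ChaseMetrics:
    """Count, rate (Hz) and per-turn durations for one chase window."""
    if not duration > 0:
        raise ValueError("duration must be > 0")
    return ChaseMetrics(
        n_turns=len(turns),
        duration=duration,
        turn_rate=len(turns) / duration,
        turn_durations=tuple(t.duration for t in turns),
    )


# ---------------------------------------------------------------------------
# trace / detection I/O

_TRACE_COLUMNS = ["t_s", "surge_g", "heave_g", "sway_g"]


def write_trace_csv(trace: AccelTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "t_s": trace.times,
            "surge_g": trace.surge,
            "heave_g": trace.heave,
            "sway_g": trace.sway,
        }
    )
    if trace.truth_turns is not None:
        truth = np.zeros(len(trace), dtype=int)
        truth[np.rint((trace.truth_turns - trace.start_time)
                      * trace.sampling_rate).astype(int)] = 1
        df["truth_turn"] = truth
    df.to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> AccelTrace:
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace file missing columns: {missing}")
    t = df["t_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace needs at least two samples")
    rate = 1.0 / float(np.median(np.diff(t)))
    truth = None
    if "truth_turn" in df.columns:
        truth = t[df["truth_turn"].to_numpy().astype(bool)]
    return AccelTrace(
        surge=df["surge_g"].to_numpy(),
        heave=df["heave_g"].to_numpy(),
        sway=df["sway_g"].to_numpy(),
        sampling_rate=rate,
        start_time=float(t[0]),
        truth_turns=truth,
    )


def write_detections_csv(turns: list[DetectedTurn], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "onset_s": t.onset,
                "peak_s": t.peak,
                "peak_g": t.peak_departure,
                "duration_s": t.duration,
            }
            for t in turns
        ],
        columns=["onset_s", "peak_s", "peak_g", "duration_s"],
    ).to_csv(path, index=False)
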