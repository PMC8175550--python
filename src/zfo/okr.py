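"""Optokinetic-response (OKR) analysis.

A fish viewing a rotating striped drum produces optokinetic nystagmus: slow
tracking phases in the stimulus direction interrupted by fast resetting
saccades.  The analysis segments the eye-angle trace into fast and slow
phases, fits a velocity to every slow phase, and reports

* optokinetic gain — slow-phase eye velocity divided by drum velocity
  (gain 1 = perfect tracking),
* eye-tracking movements (ETMs) — fast-phase counts per 10-s interval,
  split by direction,
* the spatial-acuity staircase — the stimulus spatial frequency is raised
  in 0.05 cpd steps from 0.15 cpd until the OKR disappears (verified by one
  repeat); a response is positive only when three or more consecutive
  nystagmus cycles occur in both stimulus directions.

Sign convention: positive eye angle / velocity = nasal direction; a trace's
``direction`` metadata is the direction of the slow (tracking) phase, so
fast phases run the opposite way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "EyeTrace",
    "NystagmusSegmentation",
    "AcuityResult",
    "detect_fast_phases",
    "optokinetic_gain",
    "count_etms",
    "has_consecutive_patterns",
    "acuity_staircase",
]

Direction = Literal["nasal", "temporal"]

_DIR_SIGN = {"nasal": 1.0, "temporal": -1.0}


def _opposite(direction: Direction) -> Direction:
    return "temporal" if direction == "nasal" else "nasal"


@dataclass
class EyeTrace:
    """Uniformly sampled eye-angle time series with stimulus metadata."""

    time_s: np.ndarray
    angle_deg: np.ndarray
    drum_velocity_deg_s: float
    spatial_frequency_cpd: float = 0.15
    direction: Direction = "nasal"  # direction of the slow (tracking) phase
    meta: Mapping = field(default_factory=dict)  # e.g. designed reset times

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float)
        if self.time_s.size != self.angle_deg.size:
            raise ValueError("time and angle must have equal length")
        dt = np.diff(self.time_s)
        if dt.size and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("sampling must be uniform")
        if self.drum_velocity_deg_s == 0:
            raise ValueError("drum velocity must be nonzero during stimulation")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(self.time_s[1] - self.time_s[0])


@dataclass
class FastPhase:
    time_s: float
    direction: Direction


@dataclass
class SlowPhase:
    start_s: float
    stop_s: float
    velocity_deg_s: float
    n_frames: int


@dataclass
class NystagmusSegmentation:
    fast_phases: list[FastPhase]
    slow_phases: list[SlowPhase]
    drum_velocity_deg_s: float
    slow_direction: Direction
    duration_s: float


@dataclass
class AcuityResult:
    threshold_cpd: float | None  # None = no response even at the lowest frequency
    below_grid: bool
    responses: dict[float, bool]
    gains: dict[float, float] = field(default_factory=dict)
    etm_counts: dict[float, float] = field(default_factory=dict)


def detect_fast_phases(
    trace: EyeTrace, velocity_factor: float = 3.0, min_slow_frames: int = 3
) -> NystagmusSegmentation:
    """Segment a nystagmus trace into fast-phase events and slow phases.

    Frame-to-frame angular velocity is computed by central differences.
    Samples whose speed exceeds ``velocity_factor`` times the drum speed
    *and* whose velocity opposes the slow-phase direction are grouped into
    fast-phase events; the remaining runs of at least ``min_slow_frames``
    samples become slow phases, each with a least-squares velocity.
    """
    t, a = trace.time_s, trace.angle_deg
    if t[-1] - t[0] < 1.0:
        raise ValueError("need at least 1 s of data")
    v = np.gradient(a, t)
    slow_sign = _DIR_SIGN[trace.direction]
    speed_limit = velocity_factor * abs(trace.drum_velocity_deg_s)
    fast_mask = (np.abs(v) > speed_limit) & (np.sign(v) == -slow_sign)

    fast_phases: list[FastPhase] = []
    slow_phases: list[SlowPhase] = []
    # contiguous runs of the mask
    edges = np.flatnonzero(np.diff(fast_mask.astype(int)))
    starts = np.r_[0, edges + 1]
    stops = np.r_[edges + 1, fast_mask.size]
    for s, e in zip(starts, stops):
        if fast_mask[s]:
            fast_phases.append(
                FastPhase(
                    time_s=float(t[s : e].mean()),
                    direction=_opposite(trace.direction),
                )
            )
        elif e - s >= min_slow_frames:
            res = _sps.linregress(t[s:e], a[s:e])
            slow_phases.append(
                SlowPhase(
                    start_s=float(t[s]),
                    stop_s=float(t[e - 1]),
                    velocity_deg_s=float(res.slope),
                    n_frames=int(e - s),
                )
            )
    return NystagmusSegmentation(
        fast_phases=fast_phases,
        slow_phases=slow_phases,
        drum_velocity_deg_s=trace.drum_velocity_deg_s,
        slow_direction=trace.direction,
        duration_s=float(t[-1] - t[0]),
    )


def optokinetic_gain(
    seg: NystagmusSegmentation,
    drum_velocity_deg_s: float | None = None,
    estimator: Literal["median", "mean"] = "median",
) -> float:
    """Slow-phase eye velocity over drum velocity; positive = tracking.

    The median over slow phases is the default estimator, robust to residual
    saccade contamination near segment edges.
    """
    if not seg.slow_phases:
        raise ValueError("no slow phases; gain undefined")
    drum = drum_velocity_deg_s if drum_velocity_deg_s is not None else seg.drum_velocity_deg_s
    velocities = np.array([p.velocity_deg_s for p in seg.slow_phases])
    agg = np.median if estimator == "median" else np.mean
    eye_v = float(agg(velocities))
    # sign so that motion in the slow-phase (stimulus) direction is positive
    return eye_v * _DIR_SIGN[seg.slow_direction] / abs(drum)


def count_etms(
    seg: NystagmusSegmentation, direction: Direction, window_s: float = 10.0
) -> float:
    """Fast-phase events of one direction per consecutive window, averaged.

    The trace is cut into consecutive ``window_s`` windows (incomplete tail
    discarded); the count of direction-matched fast phases is averaged over
    the complete windows.
    """
    if seg.duration_s < window_s:
        raise ValueError("trace shorter than the counting window")
    n_windows = int(seg.duration_s // window_s)
    times = [p.time_s for p in seg.fast_phases if p.direction == direction]
    counts = np.zeros(n_windows)
    for ts in times:
        w = int(ts // window_s)
        if w < n_windows:
            counts[w] += 1
    return float(counts.mean())


def has_consecutive_patterns(
    seg: NystagmusSegmentation, min_cycles: int = 3, max_gap_s: float = 1.0
) -> bool:
    """True if >= ``min_cycles`` consecutive (slow, fast) nystagmus cycles occur.

    A cycle is a slow phase followed by a fast phase within ``max_gap_s``;
    cycles are consecutive when separated by at most ``max_gap_s``.
    """
    cycles = []
    for sp in seg.slow_phases:
        nxt = [f for f in seg.fast_phases if 0 <= f.time_s - sp.stop_s <= max_gap_s]
        if nxt:
            cycles.append((sp.start_s, min(f.time_s for f in nxt)))
    if not cycles:
        return False
    cycles.sort()
    run = best = 1
    for (s0, e0), (s1, _) in zip(cycles, cycles[1:]):
        run = run + 1 if s1 - e0 <= max_gap_s else 1
        best = max(best, run)
    return best >= min_cycles


def acuity_staircase(
    observations: Sequence[tuple[float, bool]]
    | Sequence[tuple[float, NystagmusSegmentation, NystagmusSegmentation]],
    min_cycles: int = 3,
) -> AcuityResult:
    """Apply the ascending spatial-frequency staircase rule.

    ``observations`` is the tested sequence, ascending in frequency (the
    terminating frequency appears twice — the verification repeat), each item
    either ``(freq, positive)`` or ``(freq, seg_nasal, seg_temporal)``; in the
    latter case a response is positive only when both direction segmentations
    contain >= ``min_cycles`` consecutive nystagmus cycles.  The acuity
    threshold is the highest frequency with a positive response; a negative
    response at the lowest frequency is flagged as below the grid.
    """
    if not observations:
        raise ValueError("no staircase observations")
    freqs = [o[0] for o in observations]
    if any(f1 < f0 for f0, f1 in zip(freqs, freqs[1:])):
        raise ValueError("staircase frequencies must be ascending")

    responses: dict[float, bool] = {}
    order: list[tuple[float, bool]] = []
    for obs in observations:
        if len(obs) == 2:
            f, pos = obs  # type: ignore[misc]
        else:
            f, seg_n, seg_t = obs  # type: ignore[misc]
            pos = has_consecutive_patterns(seg_n, min_cycles) and has_consecutive_patterns(
                seg_t, min_cycles
            )
        order.append((float(f), bool(pos)))
        responses[float(f)] = bool(pos) or responses.get(float(f), False)

    positive_freqs = [f for f, pos in order if pos]
    if not positive_freqs:
        return AcuityResult(threshold_cpd=None, below_grid=True, responses=responses)
    return AcuityResult(
        threshold_cpd=max(positive_freqs), below_grid=False, responses=responses
    )
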