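"""Electroretinogram (ERG) B-wave extraction.

The protocol delivers two 100 ms light stimuli 8000 ms apart to a
dark-adapted eye.  The recorded voltage trace is baseline-corrected by
subtracting the mean over the 50 ms immediately preceding the first
stimulus; per-stimulus epochs aligned at onset are averaged point-wise; and
the B-wave amplitude is the maximum of the averaged, corrected epoch within
a post-onset search window (the positive ON-bipolar-cell deflection).
Because B-wave amplitude covaries with animal size, it is additionally
reported per millimetre of body length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ERGTrace",
    "BWaveResult",
    "baseline_correct",
    "average_responses",
    "b_wave_amplitude",
    "normalize_by_body_length",
    "analyze_trace",
]

BASELINE_WINDOW_MS = 50.0  # pre-stimulus averaging span


@dataclass
class ERGTrace:
    """Voltage time series with stimulus onset markers (time in ms, µV)."""

    time_ms: np.ndarray
    voltage_uv: np.ndarray
    onsets_ms: Sequence[float]
    stimulus_duration_ms: float = 100.0
    baseline_value_uv: float | None = None  # set by baseline_correct

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.voltage_uv = np.asarray(self.voltage_uv, dtype=float)
        if self.time_ms.size != self.voltage_uv.size:
            raise ValueError("time and voltage must have equal length")
        self.onsets_ms = sorted(float(o) for o in self.onsets_ms)
        if self.onsets_ms and self.onsets_ms[0] - self.time_ms[0] < BASELINE_WINDOW_MS:
            raise ValueError(
                f"need >= {BASELINE_WINDOW_MS:g} ms of pre-stimulus data "
                "before the first onset"
            )

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


@dataclass
class BWaveResult:
    amplitude_uv: float
    baseline_uv: float
    normalized_uv_per_mm: float | None = None


def baseline_correct(trace: ERGTrace) -> ERGTrace:
    """Subtract the mean voltage of the 50 ms before the first stimulus.

    Idempotent: correcting an already corrected trace subtracts (numerically)
    zero.  The subtracted baseline is recorded on the returned trace.
    """
    if not trace.onsets_ms:
        raise ValueError("trace has no stimulus onsets")
    first = trace.onsets_ms[0]
    window = (trace.time_ms >= first - BASELINE_WINDOW_MS) & (trace.time_ms < first)
    if not np.any(window):
        raise ValueError("no samples in the 50 ms pre-stimulus window")
    baseline = float(trace.voltage_uv[window].mean())
    return ERGTrace(
        time_ms=trace.time_ms,
        voltage_uv=trace.voltage_uv - baseline,
        onsets_ms=trace.onsets_ms,
        stimulus_duration_ms=trace.stimulus_duration_ms,
        baseline_value_uv=baseline,
    )


def average_responses(
    trace: ERGTrace, epoch_ms: float = 1000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Average onset-aligned epochs point-wise.

    The epoch length is the smaller of ``epoch_ms``, the inter-stimulus
    interval, and the recording available after the last onset, so
    consecutive responses never overlap and never run off the trace.
    Returns ``(epoch_time_ms, mean_voltage_uv)`` with time from onset.
    """
    onsets = np.asarray(trace.onsets_ms, dtype=float)
    if onsets.size == 0:
        raise ValueError("trace has no stimulus onsets")
    if onsets.size > 1:
        isi = float(np.min(np.diff(onsets)))
        if isi <= 0:
            raise ValueError("overlapping stimulus onsets")
        epoch_ms = min(epoch_ms, isi)
    epoch_ms = min(epoch_ms, float(trace.time_ms[-1]) - onsets[-1])
    n = int(round(epoch_ms / trace.dt_ms))
    if n < 1:
        raise ValueError("no samples available after the last stimulus onset")
    epochs = []
    for onset in onsets:
        i0 = int(np.searchsorted(trace.time_ms, onset))
        epochs.append(trace.voltage_uv[i0 : i0 + n])
    mean = np.mean(epochs, axis=0)
    tax = np.arange(n) * trace.dt_ms
    return tax, mean


def b_wave_amplitude(
    epoch_time_ms: np.ndarray,
    epoch_uv: np.ndarray,
    search_window_ms: tuple[float, float] = (0.0, 500.0),
) -> float:
    """Maximum of the averaged, baseline-corrected epoch inside the window."""
    lo, hi = search_window_ms
    mask = (epoch_time_ms >= lo) & (epoch_time_ms <= hi)
    if not np.any(mask):
        raise ValueError("empty B-wave search window")
    return float(np.max(epoch_uv[mask]))


def normalize_by_body_length(amplitude_uv: float, body_length_mm: float) -> float:
    """B-wave amplitude per millimetre of body length."""
    if body_length_mm <= 0:
        raise ValueError("body length must be positive")
    return amplitude_uv / body_length_mm


def analyze_trace(
    trace: ERGTrace,
    body_length_mm: float | None = None,
    search_window_ms: tuple[float, float] = (0.0, 500.0),
    epoch_ms: float = 1000.0,
) -> BWaveResult:
    """Full pipeline: baseline correction, epoch averaging, B-wave extraction."""
    corrected = baseline_correct(trace)
    tax, mean = average_responses(corrected, epoch_ms=epoch_ms)
    amp = b_wave_amplitude(tax, mean, search_window_ms)
    norm = (
        normalize_by_body_length(amp, body_length_mm)
        if body_length_mm is not None
        else None
    )
    return BWaveResult(
        amplitude_uv=amp,
        baseline_uv=float(corrected.baseline_value_uv or 0.0),
        normalized_uv_per_mm=norm,
    )
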