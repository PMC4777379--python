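"""Raw-channel conditioning: EMG filtering, SCL smoothing, beat detection.

All IIR filters are applied forward-backward (:func:`scipy.signal.filtfilt`)
so that filtered signals stay phase-aligned with the event timeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .exceptions import (
    AlignmentError,
    ConfigurationError,
    SamplingRateError,
    SignalQualityError,
)
from .synth import EventTimeline


@dataclass
class NNSeries:
    """Artifact-screened inter-beat (NN) interval series.

    ``beat_times`` holds the first retained beat followed by the terminating
    beat of every retained interval; after artifact rejection, intervals
    spanning a discarded beat are dropped, so ``intervals`` need not equal
    ``diff(beat_times)`` across a gap.
    """

    intervals: np.ndarray  # ms
    beat_times: np.ndarray  # s

    @property
    def n(self) -> int:
        return len(self.intervals)

    def validate(self) -> None:
        if len(self.beat_times) != len(self.intervals) + 1:
            raise SignalQualityError("NN series must have one more beat time than intervals")
        if np.any(self.intervals <= 0):
            raise SignalQualityError("NN intervals must be positive")
        if np.any(np.diff(self.beat_times) <= 0):
            raise SignalQualityError("beat times must be strictly increasing")

    def restrict(self, t0: float, t1: float) -> "NNSeries":
        """Intervals whose terminating beat falls in [t0, t1)."""
        end_times = self.beat_times[1:]
        mask = (end_times >= t0) & (end_times < t1)
        if not mask.any():
            return NNSeries(np.empty(0), self.beat_times[:1])
        first = int(np.argmax(mask))
        times = np.concatenate(([self.beat_times[first]], end_times[mask]))
        return NNSeries(self.intervals[mask], times)


@dataclass
class Segment:
    """One stimulation block of a single channel plus its pre-block baseline."""

    samples: np.ndarray
    fs: float
    condition: str
    baseline_samples: np.ndarray
    onset: float = 0.0


def bandpass_emg(samples: np.ndarray, fs: float, low: float = 20.0, high: float = 250.0, order: int = 4) -> np.ndarray:
    """20-250 Hz 4th-order Butterworth band-pass, zero phase."""
    if fs <= 2 * high:
        raise SamplingRateError(f"EMG band-pass to {high} Hz requires fs > {2 * high} Hz, got {fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def remove_powerline(samples: np.ndarray, fs: float, line_freq: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Narrow IIR notch at the power-line frequency, zero phase."""
    if fs <= 2 * line_freq:
        raise SamplingRateError(f"notch at {line_freq} Hz requires fs > {2 * line_freq} Hz, got {fs}")
    b, a = sps.iirnotch(line_freq, q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(samples, dtype=float))


def rms_envelope(samples: np.ndarray, fs: float, window: float = 0.125) -> np.ndarray:
    """Centered sliding-window RMS; truncated windows at the edges.

    The default 125 ms window is the conventional smoothing constant for
    surface-EMG amplitude envelopes.
    """
    x = np.asarray(samples, dtype=float)
    w = int(round(window * fs))
    if w < 2:
        raise ConfigurationError(f"RMS window of {window} s is under 2 samples at fs={fs}")
    half_l = w // 2
    half_r = w - half_l - 1
    sq = np.concatenate(([0.0], np.cumsum(x * x)))
    n = len(x)
    idx = np.arange(n)
    lo = np.maximum(idx - half_l, 0)
    hi = np.minimum(idx + half_r + 1, n)
    sums = sq[hi] - sq[lo]
    return np.sqrt(sums / (hi - lo))


def lowpass_scl(samples: np.ndarray, fs: float, cutoff: float = 0.2, order: int = 4) -> np.ndarray:
    """Low-pass smoothing of the skin-conductance level, zero phase, unit DC gain."""
    if fs <= 2 * cutoff:
        raise SamplingRateError(f"low-pass at {cutoff} Hz requires fs > {2 * cutoff} Hz, got {fs}")
    sos = sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def detect_beats(
    bvp_samples: np.ndarray,
    fs: float,
    *,
    min_period_ms: float = 300.0,
    max_period_ms: float = 2000.0,
    median_tolerance: float = 0.25,
) -> NNSeries:
    """Pulse-peak detection on the BVP with automatic artifact screening.

    Peaks are found on a 0.5-8 Hz band-passed copy of the signal with a
    minimum inter-peak distance of ``min_period_ms``.  Intervals outside
    [300, 2000] ms, or deviating more than 25% from the running median of
    five neighbouring intervals, are discarded; this replaces manual visual
    correction of the inter-beat series.
    """
    x = np.asarray(bvp_samples, dtype=float)
    if len(x) < 10 * fs:
        raise SignalQualityError("beat detection requires at least 10 s of signal")
    sos = sps.butter(2, [0.5, 8.0], btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    sd = float(np.std(filtered))
    if sd <= 1e-12:
        raise SignalQualityError("flat BVP signal, no beats detectable")
    distance = max(int(round(min_period_ms / 1000.0 * fs)), 1)
    # height gate: a skipped beat leaves filter ringing with full prominence
    # but near-zero amplitude in the gap
    peaks, _ = sps.find_peaks(filtered, distance=distance, prominence=0.5 * sd, height=0.5 * sd)
    if len(peaks) < 3:
        raise SignalQualityError(f"only {len(peaks)} beats detected, need >= 3")
    beat_times = peaks / fs
    nn = np.diff(beat_times) * 1000.0

    good = (nn >= min_period_ms) & (nn <= max_period_ms)
    # Running median of 5 over the physiologically plausible intervals.
    plausible = nn[good]
    if len(plausible) >= 5:
        med = sps.medfilt(nn, kernel_size=5)
        # medfilt zero-pads the edges; repair with the global median there
        med[:2] = np.median(nn)
        med[-2:] = np.median(nn)
        good &= np.abs(nn - med) <= median_tolerance * med
    if not good.any():
        raise SignalQualityError("all detected intervals rejected by the artifact rule")
    end_times = beat_times[1:][good]
    first = int(np.argmax(good))
    times = np.concatenate(([beat_times[first]], end_times))
    series = NNSeries(nn[good], times)
    series.validate()
    return series


def segment_by_timeline(
    samples: np.ndarray,
    fs: float,
    timeline: EventTimeline,
    baseline_window: float = 2.0,
) -> list[Segment]:
    """One :class:`Segment` per stimulation block, with its pre-block baseline."""
    x = np.asarray(samples, dtype=float)
    duration = len(x) / fs
    segments = []
    for onset, offset, label in timeline.blocks:
        if offset > duration + 0.5 / fs:
            raise AlignmentError(
                f"block [{onset}, {offset}] s extends past the {duration:.2f} s recording"
            )
        b0 = onset - baseline_window
        if b0 < -0.5 / fs:
            raise AlignmentError(
                f"baseline window of {baseline_window} s before t={onset} s precedes the recording"
            )
        i0, i1 = int(round(onset * fs)), int(round(offset * fs))
        j0 = max(int(round(b0 * fs)), 0)
        segments.append(
            Segment(
                samples=x[i0:i1],
                fs=fs,
                condition=label,
                baseline_samples=x[j0:i0],
                onset=onset,
            )
        )
    return segments
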