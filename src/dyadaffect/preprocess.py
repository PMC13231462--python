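"""Signal conditioning and physiological event detection.

Raw EDA, respiration and skin-temperature channels are conditioned with a
zero-phase 5-Hz fourth-order Butterworth lowpass. Peak detection then
yields R-wave, breath and skin-conductance-response (SCR) event series,
from which uniformly sampled instantaneous heart-rate and respiration-rate
series are built.

Detector scope: these peak detectors are written for clean, R-dominant ECG
and near-sinusoidal respiration (the kind the built-in simulator emits, or
well-conditioned laboratory recordings); they do not attempt artifact
rejection beyond the missed-beat gap rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import median_filter

from .errors import InvalidArgumentError, QualityError
from .recording import DyadRecording, Segment

__all__ = [
    "EventSeries",
    "RateSeries",
    "lowpass_filter",
    "detect_r_peaks",
    "detect_breath_peaks",
    "detect_scrs",
    "instantaneous_rate",
    "split_segments",
]


@dataclass
class EventSeries:
    """Detected point events: R-peaks, breath crests, or SCRs.

    ``times`` are in seconds (strictly increasing); ``amplitudes`` carry
    trough-to-peak µS for SCRs (zeros otherwise); ``interpolated`` flags
    events inserted by the missed-beat gap rule rather than detected.
    """

    kind: str
    times: np.ndarray
    amplitudes: np.ndarray
    interpolated: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if not (len(self.times) == len(self.amplitudes) == len(self.interpolated)):
            raise ValueError("times/amplitudes/interpolated must align")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be >= 0")

    def __len__(self) -> int:
        return len(self.times)

    def restrict(self, t_start: float, t_end: float) -> "EventSeries":
        """Events with t_start <= t < t_end."""
        m = (self.times >= t_start) & (self.times < t_end)
        return EventSeries(self.kind, self.times[m], self.amplitudes[m],
                          self.interpolated[m])


@dataclass
class RateSeries:
    """Uniformly sampled instantaneous rate (events per minute)."""

    kind: str
    t: np.ndarray
    values: np.ndarray
    fs: float


def lowpass_filter(series, fs: float, cutoff: float = 5.0, order: int = 4):
    """Zero-phase Butterworth lowpass (applied forward and backward).

    The two-pass application squares the magnitude response and cancels
    phase, so passband event timing is unbiased.
    """
    series = np.asarray(series, dtype=float)
    if cutoff >= fs / 2.0:
        raise InvalidArgumentError("cutoff must be below the Nyquist frequency")
    if len(series) <= 3 * order:
        raise InvalidArgumentError("series too short for the requested order")
    sos = sps.butter(order, cutoff / (fs / 2.0), btype="lowpass", output="sos")
    return sps.sosfiltfilt(sos, series)


def _running_median_intervals(intervals: np.ndarray, window: int = 11) -> np.ndarray:
    """Centered running median of the interval sequence (edge-replicated)."""
    if len(intervals) == 0:
        return intervals
    w = min(window, len(intervals))
    if w % 2 == 0:
        w -= 1
    w = max(w, 1)
    return median_filter(intervals, size=w, mode="nearest")


def _interpolate_gaps(
    times: np.ndarray, gap_factor: float = 1.8, window: int = 11
) -> tuple[np.ndarray, np.ndarray]:
    """Insert substitute events into implausibly long inter-event gaps.

    A gap longer than ``gap_factor`` × the running-median interval marks one
    or more missed events. A single gap up to 2.8× the median gets one
    midpoint event; longer gaps get round(gap/median) − 1 evenly spaced
    events. Returns (times, interpolated_flags).
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 3:
        return times, np.zeros(len(times), dtype=bool)
    iv = np.diff(times)
    med = _running_median_intervals(iv, window)
    out_t = [times[0]]
    out_f = [False]
    for i, gap in enumerate(iv):
        if med[i] > 0 and gap > gap_factor * med[i]:
            n_ins = max(1, int(round(gap / med[i])) - 1)
            inner = times[i] + gap * np.arange(1, n_ins + 1) / (n_ins + 1)
            out_t.extend(inner)
            out_f.extend([True] * n_ins)
        out_t.append(times[i + 1])
        out_f.append(False)
    return np.asarray(out_t), np.asarray(out_f, dtype=bool)


def _detect_peaks_train(
    x: np.ndarray, fs: float, refractory_s: float, kind: str, min_peaks: int = 3
) -> EventSeries:
    """Shared threshold-and-refractory peak detection with gap repair."""
    x = np.asarray(x, dtype=float)
    if len(x) < 10 * fs:
        raise QualityError(f"{kind}: need at least 10 s of signal")
    xc = x - np.median(x)
    amp = np.percentile(xc, 99.5)
    if amp <= 0:
        raise QualityError(f"{kind}: signal has no positive excursions")
    peaks, _ = sps.find_peaks(
        xc, height=0.5 * amp, distance=max(1, int(round(refractory_s * fs)))
    )
    if len(peaks) < min_peaks:
        raise QualityError(f"{kind}: fewer than {min_peaks} peaks detected")
    times = peaks / fs
    times, flags = _interpolate_gaps(times)
    return EventSeries(kind, times, np.zeros(len(times)), flags)


def detect_r_peaks(ecg, fs: float) -> EventSeries:
    """Detect R-wave peaks with a 0.25 s refractory period.

    Implausible gaps (interval > 1.8 × running-median interval over an
    11-interval window) are repaired by inserting substitute beats midway
    between the flanking valid R-waves, flagged ``interpolated``.
    """
    return _detect_peaks_train(np.asarray(ecg, float), fs, 0.25, "r_peak")


def detect_breath_peaks(resp, fs: float) -> EventSeries:
    """Detect breath crests with a 1.5 s refractory period and the same
    gap-interpolation rule as R-peak detection.

    Unlike R-peak detection, two crests are enough to return a result
    (slow breathing in a short window is not a quality failure)."""
    return _detect_peaks_train(np.asarray(resp, float), fs, 1.5, "breath",
                               min_peaks=2)


def detect_scrs(
    eda_filtered,
    fs: float,
    min_amplitude_uS: float = 0.05,
    rise_window_s: tuple[float, float] = (0.5, 5.0),
) -> EventSeries:
    """Detect skin-conductance responses in an already-lowpassed EDA trace.

    An SCR is a local trough→peak excursion whose rise time lies in
    ``rise_window_s`` and whose trough-to-peak amplitude is at least
    ``min_amplitude_uS``; the amplitude is recorded per event. An empty
    result is valid.
    """
    x = np.asarray(eda_filtered, dtype=float)
    empty = EventSeries("scr", np.array([]), np.array([]), np.array([], dtype=bool))
    if len(x) < 3:
        return empty
    min_prom = max(min_amplitude_uS * 0.5, 1e-4)
    peaks, _ = sps.find_peaks(x, prominence=min_prom)
    if len(peaks) == 0:
        return empty
    times, amps = [], []
    lo_rise, hi_rise = rise_window_s
    lookback = int(round((hi_rise + 1.5) * fs))
    prev_peak = 0
    for pk in peaks:
        # trough = last minimum in the look-back window (bounded below by
        # the previous peak): the onset of the rising limb
        lo = max(prev_peak, pk - lookback)
        w = x[lo:pk]
        tr = lo + len(w) - 1 - int(np.argmin(w[::-1]))
        rise = (pk - tr) / fs
        amp = x[pk] - x[tr]
        if lo_rise <= rise <= hi_rise and amp >= min_amplitude_uS:
            times.append(pk / fs)
            amps.append(amp)
        prev_peak = pk
    return EventSeries(
        "scr", np.asarray(times), np.asarray(amps),
        np.zeros(len(times), dtype=bool),
    )


def instantaneous_rate(
    events: EventSeries, t_start: float, t_end: float, out_fs: float = 4.0
) -> RateSeries:
    """Instantaneous event rate (per minute) on a uniform grid.

    The rate at each inter-event midpoint is 60 / interval-seconds; values
    are linearly interpolated onto the ``out_fs`` grid over
    [t_start, t_end), holding the nearest value constant at the edges.
    """
    ev = events.restrict(t_start, t_end)
    if len(ev) < 2:
        raise QualityError(f"{events.kind}: need >= 2 events in window")
    iv = np.diff(ev.times)
    mid = ev.times[:-1] + iv / 2.0
    rate = 60.0 / iv
    n = int(round((t_end - t_start) * out_fs))
    t = t_start + np.arange(n) / out_fs
    kind = "hr_bpm" if events.kind == "r_peak" else "resp_rate_bpm"
    return RateSeries(kind, t, np.interp(t, mid, rate), out_fs)


def split_segments(recording: DyadRecording) -> list[Segment]:
    """The recording's six named segments, in session order.

    Samples outside the six segments play no further role; all downstream
    feature extraction works on these half-open [start, end) views via
    :meth:`DyadRecording.slice`.
    """
    recording.validate()
    return list(recording.segments)
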