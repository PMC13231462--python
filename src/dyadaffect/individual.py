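"""Per-participant features for one segment: 18 named scalars.

ECG (9): mean/min/max heart rate from beatwise 60/RR values; SDNN, RMSSD
(ms) and pNN50 (%) from the interbeat-interval sequence; LF and HF band
power (ms²) and their ratio from a Welch spectrum of the interval series
resampled at 4 Hz (LF 0.04–0.15 Hz, HF 0.15–0.40 Hz — the standard HRV
band edges).

EDA (5): mean level (µS), final-minus-initial level, SCR count, mean and
SD of SCR trough-to-peak amplitudes.

Respiration (2): mean rate (breaths/min) and SD of breath-to-breath
periods (s).

Temperature (2): mean (°C) and final-minus-initial level.

Conventions: "initial" and "final" values are 5-s endpoint means (single
samples would be noise-dominated); dispersion statistics use the
population (ddof=0) definition so single-event cases are defined as 0;
pNN50 counts successive differences strictly greater than 50 ms.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

from .errors import QualityError
from .preprocess import EventSeries

__all__ = [
    "INDIVIDUAL_FEATURE_NAMES",
    "ecg_features",
    "eda_features",
    "respiration_features",
    "temperature_features",
    "extract_individual",
]

INDIVIDUAL_FEATURE_NAMES: tuple[str, ...] = (
    "mean_hr", "min_hr", "max_hr", "sdnn", "rmssd", "pnn50",
    "lf_power", "hf_power", "lf_hf_ratio",
    "mean_eda", "delta_eda", "n_scr", "mean_scr_amp", "sd_scr_amp",
    "mean_resp_rate", "sd_resp_period",
    "mean_temp", "delta_temp",
)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)
RR_RESAMPLE_FS = 4.0
SPECTRAL_WINDOW_S = 60.0


def _band_power(f: np.ndarray, pxx: np.ndarray, band: tuple[float, float]) -> float:
    m = (f >= band[0]) & (f <= band[1])
    if m.sum() < 2:
        return 0.0
    return float(np.trapezoid(pxx[m], f[m]))


def ecg_features(
    r_peaks: EventSeries, segment_span: tuple[float, float]
) -> dict[str, float]:
    """Nine heart-rate / HRV features from the R-peak series of a segment.

    Interpolated (gap-repaired) beats are included so the interval
    sequence stays contiguous. The ratio is NaN when HF power is zero.
    """
    ev = r_peaks.restrict(*segment_span)
    if len(ev) < 10:
        raise QualityError("ecg_features: fewer than 10 beats in segment")
    rr = np.diff(ev.times)            # s
    rr_ms = rr * 1000.0
    hr = 60.0 / rr                    # beatwise bpm
    d = np.diff(rr_ms)

    # frequency domain: RR(ms) interpolated to a uniform 4 Hz series
    mid = ev.times[:-1] + rr / 2.0
    t0, t1 = mid[0], mid[-1]
    n = max(int(round((t1 - t0) * RR_RESAMPLE_FS)), 8)
    tg = t0 + np.arange(n) / RR_RESAMPLE_FS
    rr_u = np.interp(tg, mid, rr_ms)
    nper = min(int(SPECTRAL_WINDOW_S * RR_RESAMPLE_FS), len(rr_u))
    f, pxx = sps.welch(rr_u - rr_u.mean(), fs=RR_RESAMPLE_FS, nperseg=nper)
    lf = _band_power(f, pxx, LF_BAND)
    hf = _band_power(f, pxx, HF_BAND)

    return {
        "mean_hr": float(hr.mean()),
        "min_hr": float(hr.min()),
        "max_hr": float(hr.max()),
        "sdnn": float(rr_ms.std()),
        "rmssd": float(np.sqrt(np.mean(d**2))) if len(d) else 0.0,
        "pnn50": float(100.0 * np.mean(np.abs(d) > 50.0)) if len(d) else 0.0,
        "lf_power": lf,
        "hf_power": hf,
        "lf_hf_ratio": lf / hf if hf > 0 else float("nan"),
    }


def _endpoint_means(x: np.ndarray, fs: float, window_s: float = 5.0) -> tuple[float, float]:
    w = max(1, min(int(round(window_s * fs)), len(x)))
    return float(x[:w].mean()), float(x[-w:].mean())


def eda_features(eda_segment, fs: float, scrs: EventSeries) -> dict[str, float]:
    """Five electrodermal features; SCR amplitude statistics are 0 when no
    (or a single) SCR is present."""
    x = np.asarray(eda_segment, dtype=float)
    if len(x) == 0:
        raise QualityError("eda_features: empty segment")
    initial, final = _endpoint_means(x, fs)
    amps = scrs.amplitudes
    return {
        "mean_eda": float(x.mean()),
        "delta_eda": final - initial,
        "n_scr": float(len(scrs)),
        "mean_scr_amp": float(amps.mean()) if len(amps) else 0.0,
        "sd_scr_amp": float(amps.std()) if len(amps) else 0.0,
    }


def respiration_features(
    breaths: EventSeries, segment_span: tuple[float, float]
) -> dict[str, float]:
    """Mean respiration rate (breaths/min) and SD of breath periods (s)."""
    ev = breaths.restrict(*segment_span)
    if len(ev) < 3:
        raise QualityError("respiration_features: fewer than 3 breaths")
    periods = np.diff(ev.times)
    span = ev.times[-1] - ev.times[0]
    return {
        "mean_resp_rate": float(60.0 * (len(ev) - 1) / span),
        "sd_resp_period": float(periods.std()),
    }


def temperature_features(temp_segment, fs: float) -> dict[str, float]:
    """Mean temperature and final-minus-initial change (5-s endpoint means)."""
    x = np.asarray(temp_segment, dtype=float)
    if len(x) == 0:
        raise QualityError("temperature_features: empty segment")
    initial, final = _endpoint_means(x, fs)
    return {"mean_temp": float(x.mean()), "delta_temp": final - initial}


def extract_individual(
    r_peaks: EventSeries,
    breaths: EventSeries,
    scrs: EventSeries,
    eda_segment,
    temp_segment,
    fs: float,
    segment_span: tuple[float, float],
) -> dict[str, float]:
    """Assemble the 18 per-participant features in canonical order."""
    out: dict[str, float] = {}
    out.update(ecg_features(r_peaks, segment_span))
    out.update(eda_features(eda_segment, fs, scrs))
    out.update(respiration_features(breaths, segment_span))
    out.update(temperature_features(temp_segment, fs))
    return {name: out[name] for name in INDIVIDUAL_FEATURE_NAMES}
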