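"""Synthetic dyadic physiology generator.

Emulates the statistical structure a dyadic conversation study assumes:
two participants per dyad, four 4-min conversation scenarios spanning the
valence/arousal quadrants (PV-HA, PV-LA, NV-HA, NV-LA) bracketed by two
4-min baselines, with four autonomic channels per participant sampled at a
common rate.

Scenario effects are encoded the way the downstream analysis expects to
find them:

* **arousal** drives heart rate (mean shift and variability scale), the
  skin-conductance-response rate, and respiration rate;
* **valence** drives cross-participant coupling (a shared band-limited
  latent modulator mixed into both participants' cardiac and respiratory
  dynamics) and the sign of the slow skin-temperature drift.

Participant-level offsets and per-segment jitters make no single feature a
perfect class oracle. Self-report answers (SAM valence/arousal, IIQ
amount/balance/valence) and trait questionnaire scores are drawn from
configurable per-scenario normal distributions and clipped to instrument
ranges.

Everything is a pure function of its explicit seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.integrate import cumulative_trapezoid

from .labels import SCENARIOS
from .recording import PARTICIPANTS, DyadRecording, Segment

__all__ = [
    "ScenarioParams",
    "EffectConfig",
    "ParticipantSignals",
    "Cohort",
    "default_effect_config",
    "generate_participant_signals",
    "generate_dyad_recording",
    "generate_cohort",
]

#: internal sampling rate (Hz) of latent rate/modulator processes
RATE_FS = 8.0
#: bpm of shared-modulator influence on heart rate at coupling = 1
COUPLING_HR_BPM = 5.0
#: bpm of individual (uncoupled) HR variability at hr_var_scale = 1
INDIV_HR_BPM = 3.0
#: Hz of shared-modulator influence on respiratory frequency at coupling = 1
COUPLING_RESP_HZ = 0.015

SELFREPORT_ITEMS = ("sam_valence", "sam_arousal", "iiq_amount", "iiq_balance", "iiq_valence")
TRAITS = ("social_anxiety", "depression", "cognitive_empathy", "affective_empathy")


@dataclass(frozen=True)
class ScenarioParams:
    """Generative parameters of one scenario (or baseline) condition.

    Attributes
    ----------
    valence, arousal : str
        ``"positive"``/``"negative"`` and ``"high"``/``"low"``
        (``"neutral"`` for baselines).
    hr_mean_shift : float
        Beats/min added to the participant's baseline heart rate.
    hr_var_scale : float
        Unitless multiplier on individual RR variability.
    scr_rate : float
        Skin-conductance responses per minute (Poisson rate).
    resp_rate : float
        Breaths per minute.
    temp_slope : float
        Skin-temperature drift in °C per minute.
    coupling : float in [0, 1]
        Strength of the shared latent modulator mixed into both
        participants' cardiac and respiratory processes.
    between_participant_sd : float
        Unitless master scale on participant-level offsets and per-segment
        jitters (1.0 = the default jitter magnitudes in EffectConfig).
    """

    valence: str
    arousal: str
    hr_mean_shift: float
    hr_var_scale: float
    scr_rate: float
    resp_rate: float
    temp_slope: float
    coupling: float
    between_participant_sd: float = 1.0

    def __post_init__(self) -> None:
        vals = [
            self.hr_mean_shift, self.hr_var_scale, self.scr_rate,
            self.resp_rate, self.temp_slope, self.coupling,
            self.between_participant_sd,
        ]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("all ScenarioParams fields must be finite")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.scr_rate < 0:
            raise ValueError("scr_rate must be >= 0")
        if self.resp_rate <= 0:
            raise ValueError("resp_rate must be > 0")


@dataclass(frozen=True)
class EffectConfig:
    """Full generator configuration: per-scenario effects, participant
    baselines, noise levels, self-report and trait distributions.

    ``sam_iiq[scenario][item]`` and ``traits[name]`` are ``(mean, sd)``
    pairs; defaults reproduce the study cohort's printed questionnaire
    statistics.
    """

    scenarios: dict[str, ScenarioParams]
    baseline: ScenarioParams
    hr_baseline_bpm: float = 70.0
    eda_baseline_uS: float = 2.0
    temp_baseline_C: float = 33.0
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"ecg": 0.01, "eda": 0.01, "resp": 0.05, "temp": 0.02}
    )
    sam_iiq: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    traits: dict[str, tuple[float, float]] = field(default_factory=dict)
    sam_range: tuple[float, float] = (1.0, 9.0)
    iiq_range: tuple[float, float] = (0.0, 5.0)
    trait_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "social_anxiety": (19.0, 56.0),
            "depression": (9.0, 52.0),
            "cognitive_empathy": (43.0, 76.0),
            "affective_empathy": (20.0, 45.0),
        }
    )
    # participant-level deviation scales (multiplied by between_participant_sd)
    hr_offset_sd: float = 5.0          # bpm, per participant, whole session
    hr_segment_jitter_sd: float = 1.5  # bpm, per participant per segment
    eda_offset_sd: float = 0.3         # µS tonic offset
    temp_offset_sd: float = 0.3        # °C offset
    temp_slope_jitter_sd: float = 0.03  # °C/min per participant per segment
    resp_jitter_sd: float = 0.5        # breaths/min per participant per segment
    scr_rate_jitter_sd: float = 0.2    # log-scale multiplicative jitter
    segment_seconds: float = 240.0
    fs: float = 600.0

    def __post_init__(self) -> None:
        for sc, items in self.sam_iiq.items():
            for item, (_, sd) in items.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {sc}/{item}")
        for name, (_, sd) in self.traits.items():
            if sd < 0:
                raise ValueError(f"negative SD for trait {name}")

    def params_for(self, segment_label: str | None) -> ScenarioParams:
        if segment_label is None:
            return self.baseline
        return self.scenarios[segment_label]


def default_effect_config() -> EffectConfig:
    """The default study conditions.

    Self-report (SAM/IIQ) means and SDs are the cohort's printed
    per-scenario questionnaire statistics; trait distributions are the
    cohort's printed trait statistics. Physiological effect sizes are the
    package's stated modelling assumptions (not printed by the study):
    high-arousal scenarios get larger heart-rate shift, RR variability,
    SCR rate and respiration rate than low-arousal ones, and
    positive-valence scenarios get stronger cross-participant coupling
    (and a positive rather than negative temperature drift) than
    negative-valence ones.
    """
    scen = {
        "PV-HA": ScenarioParams("positive", "high", 15.0, 1.5, 8.0, 18.0, 0.02, 0.7),
        "PV-LA": ScenarioParams("positive", "low", 5.0, 0.9, 3.0, 13.0, 0.02, 0.7),
        "NV-HA": ScenarioParams("negative", "high", 15.0, 1.5, 8.0, 18.0, -0.04, 0.2),
        "NV-LA": ScenarioParams("negative", "low", 5.0, 0.9, 3.0, 13.0, -0.04, 0.2),
    }
    baseline = ScenarioParams("neutral", "neutral", 0.0, 1.0, 1.5, 14.0, 0.0, 0.0)
    sam_iiq = {
        "PV-HA": {
            "sam_valence": (8.4, 0.8), "sam_arousal": (7.0, 1.7),
            "iiq_amount": (4.0, 1.0), "iiq_balance": (3.7, 1.1),
            "iiq_valence": (3.4, 0.9),
        },
        "PV-LA": {
            "sam_valence": (7.0, 1.2), "sam_arousal": (4.6, 1.7),
            "iiq_amount": (4.0, 1.0), "iiq_balance": (3.8, 1.2),
            "iiq_valence": (3.4, 0.9),
        },
        "NV-LA": {
            "sam_valence": (4.6, 1.7), "sam_arousal": (5.2, 1.7),
            "iiq_amount": (4.0, 1.0), "iiq_balance": (3.9, 1.2),
            "iiq_valence": (1.4, 0.6),
        },
        "NV-HA": {
            "sam_valence": (4.4, 2.4), "sam_arousal": (7.4, 1.5),
            "iiq_amount": (4.0, 1.0), "iiq_balance": (3.9, 1.2),
            "iiq_valence": (2.0, 0.7),
        },
    }
    traits = {
        "social_anxiety": (39.2, 9.7),
        "depression": (25.9, 10.7),
        "cognitive_empathy": (57.9, 7.2),
        "affective_empathy": (35.3, 5.5),
    }
    return EffectConfig(scenarios=scen, baseline=baseline, sam_iiq=sam_iiq, traits=traits)


# ---------------------------------------------------------------------------
# latent processes
# ---------------------------------------------------------------------------

def _bandlimited_noise(
    n: int, fs: float, band: tuple[float, float], rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` Hz."""
    white = rng.standard_normal(n)
    lo, hi = band
    nyq = fs / 2.0
    sos = sps.butter(2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    x = sps.sosfiltfilt(sos, white)
    sd = x.std()
    if sd > 0:
        x = x / sd
    return x


def shared_modulator(duration: float, rng: np.random.Generator) -> np.ndarray:
    """One realization of the shared latent modulator.

    Band-limited (0.03–0.15 Hz) unit-variance Gaussian noise sampled at the
    internal rate grid; both participants of a dyad receive the same
    realization within a segment, scaled by their scenario's ``coupling``.
    """
    n = int(round(duration * RATE_FS))
    return _bandlimited_noise(n, RATE_FS, (0.03, 0.15), rng)


def _ricker_template(fs: float, width_s: float = 0.012) -> np.ndarray:
    """R-wave stand-in: a Ricker (negative Gaussian second-derivative)
    pulse, whose dominant central peak sits exactly at the beat time."""
    half = int(round(6 * width_s * fs))
    t = (np.arange(2 * half + 1) - half) / fs
    a = (t / width_s) ** 2
    return (1.0 - a) * np.exp(-a / 2.0)


def _scr_kernel(fs: float, rise_s: float = 0.75, decay_s: float = 4.0) -> np.ndarray:
    """Difference-of-exponentials SCR transient, normalized to unit peak."""
    t = np.arange(0.0, 8.0 * decay_s, 1.0 / fs)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def _add_events(series: np.ndarray, fs: float, times: np.ndarray,
                kernel: np.ndarray, amplitudes: np.ndarray, center: int = 0) -> None:
    """Add ``amplitude * kernel`` into ``series`` at each event time."""
    n = len(series)
    for t, a in zip(times, amplitudes):
        i0 = int(round(t * fs)) - center
        k0, k1 = max(0, -i0), min(len(kernel), n - i0)
        if k1 > k0:
            series[i0 + k0 : i0 + k1] += a * kernel[k0:k1]


@dataclass
class ParticipantSignals:
    """Raw channels of one participant for one segment, plus the ground
    truth the generator knows (event times in segment-local seconds and the
    latent instantaneous-rate series)."""

    signals: dict[str, np.ndarray]
    beat_times: np.ndarray
    breath_times: np.ndarray
    scr_times: np.ndarray
    scr_amplitudes: np.ndarray
    rate_t: np.ndarray
    rate_bpm: np.ndarray


def generate_participant_signals(
    params: ScenarioParams,
    shared_modulator: np.ndarray,
    duration: float,
    fs: float,
    rng_seed,
    *,
    hr_baseline_bpm: float = 70.0,
    eda_baseline_uS: float = 2.0,
    temp_baseline_C: float = 33.0,
    noise_sd: dict[str, float] | None = None,
) -> ParticipantSignals:
    """Generate one participant's four raw channels for one segment.

    ECG is a train of Ricker pulses placed at beat times integrated from a
    latent instantaneous-rate process (baseline + ``hr_mean_shift`` +
    individual band-limited variability × ``hr_var_scale`` + ``coupling`` ×
    shared modulator). EDA is a tonic level plus difference-of-exponentials
    SCR transients at Poisson times with log-normal amplitudes around
    0.3 µS. Respiration is a frequency-modulated oscillation at
    ``resp_rate``/60 Hz with slow jitter and the coupling-mixed modulator.
    Temperature drifts at ``temp_slope`` with low-frequency noise.

    ``rng_seed`` may be an integer or a ``numpy.random.Generator``;
    identical seeds give bitwise-identical output.
    """
    if duration <= 0 or fs <= 0:
        raise ValueError("duration and fs must be positive")
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz for resolvable peaks")
    rng = np.random.default_rng(rng_seed)
    noise = dict(noise_sd or {"ecg": 0.01, "eda": 0.01, "resp": 0.05, "temp": 0.02})

    n = int(round(duration * fs))
    n_rate = int(round(duration * RATE_FS))
    t_rate = np.arange(n_rate) / RATE_FS
    t = np.arange(n) / fs

    mod = np.asarray(shared_modulator, dtype=float)
    if len(mod) != n_rate:  # resample the modulator onto the rate grid
        mod = np.interp(t_rate, np.linspace(0, duration, len(mod), endpoint=False), mod)

    # --- cardiac: latent rate -> beat times -> pulse train -------------
    indiv = _bandlimited_noise(n_rate, RATE_FS, (0.03, 0.4), rng)
    rate = (
        hr_baseline_bpm
        + params.hr_mean_shift
        + params.hr_var_scale * INDIV_HR_BPM * indiv
        + params.coupling * COUPLING_HR_BPM * mod
    )
    rate = np.clip(rate, 30.0, None)
    phase = cumulative_trapezoid(rate / 60.0, t_rate, initial=0.0)
    n_beats = int(np.floor(phase[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1), phase, t_rate)
    ecg = rng.normal(0.0, noise["ecg"], n)
    tmpl = _ricker_template(fs)
    _add_events(ecg, fs, beat_times, tmpl, np.ones(n_beats), center=len(tmpl) // 2)

    # --- electrodermal: tonic + Poisson SCR transients ------------------
    n_scr = rng.poisson(params.scr_rate * duration / 60.0)
    scr_times = np.sort(rng.uniform(0.0, duration, n_scr))
    scr_amps = np.exp(rng.normal(np.log(0.3), 0.4, n_scr))
    eda = np.full(n, eda_baseline_uS) + rng.normal(0.0, noise["eda"], n)
    _add_events(eda, fs, scr_times, _scr_kernel(fs), scr_amps)

    # --- respiration: frequency-modulated oscillation -------------------
    slow = _bandlimited_noise(n_rate, RATE_FS, (0.003, 0.03), rng)
    f_resp = (
        params.resp_rate / 60.0 * (1.0 + 0.05 * slow)
        + params.coupling * COUPLING_RESP_HZ * mod
    )
    f_resp = np.clip(f_resp, 0.05, None)
    resp_phase = cumulative_trapezoid(f_resp, t_rate, initial=0.0)
    resp = np.sin(2 * np.pi * np.interp(t, t_rate, resp_phase))
    resp += rng.normal(0.0, noise["resp"], n)
    # crest times: phase = 0.25, 1.25, ... cycles
    crest_phases = np.arange(0.25, resp_phase[-1], 1.0)
    breath_times = np.interp(crest_phases, resp_phase, t_rate)

    # --- temperature: linear drift + low-frequency noise ----------------
    temp = temp_baseline_C + params.temp_slope * t / 60.0
    if noise["temp"] > 0:
        # low-frequency noise lives below 0.01 Hz; synthesize it on the
        # coarse rate grid and interpolate to fs
        sos = sps.butter(2, 0.01 / (RATE_FS / 2.0), btype="lowpass", output="sos")
        slow_t = sps.sosfiltfilt(sos, rng.standard_normal(n_rate))
        sd = slow_t.std()
        if sd > 0:
            temp = temp + noise["temp"] * np.interp(t, t_rate, slow_t / sd)

    return ParticipantSignals(
        signals={"ecg": ecg, "eda": eda, "resp": resp, "temp": temp},
        beat_times=beat_times,
        breath_times=breath_times,
        scr_times=scr_times,
        scr_amplitudes=scr_amps,
        rate_t=t_rate,
        rate_bpm=rate,
    )


# ---------------------------------------------------------------------------
# dyad and cohort assembly
# ---------------------------------------------------------------------------

def _jittered_params(
    params: ScenarioParams,
    effect: EffectConfig,
    hr_offset: float,
    rng: np.random.Generator,
) -> ScenarioParams:
    """Participant/segment-level perturbation of scenario parameters."""
    s = params.between_participant_sd
    return dataclasses.replace(
        params,
        hr_mean_shift=params.hr_mean_shift + hr_offset
        + rng.normal(0.0, s * effect.hr_segment_jitter_sd),
        resp_rate=max(
            4.0, params.resp_rate + rng.normal(0.0, s * effect.resp_jitter_sd)
        ),
        temp_slope=params.temp_slope
        + rng.normal(0.0, s * effect.temp_slope_jitter_sd),
        scr_rate=params.scr_rate
        * np.exp(rng.normal(0.0, s * effect.scr_rate_jitter_sd)),
    )


def generate_dyad_recording(
    effect: EffectConfig,
    scenario_order: list[str] | tuple[str, ...],
    dyad_seed: int,
    dyad_id: str | None = None,
) -> DyadRecording:
    """Generate one dyad's six-segment session.

    The session is baseline1, the four scenarios in ``scenario_order``,
    baseline2 — contiguous segments of ``effect.segment_seconds`` each at
    ``effect.fs``. Within every segment both participants share a single
    latent-modulator realization (mixed per that segment's ``coupling``);
    participant-level offsets are drawn once per dyad with scales given by
    the config, times ``between_participant_sd``.
    """
    order = list(scenario_order)
    if sorted(order) != sorted(SCENARIOS):
        raise ValueError(f"scenario_order must be a permutation of {SCENARIOS}")
    rng = np.random.default_rng(dyad_seed)
    if dyad_id is None:
        dyad_id = f"dyad{dyad_seed:08d}"

    seg_len = int(round(effect.segment_seconds * effect.fs))
    seg_labels: list[str | None] = [None, *order, None]
    seg_names = ["baseline1"] + [f"conversation{i+1}" for i in range(4)] + ["baseline2"]

    s_base = effect.baseline.between_participant_sd
    offsets = {
        p: {
            "hr": rng.normal(0.0, s_base * effect.hr_offset_sd),
            "eda": rng.normal(0.0, s_base * effect.eda_offset_sd),
            "temp": rng.normal(0.0, s_base * effect.temp_offset_sd),
        }
        for p in PARTICIPANTS
    }

    chunks: dict[str, list[np.ndarray]] = {p: [] for p in PARTICIPANTS}
    truth: dict = {p: {"beat_times": [], "breath_times": [], "scr_times": [],
                       "scr_amplitudes": [], "rate_t": [], "rate_bpm": []}
                   for p in PARTICIPANTS}
    segments: list[Segment] = []

    for i, (name, label) in enumerate(zip(seg_names, seg_labels)):
        params = effect.params_for(label)
        mod = shared_modulator(effect.segment_seconds, rng)
        t0 = i * effect.segment_seconds
        for p in PARTICIPANTS:
            pp = _jittered_params(params, effect, offsets[p]["hr"], rng)
            sig = generate_participant_signals(
                pp, mod, effect.segment_seconds, effect.fs,
                rng.integers(2**31),
                hr_baseline_bpm=effect.hr_baseline_bpm,
                eda_baseline_uS=effect.eda_baseline_uS + offsets[p]["eda"],
                temp_baseline_C=effect.temp_baseline_C + offsets[p]["temp"],
                noise_sd=effect.noise_sd,
            )
            chunks[p].append(sig)
            tr = truth[p]
            tr["beat_times"].append(sig.beat_times + t0)
            tr["breath_times"].append(sig.breath_times + t0)
            tr["scr_times"].append(sig.scr_times + t0)
            tr["scr_amplitudes"].append(sig.scr_amplitudes)
            tr["rate_t"].append(sig.rate_t + t0)
            tr["rate_bpm"].append(sig.rate_bpm)
        segments.append(Segment(name, i * seg_len, (i + 1) * seg_len, label))

    signals = {
        p: {
            sig: np.concatenate([c.signals[sig] for c in chunks[p]])
            for sig in ("ecg", "eda", "resp", "temp")
        }
        for p in PARTICIPANTS
    }
    for p in PARTICIPANTS:
        for key in list(truth[p]):
            truth[p][key] = np.concatenate(truth[p][key])

    return DyadRecording(dyad_id=dyad_id, fs=effect.fs, signals=signals,
                         segments=segments, truth=truth)


@dataclass
class Cohort:
    """A generated study cohort.

    ``recordings`` may be ``None`` when only questionnaire channels were
    generated (e.g. for moment-recovery checks at large n).
    """

    recordings: list[DyadRecording] | None
    traits: pd.DataFrame
    selfreport: pd.DataFrame
    effect: EffectConfig
    seed: int

    @property
    def dyad_ids(self) -> list[str]:
        return list(self.traits["dyad_id"].unique())


def _clip(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip(x, lo, hi)


def generate_cohort(
    n_dyads: int,
    effect: EffectConfig | None = None,
    seed: int = 0,
    include_signals: bool = True,
) -> Cohort:
    """Generate a cohort of dyads with random per-dyad scenario orders.

    Trait scores are drawn once per participant from the configured trait
    distributions (clipped to instrument ranges); SAM/IIQ answers are drawn
    per participant per scenario from the per-scenario distributions,
    clipped to SAM 1–9 / IIQ 0–5. With ``include_signals=False`` only the
    questionnaire channels are generated (cheap; used for large-n moment
    checks).
    """
    if n_dyads < 2:
        raise ValueError("n_dyads must be >= 2")
    effect = effect or default_effect_config()
    rng = np.random.default_rng(seed)

    recordings = [] if include_signals else None
    trait_rows, sr_rows = [], []
    for d in range(n_dyads):
        dyad_id = f"dyad{d:03d}"
        order = list(rng.permutation(SCENARIOS))
        dyad_seed = int(rng.integers(2**31))
        if include_signals:
            rec = generate_dyad_recording(effect, order, dyad_seed, dyad_id=dyad_id)
            recordings.append(rec)
        for p in PARTICIPANTS:
            row = {"dyad_id": dyad_id, "participant": p}
            for name in TRAITS:
                mean, sd = effect.traits[name]
                lo, hi = effect.trait_ranges[name]
                row[name] = float(_clip(rng.normal(mean, sd), lo, hi))
            trait_rows.append(row)
            for sc in SCENARIOS:
                sr = {"dyad_id": dyad_id, "participant": p, "scenario": sc}
                for item in SELFREPORT_ITEMS:
                    mean, sd = effect.sam_iiq[sc][item]
                    lo, hi = (
                        effect.sam_range if item.startswith("sam") else effect.iiq_range
                    )
                    sr[item] = float(_clip(rng.normal(mean, sd), lo, hi))
                sr_rows.append(sr)

    return Cohort(
        recordings=recordings,
        traits=pd.DataFrame(trait_rows),
        selfreport=pd.DataFrame(sr_rows),
        effect=effect,
        seed=seed,
    )
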