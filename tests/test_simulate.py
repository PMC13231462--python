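"""Generator behaviour: questionnaire defaults, scenario effect ordering,
segment structure, determinism, and coupling-induced heart-rate
correlation."""

import dataclasses

import numpy as np
import pytest

import dyadaffect as da
from dyadaffect.simulate import shared_modulator

from conftest import CANONICAL_ORDER


class TestDefaultConfig:
    def test_table_questionnaire_defaults(self, effect):
        assert effect.sam_iiq["PV-HA"]["sam_valence"] == (8.4, 0.8)
        assert effect.sam_iiq["PV-LA"]["sam_arousal"] == (4.6, 1.7)
        assert effect.sam_iiq["NV-HA"]["sam_valence"] == (4.4, 2.4)
        assert effect.sam_iiq["NV-LA"]["iiq_valence"] == (1.4, 0.6)
        assert effect.traits["social_anxiety"] == (39.2, 9.7)
        assert effect.traits["cognitive_empathy"] == (57.9, 7.2)
        assert effect.traits["depression"] == (25.9, 10.7)
        assert effect.traits["affective_empathy"] == (35.3, 5.5)

    def test_arousal_and_valence_effect_ordering(self, effect):
        for pv, nv in (("PV-HA", "NV-HA"), ("PV-LA", "NV-LA")):
            assert effect.scenarios[pv].coupling > effect.scenarios[nv].coupling
        for hi, lo in (("PV-HA", "PV-LA"), ("NV-HA", "NV-LA")):
            hi_p, lo_p = effect.scenarios[hi], effect.scenarios[lo]
            assert hi_p.hr_mean_shift > lo_p.hr_mean_shift
            assert hi_p.scr_rate > lo_p.scr_rate
            assert hi_p.resp_rate > lo_p.resp_rate

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            da.ScenarioParams("positive", "high", 0, 1, 1, 14, 0, coupling=1.5)
        with pytest.raises(ValueError):
            da.ScenarioParams("positive", "high", 0, 1, -1, 14, 0, coupling=0.5)


class TestParticipantSignals:
    def test_zero_variability_gives_exact_metronome(self, effect):
        params = dataclasses.replace(
            effect.baseline, hr_mean_shift=-10.0, hr_var_scale=0.0, coupling=0.0
        )  # 70 - 10 = 60 bpm
        mod = np.zeros(int(60 * 8))
        sig = da.generate_participant_signals(params, mod, 60.0, 600.0, 1)
        assert np.allclose(np.diff(sig.beat_times), 1.0, atol=1e-6)

    def test_zero_scr_rate_and_noise_gives_constant_eda(self, effect):
        params = dataclasses.replace(effect.baseline, scr_rate=0.0)
        mod = np.zeros(int(30 * 8))
        sig = da.generate_participant_signals(
            params, mod, 30.0, 600.0, 1,
            noise_sd={"ecg": 0, "eda": 0, "resp": 0, "temp": 0},
        )
        assert np.allclose(sig.signals["eda"], 2.0)

    def test_same_seed_bitwise_identical(self, effect):
        mod = shared_modulator(30.0, np.random.default_rng(5))
        a = da.generate_participant_signals(effect.scenarios["PV-HA"], mod, 30.0, 600.0, 7)
        b = da.generate_participant_signals(effect.scenarios["PV-HA"], mod, 30.0, 600.0, 7)
        for s in ("ecg", "eda", "resp", "temp"):
            assert np.array_equal(a.signals[s], b.signals[s])

    def test_invalid_duration_rejected(self, effect):
        with pytest.raises(ValueError):
            da.generate_participant_signals(effect.baseline, np.zeros(8), -1.0, 600.0, 0)


def _coupling_correlation(effect, coupling, seed, duration=240.0):
    """Zero-lag Pearson r of the two participants' latent HR series when
    both receive the same modulator realization."""
    rng = np.random.default_rng(seed)
    params = dataclasses.replace(
        effect.scenarios["PV-HA"], coupling=coupling, hr_var_scale=1.0
    )
    mod = shared_modulator(duration, rng)
    a = da.generate_participant_signals(params, mod, duration, 150.0, int(rng.integers(2**31)))
    b = da.generate_participant_signals(params, mod, duration, 150.0, int(rng.integers(2**31)))
    return np.corrcoef(a.rate_bpm, b.rate_bpm)[0, 1]


class TestCoupling:
    def test_full_coupling_no_individual_noise_gives_unit_correlation(self, effect):
        rng = np.random.default_rng(0)
        params = dataclasses.replace(
            effect.scenarios["PV-HA"], coupling=1.0, hr_var_scale=0.0
        )
        mod = shared_modulator(240.0, rng)
        a = da.generate_participant_signals(params, mod, 240.0, 150.0, 1)
        b = da.generate_participant_signals(params, mod, 240.0, 150.0, 2)
        r = np.corrcoef(a.rate_bpm, b.rate_bpm)[0, 1]
        assert r > 0.95

    def test_zero_coupling_gives_near_zero_correlation(self, effect):
        rs = [_coupling_correlation(effect, 0.0, seed) for seed in range(50)]
        assert abs(np.mean(rs)) < 0.2


class TestDyadRecording:
    def test_six_segments_of_240s(self, dyad_recording, effect):
        assert len(dyad_recording.segments) == 6
        for seg in dyad_recording.segments:
            assert seg.n_samples == int(240 * effect.fs)

    def test_labels_follow_requested_order(self, dyad_recording):
        conv = [s.label for s in dyad_recording.conversation_segments]
        assert conv == list(CANONICAL_ORDER)

    def test_duplicate_scenario_rejected(self, effect):
        with pytest.raises(ValueError):
            da.generate_dyad_recording(effect, ["PV-HA"] * 4, 0)

    def test_recording_deterministic(self, effect):
        small = dataclasses.replace(effect, segment_seconds=20.0, fs=150.0)
        a = da.generate_dyad_recording(small, list(CANONICAL_ORDER), 3)
        b = da.generate_dyad_recording(small, list(CANONICAL_ORDER), 3)
        assert np.array_equal(a.signals["p1"]["ecg"], b.signals["p1"]["ecg"])
        assert np.array_equal(a.signals["p2"]["temp"], b.signals["p2"]["temp"])


class TestCohort:
    def test_counts_and_determinism(self, effect):
        small = dataclasses.replace(effect, segment_seconds=20.0, fs=150.0)
        c1 = da.generate_cohort(3, small, seed=11)
        c2 = da.generate_cohort(3, small, seed=11)
        assert len(c1.recordings) == 3
        assert sum(len(r.conversation_segments) for r in c1.recordings) == 12
        assert len(c1.traits) == 6                    # 2 participants per dyad
        assert len(c1.selfreport) == 24               # 2 x 4 scenarios per dyad
        assert c1.selfreport.equals(c2.selfreport)
        assert np.array_equal(
            c1.recordings[0].signals["p1"]["eda"], c2.recordings[0].signals["p1"]["eda"]
        )
        with pytest.raises(ValueError):
            da.generate_cohort(1, small, seed=0)

    def test_selfreport_moment_recovery(self, effect):
        """Sample means of generated questionnaire answers converge to the
        configured per-scenario means (clipping bias stays within 0.15 even
        for the most skewed item)."""
        cohort = da.generate_cohort(500, effect, seed=2, include_signals=False)
        sr = cohort.selfreport
        for sc in CANONICAL_ORDER:
            for item in ("sam_valence", "sam_arousal", "iiq_balance", "iiq_valence"):
                got = sr.loc[sr.scenario == sc, item].mean()
                want = effect.sam_iiq[sc][item][0]
                assert abs(got - want) < 0.15, (sc, item, got, want)

    def test_scenario_separation_monotone_in_arousal_effect_size(self, effect):
        """Doubling the high-vs-low arousal parameter gaps cannot decrease
        downstream 4-class recovery (averaged over seeds; small cohorts
        keep the check affordable)."""
        import dataclasses
        from dyadaffect.experiments import default_arch, featurized_datasets, recovery_accuracy

        doubled = dict(effect.scenarios)
        for hi, lo in (("PV-HA", "PV-LA"), ("NV-HA", "NV-LA")):
            h, l = effect.scenarios[hi], effect.scenarios[lo]
            # location-like parameters only: widening a dispersion gap
            # (hr_var_scale) adds noise rather than class separation
            doubled[hi] = dataclasses.replace(
                h,
                hr_mean_shift=l.hr_mean_shift + 2 * (h.hr_mean_shift - l.hr_mean_shift),
                scr_rate=l.scr_rate + 2 * (h.scr_rate - l.scr_rate),
                resp_rate=l.resp_rate + 2 * (h.resp_rate - l.resp_rate),
            )
        eff2 = dataclasses.replace(effect, scenarios=doubled)

        arch = default_arch(n_features=5)
        def mean_acc(cfg):
            accs = []
            for seed in (0, 1):
                ds, _ = featurized_datasets(8, seed=500 + seed, effect=cfg)
                accs.append(recovery_accuracy(ds, arch, seed=seed))
            return np.mean(accs)

        assert mean_acc(eff2) >= mean_acc(effect) - 1e-12

    def test_answers_respect_instrument_ranges(self, effect):
        cohort = da.generate_cohort(200, effect, seed=3, include_signals=False)
        sam = cohort.selfreport[["sam_valence", "sam_arousal"]].to_numpy()
        iiq = cohort.selfreport[["iiq_amount", "iiq_balance", "iiq_valence"]].to_numpy()
        assert sam.min() >= 1.0 and sam.max() <= 9.0
        assert iiq.min() >= 0.0 and iiq.max() <= 5.0
        for tr, (lo, hi) in effect.trait_ranges.items():
            assert cohort.traits[tr].between(lo, hi).all()
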