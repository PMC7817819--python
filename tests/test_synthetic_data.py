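"""Virtual subject / gait trial generator: determinism, contracts, physics."""

import numpy as np
import pytest

from ccistiff.subject import subject_to_dict
from ccistiff.synthetic_data import (
    CouplingScenario,
    GeneratorConfig,
    MuscleSpec,
    make_gait_trial,
    make_subject,
    synthesize_raw_emg,
)


class TestMakeSubject:
    def test_seeded_determinism_field_for_field(self, gen_config):
        s1 = make_subject(gen_config, seed=123)
        s2 = make_subject(gen_config, seed=123)
        assert subject_to_dict(s1) == subject_to_dict(s2)

    def test_default_delays_are_82_and_93_ms(self, subject):
        assert subject.legs["non-paretic"].electromechanical_delay_ms == 82.0
        assert subject.legs["paretic"].electromechanical_delay_ms == 93.0

    def test_scale_factors_in_table_range(self, subject):
        for leg in subject.legs.values():
            for m in leg.muscles:
                assert 0.05 <= m.emg_scale <= 1.0

    def test_sixteen_muscles_per_leg(self, subject):
        for leg in subject.legs.values():
            assert len(leg.muscles) == 16

    def test_degenerate_config_without_antagonism_rejected(self):
        flex_only = tuple(
            s for s in GeneratorConfig().muscle_specs
            if not ("knee_flexion" in s.roles and s.roles["knee_flexion"] == "EXT")
        )
        with pytest.raises(ValueError, match="no antagonism"):
            make_subject(GeneratorConfig(muscle_specs=flex_only), seed=0)

    def test_uniform_scale_mode_draws_in_range(self, gen_config):
        import dataclasses

        cfg = dataclasses.replace(gen_config, scale_mode="uniform")
        s = make_subject(cfg, seed=5)
        scales = [m.emg_scale for leg in s.legs.values() for m in leg.muscles]
        assert all(0.05 <= x <= 1.0 for x in scales)
        assert len(set(scales)) > 10  # actually drawn, not constant


class TestMakeGaitTrial:
    def test_heel_strike_count(self, subject, gen_config):
        trial, _ = make_gait_trial(subject, 10, "coupled", seed=3, config=gen_config)
        assert trial.heel_strikes.size == 11
        assert trial.n_cycles == 10

    def test_deterministic_for_fixed_seed(self, subject, gen_config):
        t1, g1 = make_gait_trial(subject, 2, "coupled", seed=9, config=gen_config)
        t2, g2 = make_gait_trial(subject, 2, "coupled", seed=9, config=gen_config)
        key = "paretic/soleus"
        np.testing.assert_array_equal(t1.emg_channels[key], t2.emg_channels[key])
        np.testing.assert_array_equal(
            g1.true_stiffness["paretic/knee_flexion"],
            g2.true_stiffness["paretic/knee_flexion"],
        )

    def test_nonpositive_cycles_rejected(self, subject):
        with pytest.raises(ValueError, match="n_cycles"):
            make_gait_trial(subject, 0, "coupled", seed=0)

    def test_envelopes_bounded_and_raw_mean_near_zero(self, small_trial):
        trial, truth = small_trial
        for key, env in truth.true_envelopes.items():
            assert env.min() >= 0.0 and env.max() <= 1.0
        for key, raw in trial.emg_channels.items():
            se = raw.std() / np.sqrt(len(raw))
            assert abs(raw.mean()) < 3 * se

    def test_zero_amplitude_gives_activation_free_stiffness(self, subject, gen_config):
        import dataclasses

        cfg = dataclasses.replace(gen_config, burst_amp_scale=0.0)
        _, truth = make_gait_trial(subject, 2, "coupled", seed=1, config=cfg)
        for key, act in truth.true_activations.items():
            np.testing.assert_allclose(act, 0.0, atol=1e-12)
        # stiffness reduces to the passive (activation-free) profile: identical
        # across cycles because kinematics repeat exactly
        for key, ks in truth.true_stiffness.items():
            np.testing.assert_allclose(ks[0], ks[1], atol=1e-9)

    def test_independent_amplitudes_uncorrelated_across_cycles(self, subject, gen_config):
        # averaged over five antagonist pairs to keep the sample-correlation
        # estimate well inside the noise floor (single-pair |r| has sd ~ 0.14
        # at n = 50, so a lone pair can produce tail draws above 0.3)
        _, truth = make_gait_trial(subject, 50, "independent", seed=4, config=gen_config)
        pairs = [("tibant", "soleus"), ("recfem", "semimem"), ("addlong", "glmax2"),
                 ("tibant", "gasmed"), ("vaslat", "bflh")]
        rs = [
            abs(np.corrcoef(truth.burst_amplitudes[f"non-paretic/{a}"],
                            truth.burst_amplitudes[f"non-paretic/{b}"])[0, 1])
            for a, b in pairs
        ]
        assert np.mean(rs) < 0.3

    def test_coupled_amplitudes_strongly_correlated(self, subject, gen_config):
        _, truth = make_gait_trial(subject, 50, "coupled", seed=4, config=gen_config)
        a = truth.burst_amplitudes["non-paretic/tibant"]
        b = truth.burst_amplitudes["non-paretic/soleus"]
        assert np.corrcoef(a, b)[0, 1] > 0.9

    def test_summed_antagonist_activity_tracks_true_stiffness(self, subject, gen_config):
        """Coupled world: total muscle envelope activity follows K within cycles."""
        from ccistiff.emg_processing import segment_cycles

        trial, truth = make_gait_trial(subject, 5, "coupled", seed=2, config=gen_config)
        leg = subject.legs["non-paretic"]
        delay = leg.electromechanical_delay_ms
        from ccistiff.emg_processing import delay_shift

        total = sum(
            delay_shift(truth.true_envelopes[f"non-paretic/{m.name}"],
                        trial.emg_rate, delay)
            for m in leg.muscles
        )
        cycles = segment_cycles(total, trial.emg_rate, trial.heel_strikes)
        # the hip is the reference joint for coupling checks: its stiffness is
        # dominated by the activation term rather than the passive profile
        ks = truth.true_stiffness["non-paretic/hip_flexion"]
        rs = [np.corrcoef(cycles[k], ks[k])[0, 1] for k in range(5)]
        assert np.mean(rs) > 0.7


class TestSynthesizeRawEmg:
    def test_zero_envelope_zero_floor_gives_zeros(self):
        out = synthesize_raw_emg(np.zeros(2000), 1000.0, 0.0, seed=0)
        np.testing.assert_array_equal(out, 0.0)

    def test_constant_envelope_mean_within_3se(self):
        means, ses = [], []
        for seed in range(20):
            out = synthesize_raw_emg(np.full(4000, 0.5), 1000.0, 0.0, seed=seed)
            means.append(out.mean())
            ses.append(out.std() / np.sqrt(len(out)))
        assert np.all(np.abs(means) < 3 * np.array(ses))

    def test_low_rate_rejected_and_substudy_rate_warns(self):
        with pytest.raises(ValueError, match="900"):
            synthesize_raw_emg(np.zeros(100), 880.0, 0.0, seed=0)
        with pytest.warns(UserWarning, match="1,000 Hz"):
            synthesize_raw_emg(np.zeros(5000), 950.0, 0.0, seed=0)

    def test_bad_noise_floor_rejected(self):
        with pytest.raises(ValueError, match="noise_floor"):
            synthesize_raw_emg(np.zeros(100), 1000.0, 0.5, seed=0)

    def test_envelope_recovered_after_processing(self):
        """Round trip: synthesize -> envelope pipeline, RMSE < 0.1 of peak."""
        from ccistiff.emg_processing import envelope

        rate, T = 1000.0, 1.4
        t = np.arange(int(7 * T * rate)) / rate
        true = 0.8 * np.exp(-(((t % T) - 0.6) ** 2) / (2 * 0.12**2))
        raw = synthesize_raw_emg(true, rate, 0.05, seed=21)
        est = envelope(raw, rate, T)
        sl = slice(1500, -1500)  # exclude filter edge regions
        est_n = est[sl] / est[sl].max()
        true_n = true[sl] / true[sl].max()
        rmse = np.sqrt(np.mean((est_n - true_n) ** 2))
        assert rmse < 0.1


class TestCouplingScenario:
    def test_parse_accepts_strings_and_numbers(self):
        assert CouplingScenario.parse("independent").kind == "independent"
        assert CouplingScenario.parse("coupled").strength == 1.0
        assert CouplingScenario.parse(0.4).strength == 0.4
        assert CouplingScenario.parse("0.25").strength == 0.25

    def test_bad_values_rejected(self):
        with pytest.raises(ValueError):
            CouplingScenario("both")
        with pytest.raises(ValueError):
            CouplingScenario("coupled", strength=1.5)
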