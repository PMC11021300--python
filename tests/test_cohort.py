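import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from extrot.cohort import (ANGLE_SET, ChoicePolicy, CohortConfig,
                           CohortConfigError, Distribution, choose_strategy,
                           internal_response, perceived_rt_delta,
                           profiles_to_csv, sample_cohort, sample_profile,
                           scenario_preset)

from conftest import make_profile, point_config


class TestSampleProfile:
    def test_point_mass_equals_means(self):
        cfg = point_config(a_int=1234.0, b_int=3.5, rt_bias=-50.0)
        p = sample_profile(cfg, 0)
        assert p.a_int == 1234.0 and p.b_int == 3.5 and p.rt_bias == -50.0

    def test_determinism(self):
        cfg = scenario_preset("exp1", n_participants=5, seed=99)
        assert sample_profile(cfg, 3) == sample_profile(cfg, 3)

    def test_different_indices_differ(self):
        cfg = scenario_preset("exp1", n_participants=5, seed=99)
        assert sample_profile(cfg, 0) != sample_profile(cfg, 1)

    def test_lognormal_moments(self):
        dists = point_config().distributions.copy()
        dists["b_int"] = Distribution("lognormal", 4.0, 1.2)
        cfg = CohortConfig(n_participants=10_000, distributions=dists, seed=7)
        draws = np.array([sample_profile(cfg, i).b_int for i in range(10_000)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 4.0) < 3 * se

    def test_out_of_range_index(self):
        cfg = point_config(n=2)
        with pytest.raises(CohortConfigError):
            sample_profile(cfg, 2)

    def test_invalid_distribution_rejected(self):
        dists = point_config().distributions.copy()
        dists["eps0_int"] = Distribution("point", 0.9)  # outside [0, 0.5]
        cfg = CohortConfig(n_participants=1, distributions=dists, seed=0)
        with pytest.raises(CohortConfigError, match="eps0_int"):
            sample_profile(cfg, 0)

    def test_missing_field_named(self):
        dists = point_config().distributions.copy()
        del dists["a_man"]
        with pytest.raises(CohortConfigError, match="a_man"):
            CohortConfig(n_participants=1, distributions=dists)

    def test_truncation_keeps_invariants(self):
        dists = point_config().distributions.copy()
        dists["sigma_rt"] = Distribution("normal", 10.0, 200.0)
        cfg = CohortConfig(n_participants=200, distributions=dists, seed=3)
        assert all(p.sigma_rt >= 0 for p in sample_cohort(cfg))


class TestInternalResponse:
    def test_noiseless_linear(self, rng):
        p = make_profile(a_int=1000.0, b_int=2.0)
        rt, correct = internal_response(p, 180, rng)
        assert rt == 1360.0 and correct

    def test_error_free_always_correct(self, rng):
        p = make_profile(sigma_rt=100.0)
        assert all(internal_response(p, 60, rng)[1] for _ in range(200))

    def test_mean_rt_monte_carlo(self, rng):
        p = make_profile(sigma_rt=300.0)
        rts = np.array([internal_response(p, 120, rng)[0] for _ in range(5000)])
        se = 300.0 / np.sqrt(5000)
        assert abs(rts.mean() - (1000.0 + 120 * 2.0)) < 3 * se

    def test_timeout_is_incorrect(self, rng):
        p = make_profile(a_int=11900.0, b_int=2.0)
        rt, correct = internal_response(p, 180, rng)
        assert rt == 12000.0 and not correct

    def test_error_rate_clamped(self, rng):
        p = make_profile(eps0_int=0.4, eps1_int=0.01)
        assert p.error_rate(180) == 0.5

    def test_invalid_angle(self, rng):
        with pytest.raises(ValueError):
            internal_response(make_profile(), 90, rng)


class TestPerceivedDelta:
    def test_identity_without_bias(self):
        assert perceived_rt_delta(make_profile(), 123.0) == 123.0

    def test_additivity(self):
        p = make_profile(rt_bias=-300.0)
        assert perceived_rt_delta(p, 100.0) == -200.0

    def test_population_bias_monte_carlo(self):
        dists = point_config().distributions.copy()
        dists["rt_bias"] = Distribution("normal", 200.0, 50.0)
        cfg = CohortConfig(n_participants=2000, distributions=dists, seed=5)
        deltas = [perceived_rt_delta(p, 0.0) for p in sample_cohort(cfg)]
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas) - 200.0) < 3 * se


class TestChooseStrategy:
    def test_symmetric_half(self, rng):
        pol = ChoicePolicy()
        picks = [choose_strategy(pol, 0.0, 0.0, 120, None, rng)
                 for _ in range(4000)]
        frac = np.mean([p == "extended" for p in picks])
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_perseveration_saturation(self, rng):
        pol = ChoicePolicy(beta_stick=50.0)
        picks = [choose_strategy(pol, 0.0, 0.0, 120, "internal", rng)
                 for _ in range(500)]
        assert all(p == "internal" for p in picks)

    def test_logistic_closed_form(self, rng):
        pol = ChoicePolicy(beta_rt=2.0)
        expected = 1.0 / (1.0 + np.exp(-2.0 * 0.511))
        picks = [choose_strategy(pol, 511.0, 0.0, 120, None, rng)
                 for _ in range(8000)]
        frac = np.mean([p == "extended" for p in picks])
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / 8000)


class TestScenarioPresets:
    def test_presets_exist(self):
        for name in ("exp1", "exp2", "noiseless"):
            cfg = scenario_preset(name, n_participants=4, seed=1)
            assert len(sample_cohort(cfg)) == 4

    def test_unknown_preset(self):
        with pytest.raises(CohortConfigError):
            scenario_preset("exp3")

    def test_exp1_gap_large_heterogeneous_exp2_small(self):
        gaps = {}
        for name in ("exp1", "exp2"):
            cfg = scenario_preset(name, n_participants=300, seed=11)
            g = np.array([p.a_int - p.a_man for p in sample_cohort(cfg)])
            gaps[name] = g
        assert abs(gaps["exp2"].mean() - 511.0) < 15.0
        assert gaps["exp1"].std() > 3 * gaps["exp2"].std()

    def test_csv_export(self, tmp_path):
        cfg = scenario_preset("exp1", n_participants=3, seed=2)
        path = tmp_path / "profiles.csv"
        profiles_to_csv(sample_cohort(cfg), path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 4 and lines[0].startswith("participant,a_int")


@given(st.floats(-1e4, 1e4), st.floats(-1e4, 1e4))
@settings(max_examples=50, deadline=None)
def test_perceived_delta_additive_property(bias, delta):
    p = make_profile(rt_bias=bias)
    assert perceived_rt_delta(p, delta) == pytest.approx(delta + bias)
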