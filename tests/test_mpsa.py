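"""Latin hypercube sampling, error classification and K-S scoring."""

import numpy as np
import pytest

from pd1tcr import (
    classify,
    ks_statistic,
    lhs_sample,
    module_spec,
    overall_error,
    run_mpsa,
)
from pd1tcr.mpsa import MODULE_PARAMETERS, _readout_curves, default_pd1_doses


class TestLhsSample:
    def test_one_sample_per_stratum(self):
        n = 10
        ranges = {"a": (1.0, 2.0), "b": (0.5, 1.5)}
        sample = lhs_sample(n, ranges, seed=3)
        assert sample.shape == (n, 2)
        for j, (lo, hi) in enumerate(ranges.values()):
            strata = np.floor((np.sort(sample[:, j]) - lo) / (hi - lo) * n).astype(int)
            assert list(strata) == list(range(n))

    def test_all_samples_within_half_to_three_halves(self, default_params):
        ranges = {"k_p_pd1": (0.5 * default_params.k_p_pd1, 1.5 * default_params.k_p_pd1)}
        sample = lhs_sample(500, ranges, seed=0)
        assert np.all(sample >= 0.5 * default_params.k_p_pd1)
        assert np.all(sample <= 1.5 * default_params.k_p_pd1)

    def test_deterministic_per_seed(self):
        ranges = {"a": (1.0, 2.0), "b": (3.0, 4.0)}
        np.testing.assert_array_equal(
            lhs_sample(20, ranges, seed=5), lhs_sample(20, ranges, seed=5)
        )
        assert not np.array_equal(
            lhs_sample(20, ranges, seed=5), lhs_sample(20, ranges, seed=6)
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            lhs_sample(1, {"a": (1.0, 2.0)}, seed=0)
        with pytest.raises(ValueError):
            lhs_sample(10, {"a": (2.0, 1.0)}, seed=0)
        with pytest.raises(ValueError):
            lhs_sample(10, {"a": (0.0, 1.0)}, seed=0)


class TestClassify:
    def test_two_point_example(self):
        mask, threshold = classify([1.0, 3.0])
        assert threshold == 2.0
        assert list(mask) == [True, False]

    def test_scaling_invariance(self, rng):
        errors = rng.exponential(size=50)
        mask1, _ = classify(errors)
        mask2, _ = classify(1e6 * errors)
        np.testing.assert_array_equal(mask1, mask2)

    def test_nonempty_classes_for_spread_errors(self, rng):
        for _ in range(20):
            errors = rng.lognormal(sigma=1.0, size=100)
            mask, _ = classify(errors)
            assert 0 < mask.sum() < mask.size

    def test_degenerate_errors_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            classify([2.0, 2.0, 2.0])

    def test_failed_runs_never_acceptable(self):
        mask, _ = classify([1.0, np.nan, 3.0])
        assert list(mask) == [True, False, False]


class TestKsStatistic:
    def test_identical_samples_give_zero(self):
        assert ks_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_disjoint_supports_give_one(self):
        assert ks_statistic([0.0, 1.0], [5.0, 6.0, 7.0]) == 1.0

    def test_hand_enumerated_overlap(self):
        # ECDFs step at {1,2} and {2,3}; the largest gap is 1/2.
        assert ks_statistic([1.0, 2.0], [2.0, 3.0]) == pytest.approx(0.5)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ks_statistic([], [1.0])


class TestOverallError:
    def test_defaults_give_zero_error(self, default_params):
        spec = module_spec("shp2_recruitment", n_sets=2)
        reference = _readout_curves(spec, default_params)
        assert overall_error(default_params, spec, reference) == 0.0

    def test_matches_explicit_double_loop(self, default_params):
        """The summed error equals an independently accumulated double
        loop over doses and time points."""
        spec = module_spec("shp2_recruitment", n_sets=2)
        reference = _readout_curves(spec, default_params)
        varied = default_params.replace(k_p_pd1=5.0, k_a_shp=9e-3)
        curves = _readout_curves(spec, varied)
        total = 0.0
        for i in range(len(spec.pd1_doses)):
            for j in range(len(spec.time_points)):
                total += (curves[i, j] - reference[i, j]) ** 2
        got = overall_error(varied, spec, reference)
        assert got == pytest.approx(total, rel=1e-10)
        assert got > 0

    def test_invariant_to_dose_order(self, default_params):
        spec = module_spec("shp2_recruitment", n_sets=2)
        doses = default_pd1_doses()
        spec_rev = module_spec(
            "shp2_recruitment", n_sets=2, pd1_doses=doses[::-1].copy()
        )
        varied = default_params.replace(k_a_shp=4e-3)
        err = overall_error(varied, spec, _readout_curves(spec, default_params))
        err_rev = overall_error(varied, spec_rev, _readout_curves(spec_rev, default_params))
        assert err == pytest.approx(err_rev, rel=1e-9)


class TestModuleDefinitions:
    def test_module_sizes_are_15_21_29(self):
        assert len(MODULE_PARAMETERS["shp2_recruitment"]) == 15
        assert len(MODULE_PARAMETERS["pi3k_recruitment"]) == 21
        assert len(MODULE_PARAMETERS["slp76_activation"]) == 29

    def test_slp76_module_excludes_cd28_branch_and_correction(self):
        varied = MODULE_PARAMETERS["slp76_activation"]
        for name in ("k_a_pi3k", "k_d_pi3k", "k_p_cd28", "KM_p_cd28",
                     "k_dp_cd28", "KM_dp_cd28", "k_corr"):
            assert name not in varied

    def test_spec_validation(self):
        with pytest.raises(KeyError):
            module_spec("bogus")
        with pytest.raises(ValueError):
            module_spec("shp2_recruitment", n_sets=1)
        with pytest.raises(ValueError):
            module_spec("shp2_recruitment", pd1_doses=np.array([0.0, 1.0]))


@pytest.fixture(scope="module")
def small_result():
    return run_mpsa(module_spec("shp2_recruitment", n_sets=60, seed=11))


class TestRunMpsa:
    def test_seed_reproducibility(self, small_result):
        again = run_mpsa(module_spec("shp2_recruitment", n_sets=60, seed=11))
        assert small_result.ks == again.ks
        np.testing.assert_array_equal(small_result.errors, again.errors)
        np.testing.assert_array_equal(small_result.samples, again.samples)

    def test_ks_statistics_within_unit_interval(self, small_result):
        assert set(small_result.ks) == set(MODULE_PARAMETERS["shp2_recruitment"])
        for value in small_result.ks.values():
            assert 0.0 <= value <= 1.0

    def test_diagnostics(self, small_result):
        assert small_result.n_sets_used == 60
        assert small_result.n_failed == 0
        assert 0.0 < small_result.acceptance_fraction < 1.0
        assert small_result.error_threshold > 0
        frame = small_result.to_frame()
        assert list(frame.columns) == ["parameter", "ks_statistic", "module", "n_sets", "seed"]
        assert len(frame) == 15

    def test_inert_parameter_scores_at_noise_floor(self):
        """A parameter with no influence on the readout (Gads binding
        never feeds back into Shp2 recruitment) stays near the two-sample
        null, far below a genuinely influential parameter."""
        spec = module_spec("shp2_recruitment", n_sets=100, seed=2)
        spec = spec.__class__(
            name=spec.name,
            varied_parameters=("k_p_pd1", "k_a_gads"),
            readout=spec.readout,
            base_scenario=spec.base_scenario,
            n_sets=100,
            seed=2,
        )
        result = run_mpsa(spec)
        # 5% two-sample K-S critical value at ~50/50 split of 100 is ~0.27
        assert result.ks["k_a_gads"] < 0.3
        assert result.ks["k_p_pd1"] > result.ks["k_a_gads"]
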