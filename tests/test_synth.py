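"""synth: seed expansion, outcome drawing, calibration, population synthesis."""

import numpy as np
import pandas as pd
import pytest

from popsynth.design import DesignSpec, Term
from popsynth.fitting import FittedModel, extract_seed_strata
from popsynth.synth import (
    calibrate_marginal,
    draw_outcome,
    expand_seed,
    synthesize_population,
)


class TestExpandSeed:
    def test_exact_counts(self, small_table):
        st = extract_seed_strata(small_table, ["gender", "region"], min_cell=1)
        pop = expand_seed(st)
        assert len(pop) == len(small_table)
        got = pop.groupby(["gender", "region"]).size()
        want = small_table.groupby(["gender", "region"]).size()
        pd.testing.assert_series_equal(got, want)

    def test_deterministic_order(self, small_table):
        st = extract_seed_strata(small_table, ["gender"], min_cell=1)
        a = expand_seed(st)
        b = expand_seed(st)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_strata(self):
        st = extract_seed_strata(pd.DataFrame({"g": []}), ["g"])
        assert len(expand_seed(st)) == 0


def linear_model(coef, residual_sd=0.0, family="gaussian", categories=None,
                 transform=None):
    return FittedModel(
        outcome="y", family=family, stratify_by=[], stratum=(),
        design=DesignSpec(terms=[Term("x", "linear", center=0.0)]),
        coef=np.asarray(coef, dtype=float),
        cov=np.eye(np.asarray(coef).size) * 1e-6,
        residual_sd=residual_sd, n_fit=100, categories=categories,
        transform=transform,
    )


class TestDrawOutcome:
    def test_gaussian_noiseless_equals_linear_predictor(self, rng):
        m = linear_model([1.0, 2.0], residual_sd=0.0)
        rows = pd.DataFrame({"x": [0.0, 1.0, -1.0]})
        np.testing.assert_allclose(
            draw_outcome(m, rows, rng), [1.0, 3.0, -1.0]
        )

    def test_gaussian_noise_moments(self, rng):
        m = linear_model([0.0, 0.0], residual_sd=2.0)
        rows = pd.DataFrame({"x": np.zeros(100_000)})
        y = draw_outcome(m, rows, rng)
        assert np.mean(y) == pytest.approx(0.0, abs=4 * 2 / np.sqrt(1e5))
        assert np.std(y) == pytest.approx(2.0, rel=0.02)

    def test_logit_transform_maps_to_unit_interval(self, rng):
        m = linear_model([0.5, 1.0], residual_sd=0.3, transform="logit")
        rows = pd.DataFrame({"x": rng.normal(size=1000)})
        y = draw_outcome(m, rows, rng)
        assert np.all((y > 0) & (y < 1))

    def test_logistic_frequency_within_binomial_band(self, rng):
        from scipy.special import expit

        m = linear_model([-0.4, 0.0], family="logistic", categories=[0, 1])
        n = 100_000
        rows = pd.DataFrame({"x": np.zeros(n)})
        y = draw_outcome(m, rows, rng)
        p = expit(-0.4)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(np.mean(y == 1) - p) < 4 * se

    def test_multinomial_respects_probability_override(self, rng):
        m = FittedModel(
            outcome="y", family="multinomial", stratify_by=[], stratum=(),
            design=DesignSpec(terms=[Term("x", "linear")]),
            coef=np.zeros((2, 2)), cov=np.eye(4) * 1e-6, residual_sd=None,
            n_fit=100, categories=["a", "b", "c"],
        )
        n = 50_000
        rows = pd.DataFrame({"x": np.zeros(n)})
        pr = np.tile([0.1, 0.2, 0.7], (n, 1))
        y = draw_outcome(m, rows, rng, probabilities=pr)
        freq = pd.Series(y).value_counts(normalize=True)
        for lv, p in zip(["a", "b", "c"], [0.1, 0.2, 0.7]):
            assert abs(freq[lv] - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_degenerate_model_emits_constant(self, rng):
        m = FittedModel(
            outcome="y", family="logistic", stratify_by=[], stratum=(),
            design=None, coef=None, cov=None, residual_sd=None, n_fit=10,
            categories=None, degenerate=True, constant="only",
        )
        y = draw_outcome(m, pd.DataFrame({"x": [1.0, 2.0]}), rng)
        assert list(y) == ["only", "only"]

    def test_design_mismatch_rejected(self, rng):
        m = linear_model([1.0, 2.0, 3.0])  # 3 coefs vs 2 design columns
        with pytest.raises(ValueError, match="does not match"):
            draw_outcome(m, pd.DataFrame({"x": [0.0]}), rng)


class TestCalibrateMarginal:
    def test_simple_scaling_factor_two(self):
        adjusted, c = calibrate_marginal(np.array([0.1, 0.3]), 0.4)
        assert c == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(adjusted, [0.2, 0.6], atol=1e-9)
        assert adjusted.mean() == pytest.approx(0.4, abs=1e-9)

    def test_capping_against_grid_scan_oracle(self):
        p = np.array([0.9, 0.8, 0.05, 0.05, 0.01])
        target = 0.5  # forces capping of the large probabilities
        adjusted, c = calibrate_marginal(p, target)
        assert adjusted.mean() == pytest.approx(target, abs=1e-9)
        assert np.all(adjusted <= 1.0)
        # brute-force oracle: scan c on a fine grid for the best mean match
        grid = np.linspace(0.0, 20.0, 2_000_001)
        means = np.minimum(grid[:, None] * p[None, :], 1.0).mean(axis=1)
        c_star = grid[np.argmin(np.abs(means - target))]
        assert c == pytest.approx(c_star, abs=1e-4)

    def test_downscaling(self):
        adjusted, c = calibrate_marginal(np.array([0.4, 0.6]), 0.25)
        assert c == pytest.approx(0.5, abs=1e-9)
        assert adjusted.mean() == pytest.approx(0.25, abs=1e-10)

    def test_target_not_in_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="not in"):
            calibrate_marginal(np.array([0.5]), 1.0)
        with pytest.raises(ValueError, match="not in"):
            calibrate_marginal(np.array([0.5]), 0.0)

    def test_unattainable_target_rejected(self):
        # only 50% of rows have nonzero probability: mean can never be 0.8
        with pytest.raises(ValueError, match="attainable"):
            calibrate_marginal(np.array([0.0, 0.5]), 0.8)

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError, match="lie in"):
            calibrate_marginal(np.array([-0.1, 0.5]), 0.3)


class TestSynthesizePopulation:
    def test_seed_conservation_exact(self, recovery_fit):
        truth, res = recovery_fit
        pop = res.synthesize(rng_seed=5)
        strata = res.bundle.strata
        got = pop.data.groupby(strata.seed_vars).size()
        want = strata.table.set_index(strata.seed_vars)["count"]
        want.name = None
        pd.testing.assert_series_equal(got, want.sort_index())
        assert len(pop.data) == strata.total

    def test_same_seed_reproduces_exactly(self, recovery_fit):
        truth, res = recovery_fit
        a = res.synthesize(rng_seed=3)
        b = res.synthesize(rng_seed=3)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_different_seeds_differ(self, recovery_fit):
        truth, res = recovery_fit
        a = res.synthesize(rng_seed=3)
        b = res.synthesize(rng_seed=4)
        assert not a.data["y_cont"].equals(b.data["y_cont"])

    def test_replicates_share_seed_frame_but_not_draws(self, recovery_fit):
        truth, res = recovery_fit
        pops = res.synthesize(rng_seed=3, n_replicates=2)
        assert isinstance(pops, list) and len(pops) == 2
        pd.testing.assert_frame_equal(
            pops[0].data[["age", "gender"]], pops[1].data[["age", "gender"]]
        )
        assert not pops[0].data["y_cont"].equals(pops[1].data["y_cont"])

    def test_draw_parameters_changes_draws_reproducibly(self, recovery_fit):
        truth, res = recovery_fit
        plain = res.synthesize(rng_seed=3)
        drawn1 = res.synthesize(rng_seed=3, draw_parameters=True)
        drawn2 = res.synthesize(rng_seed=3, draw_parameters=True)
        pd.testing.assert_frame_equal(drawn1.data, drawn2.data)
        assert not plain.data["y_cont"].equals(drawn1.data["y_cont"])
        assert drawn1.provenance["draw_parameters"] is True

    def test_calibration_target_hits_mean(self, recovery_fit):
        truth, res = recovery_fit
        base = res.synthesize(rng_seed=3)
        base_prev = (base.data["y_bin"] == 1).mean()
        target = min(0.95, base_prev * 1.5)
        pop = res.synthesize(
            rng_seed=3, calibration_targets={"y_bin": target},
            keep_probabilities=["y_bin"],
        )
        # the calibrated per-row probabilities average to the target
        assert pop.data["p_y_bin"].mean() == pytest.approx(target, abs=1e-6)
        # the realized draws agree within Monte-Carlo noise
        se = np.sqrt(target * (1 - target) / len(pop.data))
        assert abs((pop.data["y_bin"] == 1).mean() - target) < 4 * se
        assert "y_bin" in pop.provenance["calibration_factors"]

    def test_unknown_calibration_target_rejected(self, recovery_fit):
        truth, res = recovery_fit
        with pytest.raises(KeyError, match="not in the sequence"):
            res.synthesize(calibration_targets={"zzz": 0.5})

    def test_missing_stratum_model_error_and_nearest_fallback(self, recovery_fit):
        truth, res = recovery_fit
        import copy

        bundle = copy.deepcopy(res.bundle)
        bundle.models = [m for m in bundle.models
                         if not (m.outcome == "y_cont" and m.stratum == ("F",))]
        with pytest.raises(KeyError, match="no fitted model"):
            synthesize_population(bundle, rng_seed=1)
        pops = synthesize_population(
            bundle, rng_seed=1, stratum_fallback="nearest"
        )
        assert len(pops[0].data) == bundle.strata.total

    def test_keep_probabilities_column(self, recovery_fit):
        truth, res = recovery_fit
        pop = res.synthesize(rng_seed=2, keep_probabilities=["y_bin"])
        p = pop.data["p_y_bin"]
        assert p.between(0, 1).all()
        # drawing from these probabilities reproduces the prevalence
        prev = (pop.data["y_bin"] == 1).mean()
        assert abs(prev - p.mean()) < 4 * np.sqrt(
            (p * (1 - p)).sum() / len(p) ** 2
        )


class TestConsistencyAudit:
    def test_all_marginals_within_mc_noise(self, recovery_fit):
        truth, res = recovery_fit
        pop = res.synthesize(rng_seed=6)
        audit = res.consistency_audit(pop)
        assert {"outcome", "implied", "realized", "mc_se", "z"} <= set(
            audit.columns
        )
        assert np.all(np.abs(audit["z"]) < 4.0)

    def test_categorical_implied_probs_sum_to_one(self, recovery_fit):
        truth, res = recovery_fit
        pop = res.synthesize(rng_seed=6)
        audit = res.consistency_audit(pop)
        cat = audit[audit["outcome"] == "y_cat"]
        assert cat["implied"].sum() == pytest.approx(1.0, abs=1e-9)
        assert cat["realized"].sum() == pytest.approx(1.0, abs=1e-9)
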