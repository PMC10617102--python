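"""fitting: seed strata, per-stratum regressions, bundle (de)serialization."""

import json

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from popsynth.fitting import (
    FitError,
    FittedModel,
    extract_seed_strata,
    fit_sequence,
    fit_variable,
    read_bundle,
    write_bundle,
)
from popsynth.plan import ModelSpec, SynthesisPlan, VariableSpec
from popsynth.scenarios import (
    RECOVERY_TRUTH,
    recovery_plan,
    recovery_truth_config,
)
from popsynth.truth import simulate_truth


class TestSeedStrata:
    def test_counts_match_pandas_oracle(self, small_table):
        st = extract_seed_strata(small_table, ["gender", "region"], min_cell=1)
        oracle = small_table.groupby(["gender", "region"]).size()
        assert st.total == len(small_table)
        for row in st.table.itertuples(index=False):
            assert row.count == oracle[(row.gender, row.region)]

    def test_min_cell_boundary(self):
        data = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 9})
        st = extract_seed_strata(data, ["g"], min_cell=10, policy="waive")
        flags = dict(zip(st.table["g"], st.table["waived"]))
        assert not flags["a"]  # exactly min_cell members: kept without waiver
        assert flags["b"]

    def test_drop_policy_removes_small_cells(self):
        data = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 9})
        st = extract_seed_strata(data, ["g"], min_cell=10, policy="drop")
        assert list(st.table["g"]) == ["a"]
        assert st.total == 10
        assert st.n_waived == 0

    def test_waive_policy_keeps_everything(self):
        data = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 9})
        st = extract_seed_strata(data, ["g"], min_cell=10, policy="waive")
        assert st.total == 19
        assert st.n_waived == 1

    def test_unknown_policy_rejected(self, small_table):
        with pytest.raises(ValueError, match="policy"):
            extract_seed_strata(small_table, ["gender"], policy="hide")

    def test_nan_seed_rejected(self, small_table):
        bad = small_table.copy()
        bad.loc[bad.index[0], "gender"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            extract_seed_strata(bad, ["gender"])


def tiny_plan(vtype="continuous", levels=None, family="gaussian"):
    return SynthesisPlan(
        seed_vars=[
            VariableSpec("x", "continuous"),
            VariableSpec("g", "binary", levels=["u", "v"]),
        ],
        outcome_vars=[VariableSpec("y", vtype, levels=levels)],
        sequence=[ModelSpec("y", family, ["x"], stratify_by=[])],
        age_var="x",
    )


class TestFitVariable:
    def test_gaussian_matches_ols_closed_form(self, rng):
        n = 500
        x = rng.normal(0, 1, n)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.5, n)
        data = pd.DataFrame({"x": x, "g": ["u"] * n, "y": y})
        plan = tiny_plan()
        [m] = fit_variable(data, plan.sequence[0], plan)
        X = np.column_stack([np.ones(n), x - x.mean()])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / (n - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        np.testing.assert_allclose(m.coef, beta, rtol=1e-10)
        np.testing.assert_allclose(
            m.cov, (cov + cov.T) / 2, rtol=1e-8,
            atol=1e-14 * np.abs(cov).max(),  # off-diagonals are float noise
        )
        assert m.residual_sd == pytest.approx(np.sqrt(s2))

    def test_logistic_close_to_unpenalized_mle(self, rng):
        n = 4000
        x = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-(-0.3 + 0.8 * x)))
        y = (rng.random(n) < p).astype(int)
        data = pd.DataFrame({"x": x, "g": ["u"] * n, "y": y})
        plan = tiny_plan("binary", [0, 1], "logistic")
        [m] = fit_variable(data, plan.sequence[0], plan)
        X = np.column_stack([np.ones(n), x - x.mean()])
        ref = sm.Logit(y, X).fit(disp=0)
        # ridge alpha=1e-4 against information ~n/4: relative shift ~1e-6
        np.testing.assert_allclose(m.coef, ref.params, rtol=1e-3, atol=1e-4)
        np.testing.assert_allclose(
            np.sqrt(np.diag(m.cov)), ref.bse, rtol=1e-3
        )

    def test_logistic_survives_complete_separation(self):
        # x perfectly separates y: the unpenalized MLE does not exist,
        # the penalized fit must still return finite estimates
        n = 200
        x = np.concatenate([np.full(n, -1.0), np.full(n, 1.0)])
        y = (x > 0).astype(int)
        data = pd.DataFrame({"x": x, "g": ["u"] * 2 * n, "y": y})
        plan = tiny_plan("binary", [0, 1], "logistic")
        [m] = fit_variable(data, plan.sequence[0], plan)
        assert np.all(np.isfinite(m.coef))
        assert np.all(np.isfinite(m.cov))

    def test_multinomial_constant_intercepts(self, rng):
        n = 60_000
        probs = [0.5, 0.3, 0.2]
        y = rng.choice(["a", "b", "c"], size=n, p=probs)
        data = pd.DataFrame({"x": rng.normal(size=n), "g": ["u"] * n, "y": y})
        plan = tiny_plan("categorical", ["a", "b", "c"], "multinomial")
        [m] = fit_variable(data, plan.sequence[0], plan)
        assert m.categories[0] == "a"  # most frequent is reference
        se = np.sqrt(np.diag(m.cov)).reshape(np.asarray(m.coef).shape)
        expected = {"b": np.log(0.3 / 0.5), "c": np.log(0.2 / 0.5)}
        for j, lv in enumerate(m.categories[1:]):
            assert abs(m.coef[j][0] - expected[lv]) < 3 * se[j][0]

    def test_multinomial_cov_ordering_matches_flat_coef(self, recovery_fit):
        truth, res = recovery_fit
        models = res.bundle.models_for("y_cat")
        for m in models.values():
            flat = m.coef_flat()
            assert m.cov.shape == (flat.size, flat.size)
            # diagonal SEs must be positive and finite
            assert np.all(np.diag(m.cov) > 0)

    def test_stratified_fit_recovers_per_stratum_truth(self, recovery_fit):
        truth, res = recovery_fit
        t = RECOVERY_TRUTH
        models = res.bundle.models_for("y_cont")
        for key, m in models.items():
            g = key[0]
            center = m.design.terms[0].center
            c0, slope = t["y_cont"][g]
            expected = np.array([c0 + slope * (center - 40.0), slope])
            se = np.sqrt(np.diag(m.cov))
            assert np.all(np.abs(np.asarray(m.coef) - expected) < 4 * se)

    def test_degenerate_stratum_flagged(self):
        data = pd.DataFrame(
            {"x": [1.0, 2.0, 3.0, 4.0], "g": ["u"] * 4, "y": [1, 1, 1, 1]}
        )
        plan = tiny_plan("binary", [0, 1], "logistic")
        [m] = fit_variable(data, plan.sequence[0], plan)
        assert m.degenerate
        assert m.constant == 1

    def test_missing_outcome_rejected(self):
        data = pd.DataFrame(
            {"x": [1.0, 2.0], "g": ["u", "u"], "y": [1.0, np.nan]}
        )
        plan = tiny_plan()
        with pytest.raises(FitError, match="missing values"):
            fit_variable(data, plan.sequence[0], plan)


class TestFitSequence:
    def test_age_range_filter_recorded(self):
        cfg = recovery_truth_config(n_population=3_000, rng_seed=3)
        truth = simulate_truth(cfg)
        data = truth.data.copy()
        data.loc[data.index[:7], "age"] = 200.0
        bundle = fit_sequence(data, recovery_plan())
        assert bundle.provenance["n_age_dropped"] == 7
        assert bundle.strata.total == len(data) - 7

    def test_invalid_plan_rejected(self):
        plan = recovery_plan()
        plan.sequence[0].predictors = ["y_bin"]  # later outcome
        truth = simulate_truth(recovery_truth_config(n_population=1_000))
        with pytest.raises(ValueError, match="invalid plan"):
            fit_sequence(truth.data, plan)

    def test_models_cover_all_strata(self, recovery_fit):
        truth, res = recovery_fit
        for mspec in res.bundle.plan.sequence:
            assert set(res.bundle.models_for(mspec.outcome)) == {("F",), ("M",)}


class TestBundleRoundTrip:
    def test_lossless_round_trip(self, recovery_fit, tmp_path):
        truth, res = recovery_fit
        path = tmp_path / "bundle.json"
        write_bundle(res.bundle, path)
        back = read_bundle(path)
        assert back.plan == res.bundle.plan
        pd.testing.assert_frame_equal(
            back.strata.table, res.bundle.strata.table
        )
        assert len(back.models) == len(res.bundle.models)
        for a, b in zip(res.bundle.models, back.models):
            assert a.stratum == b.stratum
            if a.degenerate:
                assert b.degenerate and a.constant == b.constant
                continue
            # float repr round trip is bit-exact
            np.testing.assert_array_equal(a.coef, np.asarray(b.coef))
            np.testing.assert_array_equal(a.cov, b.cov)
            assert a.design == b.design

    def test_wrong_format_rejected(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text(json.dumps({"format": "something-else"}))
        with pytest.raises(ValueError, match="not a popsynth model bundle"):
            read_bundle(path)

    def test_malformed_json_rejected(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            read_bundle(path)

    def test_asymmetric_covariance_rejected(self, recovery_fit, tmp_path):
        truth, res = recovery_fit
        path = tmp_path / "bundle.json"
        write_bundle(res.bundle, path)
        doc = json.loads(path.read_text())
        for m in doc["models"]:
            if "cov" in m and len(m["cov"]) >= 2:
                m["cov"][0][1] = m["cov"][0][1] + 1.0
                break
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="not symmetric"):
            read_bundle(path)

    def test_dimension_mismatch_rejected(self, recovery_fit, tmp_path):
        truth, res = recovery_fit
        path = tmp_path / "bundle.json"
        write_bundle(res.bundle, path)
        doc = json.loads(path.read_text())
        for m in doc["models"]:
            if "coef" in m:
                m["coef"] = list(np.asarray(m["coef"]).ravel()) + [0.0]
                break
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="does not match"):
            read_bundle(path)
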