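"""Mixed-model engine and difference-in-changes contrast machinery."""

import numpy as np
import pandas as pd
import pytest

from conftest import balanced_samples
from exomix.diffchanges import test_contrast as eval_contrast
from exomix.diffchanges import (
    ContrastSpec,
    ModelSpec,
    adjust_fdr,
    build_design,
    check_eligibility,
    classify_response,
    default_contrasts,
    fit_feature,
    pc_covariate_association,
    run_da,
    variance_explained,
)
from exomix.lmm import SingularDesignError, fit_random_intercept


def _simulate(samples, icc, rng, delta=0.0, group="EE", timepoint="PLate"):
    parts = samples["participant"].unique()
    b = rng.normal(0, np.sqrt(icc), len(parts))
    bmap = dict(zip(parts, b))
    y = np.array(
        [
            bmap[p] + rng.normal(0, np.sqrt(1 - icc))
            for p in samples["participant"]
        ]
    )
    mask = (samples["group"] == group) & (samples["timepoint"] == timepoint)
    y[mask.to_numpy()] += delta
    return y


class TestLmmEngine:
    def test_matches_statsmodels_reml(self, rng):
        """Dual route: in-package REML vs statsmodels MixedLM on unbalanced data."""
        import statsmodels.api as sm

        samples = balanced_samples({"EE": 15, "CON": 10}, ("Pre", "PEarly", "PLate"))
        keep = rng.random(len(samples)) > 0.15  # unbalanced missingness
        samples = samples[keep].reset_index(drop=True)
        y = _simulate(samples, 0.5, rng)
        X, names, cells, codes = build_design(samples, ModelSpec(covariates=()))
        fit = fit_random_intercept(y, X, codes, column_names=names)
        ref = sm.MixedLM(y, X, codes).fit(reml=True)
        assert np.allclose(fit.beta, ref.fe_params, atol=1e-4)
        assert fit.sigma_e2 == pytest.approx(ref.scale, abs=1e-4)
        assert fit.sigma_b2 == pytest.approx(float(np.asarray(ref.cov_re)[0, 0]), abs=1e-3)

    def test_cell_means_equal_raw_means_on_balanced_data(self, rng):
        samples = balanced_samples({"EE": 8, "CON": 8})
        y = _simulate(samples, 0.4, rng)
        fit, cells, _ = fit_feature(y, samples, ModelSpec(covariates=()))
        df = samples.assign(y=y)
        raw = df.groupby(["group", "timepoint"])["y"].mean()
        for (g, t), j in cells.items():
            assert fit.beta[j] == pytest.approx(raw[g, t], abs=1e-8)

    def test_delta_delta_equals_mean_of_changes_oracle(self, rng):
        """Primary estimand equals direct averaging on balanced complete data."""
        samples = balanced_samples({"EE": 10, "CON": 7})
        y = _simulate(samples, 0.3, rng, delta=0.8)
        fit, cells, _ = fit_feature(y, samples, ModelSpec(covariates=()))
        res = eval_contrast(fit, cells, ContrastSpec("diff_in_changes", "EE", "PLate"))
        df = samples.assign(y=y)
        cell = df.groupby(["group", "timepoint"])["y"].mean()
        oracle = (cell["EE", "PLate"] - cell["EE", "Pre"]) - (
            cell["CON", "PLate"] - cell["CON", "Pre"]
        )
        assert res["estimate"] == pytest.approx(oracle, abs=1e-8)

    def test_icc_zero_data_gives_near_zero_intercept_variance(self, rng):
        samples = balanced_samples({"EE": 40, "CON": 40}, ("Pre", "PEarly", "PLate"))
        y = _simulate(samples, 0.0, rng)
        fit, _, _ = fit_feature(y, samples, ModelSpec(covariates=()))
        assert fit.sigma_b2 < 0.05

    def test_single_observation_per_participant_reduces_to_ols(self, rng):
        samples = balanced_samples({"EE": 20, "CON": 20}, ("Pre",))
        y = rng.normal(0, 1, len(samples))
        X, names, cells, codes = build_design(samples, ModelSpec(covariates=()))
        fit = fit_random_intercept(y, X, codes)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-10)
        assert fit.sigma_b2 == 0.0

    def test_singular_design_names_aliased_columns(self):
        X = np.column_stack([np.ones(10), np.arange(10), np.arange(10)])
        with pytest.raises(SingularDesignError) as err:
            fit_random_intercept(
                np.zeros(10), X, np.arange(10), column_names=["i", "x", "x_copy"]
            )
        assert "x_copy" in err.value.aliased

    def test_self_contrast_is_exactly_zero(self, rng):
        samples = balanced_samples({"EE": 5, "CON": 5})
        y = _simulate(samples, 0.2, rng)
        fit, cells, _ = fit_feature(y, samples, ModelSpec(covariates=()))
        c = np.zeros(len(fit.beta))  # +1 and -1 on the same cell cancel
        res = fit.contrast(c)
        assert res["estimate"] == 0.0 and res["p"] == 1.0

    def test_type_one_error_calibrated(self):
        """Gaussian null, n=20/20/10: rejection at 0.05 stays in [0.04, 0.06]."""
        rng = np.random.default_rng(99)
        samples = balanced_samples({"EE": 20, "RE": 20, "CON": 10})
        contrast = ContrastSpec("diff_in_changes", "EE", "PLate")
        rejections = 0
        n_rep = 5000
        for _ in range(n_rep):
            y = _simulate(samples, 0.5, rng)
            fit, cells, _ = fit_feature(y, samples, ModelSpec(covariates=()))
            rejections += eval_contrast(fit, cells, contrast)["p"] < 0.05
        rate = rejections / n_rep
        assert 0.04 <= rate <= 0.06

    def test_estimator_consistency_in_n(self):
        """RMSE of the planted delta-delta shrinks roughly like 1/sqrt(n)."""
        rng = np.random.default_rng(5)
        rmse = {}
        for n in (10, 40, 160):
            samples = balanced_samples({"EE": n, "CON": n})
            errs = []
            for _ in range(150):
                y = _simulate(samples, 0.5, rng, delta=1.0)
                fit, cells, _ = fit_feature(y, samples, ModelSpec(covariates=()))
                res = eval_contrast(fit, cells, ContrastSpec("diff_in_changes", "EE", "PLate"))
                errs.append(res["estimate"] - 1.0)
            rmse[n] = float(np.sqrt(np.mean(np.square(errs))))
        assert rmse[10] > rmse[40] > rmse[160]
        assert rmse[10] / rmse[160] == pytest.approx(4.0, rel=0.5)


class TestEligibility:
    def _samples(self, n_con_paired: int):
        rows = []
        for i in range(4):
            rows += [(f"E{i}", "EE", "Pre"), (f"E{i}", "EE", "PLate")]
        for i in range(n_con_paired):
            rows += [(f"C{i}", "CON", "Pre"), (f"C{i}", "CON", "PLate")]
        rows.append(("Cx", "CON", "PLate"))  # post without pre: never counts
        return pd.DataFrame(rows, columns=["participant", "group", "timepoint"])

    def test_three_paired_participants_suffice(self):
        s = self._samples(3)
        out = check_eligibility(s, contrasts=[ContrastSpec("diff_in_changes", "EE", "PLate")])
        assert out == {"diff_in_changes:EE:PLate": 3}

    def test_two_paired_in_control_is_ineligible(self):
        s = self._samples(2)
        out = check_eligibility(s, contrasts=[ContrastSpec("diff_in_changes", "EE", "PLate")])
        assert out == {}

    def test_unpaired_post_does_not_count(self):
        s = self._samples(3)
        obs = pd.Series(True, index=s["participant"] + ":" + s["timepoint"])
        obs["C0:Pre"] = False  # breaks C0's pairing -> only 2 paired controls
        out = check_eligibility(s, observed=obs, contrasts=[ContrastSpec("diff_in_changes", "EE", "PLate")])
        assert out == {}


class TestFdrAndClassification:
    def test_bh_hand_computation(self):
        res = pd.DataFrame(
            {
                "contrast": ["diff_in_changes"] * 3,
                "group": ["EE"] * 3,
                "timepoint": ["PLate"] * 3,
                "p": [0.01, 0.02, 0.03],
            }
        )
        adj = adjust_fdr(res)["adj_p"].to_numpy()
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_bh_single_and_degenerate(self):
        one = pd.DataFrame({"contrast": ["x"], "group": ["EE"], "timepoint": ["t"], "p": [0.2]})
        assert adjust_fdr(one)["adj_p"].iloc[0] == pytest.approx(0.2)
        ones = pd.DataFrame({"contrast": ["x"] * 4, "group": ["EE"] * 4, "timepoint": ["t"] * 4, "p": [1.0] * 4})
        assert (adjust_fdr(ones)["adj_p"] == 1.0).all()

    def test_bh_is_stratified(self):
        res = pd.DataFrame(
            {
                "contrast": ["diff_in_changes"] * 2 + ["group_specific"] * 2,
                "group": ["EE"] * 4,
                "timepoint": ["PLate"] * 4,
                "p": [0.01, 0.04, 0.01, 0.04],
            }
        )
        adj = adjust_fdr(res)["adj_p"].to_numpy()
        assert np.allclose(adj[:2], adj[2:])  # same pattern within each stratum
        assert np.allclose(adj[:2], [0.02, 0.04])

    @staticmethod
    def _results(dd_p, ex_p, con_p):
        return pd.DataFrame(
            {
                "contrast": ["diff_in_changes", "group_specific", "group_specific"],
                "group": ["EE", "EE", "CON"],
                "timepoint": ["PLate"] * 3,
                "adj_p": [dd_p, ex_p, con_p],
            }
        )

    def test_classification_rules(self):
        assert classify_response(self._results(0.01, 0.01, 0.8), "EE", "PLate") == "exercise_effect"
        assert classify_response(self._results(0.01, 0.5, 0.01), "EE", "PLate") == "control_driven"
        assert classify_response(self._results(0.5, 0.01, 0.01), "EE", "PLate") == "non_exercise_change"
        assert classify_response(self._results(0.5, 0.5, 0.5), "EE", "PLate") == "none"
        missing = self._results(0.01, 0.01, 0.8).iloc[:2]
        assert classify_response(missing, "EE", "PLate") == "unclassifiable"

    def test_classification_recovers_planted_truth(self, rng):
        """Simulated features with known response types are classified correctly."""
        samples = balanced_samples({"EE": 20, "RE": 20, "CON": 15})
        scenarios = {
            "exercise_effect": lambda s: ((s["group"] == "EE") & (s["timepoint"] == "PLate")) * 2.0,
            "non_exercise_change": lambda s: (s["timepoint"] == "PLate") * 2.0,
        }
        for truth, shift in scenarios.items():
            y = _simulate(samples, 0.3, rng) + shift(samples).to_numpy(float)
            mat = pd.DataFrame(
                [y], index=["f"],
                columns=(samples["participant"] + ":" + samples["timepoint"]),
            )
            res = run_da(
                mat, samples,
                contrasts=default_contrasts(samples, ("diff_in_changes", "group_specific")),
                spec=ModelSpec(covariates=()),
            )
            assert classify_response(res, "EE", "PLate") == truth


class TestVarianceDecomposition:
    def test_planted_sex_fraction(self, rng):
        n = 4000
        sex = rng.choice(["F", "M"], n)
        y = np.where(sex == "F", 1.0, -1.0) + rng.normal(0, 1, n)
        fr = variance_explained(y, pd.DataFrame({"sex": sex}))
        assert fr["sex"] == pytest.approx(0.5, abs=0.05)
        assert fr.sum() == pytest.approx(1.0, abs=1e-8)

    def test_pure_participant_effect(self, rng):
        part = np.repeat([f"P{i}" for i in range(30)], 4)
        y = np.repeat(rng.normal(0, 1, 30), 4)
        fr = variance_explained(y, pd.DataFrame({"participant": part}))
        assert fr["participant"] > 0.999

    def test_white_noise_residual_dominates(self, rng):
        y = rng.normal(0, 1, 500)
        fr = variance_explained(y, pd.DataFrame({"x": rng.normal(0, 1, 500)}))
        assert fr["residual"] > 0.95

    def test_collinear_covariates_rejected(self, rng):
        x = rng.normal(0, 1, 50)
        with pytest.raises(ValueError, match="collinear"):
            variance_explained(
                rng.normal(0, 1, 50), pd.DataFrame({"x": x, "x2": 2 * x})
            )


class TestPcCovariate:
    def test_covariate_equal_to_pc1_scores(self, rng):
        mat = pd.DataFrame(rng.normal(0, 1, (30, 50)))
        X = mat.to_numpy().T
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        pc1 = Xc @ vt[0]
        grid = pc_covariate_association(mat, pd.DataFrame({"c": pc1}), n_pcs=2)
        assert grid.loc["PC1", "c"] == pytest.approx(1.0, abs=1e-8)

    def test_independent_covariate_near_zero(self, rng):
        mat = pd.DataFrame(rng.normal(0, 1, (40, 400)))
        cov = pd.DataFrame({"c": rng.normal(0, 1, 400)})
        grid = pc_covariate_association(mat, cov, n_pcs=3)
        assert (grid["c"] < 0.15).all()

    def test_constant_covariate_is_zero(self, rng):
        mat = pd.DataFrame(rng.normal(0, 1, (10, 20)))
        grid = pc_covariate_association(mat, pd.DataFrame({"c": np.ones(20)}), n_pcs=2)
        assert (grid["c"] == 0.0).all()

    def test_rank_violation_rejected(self, rng):
        mat = pd.DataFrame(rng.normal(0, 1, (3, 4)))
        with pytest.raises(ValueError):
            pc_covariate_association(mat, pd.DataFrame({"c": np.arange(4)}), n_pcs=5)


class TestRunDa:
    def test_dd_null_and_planted_feature(self, rng):
        samples = balanced_samples({"EE": 12, "RE": 12, "CON": 8})
        y_null = _simulate(samples, 0.4, rng)
        y_eff = _simulate(samples, 0.4, rng, delta=2.5)
        ids = samples["participant"] + ":" + samples["timepoint"]
        mat = pd.DataFrame([y_null, y_eff], index=["null", "hit"], columns=ids)
        res = run_da(mat, samples, spec=ModelSpec(covariates=()))
        dd = res[(res["contrast"] == "diff_in_changes") & (res["group"] == "EE")]
        assert dd.set_index("feature").loc["hit", "adj_p"] < 0.01
        assert dd.set_index("feature").loc["hit", "estimate"] == pytest.approx(2.5, abs=0.8)

    def test_adj_p_at_least_p(self, rng):
        samples = balanced_samples({"EE": 6, "CON": 5})
        ids = samples["participant"] + ":" + samples["timepoint"]
        mat = pd.DataFrame(
            rng.normal(0, 1, (8, len(samples))),
            index=[f"f{i}" for i in range(8)],
            columns=ids,
        )
        res = run_da(mat, samples, spec=ModelSpec(covariates=()))
        assert (res["adj_p"] >= res["p"] - 1e-12).all()
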