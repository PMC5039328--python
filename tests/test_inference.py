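"""Trait linear models, pCO2 standardization and bootstrap propagation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import thermnorm as tn
from thermnorm.bootstrap import BootstrapTraitDistribution
from thermnorm.inference import COEF_NAMES, design_matrix


def balanced_design(n_per_cell=5):
    rows = []
    for sel in (15.0, 26.3):
        for pco2 in (400.0, 1100.0, 2200.0):
            for r in range(n_per_cell):
                rows.append(
                    {"replicate_id": f"S{sel:g}_C{pco2:g}_R{r}",
                     "selection_temp": sel, "pco2": pco2}
                )
    return pd.DataFrame(rows)


def constant_distributions(design, values, n_iter=40):
    """Each unit's draws constant at its entry of ``values``."""
    dists = {}
    for rid, v in zip(design["replicate_id"], values):
        dists[rid] = BootstrapTraitDistribution(
            replicate_id=rid, n_iter=n_iter,
            t_opt_draws=np.full(n_iter, float(v)),
            t_max_draws=np.full(n_iter, float(v) + 6.0),
            param_draws=np.zeros((n_iter, 4)) + [16, 24, 0.2, 0.1],
            iterations=np.arange(n_iter), n_failed=0, seed=0, mode="permute",
        )
    return dists


class TestStandardizePCO2:
    def test_mean_zero_sd_half(self):
        x = np.repeat([400.0, 1100.0, 2200.0], 10)
        s = tn.standardize_pco2(x)
        assert s.mean() == pytest.approx(0.0, abs=1e-15)
        assert s.std(ddof=1) == pytest.approx(0.5, abs=1e-15)

    def test_against_brute_force(self):
        x = np.repeat([400.0, 1100.0, 2200.0], 10)
        mean = sum(x) / len(x)
        sd = (sum((v - mean) ** 2 for v in x) / (len(x) - 1)) ** 0.5
        np.testing.assert_allclose(tn.standardize_pco2(x), (x - mean) / (2 * sd))
        assert mean == pytest.approx(1233.3333333333333)

    def test_constant_input_rejected(self):
        with pytest.raises(tn.InvalidInputError):
            tn.standardize_pco2([400.0] * 6)


class TestFitTraitLM:
    def test_noiseless_temp_effect(self):
        design = balanced_design()
        X = design_matrix(design["selection_temp"], design["pco2"])
        y = 1.0 + 0.5 * X[:, 1]
        beta, adj_r2 = tn.fit_trait_lm(X, y)
        np.testing.assert_allclose(beta, [1.0, 0.5, 0.0, 0.0], atol=1e-12)
        assert adj_r2 == pytest.approx(1.0)

    def test_constant_response(self):
        design = balanced_design()
        X = design_matrix(design["selection_temp"], design["pco2"])
        beta, _ = tn.fit_trait_lm(X, np.full(len(X), 2.0))
        np.testing.assert_allclose(beta, [2.0, 0.0, 0.0, 0.0], atol=1e-12)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(21)
        design = balanced_design()
        X = design_matrix(design["selection_temp"], design["pco2"])
        for _ in range(5):
            y = rng.normal(size=len(X))
            beta, _ = tn.fit_trait_lm(X, y)
            oracle = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(beta, oracle, atol=1e-10)

    def test_rank_deficiency_names_column(self):
        X = design_matrix([15.0] * 15 + [26.3] * 15, np.tile([400, 1100, 2200], 10))
        X[:, 3] = X[:, 2]  # interaction collinear with pco2
        with pytest.raises(tn.RankDeficientError, match="interaction"):
            tn.fit_trait_lm(X, np.zeros(30))

    def test_standardization_is_affine_reparameterization(self):
        # t statistics identical raw vs standardized; slope scales by 2*sd
        rng = np.random.default_rng(3)
        design = balanced_design()
        temp = (design["selection_temp"] == 26.3).astype(float).to_numpy()
        raw = design["pco2"].to_numpy(float)
        std = tn.standardize_pco2(raw)
        y = 20 + 0.5 * temp - 0.001 * raw + rng.normal(0, 0.3, len(raw))
        def tstats(p):
            X = np.column_stack([np.ones_like(temp), temp, p, temp * p])
            return sm.OLS(y, X).fit()
        r_raw, r_std = tstats(raw), tstats(std)
        np.testing.assert_allclose(
            r_raw.tvalues[2], r_std.tvalues[2], rtol=1e-10
        )
        sd = raw.std(ddof=1)
        assert r_std.params[2] == pytest.approx(r_raw.params[2] * 2 * sd, rel=1e-10)


class TestBootstrapTraitInference:
    def test_constant_draws_give_zero_width_cis(self):
        design = balanced_design()
        values = 21.0 + 0.7 * (design["selection_temp"] == 26.3).to_numpy()
        dists = constant_distributions(design, values)
        out = tn.bootstrap_trait_inference(dists, design, trait="t_opt")
        te = out.coefficients["temp_effect"]
        assert te.ci_lower == pytest.approx(te.ci_upper) == pytest.approx(0.7)
        assert te.significant
        ie = out.coefficients["interaction"]
        assert ie.ci_lower == pytest.approx(0.0, abs=1e-12)
        assert not ie.significant

    def test_misaligned_iteration_counts_rejected(self):
        design = balanced_design()
        values = np.full(len(design), 21.0)
        dists = constant_distributions(design, values, n_iter=40)
        bad = constant_distributions(design.iloc[:1], values[:1], n_iter=30)
        dists[design["replicate_id"].iloc[0]] = bad[design["replicate_id"].iloc[0]]
        with pytest.raises(tn.InvalidInputError, match="misaligned"):
            tn.bootstrap_trait_inference(dists, design)

    def test_failed_iterations_dropped_listwise(self):
        design = balanced_design()
        values = np.full(len(design), 21.0)
        dists = constant_distributions(design, values, n_iter=40)
        rid = design["replicate_id"].iloc[0]
        d = dists[rid]
        keep = np.arange(40) != 3  # unit 0 failed iteration 3
        dists[rid] = BootstrapTraitDistribution(
            replicate_id=rid, n_iter=40,
            t_opt_draws=d.t_opt_draws[keep], t_max_draws=d.t_max_draws[keep],
            param_draws=d.param_draws[keep], iterations=np.arange(40)[keep],
            n_failed=1, seed=0, mode="permute",
        )
        out = tn.bootstrap_trait_inference(dists, design)
        assert out.n_bootstrap == 39

    def test_interaction_masks_main_effects(self):
        rng = np.random.default_rng(17)
        design = balanced_design()
        temp = (design["selection_temp"] == 26.3).to_numpy(float)
        pstd = tn.standardize_pco2(design["pco2"])
        truth = 21.0 + 0.5 * temp + 2.0 * temp * pstd
        dists = {}
        for rid, mu in zip(design["replicate_id"], truth):
            draws = mu + rng.normal(0, 0.05, 50)
            dists[rid] = BootstrapTraitDistribution(
                replicate_id=rid, n_iter=50, t_opt_draws=draws,
                t_max_draws=draws + 6, param_draws=np.zeros((50, 4)) + 1,
                iterations=np.arange(50), n_failed=0, seed=0, mode="permute",
            )
        out = tn.bootstrap_trait_inference(dists, design, trait="t_opt")
        assert out.coefficients["interaction"].significant
        assert out.interaction_masks_main_effects
        assert not out.coefficients["temp_effect"].interpretable
        assert not out.coefficients["pco2_effect"].interpretable


class TestMuMaxInference:
    def test_noiseless_planted_effects(self):
        design = balanced_design()
        temp = (design["selection_temp"] == 26.3).to_numpy(float)
        pstd = tn.standardize_pco2(design["pco2"])
        design["mu_max"] = 1.0 - 0.06 * temp - 0.11 * pstd
        out = tn.mu_max_inference(design)
        for name, want in zip(COEF_NAMES, [1.0, -0.06, -0.11, 0.0]):
            c = out.coefficients[name]
            assert c.estimate == pytest.approx(want, abs=1e-10)
            # zero residual variance collapses the t interval to a point
            assert c.ci_upper - c.ci_lower == pytest.approx(0.0, abs=1e-8)
        assert out.adjusted_r2 == pytest.approx(1.0)

    def test_constant_trait(self):
        design = balanced_design()
        design["mu_max"] = 0.8
        out = tn.mu_max_inference(design)
        assert out.coefficients["intercept"].estimate == pytest.approx(0.8)
        for name in ("temp_effect", "pco2_effect", "interaction"):
            assert out.coefficients[name].estimate == pytest.approx(0.0, abs=1e-12)

    def test_planted_pco2_effect_detected(self):
        rng = np.random.default_rng(29)
        hits = 0
        for _ in range(20):
            design = balanced_design()
            pstd = tn.standardize_pco2(design["pco2"])
            design["mu_max"] = 1.0 - 0.1 * pstd + rng.normal(0, 0.02, len(design))
            out = tn.mu_max_inference(design)
            hits += out.coefficients["pco2_effect"].significant
        assert hits >= 18  # planted effect is ~9 residual SDs of the slope

    def test_ci_matches_t_formula(self):
        rng = np.random.default_rng(31)
        design = balanced_design()
        design["mu_max"] = rng.normal(0.9, 0.05, len(design))
        out = tn.mu_max_inference(design)
        # hand-computed normal-theory interval on n - 4 df
        from scipy import stats

        X = design_matrix(design["selection_temp"], design["pco2"])
        y = design["mu_max"].to_numpy()
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        n, p = X.shape
        s2 = resid @ resid / (n - p)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        tcrit = stats.t.ppf(0.975, n - p)
        for j, name in enumerate(COEF_NAMES):
            c = out.coefficients[name]
            assert c.ci_lower == pytest.approx(beta[j] - tcrit * se[j], rel=1e-8)
            assert c.ci_upper == pytest.approx(beta[j] + tcrit * se[j], rel=1e-8)


class TestTreatmentSummary:
    def test_single_unit_cells(self):
        design = balanced_design(n_per_cell=1)
        point = pd.DataFrame(
            {
                "replicate_id": design["replicate_id"],
                "t_opt": np.linspace(20, 23, len(design)),
                "t_max": np.linspace(27, 29, len(design)),
                "mu_max": np.linspace(0.7, 1.1, len(design)),
            }
        )
        out = tn.summarize_traits_by_treatment(design, None, point)
        assert len(out) == 6
        merged = out.merge(
            design.merge(point, on="replicate_id"), on=["selection_temp", "pco2"]
        )
        np.testing.assert_allclose(merged["t_opt_mean"], merged["t_opt"])
        np.testing.assert_allclose(merged["mu_max_ci_lo"], merged["mu_max"])

    def test_planted_separation_and_zero_spread(self):
        design = balanced_design()
        temp = (design["selection_temp"] == 26.3).to_numpy(float)
        values = 21.3 + 0.7 * temp
        dists = constant_distributions(design, values)
        point = pd.DataFrame(
            {
                "replicate_id": design["replicate_id"],
                "t_opt": values,
                "t_max": values + 6.0,
                "mu_max": np.full(len(design), 0.9),
            }
        )
        out = tn.summarize_traits_by_treatment(design, dists, point)
        lo = out[out["selection_temp"] == 15.0]["t_opt_mean"].mean()
        hi = out[out["selection_temp"] == 26.3]["t_opt_mean"].mean()
        assert hi - lo == pytest.approx(0.7)
        # identical replicates: zero-width across-replicate spread for mu_max
        np.testing.assert_allclose(out["mu_max_ci_lo"], 0.9)
        np.testing.assert_allclose(out["mu_max_ci_hi"], 0.9)

    def test_empty_cell_rejected(self):
        design = balanced_design(n_per_cell=1).iloc[:5]
        point = pd.DataFrame(
            {
                "replicate_id": design["replicate_id"],
                "t_opt": np.full(5, 21.0),
                "t_max": np.full(5, 28.0),
                "mu_max": np.full(5, 0.9),
            }
        )
        out = tn.summarize_traits_by_treatment(design, None, point)
        assert len(out) == 5  # groupby never fabricates empty cells
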