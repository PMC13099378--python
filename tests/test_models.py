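"""Association models: splines, fits, EMMs, GVIF, interactions, partial
Spearman correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from abxgut import exposure as ex
from abxgut import microbiome as mb
from abxgut import models as mod
from abxgut import synthetic as sy


class TestRcsBasis:
    def test_left_of_first_knot_is_linear(self):
        x = np.linspace(-5, 1, 50)
        B = mod.rcs_basis(x, (1.0, 2.0, 4.0))
        assert np.allclose(B[:, 1], 0.0)
        assert np.allclose(B[:, 0], x)

    def test_zero_nonlinear_coefficient_gives_affine_curve(self):
        x = np.linspace(0, 10, 100)
        B = mod.rcs_basis(x, (2.0, 5.0, 8.0))
        y = 3.0 + 1.5 * B[:, 0] + 0.0 * B[:, 1]
        assert np.allclose(np.diff(y, 2), 0.0, atol=1e-9)

    def test_second_derivative_vanishes_beyond_last_knot(self):
        """Finite-difference oracle: curvature of the full expansion is zero
        for x > k3 (the restricted/natural condition)."""
        knots = (1.0, 3.0, 6.0)
        coef = np.array([0.7, -2.3])  # arbitrary spline coefficients
        h = 1e-4

        def f(x):
            return mod.rcs_basis(np.atleast_1d(x), knots) @ coef

        for x0 in (6.5, 8.0, 20.0):
            second = (f(x0 + h) - 2 * f(x0) + f(x0 - h)) / h**2
            assert abs(second[0]) < 1e-4

    def test_non_distinct_knots_rejected(self):
        with pytest.raises(ValueError):
            mod.rcs_basis(np.arange(5.0), (1.0, 1.0, 2.0))

    def test_default_knots_quantiles(self):
        x = np.concatenate([np.zeros(50), np.ones(30), np.full(15, 2.0), np.full(5, 4.0)])
        knots = mod.default_knots(x)
        assert len(set(knots)) == 3
        with pytest.raises(ValueError):
            mod.default_knots(np.array([1.0, 1.0, 2.0, 2.0]))


@pytest.fixture(scope="module")
def assoc_data(small_sim):
    """Eligible cohort-1 rows with raw-count diversity outcomes."""
    part = small_sim.participants
    _, eligible = ex.apply_exclusions(part, small_sim.records)
    part = part.loc[eligible]
    exps = ex.build_exposures(part, small_sim.records)
    data = part.join(exps.counts)
    div = mb.diversity_table(small_sim.counts.loc[part.index])
    data = data.join(div)
    return data[data["cohort"] == "cohort1"]


class TestFitAssociation:
    def test_reml_with_degenerate_grouping_matches_ols(self):
        """family_sd = 0 in the generator: the random-intercept fit collapses
        to OLS."""
        cfg = sy.SimConfig(
            n_per_cohort=(5, 5, 300), species_count=40, sequencing_depth=6000,
            family_sd=0.0, plate_sd=0.0, confounding_strength=0.0, seed=11,
        )
        data = sy.simulate(cfg)
        part = data.participants[data.participants["cohort"] == "cohort3"]
        exps = ex.build_exposures(part, data.records)
        d = part.join(exps.counts).join(mb.diversity_table(data.counts.loc[part.index]))
        terms = [t for t in ex.EXPOSURE_COLUMNS if (d[t] > 0).sum() > 3]
        ols = mod.fit_association(d, "richness", terms, covariates=(("age",), ("sex",)))
        reml = mod.fit_association(
            d, "richness", terms, covariates=(("age",), ("sex",)), group="family_id"
        )
        assert np.allclose(ols.params[terms], reml.params[terms], atol=1e-4)

    def test_permutation_null_calibration(self, assoc_data):
        """Permuting the outcome: ~5% of exposure terms exceed |t| > 1.96."""
        d = assoc_data.copy()
        terms = [t for t in ex.EXPOSURE_COLUMNS if (d[t] > 0).sum() > 2]
        rng = np.random.default_rng(99)
        n_sig = n_tot = 0
        y = d["shannon"].to_numpy().copy()
        for _ in range(50):
            d["shannon"] = rng.permutation(y)
            res = mod.fit_association(d, "shannon", terms, covariates="basic")
            t = res.params[terms] / res.bse[terms]
            n_sig += int((np.abs(t) > 1.96).sum())
            n_tot += len(terms)
        frac = n_sig / n_tot
        se = np.sqrt(0.05 * 0.95 / n_tot)
        assert abs(frac - 0.05) < 3 * se + 1e-9

    def test_rank_deficiency_error_names_terms(self, assoc_data):
        d = assoc_data.copy()
        d["dup"] = d["clindamycin_lt1y"]
        with pytest.raises(ValueError, match="aliased"):
            mod.fit_association(
                d, "shannon", ["clindamycin_lt1y", "dup"], covariates="basic"
            )

    def test_fit_many_ols_matches_per_outcome_fits(self, assoc_data, small_sim):
        d = assoc_data
        clr = mb.clr_transform(
            mb.relative_abundance(small_sim.counts.loc[d.index]).iloc[:, :5]
        )
        terms = [t for t in ex.EXPOSURE_COLUMNS if (d[t] > 0).sum() > 2][:6]
        long = mod.fit_many_ols(d, clr, terms, covariates="basic")
        for spc in clr.columns[:2]:
            res = mod.fit_association(
                d.join(clr[[spc]]), spc, terms, covariates="basic"
            )
            sub = long[long["outcome"] == spc].set_index("term")
            assert np.allclose(sub["beta"], res.params[terms], atol=1e-10)
            assert np.allclose(sub["se"], res.bse[terms], atol=1e-10)

    def test_basic_full_concordance_without_confounding(self):
        """With no planted confounding, basic- and full-model coefficients
        agree closely (rank correlation >= 0.95 across exposure terms)."""
        cfg = sy.SimConfig(
            n_per_cohort=(1500, 5, 5), species_count=60, sequencing_depth=8000,
            confounding_strength=0.0, seed=13,
        )
        data = sy.simulate(cfg)
        part = data.participants[data.participants["cohort"] == "cohort1"]
        d = part.join(ex.build_exposures(part, data.records).counts)
        d = d.join(mb.diversity_table(data.counts.loc[part.index]))
        terms = [t for t in ex.EXPOSURE_COLUMNS if (d[t] > 0).sum() > 2]
        basic = mod.fit_association(d, "richness", terms, covariates="basic")
        full = mod.fit_association(d, "richness", terms, covariates="full")
        rho = stats.spearmanr(basic.params[terms], full.params[terms])[0]
        assert rho >= 0.95


class TestEmm:
    def linear_data(self, beta=-20.0, n=300):
        rng = np.random.default_rng(21)
        d = pd.DataFrame(
            {
                "c_lt1y": rng.integers(0, 5, n).astype(float),
                "c_1to4y": rng.integers(0, 5, n).astype(float),
                "c_4to8y": rng.integers(0, 5, n).astype(float),
            }
        )
        d["y"] = 100.0 + beta * d["c_lt1y"] - 3.0 * d["c_1to4y"]
        return d

    def test_linear_case_recovers_slope_exactly(self):
        d = self.linear_data()
        grid = mod.emm_curve(
            d, "y", {p: f"c_{p}" for p in ex.PERIOD_ORDER}, "lt1y",
            covariates=((), ()), grid=(0, 1, 2, 3, 4),
        )
        diffs = np.diff(grid.emm)
        assert np.allclose(diffs, -20.0, atol=1e-8)

    def test_emm_at_zero_independent_of_knots(self):
        d = self.linear_data()
        args = (d, "y", {p: f"c_{p}" for p in ex.PERIOD_ORDER}, "lt1y")
        g1 = mod.emm_curve(*args, covariates=((), ()), knots={"lt1y": (0.0, 1.0, 4.0)})
        g2 = mod.emm_curve(*args, covariates=((), ()), knots={"lt1y": (0.0, 2.0, 4.0)})
        assert g1.emm[0] == pytest.approx(g2.emm[0], abs=1e-8)

    def test_pairwise_contrast_antisymmetry_and_se(self):
        rng = np.random.default_rng(22)
        d = self.linear_data()
        d["y"] = d["y"] + rng.normal(0, 5.0, len(d))
        grid = mod.emm_curve(
            d, "y", {p: f"c_{p}" for p in ex.PERIOD_ORDER}, "lt1y",
            covariates=((), ()),
        )
        c = grid.contrasts.set_index(["a", "b"])
        assert c.loc[(0, 1), "diff"] == pytest.approx(-(grid.emm[1] - grid.emm[0]))
        # delta-method closed form for the (1 vs 0) contrast in a pure-linear
        # fit equals the SE of the slope; here the spline term is active, so
        # just check the SE is positive and finite
        assert (grid.contrasts["se"] > 0).all()


class TestGvif:
    def test_orthogonal_predictors_give_unity(self):
        rng = np.random.default_rng(30)
        n = 4000
        X = pd.DataFrame(
            {"Intercept": 1.0, "a": rng.normal(size=n), "b": rng.normal(size=n)}
        )
        out = mod.gvif(X, {"a": ["a"], "b": ["b"]})
        assert np.allclose(out["gvif"], 1.0, atol=0.02)

    def test_near_collinearity_explodes(self):
        rng = np.random.default_rng(31)
        n = 500
        a = rng.normal(size=n)
        X = pd.DataFrame(
            {"Intercept": 1.0, "a": a, "b": a + rng.normal(0, 0.01, n)}
        )
        out = mod.gvif(X, {"a": ["a"]})
        assert out.loc["a", "gvif"] > 100

    def test_single_column_terms_match_auxiliary_regression_oracle(self):
        """1/(1-R^2) from regressing each predictor on the others."""
        rng = np.random.default_rng(32)
        n = 800
        z = rng.normal(size=(n, 2))
        X = pd.DataFrame(
            {
                "Intercept": 1.0,
                "x1": z[:, 0],
                "x2": 0.6 * z[:, 0] + 0.8 * z[:, 1],
                "x3": rng.normal(size=n),
            }
        )
        out = mod.gvif(X, {c: [c] for c in ["x1", "x2", "x3"]})
        M = X[["x1", "x2", "x3"]].to_numpy()
        for i, c in enumerate(["x1", "x2", "x3"]):
            others = np.column_stack(
                [np.ones(n), np.delete(M, i, axis=1)]
            )
            yhat = others @ np.linalg.lstsq(others, M[:, i], rcond=None)[0]
            r2 = 1 - ((M[:, i] - yhat) ** 2).sum() / (
                (M[:, i] - M[:, i].mean()) ** 2
            ).sum()
            assert out.loc[c, "gvif"] == pytest.approx(1 / (1 - r2), rel=1e-6)

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"Intercept": 1.0, "a": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="constant"):
            mod.gvif(X, {"a": ["a"]})


class TestInteractionLrt:
    def test_no_interaction_columns_gives_p_one(self, assoc_data):
        p = mod.interaction_lrt(
            assoc_data, "shannon", [], "sex",
            [t for t in ex.EXPOSURE_COLUMNS if (assoc_data[t] > 0).sum() > 2],
            covariates="basic",
        )
        assert p == 1.0

    def test_planted_sex_specific_effect_detected(self):
        cfg = sy.SimConfig(
            n_per_cohort=(2500, 5, 5), species_count=50, sequencing_depth=8000,
            diversity_effect={"clindamycin": 40.0},
            sex_specific_scale={"clindamycin": (1.0, 0.0)},  # women only
            decay_halflife_months=float("inf"),
            confounding_strength=0.0, seed=17,
        )
        data = sy.simulate(cfg)
        part = data.participants[data.participants["cohort"] == "cohort1"]
        d = part.join(ex.build_exposures(part, data.records).counts)
        d = d.join(mb.diversity_table(data.counts.loc[part.index]))
        cls_cols = [f"clindamycin_{p}" for p in ex.PERIOD_ORDER]
        terms = [t for t in ex.EXPOSURE_COLUMNS if (d[t] > 0).sum() > 2]
        assert mod.interaction_eligible(d, cls_cols, "sex")
        p = mod.interaction_lrt(
            d, "richness", cls_cols, "sex", terms, covariates="basic"
        )
        assert p < 0.01


class TestPartialSpearman:
    def test_no_covariates_equals_plain_spearman(self):
        rng = np.random.default_rng(40)
        x, y = rng.normal(size=200), rng.normal(size=200)
        rho, p = mod.partial_spearman(x, y)
        rho0, p0 = stats.spearmanr(x, y)
        assert rho == pytest.approx(rho0) and p == pytest.approx(p0)

    def test_identity_relation_with_irrelevant_covariate(self):
        rng = np.random.default_rng(41)
        x = rng.normal(size=300)
        z = pd.DataFrame({"z": rng.normal(size=300)})
        rho, _ = mod.partial_spearman(x, x.copy(), z)
        assert rho > 0.99

    def test_confounder_induced_association_removed(self):
        """x and y linked only through z: partial rho collapses toward 0."""
        rng = np.random.default_rng(42)
        n = 1000
        z = rng.normal(size=n)
        x = z + rng.normal(0, 0.5, n)
        y = z + rng.normal(0, 0.5, n)
        plain = abs(stats.spearmanr(x, y)[0])
        rho, _ = mod.partial_spearman(x, y, pd.DataFrame({"z": z}))
        assert abs(rho) < plain
        assert abs(rho) < 3 / np.sqrt(n)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mod.partial_spearman(np.ones(10), np.arange(10.0))
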