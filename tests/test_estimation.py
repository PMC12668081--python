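import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hatrial import estimation as E
from hatrial.synthetic_cohort import CohortSpec, generate_cohort

from conftest import (
    CORRECT_OUTCOME_TERMS,
    CORRECT_PS_TERMS,
    brute_force_weighted_quantile,
    make_confounded_dgp,
    saturated_gcomp,
)


class TestTruncationBound:
    def test_printed_formula_values(self):
        assert E.truncation_bound(2842) == pytest.approx(30.07, abs=0.005)
        assert E.truncation_bound(100) == pytest.approx(4.29, abs=0.005)

    def test_monotone_in_n(self):
        assert E.truncation_bound(2843) > E.truncation_bound(2842)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            E.truncation_bound(1)


class TestPropensity:
    def test_null_model_recovers_marginal(self, rng):
        n = 2000
        df = pd.DataFrame(
            {
                "w": rng.normal(size=n),
                "strategy": np.where(rng.random(n) < 0.5, "HA", "no_HA"),
            }
        )
        fit = E.fit_propensity(df, "strategy", ["w"], strategies=("no_HA", "HA"))
        assert np.all(np.abs(fit.proba[:, 1] - 0.5) < 0.05)

    def test_multinomial_probabilities_sum_to_one(self, rng):
        n = 900
        df = pd.DataFrame(
            {
                "w": rng.normal(size=n),
                "strategy": rng.choice(["a", "b", "c"], size=n),
            }
        )
        fit = E.fit_propensity(df, "strategy", ["w"], strategies=("a", "b", "c"))
        np.testing.assert_allclose(fit.proba.sum(axis=1), 1.0, atol=1e-8)

    def test_logistic_coefficient_recovery(self):
        reps = 30
        coefs = []
        for s in range(reps):
            r = np.random.default_rng(1000 + s)
            n = 5000
            w = r.normal(size=n)
            p = 1 / (1 + np.exp(-(-0.5 + 0.8 * w)))
            a = (r.random(n) < p).astype(int)
            df = pd.DataFrame(
                {"w": w, "strategy": np.where(a == 1, "HA", "no_HA")}
            )
            fit = E.fit_propensity(
                df, "strategy", ["w"], strategies=("no_HA", "HA")
            )
            # recover the slope from the fitted probabilities
            lp = np.log(fit.proba[:, 1] / fit.proba[:, 0])
            slope = np.polyfit(w, lp, 1)[0]
            coefs.append(slope)
        se = np.std(coefs, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(coefs) - 0.8) < 2 * se + 0.02

    def test_truncation_floors_probabilities(self, rng):
        n = 400
        w = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(4.0 * w)))
        a = (rng.random(n) < p).astype(int)
        df = pd.DataFrame({"w": w, "strategy": np.where(a == 1, "HA", "no_HA")})
        fit = E.fit_propensity(df, "strategy", ["w"], strategies=("no_HA", "HA"))
        assert np.all(1.0 / fit.proba_trunc <= fit.bound + 1e-9)
        assert fit.n_truncated > 0

    def test_perfect_separation_rejected(self):
        df = pd.DataFrame(
            {
                "w": np.r_[np.zeros(15), np.ones(15)],
                "strategy": ["no_HA"] * 15 + ["HA"] * 15,
            }
        )
        with pytest.raises(ValueError, match="separation|converge"):
            E.fit_propensity(df, "strategy", ["w"], strategies=("no_HA", "HA"))


def _constant_propensity(n, strategies, p):
    proba = np.tile(np.asarray(p, dtype=float), (n, 1))
    return E.PropensityFit(
        strategies=tuple(strategies),
        proba=proba,
        proba_trunc=proba,
        bound=E.truncation_bound(n),
        n_truncated=0,
        terms=(),
    )


class TestTMLE:
    def test_randomized_equals_gcomp_with_eps_zero(self):
        r = np.random.default_rng(4)
        n = 3000
        w = r.normal(size=n)
        a = r.integers(2, size=n)
        y = 1 + 2.0 * a + 1.5 * w + r.normal(size=n)
        df = pd.DataFrame(
            {"w": w, "strategy": np.where(a == 1, "HA", "no_HA"), "Y": y}
        )
        prop = _constant_propensity(n, ("no_HA", "HA"), [0.5, 0.5])
        t = E.tmle_mean_contrast(df, "strategy", "Y", ["w"], prop)
        # g-computation with the same linear model and the same boundary
        # clipping the estimator contract mandates for its predictions
        lo, hi = y.min(), y.max()
        ys = (y - lo) / (hi - lo)
        X = np.column_stack([np.ones(n), a, w])
        beta = np.linalg.lstsq(X, ys, rcond=None)[0]
        gcomp = {}
        for level in (0, 1):
            pred = np.column_stack(
                [np.ones(n), np.full(n, level), w]
            ) @ beta
            gcomp[level] = lo + np.clip(pred, 1e-4, 1 - 1e-4).mean() * (hi - lo)
        assert abs(t.epsilon["HA"]) < 1e-10
        assert t.contrasts["HA"] == pytest.approx(
            gcomp[1] - gcomp[0], abs=1e-6
        )

    def test_discrete_toy_equals_hand_gcomp(self):
        # 12 rows, binary W, binary A; outcome table fixed; every (A, W)
        # cell mean is interior so prediction clipping is inert
        df = pd.DataFrame(
            {
                "W": [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1],
                "A": [0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 0, 1],
                "Y": [3.0, 5.0, 7.0, 9.0, 8.0, 4.0, 6.0, 2.0, 9.0, 7.0, 4.0, 8.0],
            }
        )
        df["strategy"] = np.where(df["A"] == 1, "HA", "no_HA")
        pf = E.fit_propensity(
            df, "strategy", ["W"], strategies=("no_HA", "HA"),
            min_rows_per_strategy=1,
        )
        t = E.tmle_mean_contrast(
            df, "strategy", "Y", ["W"], pf, interactions=True
        )
        for label, a in (("no_HA", "no_HA"), ("HA", "HA")):
            oracle = saturated_gcomp(df, a)
            assert t.means[label] == pytest.approx(oracle, abs=1e-9)

    def test_score_equation_solved(self):
        df = make_confounded_dgp(1500, seed=9)
        pf = E.fit_propensity(
            df, "strategy", CORRECT_PS_TERMS, strategies=("no_HA", "HA")
        )
        t = E.tmle_mean_contrast(
            df, "strategy", "ptau181_fu", CORRECT_OUTCOME_TERMS, pf
        )
        for s, resid in t.score_residuals.items():
            assert abs(resid) < 1e-8

    def test_mean_influence_curve_near_zero(self):
        df = make_confounded_dgp(1200, seed=10)
        pf = E.fit_propensity(
            df, "strategy", CORRECT_PS_TERMS, strategies=("no_HA", "HA")
        )
        t = E.tmle_mean_contrast(
            df, "strategy", "ptau181_fu", CORRECT_OUTCOME_TERMS, pf
        )
        for s in t.strategies:
            assert abs(t.influence[s].mean()) < 1e-6

    def test_targeted_mean_within_bounds(self):
        df = make_confounded_dgp(900, seed=11)
        pf = E.fit_propensity(
            df, "strategy", CORRECT_PS_TERMS, strategies=("no_HA", "HA")
        )
        t = E.tmle_mean_contrast(
            df, "strategy", "ptau181_fu", CORRECT_OUTCOME_TERMS, pf
        )
        a, b = t.bounds
        for s in t.strategies:
            assert a <= t.means[s] <= b

    def test_constant_outcome_rejected(self):
        df = make_confounded_dgp(300, seed=12)
        df["flat"] = 1.0
        pf = E.fit_propensity(
            df, "strategy", CORRECT_PS_TERMS, strategies=("no_HA", "HA")
        )
        with pytest.raises(ValueError, match="constant"):
            E.tmle_mean_contrast(df, "strategy", "flat", ["age"], pf)

    def test_affine_rescaling_equivariance(self):
        df = make_confounded_dgp(1000, seed=13)
        pf = E.fit_propensity(
            df, "strategy", CORRECT_PS_TERMS, strategies=("no_HA", "HA")
        )
        t1 = E.tmle_mean_contrast(
            df, "strategy", "ptau181_fu", CORRECT_OUTCOME_TERMS, pf
        )
        df2 = df.copy()
        df2["ptau181_fu"] = 3.0 * df2["ptau181_fu"] + 7.0
        t2 = E.tmle_mean_contrast(
            df2, "strategy", "ptau181_fu", CORRECT_OUTCOME_TERMS, pf
        )
        assert t2.contrasts["HA"] == pytest.approx(
            3.0 * t1.contrasts["HA"], rel=1e-9
        )


class TestWeightedQuantile:
    def test_equal_weights_type1(self):
        assert E.weighted_quantile(np.array([1, 2, 3, 4.0]), np.ones(4), 0.5) == 2

    def test_cumulative_weight_enumeration(self):
        y = np.array([1, 2, 3, 4.0])
        w = np.array([0.1, 0.1, 0.1, 0.7])
        assert E.weighted_quantile(y, w, 0.5) == 4

    def test_randomized_matches_unweighted(self, rng):
        n = 3000
        y = rng.normal(size=n)
        a = rng.integers(2, size=n)
        df = pd.DataFrame(
            {"Y": y, "strategy": np.where(a == 1, "HA", "no_HA")}
        )
        pf = _constant_propensity(n, ("no_HA", "HA"), [0.5, 0.5])
        q = E.ipw_quantile_contrast(df, "strategy", "Y", pf, 0.9)
        for s, sel in (("no_HA", a == 0), ("HA", a == 1)):
            unweighted = np.quantile(y[sel], 0.9, method="inverted_cdf")
            assert q.quantiles[s] == pytest.approx(unweighted, abs=1e-12)

    @settings(max_examples=150, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.integers(min_value=-5, max_value=5),
                st.floats(min_value=0.01, max_value=10.0),
            ),
            min_size=1,
            max_size=50,
        ),
        tau=st.floats(min_value=0.02, max_value=0.98),
    )
    def test_exhaustive_brute_force_property(self, data, tau):
        y = np.array([d[0] for d in data], dtype=float)
        w = np.array([d[1] for d in data])
        assert E.weighted_quantile(y, w, tau) == brute_force_weighted_quantile(
            y, w, tau
        )

    def test_empty_strategy_rejected(self, rng):
        df = pd.DataFrame({"Y": [1.0, 2.0], "strategy": ["HA", "HA"]})
        pf = _constant_propensity(2, ("no_HA", "HA"), [0.5, 0.5])
        with pytest.raises(ValueError, match="no_HA"):
            E.ipw_quantile_contrast(df, "strategy", "Y", pf, 0.9)

    def test_invalid_tau(self, rng):
        with pytest.raises(ValueError, match="tau"):
            E.weighted_quantile(np.array([1.0]), np.array([1.0]), 1.5)


class TestRCS:
    def test_three_knots_two_columns(self):
        B = E.rcs_basis(np.linspace(0, 10, 30), [2, 5, 8])
        assert B.shape[1] == 2

    def test_left_tail_nonlinear_zero(self):
        x = np.linspace(-10, 1, 40)
        B = E.rcs_basis(x, [2, 5, 8])
        assert np.allclose(B[:, 1], 0.0)

    def test_second_derivative_zero_beyond_boundaries(self):
        x = np.linspace(-10, 20, 6001)
        h = x[1] - x[0]
        B = E.rcs_basis(x, [2.0, 5.0, 8.0])
        d2 = np.diff(B[:, 1], 2) / h**2
        inner_x = x[1:-1]
        assert np.abs(d2[inner_x < 1.9]).max() < 1e-6
        assert np.abs(d2[inner_x > 8.1]).max() < 1e-6

    def test_nonincreasing_knots_rejected(self):
        with pytest.raises(ValueError):
            E.rcs_basis(np.arange(5.0), [3, 3, 8])


class TestMSM:
    def test_strategy_only_msm_reproduces_tmle_means(self):
        df = make_confounded_dgp(1200, seed=17)
        pf = E.fit_propensity(
            df, "strategy", CORRECT_PS_TERMS, strategies=("no_HA", "HA")
        )
        t = E.tmle_mean_contrast(
            df, "strategy", "ptau181_fu", CORRECT_OUTCOME_TERMS, pf
        )
        msm = E.tmle_msm_effect_modification(
            df, "strategy", "ptau181_fu", None, CORRECT_OUTCOME_TERMS, pf,
            tmle=t,
        )
        for s in t.strategies:
            assert msm.implied_means[s] == pytest.approx(t.means[s], abs=1e-8)

    def test_null_modification_product_coefficient(self):
        reps = 40
        coefs = []
        for s in range(reps):
            df = make_confounded_dgp(1200, seed=5000 + s)
            pf = E.fit_propensity(
                df, "strategy", CORRECT_PS_TERMS, strategies=("no_HA", "HA")
            )
            msm = E.tmle_msm_effect_modification(
                df, "strategy", "ptau181_fu", "apoe_e4",
                CORRECT_OUTCOME_TERMS, pf,
            )
            idx = msm.term_names.index("strategy[HA]:modifier")
            coefs.append(msm.coef[idx])
        se = np.std(coefs, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(coefs)) < 2 * se + 0.02

    def test_linear_modification_recovery(self):
        spec_kwargs = dict(
            effect_mod_col="cognition_3ms",
            effect_mod_slope={"ptau181": 0.5},
        )
        df = make_confounded_dgp(4000, seed=23, effect=1.0,
                                 spec_kwargs=spec_kwargs)
        pf = E.fit_propensity(
            df, "strategy", CORRECT_PS_TERMS, strategies=("no_HA", "HA")
        )
        covs = CORRECT_OUTCOME_TERMS + ["cognition_3ms"]
        msm = E.tmle_msm_effect_modification(
            df, "strategy", "ptau181_fu", "cognition_3ms", covs, pf,
            grid_size=41,
        )
        curve = msm.curve.pivot(
            index="modifier", columns="strategy", values="predicted_mean"
        )
        contrast = curve["HA"] - curve["no_HA"]
        grid = contrast.index.to_numpy()
        i0 = 5
        i1 = int(np.argmin(np.abs(grid - (grid[i0] + 2.0))))
        span = grid[i1] - grid[i0]
        diff = (contrast.iloc[i1] - contrast.iloc[i0]) / span * 2.0
        assert diff == pytest.approx(1.0, abs=0.2)

    def test_constant_modifier_rejected(self):
        df = make_confounded_dgp(500, seed=29)
        df["const_mod"] = 2.0
        pf = E.fit_propensity(
            df, "strategy", CORRECT_PS_TERMS, strategies=("no_HA", "HA")
        )
        with pytest.raises(ValueError, match="constant"):
            E.tmle_msm_effect_modification(
                df, "strategy", "ptau181_fu", "const_mod",
                CORRECT_OUTCOME_TERMS, pf,
            )

    def test_knots_at_sample_percentiles(self):
        df = make_confounded_dgp(1500, seed=31)
        pf = E.fit_propensity(
            df, "strategy", CORRECT_PS_TERMS, strategies=("no_HA", "HA")
        )
        msm = E.tmle_msm_effect_modification(
            df, "strategy", "ptau181_fu", "cognition_3ms",
            CORRECT_OUTCOME_TERMS, pf,
        )
        expected = np.quantile(df["cognition_3ms"], [0.1, 0.5, 0.9])
        np.testing.assert_allclose(msm.knots, expected)


class TestMARS:
    def test_linear_generator_cross_estimator_agreement(self):
        df = make_confounded_dgp(3000, seed=37, effect=2.0)
        pf = E.fit_propensity(
            df, "strategy", CORRECT_PS_TERMS, strategies=("no_HA", "HA")
        )
        glm = E.tmle_mean_contrast(
            df, "strategy", "ptau181_fu", CORRECT_OUTCOME_TERMS, pf
        )
        mars = E.tmle_mean_contrast(
            df, "strategy", "ptau181_fu", CORRECT_OUTCOME_TERMS, pf,
            nuisance="mars",
        )
        assert mars.contrasts["HA"] == pytest.approx(
            glm.contrasts["HA"], abs=0.2
        )

    def test_hinge_confounder_mars_beats_glm(self):
        # confounder enters the outcome through a threshold; the linear
        # initial fit is misspecified while MARS can represent the hinge.
        reps = 25
        glm_err, mars_err = [], []
        for s in range(reps):
            r = np.random.default_rng(7000 + s)
            n = 800
            w = r.normal(size=n)
            p = 1 / (1 + np.exp(-1.2 * w))
            a = (r.random(n) < p).astype(int)
            y = 5.0 * np.clip(w - 0.3, 0, None) + 1.0 * a + 0.5 * r.normal(size=n)
            df = pd.DataFrame(
                {"w": w, "strategy": np.where(a == 1, "HA", "no_HA"), "Y": y}
            )
            # misspecified propensity (null model) isolates the outcome fit
            pf = _constant_propensity(n, ("no_HA", "HA"), [1 - a.mean(), a.mean()])
            glm = E.tmle_mean_contrast(df, "strategy", "Y", ["w"], pf)
            mars = E.tmle_mean_contrast(
                df, "strategy", "Y", ["w"], pf, nuisance="mars"
            )
            glm_err.append(glm.contrasts["HA"] - 1.0)
            mars_err.append(mars.contrasts["HA"] - 1.0)
        assert abs(np.mean(mars_err)) < abs(np.mean(glm_err))

    def test_interaction_degree_capped_at_two(self, rng):
        n = 600
        X = rng.normal(size=(n, 4))
        y = (
            np.clip(X[:, 0], 0, None) * np.clip(X[:, 1], 0, None)
            + X[:, 2]
            + 0.3 * rng.normal(size=n)
        )
        m = E.MarsModel(max_terms=21).fit(X, y)
        assert m.max_interaction_order() <= 2

    def test_propensity_variant_in_unit_interval(self):
        df = make_confounded_dgp(800, seed=41)
        proba = E.mars_nuisance_fit(
            df, "propensity", "strategy", None, CORRECT_PS_TERMS,
            strategies=("no_HA", "HA"),
        )
        assert np.all((proba > 0) & (proba < 1))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-8)
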