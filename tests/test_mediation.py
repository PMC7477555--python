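import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize
from scipy.special import expit

from tdluprs import (
    ExternalEstimates,
    GeneratorConfig,
    JointRiskModel,
    MediatorModel,
    bootstrap_proportion_ci,
    calibrate_joint_model,
    estimate_mediation,
    estimate_pm_percent,
    fit_mediator_model,
    generate_cohort,
    induced_marginal_slope,
    mediation_grid,
)
from tdluprs.mediation import _fractional_logistic_fit

from conftest import small_config


def _independent_cohort(n=300, seed=2, rate=3.0):
    """Cohort whose TDLU counts are independent of the score."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "tdlu_count": rng.poisson(rate, n),
            "tissue_area_mm2": rng.uniform(20, 60, n),
            "prs_std": rng.standard_normal(n),
            "age_years": rng.uniform(25, 65, n),
            "study": np.where(rng.random(n) < 0.8, "KTB", "STAMP"),
            "acini_per_tdlu": np.nan,
        }
    )


def _product_cohort(reps=4):
    """Every (count, score) pair crossed: exact empirical independence."""
    counts = np.arange(7.0)
    scores = np.array([-1.5, -0.5, 0.5, 1.5])
    m, x = np.meshgrid(counts, scores)
    m, x = np.tile(m.ravel(), reps), np.tile(x.ravel(), reps)
    return pd.DataFrame(
        {
            "tdlu_count": m,
            "prs_std": x,
            "tissue_area_mm2": 30.0,
            "age_years": 45.0,
            "study": "KTB",
            "acini_per_tdlu": np.nan,
        }
    )


def _manual_joint(beta0, beta, gamma, scale=1.0, **targets):
    return JointRiskModel(
        beta0=beta0, beta=beta, gamma=gamma,
        calibration_residuals=(0.0, 0.0, 0.0),
        targets=ExternalEstimates(**targets), tdlu_scale=scale,
    )


def _manual_mediator(intercept, prs_slope):
    return MediatorModel(
        coefficients={"intercept": intercept, "prs": prs_slope},
        offset_used=False, mean_covariate_part=intercept,
        mean_log_offset=0.0, converged=True,
    )


class TestFractionalLogisticFit:
    def test_matches_dense_grid_oracle_on_six_rows(self):
        v = np.array([-1.2, -0.4, 0.0, 0.3, 0.9, 2.0])
        p = expit(-0.7 + 0.55 * v + 0.2 * np.sin(3 * v))  # not exactly logistic

        def negll(theta):
            q = expit(theta[0] + theta[1] * v)
            return -(p @ np.log(q) + (1 - p) @ np.log(1 - q))

        grid_a = np.linspace(-3, 3, 121)
        grid_b = np.linspace(-3, 3, 121)
        vals = [(negll((a, b)), a, b) for a in grid_a for b in grid_b]
        _, a0, b0 = min(vals)
        polish = optimize.minimize(negll, [a0, b0], method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-14})
        a, b = _fractional_logistic_fit(p, v)
        assert a == pytest.approx(polish.x[0], abs=1e-4)
        assert b == pytest.approx(polish.x[1], abs=1e-4)

    def test_recovers_exact_logistic_law(self):
        v = np.linspace(-2, 2, 50)
        p = expit(0.4 - 1.1 * v)
        a, b = _fractional_logistic_fit(p, v)
        assert (a, b) == (pytest.approx(0.4, abs=1e-8), pytest.approx(-1.1, abs=1e-8))


class TestInducedMarginalSlope:
    def test_no_mediator_effect_prs_slope_is_gamma(self, small_cohort):
        model = _manual_joint(-2.0, 0.0, 0.45)
        slope = induced_marginal_slope(model, small_cohort, "prs")
        assert slope == pytest.approx(0.45, abs=1e-7)

    def test_no_pathway_tdlu_slope_zero_under_independence(self):
        cohort = _product_cohort()
        model = _manual_joint(-2.0, 0.0, 0.45)
        slope = induced_marginal_slope(model, cohort, "tdlu")
        assert abs(slope) < 1e-8


class TestCalibration:
    def test_reproduces_targets_and_prevalence(self, default_cohort):
        ext = ExternalEstimates(or_prs_bc_per_sd=1.61, or_tdlu_bc=1.45,
                                prevalence=0.1)
        model = calibrate_joint_model(ext, default_cohort)
        assert max(abs(r) for r in model.calibration_residuals) < 1e-6
        s_prs = induced_marginal_slope(model, default_cohort, "prs")
        s_tdlu = induced_marginal_slope(model, default_cohort, "tdlu")
        assert s_prs == pytest.approx(np.log(1.61), abs=1e-6)
        assert s_tdlu == pytest.approx(np.log(1.45), abs=1e-6)

    def test_unit_or_forces_beta_zero(self):
        cohort = _product_cohort()
        ext = ExternalEstimates(or_prs_bc_per_sd=1.5, or_tdlu_bc=1.0,
                                prevalence=0.2)
        model = calibrate_joint_model(ext, cohort)
        assert model.beta == pytest.approx(0.0, abs=1e-7)
        assert model.gamma == pytest.approx(np.log(1.5), abs=1e-7)

    def test_idempotent_recalibration(self, default_cohort):
        ext = ExternalEstimates()
        m1 = calibrate_joint_model(ext, default_cohort)
        m2 = calibrate_joint_model(ext, default_cohort)
        assert abs(m1.beta0 - m2.beta0) < 1e-8
        assert abs(m1.beta - m2.beta) < 1e-8
        assert abs(m1.gamma - m2.gamma) < 1e-8

    def test_matches_grid_polish_oracle_on_small_fixture(self):
        cohort = _independent_cohort(n=50, seed=8)
        ext = ExternalEstimates(or_prs_bc_per_sd=1.5, or_tdlu_bc=1.2,
                                tdlu_or_unit="per_count", prevalence=0.2)
        model = calibrate_joint_model(ext, cohort)

        prs = cohort["prs_std"].to_numpy()
        m = cohort["tdlu_count"].to_numpy(dtype=float)

        def sq_residuals(theta):
            p = expit(theta[0] + theta[1] * m + theta[2] * prs)
            _, s_prs = _fractional_logistic_fit(p, prs)
            _, s_tdlu = _fractional_logistic_fit(p, m)
            from scipy.special import logit
            return (
                (s_prs - np.log(1.5)) ** 2
                + (s_tdlu - np.log(1.2)) ** 2
                + (logit(p.mean()) - logit(0.2)) ** 2
            )

        best = None
        for b0 in np.linspace(-3, 0, 7):
            for b in np.linspace(-0.1, 0.4, 6):
                for g in np.linspace(0.0, 0.8, 5):
                    v = sq_residuals((b0, b, g))
                    if best is None or v < best[0]:
                        best = (v, (b0, b, g))
        polish = optimize.minimize(sq_residuals, best[1], method="Nelder-Mead",
                                   options={"xatol": 1e-9, "fatol": 1e-16,
                                            "maxiter": 2000, "maxfev": 4000})
        assert model.beta0 == pytest.approx(polish.x[0], abs=1e-3)
        assert model.beta == pytest.approx(polish.x[1], abs=1e-3)
        assert model.gamma == pytest.approx(polish.x[2], abs=1e-3)

    def test_infeasible_targets_raise_with_residuals(self):
        cohort = _independent_cohort(n=80, seed=12)
        ext = ExternalEstimates(or_prs_bc_per_sd=50.0, or_tdlu_bc=50.0,
                                prevalence=0.999)
        with pytest.raises(RuntimeError, match="residuals"):
            calibrate_joint_model(ext, cohort)


class TestMediatorModel:
    def test_large_n_slope_recovery(self):
        cfg = small_config(n=20_000, prs_effect_log_rr=0.113, seed=41)
        cohort = generate_cohort(cfg)
        model = fit_mediator_model(cohort)
        from tdluprs import RegressionSpec, fit_poisson_robust
        se = fit_poisson_robust(cohort, RegressionSpec()).term("prs")["se"]
        assert abs(model.coefficients["prs"] - 0.113) < 3 * se

    def test_null_slope(self, null_cohort):
        model = fit_mediator_model(null_cohort)
        from tdluprs import RegressionSpec, fit_poisson_robust
        se = fit_poisson_robust(null_cohort, RegressionSpec()).term("prs")["se"]
        assert abs(model.coefficients["prs"]) < 3 * se

    def test_glm_mean_identity(self, default_cohort):
        """Score equations force fitted means to average to the observed mean."""
        from tdluprs import RegressionSpec
        from tdluprs.association import _fit_poisson, build_design

        y, design, offset, _ = build_design(default_cohort, RegressionSpec())
        coef, _ = _fit_poisson(y, design, offset)
        fitted = np.exp(design.to_numpy() @ coef + offset)
        assert fitted.mean() == pytest.approx(y.mean(), rel=1e-8)


class TestDecomposition:
    def test_acme_plus_ade_equals_te(self):
        rng = np.random.default_rng(0)
        med = _manual_mediator(np.log(4.0), 0.2)
        for _ in range(25):
            joint = _manual_joint(rng.normal(-2, 0.5), rng.normal(0, 0.3),
                                  rng.normal(0, 0.4), scale=rng.uniform(1, 10))
            res = estimate_mediation(joint, med)
            assert res.acme + res.ade == pytest.approx(res.total_effect, abs=1e-10)
            assert res.pm_percent == pytest.approx(
                100 * res.acme / res.total_effect, abs=1e-9
            )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        st.floats(-4.0, 0.0), st.floats(-1.0, 1.0), st.floats(-1.0, 1.0),
        st.floats(0.5, 12.0), st.floats(0.5, 20.0), st.floats(-0.5, 0.5),
    )
    def test_decomposition_identity_property(self, b0, b, g, scale, lam, slope):
        joint = _manual_joint(b0, b, g, scale=scale)
        med = _manual_mediator(np.log(lam), slope)
        res = estimate_mediation(joint, med)
        assert res.acme + res.ade == pytest.approx(res.total_effect, abs=1e-10)

    def test_beta_zero_means_nothing_mediated(self):
        joint = _manual_joint(-2.0, 0.0, 0.5)
        res = estimate_mediation(joint, _manual_mediator(np.log(3.0), 0.3))
        assert res.acme == pytest.approx(0.0, abs=1e-12)
        assert res.proportion_mediated == pytest.approx(0.0, abs=1e-11)

    def test_gamma_zero_means_fully_mediated(self):
        joint = _manual_joint(-2.0, 0.4, 0.0)
        res = estimate_mediation(joint, _manual_mediator(np.log(3.0), 0.3))
        assert res.ade == pytest.approx(0.0, abs=1e-14)
        assert res.proportion_mediated == pytest.approx(1.0, abs=1e-12)

    def test_tiny_total_effect_flagged(self):
        joint = _manual_joint(-2.0, 0.0, 0.0)
        res = estimate_mediation(joint, _manual_mediator(np.log(3.0), 0.3))
        assert not res.pm_defined
        assert np.isnan(res.proportion_mediated)

    def test_binary_mediator_enumeration_oracle(self):
        """Two-point mediator: every expectation enumerable by hand."""
        beta0, beta, gamma = -1.5, 0.8, 0.4
        pi = {-0.5: 0.3, 0.5: 0.55}  # P(M=1 | x)
        joint = _manual_joint(beta0, beta, gamma)

        def law(x):
            return np.array([0.0, 1.0]), np.array([1 - pi[x], pi[x]])

        res = estimate_mediation(joint, None, mediator_pmf=law)

        def p(m, x):
            return expit(beta0 + beta * m + gamma * x)

        def e(mx, x):
            return (1 - pi[mx]) * p(0, x) + pi[mx] * p(1, x)

        acme = 0.5 * ((e(0.5, 0.5) - e(-0.5, 0.5)) + (e(0.5, -0.5) - e(-0.5, -0.5)))
        ade = 0.5 * ((e(-0.5, 0.5) - e(-0.5, -0.5)) + (e(0.5, 0.5) - e(0.5, -0.5)))
        te = e(0.5, 0.5) - e(-0.5, -0.5)
        assert res.acme == pytest.approx(acme, abs=1e-12)
        assert res.ade == pytest.approx(ade, abs=1e-12)
        assert res.total_effect == pytest.approx(te, abs=1e-12)

    def test_three_point_mediator_enumeration(self):
        joint = _manual_joint(-2.0, 0.3, 0.25, scale=2.0)
        w = {-0.5: np.array([0.5, 0.3, 0.2]), 0.5: np.array([0.2, 0.3, 0.5])}

        def law(x):
            return np.array([0.0, 1.0, 4.0]), w[x]

        res = estimate_mediation(joint, None, mediator_pmf=law)
        support = np.array([0.0, 1.0, 4.0])

        def e(mx, x):
            return float(w[mx] @ expit(-2.0 + 0.3 * support / 2.0 + 0.25 * x))

        te = e(0.5, 0.5) - e(-0.5, -0.5)
        assert res.total_effect == pytest.approx(te, abs=1e-14)
        assert res.acme + res.ade == pytest.approx(te, abs=1e-14)


class TestEndToEnd:
    def test_area_rescaling_leaves_pm(self, default_cohort):
        ext = ExternalEstimates()
        base = estimate_pm_percent(default_cohort, ext)
        scaled = default_cohort.copy()
        scaled["tissue_area_mm2"] = scaled["tissue_area_mm2"] * 12.0
        res = estimate_pm_percent(scaled, ext)
        assert res.pm_percent == pytest.approx(base.pm_percent, abs=1e-6)

    def test_rare_disease_log_odds_approximation(self, default_cohort):
        ext = ExternalEstimates(or_prs_bc_per_sd=1.61, or_tdlu_bc=1.35,
                                prevalence=0.005)
        mediator = fit_mediator_model(default_cohort)
        joint = calibrate_joint_model(ext, default_cohort)
        res = estimate_mediation(joint, mediator)
        delta = (mediator.mean_count(0.5) - mediator.mean_count(-0.5)) / joint.tdlu_scale
        approx = 100 * joint.beta * delta / np.log(1.61)
        assert res.pm_percent == pytest.approx(approx, rel=0.10)

    def test_prevalence_insensitivity_in_rare_to_moderate_range(self, default_cohort):
        vals = [
            estimate_pm_percent(
                default_cohort,
                ExternalEstimates(or_tdlu_bc=1.35, prevalence=k),
            ).pm_percent
            for k in (0.01, 0.05, 0.10, 0.15)
        ]
        assert max(vals) - min(vals) < 0.15 * max(vals)


class TestBootstrap:
    def test_seed_reproducibility(self, small_cohort):
        ext = ExternalEstimates(or_tdlu_bc=1.35)
        a = bootstrap_proportion_ci(small_cohort, ext, n_boot=120, seed=7)
        b = bootstrap_proportion_ci(small_cohort, ext, n_boot=120, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.n_boot_failed == b.n_boot_failed == 0

    def test_n_boot_floor(self, small_cohort):
        with pytest.raises(ValueError, match="at least 100"):
            bootstrap_proportion_ci(small_cohort, ExternalEstimates(), n_boot=50)

    def test_ci_covers_large_sample_truth(self):
        """Scaled-down coverage check of the percentile bootstrap CI."""
        ext = ExternalEstimates(or_tdlu_bc=1.35)
        truth = estimate_pm_percent(
            generate_cohort(small_config(n=80_000, seed=999)), ext
        ).pm_percent
        covered, reps = 0, 40
        for i in range(reps):
            cohort = generate_cohort(small_config(n=500, seed=3000 + i))
            res = bootstrap_proportion_ci(cohort, ext, n_boot=120, seed=i)
            covered += res.ci_low <= truth <= res.ci_high
        assert 0.85 <= covered / reps <= 1.0


class TestGrid:
    def test_monotone_in_tdlu_or_and_near_zero_at_unit(self, default_cohort):
        grid = [ExternalEstimates(or_tdlu_bc=v) for v in (1.0, 1.25, 1.35, 1.45)]
        table = mediation_grid(default_cohort, grid)
        pm = table["pm_percent"].to_numpy()
        assert np.all(np.diff(pm) > 0)
        # at a unit external OR the mediated share nearly vanishes; it is not
        # exactly zero because the calibrated beta must offset the slope the
        # real score->count association leaks into the TDLU marginal
        assert abs(pm[0]) < 0.5

    def test_default_grid_shape(self, default_cohort):
        table = mediation_grid(default_cohort)
        assert len(table) == 9
        assert set(table["score"]) == {"overall", "ER_positive", "ER_negative"}
        assert set(table["or_tdlu_bc"]) == {1.25, 1.35, 1.45}

    def test_cell_failure_isolated(self, small_cohort):
        grid = [
            ExternalEstimates(or_tdlu_bc=1.25),
            ExternalEstimates(or_tdlu_bc=1.25, score_label="no_such_score"),
        ]
        table = mediation_grid(small_cohort, grid)
        assert len(table) == 2
        assert np.isfinite(table.iloc[0]["pm_percent"])
        assert isinstance(table.iloc[1].get("error"), str)
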