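"""Multi-source mediation analysis.

No single study holds the polygenic score, the TDLU involution measures and
breast-cancer outcomes together, so the percent of the score–cancer
association explained by TDLU counts is estimated by combining three
sources: (i) the score→cancer odds ratio from an external consortium,
(ii) a candidate TDLU→cancer odds ratio from an external benign-breast-
disease cohort, and (iii) the score→TDLU relationship fitted on the
in-hand cohort. A joint logistic risk model

    P(D=1 | M, X) = expit(beta0 + beta·M + gamma·X)

(M the TDLU count on its declared unit, X the standardized score) is
calibrated so that its three induced marginals — the single-variable
logistic slope on X, the single-variable logistic slope on M, and the mean
risk — reproduce the two external log odds ratios and an assumed
prevalence. Mediation effects then follow the counterfactual decomposition
of Imai et al.: the average causal mediation effect (ACME) moves the
mediator distribution between score values while holding the exposure slot
fixed, the average direct effect (ADE) does the converse, and
ACME + ADE = total effect holds exactly for the averaged decomposition.
Uncertainty comes from bootstrap resampling of the in-hand cohort with the
external estimates held fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from . import association as assoc_mod

logger = logging.getLogger("tdluprs.mediation")

TDLU_OR_UNITS = ("per_sd_of_tdlu_count", "per_count")

#: published external summary inputs: score→cancer OR per SD by score label,
#: and the candidate grid of TDLU→cancer ORs.
DEFAULT_OR_PRS_BC = {"overall": 1.61, "ER_positive": 1.68, "ER_negative": 1.45}
DEFAULT_OR_TDLU_GRID = (1.25, 1.35, 1.45)
DEFAULT_PREVALENCE = 0.10


@dataclass(frozen=True)
class ExternalEstimates:
    """External summary inputs pinning the joint risk model's marginals."""

    or_prs_bc_per_sd: float = 1.61
    or_tdlu_bc: float = 1.25
    tdlu_or_unit: str = "per_sd_of_tdlu_count"
    prevalence: float = DEFAULT_PREVALENCE
    score_label: str = "overall"

    def __post_init__(self) -> None:
        for name in ("or_prs_bc_per_sd", "or_tdlu_bc"):
            v = getattr(self, name)
            if not (0 < v < np.inf):
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly inside (0, 1)")
        if self.tdlu_or_unit not in TDLU_OR_UNITS:
            raise ValueError(f"tdlu_or_unit must be one of {TDLU_OR_UNITS}")


@dataclass
class MediatorModel:
    """Fitted score→TDLU count model (robust Poisson with area offset)."""

    coefficients: dict[str, float]
    offset_used: bool
    mean_covariate_part: float  # intercept + covariate slopes · cohort means
    mean_log_offset: float
    converged: bool

    def mean_count(self, x: float) -> float:
        """Fitted mean count at score x, covariates and offset cohort-averaged."""
        return float(
            np.exp(self.mean_covariate_part + self.coefficients["prs"] * x
                   + self.mean_log_offset)
        )


@dataclass
class JointRiskModel:
    beta0: float
    beta: float
    gamma: float
    calibration_residuals: tuple[float, float, float]
    targets: ExternalEstimates
    tdlu_scale: float  # divisor putting counts on beta's unit (SD or 1)

    @property
    def converged(self) -> bool:
        return max(abs(r) for r in self.calibration_residuals) < 1e-6


@dataclass
class MediationResult:
    acme: float
    ade: float
    total_effect: float
    proportion_mediated: float
    pm_percent: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    n_boot_failed: int = 0
    seed: int | None = None
    pm_defined: bool = True


# ---------------------------------------------------------------------------
# mediator model
# ---------------------------------------------------------------------------

def fit_mediator_model(
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "study"),
    score_column: str = "prs_std",
) -> MediatorModel:
    """Robust-Poisson fit of TDLU count on the score with area offset."""
    spec = assoc_mod.RegressionSpec(
        outcome="tdlu_count",
        exposure="prs_continuous",
        covariates=covariates,
        use_offset=True,
        score_column=score_column,
    )
    y, design, offset, _ = assoc_mod.build_design(cohort, spec)
    coef, converged = assoc_mod._fit_poisson(y, design, offset)
    named = dict(zip(design.columns, coef))
    x = design.to_numpy(dtype=float)
    means = x.mean(axis=0)
    prs_ix = list(design.columns).index("prs")
    mean_cov = float(means @ coef - means[prs_ix] * coef[prs_ix])
    return MediatorModel(
        coefficients=named,
        offset_used=True,
        mean_covariate_part=mean_cov,
        mean_log_offset=float(np.mean(offset)),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# induced marginals and calibration
# ---------------------------------------------------------------------------

def _fractional_logistic_fit(p: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """MLE (intercept, slope) of the expected-outcome logistic fit of p on v.

    Maximizes sum_i [p_i log q_i + (1-p_i) log(1-q_i)] with
    q_i = expit(a + b v_i) by Newton iterations with step halving.
    """
    x = np.column_stack([np.ones_like(v), v])
    n = x.shape[0]
    pbar = float(np.clip(p.mean(), 1e-12, 1 - 1e-12))
    theta = np.array([logit(pbar), 0.0])
    gtol = 1e-10 * max(n, 10)

    def negll(t):
        q = np.clip(expit(np.clip(x @ t, -35, 35)), 1e-15, 1 - 1e-15)
        return -float(p @ np.log(q) + (1 - p) @ np.log1p(-q))

    f = negll(theta)
    for _ in range(200):
        q = expit(np.clip(x @ theta, -35, 35))
        grad = x.T @ (p - q)
        if np.max(np.abs(grad)) < gtol:
            return float(theta[0]), float(theta[1])
        w = np.maximum(q * (1 - q), 1e-12)
        hess = x.T @ (w[:, None] * x)
        ridge = 0.0
        for _ in range(10):
            try:
                step = np.linalg.solve(hess + ridge * np.eye(2), grad)
                if np.all(np.isfinite(step)):
                    break
            except np.linalg.LinAlgError:
                pass
            ridge = max(ridge * 10, 1e-8 * np.trace(hess))
        else:
            raise RuntimeError("singular Hessian in marginal logistic fit")
        # damped Newton: halve until the objective does not materially worsen
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            fc = negll(cand)
            if fc <= f + 1e-10 * (1.0 + abs(f)):
                theta, f = cand, fc
                break
            scale /= 2.0
        else:  # no productive step; fall through to the final gradient check
            break
    q = expit(np.clip(x @ theta, -35, 35))
    if np.max(np.abs(x.T @ (p - q))) > 1e-6 * max(n, 10):
        raise RuntimeError("marginal logistic fit did not converge (separation?)")
    return float(theta[0]), float(theta[1])


def _joint_probabilities(
    beta0: float, beta: float, gamma: float,
    m_scaled: np.ndarray, prs: np.ndarray,
) -> np.ndarray:
    return expit(beta0 + beta * m_scaled + gamma * prs)


def induced_marginal_slope(
    model: JointRiskModel, cohort: pd.DataFrame, variable: str,
    score_column: str = "prs_std",
) -> float:
    """Single-variable log-odds slope induced by the joint model.

    Evaluates the joint risk for every cohort member, then fits the
    fractional-outcome logistic of those risks on the named variable — a
    deterministic functional of the model and the empirical joint
    distribution of (score, TDLU count).
    """
    if not all(np.isfinite([model.beta0, model.beta, model.gamma])):
        raise ValueError("joint model parameters must be finite")
    prs = cohort[score_column].to_numpy(dtype=float)
    m = cohort["tdlu_count"].to_numpy(dtype=float) / model.tdlu_scale
    p = _joint_probabilities(model.beta0, model.beta, model.gamma, m, prs)
    v = {"prs": prs, "tdlu": m}[variable]
    _, slope = _fractional_logistic_fit(p, v)
    return slope


def _tdlu_scale(cohort: pd.DataFrame, unit: str) -> float:
    if unit == "per_count":
        return 1.0
    sd = float(cohort["tdlu_count"].to_numpy(dtype=float).std(ddof=1))
    if sd == 0:
        raise ValueError("TDLU counts are constant; per-SD unit undefined")
    return sd


def calibrate_joint_model(
    externals: ExternalEstimates,
    cohort: pd.DataFrame,
    score_column: str = "prs_std",
) -> JointRiskModel:
    """Solve (beta0, beta, gamma) so the induced marginals hit the targets.

    Three constraints: induced score slope = log OR_PRS-BC, induced TDLU
    slope = log OR_TDLU-BC (on the declared unit), mean risk = prevalence.
    Residuals are kept on a common log-odds scale (the prevalence constraint
    via logit of the mean risk). Root-finding starts from the direct plug-in
    (logit prevalence, log OR, log OR).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    prs = cohort[score_column].to_numpy(dtype=float)
    scale = _tdlu_scale(cohort, externals.tdlu_or_unit)
    m = cohort["tdlu_count"].to_numpy(dtype=float) / scale
    t_prs = float(np.log(externals.or_prs_bc_per_sd))
    t_tdlu = float(np.log(externals.or_tdlu_bc))
    t_prev = float(logit(externals.prevalence))

    def residuals(theta):
        b0, b, g = theta
        p = _joint_probabilities(b0, b, g, m, prs)
        _, s_prs = _fractional_logistic_fit(p, prs)
        _, s_tdlu = _fractional_logistic_fit(p, m)
        return [
            s_prs - t_prs,
            s_tdlu - t_tdlu,
            float(logit(np.clip(p.mean(), 1e-12, 1 - 1e-12))) - t_prev,
        ]

    x0 = np.array([t_prev, t_tdlu, t_prs])
    try:
        sol = optimize.root(residuals, x0, method="hybr", tol=1e-13)
        res = residuals(sol.x)
    except RuntimeError as exc:
        raise RuntimeError(
            f"joint-model calibration failed for targets {externals}: {exc}"
        ) from exc
    if max(abs(r) for r in res) > 1e-8:
        raise RuntimeError(
            "joint-model calibration failed: residuals "
            f"{res} for targets {externals} (targets may be infeasible "
            "given the prevalence and the cohort's joint distribution)"
        )
    return JointRiskModel(
        beta0=float(sol.x[0]),
        beta=float(sol.x[1]),
        gamma=float(sol.x[2]),
        calibration_residuals=tuple(float(r) for r in res),
        targets=externals,
        tdlu_scale=scale,
    )


# ---------------------------------------------------------------------------
# mediation effects
# ---------------------------------------------------------------------------

_TAIL_MASS = 1e-10


def _mediator_pmf(mean: float) -> tuple[np.ndarray, np.ndarray]:
    """Poisson pmf over a support truncated where the upper tail < 1e-10."""
    k_max = int(stats.poisson.ppf(1.0 - _TAIL_MASS, mean)) + 2
    k = np.arange(k_max + 1)
    return k, stats.poisson.pmf(k, mean)


def estimate_mediation(
    joint: JointRiskModel,
    mediator: MediatorModel,
    cohort: pd.DataFrame | None = None,
    contrast: tuple[float, float] = (-0.5, 0.5),
    mediator_pmf=None,
) -> MediationResult:
    """Averaged counterfactual decomposition over the fitted mediator law.

    The counterfactual mediator distribution f(M | x) is the fitted Poisson
    count distribution at the cohort-average offset with covariates at their
    cohort means; outcome probabilities come from the joint logistic model.
    Expectations are exact sums over the truncated support. The default
    contrast (−0.5, +0.5) is a centered one-SD change in the score.
    ``mediator_pmf``, mapping a score value to a (support, weights) pair,
    overrides the Poisson law (used for discrete-mediator checks).
    """
    x0, x1 = contrast
    law = mediator_pmf or (lambda x: _mediator_pmf(mediator.mean_count(x)))
    pmf = {x: law(x) for x in (x0, x1)}

    def e_p(m_at: float, x_at: float) -> float:
        k, w = pmf[m_at]
        p = _joint_probabilities(
            joint.beta0, joint.beta, joint.gamma, k / joint.tdlu_scale,
            np.full_like(k, x_at, dtype=float),
        )
        return float(w @ p)

    acme = 0.5 * ((e_p(x1, x1) - e_p(x0, x1)) + (e_p(x1, x0) - e_p(x0, x0)))
    ade = 0.5 * ((e_p(x0, x1) - e_p(x0, x0)) + (e_p(x1, x1) - e_p(x1, x0)))
    te = e_p(x1, x1) - e_p(x0, x0)
    defined = abs(te) >= 1e-12
    pm = acme / te if defined else float("nan")
    if not defined:
        logger.warning("total effect below 1e-12; proportion mediated undefined")
    return MediationResult(
        acme=acme,
        ade=ade,
        total_effect=te,
        proportion_mediated=pm,
        pm_percent=100.0 * pm,
        pm_defined=defined,
    )


def estimate_pm_percent(
    cohort: pd.DataFrame,
    externals: ExternalEstimates,
    covariates: tuple[str, ...] = ("age", "study"),
    score_column: str = "prs_std",
    contrast: tuple[float, float] = (-0.5, 0.5),
) -> MediationResult:
    """Full single-pass estimate: mediator fit → calibration → decomposition."""
    mediator = fit_mediator_model(cohort, covariates, score_column)
    joint = calibrate_joint_model(externals, cohort, score_column)
    return estimate_mediation(joint, mediator, cohort, contrast)


def bootstrap_proportion_ci(
    cohort: pd.DataFrame,
    externals: ExternalEstimates,
    n_boot: int = 10_000,
    seed: int = 0,
    covariates: tuple[str, ...] = ("age", "study"),
    score_column: str = "prs_std",
    contrast: tuple[float, float] = (-0.5, 0.5),
) -> MediationResult:
    """Percentile bootstrap CI for the percent mediated.

    Cohort rows are resampled with replacement; the mediator model is refit
    and the joint model recalibrated per resample with the external
    estimates held fixed. Resamples failing calibration are dropped and
    counted; more than 1% failures is an error.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    point = estimate_pm_percent(cohort, externals, covariates, score_column, contrast)
    rng = np.random.default_rng(seed)
    n = len(cohort)
    values, failed = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        boot = cohort.iloc[idx].reset_index(drop=True)
        try:
            res = estimate_pm_percent(boot, externals, covariates, score_column,
                                      contrast)
            if not res.pm_defined:
                raise RuntimeError("undefined proportion in resample")
            values.append(res.pm_percent)
        except Exception:
            failed += 1
    if failed > 0.01 * n_boot:
        raise RuntimeError(
            f"{failed}/{n_boot} bootstrap resamples failed calibration"
        )
    lo, hi = np.percentile(values, [2.5, 97.5])
    return replace(
        point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        n_boot_failed=failed,
        seed=seed,
    )


def mediation_grid(
    cohort: pd.DataFrame,
    grid: list[ExternalEstimates] | None = None,
    n_boot: int | None = None,
    seed: int = 0,
    covariates: tuple[str, ...] = ("age", "study"),
) -> pd.DataFrame:
    """Percent-mediated report: rows = score labels, one row per grid cell.

    With ``n_boot`` set, each cell carries a bootstrap CI; cells that fail
    are reported with their error and do not abort the rest.
    """
    if grid is None:
        grid = [
            ExternalEstimates(
                or_prs_bc_per_sd=DEFAULT_OR_PRS_BC[label],
                or_tdlu_bc=ort,
                score_label=label,
            )
            for label in DEFAULT_OR_PRS_BC
            for ort in DEFAULT_OR_TDLU_GRID
        ]
    if not grid:
        raise ValueError("grid must be nonempty")
    rows = []
    for cell, ext in enumerate(grid):
        base = {
            "score": ext.score_label,
            "or_prs_bc": ext.or_prs_bc_per_sd,
            "or_tdlu_bc": ext.or_tdlu_bc,
            "prevalence": ext.prevalence,
        }
        try:
            score_column = assoc_mod.SCORE_COLUMNS[ext.score_label]
            if n_boot:
                res = bootstrap_proportion_ci(
                    cohort, ext, n_boot=n_boot, seed=seed + cell,
                    covariates=covariates, score_column=score_column,
                )
            else:
                res = estimate_pm_percent(
                    cohort, ext, covariates=covariates, score_column=score_column
                )
            rows.append({
                **base,
                "pm_percent": res.pm_percent,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "acme": res.acme,
                "ade": res.ade,
                "total_effect": res.total_effect,
                "n_boot_failed": res.n_boot_failed,
            })
        except Exception as exc:
            logger.error("mediation cell %s failed: %s", base, exc)
            rows.append({**base, "error": str(exc)})
    return pd.DataFrame(rows)
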