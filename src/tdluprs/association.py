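"""Association models between the polygenic score and involution measures.

The primary model is Poisson regression with a log link, a log tissue-area
offset (turning counts into rates per unit area) and a robust sandwich
variance, reported as relative risks per SD of the score and across score
quartiles with a Wald trend test. Acini-per-TDLU outcomes are non-integer
medians and enter the same score equations (quasi-likelihood reading), by
default without an offset and excluding women with no observed TDLUs.
Coefficients come from the standard IRLS fit (statsmodels GLM); the
sandwich covariance is assembled explicitly here so it can be verified
against brute-force oracles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import prs as prs_mod

logger = logging.getLogger("tdluprs.association")

OUTCOMES = ("tdlu_count", "acini_per_tdlu")
Z95 = 1.959963984540054  # two-sided 95% normal quantile

#: per-SD gap between top- and bottom-quartile means of a standard normal
QUARTILE_GAP = float(2.0 * stats.norm.pdf(stats.norm.ppf(0.75)) / 0.25)


@dataclass
class RegressionSpec:
    """Declarative description of one model fit."""

    outcome: str = "tdlu_count"
    exposure: str = "prs_continuous"  # prs_continuous | prs_quartiles | single_variant_dosage
    covariates: tuple[str, ...] = ("age", "study")
    use_offset: bool = True
    robust: bool = True
    score_column: str = "prs_std"
    include_zero_tdlu_acini: bool = False

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if len(set(self.covariates)) != len(self.covariates):
            raise ValueError("covariates must be duplicate-free")
        if self.use_offset and self.outcome != "tdlu_count":
            raise ValueError("offset is only used for the tdlu_count outcome")


@dataclass
class AssociationResult:
    term_labels: list[str]
    rr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_value: np.ndarray
    n_used: int
    converged: bool
    coef: np.ndarray = field(default=None, repr=False)
    se: np.ndarray = field(default=None, repr=False)
    trend_p: float | None = None

    def term(self, label: str) -> dict:
        i = self.term_labels.index(label)
        return {
            "rr": float(self.rr[i]),
            "ci_low": float(self.ci_low[i]),
            "ci_high": float(self.ci_high[i]),
            "p": float(self.p_value[i]),
            "coef": float(self.coef[i]),
            "se": float(self.se[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.term_labels,
                "rr": self.rr,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_value": self.p_value,
            }
        )


def implied_quartile_rr(rr_per_sd: float) -> float:
    """Top- vs bottom-quartile RR implied by a per-SD RR under a normal score.

    For a standard-normal exposure with log-linear effect b per SD, the gap
    between quartile means is 2·φ(z₀.₇₅)/0.25 ≈ 2.5416 SD, so the implied
    contrast is exp(b × 2.5416).
    """
    return float(np.exp(np.log(rr_per_sd) * QUARTILE_GAP))


# ---------------------------------------------------------------------------
# design assembly
# ---------------------------------------------------------------------------

def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # columns with a negligible QR diagonal are the collinear ones
        _, rmat = np.linalg.qr(x)
        diag = np.abs(np.diag(rmat))
        tol = diag.max() * max(x.shape) * np.finfo(float).eps
        bad = [design.columns[i] for i in range(len(diag)) if diag[i] <= tol]
        raise np.linalg.LinAlgError(
            f"design matrix rank {rank} < {x.shape[1]}; "
            f"collinear column(s): {bad or list(design.columns)}"
        )


def build_design(
    cohort: pd.DataFrame,
    spec: RegressionSpec,
    exposure_values: np.ndarray | None = None,
) -> tuple[pd.Series, pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Assemble (outcome, design, offset, rows-used view) for one fit."""
    df = cohort.copy()
    if spec.outcome == "acini_per_tdlu":
        col = "acini_per_tdlu_incl_zero" if spec.include_zero_tdlu_acini else "acini_per_tdlu"
        if col not in df.columns:
            raise KeyError(f"cohort lacks required column {col!r}")
        df = df[df[col].notna()]
        y = df[col]
    else:
        y = df["tdlu_count"]
    if (y < 0).any():
        raise ValueError("outcome must be nonnegative")

    design = pd.DataFrame(index=df.index)
    design["intercept"] = 1.0
    if spec.exposure == "prs_continuous":
        design["prs"] = df[spec.score_column].to_numpy()
    elif spec.exposure == "prs_quartiles":
        quart = prs_mod.assign_quartiles(df[spec.score_column].to_numpy())
        for qq in ("Q2", "Q3", "Q4"):
            design[qq] = (quart == qq).astype(float)
        counts = pd.Series(quart).value_counts()
        if any(counts.get(qq, 0) == 0 for qq in ("Q1", "Q2", "Q3", "Q4")):
            raise ValueError(f"empty quartile category: counts {dict(counts)}")
    elif spec.exposure == "single_variant_dosage":
        if exposure_values is None:
            raise ValueError("single_variant_dosage requires exposure_values")
        design["dosage"] = np.asarray(exposure_values, dtype=float)[df.index]
    elif spec.exposure == "quartile_trend":
        quart = prs_mod.assign_quartiles(df[spec.score_column].to_numpy())
        design["trend"] = np.char.strip(quart.astype(str), "Q").astype(float) - 1.0
    else:
        raise ValueError(f"unknown exposure {spec.exposure!r}")

    for cov in spec.covariates:
        if cov == "age":
            design["age"] = df["age_years"].to_numpy()
        elif cov == "study":
            design["study_STAMP"] = (df["study"] == "STAMP").astype(float)
        elif cov in ("family_history", "fibroglandular_proportion", "parous",
                     "menopausal"):
            if cov not in df.columns:
                raise KeyError(f"cohort lacks covariate column {cov!r}")
            design[cov] = df[cov].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown covariate {cov!r}")

    if spec.use_offset:
        area = df["tissue_area_mm2"].to_numpy(dtype=float)
        if (area <= 0).any():
            raise ValueError("tissue areas must be strictly positive for the offset")
        offset = np.log(area)
    else:
        offset = np.zeros(len(df))

    keep = design.notna().all(axis=1) & y.notna()
    design, y, offset = design[keep.to_numpy()], y[keep.to_numpy()], offset[keep.to_numpy()]
    _check_full_rank(design)
    return y, design, offset, df.loc[keep[keep].index]


# ---------------------------------------------------------------------------
# sandwich covariance
# ---------------------------------------------------------------------------

def sandwich_covariance(
    design: np.ndarray,
    outcome: np.ndarray,
    offset: np.ndarray,
    fitted_coefficients: np.ndarray,
) -> np.ndarray:
    """HC0 sandwich for a log-link Poisson/quasi-Poisson fit.

    bread = (Xᵀ diag(μ) X)⁻¹ with μ the fitted means (expected information,
    which equals the observed information under the canonical log link);
    meat = Xᵀ diag((y−μ)²) X, the outer product of per-observation scores.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    mu = np.exp(x @ np.asarray(fitted_coefficients, dtype=float) + np.asarray(offset))
    info = x.T @ (mu[:, None] * x)
    try:
        bread = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular information (bread) matrix: {exc}")
    resid = y - mu
    meat = x.T @ ((resid**2)[:, None] * x)
    cov = bread @ meat @ bread
    return (cov + cov.T) / 2.0


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

_MAXITER = 200


def _fit_poisson(y, x, offset):
    """Quasi-Poisson IRLS via statsmodels; returns (coef, converged)."""
    model = sm.GLM(
        np.asarray(y, dtype=float),
        np.asarray(x, dtype=float),
        family=sm.families.Poisson(),
        offset=np.asarray(offset, dtype=float),
    )
    res = model.fit(maxiter=_MAXITER, tol=1e-10)
    converged = bool(getattr(res, "converged", True))
    if not converged:
        logger.warning("Poisson fit did not converge in %d iterations", _MAXITER)
    return np.asarray(res.params, dtype=float), converged


def fit_poisson_robust(
    cohort: pd.DataFrame,
    spec: RegressionSpec,
    exposure_values: np.ndarray | None = None,
) -> AssociationResult:
    """Poisson/quasi-Poisson fit with HC0 sandwich CIs, reported as RRs."""
    y, design, offset, _ = build_design(cohort, spec, exposure_values)
    coef, converged = _fit_poisson(y, design, offset)
    if spec.robust:
        cov = sandwich_covariance(design.to_numpy(), y.to_numpy(), offset, coef)
    else:
        x = design.to_numpy(dtype=float)
        mu = np.exp(x @ coef + offset)
        cov = np.linalg.inv(x.T @ (mu[:, None] * x))
    se = np.sqrt(np.diag(cov))
    z = coef / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return AssociationResult(
        term_labels=list(design.columns),
        rr=np.exp(coef),
        ci_low=np.exp(coef - Z95 * se),
        ci_high=np.exp(coef + Z95 * se),
        p_value=p,
        n_used=len(y),
        converged=converged,
        coef=coef,
        se=se,
    )


def wald_trend_test(cohort: pd.DataFrame, spec: RegressionSpec) -> float:
    """Robust Wald p for a linear trend across quartiles scored 0,1,2,3."""
    if spec.exposure != "prs_quartiles":
        raise ValueError("trend test applies to quartile exposures")
    trend_spec = RegressionSpec(
        outcome=spec.outcome,
        exposure="quartile_trend",
        covariates=spec.covariates,
        use_offset=spec.use_offset,
        robust=spec.robust,
        score_column=spec.score_column,
        include_zero_tdlu_acini=spec.include_zero_tdlu_acini,
    )
    res = fit_poisson_robust(cohort, trend_spec)
    return res.term("trend")["p"]


def per_allele_scan(
    cohort: pd.DataFrame,
    dosages: pd.DataFrame,
    spec: RegressionSpec | None = None,
) -> pd.DataFrame:
    """One robust-Poisson fit per variant, dosage as exposure.

    Raw two-sided p values, no multiplicity adjustment; monomorphic variants
    are skipped with a logged count.
    """
    if len(dosages) != len(cohort):
        raise ValueError("dosage rows must align with cohort rows")
    if spec is None:
        spec = RegressionSpec()
    rows, skipped = [], 0
    for vid in dosages.columns:
        d = dosages[vid].to_numpy(dtype=float)
        if np.nanstd(d) == 0:
            skipped += 1
            continue
        vspec = RegressionSpec(
            outcome=spec.outcome,
            exposure="single_variant_dosage",
            covariates=spec.covariates,
            use_offset=spec.use_offset,
            robust=spec.robust,
        )
        res = fit_poisson_robust(cohort, vspec, exposure_values=d)
        t = res.term("dosage")
        rows.append(
            {
                "variant_id": vid,
                "rr": t["rr"],
                "ci_low": t["ci_low"],
                "ci_high": t["ci_high"],
                "p_value": t["p"],
                "n_used": res.n_used,
                "converged": res.converged,
            }
        )
    if skipped:
        logger.info("per-allele scan skipped %d monomorphic variant(s)", skipped)
    out = pd.DataFrame(rows)
    out.attrs["n_skipped_monomorphic"] = skipped
    return out


def fit_linear_sensitivity(
    cohort: pd.DataFrame, spec: RegressionSpec
) -> AssociationResult:
    """OLS on the outcome rate with heteroskedasticity-consistent (HC0) SEs.

    A check that the direction of association does not hinge on the Poisson
    mean-variance assumption. When an offset is requested the outcome is the
    rate count/area (per mm²); slopes are reported on the identity scale so
    ``rr`` here holds the raw slope, not an exponentiated one.
    """
    y, design, offset, _ = build_design(cohort, spec)
    yy = y.to_numpy(dtype=float)
    if spec.use_offset:
        yy = yy / np.exp(offset)
    res = sm.OLS(yy, design.to_numpy(dtype=float)).fit(cov_type="HC0")
    coef = np.asarray(res.params)
    se = np.asarray(res.bse)
    p = 2.0 * stats.norm.sf(np.abs(coef / se))
    return AssociationResult(
        term_labels=list(design.columns),
        rr=coef,
        ci_low=coef - Z95 * se,
        ci_high=coef + Z95 * se,
        p_value=p,
        n_used=len(yy),
        converged=True,
        coef=coef,
        se=se,
    )


SCORE_COLUMNS = {
    "overall": "prs_std",
    "ER_positive": "prs_er_pos_std",
    "ER_negative": "prs_er_neg_std",
}


def run_association_suite(
    cohort: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "study"),
) -> pd.DataFrame:
    """Assemble the full score × outcome report (continuous, quartiles, trend).

    One row per reported cell; the Q1 reference row carries RR 1.00 with no
    CI. Per-cell failures are logged and isolated.
    """
    rows = []
    for label, score_col in SCORE_COLUMNS.items():
        if score_col not in cohort.columns:
            continue
        for outcome in OUTCOMES:
            use_offset = outcome == "tdlu_count"
            base = dict(score=label, outcome=outcome)
            try:
                spec = RegressionSpec(
                    outcome=outcome, exposure="prs_continuous",
                    covariates=covariates, use_offset=use_offset,
                    score_column=score_col,
                )
                res = fit_poisson_robust(cohort, spec)
                t = res.term("prs")
                rows.append({**base, "term": "continuous", "rr": t["rr"],
                             "ci_low": t["ci_low"], "ci_high": t["ci_high"],
                             "p_value": t["p"], "n_used": res.n_used})
            except Exception as exc:  # isolate per-cell failures
                logger.error("continuous fit failed (%s, %s): %s", label, outcome, exc)
                rows.append({**base, "term": "continuous", "error": str(exc)})
                continue
            try:
                qspec = RegressionSpec(
                    outcome=outcome, exposure="prs_quartiles",
                    covariates=covariates, use_offset=use_offset,
                    score_column=score_col,
                )
                qres = fit_poisson_robust(cohort, qspec)
                rows.append({**base, "term": "Q1", "rr": 1.0, "ci_low": np.nan,
                             "ci_high": np.nan, "p_value": np.nan,
                             "n_used": qres.n_used})
                for qq in ("Q2", "Q3", "Q4"):
                    t = qres.term(qq)
                    rows.append({**base, "term": qq, "rr": t["rr"],
                                 "ci_low": t["ci_low"], "ci_high": t["ci_high"],
                                 "p_value": t["p"], "n_used": qres.n_used})
                trend_p = wald_trend_test(cohort, qspec)
                rows.append({**base, "term": "trend", "rr": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan,
                             "p_value": trend_p, "n_used": qres.n_used})
            except Exception as exc:
                logger.error("quartile fit failed (%s, %s): %s", label, outcome, exc)
                rows.append({**base, "term": "quartiles", "error": str(exc)})
    return pd.DataFrame(rows)
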