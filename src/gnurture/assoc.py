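"""Family-clustered association models for PGS-T / PGS-NT effects.

Continuous outcomes are fitted with a linear mixed model (REML, Gaussian
family random intercept, via statsmodels MixedLM); binary outcomes with a
random-intercept logistic model estimated by Gauss-Hermite quadrature.
Both PGS-T and PGS-NT enter jointly by default (a separate-fits mode is
available), with standardized age at first assessment, sex and genotyping
array as covariates.  Parent-of-origin models fit each parent's
transmitted and non-transmitted haplotype scores in the subsample with
that parent genotyped.  Wald tests and normal-approximation confidence
intervals throughout; multiple testing handled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from gnurture.glmm import fit_logistic_gh

DEFAULT_COVARIATES = ("age_z", "sex_code", "array_code")
Z975 = 1.959963984540054


@dataclass
class ModelResult:
    """One predictor's estimate from one fitted model."""

    outcome: str
    predictor: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    outcome_type: str  # 'binary' or 'continuous'
    model: str  # 'mixed_logistic', 'mixed_linear', 'glm_fallback', 'ols_fallback'
    converged: bool
    re_var: float
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    q: float | None = None


def results_to_frame(results: list[ModelResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def _complete_case(
    data: pd.DataFrame, outcome: str, predictors: list[str], covariates: list[str]
) -> pd.DataFrame:
    cols = [outcome, *predictors, *covariates, "family_id"]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns in model data: {missing}")
    return data[cols].dropna()


def _wald(est: float, se: float) -> tuple[float, float, float]:
    if se == 0 or not np.isfinite(se):
        return np.nan, est, est
    p = 2.0 * stats.norm.sf(abs(est / se))
    return p, est - Z975 * se, est + Z975 * se


def fit_mixed_linear(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    covariates: list[str] = list(DEFAULT_COVARIATES),
) -> list[ModelResult]:
    """REML linear mixed model with a family random intercept.

    Returns one ModelResult per predictor.  A singular random intercept
    triggers an OLS refit flagged in the ``model`` field; non-convergence
    is flagged, never raised.
    """
    df = _complete_case(data, outcome, predictors, covariates)
    if df["family_id"].nunique() < 2:
        raise ValueError("need at least 2 families")
    exog_cols = [*predictors, *covariates]
    X = sm.add_constant(df[exog_cols].to_numpy(dtype=float), has_constant="add")
    names = ["const", *exog_cols]
    y = df[outcome].to_numpy(dtype=float)
    groups = df["family_id"].to_numpy()

    converged = True
    model_name = "mixed_linear"
    re_var = np.nan
    singletons_only = pd.Series(groups).value_counts().max() == 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if singletons_only:
                # no within-family replication: the intercept variance is not
                # identified and the mixed model degenerates to OLS
                raise ValueError("all families are singletons")
            fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
            converged = bool(fit.converged)
            re_var = float(np.asarray(fit.cov_re)[0, 0])
            params = np.asarray(fit.fe_params)
            bse = np.asarray(fit.bse_fe)
            if not np.isfinite(bse).all() or re_var < 1e-10:
                raise ValueError("singular random intercept")
        except Exception:
            ols = sm.OLS(y, X).fit()
            params, bse = np.asarray(ols.params), np.asarray(ols.bse)
            model_name, re_var = "ols_fallback", 0.0

    out = []
    for pred in predictors:
        i = names.index(pred)
        p, lo, hi = _wald(params[i], bse[i])
        out.append(
            ModelResult(
                outcome=outcome,
                predictor=pred,
                estimate=float(params[i]),
                se=float(bse[i]),
                ci_low=lo,
                ci_high=hi,
                p=p,
                n=len(df),
                outcome_type="continuous",
                model=model_name,
                converged=converged,
                re_var=re_var,
            )
        )
    return out


def fit_mixed_logistic(
    data: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    covariates: list[str] = list(DEFAULT_COVARIATES),
    n_nodes: int = 25,
) -> list[ModelResult]:
    """Random-intercept logistic model; odds ratios per SD of PGS-T.

    Separation and non-convergence are flagged on the result, not raised;
    a singular random intercept reports the plain logistic fit.
    """
    df = _complete_case(data, outcome, predictors, covariates)
    y = df[outcome].to_numpy(dtype=float)
    if not np.isin(y, [0.0, 1.0]).all():
        raise ValueError("binary outcome must be coded 0 (control) or 1 (case)")
    exog_cols = [*predictors, *covariates]
    X = sm.add_constant(df[exog_cols].to_numpy(dtype=float), has_constant="add")
    names = ["const", *exog_cols]
    groups = df["family_id"].to_numpy()
    if pd.Series(groups).value_counts().max() == 1:
        # intercept variance not identified without within-family replication
        groups = np.arange(len(df))  # keeps the GH path well-defined if used
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        from gnurture.glmm import GHLogitFit

        fit = GHLogitFit(
            params=np.asarray(glm.params),
            bse=np.asarray(glm.bse),
            re_var=0.0,
            llf=float(glm.llf),
            converged=bool(glm.converged),
            singular=True,
            separation=bool(np.abs(glm.params).max() > 30),
        )
    else:
        fit = fit_logistic_gh(y, X, groups, n_nodes=n_nodes)
    model_name = "glm_fallback" if fit.singular else "mixed_logistic"

    out = []
    for pred in predictors:
        i = names.index(pred)
        est, se = float(fit.params[i]), float(fit.bse[i])
        p, lo, hi = _wald(est, se)
        out.append(
            ModelResult(
                outcome=outcome,
                predictor=pred,
                estimate=est,
                se=se,
                ci_low=lo,
                ci_high=hi,
                p=p,
                n=len(df),
                outcome_type="binary",
                model=model_name,
                converged=fit.converged and not fit.separation,
                re_var=fit.re_var,
                odds_ratio=float(np.exp(est)),
                or_ci_low=float(np.exp(lo)),
                or_ci_high=float(np.exp(hi)),
            )
        )
    return out


def fit_outcome(
    data: pd.DataFrame,
    outcome: str,
    outcome_type: str,
    predictors: list[str],
    covariates: list[str] = list(DEFAULT_COVARIATES),
    joint: bool = True,
) -> list[ModelResult]:
    """Fit one outcome, either with all predictors jointly or one at a time."""
    fitter = fit_mixed_logistic if outcome_type == "binary" else fit_mixed_linear
    if joint:
        return fitter(data, outcome, predictors, covariates)
    out: list[ModelResult] = []
    for pred in predictors:
        out.extend(fitter(data, outcome, [pred], covariates))
    return out


def parent_of_origin_fit(
    data: pd.DataFrame,
    outcome: str,
    outcome_type: str,
    side: str,
    covariates: list[str] = list(DEFAULT_COVARIATES),
) -> list[ModelResult]:
    """Maternal or paternal model with that parent's haplotype scores.

    ``side`` is 'mat' or 'pat'; rows are restricted to offspring with the
    relevant parent genotyped (pairs missing that parent are excluded, so
    maternal and paternal sample sizes differ).
    """
    if side not in ("mat", "pat"):
        raise ValueError("side must be 'mat' or 'pat'")
    keep_designs = {"trio", "mother_pair"} if side == "mat" else {"trio", "father_pair"}
    sub = data[data["design"].isin(keep_designs)]
    if sub.empty:
        label = "mothers" if side == "mat" else "fathers"
        raise ValueError(f"no offspring with genotyped {label}; cannot fit the {side} model")
    predictors = [f"z_s_t_{side}", f"z_s_nt_{side}"]
    return fit_outcome(sub, outcome, outcome_type, predictors, covariates)


def spousal_correlation(
    father_pgs: np.ndarray, mother_pgs: np.ndarray
) -> tuple[float, tuple[float, float]]:
    """Pearson correlation of spousal diploid PGSs with a Fisher-z 95% CI."""
    f = np.asarray(father_pgs, dtype=float)
    m = np.asarray(mother_pgs, dtype=float)
    ok = ~(np.isnan(f) | np.isnan(m))
    f, m = f[ok], m[ok]
    n = f.size
    if n < 3:
        raise ValueError("need at least 3 complete couples")
    if f.std() == 0 or m.std() == 0:
        raise ValueError("constant score vector")
    r = float(np.corrcoef(f, m)[0, 1])
    z = np.arctanh(np.clip(r, -0.999999, 0.999999))
    half = Z975 / np.sqrt(n - 3)
    return r, (float(np.tanh(z - half)), float(np.tanh(z + half)))


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(
    results: pd.DataFrame, family_mask: pd.Series | None = None
) -> pd.DataFrame:
    """Attach q-values over one FDR family (default: all PGS-NT tests).

    The family pools every row whose predictor is a non-transmitted score
    (``z_pgs_nt`` or a parent-of-origin ``z_s_nt_*``) across outcomes and
    waves; pass a boolean mask to redefine it.
    """
    out = results.copy()
    if family_mask is None:
        family_mask = out["predictor"].str.contains("nt")
    out["q"] = np.nan
    idx = out.index[family_mask]
    if len(idx):
        out.loc[idx, "q"] = fdr_adjust(out.loc[idx, "p"].to_numpy())
    return out
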