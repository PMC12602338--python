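"""Outcome construction from per-wave phenotype tables.

Scoring rules for depression/anxiety outcomes measured repeatedly:
lifetime case aggregation (case at any observed wave), cross-wave symptom
averaging, neuroticism facet scoring with within-person facet-mean item
imputation, a negative-affect sum score with listwise missingness, and
Cronbach's alpha for internal reliability.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gnurture.phenosim import N_ITEMS_PER_FACET, NEUROTICISM_FACETS

#: Facets entering the default neuroticism total: the depression and
#: anxiety facets are excluded so the trait measure is not contaminated by
#: the disorders it is modelled against.
DEFAULT_FACETS_4 = ("anger", "self_consciousness", "impulsiveness", "vulnerability")


def aggregate_lifetime_case(flags: pd.DataFrame) -> pd.Series:
    """Lifetime case status from per-wave binary flags.

    1 if the individual met criteria at any observed wave, 0 if observed
    at least once and never a case, NaN if never observed.
    """
    vals = flags.to_numpy(dtype=float)
    any_case = np.nanmax(np.where(np.isnan(vals), -np.inf, vals), axis=1) >= 1
    any_obs = (~np.isnan(vals)).any(axis=1)
    out = np.where(any_case, 1.0, np.where(any_obs, 0.0, np.nan))
    return pd.Series(out, index=flags.index)


def average_symptoms(sums: pd.DataFrame) -> pd.Series:
    """Mean symptom sum over observed waves; NaN when none observed."""
    return sums.mean(axis=1, skipna=True)


def score_neuroticism(
    items: pd.DataFrame,
    facets: tuple[str, ...] = DEFAULT_FACETS_4,
) -> tuple[pd.Series, pd.DataFrame]:
    """Neuroticism total and per-facet scores with facet-mean imputation.

    ``items`` holds columns ``neuro_{facet}_{j}`` (j = 1..8, responses
    1-5 or NaN).  Within each facet, a missing item is replaced by that
    individual's mean over the facet's observed items; a facet with no
    observed item is NaN and propagates to the total.  Responses outside
    1-5 raise.
    """
    facet_scores = {}
    for facet in facets:
        cols = [f"neuro_{facet}_{j + 1}" for j in range(N_ITEMS_PER_FACET)]
        missing_cols = [c for c in cols if c not in items.columns]
        if missing_cols:
            raise ValueError(f"missing item columns: {missing_cols}")
        sub = items[cols].astype(float)
        _check_likert(sub)
        row_mean = sub.mean(axis=1, skipna=True)
        imputed = sub.apply(lambda col: col.fillna(row_mean))
        score = imputed.sum(axis=1, min_count=N_ITEMS_PER_FACET)
        facet_scores[facet] = score
    facet_df = pd.DataFrame(facet_scores)
    total = facet_df.sum(axis=1, min_count=len(facets))
    return total, facet_df


def score_negative_affect(items: pd.DataFrame) -> pd.Series:
    """Sum of the 10 negative-affect items (range 10-50); listwise NaN.

    No imputation: any missing item makes the sum missing.
    """
    if items.shape[1] != 10:
        raise ValueError(f"expected 10 items, got {items.shape[1]}")
    sub = items.astype(float)
    _check_likert(sub)
    return sub.sum(axis=1, min_count=10)


def _check_likert(df: pd.DataFrame) -> None:
    vals = df.to_numpy(dtype=float)
    bad = ~np.isnan(vals) & ((vals < 1) | (vals > 5))
    if bad.any():
        raise ValueError("item responses must lie in 1-5 (or be missing)")


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha over complete rows.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row sums),
    with sample (ddof=1) variances.
    """
    X = np.asarray(items, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n, k = X.shape
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    if n < 2:
        raise ValueError("Cronbach's alpha needs at least 2 complete rows")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def standardize(x: pd.Series) -> pd.Series:
    """Z-score a continuous outcome to mean 0, variance 1 over observed rows."""
    mu = x.mean()
    sd = x.std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize a constant outcome")
    return (x - mu) / sd


def build_outcomes(
    pheno: pd.DataFrame,
    outcomes: list[str],
    n_waves: int,
    facets: tuple[str, ...] = DEFAULT_FACETS_4,
) -> pd.DataFrame:
    """Assemble the analysis outcome table from a wide per-wave table.

    Produces lifetime flags per disorder, cross-wave symptom averages,
    the neuroticism total (facet-imputed) and negative-affect sum with
    standardized versions, retains per-wave flags for wave-specific
    models, and carries covariates (standardized age, sex, array) and
    family ID.
    """
    out = pd.DataFrame({"iid": pheno["iid"]})
    for outcome in outcomes:
        cols = [f"{outcome}_w{w + 1}" for w in range(n_waves)]
        out[outcome] = aggregate_lifetime_case(pheno[cols]).to_numpy()
        for c in cols:
            out[c] = pheno[c].to_numpy()
    for name in ("mdd_symptoms", "gad_symptoms"):
        cols = [f"{name}_w{w + 1}" for w in range(n_waves)]
        out[name] = average_symptoms(pheno[cols]).to_numpy()
        for c in cols:
            out[c] = pheno[c].to_numpy()

    neuro_cols = [
        f"neuro_{facet}_{j + 1}" for facet in NEUROTICISM_FACETS for j in range(N_ITEMS_PER_FACET)
    ]
    present = [c for c in neuro_cols if c in pheno.columns]
    total, _ = score_neuroticism(pheno[present], facets=facets)
    out["neuroticism"] = total.to_numpy()
    na_cols = [f"na_{j + 1}" for j in range(10)]
    out["negative_affect"] = score_negative_affect(pheno[na_cols]).to_numpy()

    for cont in ("mdd_symptoms", "gad_symptoms", "neuroticism", "negative_affect"):
        out[f"{cont}_z"] = standardize(out[cont]).to_numpy()

    out["age"] = pheno["age"].to_numpy()
    out["age_z"] = standardize(pheno["age"]).to_numpy()
    out["sex"] = pheno["sex"].to_numpy()
    out["sex_code"] = (pheno["sex"].to_numpy() == "F").astype(float)
    out["array"] = pheno["array"].to_numpy()
    out["array_code"] = (pheno["array"].to_numpy() == "chipB").astype(float)
    out["family_id"] = pheno["family_id"].to_numpy()
    return out
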