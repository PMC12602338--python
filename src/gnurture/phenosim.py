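"""Phenotype generation on top of the simulated cohort's genetic ground truth.

Outcomes follow a liability-threshold construction: a latent liability

    y = beta_T * z(PGS-T) + beta_NT * z(PGS-NT) + family effect + residual

where the true transmitted and non-transmitted parental scores come from
the simulator's TruthRecord (never from inference), both z-scored with the
mean and SD of the true PGS-T.  Binary diagnoses are cases when an
outcome-specific liability exceeds the (1 - prevalence) quantile of its
analytic marginal distribution; symptom counts and item-level scale
responses are monotone discretizations of related liabilities.

What this emulates: family clustering through a shared random intercept,
repeated assessment waves with missingness, item-level scale structure
(six 8-item neuroticism facets, a 10-item negative-affect scale) so the
downstream scoring rules have something real to chew on.  What it does not
emulate: diagnostic-instrument skip logic beyond extra wave-1 symptom
missingness, age/cohort trends (covariates are drawn independently of
genetics), or measurement invariance across waves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from gnurture.famsim import SimConfig, TruthRecord

#: NEO-style neuroticism facets; the default 4-facet total excludes the
#: depression and anxiety facets.
NEUROTICISM_FACETS = (
    "anxiety",
    "anger",
    "depression",
    "self_consciousness",
    "impulsiveness",
    "vulnerability",
)
N_ITEMS_PER_FACET = 8
N_NEGATIVE_AFFECT_ITEMS = 10

#: Per-wave wave-level noise variance added to symptom liabilities, item
#: loading/noise for Likert scales, and item missingness rates.  Fixed
#: generator choices, not user knobs.
_WAVE_NOISE_VAR = 0.25
_ITEM_LOADING = 0.9
_ITEM_NOISE_SD = 1.0
_ITEM_MISSINGNESS = 0.05
_NA_ITEM_MISSINGNESS = 0.02
_WAVE1_EXTRA_SYMPTOM_MISSINGNESS = 0.10
_MDD_SYMPTOM_MEAN, _MDD_SYMPTOM_MAX = 0.7, 9
_GAD_SYMPTOM_MEAN, _GAD_SYMPTOM_MAX = 1.4, 7


def true_scores(truth: TruthRecord, weights_vector: np.ndarray) -> pd.DataFrame:
    """Per-offspring true haplotype scores from the simulator's ground truth.

    ``weights_vector`` is the aligned per-marker weight array (NaN for
    markers without a weight, as returned by
    :func:`gnurture.scores.align_weights`).
    """
    w = np.nan_to_num(np.asarray(weights_vector, dtype=float))
    df = pd.DataFrame(
        {
            "iid": truth.offspring,
            "s_t_pat": truth.t_pat @ w,
            "s_nt_pat": truth.nt_pat @ w,
            "s_t_mat": truth.t_mat @ w,
            "s_nt_mat": truth.nt_mat @ w,
        }
    )
    df["pgs_t"] = df["s_t_pat"] + df["s_t_mat"]
    df["pgs_nt"] = df["s_nt_pat"] + df["s_nt_mat"]
    return df


def _count_from_liability(liab: np.ndarray, sd: float, mean_count: float, max_count: int) -> np.ndarray:
    """Map a Gaussian liability to a right-skewed bounded count.

    Quantile transform through a Poisson(mean_count) distribution truncated
    at max_count: monotone in the liability, with a realistic pile-up at 0.
    """
    u = stats.norm.cdf(liab / sd)
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    counts = stats.poisson.ppf(u, mean_count)
    return np.minimum(counts, max_count).astype(float)


def simulate_phenotypes(
    truth: TruthRecord,
    scores: pd.DataFrame,
    pedigree: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-offspring wide phenotype table; attaches liability truth to ``truth``.

    Columns: per-wave binary diagnosis flags (``{outcome}_w{k}``), per-wave
    symptom sums (``mdd_symptoms_w{k}``, ``gad_symptoms_w{k}``), item-level
    neuroticism (``neuro_{facet}_{j}``) and negative affect (``na_{j}``)
    responses measured at baseline, covariates (age, sex, array) and family
    ID.  The family random intercept is drawn once per family and shared
    across outcomes; residuals are outcome-specific.
    """
    for prev in config.prevalence_per_outcome.values():
        if not 0.0 < prev < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
    n = len(scores)
    if list(scores["iid"]) != list(truth.offspring):
        raise ValueError("scores and truth are not aligned on offspring")

    sd_t = scores["pgs_t"].std(ddof=0)
    if sd_t == 0:
        raise ValueError("true PGS-T has zero variance; cannot standardize")
    mu_t = scores["pgs_t"].mean()
    z_t = ((scores["pgs_t"] - mu_t) / sd_t).to_numpy()
    z_nt = ((scores["pgs_nt"] - mu_t) / sd_t).to_numpy()
    g = config.beta_T * z_t + config.beta_NT * z_nt

    fam_ids = pedigree["family_id"].to_numpy()
    uniq_fams, fam_idx = np.unique(fam_ids, return_inverse=True)
    fam_effect = np.sqrt(config.family_var) * rng.standard_normal(uniq_fams.size)
    fam = fam_effect[fam_idx]

    # analytic marginal liability variance with empirically standardized scores
    rho = float(np.corrcoef(z_t, z_nt)[0, 1]) if n > 1 else 0.0
    v_liab = (
        config.beta_T**2
        + config.beta_NT**2
        + 2.0 * config.beta_T * config.beta_NT * rho
        + config.family_var
        + config.resid_var
    )

    out: dict[str, np.ndarray] = {"iid": np.asarray(truth.offspring, dtype=object)}
    resid_sd = np.sqrt(config.resid_var)

    liab_records = {
        "iid": truth.offspring,
        "z_pgs_t_true": z_t,
        "z_pgs_nt_true": z_nt,
        "direct_term": config.beta_T * z_t,
        "nurture_term": config.beta_NT * z_nt,
        "family_effect": fam,
    }

    wave_observed = rng.random((n, config.n_waves)) >= config.wave_missingness

    for outcome, prev in config.prevalence_per_outcome.items():
        resid = resid_sd * rng.standard_normal(n)
        liab = g + fam + resid
        threshold = np.sqrt(v_liab) * stats.norm.ppf(1.0 - prev)
        case = (liab > threshold).astype(float)
        liab_records[f"liability_{outcome}"] = liab
        for wv in range(config.n_waves):
            col = case.copy()
            col[~wave_observed[:, wv]] = np.nan
            out[f"{outcome}_w{wv + 1}"] = col

    # continuous symptom liabilities share the genetic and family terms
    for name, mean_count, max_count in (
        ("mdd_symptoms", _MDD_SYMPTOM_MEAN, _MDD_SYMPTOM_MAX),
        ("gad_symptoms", _GAD_SYMPTOM_MEAN, _GAD_SYMPTOM_MAX),
    ):
        person = g + fam + resid_sd * rng.standard_normal(n)
        liab_records[f"liability_{name}"] = person
        sd_wave = np.sqrt(v_liab + _WAVE_NOISE_VAR)
        for wv in range(config.n_waves):
            wave_liab = person + np.sqrt(_WAVE_NOISE_VAR) * rng.standard_normal(n)
            col = _count_from_liability(wave_liab, sd_wave, mean_count, max_count)
            miss = ~wave_observed[:, wv]
            if wv == 0:
                miss = miss | (rng.random(n) < _WAVE1_EXTRA_SYMPTOM_MISSINGNESS)
            col[miss] = np.nan
            out[f"{name}_w{wv + 1}"] = col

    # baseline item-level scales
    def likert_items(latent_z: np.ndarray, n_items: int, miss_rate: float, prefix: str) -> None:
        for j in range(n_items):
            raw = 3.0 + _ITEM_LOADING * latent_z + _ITEM_NOISE_SD * rng.standard_normal(n)
            item = np.clip(np.round(raw), 1, 5).astype(float)
            item[rng.random(n) < miss_rate] = np.nan
            out[f"{prefix}{j + 1}"] = item

    neuro_latent = (g + fam + resid_sd * rng.standard_normal(n)) / np.sqrt(v_liab)
    liab_records["liability_neuroticism"] = neuro_latent
    for facet in NEUROTICISM_FACETS:
        # facet-specific wobble around the shared neuroticism latent
        facet_z = 0.9 * neuro_latent + 0.45 * rng.standard_normal(n)
        likert_items(facet_z, N_ITEMS_PER_FACET, _ITEM_MISSINGNESS, f"neuro_{facet}_")

    na_latent = (g + fam + resid_sd * rng.standard_normal(n)) / np.sqrt(v_liab)
    liab_records["liability_negative_affect"] = na_latent
    likert_items(na_latent, N_NEGATIVE_AFFECT_ITEMS, _NA_ITEM_MISSINGNESS, "na_")

    # raw continuous trait on the liability scale itself (no discretization):
    # the cleanest target for effect-recovery checks
    trait = g + fam + resid_sd * rng.standard_normal(n)
    out["trait"] = trait
    liab_records["liability_trait"] = trait

    out["age"] = np.clip(rng.normal(30.7, 8.8, size=n), 18.0, 75.0)
    out["sex"] = pedigree["sex"].to_numpy()
    out["array"] = np.where(rng.random(n) < 0.5, "chipA", "chipB")
    out["family_id"] = fam_ids

    truth.liability = pd.DataFrame(liab_records)
    return pd.DataFrame(out)
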