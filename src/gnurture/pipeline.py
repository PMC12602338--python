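"""End-to-end orchestration: simulate, infer, score, model.

Thin glue over the library modules so analysis drivers, tests and the
acceptance script all run the identical pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gnurture import phenotypes as ph
from gnurture.assoc import (
    apply_fdr,
    fit_outcome,
    parent_of_origin_fit,
    results_to_frame,
    spousal_correlation,
)
from gnurture.famsim import (
    GeneticMap,
    HaplotypePanel,
    SimConfig,
    TruthRecord,
    simulate_founders,
    simulate_markers,
    simulate_offspring,
    simulate_weights,
)
from gnurture.phenosim import simulate_phenotypes, true_scores
from gnurture.scores import (
    ScoreTable,
    align_weights,
    assemble_scores,
    impute_missing_nt,
    standardize_scores,
)
from gnurture.transmission import TileConfig, TransmissionResult, evaluate_concordance, infer_cohort


@dataclass
class CohortBundle:
    """Everything one simulated cohort produced."""

    config: SimConfig
    markers: pd.DataFrame
    maf: np.ndarray
    weights: pd.DataFrame
    gmap: GeneticMap
    founders: HaplotypePanel
    panel: HaplotypePanel
    pedigree: pd.DataFrame
    truth: TruthRecord
    pheno: pd.DataFrame
    true_score_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def simulate_cohort(config: SimConfig, with_phenotypes: bool = True) -> CohortBundle:
    """Simulate one family cohort from a SimConfig (seeded by config.seed)."""
    rng = np.random.default_rng(config.seed)
    markers, maf = simulate_markers(config, rng)
    weights = simulate_weights(markers, rng)
    gmap = GeneticMap.uniform(markers, config.map_length_cM_per_chrom)
    founders, pedigree = simulate_founders(config, rng, weights=weights, markers=markers, maf=maf)
    panel, truth = simulate_offspring(founders, pedigree, gmap, config, rng)
    tscores = true_scores(truth, align_weights(markers, weights))
    pheno = (
        simulate_phenotypes(truth, tscores, pedigree, config, rng)
        if with_phenotypes
        else pd.DataFrame({"iid": truth.offspring})
    )
    return CohortBundle(
        config=config,
        markers=markers,
        maf=maf,
        weights=weights,
        gmap=gmap,
        founders=founders,
        panel=panel,
        pedigree=pedigree,
        truth=truth,
        pheno=pheno,
        true_score_table=tscores,
    )


def infer_transmission(bundle: CohortBundle, tile_cfg: TileConfig | None = None) -> TransmissionResult:
    return infer_cohort(bundle.panel, bundle.pedigree, tile_cfg or TileConfig())


def build_score_table(
    bundle: CohortBundle,
    transmission: TransmissionResult,
    impute: bool = True,
    standardize: bool = True,
) -> ScoreTable:
    scores = assemble_scores(bundle.panel, bundle.pedigree, transmission, bundle.weights)
    if impute:
        scores = impute_missing_nt(scores)
    if standardize:
        scores = standardize_scores(scores)
    return scores


def analysis_frame(scores: ScoreTable, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Merge standardized scores with the outcome table, one row per offspring."""
    score_cols = [
        "iid",
        "design",
        "imputed_nt",
        "z_pgs_t",
        "z_pgs_nt",
        "z_s_t_pat",
        "z_s_nt_pat",
        "z_s_t_mat",
        "z_s_nt_mat",
    ]
    return scores.table[score_cols].merge(outcomes, on="iid", validate="1:1")


def fit_all_models(
    data: pd.DataFrame,
    binary_outcomes: list[str],
    continuous_outcomes: list[str],
    mode: str = "joint",
    wave_outcomes: list[str] | None = None,
) -> pd.DataFrame:
    """Fit every outcome and attach FDR q-values over the PGS-NT family.

    ``mode``: 'joint' (PGS-T and PGS-NT in one model), 'split' (separate
    models per predictor) or 'parent_of_origin' (maternal and paternal
    haplotype-score models on the respective subsamples).
    """
    results = []
    specs = [(o, "binary") for o in binary_outcomes] + [
        (o, "continuous") for o in continuous_outcomes
    ]
    for outcome, otype in specs:
        if mode == "parent_of_origin":
            for side in ("mat", "pat"):
                results.extend(parent_of_origin_fit(data, outcome, otype, side))
        else:
            results.extend(
                fit_outcome(
                    data,
                    outcome,
                    otype,
                    ["z_pgs_t", "z_pgs_nt"],
                    joint=(mode == "joint"),
                )
            )
    for outcome in wave_outcomes or []:
        otype = "binary" if outcome.split("_w")[0] in binary_outcomes else "continuous"
        results.extend(
            fit_outcome(data, outcome, otype, ["z_pgs_t", "z_pgs_nt"], joint=(mode != "split"))
        )
    return apply_fdr(results_to_frame(results))


def replicate_frame(
    config: SimConfig, tile_cfg: TileConfig | None = None
) -> pd.DataFrame:
    """One simulated cohort run through inference and scoring, as a flat frame.

    Returns one row per offspring with standardized scores, the raw
    continuous ``trait``, per-wave binary flags, covariate codes and family
    ID — the minimal dataset for replicate-based calibration studies
    (parameter recovery, type-I error, attenuation), without the full
    outcome-construction machinery.
    """
    bundle = simulate_cohort(config)
    transmission = infer_transmission(bundle, tile_cfg)
    scores = build_score_table(bundle, transmission)
    df = scores.table[
        [
            "iid",
            "design",
            "imputed_nt",
            "z_pgs_t",
            "z_pgs_nt",
            "z_s_t_pat",
            "z_s_nt_pat",
            "z_s_t_mat",
            "z_s_nt_mat",
        ]
    ].copy()
    pheno = bundle.pheno
    keep = ["iid", "trait", "age", "family_id"]
    keep += [c for c in pheno.columns if any(c == f"{o}_w{w+1}" for o in config.prevalence_per_outcome for w in range(config.n_waves))]
    df = df.merge(pheno[keep], on="iid", validate="1:1")
    df["age_z"] = (df["age"] - df["age"].mean()) / df["age"].std(ddof=0)
    df["sex_code"] = (pheno["sex"].to_numpy() == "F").astype(float)
    df["array_code"] = (pheno["array"].to_numpy() == "chipB").astype(float)
    return df


def cohort_spousal_correlation(bundle: CohortBundle, scores: ScoreTable) -> tuple[float, tuple[float, float]]:
    """Spousal PGS correlation over couples with both parents genotyped."""
    couples = bundle.pedigree.drop_duplicates("family_id")
    couples = couples[couples["design"] == "trio"]
    f = couples["father_id"].map(scores.parent_pgs).to_numpy(dtype=float)
    m = couples["mother_id"].map(scores.parent_pgs).to_numpy(dtype=float)
    return spousal_correlation(f, m)


def run_study(
    config: SimConfig,
    tile_cfg: TileConfig | None = None,
    mode: str = "joint",
) -> dict:
    """Full pipeline on one simulated cohort; returns all intermediate stages."""
    bundle = simulate_cohort(config)
    transmission = infer_transmission(bundle, tile_cfg)
    concordance = evaluate_concordance(transmission, bundle.truth)
    scores = build_score_table(bundle, transmission)
    outcomes = ph.build_outcomes(
        bundle.pheno, list(config.prevalence_per_outcome), config.n_waves
    )
    data = analysis_frame(scores, outcomes)
    results = fit_all_models(
        data,
        binary_outcomes=list(config.prevalence_per_outcome),
        continuous_outcomes=["mdd_symptoms_z", "gad_symptoms_z", "neuroticism_z", "negative_affect_z"],
        mode=mode,
    )
    spousal = (
        cohort_spousal_correlation(bundle, scores) if config.n_trios >= 3 else (np.nan, (np.nan, np.nan))
    )
    return {
        "bundle": bundle,
        "transmission": transmission,
        "concordance": concordance,
        "scores": scores,
        "outcomes": outcomes,
        "data": data,
        "results": results,
        "spousal_r": spousal[0],
        "spousal_ci": spousal[1],
    }
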