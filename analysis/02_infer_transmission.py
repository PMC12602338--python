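"""Infer transmitted / non-transmitted haplotypes and validate against truth.

Re-creates the study cohort (same seed as 01), runs the 150-marker tile
inference for every offspring/genotyped-parent duo, and scores the result
against the simulator's ground truth: non-transmitted allele concordance
(the pipeline's headline validation figure), breakpoint localization, and
per-duo QC. Summary tables go to results/.
"""

from pathlib import Path

import pandas as pd

from gnurture import io
from gnurture.famsim import SimConfig
from gnurture.pipeline import infer_transmission, simulate_cohort
from gnurture.transmission import TileConfig, evaluate_concordance

RESULTS = Path(__file__).resolve().parents[1] / "results"
STUDY_SEED = 11


def main() -> None:
    config = SimConfig(seed=STUDY_SEED)
    bundle = simulate_cohort(config)
    transmission = infer_transmission(bundle, TileConfig(tile_size=150))
    conc = evaluate_concordance(transmission, bundle.truth)

    qc = transmission.qc
    summary = pd.DataFrame(
        {
            "quantity": [
                "non_transmitted_concordance_pct",
                "concordance_paternal_pct",
                "concordance_maternal_pct",
                "n_alleles_compared",
                "breakpoint_error_median_markers",
                "breakpoint_error_mean_markers",
                "inferred_breakpoints",
                "mendelian_conflicts_total",
                "ambiguous_marker_fraction_mean",
            ],
            "value": [
                round(100 * conc["concordance"], 3),
                round(100 * conc["concordance_pat"], 3),
                round(100 * conc["concordance_mat"], 3),
                conc["n_sites"],
                conc["breakpoint_error_median"],
                round(conc["breakpoint_error_mean"], 2),
                len(transmission.breakpoints),
                int(qc["n_conflicts"].sum()),
                round(float(qc["ambiguous_fraction"].mean()), 5),
            ],
        }
    )
    RESULTS.mkdir(parents=True, exist_ok=True)
    io.write_table(summary, RESULTS / "transmission_summary.tsv")
    io.write_table(qc, RESULTS / "transmission_qc.tsv")
    print(summary.to_string(index=False))
    print(
        f"\nnon-transmitted alleles recovered at {100 * conc['concordance']:.2f}% "
        "concordance with simulated truth"
    )


if __name__ == "__main__":
    main()
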