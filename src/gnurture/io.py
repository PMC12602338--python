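"""Readers and writers for the pipeline's text formats.

Phased VCF (GT with '|', one ALT per record), PED/FAM pedigree ('0' for a
missing parent), genetic-map TSV (chrom, pos, cM), weight-table TSV
(ID CHROM BP EA OA WEIGHT) and plain TSV tables.  Every writer stamps a
header comment with the simulation seed and config hash when available.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from gnurture.famsim import GeneticMap, HaplotypePanel, SimConfig

# genotype string lookup indexed by (h0 + 1) * 3 + (h1 + 1), alleles in {-1,0,1}
_GT_STRINGS = np.array(
    [".|.", ".|0", ".|1", "0|.", "0|0", "0|1", "1|.", "1|0", "1|1"]
)


def _meta_lines(meta: dict | None, prefix: str) -> list[str]:
    if not meta:
        return []
    return [f"{prefix}{key}={value}" for key, value in meta.items()]


def write_vcf(panel: HaplotypePanel, path: str | Path, meta: dict | None = None) -> None:
    """Write the panel as an uncompressed phased VCF (GT only)."""
    markers = panel.markers
    lines = ["##fileformat=VCFv4.2", "##source=gnurture"]
    lines += _meta_lines(meta, "##gnurture_")
    for chrom in sorted(markers["chrom"].unique()):
        max_pos = int(markers.loc[markers["chrom"] == chrom, "pos"].max())
        lines.append(f"##contig=<ID={chrom},length={max_pos + 1}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.samples)
    )
    h0 = panel.haps[:, 0, :].astype(np.int16) + 1
    h1 = panel.haps[:, 1, :].astype(np.int16) + 1
    gt = _GT_STRINGS[h0 * 3 + h1]  # (n_samples, n_markers)
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    ids = markers["id"].to_numpy()
    ref = markers["ref"].to_numpy()
    alt = markers["alt"].to_numpy()
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for j in range(panel.n_markers):
            fh.write(
                f"{chroms[j]}\t{pos[j]}\t{ids[j]}\t{ref[j]}\t{alt[j]}\t.\tPASS\t.\tGT\t"
                + "\t".join(gt[:, j])
                + "\n"
            )


def read_vcf(path: str | Path) -> HaplotypePanel:
    """Read a phased VCF into a HaplotypePanel (ALT as the effect allele)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    haps_cols = []
    for variant in vcf:
        rows.append(
            (
                int(variant.CHROM),
                variant.POS,
                variant.ID or f"{variant.CHROM}:{variant.POS}",
                variant.REF,
                variant.ALT[0] if variant.ALT else ".",
            )
        )
        gts = np.asarray(variant.genotypes, dtype=np.int16)[:, :2]
        haps_cols.append(gts)
    vcf.close()
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    markers["effect_allele"] = markers["alt"]
    haps = np.stack(haps_cols, axis=2).astype(np.int8)  # (n_samples, 2, n_markers)
    haps[haps < 0] = -1
    return HaplotypePanel(markers, samples, haps)


def write_ped(
    pedigree: pd.DataFrame,
    path: str | Path,
    panel: HaplotypePanel | None = None,
    meta: dict | None = None,
) -> None:
    """Write a FAM-dialect pedigree; ungenotyped parents become '0'.

    Parents are emitted as founder rows; offspring rows reference only the
    parents present in ``panel`` (all of them when no panel is given).
    """
    sex_code = {"M": 1, "F": 2}
    lines = _meta_lines(meta, "# gnurture_")
    seen: set[str] = set()
    for row in pedigree.itertuples(index=False):
        for pid, sx in ((row.father_id, 1), (row.mother_id, 2)):
            if pid and not pd.isna(pid) and pid not in seen and (panel is None or pid in panel):
                lines.append(f"{row.family_id}\t{pid}\t0\t0\t{sx}\t-9")
                seen.add(pid)
    for row in pedigree.itertuples(index=False):
        fid = row.father_id if (row.father_id and (panel is None or row.father_id in panel)) else "0"
        mid = row.mother_id if (row.mother_id and (panel is None or row.mother_id in panel)) else "0"
        lines.append(f"{row.family_id}\t{row.iid}\t{fid}\t{mid}\t{sex_code.get(row.sex, 0)}\t-9")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ped(path: str | Path) -> pd.DataFrame:
    """Read a FAM-dialect pedigree; returns offspring rows with design class.

    An offspring is any row with at least one non-'0' parent; design is
    'trio', 'father_pair' or 'mother_pair' depending on which parents are
    recorded.
    """
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["family_id", "iid", "father_id", "mother_id", "sex_code", "phenotype"],
        dtype=str,
    )
    off = df[(df["father_id"] != "0") | (df["mother_id"] != "0")].copy()
    if off.empty:
        raise ValueError("pedigree contains no offspring with a genotyped parent")
    off["father_id"] = off["father_id"].replace("0", np.nan)
    off["mother_id"] = off["mother_id"].replace("0", np.nan)
    off["sex"] = off["sex_code"].map({"1": "M", "2": "F"}).fillna("M")
    has_f, has_m = off["father_id"].notna(), off["mother_id"].notna()
    off["design"] = np.where(has_f & has_m, "trio", np.where(has_f, "father_pair", "mother_pair"))
    return off[["iid", "father_id", "mother_id", "sex", "family_id", "design"]].reset_index(
        drop=True
    )


def write_genetic_map(gmap: GeneticMap, path: str | Path, meta: dict | None = None) -> None:
    df = gmap.to_frame()
    header = "\n".join(_meta_lines(meta, "# gnurture_"))
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_genetic_map(path: str | Path) -> GeneticMap:
    return GeneticMap.from_frame(pd.read_csv(path, sep="\t", comment="#"))


def write_table(df: pd.DataFrame, path: str | Path, meta: dict | None = None) -> None:
    """TSV writer with the standard provenance comment header."""
    header = "\n".join(_meta_lines(meta, "# gnurture_"))
    with open(path, "w") as fh:
        if header:
            fh.write(header + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_config(config: SimConfig, path: str | Path) -> None:
    payload = {"config_hash": config.config_hash(), **config.to_dict()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_config(path: str | Path) -> SimConfig:
    payload = yaml.safe_load(Path(path).read_text())
    payload.pop("config_hash", None)
    payload["maf_range"] = tuple(payload["maf_range"])
    return SimConfig(**payload)


def haplotype_dataset_frame(
    offspring: list[str], alleles: np.ndarray, markers: pd.DataFrame
) -> pd.DataFrame:
    """VCF-like table of one haplotype dataset (transmitted or not).

    One row per marker, one column per offspring, '.' for missing — the
    'separate dataset' representation of transmitted / non-transmitted
    alleles.
    """
    out = markers[["chrom", "pos", "id", "ref", "alt"]].copy()
    coded = np.where(alleles.T == -1, ".", alleles.T.astype(str))
    for j, iid in enumerate(offspring):
        out[iid] = coded[:, j]
    return out
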