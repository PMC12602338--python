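"""Polygenic scores on transmitted and non-transmitted haplotype sets.

PGS-T is the sum of the paternal and maternal transmitted haplotype
scores; PGS-NT the sum of the non-transmitted ones.  For parent-offspring
pairs, the missing per-parent non-transmitted component is imputed with
half the cohort mean diploid score of all genotyped parents, and both
scores are standardized with the mean and SD of the full PGS-T so a unit
is one SD of PGS-T.  Scores can additionally be residualized on principal
components before modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from gnurture.famsim import MISSING, HaplotypePanel
from gnurture.transmission import TransmissionResult


def align_weights(markers: pd.DataFrame, weight_table: pd.DataFrame) -> np.ndarray:
    """Per-marker weight vector aligned to a panel marker index.

    Matches by variant ID, verifies the weight table's allele pair against
    the panel's ref/alt, and flips the weight sign when the effect allele
    is the panel's other allele (the resulting additive constant is
    irrelevant for association and cancels in all score contrasts).
    Markers without a usable weight get NaN.  Strand-ambiguous pairs are
    kept as-is; this panel dialect has none.
    """
    w = np.full(len(markers), np.nan)
    lookup = {
        row.ID: (str(row.EA), str(row.OA), float(row.WEIGHT))
        for row in weight_table.itertuples(index=False)
    }
    ids = markers["id"].to_numpy()
    ref = markers["ref"].to_numpy()
    alt = markers["alt"].to_numpy()
    eff = markers["effect_allele"].to_numpy()
    n_mismatch = 0
    for i in range(len(markers)):
        rec = lookup.get(ids[i])
        if rec is None:
            continue
        ea, oa, weight = rec
        if {ea, oa} != {ref[i], alt[i]}:
            n_mismatch += 1
            continue
        w[i] = weight if ea == eff[i] else -weight
    if n_mismatch:
        warnings.warn(
            f"{n_mismatch} weight-table variants had allele pairs not matching the panel "
            "and were skipped",
            stacklevel=2,
        )
    return w


def score_haplotype(hap: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    """Weighted effect-allele sum over non-missing, weighted markers.

    Returns (score, number of contributing markers).  Raises when no
    marker contributes.
    """
    hap = np.asarray(hap)
    weights = np.asarray(weights, dtype=float)
    if hap.shape != weights.shape:
        raise ValueError("haplotype and weight vectors are misaligned")
    mask = (hap != MISSING) & np.isfinite(weights)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no overlapping non-missing weighted markers")
    return float(weights[mask] @ hap[mask]), n


def _score_or_nan(hap: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    mask = (hap != MISSING) & np.isfinite(weights)
    n = int(mask.sum())
    if n == 0:
        return np.nan, 0
    return float(weights[mask] @ hap[mask]), n


@dataclass
class ScoreTable:
    """Per-offspring haplotype scores plus the genotyped parents' diploid PGSs.

    ``table`` holds one row per offspring: own diploid PGS, the four
    per-parent haplotype scores (NaN when unavailable), PGS-T, PGS-NT, the
    imputation flag and design class; standardized columns are added by
    :func:`standardize_scores`.
    """

    table: pd.DataFrame
    parent_pgs: pd.Series

    def copy(self) -> "ScoreTable":
        return replace(self, table=self.table.copy(), parent_pgs=self.parent_pgs.copy())


def assemble_scores(
    panel: HaplotypePanel,
    pedigree: pd.DataFrame,
    transmission: TransmissionResult,
    weight_table: pd.DataFrame,
) -> ScoreTable:
    """Build the per-offspring score table from inferred transmission.

    The transmitted side of an ungenotyped parent comes from the
    offspring's own phased haplotype (already filled by
    :func:`gnurture.transmission.infer_cohort`); its non-transmitted score
    is NaN until imputation.
    """
    w = align_weights(panel.markers, weight_table)
    if not np.isfinite(w).any():
        raise ValueError("weight table shares no variants with the panel")
    if transmission.offspring != list(pedigree["iid"]):
        raise ValueError("transmission result and pedigree are misaligned")

    parent_cache: dict[str, float] = {}

    def parent_score(pid) -> float:
        if pid is None or pd.isna(pid) or pid not in panel:
            return np.nan
        if pid not in parent_cache:
            parent_cache[pid] = _score_or_nan(panel.dosage(pid), w)[0]
        return parent_cache[pid]

    rows = []
    for k, row in enumerate(pedigree.itertuples(index=False)):
        own, n_own = _score_or_nan(panel.dosage(row.iid), w)
        s_t_pat, _ = _score_or_nan(transmission.t_pat[k], w)
        s_nt_pat, _ = _score_or_nan(transmission.nt_pat[k], w)
        s_t_mat, _ = _score_or_nan(transmission.t_mat[k], w)
        s_nt_mat, _ = _score_or_nan(transmission.nt_mat[k], w)
        rows.append(
            {
                "iid": row.iid,
                "family_id": row.family_id,
                "design": row.design,
                "own_pgs": own,
                "n_markers": n_own,
                "s_t_pat": s_t_pat,
                "s_nt_pat": s_nt_pat,
                "s_t_mat": s_t_mat,
                "s_nt_mat": s_nt_mat,
                "father_pgs": parent_score(row.father_id),
                "mother_pgs": parent_score(row.mother_id),
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no offspring to score")
    table["pgs_t"] = table["s_t_pat"] + table["s_t_mat"]
    table["pgs_nt"] = table["s_nt_pat"] + table["s_nt_mat"]
    table["imputed_nt"] = False

    parent_ids = sorted(
        {
            pid
            for col in ("father_id", "mother_id")
            for pid in pedigree[col]
            if pid is not None and not pd.isna(pid) and pid in panel
        }
    )
    if not parent_ids:
        raise ValueError("no genotyped parents in the cohort")
    parent_pgs = pd.Series(
        {pid: _score_or_nan(panel.dosage(pid), w)[0] for pid in parent_ids}, name="parent_pgs"
    )
    return ScoreTable(table=table, parent_pgs=parent_pgs)


def impute_missing_nt(scores: ScoreTable, method: str = "observed_parent") -> ScoreTable:
    """Fill the missing non-transmitted component of pair offspring.

    ``method='observed_parent'`` (default): the missing haplotype component
    is the average haplotype score of the family's observed parent, i.e.
    half that parent's diploid PGS.  Because this borrows the observed
    parent's own genetics, the resulting PGS-NT partially overlaps PGS-T
    and nurture estimates from imputed pairs are attenuated — the price of
    keeping pairs in the analysis.

    ``method='cohort_mean'``: half the mean diploid PGS over all genotyped
    parents in the cohort — a family-independent constant that leaves pair
    estimates unbiased but discards all family information.

    PGS-NT is recomputed and the imputation flag set; trio offspring are
    untouched.
    """
    if scores.parent_pgs.dropna().empty:
        raise ValueError("no genotyped parents available for imputation")
    out = scores.copy()
    t = out.table
    fill_pat = t["s_nt_pat"].isna() & t["s_nt_mat"].notna()
    fill_mat = t["s_nt_mat"].isna() & t["s_nt_pat"].notna()
    if method == "observed_parent":
        # the observed parent of a father-missing offspring is the mother,
        # and vice versa
        t.loc[fill_pat, "s_nt_pat"] = 0.5 * t.loc[fill_pat, "mother_pgs"]
        t.loc[fill_mat, "s_nt_mat"] = 0.5 * t.loc[fill_mat, "father_pgs"]
    elif method == "cohort_mean":
        half_mean = 0.5 * float(scores.parent_pgs.dropna().mean())
        t.loc[fill_pat, "s_nt_pat"] = half_mean
        t.loc[fill_mat, "s_nt_mat"] = half_mean
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    t["pgs_nt"] = t["s_nt_pat"] + t["s_nt_mat"]
    t["imputed_nt"] = fill_pat | fill_mat
    return out


def standardize_scores(scores: ScoreTable) -> ScoreTable:
    """Z-score PGS-T and PGS-NT with the mean and SD of the full PGS-T.

    Both scores are expressed in units of one SD of PGS-T over the full
    analysis sample.  The four per-parent haplotype components are
    standardized analogously with the pooled transmitted haplotype scores,
    for parent-of-origin models.
    """
    out = scores.copy()
    t = out.table
    mu = t["pgs_t"].mean()
    sd = t["pgs_t"].std(ddof=0)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("PGS-T has zero or undefined variance; cannot standardize")
    t["z_pgs_t"] = (t["pgs_t"] - mu) / sd
    t["z_pgs_nt"] = (t["pgs_nt"] - mu) / sd

    pooled = pd.concat([t["s_t_pat"], t["s_t_mat"]])
    mu_h, sd_h = pooled.mean(), pooled.std(ddof=0)
    if not np.isfinite(sd_h) or sd_h == 0:
        raise ValueError("transmitted haplotype scores have zero variance")
    for col in ("s_t_pat", "s_t_mat", "s_nt_pat", "s_nt_mat"):
        t[f"z_{col}"] = (t[col] - mu_h) / sd_h
    return out


def residualize_on_pcs(score: np.ndarray, pcs: np.ndarray) -> np.ndarray:
    """Least-squares residuals of a score on an intercept plus PCs.

    Residuals are orthogonal to every retained component; collinear PC
    columns are dropped with a warning.  Rows with NaN in the score are
    passed through as NaN.
    """
    score = np.asarray(score, dtype=float)
    pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
    if pcs.shape[0] != score.shape[0]:
        pcs = pcs.T
    if pcs.shape[0] != score.shape[0]:
        raise ValueError("PC matrix rows do not align with the score vector")
    design = np.column_stack([np.ones(score.shape[0]), pcs])
    keep = ~np.isnan(score)
    X = design[keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # greedily drop collinear columns (never the intercept)
        cols = [0]
        for j in range(1, design.shape[1]):
            trial = X[:, cols + [j]]
            if np.linalg.matrix_rank(trial) > len(cols):
                cols.append(j)
        warnings.warn(
            f"dropped {design.shape[1] - len(cols)} collinear PC column(s) before residualizing",
            stacklevel=2,
        )
        design = design[:, cols]
        X = design[keep]
    beta, *_ = np.linalg.lstsq(X, score[keep], rcond=None)
    resid = np.full_like(score, np.nan)
    resid[keep] = score[keep] - X @ beta
    return resid
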