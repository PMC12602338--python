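"""Synthetic phased family cohorts with known transmission ground truth.

Simulates founder haplotypes, Mendelian transmission with map-based
recombination (Poisson crossovers, no interference), optional assortative
mating on a polygenic score, and optional phase errors, for cohorts mixing
complete trios with father-only and mother-only parent-offspring pairs.

Alleles are coded as counts of the effect allele on a single haplotype
(0/1), with ``-1`` for missing.  Offspring haplotype 0 is the paternal
gamete and haplotype 1 the maternal gamete (pedigree-phased convention).
Founder haplotypes are drawn site-independently: there is no background LD,
so linkage arises only within families through co-transmission.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

MISSING = np.int8(-1)

#: Default per-outcome lifetime prevalences for the binary diagnoses carried
#: by the synthetic cohort (approximate adult general-population rates for
#: depressive and anxiety disorders).
DEFAULT_PREVALENCES = {
    "mdd": 0.185,
    "dysthymia": 0.026,
    "gad": 0.115,
    "panic": 0.033,
    "agoraphobia": 0.071,
    "social_phobia": 0.040,
}


@dataclass
class SimConfig:
    """Knobs of the synthetic family cohort.

    Default cohort shape follows a roughly 3:5:9 ratio of trios to
    father-only to mother-only pairs, as seen in large population biobanks
    where mothers are genotyped more often than fathers.

    Parameters
    ----------
    n_trios, n_father_pairs, n_mother_pairs
        Number of families of each design.  In a pair design the second
        parent is simulated (so ground truth exists) but withheld from the
        released genotype panel.
    n_markers, n_chromosomes
        Total biallelic marker count, split evenly across chromosomes.
    maf_range
        Effect-allele frequencies drawn uniformly within this range.
    map_length_cM_per_chrom
        Genetic length of every chromosome; the expected crossover count
        per gamete per chromosome is this value / 100.
    beta_T, beta_NT
        Liability-scale effects per SD of the transmitted and
        non-transmitted parental polygenic scores (direct and
        genetic-nurture effects).
    spousal_corr
        Target Pearson correlation of spousal diploid polygenic scores
        (assortative mating at the score level).
    family_var, resid_var
        Variance of the family-shared random intercept and of the
        individual residual on the liability scale.
    prevalence_per_outcome
        Lifetime prevalence of each binary diagnosis.
    n_waves
        Number of assessment waves.
    wave_missingness
        Probability that an offspring misses a given wave.
    phase_error_rate
        Per-heterozygous-site probability of swapping the two offspring
        haplotype alleles (imperfect statistical phasing).
    sibling_rate
        Probability that a couple contributes a second offspring, to
        exercise the family random intercept.
    """

    n_trios: int = 279
    n_father_pairs: int = 525
    n_mother_pairs: int = 914
    n_markers: int = 10_000
    n_chromosomes: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    map_length_cM_per_chrom: float = 100.0
    beta_T: float = 0.15
    beta_NT: float = 0.0
    spousal_corr: float = 0.02
    family_var: float = 0.2
    resid_var: float = 0.8
    prevalence_per_outcome: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    n_waves: int = 3
    wave_missingness: float = 0.2
    phase_error_rate: float = 0.0
    sibling_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_markers": self.n_markers,
            "n_chromosomes": self.n_chromosomes,
            "n_waves": self.n_waves,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        for name in ("n_trios", "n_father_pairs", "n_mother_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_trios + self.n_father_pairs + self.n_mother_pairs <= 0:
            raise ValueError("cohort must contain at least one family")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, got {self.maf_range}")
        if not 0.0 <= self.spousal_corr < 1.0:
            raise ValueError("spousal_corr must lie in [0, 1)")
        for name in ("wave_missingness", "phase_error_rate", "sibling_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for name in ("family_var", "resid_var"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for outcome, prev in self.prevalence_per_outcome.items():
            if not 0.0 < prev < 1.0:
                raise ValueError(f"prevalence for {outcome!r} must lie in (0, 1), got {prev}")
        if self.map_length_cM_per_chrom < 0:
            raise ValueError("map_length_cM_per_chrom must be >= 0")

    @property
    def n_couples(self) -> int:
        return self.n_trios + self.n_father_pairs + self.n_mother_pairs

    def with_(self, **kwargs) -> "SimConfig":
        """Return a copy with some fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["maf_range"] = list(self.maf_range)
        return d

    def config_hash(self) -> str:
        """Stable short hash of the configuration, for output headers."""
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class GeneticMap:
    """Piecewise-linear map between physical (bp) and genetic (cM) position.

    Stores, per chromosome, ordered (bp, cumulative cM) anchor points;
    positions must be strictly increasing and cM non-decreasing.
    """

    def __init__(self, anchors: dict[int, tuple[np.ndarray, np.ndarray]]):
        self.anchors = {}
        for chrom, (pos, cm) in anchors.items():
            pos = np.asarray(pos, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if pos.ndim != 1 or pos.shape != cm.shape or pos.size < 2:
                raise ValueError("each chromosome needs >= 2 aligned (bp, cM) anchors")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"chromosome {chrom}: bp positions must strictly increase")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {chrom}: cM must be non-decreasing")
            self.anchors[int(chrom)] = (pos, cm)

    @classmethod
    def uniform(cls, markers: pd.DataFrame, length_cM: float) -> "GeneticMap":
        """Constant-rate map spanning each chromosome's marker range."""
        anchors = {}
        for chrom, sub in markers.groupby("chrom", sort=True):
            pos = sub["pos"].to_numpy(dtype=float)
            lo, hi = pos[0], pos[-1]
            anchors[int(chrom)] = (np.array([lo, hi]), np.array([0.0, length_cM]))
        return cls(anchors)

    def chromosomes(self) -> list[int]:
        return sorted(self.anchors)

    def length_cM(self, chrom: int) -> float:
        _, cm = self.anchors[chrom]
        return float(cm[-1] - cm[0])

    def cM_at(self, chrom: int, pos) -> np.ndarray:
        p, cm = self.anchors[chrom]
        return np.interp(np.asarray(pos, dtype=float), p, cm)

    def bp_at(self, chrom: int, cm_query) -> np.ndarray:
        p, cm = self.anchors[chrom]
        return np.interp(np.asarray(cm_query, dtype=float), cm, p)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chromosomes():
            pos, cm = self.anchors[chrom]
            rows.append(pd.DataFrame({"chrom": chrom, "pos": pos.astype(int), "cM": cm}))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeneticMap":
        anchors = {
            int(chrom): (sub["pos"].to_numpy(float), sub["cM"].to_numpy(float))
            for chrom, sub in df.groupby("chrom", sort=True)
        }
        return cls(anchors)


class HaplotypePanel:
    """Phased alleles for a set of samples over an ordered marker index.

    ``haps`` has shape (n_samples, 2, n_markers) with entries in {0, 1, -1};
    an entry counts copies of the effect allele on that haplotype, -1 is
    missing.  ``markers`` is a DataFrame with columns
    chrom, pos, id, ref, alt, effect_allele (sorted by chrom then pos).
    """

    def __init__(self, markers: pd.DataFrame, samples: list[str], haps: np.ndarray):
        haps = np.asarray(haps, dtype=np.int8)
        if haps.shape != (len(samples), 2, len(markers)):
            raise ValueError(
                f"haps shape {haps.shape} does not match "
                f"({len(samples)}, 2, {len(markers)})"
            )
        if not np.isin(haps, [-1, 0, 1]).all():
            raise ValueError("haplotype alleles must be coded 0/1 with -1 for missing")
        self.markers = markers.reset_index(drop=True)
        self.samples = list(samples)
        self.haps = haps
        self._index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def __contains__(self, sample: str) -> bool:
        return sample in self._index

    def sample_haps(self, sample: str) -> np.ndarray:
        """(2, n_markers) haplotypes of one sample."""
        return self.haps[self._index[sample]]

    def dosage(self, sample: str) -> np.ndarray:
        """Diploid effect-allele counts; -1 where either haplotype missing."""
        h = self.sample_haps(sample)
        d = (h[0] + h[1]).astype(np.int8)
        d[(h[0] == MISSING) | (h[1] == MISSING)] = MISSING
        return d

    def chrom_slices(self) -> list[tuple[int, slice]]:
        """Contiguous marker slice per chromosome, in panel order."""
        chroms = self.markers["chrom"].to_numpy()
        out = []
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                out.append((int(chroms[start]), slice(start, i)))
                start = i
        return out

    def subset_samples(self, keep: list[str]) -> "HaplotypePanel":
        idx = [self._index[s] for s in keep]
        return HaplotypePanel(self.markers, list(keep), self.haps[idx])


@dataclass
class TruthRecord:
    """Ground truth of one simulated cohort.

    Per offspring (rows aligned with ``offspring``): the true transmitted
    and non-transmitted allele vectors on each parental side, the gamete
    origin vectors (which of the parent's two haplotypes each marker was
    copied from), crossover positions, and the haplotypes of parents
    withheld from the released panel.  Liability components are attached by
    the phenotype simulator.
    """

    offspring: list[str]
    t_pat: np.ndarray
    nt_pat: np.ndarray
    t_mat: np.ndarray
    nt_mat: np.ndarray
    origin_pat: np.ndarray
    origin_mat: np.ndarray
    crossovers: pd.DataFrame
    masked_parents: dict[str, np.ndarray]
    liability: pd.DataFrame | None = None

    def index_of(self, offspring_id: str) -> int:
        return self.offspring.index(offspring_id)


def simulate_markers(config: SimConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    """Marker index and per-marker effect-allele frequencies.

    Markers are spread evenly across chromosomes at 5 kb spacing; the ALT
    allele is the effect allele throughout.
    """
    per_chrom = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per_chrom[: config.n_markers % config.n_chromosomes] += 1
    chroms = np.repeat(np.arange(1, config.n_chromosomes + 1), per_chrom)
    pos = np.concatenate([5000 * (np.arange(n) + 1) for n in per_chrom])
    markers = pd.DataFrame(
        {
            "chrom": chroms.astype(int),
            "pos": pos.astype(int),
            "id": [f"snp{i + 1}" for i in range(config.n_markers)],
            "ref": "A",
            "alt": "G",
            "effect_allele": "G",
        }
    )
    lo, hi = config.maf_range
    maf = rng.uniform(lo, hi, size=config.n_markers)
    return markers, maf


def simulate_weights(
    markers: pd.DataFrame, rng: np.random.Generator, scale: float | None = None
) -> pd.DataFrame:
    """Random per-allele score weights for the marker panel.

    Weights are i.i.d. Normal(0, scale^2) with scale defaulting to
    1/sqrt(M) so the diploid score variance is O(1) regardless of panel
    size.  Returned in the standard score-file layout
    (ID, CHROM, BP, EA, OA, WEIGHT).
    """
    m = len(markers)
    if scale is None:
        scale = 1.0 / np.sqrt(m)
    return pd.DataFrame(
        {
            "ID": markers["id"],
            "CHROM": markers["chrom"],
            "BP": markers["pos"],
            "EA": markers["effect_allele"],
            "OA": np.where(markers["effect_allele"] == markers["alt"], markers["ref"], markers["alt"]),
            "WEIGHT": rng.normal(0.0, scale, size=m),
        }
    )


def _rank_match_couples(
    father_score: np.ndarray,
    mother_score: np.ndarray,
    target_corr: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Permutation of mothers pairing them to fathers.

    Rank-matching on a noisy latent: each father gets a key correlated
    ``target_corr`` with his standardized score; mothers sorted by score are
    assigned to fathers sorted by key.  For jointly Gaussian scores the
    resulting spousal correlation approaches the target.
    """
    n = father_score.size
    z_f = (father_score - father_score.mean()) / father_score.std()
    r = target_corr
    key = r * z_f + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
    father_rank = np.argsort(np.argsort(key))
    mothers_sorted = np.argsort(mother_score)
    return mothers_sorted[father_rank]


def simulate_founders(
    config: SimConfig,
    rng: np.random.Generator,
    weights: pd.DataFrame | None = None,
    markers: pd.DataFrame | None = None,
    maf: np.ndarray | None = None,
) -> tuple[HaplotypePanel, pd.DataFrame]:
    """Founder haplotypes plus a pedigree plan for their offspring.

    Returns the founder panel (all parents, including those later masked in
    pair designs) and a pedigree DataFrame with one row per planned
    offspring: iid, father_id, mother_id, sex ('M'/'F'), family_id and
    design ('trio' / 'father_pair' / 'mother_pair').  Couples are paired to
    approach ``config.spousal_corr`` on the diploid polygenic score; when no
    weight table is supplied a uniform-weight latent score is used.
    A precomputed marker index / frequency vector can be passed so that the
    same panel definition is shared with a weight table drawn beforehand.
    """
    if markers is None or maf is None:
        markers, maf = simulate_markers(config, rng)
    n = config.n_couples
    haps = (rng.random((2 * n, 2, config.n_markers)) < maf).astype(np.int8)

    if weights is not None:
        from gnurture.scores import align_weights

        w = align_weights(markers, weights)
        if not np.isfinite(w).any():
            raise ValueError("weight table shares no variants with the simulated panel")
        w = np.nan_to_num(w)
    else:
        w = np.full(config.n_markers, 1.0 / np.sqrt(config.n_markers))
    dosages = haps.sum(axis=1)
    scores = dosages @ w

    father_rows = np.arange(n)
    mother_rows = np.arange(n, 2 * n)
    mother_perm = _rank_match_couples(
        scores[father_rows], scores[mother_rows], config.spousal_corr, rng
    )
    mother_rows = mother_rows[mother_perm]

    fathers = [f"F{i + 1:05d}" for i in range(n)]
    mothers = [f"M{i + 1:05d}" for i in range(n)]
    samples = fathers + mothers
    order = np.concatenate([father_rows, mother_rows])
    panel = HaplotypePanel(markers, samples, haps[order])

    designs = (
        ["trio"] * config.n_trios
        + ["father_pair"] * config.n_father_pairs
        + ["mother_pair"] * config.n_mother_pairs
    )
    rows = []
    child = 0
    for i, design in enumerate(designs):
        n_children = 1 + int(rng.random() < config.sibling_rate)
        for _ in range(n_children):
            child += 1
            rows.append(
                {
                    "iid": f"O{child:05d}",
                    "father_id": fathers[i],
                    "mother_id": mothers[i],
                    "sex": "F" if rng.random() < 0.5 else "M",
                    "family_id": f"FAM{i + 1:05d}",
                    "design": design,
                }
            )
    pedigree = pd.DataFrame(rows)
    return panel, pedigree


def meiosis(
    parent_haps: np.ndarray,
    markers: pd.DataFrame,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, float]]]:
    """One gamete from a parent's two haplotypes.

    Crossover counts per chromosome are Poisson with mean equal to the map
    length in Morgans (no interference, Haldane model); crossover positions
    are uniform on the cM scale.  The starting haplotype of each chromosome
    is chosen fairly at random.

    Returns (gamete alleles, origin vector with the source haplotype index
    per marker, crossovers as (chrom, cM) tuples).
    """
    m = len(markers)
    gamete = np.empty(m, dtype=np.int8)
    origin = np.empty(m, dtype=np.int8)
    crossovers: list[tuple[int, float]] = []
    chroms = markers["chrom"].to_numpy()
    pos = markers["pos"].to_numpy()
    start_idx = 0
    for i in range(1, m + 1):
        if i < m and chroms[i] == chroms[start_idx]:
            continue
        sl = slice(start_idx, i)
        chrom = int(chroms[start_idx])
        if chrom not in gmap.anchors:
            raise ValueError(f"genetic map does not cover chromosome {chrom}")
        length = gmap.length_cM(chrom)
        marker_cM = gmap.cM_at(chrom, pos[sl])
        n_xo = rng.poisson(length / 100.0) if length > 0 else 0
        xo = np.sort(rng.uniform(0.0, length, size=n_xo))
        start_hap = int(rng.integers(2))
        origin[sl] = (start_hap + np.searchsorted(xo, marker_cM, side="left")) % 2
        crossovers.extend((chrom, float(c)) for c in xo)
        start_idx = i
    cols = np.arange(m)
    gamete[:] = parent_haps[origin, cols]
    origin_missing = parent_haps[origin, cols] == MISSING
    gamete[origin_missing] = MISSING
    return gamete, origin, crossovers


def simulate_offspring(
    founders: HaplotypePanel,
    pedigree: pd.DataFrame,
    gmap: GeneticMap,
    config: SimConfig,
    rng: np.random.Generator,
) -> tuple[HaplotypePanel, TruthRecord]:
    """Offspring panel plus ground truth; masks the unobserved parent in pairs.

    The released panel contains each offspring (haplotype 0 paternal,
    haplotype 1 maternal) and only the genotyped parents of its design;
    the withheld parent of a pair design is kept in the TruthRecord.
    Phase errors swap the two offspring alleles independently at
    heterozygous sites with probability ``config.phase_error_rate``.
    """
    markers = founders.markers
    m = founders.n_markers
    n_off = len(pedigree)
    off_haps = np.empty((n_off, 2, m), dtype=np.int8)
    t_pat = np.empty((n_off, m), dtype=np.int8)
    nt_pat = np.empty((n_off, m), dtype=np.int8)
    t_mat = np.empty((n_off, m), dtype=np.int8)
    nt_mat = np.empty((n_off, m), dtype=np.int8)
    origin_pat = np.empty((n_off, m), dtype=np.int8)
    origin_mat = np.empty((n_off, m), dtype=np.int8)
    xo_rows = []
    cols = np.arange(m)

    for k, row in enumerate(pedigree.itertuples(index=False)):
        fhap = founders.sample_haps(row.father_id)
        mhap = founders.sample_haps(row.mother_id)
        pat_gamete, pat_origin, pat_xo = meiosis(fhap, markers, gmap, rng)
        mat_gamete, mat_origin, mat_xo = meiosis(mhap, markers, gmap, rng)
        off_haps[k, 0] = pat_gamete
        off_haps[k, 1] = mat_gamete
        t_pat[k] = pat_gamete
        nt_pat[k] = fhap[1 - pat_origin, cols]
        t_mat[k] = mat_gamete
        nt_mat[k] = mhap[1 - mat_origin, cols]
        origin_pat[k] = pat_origin
        origin_mat[k] = mat_origin
        for chrom, cm in pat_xo:
            xo_rows.append((row.iid, "pat", chrom, cm))
        for chrom, cm in mat_xo:
            xo_rows.append((row.iid, "mat", chrom, cm))
        if config.phase_error_rate > 0:
            het = off_haps[k, 0] != off_haps[k, 1]
            flip = het & (rng.random(m) < config.phase_error_rate)
            h0 = off_haps[k, 0, flip].copy()
            off_haps[k, 0, flip] = off_haps[k, 1, flip]
            off_haps[k, 1, flip] = h0

    crossovers = pd.DataFrame(xo_rows, columns=["offspring", "parent", "chrom", "cM"])

    masked: dict[str, np.ndarray] = {}
    released: list[str] = []
    for row in pedigree.drop_duplicates("family_id").itertuples(index=False):
        if row.design in ("trio", "father_pair"):
            released.append(row.father_id)
        else:
            masked[row.father_id] = founders.sample_haps(row.father_id).copy()
        if row.design in ("trio", "mother_pair"):
            released.append(row.mother_id)
        else:
            masked[row.mother_id] = founders.sample_haps(row.mother_id).copy()

    parent_panel = founders.subset_samples(released)
    samples = parent_panel.samples + list(pedigree["iid"])
    haps = np.concatenate([parent_panel.haps, off_haps], axis=0)
    panel = HaplotypePanel(markers, samples, haps)

    truth = TruthRecord(
        offspring=list(pedigree["iid"]),
        t_pat=t_pat,
        nt_pat=nt_pat,
        t_mat=t_mat,
        nt_mat=nt_mat,
        origin_pat=origin_pat,
        origin_mat=origin_mat,
        crossovers=crossovers,
        masked_parents=masked,
    )
    return panel, truth
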