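"""Tile-based inference of transmitted vs non-transmitted parental haplotypes.

For each offspring/parent duo the offspring haplotype attributed to that
parent (paternal = haplotype 0, maternal = haplotype 1 under the
pedigree-phased convention) is compared to the parent's two haplotypes in
tiles of consecutive markers (150 by default).  Within a tile, agreement
with each parental haplotype is scored over the markers where the parent is
heterozygous — homozygous sites cannot distinguish the haplotypes — and the
better-matching haplotype is assigned.  Ambiguous tiles are filled from
their flanks, isolated weak single-tile switches are smoothed away, each
retained switch is refined to a marker interval by a cumulative agreement
criterion, and double crossovers hidden inside a single tile are recovered
by a maximum-subarray rescue scan.  The assigned haplotype's alleles form
the transmitted vector; the other haplotype's alleles the non-transmitted
vector.  For an ungenotyped parent the non-transmitted side is entirely
missing.

Inference is deterministic: no randomness anywhere in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gnurture.famsim import MISSING, HaplotypePanel, TruthRecord

AMBIGUOUS = -1

_BP_COLUMNS = ["chrom", "left_marker", "right_marker", "from_hap", "to_hap"]


@dataclass
class TileConfig:
    """Tiling, smoothing and rescue knobs.

    tile_size: markers per tile (final partial tile kept).
    min_informative: minimum parent-heterozygous, fully observed markers for
        a tile to be assigned directly; partial tiles scale this
        proportionally.
    smoothing: revert isolated single-tile switches with a weak score margin.
    smoothing_margin: margin (winner minus loser agreement fraction) below
        which an isolated switch is considered weak.
    rescue_double_crossovers: scan assigned segments for interior intervals
        that favour the other haplotype (crossover pairs closer than a
        tile, invisible to tile-level matching).
    rescue_min_evidence / rescue_min_purity: net informative support and
        within-interval agreement purity an interior interval must show.
    """

    tile_size: int = 150
    min_informative: int = 5
    smoothing: bool = True
    smoothing_margin: float = 0.2
    rescue_double_crossovers: bool = True
    rescue_min_evidence: int = 10
    rescue_min_purity: float = 0.9

    def __post_init__(self) -> None:
        if self.tile_size < 2:
            raise ValueError("tile_size must be >= 2")
        if self.min_informative < 0:
            raise ValueError("min_informative must be >= 0")
        if self.smoothing_margin < 0:
            raise ValueError("smoothing_margin must be >= 0")
        if self.rescue_min_evidence < 1:
            raise ValueError("rescue_min_evidence must be >= 1")
        if not 0.5 < self.rescue_min_purity <= 1.0:
            raise ValueError("rescue_min_purity must lie in (0.5, 1]")


@dataclass
class DuoResult:
    """Inference output for one offspring/parent duo."""

    transmitted: np.ndarray
    non_transmitted: np.ndarray
    tiles: pd.DataFrame
    marker_assign: np.ndarray
    breakpoints: pd.DataFrame
    n_conflicts: int
    ambiguous_fraction: float


@dataclass
class TransmissionResult:
    """Cohort-level transmitted / non-transmitted haplotype datasets.

    Arrays are (n_offspring, n_markers) with -1 for missing; the
    non-transmitted side of an ungenotyped parent is entirely missing,
    while its transmitted side is read off the offspring's own phased
    haplotype.
    """

    offspring: list[str]
    t_pat: np.ndarray
    nt_pat: np.ndarray
    t_mat: np.ndarray
    nt_mat: np.ndarray
    breakpoints: pd.DataFrame
    qc: pd.DataFrame
    chroms: np.ndarray | None = None
    tile_config: TileConfig = field(default_factory=TileConfig)

    def index_of(self, offspring_id: str) -> int:
        return self.offspring.index(offspring_id)


def _chrom_slices(chroms: np.ndarray) -> list[tuple[int, slice]]:
    out = []
    start = 0
    n = len(chroms)
    for i in range(1, n + 1):
        if i == n or chroms[i] != chroms[start]:
            out.append((int(chroms[start]), slice(start, i)))
            start = i
    return out


def _tile_arrays(
    off: np.ndarray, p0: np.ndarray, p1: np.ndarray, chroms: np.ndarray, cfg: TileConfig
) -> dict[str, np.ndarray]:
    """Per-tile counts, agreement scores and raw assignments (numpy only)."""
    informative = (p0 != p1) & (p0 != MISSING) & (p1 != MISSING) & (off != MISSING)
    agree0 = informative & (off == p0)
    agree1 = informative & (off == p1)
    cs_inf = np.concatenate([[0], np.cumsum(informative)])
    cs_a0 = np.concatenate([[0], np.cumsum(agree0)])
    cs_a1 = np.concatenate([[0], np.cumsum(agree1)])

    t_chrom, t_start, t_end = [], [], []
    for chrom, sl in _chrom_slices(chroms):
        starts = np.arange(sl.start, sl.stop, cfg.tile_size)
        t_chrom.append(np.full(starts.size, chrom))
        t_start.append(starts)
        t_end.append(np.minimum(starts + cfg.tile_size, sl.stop))
    t_chrom = np.concatenate(t_chrom)
    t_start = np.concatenate(t_start)
    t_end = np.concatenate(t_end)

    n_inf = cs_inf[t_end] - cs_inf[t_start]
    n_a0 = cs_a0[t_end] - cs_a0[t_start]
    n_a1 = cs_a1[t_end] - cs_a1[t_start]
    with np.errstate(invalid="ignore", divide="ignore"):
        s0 = np.where(n_inf > 0, n_a0 / np.maximum(n_inf, 1), np.nan)
        s1 = np.where(n_inf > 0, n_a1 / np.maximum(n_inf, 1), np.nan)
    tile_len = t_end - t_start
    eff_min = np.maximum(1, np.ceil(cfg.min_informative * tile_len / cfg.tile_size).astype(int))
    assign = np.where(s0 > s1, 0, np.where(s1 > s0, 1, AMBIGUOUS))
    assign = np.where(n_inf >= eff_min, assign, AMBIGUOUS)
    return {
        "chrom": t_chrom,
        "start": t_start,
        "end": t_end,
        "n_informative": n_inf,
        "score0": s0,
        "score1": s1,
        "assign": assign.astype(np.int8),
    }


def match_tiles(
    offspring_hap: np.ndarray,
    parent_haps: np.ndarray,
    chroms: np.ndarray,
    cfg: TileConfig | None = None,
) -> pd.DataFrame:
    """Per-tile agreement with each parental haplotype and an assignment.

    Returns a DataFrame with one row per tile: chrom, start, end (half-open
    global marker indices), n_informative, score0, score1 (agreement
    fractions with parental haplotypes 0 and 1; NaN when uninformative) and
    assign (0, 1, or -1 for ambiguous).  Agreement is computed only over
    parent-heterozygous, fully observed markers.  Tiles with fewer
    informative markers than the (proportionally scaled) minimum, or with
    exactly tied scores, are ambiguous.
    """
    cfg = cfg or TileConfig()
    off = np.asarray(offspring_hap)
    p0, p1 = np.asarray(parent_haps[0]), np.asarray(parent_haps[1])
    chroms = np.asarray(chroms)
    if not (off.shape == p0.shape == p1.shape == chroms.shape):
        raise ValueError("offspring, parent haplotypes and chromosome index are misaligned")
    if off.size == 0:
        raise ValueError("empty marker index")
    return pd.DataFrame(_tile_arrays(off, p0, p1, chroms, cfg))


def _refine_breakpoint(
    lo: int, hi: int, a: int, b: int, off: np.ndarray, p0: np.ndarray, p1: np.ndarray
) -> int:
    """Split index in [lo, hi) separating segment a from segment b.

    Maximizes total agreement (markers before the split matching haplotype
    ``a`` plus markers from the split on matching ``b``) over
    parent-heterozygous markers; equivalently the first argmax of the
    cumulative agreement difference, which is where it changes sign for a
    clean crossover.
    """
    pa = p0[lo:hi] if a == 0 else p1[lo:hi]
    pb = p0[lo:hi] if b == 0 else p1[lo:hi]
    o = off[lo:hi]
    informative = (pa != pb) & (pa != MISSING) & (pb != MISSING) & (o != MISSING)
    s = np.where(informative, (o == pa).astype(int) - (o == pb).astype(int), 0)
    prefix = np.concatenate([[0], np.cumsum(s)])
    return lo + int(np.argmax(prefix))


def _rescue_interior_segments(
    marker_assign: np.ndarray,
    lo: int,
    hi: int,
    chrom: int,
    off: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    cfg: TileConfig,
    bp_rows: list,
) -> None:
    """Recover double crossovers hidden inside assigned segments.

    A crossover pair closer together than a tile leaves both flanking
    tiles assigned to the same haplotype, so the interior segment is
    invisible to tile-level matching.  Within every constant-assignment
    run, the best interior interval favouring the other haplotype (maximum
    subarray of the per-marker agreement difference over
    parent-heterozygous markers) is flipped when it carries enough nearly
    pure evidence, emitting a breakpoint at each end.  Iterates until no
    run changes.
    """
    informative = (p0 != p1) & (p0 != MISSING) & (p1 != MISSING) & (off != MISSING)
    for _ in range(4):  # nested interior segments are vanishingly rare
        changed = False
        i = lo
        while i < hi:
            a = marker_assign[i]
            j = i
            while j < hi and marker_assign[j] == a:
                j += 1
            if a != AMBIGUOUS:
                b = 1 - a
                pb = p1 if b == 1 else p0
                idx = np.flatnonzero(informative[i:j]) + i
                if idx.size:
                    s = np.where(off[idx] == pb[idx], 1, -1)
                    best, best_lo, best_hi = 0, -1, -1
                    run, start = 0, 0
                    for t in range(s.size):
                        if run <= 0:
                            run, start = 0, t
                        run += s[t]
                        if run > best:
                            best, best_lo, best_hi = run, start, t
                    if best >= cfg.rescue_min_evidence:
                        seg = s[best_lo : best_hi + 1]
                        purity = (seg == 1).sum() / seg.size
                        if purity >= cfg.rescue_min_purity:
                            flip_lo, flip_hi = int(idx[best_lo]), int(idx[best_hi])
                            marker_assign[flip_lo : flip_hi + 1] = b
                            bp_rows.append((chrom, max(lo, flip_lo - 1), flip_lo, int(a), int(b)))
                            bp_rows.append((chrom, flip_hi, min(flip_hi + 1, hi - 1), int(b), int(a)))
                            changed = True
            i = j
        if not changed:
            break


def _resolve_arrays(
    tiles: dict[str, np.ndarray],
    off: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    cfg: TileConfig,
) -> tuple[np.ndarray, list]:
    """Core of resolve_assignments, operating on tile arrays."""
    n_markers = off.size
    marker_assign = np.full(n_markers, AMBIGUOUS, dtype=np.int8)
    bp_rows: list = []
    t_chrom = tiles["chrom"]
    scores = np.column_stack([tiles["score0"], tiles["score1"]])

    for chrom, tsl in _chrom_slices(t_chrom):
        assign = tiles["assign"][tsl].copy()
        starts = tiles["start"][tsl]
        ends = tiles["end"][tsl]
        sc = scores[tsl]
        k = assign.size

        if (assign == AMBIGUOUS).all():
            continue

        # smoothing: revert isolated weak single-tile switches
        if cfg.smoothing:
            for i in range(1, k - 1):
                a_prev, a_next, b = assign[i - 1], assign[i + 1], assign[i]
                if b == AMBIGUOUS or a_prev == AMBIGUOUS or a_prev != a_next or b == a_prev:
                    continue
                if sc[i, b] - sc[i, a_prev] < cfg.smoothing_margin:
                    assign[i] = a_prev

        # run-length fill of ambiguous tiles
        assigned_idx = np.flatnonzero(assign != AMBIGUOUS)
        first, last = assigned_idx[0], assigned_idx[-1]
        assign[:first] = assign[first]
        assign[last + 1 :] = assign[last]
        i = 0
        while i < k:
            if assign[i] == AMBIGUOUS:
                j = i
                while assign[j] == AMBIGUOUS:
                    j += 1
                if assign[i - 1] == assign[j]:
                    assign[i:j] = assign[j]
                i = j
            else:
                i += 1

        # default per-marker assignment from tiles, then refine switches
        for t in range(k):
            if assign[t] != AMBIGUOUS:
                marker_assign[starts[t] : ends[t]] = assign[t]

        current = None
        segment_last = None  # last tile index of the current segment
        for t in range(k):
            if assign[t] == AMBIGUOUS:
                continue
            if current is None or assign[t] == current:
                current, segment_last = assign[t], t
                continue
            lo, hi = int(starts[segment_last]), int(ends[t])
            split = _refine_breakpoint(lo, hi, int(current), int(assign[t]), off, p0, p1)
            marker_assign[lo:split] = current
            marker_assign[split:hi] = assign[t]
            bp_rows.append(
                (int(chrom), max(lo, split - 1), min(split, n_markers - 1), int(current), int(assign[t]))
            )
            current, segment_last = assign[t], t

        if cfg.rescue_double_crossovers:
            _rescue_interior_segments(
                marker_assign, int(starts[0]), int(ends[-1]), int(chrom), off, p0, p1, cfg, bp_rows
            )

    return marker_assign, bp_rows


def resolve_assignments(
    tiles: pd.DataFrame,
    offspring_hap: np.ndarray,
    parent_haps: np.ndarray,
    cfg: TileConfig | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Smoothed per-marker haplotype assignment and crossover breakpoints.

    Ambiguous tiles flanked by agreeing assignments inherit that
    assignment (run-length fill; chromosome-leading/trailing runs take the
    nearest assigned tile).  With smoothing on, an isolated single-tile
    switch whose score margin is below ``smoothing_margin`` is reverted.
    Every retained switch is refined to a marker interval inside the
    flanking tile pair (plus any ambiguous tiles between them) where the
    cumulative agreement difference between the two parental haplotypes
    turns, and is emitted as a half-open breakpoint interval
    [last marker of the old segment, first marker of the new segment).
    A chromosome whose tiles are all ambiguous stays entirely unassigned.
    """
    cfg = cfg or TileConfig()
    tile_arrays = {col: tiles[col].to_numpy() for col in tiles.columns}
    off = np.asarray(offspring_hap)
    p0, p1 = np.asarray(parent_haps[0]), np.asarray(parent_haps[1])
    marker_assign, bp_rows = _resolve_arrays(tile_arrays, off, p0, p1, cfg)
    return marker_assign, pd.DataFrame(bp_rows, columns=_BP_COLUMNS)


def extract_transmitted(
    marker_assign: np.ndarray,
    parent_haps: np.ndarray,
    offspring_hap: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Transmitted / non-transmitted allele vectors from a resolved assignment.

    The assigned parental haplotype's alleles are the transmitted vector
    and the other haplotype's alleles the non-transmitted vector;
    unassigned markers are missing in both.  A Mendelian conflict — the
    offspring carries an allele absent from the parent (parent homozygous
    for the other allele) at an assigned marker — is counted and the site
    set to missing in both vectors.  Conflicts are data, not exceptions.
    """
    m = marker_assign.size
    cols = np.arange(m)
    p0, p1 = np.asarray(parent_haps[0]), np.asarray(parent_haps[1])
    stacked = np.stack([p0, p1])
    assigned = marker_assign != AMBIGUOUS
    safe = np.where(assigned, marker_assign, 0)
    transmitted = np.where(assigned, stacked[safe, cols], MISSING).astype(np.int8)
    non_transmitted = np.where(assigned, stacked[1 - safe, cols], MISSING).astype(np.int8)

    conflict = (
        assigned
        & (offspring_hap != MISSING)
        & (p0 != MISSING)
        & (p1 != MISSING)
        & (p0 == p1)
        & (offspring_hap != p0)
    )
    transmitted[conflict] = MISSING
    non_transmitted[conflict] = MISSING
    return transmitted, non_transmitted, int(conflict.sum())


def _infer_duo_fast(
    off: np.ndarray, parent_haps: np.ndarray, chroms: np.ndarray, cfg: TileConfig
) -> tuple[np.ndarray, np.ndarray, list, int, float]:
    p0, p1 = np.asarray(parent_haps[0]), np.asarray(parent_haps[1])
    tiles = _tile_arrays(off, p0, p1, chroms, cfg)
    marker_assign, bp_rows = _resolve_arrays(tiles, off, p0, p1, cfg)
    transmitted, non_transmitted, n_conflicts = extract_transmitted(marker_assign, parent_haps, off)
    return (
        transmitted,
        non_transmitted,
        bp_rows,
        n_conflicts,
        float(np.mean(marker_assign == AMBIGUOUS)),
    )


def infer_duo(
    offspring_hap: np.ndarray,
    parent_haps: np.ndarray,
    chroms: np.ndarray,
    cfg: TileConfig | None = None,
) -> DuoResult:
    """Full inference for one offspring/parent duo."""
    cfg = cfg or TileConfig()
    tiles = match_tiles(offspring_hap, parent_haps, chroms, cfg)
    marker_assign, breakpoints = resolve_assignments(tiles, offspring_hap, parent_haps, cfg)
    transmitted, non_transmitted, n_conflicts = extract_transmitted(
        marker_assign, parent_haps, offspring_hap
    )
    return DuoResult(
        transmitted=transmitted,
        non_transmitted=non_transmitted,
        tiles=tiles,
        marker_assign=marker_assign,
        breakpoints=breakpoints,
        n_conflicts=n_conflicts,
        ambiguous_fraction=float(np.mean(marker_assign == AMBIGUOUS)),
    )


def infer_cohort(
    panel: HaplotypePanel,
    pedigree: pd.DataFrame,
    cfg: TileConfig | None = None,
) -> TransmissionResult:
    """Run duo inference for every offspring and genotyped parent.

    Offspring haplotype 0 is matched against the father and haplotype 1
    against the mother (pedigree-phased convention).  For an ungenotyped
    parent the transmitted vector is the offspring's own corresponding
    haplotype and the non-transmitted vector is entirely missing.
    """
    cfg = cfg or TileConfig()
    chroms = panel.markers["chrom"].to_numpy()
    n_off = len(pedigree)
    m = panel.n_markers
    t_pat = np.full((n_off, m), MISSING, dtype=np.int8)
    nt_pat = np.full((n_off, m), MISSING, dtype=np.int8)
    t_mat = np.full((n_off, m), MISSING, dtype=np.int8)
    nt_mat = np.full((n_off, m), MISSING, dtype=np.int8)
    bp_records: list = []
    qc_rows = []

    for k, row in enumerate(pedigree.itertuples(index=False)):
        off = panel.sample_haps(row.iid)
        for parent_label, parent_id, hap_idx in (
            ("pat", row.father_id, 0),
            ("mat", row.mother_id, 1),
        ):
            t_arr = t_pat if parent_label == "pat" else t_mat
            nt_arr = nt_pat if parent_label == "pat" else nt_mat
            if parent_id is not None and not pd.isna(parent_id) and parent_id in panel:
                transmitted, non_transmitted, bp_rows, n_conflicts, ambig = _infer_duo_fast(
                    off[hap_idx], panel.sample_haps(parent_id), chroms, cfg
                )
                t_arr[k] = transmitted
                nt_arr[k] = non_transmitted
                bp_records.extend((row.iid, parent_label, *bp) for bp in bp_rows)
                qc_rows.append((row.iid, parent_label, n_conflicts, ambig))
            else:
                t_arr[k] = off[hap_idx]

    breakpoints = pd.DataFrame(bp_records, columns=["offspring", "parent", *_BP_COLUMNS])
    qc = pd.DataFrame(qc_rows, columns=["offspring", "parent", "n_conflicts", "ambiguous_fraction"])
    return TransmissionResult(
        offspring=list(pedigree["iid"]),
        t_pat=t_pat,
        nt_pat=nt_pat,
        t_mat=t_mat,
        nt_mat=nt_mat,
        breakpoints=breakpoints,
        qc=qc,
        chroms=chroms,
        tile_config=cfg,
    )


def evaluate_concordance(result: TransmissionResult, truth: TruthRecord) -> dict:
    """Concordance of inferred non-transmitted alleles against ground truth.

    Returns the fraction of non-missing inferred non-transmitted alleles
    equal to the simulator's truth, pooled over both parents and per
    parent, plus the breakpoint localization error distribution (in
    markers, for offspring/parent/chromosome combinations where the
    inferred and true switch counts agree).
    """
    if result.offspring != truth.offspring:
        raise ValueError("transmission result and truth cover different offspring")

    def side_concordance(inferred: np.ndarray, true: np.ndarray) -> tuple[int, int]:
        mask = inferred != MISSING
        return int((inferred[mask] == true[mask]).sum()), int(mask.sum())

    hit_pat, n_pat = side_concordance(result.nt_pat, truth.nt_pat)
    hit_mat, n_mat = side_concordance(result.nt_mat, truth.nt_mat)

    errors: list[int] = []
    if len(result.breakpoints) and result.chroms is not None:
        chroms = np.asarray(result.chroms)
        true_switches: dict[tuple[str, str], np.ndarray] = {}
        for label, origin in (("pat", truth.origin_pat), ("mat", truth.origin_mat)):
            # a true switch between markers c and c+1 is recorded as the
            # first marker of the new segment; switches coinciding with a
            # chromosome boundary are not real crossovers
            switch_rows, switch_cols = np.nonzero(np.diff(origin, axis=1) != 0)
            visible = chroms[switch_cols] == chroms[switch_cols + 1]
            switch_rows, switch_cols = switch_rows[visible], switch_cols[visible]
            for k, iid in enumerate(truth.offspring):
                true_switches[(iid, label)] = switch_cols[switch_rows == k] + 1
        for (iid, parent, chrom), sub in result.breakpoints.groupby(
            ["offspring", "parent", "chrom"]
        ):
            tp = true_switches.get((iid, parent), np.array([], dtype=int))
            tp = tp[chroms[tp] == chrom]
            inf_pos = np.sort(sub["right_marker"].to_numpy())
            if len(tp) == len(inf_pos) and len(tp):
                errors.extend(np.abs(np.sort(tp) - inf_pos).tolist())

    err = np.asarray(errors, dtype=float)
    total_hits = hit_pat + hit_mat
    total_n = n_pat + n_mat
    return {
        "concordance": total_hits / total_n if total_n else float("nan"),
        "concordance_pat": hit_pat / n_pat if n_pat else float("nan"),
        "concordance_mat": hit_mat / n_mat if n_mat else float("nan"),
        "n_sites": total_n,
        "breakpoint_errors": err,
        "breakpoint_error_mean": float(err.mean()) if err.size else float("nan"),
        "breakpoint_error_median": float(np.median(err)) if err.size else float("nan"),
    }
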