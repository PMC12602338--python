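"""Score arithmetic, conservation, imputation, standardization, PC residuals."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from gnurture.famsim import MISSING, SimConfig
from gnurture.pipeline import (
    build_score_table,
    infer_transmission,
    simulate_cohort,
)
from gnurture.scores import (
    ScoreTable,
    align_weights,
    impute_missing_nt,
    residualize_on_pcs,
    score_haplotype,
    standardize_scores,
)


def _weight_frame(ids, eas, oas, ws):
    return pd.DataFrame(
        {"ID": ids, "CHROM": 1, "BP": range(1, len(ids) + 1), "EA": eas, "OA": oas, "WEIGHT": ws}
    )


def _marker_frame(ids):
    return pd.DataFrame(
        {
            "chrom": 1,
            "pos": range(1, len(ids) + 1),
            "id": ids,
            "ref": "A",
            "alt": "G",
            "effect_allele": "G",
        }
    )


def test_score_haplotype_hand_arithmetic():
    w = np.array([0.1, -0.2, 0.3])
    hap = np.array([1, 1, 0], dtype=np.int8)
    score, n = score_haplotype(hap, w)
    assert score == pytest.approx(-0.1)
    assert n == 3


def test_score_haplotype_skips_missing_sites():
    w = np.array([0.1, -0.2, 0.3])
    hap = np.array([1, MISSING, 1], dtype=np.int8)
    score, n = score_haplotype(hap, w)
    assert score == pytest.approx(0.4)
    assert n == 2


def test_score_haplotype_zero_weights_and_zero_overlap():
    assert score_haplotype(np.ones(3, np.int8), np.zeros(3))[0] == 0.0
    with pytest.raises(ValueError):
        score_haplotype(np.full(3, MISSING, np.int8), np.ones(3))


def test_align_weights_flips_sign_for_swapped_effect_allele():
    markers = _marker_frame(["a", "b", "c"])
    weights = _weight_frame(["a", "b", "d"], ["G", "A", "G"], ["A", "G", "A"], [0.5, 0.25, 1.0])
    w = align_weights(markers, weights)
    assert w[0] == 0.5  # EA matches the panel effect allele
    assert w[1] == -0.25  # EA is the other allele: sign flipped
    assert np.isnan(w[2])  # no such variant in the panel


def test_align_weights_skips_mismatching_allele_pairs():
    markers = _marker_frame(["a", "b"])
    weights = _weight_frame(["a", "b"], ["G", "C"], ["A", "T"], [0.5, 0.7])
    with pytest.warns(UserWarning, match="allele pairs"):
        w = align_weights(markers, weights)
    assert w[0] == 0.5 and np.isnan(w[1])


@given(
    st.integers(min_value=2, max_value=30),
    st.integers(min_value=0, max_value=10_000),
)
def test_score_is_additive_over_disjoint_marker_sets(n, seed):
    """score(w, a+b masks) decomposes additively over disjoint marker sets."""
    r = np.random.default_rng(seed)
    w = r.normal(size=n)
    hap = r.integers(0, 2, size=n).astype(np.int8)
    mask = r.random(n) < 0.5
    left = hap.copy()
    left[~mask] = MISSING
    right = hap.copy()
    right[mask] = MISSING
    total = score_haplotype(hap, w)[0]
    parts = 0.0
    for piece in (left, right):
        if (piece != MISSING).any():
            parts += score_haplotype(piece, w)[0]
    assert total == pytest.approx(parts, abs=1e-12)


def test_trio_conservation_is_exact_on_error_free_data(mixed_cohort, mixed_scores):
    """PGS-T + PGS-NT equals the parents' diploid PGS sum on error-free trios."""
    t = mixed_scores.table
    trios = t[t["design"] == "trio"]
    ped = mixed_cohort.pedigree.set_index("iid")
    fs = ped.loc[trios["iid"], "father_id"].map(mixed_scores.parent_pgs).to_numpy()
    ms = ped.loc[trios["iid"], "mother_id"].map(mixed_scores.parent_pgs).to_numpy()
    lhs = (trios["pgs_t"] + trios["pgs_nt"]).to_numpy()
    assert np.allclose(lhs, fs + ms, rtol=1e-9, atol=0)


def test_own_pgs_equals_pgs_t_when_transmitted_vectors_complete():
    # without recombination the transmitted vectors reconstruct the
    # offspring's own haplotypes exactly, so own PGS == PGS-T by definition
    config = SimConfig(
        n_trios=25,
        n_father_pairs=0,
        n_mother_pairs=0,
        n_markers=600,
        n_chromosomes=2,
        map_length_cM_per_chrom=0.0,
        seed=53,
    )
    bundle = simulate_cohort(config)
    t = build_score_table(bundle, infer_transmission(bundle)).table
    assert np.allclose(t["own_pgs"], t["pgs_t"], atol=1e-12)
    assert np.allclose(t["own_pgs"], t["s_t_pat"] + t["s_t_mat"], atol=1e-12)


def test_trio_conservation_under_phase_errors_stays_tight():
    """With 0.5% phase errors, transmitted/non-transmitted swaps cancel in
    the sum, so conservation over co-observed markers stays exact and the
    weight mass lost to conflict-masked sites is below 1%."""
    config = SimConfig(
        n_trios=40,
        n_father_pairs=0,
        n_mother_pairs=0,
        n_markers=3000,
        n_chromosomes=3,
        phase_error_rate=0.005,
        seed=51,
    )
    bundle = simulate_cohort(config)
    transmission = infer_transmission(bundle)
    w = np.nan_to_num(align_weights(bundle.markers, bundle.weights))
    ped = bundle.pedigree.set_index("iid")
    for k, iid in enumerate(transmission.offspring):
        fa = bundle.founders.sample_haps(ped.loc[iid, "father_id"]).sum(axis=0)
        observed = transmission.t_pat[k] != MISSING
        lhs = (transmission.t_pat[k] + transmission.nt_pat[k])[observed] @ w[observed]
        rhs = fa[observed] @ w[observed]
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-12)
        masked_mass = np.abs(w[~observed]).sum() / np.abs(w).sum()
        assert masked_mass < 0.01


def _toy_score_table():
    table = pd.DataFrame(
        {
            "iid": ["o1", "o2", "o3"],
            "family_id": ["f1", "f2", "f3"],
            "design": ["trio", "father_pair", "mother_pair"],
            "own_pgs": [0.3, 0.1, 0.2],
            "n_markers": [4, 4, 4],
            "s_t_pat": [0.1, 0.05, 0.12],
            "s_nt_pat": [0.2, 0.15, np.nan],
            "s_t_mat": [0.2, 0.05, 0.08],
            "s_nt_mat": [0.05, np.nan, 0.3],
            "father_pgs": [0.5, 0.2, np.nan],
            "mother_pgs": [0.3, np.nan, 0.6],
        }
    )
    table["pgs_t"] = table["s_t_pat"] + table["s_t_mat"]
    table["pgs_nt"] = table["s_nt_pat"] + table["s_nt_mat"]
    table["imputed_nt"] = False
    parent_pgs = pd.Series({"F1": 0.2, "M1": 0.6})
    return ScoreTable(table=table, parent_pgs=parent_pgs)


def test_imputation_uses_half_observed_parent_pgs():
    # missing component = the observed parent's average haplotype score,
    # i.e. half that parent's diploid PGS
    st_ = impute_missing_nt(_toy_score_table())
    t = st_.table
    assert t.loc[1, "s_nt_mat"] == pytest.approx(0.1)  # father pair: 0.5 * 0.2
    assert t.loc[2, "s_nt_pat"] == pytest.approx(0.3)  # mother pair: 0.5 * 0.6
    assert t.loc[1, "pgs_nt"] == pytest.approx(0.15 + 0.1)
    assert t["imputed_nt"].tolist() == [False, True, True]


def test_cohort_mean_imputation_uses_half_mean_parent_pgs():
    # genotyped parents have diploid PGS 0.2 and 0.6 -> imputed component
    # 0.5 * mean = 0.2 for every pair offspring
    st_ = impute_missing_nt(_toy_score_table(), method="cohort_mean")
    t = st_.table
    assert t.loc[1, "s_nt_mat"] == pytest.approx(0.2)
    assert t.loc[2, "s_nt_pat"] == pytest.approx(0.2)
    with pytest.raises(ValueError, match="method"):
        impute_missing_nt(_toy_score_table(), method="nope")


def test_imputation_is_noop_for_trios():
    before = _toy_score_table()
    after = impute_missing_nt(before)
    row0 = after.table.iloc[0]
    assert row0["pgs_nt"] == pytest.approx(before.table.iloc[0]["pgs_nt"])
    assert not row0["imputed_nt"]


def test_zero_mean_parent_pgs_imputes_zero_component():
    st_ = _toy_score_table()
    st_.parent_pgs = pd.Series({"F1": 0.4, "M1": -0.4})
    out = impute_missing_nt(st_, method="cohort_mean")
    assert out.table.loc[1, "s_nt_mat"] == pytest.approx(0.0)
    assert out.table.loc[1, "pgs_nt"] == pytest.approx(0.15)


def test_standardization_uses_pgs_t_scale():
    st_ = impute_missing_nt(_toy_score_table())
    out = standardize_scores(st_)
    t = out.table
    assert t["z_pgs_t"].mean() == pytest.approx(0.0, abs=1e-12)
    assert t["z_pgs_t"].std(ddof=0) == pytest.approx(1.0)
    # PGS-NT is scaled by PGS-T's SD, not its own
    sd_t = st_.table["pgs_t"].std(ddof=0)
    expected = (st_.table["pgs_nt"] - st_.table["pgs_t"].mean()) / sd_t
    assert np.allclose(t["z_pgs_nt"], expected)


def test_standardization_is_location_invariant():
    a = impute_missing_nt(_toy_score_table())
    b = impute_missing_nt(_toy_score_table())
    for col in ("s_t_pat", "s_t_mat", "s_nt_pat", "s_nt_mat", "pgs_t", "pgs_nt", "own_pgs"):
        b.table[col] = b.table[col] + 5.0
    za, zb = standardize_scores(a).table, standardize_scores(b).table
    assert np.allclose(za["z_pgs_t"], zb["z_pgs_t"])
    assert np.allclose(za["z_pgs_nt"], zb["z_pgs_nt"])


def test_standardization_rejects_constant_scores():
    st_ = _toy_score_table()
    st_.table["pgs_t"] = 1.0
    with pytest.raises(ValueError, match="variance"):
        standardize_scores(st_)


def test_imputation_preserves_null_cohort_expectation():
    """Under null effects and random mating, the mean imputed PGS-NT matches
    the trio PGS-NT mean within sampling error."""
    config = SimConfig(
        n_trios=400,
        n_father_pairs=200,
        n_mother_pairs=200,
        n_markers=500,
        n_chromosomes=1,
        beta_T=0.0,
        beta_NT=0.0,
        spousal_corr=0.0,
        sibling_rate=0.0,
        seed=52,
    )
    bundle = simulate_cohort(config)
    scores = build_score_table(bundle, infer_transmission(bundle), standardize=False)
    t = scores.table
    trio_mean = t.loc[t["design"] == "trio", "pgs_nt"].mean()
    pair_mean = t.loc[t["design"] != "trio", "pgs_nt"].mean()
    pooled_sd = t["pgs_nt"].std()
    assert abs(pair_mean - trio_mean) < 4 * pooled_sd / np.sqrt(400)


def test_residuals_are_orthogonal_to_pcs(rng):
    n = 1000
    pcs = rng.standard_normal((n, 10))
    score = rng.standard_normal(n)
    resid = residualize_on_pcs(score, pcs)
    assert np.abs(pcs.T @ resid).max() < 1e-8
    # matches the least-squares residual from an independent implementation
    ols = sm.OLS(score, sm.add_constant(pcs)).fit()
    assert np.allclose(resid, ols.resid, atol=1e-10)


def test_exact_linear_combination_residualizes_to_zero(rng):
    pcs = rng.standard_normal((200, 10))
    score = pcs @ rng.standard_normal(10) + 2.0
    resid = residualize_on_pcs(score, pcs)
    assert np.abs(resid).max() < 1e-8


def test_orthogonal_pcs_leave_centered_score(rng):
    n = 400
    score = rng.standard_normal(n)
    # build PCs orthogonal to the score and to the intercept
    q, _ = np.linalg.qr(np.column_stack([np.ones(n), score, rng.standard_normal((n, 3))]))
    pcs = q[:, 2:]
    resid = residualize_on_pcs(score, pcs)
    assert np.allclose(resid, score - score.mean(), atol=1e-10)


def test_collinear_pcs_are_dropped_with_warning(rng):
    pcs = rng.standard_normal((100, 3))
    pcs = np.column_stack([pcs, pcs[:, 0] * 2.0])
    with pytest.warns(UserWarning, match="collinear"):
        resid = residualize_on_pcs(rng.standard_normal(100), pcs)
    assert np.isfinite(resid).all()
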