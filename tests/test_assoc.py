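"""Mixed-model association stage: oracles, calibration, FDR, parent-of-origin."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st

from gnurture.assoc import (
    fdr_adjust,
    fit_mixed_linear,
    fit_mixed_logistic,
    parent_of_origin_fit,
    spousal_correlation,
)
from gnurture.famsim import SimConfig
from gnurture.glmm import fit_logistic_gh
from gnurture.pipeline import replicate_frame, simulate_cohort


def _singleton_frame(rng, n=4000, binary=False):
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    age = rng.standard_normal(n)
    sex = (rng.random(n) < 0.5).astype(float)
    arr = (rng.random(n) < 0.5).astype(float)
    eta = 0.3 * x1 - 0.1 * x2 + 0.05 * age
    if binary:
        y = (rng.random(n) < 1 / (1 + np.exp(-(eta - 1.0)))).astype(float)
    else:
        y = eta + rng.standard_normal(n)
    return pd.DataFrame(
        {
            "y": y,
            "z_pgs_t": x1,
            "z_pgs_nt": x2,
            "age_z": age,
            "sex_code": sex,
            "array_code": arr,
            "family_id": [f"f{i}" for i in range(n)],
        }
    )


def test_linear_fit_matches_ols_without_family_structure(rng):
    """All-singleton families: the mixed fit collapses to ordinary least
    squares within 1e-4 on every fixed effect."""
    df = _singleton_frame(rng)
    results = fit_mixed_linear(df, "y", ["z_pgs_t", "z_pgs_nt"])
    X = sm.add_constant(df[["z_pgs_t", "z_pgs_nt", "age_z", "sex_code", "array_code"]])
    ols = sm.OLS(df["y"], X).fit()
    for r in results:
        assert r.estimate == pytest.approx(ols.params[r.predictor], abs=1e-4)
        assert r.se == pytest.approx(ols.bse[r.predictor], abs=1e-4)


def test_logistic_fit_matches_glm_without_family_structure(rng):
    df = _singleton_frame(rng, n=5000, binary=True)
    results = fit_mixed_logistic(df, "y", ["z_pgs_t", "z_pgs_nt"])
    X = sm.add_constant(df[["z_pgs_t", "z_pgs_nt", "age_z", "sex_code", "array_code"]])
    glm = sm.GLM(df["y"], X, family=sm.families.Binomial()).fit()
    for r in results:
        assert r.estimate == pytest.approx(glm.params[r.predictor], abs=1e-3)
        assert r.odds_ratio == pytest.approx(np.exp(glm.params[r.predictor]), rel=1e-3)


def test_gh_logistic_agrees_with_lme4_glmer(tmp_path):
    """Coefficients, SEs and the random-intercept SD match lme4::glmer with
    adaptive quadrature (nAGQ = 25) to three decimals on clustered data."""
    rng = np.random.default_rng(42)
    n_fam, fam_size = 200, 3
    n = n_fam * fam_size
    fam = np.repeat(np.arange(n_fam), fam_size)
    x1 = rng.standard_normal(n)
    x2 = rng.standard_normal(n)
    b = 0.8 * rng.standard_normal(n_fam)
    eta = -0.5 + 0.6 * x1 - 0.3 * x2 + b[fam]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)

    X = np.column_stack([np.ones(n), x1, x2])
    fit = fit_logistic_gh(y, X, fam)

    csv = tmp_path / "d.csv"
    pd.DataFrame({"y": y, "x1": x1, "x2": x2, "fam": fam}).to_csv(csv, index=False)
    rscript = textwrap.dedent(
        f"""
        d <- read.csv("{csv}")
        suppressMessages(library(lme4))
        m <- glmer(y ~ x1 + x2 + (1|fam), data=d, family=binomial, nAGQ=25)
        co <- summary(m)$coefficients
        cat(co[,1], co[,2], sqrt(unlist(VarCorr(m))), sep="\\n")
        """
    )
    proc = subprocess.run(
        ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
    )
    if proc.returncode != 0:
        pytest.skip(f"Rscript/lme4 unavailable: {proc.stderr[-200:]}")
    vals = [float(v) for v in proc.stdout.split()]
    r_params, r_se, r_sd = np.array(vals[:3]), np.array(vals[3:6]), vals[6]
    assert np.allclose(fit.params, r_params, atol=1e-3)
    assert np.allclose(fit.bse, r_se, atol=1e-3)
    assert np.sqrt(fit.re_var) == pytest.approx(r_sd, abs=1e-3)


def test_mixed_models_recover_family_variance():
    config = SimConfig(
        n_trios=800,
        n_father_pairs=0,
        n_mother_pairs=0,
        n_markers=300,
        n_chromosomes=1,
        beta_T=0.15,
        beta_NT=0.0,
        family_var=0.3,
        sibling_rate=0.6,
        prevalence_per_outcome={"case": 0.3},
        n_waves=1,
        wave_missingness=0.0,
        seed=61,
    )
    df = replicate_frame(config)
    lin = fit_mixed_linear(df, "trait", ["z_pgs_t", "z_pgs_nt"])
    assert lin[0].model == "mixed_linear"
    assert 0.1 < lin[0].re_var < 0.6
    assert lin[0].estimate == pytest.approx(0.15, abs=3 * lin[0].se)
    log = fit_mixed_logistic(df, "case_w1", ["z_pgs_t", "z_pgs_nt"])
    assert log[0].model == "mixed_logistic"
    assert log[0].re_var > 0.0
    assert log[0].odds_ratio > 1.0


def test_model_fits_are_deterministic(rng):
    df = _singleton_frame(rng, n=1500, binary=True)
    a = fit_mixed_logistic(df, "y", ["z_pgs_t", "z_pgs_nt"])
    b = fit_mixed_logistic(df, "y", ["z_pgs_t", "z_pgs_nt"])
    assert [r.estimate for r in a] == [r.estimate for r in b]
    assert [r.se for r in a] == [r.se for r in b]


def test_power_increases_with_nurture_effect():
    """Mean PGS-NT Wald statistic grows with the simulated beta_NT."""
    mean_abs_z = []
    for beta_nt in (0.0, 0.05, 0.1):
        zs = []
        for rep in range(8):
            config = SimConfig(
                n_trios=1200,
                n_father_pairs=0,
                n_mother_pairs=0,
                n_markers=300,
                n_chromosomes=1,
                beta_T=0.1,
                beta_NT=beta_nt,
                sibling_rate=0.0,
                prevalence_per_outcome={"case": 0.3},
                n_waves=1,
                wave_missingness=0.0,
                seed=700 + rep,
            )
            df = replicate_frame(config)
            r = fit_mixed_linear(df, "trait", ["z_pgs_t", "z_pgs_nt"])[1]
            zs.append(abs(r.estimate / r.se))
        mean_abs_z.append(np.mean(zs))
    assert mean_abs_z[0] < mean_abs_z[1] < mean_abs_z[2]


def test_parent_of_origin_recovers_asymmetric_nurture():
    """A maternal-only indirect effect lands in the maternal model while the
    paternal model stays null."""
    config = SimConfig(
        n_trios=3000,
        n_father_pairs=0,
        n_mother_pairs=0,
        n_markers=400,
        n_chromosomes=1,
        beta_T=0.0,
        beta_NT=0.0,
        sibling_rate=0.0,
        prevalence_per_outcome={"case": 0.3},
        n_waves=1,
        wave_missingness=0.0,
        seed=62,
    )
    bundle = simulate_cohort(config)
    df = replicate_frame(config)
    rng = np.random.default_rng(63)
    z_nt_mat = df["z_s_nt_mat"].to_numpy()
    df["trait"] = 0.1 * z_nt_mat + rng.standard_normal(len(df))
    mat = parent_of_origin_fit(df, "trait", "continuous", "mat")
    pat = parent_of_origin_fit(df, "trait", "continuous", "pat")
    mat_nt = next(r for r in mat if "nt" in r.predictor)
    pat_nt = next(r for r in pat if "nt" in r.predictor)
    assert mat_nt.ci_low < 0.1 < mat_nt.ci_high
    assert pat_nt.ci_low < 0.0 < pat_nt.ci_high
    assert abs(mat_nt.estimate) > abs(pat_nt.estimate)


def test_parent_of_origin_symmetric_effects_agree():
    """Equal maternal and paternal contributions: the parent-of-origin
    estimates agree within twice their joint standard error."""
    config = SimConfig(
        n_trios=2500,
        n_father_pairs=0,
        n_mother_pairs=0,
        n_markers=400,
        n_chromosomes=1,
        beta_T=0.15,
        beta_NT=0.05,
        sibling_rate=0.0,
        prevalence_per_outcome={"case": 0.3},
        n_waves=1,
        wave_missingness=0.0,
        seed=65,
    )
    df = replicate_frame(config)
    mat = parent_of_origin_fit(df, "trait", "continuous", "mat")
    pat = parent_of_origin_fit(df, "trait", "continuous", "pat")
    for m, p in zip(mat, pat):
        joint_se = np.hypot(m.se, p.se)
        assert abs(m.estimate - p.estimate) < 2 * joint_se


def test_parent_of_origin_refuses_empty_design(mixed_scores):
    data = mixed_scores.table.copy()
    data = data[data["design"] == "mother_pair"]
    data["trait"] = 0.0
    data["age_z"] = 0.0
    data["sex_code"] = 0.0
    data["array_code"] = 0.0
    with pytest.raises(ValueError, match="fathers"):
        parent_of_origin_fit(data, "trait", "continuous", "pat")


def test_spousal_correlation_identical_vectors(rng):
    x = rng.standard_normal(50)
    r, (lo, hi) = spousal_correlation(x, x)
    assert r == pytest.approx(1.0)
    with pytest.raises(ValueError):
        spousal_correlation(np.ones(10), rng.standard_normal(10))


def test_spousal_correlation_null_sampling_distribution(rng):
    hits = 0
    for _ in range(40):
        r, _ = spousal_correlation(rng.standard_normal(2000), rng.standard_normal(2000))
        hits += abs(r) < 0.05
    assert hits >= 38  # >= 95% of replicates


def test_spousal_correlation_ci_covers_configured_target():
    from gnurture.pipeline import build_score_table, cohort_spousal_correlation, infer_transmission

    config = SimConfig(
        n_trios=1500,
        n_father_pairs=0,
        n_mother_pairs=0,
        n_markers=400,
        n_chromosomes=1,
        spousal_corr=0.5,
        sibling_rate=0.0,
        seed=64,
    )
    bundle = simulate_cohort(config)
    scores = build_score_table(bundle, infer_transmission(bundle))
    r, (lo, hi) = cohort_spousal_correlation(bundle, scores)
    assert lo < 0.5 < hi
    assert abs(r - 0.5) < 0.08


def _bh_reference(p):
    """Textbook step-up BH: q_i = min over j >= rank(i) of p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]),
    ],
)
def test_fdr_worked_examples(p, expected):
    assert np.allclose(fdr_adjust(p), expected)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_fdr_matches_reference_and_never_decreases(p):
    q = fdr_adjust(p)
    assert np.allclose(q, _bh_reference(p), atol=1e-12)
    assert (q >= np.asarray(p) - 1e-12).all()
    assert (q <= 1.0).all()


def test_fdr_rejects_invalid_pvalues():
    with pytest.raises(ValueError):
        fdr_adjust([0.5, 1.2])
    with pytest.raises(ValueError):
        fdr_adjust([-0.1])
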