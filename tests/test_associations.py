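import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from ctprop.associations import (AssociationError, AssociationResult,
                                 _ols_via_fwl, adjust_pvalues,
                                 marker_gene_models, mega_model,
                                 phenotype_battery, results_frame, sn_model,
                                 variance_explained)
from ctprop.simulate import (PATHOLOGIES, StudyDesign, StudySpec,
                             default_design, simulate_score_table)

CALIB_DESIGN = StudyDesign(studies=[
    StudySpec("a", ("r1",), 30, 30, 0),
    StudySpec("b", ("r1", "r2"), 20, 20, 0),
    StudySpec("c", ("r1",), 20, 20, 0),
])


# ---------------------------------------------------------------- FWL core

def test_fwl_matches_full_multiple_regression():
    rng = np.random.default_rng(0)
    n = 120
    covs = rng.normal(0, 1, (n, 3))
    x = rng.normal(0, 1, n) + 0.5 * covs[:, 0]
    y = 0.4 * x + covs @ np.array([0.2, -0.1, 0.3]) + rng.normal(0, 1, n)
    beta, se, p = _ols_via_fwl(y, x, covs)
    full = sm.OLS(y, sm.add_constant(np.column_stack([x, covs]))).fit()
    assert beta == pytest.approx(full.params[1], abs=1e-10)
    assert se == pytest.approx(full.bse[1], abs=1e-10)
    assert p == pytest.approx(full.pvalues[1], abs=1e-10)


def test_fwl_collinear_predictor_raises():
    rng = np.random.default_rng(1)
    covs = rng.normal(0, 1, (50, 2))
    with pytest.raises(AssociationError, match="collinear"):
        _ols_via_fwl(rng.normal(0, 1, 50), covs[:, 0] * 2.0, covs)


# ---------------------------------------------------------------- multiple testing

def _bh_oracle(p):
    """Independent step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_adjust_pvalues_matches_oracles():
    rng = np.random.default_rng(2)
    p = np.concatenate([rng.uniform(0, 1, 150), rng.uniform(0, 1e-3, 50)])
    results = [AssociationResult("c", "o", 0.0, 1.0, float(v), 10, 10)
               for v in p]
    adjust_pvalues(results)
    got_bonf = np.array([r.p_bonf for r in results])
    got_fdr = np.array([r.p_fdr for r in results])
    assert np.abs(got_bonf - np.minimum(p * len(p), 1.0)).max() < 1e-12
    assert np.abs(got_fdr - _bh_oracle(p)).max() < 1e-12
    # monotonicity: FDR-adjusted never below raw, never above Bonferroni
    assert (got_fdr >= p - 1e-12).all()
    assert (got_fdr <= got_bonf + 1e-12).all()


def test_adjust_pvalues_validation():
    with pytest.raises(AssociationError, match="empty"):
        adjust_pvalues([])
    bad = [AssociationResult("c", "o", 0.0, 1.0, 1.5, 10, 10)]
    with pytest.raises(AssociationError, match="outside"):
        adjust_pvalues(bad)


# ---------------------------------------------------------------- mega model

def test_mega_model_recovers_planted_effect():
    df = simulate_score_table(CALIB_DESIGN, effect=-0.8, seed=11)
    res = mega_model(df, "SST")
    assert res.beta < -0.4
    assert res.p < 0.01
    assert res.n_subjects == 140
    assert res.n_samples == 180  # study b contributes two regions


def test_mega_model_singleton_matches_ols():
    design = StudyDesign(studies=[StudySpec("a", ("r1",), 40, 40, 0),
                                  StudySpec("c", ("r1",), 30, 30, 0)])
    df = simulate_score_table(design, effect=-0.5, seed=5)
    res = mega_model(df, "SST")
    ols = smf.ols("score ~ ad + C(study) + age_at_death + sex", data=df).fit()
    assert res.model in ("lmm_singleton", "ols_fallback")
    assert res.beta == pytest.approx(float(ols.params["ad"]), abs=1e-3)


def test_mega_model_drops_other_group_rows():
    design = StudyDesign(studies=[StudySpec("a", ("r1",), 20, 20, 15)])
    df = simulate_score_table(design, effect=0.0, seed=6)
    res = mega_model(df, "SST")
    assert res.n_subjects == 40


def test_mega_model_empty_raises():
    df = simulate_score_table(CALIB_DESIGN, seed=7)
    df["ad"] = np.nan
    with pytest.raises(AssociationError, match="no case/control"):
        mega_model(df, "SST")


# ---------------------------------------------------------------- sn model

def test_sn_model_planted_effect():
    rng = np.random.default_rng(8)
    n = 120
    ad = np.repeat([0.0, 1.0], n // 2)
    df = pd.DataFrame({
        "snctp": 5.0 - 1.5 * ad + rng.normal(0, 1.0, n),
        "ad": ad,
        "dataset": np.tile(["d1", "d2", "d3"], n // 3),
        "age_at_death": rng.normal(85, 5, n),
        "sex": rng.integers(0, 2, n).astype(float),
        "pmi": rng.normal(8, 2, n),
        "subject_id": [f"s{i}" for i in range(n)],
    })
    res = sn_model(df, "SST")
    assert res.beta < -0.5
    assert res.p < 1e-6
    assert res.model == "ols"


# ---------------------------------------------------------------- battery

def _toy_derived(rng, n=300):
    d = pd.DataFrame({p: rng.normal(0, 1, n) for p in PATHOLOGIES},
                     index=[f"s{i}" for i in range(n)])
    d["age_at_death"] = rng.normal(85, 5, n)
    d["sex"] = rng.integers(0, 2, n).astype(float)
    d["pmi"] = rng.normal(8, 2, n)
    d["education"] = rng.normal(16, 3, n)
    d["age_baseline"] = rng.normal(78, 5, n)
    d["cognitive_slope"] = rng.normal(-0.05, 0.03, n)
    d["cognition_at_death"] = rng.normal(0, 1, n)
    d["residual_cognition"] = rng.normal(0, 1, n)
    return d


def test_battery_instantiates_full_grid(processed, derived):
    battery = phenotype_battery(processed["subj_rctp"], derived["cross"],
                                list(PATHOLOGIES))
    assert len(battery) == 266  # 19 subclasses x (11 pathologies + 3 cognitive)
    assert battery.p_fdr.notna().all()
    assert battery.p_bonf.between(0, 1).all()


def test_battery_planted_effect_recovered():
    rng = np.random.default_rng(9)
    d = _toy_derived(rng)
    rctp = pd.DataFrame({
        "SST": -0.6 * d["amyloid"] + rng.normal(0, 0.8, len(d)),
        "IT": rng.normal(0, 1, len(d)),
    }, index=d.index)
    out = phenotype_battery(rctp, d, list(PATHOLOGIES)).set_index(
        ["cell_type", "outcome"])
    planted = out.loc[("SST", "amyloid")]
    # true standardized beta: -0.6 / sqrt(0.36 + 0.64) = -0.6
    assert planted.beta == pytest.approx(-0.6, abs=0.12)
    assert planted.p_fdr < 1e-6
    null = out.loc[("IT", "tangles")]
    assert abs(null.beta) < 0.2


def test_battery_missing_outcome_shrinks_family():
    rng = np.random.default_rng(10)
    d = _toy_derived(rng).drop(columns=["cognitive_slope"])
    rctp = pd.DataFrame({"SST": rng.normal(0, 1, len(d))}, index=d.index)
    out = phenotype_battery(rctp, d, list(PATHOLOGIES))
    assert len(out) == 13  # 11 pathologies + 2 remaining cognitive outcomes


# ---------------------------------------------------------------- marker models

def test_marker_gene_models(cohort, processed):
    key, norm = next(iter(processed["normalized"].items()))
    meta = cohort["metadata"].loc[norm.log_expr.columns]
    markers = processed["markers"].markers["SST"][:5]
    out = marker_gene_models(norm, markers, meta)
    present = [g for g in markers if g in norm.log_expr.index]
    assert set(out.gene) == set(present)
    assert out.p_fdr.notna().all()
    with pytest.raises(AssociationError, match="no marker genes"):
        marker_gene_models(norm, ["absent_gene"], meta)


# ---------------------------------------------------------------- 0.632+ bootstrap

def test_variance_explained_nested_consistency():
    rng = np.random.default_rng(12)
    n = 200
    d = pd.DataFrame({
        "y": rng.normal(0, 1, n),
        "c1": rng.normal(0, 1, n),
        "c2": rng.normal(0, 1, n),
        "z": rng.normal(0, 1, n),
    })
    d["y"] = 0.5 * d["c1"] + rng.normal(0, 1, n)
    vp = variance_explained(d, "y", ["c1", "c2"], "z", n_boot=50, seed=0)
    assert vp.delta_r2 >= 0                      # apparent R2 never decreases
    assert vp.adj_delta_r2 <= vp.delta_r2 + 1e-12
    assert vp.adj_r2_baseline <= vp.r2_baseline + 1e-12
    assert vp.lrt_p > 0.001                      # pure-noise predictor
    assert vp.n == n and vp.n_boot == 50


def test_variance_explained_planted_predictor():
    rng = np.random.default_rng(13)
    n = 900
    c1 = rng.normal(0, 1, n)
    z = rng.normal(0, 1, n)
    y = np.sqrt(0.08) * c1 + np.sqrt(0.02) * z + rng.normal(0, np.sqrt(0.90), n)
    d = pd.DataFrame({"y": y, "c1": c1, "z": z})
    vp = variance_explained(d, "y", ["c1"], "z", n_boot=100, seed=1)
    assert vp.lrt_p < 1e-3
    assert vp.adj_delta_r2 == pytest.approx(0.02, abs=0.01)


def test_variance_explained_needs_enough_rows():
    d = pd.DataFrame({"y": [1.0, 2.0], "c": [0.0, 1.0], "z": [1.0, 0.0]})
    with pytest.raises(AssociationError, match="need n"):
        variance_explained(d, "y", ["c"], "z", n_boot=5)
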