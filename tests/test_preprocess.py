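import numpy as np
import pandas as pd
import pytest

from ctprop.preprocess import (CountMatrix, PreprocessError,
                               detect_outlier_samples, filter_genes, log2_cpm,
                               mds_embedding, normalized_log_expression,
                               observation_weights, preprocess_pipeline,
                               remove_technical, tmm_factors, winsorize_log2)


def _random_counts(rng, n_genes=60, n_samples=12, lam=50.0):
    counts = rng.poisson(lam, size=(n_genes, n_samples)).astype(float)
    return CountMatrix(
        pd.DataFrame(counts,
                     index=[f"g{i}" for i in range(n_genes)],
                     columns=[f"s{j}" for j in range(n_samples)]),
        dataset="fix",
    )


# ---------------------------------------------------------------- filtering

def test_filter_genes_matches_brute_force_median():
    rng = np.random.default_rng(3)
    c = _random_counts(rng, n_genes=200, n_samples=9, lam=16.0)
    kept = set(filter_genes(c, threshold=15.0).genes)
    # independent oracle: median as the middle order statistic
    expect = set()
    for g in c.genes:
        v = np.sort(c.counts.loc[g].to_numpy())
        n = len(v)
        med = v[n // 2] if n % 2 else 0.5 * (v[n // 2 - 1] + v[n // 2])
        if med > 15.0:
            expect.add(g)
    assert kept == expect


def test_filter_genes_all_removed_raises():
    c = CountMatrix(pd.DataFrame(np.zeros((5, 6)),
                                 index=list("abcde"), columns=list("uvwxyz")))
    with pytest.raises(PreprocessError, match="every gene"):
        filter_genes(c)


# ---------------------------------------------------------------- MDS / outliers

def _classical_mds_oracle(x, k):
    """Principal coordinates from the double-centered squared distance matrix."""
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    return vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))


def _inverted_cdf_quartiles_oracle(v):
    s = np.sort(v)
    n = len(s)
    q25 = s[int(np.ceil(0.25 * n)) - 1]
    q75 = s[int(np.ceil(0.75 * n)) - 1]
    return q25, q75


def test_mds_outliers_match_brute_force_oracle():
    rng = np.random.default_rng(5)
    c = _random_counts(rng, n_genes=150, n_samples=20, lam=60.0)
    # plant a composition outlier (library depth alone is normalized away)
    c.counts.iloc[:30, 0] *= 20.0
    flagged = detect_outlier_samples(c, n_components=5, k_iqr=3.0)

    x = log2_cpm(c.counts).to_numpy().T
    coords = _classical_mds_oracle(x, 5)
    expect = set()
    for k in range(coords.shape[1]):
        v = coords[:, k]
        med = np.median(v)
        q25, q75 = _inverted_cdf_quartiles_oracle(v)
        iqr = q75 - q25
        if iqr <= 0:
            continue
        expect.update(c.samples[np.abs(v - med) > 3.0 * iqr])
    assert set(flagged) == expect
    assert "s0" in flagged


def test_mds_embedding_matches_pca_scores():
    rng = np.random.default_rng(6)
    c = _random_counts(rng, n_genes=80, n_samples=10)
    emb = mds_embedding(c, n_components=3).to_numpy()
    oracle = _classical_mds_oracle(log2_cpm(c.counts).to_numpy().T, 3)
    # same subspace coordinates up to per-component sign
    for k in range(3):
        assert (np.allclose(emb[:, k], oracle[:, k], atol=1e-8)
                or np.allclose(emb[:, k], -oracle[:, k], atol=1e-8))


def test_detect_outliers_needs_enough_samples():
    rng = np.random.default_rng(7)
    c = _random_counts(rng, n_genes=30, n_samples=5)
    with pytest.raises(PreprocessError, match="at least 6 samples"):
        detect_outlier_samples(c, n_components=5)


# ---------------------------------------------------------------- winsorization

def test_winsorize_idempotent_and_in_band_unchanged():
    rng = np.random.default_rng(11)
    for rep in range(200):
        n_genes = int(rng.integers(1, 8))
        n_samples = int(rng.integers(4, 25))
        counts = rng.poisson(rng.uniform(0.5, 200), size=(n_genes, n_samples)).astype(float)
        # sprinkle outliers
        k = int(rng.integers(0, 3))
        for _ in range(k):
            counts[rng.integers(n_genes), rng.integers(n_samples)] *= 50
        c = CountMatrix(pd.DataFrame(
            counts, index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n_samples)]))
        w1 = winsorize_log2(c)
        w2 = winsorize_log2(w1)
        assert np.array_equal(w1.counts.to_numpy(), w2.counts.to_numpy())
        # in-band values are bit-for-bit untouched
        x = np.log2(counts + 0.5)
        med = np.median(x, axis=1, keepdims=True)
        q = np.array([_inverted_cdf_quartiles_oracle(row) for row in x])
        iqr = (q[:, 1] - q[:, 0])[:, None]
        inside = (x >= med - 3 * iqr) & (x <= med + 3 * iqr)
        assert np.array_equal(w1.counts.to_numpy()[inside], counts[inside])
        # band containment after clamping
        xw = np.log2(w1.counts.to_numpy() + 0.5)
        assert (xw >= med - 3 * iqr - 1e-9).all()
        assert (xw <= med + 3 * iqr + 1e-9).all()


def test_winsorize_small_n_edge_case():
    # n=4 with one huge value: interpolated quartiles would not be idempotent
    c = CountMatrix(pd.DataFrame([[0.0, 0.0, 0.0, 100.0]],
                                 index=["g"], columns=list("abcd")))
    w1 = winsorize_log2(c)
    w2 = winsorize_log2(w1)
    assert np.array_equal(w1.counts.to_numpy(), w2.counts.to_numpy())


# ---------------------------------------------------------------- TMM

def _tmm_oracle(counts, trim_m=0.3, trim_a=0.05):
    """Independent brute-force TMM (pandas ranks, explicit loops)."""
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    f75 = np.array([np.quantile(y[:, j], 0.75) for j in range(y.shape[1])]) / lib
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    out = []
    for j in range(y.shape[1]):
        if j == ref:
            out.append(1.0)
            continue
        mask = (y[:, j] > 0) & (y[:, ref] > 0)
        o = y[mask, j] / lib[j]
        r = y[mask, ref] / lib[ref]
        # same arithmetic formulation as the implementation: alternate but
        # mathematically equal expressions differ in the last float bit,
        # which can break exact ties at the trim boundary
        m = np.log2(o / r)
        a = 0.5 * np.log2(o * r)
        v = ((lib[j] - y[mask, j]) / (lib[j] * y[mask, j])
             + (lib[ref] - y[mask, ref]) / (lib[ref] * y[mask, ref]))
        n = len(m)
        rm = pd.Series(m).rank().to_numpy()
        ra = pd.Series(a).rank().to_numpy()
        lo_m, lo_a = np.floor(n * trim_m) + 1, np.floor(n * trim_a) + 1
        keep = ((rm >= lo_m) & (rm <= n + 1 - lo_m)
                & (ra >= lo_a) & (ra <= n + 1 - lo_a))
        if not keep.any() or np.abs(m).max() < 1e-6:
            out.append(1.0)
            continue
        f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
        out.append(2.0 ** f)
    out = np.array(out)
    return out / np.exp(np.mean(np.log(out)))


def test_tmm_matches_brute_force_oracle():
    rng = np.random.default_rng(13)
    base = rng.lognormal(3.0, 1.5, 200)
    lib_mult = np.array([1.0, 1.6, 0.7, 2.2, 1.1, 0.8, 1.3, 0.9])
    mu = np.outer(base, lib_mult)
    mu[-25:, 0] *= 5.0  # composition bias in one sample
    counts = rng.poisson(rng.gamma(10.0, mu / 10.0)).astype(float)
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(200)],
                      columns=[f"s{j}" for j in range(8)])
    got = tmm_factors(CountMatrix(df)).to_numpy()
    assert np.abs(got - _tmm_oracle(df)).max() < 1e-8


def test_tmm_properties():
    rng = np.random.default_rng(14)
    c = _random_counts(rng, n_genes=120, n_samples=6, lam=80.0)
    f = tmm_factors(c)
    assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)
    # identical samples: all factors 1
    same = CountMatrix(pd.DataFrame(
        np.tile(rng.poisson(50, 100)[:, None], (1, 5)).astype(float),
        index=[f"g{i}" for i in range(100)], columns=list("abcde")))
    assert np.allclose(tmm_factors(same).to_numpy(), 1.0)


def test_tmm_zero_library_raises():
    c = pd.DataFrame(np.zeros((4, 3)), index=list("abcd"), columns=list("xyz"))
    with pytest.raises(PreprocessError, match="positive library"):
        tmm_factors(CountMatrix(c))


# ---------------------------------------------------------------- weights / removal

def test_observation_weights_shape_and_fallback():
    rng = np.random.default_rng(15)
    c = _random_counts(rng, n_genes=300, n_samples=12, lam=40.0)
    expr = normalized_log_expression(c, tmm_factors(c))
    w = observation_weights(expr)
    assert w.shape == expr.shape
    assert (w.to_numpy() > 0).all()
    with pytest.warns(UserWarning, match="fewer than 10 genes"):
        w_small = observation_weights(expr.iloc[:5])
    assert np.array_equal(w_small.to_numpy(), np.ones((5, 12)))


def test_remove_technical_removes_planted_batch_effect():
    rng = np.random.default_rng(16)
    n_genes, n = 50, 40
    batch = np.array(["a"] * 20 + ["b"] * 20)
    expr = rng.normal(5.0, 1.0, (n_genes, n))
    expr[:, batch == "b"] += 2.0  # planted batch shift
    samples = [f"s{j}" for j in range(n)]
    frame = pd.DataFrame(expr, index=[f"g{i}" for i in range(n_genes)],
                         columns=samples)
    cov = pd.DataFrame({"batch": batch}, index=samples)
    from ctprop.preprocess import NormalizedMatrix
    norm = NormalizedMatrix(frame, pd.Series(1.0, index=samples))
    cleaned = remove_technical(norm, cov).log_expr.to_numpy()
    gap = np.abs(cleaned[:, batch == "b"].mean() - cleaned[:, batch == "a"].mean())
    assert gap < 1e-10
    # grand level retained (sum-to-zero contrasts keep the intercept)
    assert np.allclose(cleaned.mean(), expr.mean(), atol=1e-10)


def test_remove_technical_collinear_raises():
    samples = [f"s{j}" for j in range(10)]
    frame = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 10)),
                         index=list("abcde"), columns=samples)
    v = np.arange(10, dtype=float)
    cov = pd.DataFrame({"rin": v, "pmi": 2 * v}, index=samples)
    from ctprop.preprocess import NormalizedMatrix
    norm = NormalizedMatrix(frame, pd.Series(1.0, index=samples))
    with pytest.raises(PreprocessError, match="collinear"):
        remove_technical(norm, cov)


def test_preprocess_pipeline_report(cohort):
    cm = next(iter(cohort["datasets"].values()))
    norm, report = preprocess_pipeline(cm)
    assert report["n_genes_in"] == cm.counts.shape[0]
    assert report["n_genes_out"] == norm.log_expr.shape[0]
    assert report["n_samples_out"] == norm.log_expr.shape[1]
    assert set(report["technical_covariates"]) <= {
        "batch", "pct_mapped", "pct_usable", "rin", "pmi"}
    assert norm.weights is not None
    assert len(report["tmm_factors"]) == report["n_samples_out"]
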