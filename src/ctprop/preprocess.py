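"""Bulk RNA-seq quality control and normalization.

The protocol operates on expected-count matrices (genes x samples) and runs,
in a fixed order:

1. ``filter_genes`` — drop genes with median expected count <= 15.
2. ``detect_outlier_samples`` — classical MDS on log2 CPM; flag samples more
   than 3 IQRs from the component median on any of the first 5 components.
3. ``winsorize_log2`` — per gene, clamp log2(count + 0.5) into a 3-IQR band
   around the gene median, then transform back to the count scale.
4. ``tmm_factors`` — trimmed mean of M-values library-composition factors.
5. ``observation_weights`` — mean-variance trend precision weights.
6. ``remove_technical`` — weighted linear removal of technical covariates
   (batch, RIN, PMI, percent mapped/usable bases).

Quartiles in the winsorization band use the inverted-CDF (order-statistic)
definition; with that choice clamping never moves the gene median or
quartiles, so the operation is exactly idempotent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

TECHNICAL_COVARIATES = ("batch", "pct_mapped", "pct_usable", "rin", "pmi")


class PreprocessError(RuntimeError):
    pass


@dataclass
class CountMatrix:
    """Expected counts (genes x samples) with per-sample technical covariates."""

    counts: pd.DataFrame
    dataset: str = ""
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("gene and sample ids must be unique")
        if self.covariates is not None:
            missing = self.counts.columns.difference(self.covariates.index)
            if len(missing):
                raise ValueError(f"covariates missing for samples: {list(missing)[:5]}")
            self.covariates = self.covariates.loc[self.counts.columns]

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, samples) -> "CountMatrix":
        cov = None if self.covariates is None else self.covariates.loc[samples]
        return CountMatrix(self.counts[list(samples)], self.dataset, cov)


@dataclass
class NormalizedMatrix:
    """Log2-scale expression with TMM factors and observation weights."""

    log_expr: pd.DataFrame                 # genes x samples
    tmm: pd.Series
    weights: pd.DataFrame | None = None    # genes x samples
    dataset: str = ""


def _quartiles_inverted_cdf(x: np.ndarray, axis: int = -1):
    q25 = np.percentile(x, 25, axis=axis, method="inverted_cdf")
    q75 = np.percentile(x, 75, axis=axis, method="inverted_cdf")
    return q25, q75


def filter_genes(c: CountMatrix, threshold: float = 15.0) -> CountMatrix:
    """Keep genes whose median expected count is strictly above ``threshold``."""
    med = c.counts.median(axis=1)
    keep = med > threshold
    if not keep.any():
        raise PreprocessError("gene filter removed every gene")
    out = CountMatrix(c.counts.loc[keep], c.dataset, c.covariates)
    logger.info("filter_genes: retained %d/%d genes", keep.sum(), len(keep))
    return out


def log2_cpm(counts: pd.DataFrame, prior: float = 1.0) -> pd.DataFrame:
    lib = counts.sum(axis=0)
    return np.log2(counts.div(lib, axis=1) * 1e6 + prior)


def mds_embedding(c: CountMatrix, n_components: int = 5) -> pd.DataFrame:
    """Classical MDS (principal coordinates of Euclidean distances on log2 CPM).

    For Euclidean distances this equals PCA scores of the centered
    sample x gene matrix, computed here by SVD for determinism.
    """
    x = log2_cpm(c.counts).to_numpy().T  # samples x genes
    x = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    return pd.DataFrame(
        scores, index=c.samples, columns=[f"MDS{i+1}" for i in range(k)]
    )


def detect_outlier_samples(
    c: CountMatrix, n_components: int = 5, k_iqr: float = 3.0
) -> list[str]:
    """Flag samples > ``k_iqr`` IQRs from the median on any MDS component."""
    if c.counts.shape[1] < n_components + 1:
        raise PreprocessError(
            f"need at least {n_components + 1} samples for {n_components} components"
        )
    emb = mds_embedding(c, n_components)
    flagged: set[str] = set()
    for col in emb.columns:
        v = emb[col].to_numpy()
        med = np.median(v)
        q25, q75 = _quartiles_inverted_cdf(v)
        iqr = q75 - q25
        if iqr <= 0:
            continue
        out = np.abs(v - med) > k_iqr * iqr
        flagged.update(emb.index[out])
    return sorted(flagged)


def winsorize_log2(
    c: CountMatrix, offset: float = 0.5, k_iqr: float = 3.0
) -> CountMatrix:
    """Clamp per-gene log2(count + offset) into a +/- ``k_iqr`` IQR band.

    Only values outside the band are transformed (back to the count scale,
    floored at 0); in-band values are returned bit-for-bit unchanged.
    """
    vals = c.counts.to_numpy(dtype=float)
    x = np.log2(vals + offset)
    med = np.median(x, axis=1, keepdims=True)
    q25, q75 = _quartiles_inverted_cdf(x, axis=1)
    iqr = (q75 - q25)[:, None]
    lo = med - k_iqr * iqr
    hi = med + k_iqr * iqr
    clamped = np.clip(x, lo, hi)
    outside = (x < lo) | (x > hi)
    out = vals.copy()
    out[outside] = np.maximum(2.0 ** clamped[outside] - offset, 0.0)
    return CountMatrix(
        pd.DataFrame(out, index=c.genes, columns=c.samples), c.dataset, c.covariates
    )


def tmm_factors(
    c: CountMatrix | pd.DataFrame,
    trim_M: float = 0.3,
    trim_A: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors.

    Reference sample: upper-quartile/library ratio closest to the mean ratio.
    Per sample, M (log ratio) and A (log abundance) are computed over genes
    positive in both sample and reference, doubly trimmed (``trim_M`` on M,
    ``trim_A`` on A), and the factor is 2**(precision-weighted mean of the
    retained M values), with weights from the asymptotic binomial variance.
    Factors are rescaled to geometric mean 1.
    """
    counts = c.counts if isinstance(c, CountMatrix) else c
    y = counts.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    if (lib <= 0).any():
        raise PreprocessError("every sample needs a positive library size")
    f75 = np.percentile(y, 75, axis=0) / lib
    ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    r = y[:, ref_idx]
    nr = lib[ref_idx]

    factors = np.ones(y.shape[1])
    for j in range(y.shape[1]):
        if j == ref_idx:
            factors[j] = 1.0
            continue
        obs = y[:, j]
        pos = (obs > 0) & (r > 0)
        if not pos.any():
            raise PreprocessError(
                f"sample {counts.columns[j]!r} shares no positive genes with reference"
            )
        o = obs[pos] / lib[j]
        rr = r[pos] / nr
        m = np.log2(o / rr)
        a = 0.5 * np.log2(o * rr)
        w = (lib[j] - obs[pos]) / (lib[j] * obs[pos]) + (nr - r[pos]) / (nr * r[pos])
        n = m.size
        lo_m = np.floor(n * trim_M) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * trim_A) + 1
        hi_a = n + 1 - lo_a
        rm = rankdata(m)
        ra = rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not keep.any() or np.abs(m).max() < 1e-6:
            factors[j] = 1.0
            continue
        # precision weights: inverse asymptotic binomial variance of M
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[j] = 2.0 ** f if np.isfinite(f) else 1.0

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm")


def normalized_log_expression(
    c: CountMatrix, factors: pd.Series, prior: float = 0.5
) -> pd.DataFrame:
    """Log2 CPM using TMM-adjusted effective library sizes."""
    eff = c.counts.sum(axis=0) * factors.loc[c.samples]
    return np.log2((c.counts + prior).div(eff + 1.0, axis=1) * 1e6)


def observation_weights(log_expr: pd.DataFrame, span: float = 0.5) -> pd.DataFrame:
    """Mean-variance trend precision weights.

    Fits a lowess of per-gene sqrt(residual SD) on mean log2 expression and
    inverts the trend, evaluated at each observation's log expression, to a
    precision weight (trend**-4). Falls back to unit weights with a warning
    when fewer than 10 genes are available.
    """
    x = log_expr.to_numpy(dtype=float)
    if x.shape[0] < 10:
        warnings.warn("fewer than 10 genes; using unit observation weights")
        return pd.DataFrame(
            np.ones_like(x), index=log_expr.index, columns=log_expr.columns
        )
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    sq = np.sqrt(np.maximum(sd, 0.0))
    fit = lowess(sq, mean, frac=span, return_sorted=True)
    xs, ys = fit[:, 0], fit[:, 1]
    trend = np.interp(x, xs, ys)
    trend = np.maximum(trend, 1e-4)
    w = trend ** -4.0
    return pd.DataFrame(w, index=log_expr.index, columns=log_expr.columns)


def _technical_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Expand covariates to a centered design: numeric columns centered,
    categoricals as sum-to-zero (effects) contrasts."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            v = col.to_numpy(dtype=float)
            cols.append(v - v.mean())
            names.append(name)
        else:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                continue
            base = levels[-1]
            for lev in levels[:-1]:
                v = (col.astype(str) == lev).astype(float).to_numpy()
                v[col.astype(str).to_numpy() == base] = -1.0
                cols.append(v - v.mean())
                names.append(f"{name}[{lev}]")
    if not cols:
        raise PreprocessError("no usable technical covariates")
    return np.column_stack(cols), names


def remove_technical(
    m: NormalizedMatrix, covariates: pd.DataFrame | None = None
) -> NormalizedMatrix:
    """Per gene, weighted least-squares removal of technical covariates.

    Fits expression on [intercept | covariates] and subtracts the covariate
    component, keeping the intercept. Categorical covariates use sum-to-zero
    contrasts so the retained intercept is the unweighted grand level.
    """
    if covariates is None:
        raise PreprocessError("covariates required")
    covariates = covariates.loc[m.log_expr.columns]
    z, names = _technical_design(covariates)
    x = np.column_stack([np.ones(z.shape[0]), z])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        # name collinear columns via the QR diagonal
        rdiag = np.abs(np.diag(np.linalg.qr(x, mode="r")))
        bad = [names[i - 1] for i in range(1, x.shape[1]) if rdiag[i] < 1e-10]
        raise PreprocessError(f"technical covariates are collinear: {bad}")

    y = m.log_expr.to_numpy(dtype=float)
    w = None if m.weights is None else m.weights.to_numpy(dtype=float)
    out = np.empty_like(y)
    for g in range(y.shape[0]):
        if w is None:
            beta, *_ = np.linalg.lstsq(x, y[g], rcond=None)
        else:
            sw = np.sqrt(w[g])
            beta, *_ = np.linalg.lstsq(x * sw[:, None], y[g] * sw, rcond=None)
        out[g] = y[g] - z @ beta[1:]
    cleaned = pd.DataFrame(out, index=m.log_expr.index, columns=m.log_expr.columns)
    return NormalizedMatrix(cleaned, m.tmm, m.weights, m.dataset)


def preprocess_pipeline(
    c: CountMatrix,
    filter_threshold: float = 15.0,
    n_components: int = 5,
    k_iqr: float = 3.0,
    weight_span: float = 0.5,
    technical_covariates: tuple[str, ...] = TECHNICAL_COVARIATES,
) -> tuple[NormalizedMatrix, dict]:
    """Run the full QC/normalization protocol in its fixed order.

    Returns the normalized matrix and a QC report (genes removed, samples
    flagged, TMM factors, covariates used).
    """
    report: dict = {"dataset": c.dataset, "n_genes_in": int(c.counts.shape[0]),
                    "n_samples_in": int(c.counts.shape[1])}
    filtered = filter_genes(c, filter_threshold)
    report["genes_removed"] = int(c.counts.shape[0] - filtered.counts.shape[0])
    outliers = detect_outlier_samples(filtered, n_components, k_iqr)
    report["outlier_samples"] = outliers
    kept = [s for s in filtered.samples if s not in set(outliers)]
    filtered = filtered.subset_samples(kept)
    wins = winsorize_log2(filtered, k_iqr=k_iqr)
    factors = tmm_factors(wins)
    report["tmm_factors"] = {k: float(v) for k, v in factors.items()}
    log_expr = normalized_log_expression(wins, factors)
    weights = observation_weights(log_expr, span=weight_span)
    norm = NormalizedMatrix(log_expr, factors, weights, c.dataset)
    if c.covariates is not None:
        use = [col for col in technical_covariates if col in c.covariates.columns]
        report["technical_covariates"] = use
        if use:
            norm = remove_technical(norm, c.covariates.loc[kept, use])
    else:
        report["technical_covariates"] = []
    report["n_genes_out"] = int(norm.log_expr.shape[0])
    report["n_samples_out"] = int(norm.log_expr.shape[1])
    return norm, report
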