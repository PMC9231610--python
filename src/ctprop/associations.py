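"""Case/control mega-analysis, phenotype battery, multiple-testing control,
and nested-model variance partitioning with the 0.632+ bootstrap.

The mega-analysis pools subject-level data across cohorts (one model per cell
type): a linear mixed model of the z-scored rCTP on AD status with a random
intercept per subject (subjects contribute multiple regional samples in the
multi-region study) and fixed effects of study, age at death and sex, fit by
REML with Wald two-sided p-values. "Standardized beta" throughout means the
outcome is z-scored, binary predictors stay 0/1, and continuous predictors
are z-scored, so coefficients read as SD units of the outcome.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

PATHOLOGY_COVARIATES = ("age_at_death", "sex", "pmi")
COGNITIVE_COVARIATES = ("sex", "education", "age_baseline")
COGNITIVE_OUTCOMES = ("cognitive_slope", "cognition_at_death", "residual_cognition")


class AssociationError(RuntimeError):
    pass


@dataclass
class AssociationResult:
    cell_type: str
    outcome: str
    beta: float
    se: float
    p: float
    n_subjects: int
    n_samples: int
    model: str = "lmm"
    p_bonf: float | None = None
    p_fdr: float | None = None

    def as_dict(self) -> dict:
        return dict(
            cell_type=self.cell_type, outcome=self.outcome, beta=self.beta,
            se=self.se, p=self.p, p_bonf=self.p_bonf, p_fdr=self.p_fdr,
            n_subjects=self.n_subjects, n_samples=self.n_samples,
            model=self.model,
        )


@dataclass
class VariancePartition:
    r2_baseline: float
    r2_augmented: float
    delta_r2: float
    lrt_p: float
    adj_r2_baseline: float
    adj_r2_augmented: float
    adj_delta_r2: float
    n_boot: int
    n: int


def _zscore(x: pd.Series | np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std(ddof=0)
    if sd == 0:
        raise AssociationError("cannot z-score a constant column")
    return (x - x.mean()) / sd


# --------------------------------------------------------------------------
# mega-analysis and single-nucleus models
# --------------------------------------------------------------------------

def mega_model(
    rctp_long: pd.DataFrame,
    cell_type: str,
    score_col: str = "score",
    allow_ols_fallback: bool = True,
) -> AssociationResult:
    """Cross-cohort mixed-model association of AD with one cell type's rCTP.

    ``rctp_long`` stacks all datasets: columns ``score`` (z-scored rCTP),
    ``ad`` (0/1), ``subject_id``, ``study``, ``age_at_death``, ``sex``.
    Rows with ad missing (subjects meeting neither criterion) are dropped.
    A singular random-intercept fit falls back to OLS, flagged in the model
    tag; non-convergence raises with diagnostics.
    """
    df = rctp_long.dropna(subset=[score_col, "ad"]).copy()
    if df.empty:
        raise AssociationError("no case/control rows")
    terms = ["ad"]
    if df["study"].nunique() > 1:
        terms.append("C(study)")
    terms += ["age_at_death", "sex"]
    formula = f"{score_col} ~ " + " + ".join(terms)

    singleton = df.groupby("subject_id").size().max() == 1
    tag = "lmm"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            model = smf.mixedlm(formula, data=df, groups=df["subject_id"])
            res = model.fit(reml=True)
            var_re = float(np.asarray(res.cov_re).ravel()[0])
            if not np.isfinite(res.params["ad"]):
                raise np.linalg.LinAlgError("non-finite estimate")
            if singleton or var_re < 1e-10:
                tag = "lmm_boundary" if not singleton else "lmm_singleton"
            beta = float(res.params["ad"])
            se = float(res.bse["ad"])
            p = float(res.pvalues["ad"])
        except (np.linalg.LinAlgError, ValueError) as err:
            if not allow_ols_fallback:
                raise AssociationError(f"mixed model failed: {err}") from err
            ols = smf.ols(formula, data=df).fit()
            beta, se, p = (float(ols.params["ad"]), float(ols.bse["ad"]),
                           float(ols.pvalues["ad"]))
            tag = "ols_fallback"
    return AssociationResult(
        cell_type=cell_type, outcome="ad_diagnosis", beta=beta, se=se, p=p,
        n_subjects=int(df.subject_id.nunique()), n_samples=int(len(df)),
        model=tag,
    )


def sn_model(snctp_long: pd.DataFrame, cell_type: str,
             value_col: str = "snctp") -> AssociationResult:
    """AD association of a subclass snCTP: OLS of the z-scored snCTP on AD +
    dataset + age + sex + PMI (a plain linear model; the sn cohorts overlap
    too little for a random effect)."""
    df = snctp_long.dropna(subset=[value_col, "ad"]).copy()
    if df.empty:
        raise AssociationError("no case/control rows")
    df["z"] = _zscore(df[value_col])
    terms = ["ad"]
    if "dataset" in df.columns and df["dataset"].nunique() > 1:
        terms.append("C(dataset)")
    terms += ["age_at_death", "sex", "pmi"]
    formula = "z ~ " + " + ".join(terms)
    ols = smf.ols(formula, data=df).fit()
    if ols.df_resid <= 0 or np.linalg.matrix_rank(ols.model.exog) < ols.model.exog.shape[1]:
        raise AssociationError("rank-deficient single-nucleus design")
    return AssociationResult(
        cell_type=cell_type, outcome="ad_diagnosis",
        beta=float(ols.params["ad"]), se=float(ols.bse["ad"]),
        p=float(ols.pvalues["ad"]),
        n_subjects=int(df.subject_id.nunique()) if "subject_id" in df else len(df),
        n_samples=int(len(df)), model="ols",
    )


# --------------------------------------------------------------------------
# multiple-testing control
# --------------------------------------------------------------------------

def adjust_pvalues(results: list[AssociationResult], family: str = "") -> list[AssociationResult]:
    """Fill Bonferroni and Benjamini-Hochberg adjusted p within one family."""
    if not results:
        raise AssociationError("empty family")
    p = np.array([r.p for r in results], dtype=float)
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise AssociationError("p-values outside [0, 1]")
    m = len(p)
    p_bonf = np.minimum(p * m, 1.0)
    _, p_fdr, _, _ = multipletests(p, method="fdr_bh")
    for r, pb, pf in zip(results, p_bonf, p_fdr):
        r.p_bonf = float(pb)
        r.p_fdr = float(pf)
    logger.info("adjusted %d p-values in family %r", m, family)
    return results


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in results])


# --------------------------------------------------------------------------
# phenotype battery
# --------------------------------------------------------------------------

def _ols_via_fwl(y: np.ndarray, x: np.ndarray, covs: np.ndarray
                 ) -> tuple[float, float, float]:
    """Coefficient of x in OLS(y ~ 1 + x + covs) by residualization.

    Returns (beta, se, two-sided p) identical to the full multiple
    regression (Frisch-Waugh-Lovell), with df = n - (k_cov + 2).
    """
    n = len(y)
    c = np.column_stack([np.ones(n), covs]) if covs.size else np.ones((n, 1))
    q, _ = np.linalg.qr(c)
    ry = y - q @ (q.T @ y)
    rx = x - q @ (q.T @ x)
    sxx = float(rx @ rx)
    if sxx <= 1e-10 * max(float(x @ x), 1.0):
        raise AssociationError("predictor collinear with covariates")
    beta = float(rx @ ry) / sxx
    resid = ry - beta * rx
    df_resid = n - c.shape[1] - 1
    if df_resid <= 0:
        raise AssociationError("not enough residual degrees of freedom")
    sigma2 = float(resid @ resid) / df_resid
    se = float(np.sqrt(sigma2 / sxx))
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), df_resid)
    return beta, se, float(p)


def phenotype_battery(
    rctp: pd.DataFrame,
    derived: pd.DataFrame,
    pathology_cols: list[str],
    cognitive_outcomes: tuple[str, ...] = COGNITIVE_OUTCOMES,
    fdr_q: float | None = None,
) -> pd.DataFrame:
    """The full cell type x outcome association grid.

    ``rctp`` is subject x subclass (z-scored scores); ``derived`` carries the
    outcomes and covariates per subject. Pathology outcomes covary for age at
    death, sex and PMI; cognitive outcomes for sex, education and baseline
    age. Both outcome and rCTP are z-scored per test, so betas are in SD
    units. FDR (BH) is applied across the whole grid; missing outcome columns
    shrink the family and are logged.
    """
    outcomes = [(o, PATHOLOGY_COVARIATES) for o in pathology_cols]
    outcomes += [(o, COGNITIVE_COVARIATES) for o in cognitive_outcomes]
    shared = rctp.index.intersection(derived.index)
    rows: list[AssociationResult] = []
    for outcome, covs in outcomes:
        if outcome not in derived.columns:
            logger.warning("outcome %r missing; untested (family reduced)", outcome)
            continue
        cols = [outcome, *covs]
        data = derived.loc[shared, cols].dropna()
        idx = data.index
        cmat = data[list(covs)].to_numpy(dtype=float)
        cmat = (cmat - cmat.mean(axis=0))
        for cell in rctp.columns:
            xv = rctp.loc[idx, cell]
            ok = xv.notna().to_numpy()
            y = _zscore(data.loc[ok, outcome])
            x = _zscore(xv[ok])
            beta, se, p = _ols_via_fwl(y, x, cmat[ok])
            rows.append(AssociationResult(
                cell_type=cell, outcome=outcome, beta=beta, se=se, p=p,
                n_subjects=int(ok.sum()), n_samples=int(ok.sum()),
                model="ols",
            ))
    adjust_pvalues(rows, family="phenotype_battery")
    return results_frame(rows)


def marker_gene_models(
    expr, markers: list[str], meta: pd.DataFrame
) -> pd.DataFrame:
    """Per marker gene, OLS of z-scored expression on AD + age + sex,
    FDR-adjusted within the marker family (heatmap support)."""
    from .preprocess import NormalizedMatrix

    frame = expr.log_expr if isinstance(expr, NormalizedMatrix) else expr
    meta = meta.loc[frame.columns]
    keep = meta.ad.notna()
    covs = meta.loc[keep, ["age_at_death", "sex"]].to_numpy(dtype=float)
    covs = np.column_stack([meta.loc[keep, "ad"].to_numpy(dtype=float), covs])
    results = []
    for gene in markers:
        if gene not in frame.index:
            logger.warning("marker %r absent from expression; skipped", gene)
            continue
        y = _zscore(frame.loc[gene, keep.index[keep]])
        beta, se, p = _ols_via_fwl(y, covs[:, 0], covs[:, 1:])
        results.append(AssociationResult(
            cell_type="", outcome=gene, beta=beta, se=se, p=p,
            n_subjects=int(keep.sum()), n_samples=int(keep.sum()), model="ols",
        ))
    if not results:
        raise AssociationError("no marker genes present in expression")
    adjust_pvalues(results, family="marker_genes")
    out = results_frame(results).rename(columns={"outcome": "gene"})
    return out.drop(columns=["cell_type"])


# --------------------------------------------------------------------------
# nested-model variance partitioning with the 0.632+ bootstrap
# --------------------------------------------------------------------------

def _fit_predict(x: np.ndarray, y: np.ndarray, idx: np.ndarray,
                 x_eval: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(x[idx], y[idx], rcond=None)
    return x_eval @ beta


def _boot632_error(x: np.ndarray, y: np.ndarray, boots: list[np.ndarray],
                   rng: np.random.Generator, max_retries: int = 10
                   ) -> tuple[float, float]:
    """(apparent squared error, 0.632+ adjusted squared error)."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    pred = x @ beta
    err_app = float(np.mean((y - pred) ** 2))
    # no-information error: all (y_i, prediction_j) pairs
    gamma = float(np.mean((y[:, None] - pred[None, :]) ** 2))
    oob_errs = []
    for idx in boots:
        for _ in range(max_retries + 1):
            oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
            if oob.size and np.linalg.matrix_rank(x[idx]) == x.shape[1]:
                break
            logger.info("degenerate bootstrap resample; redrawing")
            idx = rng.integers(0, n, n)
        else:
            continue
        p = _fit_predict(x, y, idx, x[oob])
        oob_errs.append(float(np.mean((y[oob] - p) ** 2)))
    err_oob = float(np.mean(oob_errs))
    denom = gamma - err_app
    r_overfit = 0.0 if denom <= 0 else float(np.clip((err_oob - err_app) / denom, 0, 1))
    w = 0.632 / (1.0 - 0.368 * r_overfit)
    return err_app, (1.0 - w) * err_app + w * err_oob


def variance_explained(
    data: pd.DataFrame,
    outcome: str,
    baseline_covariates: list[str],
    added_predictor: str,
    n_boot: int = 100,
    seed: int = 0,
) -> VariancePartition:
    """R-squared gained by one predictor over a baseline model.

    Fits nested OLS models (baseline vs baseline + predictor), compares them
    with a likelihood-ratio test, and reports generalizable R-squared from
    the 0.632+ bootstrap: the apparent and out-of-bag squared errors are
    blended with a weight that grows with the relative overfit, and adjusted
    R-squared is 1 - adjusted error / outcome variance. The same bootstrap
    resamples are used for both models so the adjusted delta is paired.
    """
    cols = [outcome, *baseline_covariates, added_predictor]
    df = data[cols].dropna()
    n = len(df)
    y = df[outcome].to_numpy(dtype=float)
    x0 = np.column_stack([np.ones(n), df[baseline_covariates].to_numpy(dtype=float)])
    x1 = np.column_stack([x0, df[added_predictor].to_numpy(dtype=float)])
    if n <= x1.shape[1]:
        raise AssociationError("need n > number of parameters")

    def _rss(x):
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        return float(np.sum((y - x @ beta) ** 2))

    rss0, rss1 = _rss(x0), _rss(x1)
    var_y = float(np.var(y))
    r2_0 = 1.0 - rss0 / (n * var_y)
    r2_1 = 1.0 - rss1 / (n * var_y)
    lrt = n * np.log(rss0 / rss1)
    lrt_p = float(stats.chi2.sf(lrt, df=x1.shape[1] - x0.shape[1]))

    rng = np.random.default_rng(seed)
    boots = [rng.integers(0, n, n) for _ in range(n_boot)]
    _, adj_err0 = _boot632_error(x0, y, boots, rng)
    _, adj_err1 = _boot632_error(x1, y, boots, rng)
    adj_r2_0 = 1.0 - adj_err0 / var_y
    adj_r2_1 = 1.0 - adj_err1 / var_y
    return VariancePartition(
        r2_baseline=r2_0, r2_augmented=r2_1, delta_r2=r2_1 - r2_0,
        lrt_p=lrt_p, adj_r2_baseline=adj_r2_0, adj_r2_augmented=adj_r2_1,
        adj_delta_r2=adj_r2_1 - adj_r2_0, n_boot=n_boot, n=n,
    )
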