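"""Causal mediation analysis for linear models.

Decomposes the effect of a treatment variable on an outcome into the average
causal mediation effect (ACME, the product of the treatment -> mediator and
mediator -> outcome coefficients) and the average direct effect (ADE), with
percentile confidence intervals from a nonparametric (row-resampling)
bootstrap. For linear models without a treatment-mediator interaction the
decomposition is exact within every draw: total = ACME + ADE.

The standard battery runs four configurations: SST and IT relative
proportions each take the predictor and the mediator role against global AD
pathology, with cognition proximal to death always the outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class MediationError(RuntimeError):
    pass


@dataclass
class MediationResult:
    treatment: str
    mediator: str
    outcome: str
    covariates: tuple[str, ...]
    acme: float
    acme_ci: tuple[float, float]
    acme_p: float
    ade: float
    ade_ci: tuple[float, float]
    ade_p: float
    total: float
    total_ci: tuple[float, float]
    total_p: float
    prop_mediated: float
    n: int
    n_draws: int
    seed: int

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "treatment", "mediator", "outcome", "acme", "acme_p", "ade",
            "ade_p", "total", "total_p", "prop_mediated", "n", "n_draws")}
        d["acme_lo"], d["acme_hi"] = self.acme_ci
        d["ade_lo"], d["ade_hi"] = self.ade_ci
        d["total_lo"], d["total_hi"] = self.total_ci
        return d


def _solve_batch(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least squares for a batch of designs: x (d, n, p), y (d, n)."""
    g = np.einsum("dni,dnj->dij", x, x)
    b = np.einsum("dni,dn->di", x, y)
    try:
        return np.linalg.solve(g, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        out = np.empty((x.shape[0], x.shape[2]))
        for d in range(x.shape[0]):
            out[d], *_ = np.linalg.lstsq(x[d], y[d], rcond=None)
        return out


def _boot_p(draws: np.ndarray) -> float:
    lo = float(np.mean(draws <= 0))
    hi = float(np.mean(draws >= 0))
    return min(1.0, 2.0 * min(lo, hi))


def fit_mediation(
    data: pd.DataFrame,
    treatment: str,
    mediator: str,
    outcome: str,
    covariates: tuple[str, ...] = (),
    n_draws: int = 1000,
    seed: int = 0,
) -> MediationResult:
    """Product-of-coefficients mediation with a nonparametric bootstrap.

    Fits M ~ T + X and Y ~ T + M + X by OLS; per bootstrap draw (rows
    resampled with replacement) ACME = a*b, ADE = the outcome-model T
    coefficient, total = ACME + ADE. Point estimates come from the full-data
    fit, intervals are 95% percentile intervals over ``n_draws`` draws, and
    the two-sided bootstrap p is 2 * min(frac <= 0, frac >= 0).
    """
    cols = [treatment, mediator, outcome, *covariates]
    df = data[cols].dropna()
    n = len(df)
    if n < 50:
        warnings.warn(f"mediation on only {n} rows; estimates will be unstable")
    t = df[treatment].to_numpy(dtype=float)
    m = df[mediator].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    if t.std() == 0 or m.std() == 0:
        raise MediationError("constant treatment or mediator")
    x = df[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((n, 0))
    ones = np.ones((n, 1))
    xm = np.hstack([ones, t[:, None], x])                 # mediator model
    xy = np.hstack([ones, t[:, None], m[:, None], x])     # outcome model
    for mat, name in ((xm, "mediator"), (xy, "outcome")):
        if np.linalg.matrix_rank(mat) < mat.shape[1]:
            raise MediationError(f"rank-deficient {name} model design: {cols}")

    bm, *_ = np.linalg.lstsq(xm, m, rcond=None)
    by, *_ = np.linalg.lstsq(xy, y, rcond=None)
    a_hat, b_hat, ade_hat = bm[1], by[2], by[1]
    acme_hat = a_hat * b_hat
    total_hat = acme_hat + ade_hat

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_draws, n))
    bm_d = _solve_batch(xm[idx], m[idx])
    by_d = _solve_batch(xy[idx], y[idx])
    acme_d = bm_d[:, 1] * by_d[:, 2]
    ade_d = by_d[:, 1]
    total_d = acme_d + ade_d

    def ci(d):
        return (float(np.percentile(d, 2.5)), float(np.percentile(d, 97.5)))

    prop = float(acme_hat / total_hat) if abs(total_hat) > 1e-12 else float("nan")
    return MediationResult(
        treatment=treatment, mediator=mediator, outcome=outcome,
        covariates=tuple(covariates),
        acme=float(acme_hat), acme_ci=ci(acme_d), acme_p=_boot_p(acme_d),
        ade=float(ade_hat), ade_ci=ci(ade_d), ade_p=_boot_p(ade_d),
        total=float(total_hat), total_ci=ci(total_d), total_p=_boot_p(total_d),
        prop_mediated=prop, n=n, n_draws=n_draws, seed=seed,
    )


def run_four_models(
    data: pd.DataFrame,
    sst_col: str = "SST",
    it_col: str = "IT",
    pathology_col: str = "global_pathology",
    outcome_col: str = "cognition_at_death",
    covariates: tuple[str, ...] = ("age_at_death", "sex", "education", "apoe4"),
    n_draws: int = 1000,
    seed: int = 0,
) -> dict[str, MediationResult]:
    """The four-configuration mediation battery.

    SST and IT each appear as predictor with pathology mediating, and as
    mediator with pathology predicting; cognition proximal to death is always
    the outcome, and the APOE e4 dose is among the covariates. Per-model
    seeds are derived from ``seed`` deterministically.
    """
    configs = {
        "sst_via_pathology": (sst_col, pathology_col),
        "pathology_via_sst": (pathology_col, sst_col),
        "it_via_pathology": (it_col, pathology_col),
        "pathology_via_it": (pathology_col, it_col),
    }
    out = {}
    for i, (name, (t, m)) in enumerate(configs.items()):
        sub_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        out[name] = fit_mediation(
            data, treatment=t, mediator=m, outcome=outcome_col,
            covariates=covariates, n_draws=n_draws, seed=sub_seed,
        )
    return out
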