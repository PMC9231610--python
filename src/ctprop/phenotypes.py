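"""Analysis-ready phenotypes: consensus diagnosis, cognitive composites,
longitudinal slopes, residual cognition, and global pathology.

The consensus case/control definition combines neuropathological staging
(Braak, CERAD) with antemortem cognitive status; subjects meeting neither
arm are labeled "other". Cut-points are configuration, not constants: the
published harmonization states the ingredients, and per-study variants (for
example a neuropathology-only rule) are expressed by the same dataclass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

CERAD_LEVELS = ("none", "sparse", "moderate", "frequent")


class PhenotypeError(RuntimeError):
    pass


@dataclass
class PhenotypeTable:
    """Cross-sectional phenotypes plus a longitudinal cognition block.

    ``cross`` has one row per subject; ``longitudinal`` is keyed
    (subject_id, visit); ``tests`` optionally carries raw per-visit test
    scores for composite construction.
    """

    cross: pd.DataFrame
    longitudinal: pd.DataFrame | None = None
    tests: pd.DataFrame | None = None


@dataclass(frozen=True)
class DiagnosisRule:
    """Thresholds for the consensus AD case/control definition."""

    braak_case_min: int = 4
    cerad_case: tuple[str, ...] = ("moderate", "frequent")
    braak_control_max: int = 3
    cerad_control: tuple[str, ...] = ("none", "sparse")
    use_cognition: bool = True
    cdr_case_min: float = 1.0
    cdr_control_max: float = 0.5


def classify_ad(p: PhenotypeTable | pd.DataFrame, rule: DiagnosisRule | None = None
                ) -> pd.Series:
    """Label every subject control / AD / other under the consensus rule.

    AD requires Braak >= case threshold, CERAD in the case set, and (when the
    rule uses cognition) cognitive impairment (``cog_impaired`` True or CDR >=
    threshold); control requires the converse on all axes. Mixed profiles and
    rows with missing required fields are "other" (missingness is logged,
    never silent). The case and control regions are disjoint by construction.
    """
    rule = rule or DiagnosisRule()
    df = p.cross if isinstance(p, PhenotypeTable) else p
    labels = []
    for sid, row in df.iterrows():
        braak = row.get("braak_stage")
        cerad = row.get("cerad")
        if pd.isna(braak) or (not isinstance(cerad, str)) or cerad not in CERAD_LEVELS:
            logger.info("subject %s -> other: missing braak/cerad", sid)
            labels.append("other")
            continue
        if rule.use_cognition:
            impaired = row.get("cog_impaired")
            cdr = row.get("cdr")
            if pd.isna(impaired) and pd.isna(cdr):
                logger.info("subject %s -> other: missing cognitive status", sid)
                labels.append("other")
                continue
            if pd.isna(impaired):
                is_imp = cdr >= rule.cdr_case_min
                not_imp = cdr <= rule.cdr_control_max
            else:
                is_imp, not_imp = bool(impaired), not bool(impaired)
        else:
            is_imp = not_imp = True
        if braak >= rule.braak_case_min and cerad in rule.cerad_case and is_imp:
            labels.append("ad")
        elif (braak <= rule.braak_control_max and cerad in rule.cerad_control
              and not_imp):
            labels.append("control")
        else:
            labels.append("other")
    return pd.Series(labels, index=df.index, name="consensus_label")


def baseline_reference(tests: pd.DataFrame, test_cols: list[str],
                       visit_col: str = "visit") -> pd.DataFrame:
    """Population baseline means/SDs per test (computed once, at visit 0)."""
    base = tests[tests[visit_col] == tests[visit_col].min()]
    ref = pd.DataFrame({
        "mean": base[test_cols].mean(),
        "sd": base[test_cols].std(ddof=1),
    })
    if (ref.sd <= 0).any():
        raise PhenotypeError("zero-variance test at baseline")
    return ref


def compute_global_cognition(
    tests: pd.DataFrame,
    domains: dict[str, list[str]],
    baseline_ref: pd.DataFrame,
    min_domain_frac: float = 0.5,
) -> pd.DataFrame:
    """Global cognitive composite per (subject, visit).

    Each test is z-scored against the population baseline reference; tests
    are averaged within domain (a domain counts only when at least
    ``min_domain_frac`` of its tests are present); the global composite is
    the mean of available domain composites, missing when all domains are.
    """
    out = tests[["subject_id", "visit"]].copy()
    if "years" in tests.columns:
        out["years"] = tests["years"]
    domain_cols = []
    for dom, cols in domains.items():
        have = [c for c in cols if c in tests.columns]
        if not have:
            continue
        z = (tests[have] - baseline_ref["mean"].reindex(have)) / \
            baseline_ref["sd"].reindex(have)
        n_present = z.notna().sum(axis=1)
        dvals = z.mean(axis=1)
        dvals[n_present < min_domain_frac * len(cols)] = np.nan
        out[f"domain_{dom}"] = dvals
        domain_cols.append(f"domain_{dom}")
    if not domain_cols:
        raise PhenotypeError("no domain has any test column present")
    out["composite"] = out[domain_cols].mean(axis=1)
    return out


def estimate_cognitive_slope(
    longitudinal: pd.DataFrame,
    composite_col: str = "composite",
    years_col: str = "years",
    min_subjects: int = 20,
) -> pd.Series:
    """Per-subject rate of cognitive change (composite SD units / year).

    Fits a linear mixed model with correlated random intercepts and slopes;
    a subject's slope is the fixed slope plus their empirical-Bayes random
    slope. Subjects with fewer than 2 visits get a missing slope. When the
    trajectories are exactly linear (zero residual), the mixed fit is
    degenerate and per-subject least squares is used instead — the two
    coincide in that limit.
    """
    df = longitudinal.dropna(subset=[composite_col, years_col]).copy()
    visit_counts = df.groupby("subject_id")[years_col].nunique()
    usable = visit_counts[visit_counts >= 2].index
    fit_df = df[df.subject_id.isin(usable)]
    if usable.size < min_subjects:
        raise PhenotypeError(
            f"need >= {min_subjects} subjects with >= 2 visits (have {usable.size})"
        )

    def _per_subject_ols() -> pd.Series:
        out = {}
        for sid, g in fit_df.groupby("subject_id"):
            slope, _ = np.polyfit(g[years_col], g[composite_col], 1)
            out[sid] = slope
        return pd.Series(out, name="slope")

    # degenerate (noiseless) input: per-subject OLS is exact
    resid_ss = 0.0
    for _, g in fit_df.groupby("subject_id"):
        r = np.polyfit(g[years_col], g[composite_col], 1, full=True)[1]
        resid_ss += float(r[0]) if len(r) else 0.0
    if resid_ss < 1e-16 * len(fit_df):
        return _per_subject_ols()

    try:
        model = smf.mixedlm(
            f"{composite_col} ~ {years_col}", data=fit_df,
            groups=fit_df["subject_id"], re_formula=f"~{years_col}",
        )
        res = model.fit(reml=True)
        fixed = float(res.params[years_col])
        slopes = {}
        for sid, re in res.random_effects.items():
            slopes[sid] = fixed + float(re.get(years_col, 0.0))
        return pd.Series(slopes, name="slope")
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("mixed slope model failed; using per-subject OLS")
        return _per_subject_ols()


def compute_residual_cognition(
    p: PhenotypeTable | pd.DataFrame,
    pathology_cols: list[str],
    cognition_col: str = "cognition_at_death",
    demographic_cols: tuple[str, ...] = ("age_at_death", "sex", "education"),
) -> pd.Series:
    """Residual cognition: the part of late-life cognition not explained by
    measured neuropathology and demographics (a cognitive-resilience proxy).

    OLS of cognition proximal to death on the pathology measures plus
    demographics; returns the residuals.
    """
    df = p.cross if isinstance(p, PhenotypeTable) else p
    cols = list(pathology_cols) + list(demographic_cols)
    data = df[[cognition_col] + cols].dropna()
    x = sm.add_constant(data[cols].astype(float))
    if np.linalg.matrix_rank(x.to_numpy()) < x.shape[1]:
        rdiag = np.abs(np.diag(np.linalg.qr(x.to_numpy(), mode="r")))
        bad = [c for c, d in zip(x.columns, rdiag) if d < 1e-10]
        raise PhenotypeError(f"rank-deficient residual-cognition design: {bad}")
    fit = sm.OLS(data[cognition_col], x).fit()
    return fit.resid.rename("residual_cognition")


def compute_global_pathology(
    p: PhenotypeTable | pd.DataFrame,
    components: tuple[str, ...] = ("diffuse_plaques", "neuritic_plaques", "tangles"),
    sqrt_transform: bool = False,
) -> pd.Series:
    """Global AD pathology: the mean of brain-wide diffuse plaques, neuritic
    plaques and neurofibrillary tangles (optionally square-root transformed
    first; off by default). Missing any component makes the score missing."""
    df = p.cross if isinstance(p, PhenotypeTable) else p
    missing_cols = [c for c in components if c not in df.columns]
    if missing_cols:
        raise PhenotypeError(f"missing pathology columns: {missing_cols}")
    vals = df[list(components)].astype(float)
    if sqrt_transform:
        vals = np.sqrt(vals.clip(lower=0))
    out = vals.mean(axis=1)
    out[vals.isna().any(axis=1)] = np.nan
    return out.rename("global_pathology")
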