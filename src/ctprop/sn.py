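"""Single-nucleus cell-type proportions (snCTPs) and bulk concordance.

snCTPs are direct estimates: the percentage of a subject's QC-passing nuclei
annotated to each subclass. Subjects below a minimum nucleus count are
excluded, since percentages from a handful of nuclei are unstable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm


class SnCTPError(RuntimeError):
    pass


@dataclass
class SnCTPMatrix:
    """Subject x subclass percentages (rows sum to 100) and nucleus totals."""

    percents: pd.DataFrame
    n_nuclei: pd.Series


def compute_snctp(
    annotations: pd.DataFrame,
    subclasses: list[str] | None = None,
    min_nuclei: int = 100,
) -> SnCTPMatrix:
    """Count annotated nuclei per (subject, subclass) and convert to percent.

    ``annotations`` needs columns subject_id and subclass. Subclasses absent
    in a subject get 0; subjects with fewer than ``min_nuclei`` nuclei are
    excluded with a warning.
    """
    required = {"subject_id", "subclass"}
    if not required.issubset(annotations.columns):
        raise SnCTPError(f"annotation table needs columns {sorted(required)}")
    counts = pd.crosstab(annotations.subject_id, annotations.subclass)
    if subclasses is not None:
        counts = counts.reindex(columns=subclasses, fill_value=0)
    total = counts.sum(axis=1)
    low = total[total < min_nuclei]
    if len(low):
        warnings.warn(
            f"excluding {len(low)} subject(s) with < {min_nuclei} nuclei: "
            f"{list(low.index)[:5]}"
        )
        counts = counts.loc[total >= min_nuclei]
        total = total[total >= min_nuclei]
    if counts.empty:
        raise SnCTPError("no subjects left after the minimum-nuclei filter")
    percents = counts.div(total, axis=0) * 100.0
    return SnCTPMatrix(percents=percents, n_nuclei=total.rename("n_nuclei"))


def bulk_sn_concordance(
    rctp_scores: pd.DataFrame,
    sn: SnCTPMatrix,
    min_overlap: int = 5,
) -> pd.DataFrame:
    """Per-subclass Spearman correlation across overlapping subjects.

    ``rctp_scores`` must be indexed by subject id (one row per subject).
    """
    shared = rctp_scores.index.intersection(sn.percents.index)
    if len(shared) < min_overlap:
        raise SnCTPError(
            f"only {len(shared)} overlapping subjects (need >= {min_overlap})"
        )
    rows = []
    for sub in rctp_scores.columns:
        if sub not in sn.percents.columns:
            continue
        rho, p = stats.spearmanr(
            rctp_scores.loc[shared, sub], sn.percents.loc[shared, sub]
        )
        rows.append(dict(subclass=sub, rho=float(rho), p=float(p), n=len(shared)))
    return pd.DataFrame(rows).set_index("subclass")


def effect_concordance(bulk_betas: pd.Series, sn_betas: pd.Series) -> float:
    """Spearman rho between per-subclass standardized betas from the bulk and
    single-nucleus analyses (matched on subclass)."""
    shared = bulk_betas.index.intersection(sn_betas.index)
    if len(shared) < 2:
        raise SnCTPError("need at least 2 matched effect estimates")
    rho, _ = stats.spearmanr(bulk_betas.loc[shared], sn_betas.loc[shared])
    return float(rho)


def within_type_expression_model(
    expr: pd.Series,
    annotations: pd.DataFrame,
    subclass: str,
    ad_status: pd.Series,
    snctp: pd.Series,
) -> dict:
    """Disease effect on a gene's expression within one subclass,
    covarying for that subclass's proportion.

    ``expr`` is per-nucleus expression indexed by nucleus_id. Nuclei of the
    subclass are aggregated to subject-level pseudobulk means (nuclei are not
    independent within subject), z-scored, and regressed on AD status plus
    the subclass snCTP. Returns standardized beta, SE and two-sided p.
    """
    ann = annotations[annotations.subclass == subclass]
    if ann.empty:
        raise SnCTPError(f"no nuclei annotated to {subclass!r}")
    vals = expr.reindex(ann.nucleus_id)
    if vals.isna().all():
        raise SnCTPError("expression missing for every nucleus of the subclass")
    by_subject = pd.DataFrame(
        {"expr": vals.to_numpy(), "subject_id": ann.subject_id.to_numpy()}
    ).groupby("subject_id")["expr"].mean()
    df = pd.DataFrame({
        "expr": by_subject,
        "ad": ad_status.reindex(by_subject.index),
        "snctp": snctp.reindex(by_subject.index),
    }).dropna()
    n_case = int((df.ad == 1).sum())
    n_ctrl = int((df.ad == 0).sum())
    if n_case < 2 or n_ctrl < 2:
        raise SnCTPError("need at least 2 subjects per group")
    y = (df.expr - df.expr.mean()) / df.expr.std(ddof=0)
    x = sm.add_constant(df[["ad", "snctp"]])
    fit = sm.OLS(y, x).fit()
    return dict(
        gene=expr.name, subclass=subclass,
        beta=float(fit.params["ad"]), se=float(fit.bse["ad"]),
        p=float(fit.pvalues["ad"]), n=int(len(df)),
    )
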