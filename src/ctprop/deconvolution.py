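"""Relative cell-type proportion (rCTP) estimation by marker-gene profiles.

The rCTP of a subclass in a sample is the sample's score on the first
principal component of that subclass's marker-gene expression: markers are
z-scored per gene across samples (correlation-mode PCA), the PCA is computed
by SVD, and the component sign is fixed so that the sum of loadings is
positive — a higher score always means higher average marker expression,
hence relatively more of the cell type. Scores are z-scored within dataset.

rCTPs are relative latent scores, not absolute proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerGeneSet
from .preprocess import NormalizedMatrix


class DeconvolutionError(RuntimeError):
    pass


@dataclass
class RCTPMatrix:
    """Sample x subclass rCTP scores (z-scored within dataset)."""

    scores: pd.DataFrame
    variance_explained: dict[str, float]
    markers_used: dict[str, list[str]]
    failures: dict[str, str] = field(default_factory=dict)
    dataset: str = ""


def _as_frame(expr) -> pd.DataFrame:
    return expr.log_expr if isinstance(expr, NormalizedMatrix) else expr


def estimate_rctp(
    expr, markers: list[str], min_markers: int = 3,
    drop_misaligned_markers: bool = False,
) -> tuple[pd.Series, float, pd.Series]:
    """PC1 score of the z-scored marker sub-matrix.

    Returns (per-sample scores, variance explained by PC1, loadings).
    Markers absent from the expression matrix are silently dropped (mirroring
    cross-dataset harmonization); zero-variance markers are dropped with a
    warning; fewer than ``min_markers`` remaining is a failure.
    ``drop_misaligned_markers`` optionally removes markers whose PC1 loading
    opposes the majority sign and refits once (off by default).
    """
    frame = _as_frame(expr)
    present = [g for g in markers if g in frame.index]
    x = frame.loc[present].to_numpy(dtype=float).T  # samples x markers
    if x.shape[0] < 4:
        raise DeconvolutionError("need at least 4 samples")
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if (~keep).any():
        warnings.warn(
            f"dropping zero-variance markers: {[g for g, k in zip(present, keep) if not k]}"
        )
    present = [g for g, k in zip(present, keep) if k]
    if len(present) < min_markers:
        raise DeconvolutionError(
            f"only {len(present)} usable markers (< {min_markers}): {present}"
        )
    x = x[:, keep]
    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # scale by sqrt(n markers): PC1 of m identical markers is then exactly the
    # shared z-scored profile, giving the score an average-marker scale
    scores = u[:, 0] * s[0] / np.sqrt(z.shape[1])
    loadings = vt[0]
    lsum = loadings.sum()
    if lsum < 0 or (lsum == 0 and loadings[np.nonzero(loadings)[0][0]] < 0):
        scores, loadings = -scores, -loadings
    if drop_misaligned_markers:
        aligned = loadings > 0
        if aligned.sum() >= min_markers and not aligned.all():
            kept = [g for g, a in zip(present, aligned) if a]
            return estimate_rctp(frame, kept, min_markers, False)
    var_explained = float(s[0] ** 2 / np.sum(s ** 2))
    return (
        pd.Series(scores, index=frame.columns, name="rctp"),
        var_explained,
        pd.Series(loadings, index=present, name="loading"),
    )


def estimate_all(
    expr, m: MarkerGeneSet, min_markers: int = 3,
    drop_misaligned_markers: bool = False,
) -> RCTPMatrix:
    """Estimate rCTPs for every subclass and z-score within the dataset.

    Per-subclass failures are recorded in a partial-result manifest and do
    not abort the remaining subclasses.
    """
    frame = _as_frame(expr)
    cols, var_exp, used, failures = {}, {}, {}, {}
    for sub, genes in m.markers.items():
        try:
            scores, ve, loadings = estimate_rctp(
                frame, genes, min_markers, drop_misaligned_markers
            )
        except DeconvolutionError as e:
            failures[sub] = str(e)
            continue
        z = (scores - scores.mean()) / scores.std(ddof=0)
        cols[sub] = z
        var_exp[sub] = ve
        used[sub] = list(loadings.index)
    if not cols:
        raise DeconvolutionError(f"every subclass failed: {failures}")
    dataset = expr.dataset if isinstance(expr, NormalizedMatrix) else ""
    return RCTPMatrix(
        scores=pd.DataFrame(cols), variance_explained=var_exp,
        markers_used=used, failures=failures, dataset=dataset,
    )


def leave_one_marker_out(expr, markers: list[str], excluded_gene: str,
                         min_markers: int = 3) -> pd.Series:
    """rCTP scores re-estimated with one marker removed."""
    if excluded_gene not in markers:
        raise DeconvolutionError(f"{excluded_gene!r} is not in the marker list")
    remaining = [g for g in markers if g != excluded_gene]
    scores, _, _ = estimate_rctp(expr, remaining, min_markers)
    return scores
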