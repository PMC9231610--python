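"""Shared fixtures: one synthetic end-to-end cohort built once per session.

The cohort uses the package defaults at seed 7 (400 subjects across three
studies and five datasets, 2000 genes, 20 designated markers per subclass)
and is shared between the unit tests and the acceptance tests so the heavy
generation and preprocessing run once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ctprop.deconvolution import estimate_all
from ctprop.markers import harmonize_markers, select_markers
from ctprop.phenotypes import (DiagnosisRule, classify_ad,
                               compute_global_pathology,
                               compute_residual_cognition,
                               estimate_cognitive_slope)
from ctprop.preprocess import preprocess_pipeline
from ctprop.simulate import (PATHOLOGIES, default_design, generate_bulk_cohort,
                             generate_phenotypes, generate_reference,
                             generate_sn_cohort)

COHORT_SEED = 7


@pytest.fixture(scope="session")
def cohort():
    """Reference, bulk datasets, metadata and truth at seed 7."""
    ref, labels, truth = generate_reference(
        n_nuclei_per_type=100, n_genes=2000, seed=COHORT_SEED
    )
    design = default_design(scale=1.0)
    datasets, metadata, truth = generate_bulk_cohort(
        truth, design, seed=COHORT_SEED
    )
    return dict(ref=ref, labels=labels, truth=truth, design=design,
                datasets=datasets, metadata=metadata)


@pytest.fixture(scope="session")
def processed(cohort):
    """Per-dataset normalized matrices, harmonized markers, stacked rCTPs."""
    mset = select_markers(cohort["ref"], cohort["labels"])
    normalized, reports = {}, {}
    for key, cm in cohort["datasets"].items():
        norm, rep = preprocess_pipeline(cm)
        normalized[key] = norm
        reports[key] = rep
    markers = harmonize_markers(
        mset, [set(n.log_expr.index) for n in normalized.values()]
    )
    frames = []
    for key, norm in normalized.items():
        r = estimate_all(norm, markers)
        df = r.scores.copy()
        df.insert(0, "dataset", key)
        frames.append(df)
    rctp = pd.concat(frames)
    meta = cohort["metadata"]
    subclasses = list(cohort["truth"].taxonomy.subclasses)
    subj_rctp = rctp.join(meta[["subject_id"]]).groupby("subject_id")[
        subclasses].mean()
    return dict(markers_raw=mset, markers=markers, normalized=normalized,
                reports=reports, rctp=rctp, subj_rctp=subj_rctp)


@pytest.fixture(scope="session")
def derived(cohort):
    """Cross-sectional phenotypes with all derived columns, at seed 7."""
    pheno = generate_phenotypes(cohort["truth"], seed=COHORT_SEED)
    cross = pheno.cross.copy()
    cross["consensus_label"] = classify_ad(cross, DiagnosisRule())
    cross["cognitive_slope"] = estimate_cognitive_slope(
        pheno.longitudinal).reindex(cross.index)
    cross["global_pathology"] = compute_global_pathology(cross)
    cross["residual_cognition"] = compute_residual_cognition(
        cross, pathology_cols=list(PATHOLOGIES)).reindex(cross.index)
    return dict(pheno=pheno, cross=cross)


@pytest.fixture(scope="session")
def sn_annotations(cohort):
    return generate_sn_cohort(cohort["truth"], n_subjects=40, seed=COHORT_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
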