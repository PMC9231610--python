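"""Cohort design bookkeeping.

Encodes the published per-dataset sample accounting of the three AMP-AD bulk
cohorts (ROS/MAP DLPFC; MSBB frontal pole, inferior frontal gyrus,
parahippocampal gyrus, superior temporal gyrus; Mayo temporal cortex), the
three case/control single-nucleus cohorts, and the single-nucleus reference
composition, as plain data. These printed counts are inputs to the synthetic
generator configuration and to sanity arithmetic; MSBB individuals are shared
across its four regions, so study-level individual counts count MSBB once.
"""

from __future__ import annotations

import pandas as pd

_COHORT_ROWS = [
    # dataset, study, data_type, region, total, controls, ad, other
    ("DLPFC", "ROSMAP", "bulk", "Dorsolateral Prefrontal Cortex", 1092, 138, 285, 669),
    ("FP", "MSBB", "bulk", "Frontal Pole", 134, 44, 90, 0),
    ("IFG", "MSBB", "bulk", "Inferior Frontal Gyrus", 112, 34, 78, 0),
    ("PHG", "MSBB", "bulk", "Parahippocampal Gyrus", 104, 38, 66, 0),
    ("STG", "MSBB", "bulk", "Superior Temporal Gyrus", 117, 35, 82, 0),
    ("TCX", "Mayo", "bulk", "Temporal Cortex", 147, 67, 80, 0),
    ("Mathys", "ROSMAP", "sn", "Dorsolateral Prefrontal Cortex", 47, 9, 16, 22),
    ("Zhou", "ROSMAP", "sn", "Dorsolateral Prefrontal Cortex", 32, 8, 8, 16),
    ("Cain", "ROSMAP", "sn", "Dorsolateral Prefrontal Cortex", 24, 5, 5, 14),
]

#: Non-neuronal nuclei supplementing the cingulate + medial temporal reference,
#: by donor cortical region.
REFERENCE_NONNEURONAL_SUPPLEMENT = {
    "visual": 502,
    "auditory": 742,
    "somatosensory": 595,
    "motor": 781,
}


def cohort_table() -> pd.DataFrame:
    """Per-dataset individual counts for the bulk and single-nucleus cohorts."""
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=["dataset", "study", "data_type", "region", "total", "controls",
                 "ad", "other"],
    )


def bulk_case_control_samples(table: pd.DataFrame | None = None) -> int:
    """Total bulk samples entering the case/control mega-analysis:
    controls + AD summed over every bulk dataset row (regions counted
    separately, since each region contributes a distinct sample)."""
    t = cohort_table() if table is None else table
    bulk = t[t.data_type == "bulk"]
    return int((bulk.controls + bulk.ad).sum())


def bulk_individuals(table: pd.DataFrame | None = None) -> int:
    """Distinct individuals with bulk data, counting each study's shared
    subjects once (MSBB's largest region covers its subject pool)."""
    t = cohort_table() if table is None else table
    bulk = t[t.data_type == "bulk"]
    return int(bulk.groupby("study")["total"].max().sum())


def mega_analysis_individuals(table: pd.DataFrame | None = None) -> int:
    """Individuals meeting case or control criteria, per study, shared
    subjects counted once."""
    t = cohort_table() if table is None else table
    bulk = t[t.data_type == "bulk"].assign(cc=lambda d: d.controls + d.ad)
    return int(bulk.groupby("study")["cc"].max().sum())


def reference_supplement_total() -> int:
    """Total supplementary non-neuronal nuclei in the reference composition."""
    return int(sum(REFERENCE_NONNEURONAL_SUPPLEMENT.values()))
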