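"""Subclass marker-gene derivation from a labeled single-nucleus reference.

A gene is a marker for a subclass when its mean CPM in that subclass is at
least ``fold_threshold`` times the maximum mean CPM over every other subclass
(plus a pseudocount of 1 CPM), and it is detected in at least ``min_detect``
of in-type nuclei. Using the maximum rather than the mean of the other
subclasses makes the statistic robust to one confusable sibling subclass,
the failure mode that matters at subclass resolution. Genes qualifying for
more than one subclass are dropped everywhere, so the final assignment is a
partial function gene -> subclass.

The exact derivation criteria behind published subclass marker panels vary;
the thresholds here are declared defaults and fully configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class MarkerSelectionError(RuntimeError):
    pass


@dataclass
class MarkerGeneSet:
    """Subclass -> ordered marker lists with per-(subclass, gene) statistics."""

    markers: dict[str, list[str]]
    stats: pd.DataFrame  # columns: subclass, gene, in_mean_cpm, max_out_cpm,
    #          fold_enrichment, detect_frac
    min_markers: int = 3

    def __post_init__(self) -> None:
        assigned: dict[str, str] = {}
        for sub, genes in self.markers.items():
            for g in genes:
                if g in assigned:
                    raise ValueError(
                        f"gene {g!r} assigned to both {assigned[g]!r} and {sub!r}"
                    )
                assigned[g] = sub

    @property
    def subclasses(self) -> list[str]:
        return list(self.markers)

    def genes(self) -> set[str]:
        return {g for gs in self.markers.values() for g in gs}


def select_markers(
    reference_counts: pd.DataFrame,
    labels: pd.Series,
    fold_threshold: float = 4.0,
    min_detect: float = 0.3,
    top_n: int = 50,
    pseudocount: float = 1.0,
    min_markers: int = 3,
) -> MarkerGeneSet:
    """Derive subclass-specific markers from nuclei x genes counts.

    Ranks qualifying genes per subclass by fold enrichment, keeps ``top_n``,
    then drops genes qualifying for more than one subclass. Subclasses with
    zero nuclei are excluded with a warning; a subclass ending with no
    markers is an explicit failure naming it.
    """
    if (reference_counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    labels = labels.loc[reference_counts.index]
    present = [s for s in pd.unique(labels) if (labels == s).sum() > 0]
    if len(present) < 2:
        raise MarkerSelectionError("need at least two subclasses with nuclei")
    empty = set(pd.unique(labels)) - set(present)
    for s in sorted(empty):
        warnings.warn(f"subclass {s!r} has zero nuclei; excluded")

    lib = reference_counts.sum(axis=1).to_numpy()[:, None]
    cpm = reference_counts.to_numpy(dtype=float) / np.maximum(lib, 1.0) * 1e6
    genes = reference_counts.columns

    mean_cpm = {}
    detect = {}
    for s in present:
        mask = (labels == s).to_numpy()
        mean_cpm[s] = cpm[mask].mean(axis=0)
        detect[s] = (reference_counts.to_numpy()[mask] > 0).mean(axis=0)
    mean_df = pd.DataFrame(mean_cpm, index=genes)  # genes x subclasses

    qualify: dict[str, pd.DataFrame] = {}
    for s in present:
        others = mean_df.drop(columns=s)
        max_out = others.max(axis=1)
        fold = mean_df[s] / (max_out + pseudocount)
        ok = (fold >= fold_threshold) & (pd.Series(detect[s], index=genes) >= min_detect)
        d = pd.DataFrame({
            "subclass": s,
            "gene": genes[ok],
            "in_mean_cpm": mean_df.loc[ok, s].to_numpy(),
            "max_out_cpm": max_out[ok].to_numpy(),
            "fold_enrichment": fold[ok].to_numpy(),
            "detect_frac": np.asarray(detect[s])[ok.to_numpy()],
        })
        qualify[s] = d

    # exclusivity: drop genes qualifying for more than one subclass
    counts = pd.concat(qualify.values())["gene"].value_counts() if qualify else pd.Series(dtype=int)
    dupes = set(counts[counts > 1].index)

    markers: dict[str, list[str]] = {}
    stats_rows = []
    failed = []
    for s in present:
        d = qualify[s]
        d = d[~d.gene.isin(dupes)].sort_values(
            "fold_enrichment", ascending=False, kind="mergesort"
        ).head(top_n)
        if d.empty:
            failed.append(s)
            continue
        markers[s] = list(d.gene)
        stats_rows.append(d)
    if failed:
        raise MarkerSelectionError(
            f"no markers found for subclasses: {sorted(failed)}"
        )
    stats = pd.concat(stats_rows, ignore_index=True)
    return MarkerGeneSet(markers=markers, stats=stats, min_markers=min_markers)


def harmonize_markers(
    m: MarkerGeneSet, qc_gene_sets: list[set[str]]
) -> MarkerGeneSet:
    """Intersect every subclass list with the genes passing QC in all datasets.

    Order and statistics are carried over. Any subclass falling below
    ``m.min_markers`` is an explicit failure naming it.
    """
    if not qc_gene_sets:
        raise ValueError("qc_gene_sets must be non-empty")
    common = set.intersection(*(set(s) for s in qc_gene_sets))
    new = {s: [g for g in gs if g in common] for s, gs in m.markers.items()}
    short = sorted(s for s, gs in new.items() if len(gs) < m.min_markers)
    if short:
        raise MarkerSelectionError(
            f"harmonization left fewer than {m.min_markers} markers for: {short}"
        )
    stats = m.stats[m.stats.apply(lambda r: r.gene in set(new[r.subclass]), axis=1)]
    return MarkerGeneSet(markers=new, stats=stats.reset_index(drop=True),
                         min_markers=m.min_markers)
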