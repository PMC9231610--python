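"""Readers and writers for the pipeline's on-disk formats.

Counts travel as TSV (genes x samples, index column of gene ids) or
MatrixMarket MTX with sidecar row/column id files; marker sets as two-column
TSV plus a stats TSV; ground truth as a YAML + TSV bundle.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .markers import MarkerGeneSet
from .preprocess import CountMatrix
from .simulate import SyntheticTruth


def write_counts_tsv(c: CountMatrix, path: str | Path) -> None:
    c.counts.to_csv(path, sep="\t")
    if c.covariates is not None:
        c.covariates.to_csv(Path(path).with_suffix(".covariates.tsv"), sep="\t")


def read_counts_tsv(path: str | Path, dataset: str = "") -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    cov_path = Path(path).with_suffix(".covariates.tsv")
    cov = pd.read_csv(cov_path, sep="\t", index_col=0) if cov_path.exists() else None
    return CountMatrix(counts, dataset=dataset or Path(path).stem, covariates=cov)


def write_counts_mtx(counts: pd.DataFrame, prefix: str | Path) -> None:
    prefix = Path(prefix)
    spio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".rows.txt").write_text("\n".join(map(str, counts.index)) + "\n")
    prefix.with_suffix(".cols.txt").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(prefix: str | Path) -> pd.DataFrame:
    prefix = Path(prefix)
    mat = spio.mmread(str(prefix.with_suffix(".mtx")))
    rows = prefix.with_suffix(".rows.txt").read_text().splitlines()
    cols = prefix.with_suffix(".cols.txt").read_text().splitlines()
    return pd.DataFrame(np.asarray(mat.todense()), index=rows, columns=cols)


def write_markers(m: MarkerGeneSet, path: str | Path) -> None:
    rows = [(s, g) for s, gs in m.markers.items() for g in gs]
    pd.DataFrame(rows, columns=["subclass", "gene"]).to_csv(
        path, sep="\t", index=False)
    m.stats.to_csv(Path(path).with_suffix(".stats.tsv"), sep="\t", index=False)


def read_markers(path: str | Path, min_markers: int = 3) -> MarkerGeneSet:
    df = pd.read_csv(path, sep="\t")
    stats_path = Path(path).with_suffix(".stats.tsv")
    stats = (pd.read_csv(stats_path, sep="\t") if stats_path.exists()
             else pd.DataFrame(columns=["subclass", "gene"]))
    markers = {s: list(g.gene) for s, g in df.groupby("subclass", sort=False)}
    return MarkerGeneSet(markers=markers, stats=stats, min_markers=min_markers)


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = dict(
        seed=int(truth.seed),
        logit_sd=float(truth.logit_sd),
        cognition_model={k: float(v) for k, v in truth.cognition_model.items()},
        effect_sizes={k: float(v) for k, v in truth.effect_sizes.items()},
        marker_genes={k: list(v) for k, v in truth.marker_genes.items()},
        subclasses=list(truth.taxonomy.subclasses),
    )
    (outdir / "truth.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    truth.signatures.to_csv(outdir / "signatures.tsv", sep="\t")
    truth.pathology_loadings.to_csv(outdir / "pathology_loadings.tsv", sep="\t")
    if truth.true_proportions is not None:
        truth.true_proportions.to_csv(outdir / "true_proportions.tsv", sep="\t")
    if truth.subjects is not None:
        truth.subjects.to_csv(outdir / "subjects.tsv", sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
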