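"""End-to-end pipeline: simulate -> markers -> preprocess -> rctp -> snctp ->
phenotypes -> associate -> mediate, with config validation, per-stage seeds
and an output manifest.

A single global seed is expanded into per-stage seeds through a counter-based
scheme (SeedSequence([seed, stage_index])), so stages are individually
reproducible and never share streams.
"""

from __future__ import annotations

import hashlib
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .associations import (adjust_pvalues, mega_model, phenotype_battery,
                           results_frame, sn_model, variance_explained)
from .deconvolution import estimate_all
from .markers import harmonize_markers, select_markers
from .mediate import run_four_models
from .phenotypes import (DiagnosisRule, classify_ad, compute_global_pathology,
                         compute_residual_cognition, estimate_cognitive_slope)
from .preprocess import preprocess_pipeline
from .simulate import (PATHOLOGIES, StudyDesign, StudySpec, default_design,
                       generate_bulk_cohort, generate_phenotypes,
                       generate_reference, generate_sn_cohort)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "markers", "preprocess", "rctp", "snctp", "phenotypes",
          "associate", "mediate")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": "ctprop_out",
    "stages": list(STAGES),
    "simulate": {
        "n_genes": 2000, "n_nuclei_per_type": 100, "marker_frac": 0.01,
        "fold": 32.0, "reference_dispersion": 0.2, "design_scale": 0.35,
        "library_size": 2.0e6, "bulk_dispersion": 0.05, "batch_sd": 0.1,
        "n_sn_subjects": 30, "nuclei_min": 800, "nuclei_max": 2000,
        "n_visits": 8,
    },
    "markers": {"fold_threshold": 4.0, "min_detect": 0.3, "top_n": 50,
                "min_markers": 3},
    "preprocess": {"filter_threshold": 15.0, "n_components": 5, "k_iqr": 3.0,
                   "weight_span": 0.5},
    "rctp": {"min_markers": 3, "drop_misaligned_markers": False},
    "snctp": {"min_nuclei": 100},
    "associate": {"n_boot": 100},
    "mediate": {"n_draws": 1000},
}


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Merge with defaults and enumerate every schema violation up front."""
    errors = []
    merged = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for key, val in (config or {}).items():
        if key not in DEFAULT_CONFIG and key != "inputs":
            errors.append(f"unknown config key: {key}")
            continue
        if isinstance(val, dict) and key != "inputs":
            for sub, sval in val.items():
                if sub not in DEFAULT_CONFIG[key]:
                    errors.append(f"unknown config key: {key}.{sub}")
                else:
                    merged[key][sub] = sval
        else:
            merged[key] = val
    for st in merged.get("stages", []):
        if st not in STAGES:
            errors.append(f"unknown stage: {st}")
    for path in (config or {}).get("inputs", {}).values():
        if not Path(path).exists():
            errors.append(f"missing input path: {path}")
    if errors:
        raise ConfigError("; ".join(errors))
    return merged


def load_config(path: str | Path | None) -> dict:
    raw = yaml.safe_load(Path(path).read_text()) if path else {}
    return validate_config(raw or {})


def stage_seed(seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([int(seed), idx]).generate_state(1)[0] % 2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: dict | None = None, seed: int | None = None,
                 outdir: str | Path | None = None) -> dict:
    """Execute the configured stages and return the run manifest.

    Any stage failure halts the run with the stage name in the raised error.
    The manifest records per-stage seeds, row/column counts, and a content
    hash for every file written.
    """
    cfg = validate_config(config or {})
    if seed is not None:
        cfg["seed"] = int(seed)
    out = Path(outdir or cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg["seed"], "stages": {}, "files": {}}
    state: dict = {}
    t0 = time.time()
    for stage in cfg["stages"]:
        s = stage_seed(cfg["seed"], stage)
        logger.info("stage %s (seed %d)", stage, s)
        try:
            info = _STAGE_FUNCS[stage](cfg, state, out, s)
        except Exception as err:
            raise RuntimeError(f"stage {stage!r} failed: {err}") from err
        manifest["stages"][stage] = {"seed": s, **(info or {})}
    for f in sorted(out.rglob("*")):
        if f.is_file():
            manifest["files"][str(f.relative_to(out))] = _hash_file(f)
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    cio.write_json(manifest, out / "manifest.json")
    return manifest


# ---------------------------------------------------------------- stages ---

def _stage_simulate(cfg, state, out, seed):
    p = cfg["simulate"]
    ref, labels, truth = generate_reference(
        n_nuclei_per_type=p["n_nuclei_per_type"], n_genes=p["n_genes"],
        marker_frac=p["marker_frac"], fold=p["fold"],
        dispersion=p["reference_dispersion"], seed=seed,
    )
    design = default_design(scale=p["design_scale"])
    datasets, metadata, truth = generate_bulk_cohort(
        truth, design, library_size=p["library_size"],
        dispersion=p["bulk_dispersion"], batch_sd=p["batch_sd"], seed=seed + 1,
    )
    annotations = generate_sn_cohort(
        truth, n_subjects=p["n_sn_subjects"],
        nuclei_per_subject=(p["nuclei_min"], p["nuclei_max"]), seed=seed + 2,
    )
    pheno = generate_phenotypes(truth, n_visits=p["n_visits"], seed=seed + 3)
    state.update(ref=ref, labels=labels, truth=truth, datasets=datasets,
                 metadata=metadata, annotations=annotations, pheno=pheno)
    cio.write_counts_mtx(ref, out / "reference")
    labels.to_csv(out / "reference_labels.tsv", sep="\t")
    for key, cm in datasets.items():
        cio.write_counts_tsv(cm, out / f"bulk_{key}.tsv")
    metadata.to_csv(out / "sample_metadata.tsv", sep="\t")
    annotations.to_csv(out / "sn_annotations.tsv", sep="\t", index=False)
    pheno.cross.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    pheno.longitudinal.to_csv(out / "cognition_longitudinal.tsv", sep="\t",
                              index=False)
    cio.write_truth(truth, out / "truth")
    return {"n_datasets": len(datasets), "n_subjects": len(truth.subjects),
            "n_nuclei": len(annotations)}


def _stage_markers(cfg, state, out, seed):
    p = cfg["markers"]
    mset = select_markers(state["ref"], state["labels"],
                          fold_threshold=p["fold_threshold"],
                          min_detect=p["min_detect"], top_n=p["top_n"],
                          min_markers=p["min_markers"])
    state["markers_raw"] = mset
    cio.write_markers(mset, out / "markers.tsv")
    return {"n_subclasses": len(mset.markers),
            "n_markers": sum(len(v) for v in mset.markers.values())}


def _stage_preprocess(cfg, state, out, seed):
    p = cfg["preprocess"]
    normalized, reports = {}, {}
    for key, cm in state["datasets"].items():
        norm, rep = preprocess_pipeline(
            cm, filter_threshold=p["filter_threshold"],
            n_components=p["n_components"], k_iqr=p["k_iqr"],
            weight_span=p["weight_span"],
        )
        normalized[key] = norm
        reports[key] = rep
    state["normalized"] = normalized
    qc_sets = [set(n.log_expr.index) for n in normalized.values()]
    state["markers"] = harmonize_markers(state["markers_raw"], qc_sets)
    cio.write_json(reports, out / "qc_report.json")
    return {"datasets": list(normalized)}


def _stage_rctp(cfg, state, out, seed):
    p = cfg["rctp"]
    frames = []
    for key, norm in state["normalized"].items():
        r = estimate_all(norm, state["markers"], min_markers=p["min_markers"],
                         drop_misaligned_markers=p["drop_misaligned_markers"])
        df = r.scores.copy()
        df.insert(0, "dataset", key)
        frames.append(df)
    rctp = pd.concat(frames)
    state["rctp"] = rctp
    rctp.to_csv(out / "rctp.tsv", sep="\t")
    return {"n_samples": len(rctp), "n_subclasses": rctp.shape[1] - 1}


def _stage_snctp(cfg, state, out, seed):
    from .sn import compute_snctp

    snm = compute_snctp(state["annotations"],
                        subclasses=list(state["truth"].taxonomy.subclasses),
                        min_nuclei=cfg["snctp"]["min_nuclei"])
    state["snctp"] = snm
    snm.percents.to_csv(out / "snctp.tsv", sep="\t")
    return {"n_subjects": len(snm.percents)}


def _stage_phenotypes(cfg, state, out, seed):
    pheno = state["pheno"]
    cross = pheno.cross.set_index("subject_id", drop=False) \
        if pheno.cross.index.name != "subject_id" else pheno.cross.copy()
    cross["consensus_label"] = classify_ad(cross, DiagnosisRule())
    slopes = estimate_cognitive_slope(pheno.longitudinal)
    cross["cognitive_slope"] = slopes.reindex(cross.index)
    cross["global_pathology"] = compute_global_pathology(cross)
    cross["residual_cognition"] = compute_residual_cognition(
        cross, pathology_cols=list(PATHOLOGIES)).reindex(cross.index)
    state["derived"] = cross
    cross.to_csv(out / "derived_phenotypes.tsv", sep="\t", index=False)
    return {"n_subjects": len(cross),
            "n_cases": int((cross.consensus_label == "ad").sum())}


def _stage_associate(cfg, state, out, seed):
    meta = state["metadata"]
    rctp = state["rctp"]
    truth = state["truth"]
    subclasses = list(truth.taxonomy.subclasses)
    long = rctp.join(meta[["subject_id", "study", "ad", "age_at_death", "sex"]])
    mega = []
    for sub in subclasses:
        d = long.rename(columns={sub: "score"})[
            ["score", "ad", "subject_id", "study", "age_at_death", "sex"]]
        mega.append(mega_model(d, sub))
    adjust_pvalues(mega, family="mega_cc")
    mega_df = results_frame(mega)
    mega_df.to_csv(out / "mega_case_control.tsv", sep="\t", index=False)

    sn_results = []
    snp = state["snctp"].percents
    derived = state["derived"]
    for sub in subclasses:
        d = pd.DataFrame({
            "snctp": snp[sub],
            "ad": derived.ad.reindex(snp.index),
            "age_at_death": derived.age_at_death.reindex(snp.index),
            "sex": derived.sex.reindex(snp.index),
            "pmi": derived.pmi.reindex(snp.index),
            "subject_id": snp.index,
        })
        try:
            sn_results.append(sn_model(d, sub))
        except Exception as err:  # limited sn overlap can starve a subclass
            logger.warning("sn model failed for %s: %s", sub, err)
    if sn_results:
        adjust_pvalues(sn_results, family="sn_cc")
        results_frame(sn_results).to_csv(out / "sn_case_control.tsv", sep="\t",
                                         index=False)

    subj_rctp = rctp.join(meta[["subject_id"]]).groupby("subject_id")[
        subclasses].mean()
    battery = phenotype_battery(subj_rctp, derived, list(PATHOLOGIES))
    battery.to_csv(out / "phenotype_battery.tsv", sep="\t", index=False)

    vp_data = derived.join(subj_rctp, how="inner")
    vp = variance_explained(
        vp_data, outcome="cognition_at_death",
        baseline_covariates=list(PATHOLOGIES) + ["age_at_death", "sex",
                                                 "education"],
        added_predictor="IT", n_boot=cfg["associate"]["n_boot"], seed=seed,
    )
    cio.write_json(vp.__dict__, out / "variance_partition_it.json")
    state["battery"] = battery
    state["subj_rctp"] = subj_rctp
    return {"n_mega": len(mega), "n_battery": len(battery)}


def _stage_mediate(cfg, state, out, seed):
    data = state["derived"].join(state["subj_rctp"], how="inner")
    res = run_four_models(data, n_draws=cfg["mediate"]["n_draws"], seed=seed)
    rows = pd.DataFrame([r.as_dict() for r in res.values()])
    rows.insert(0, "model", list(res))
    rows.to_csv(out / "mediation.tsv", sep="\t", index=False)
    return {"n_models": len(res)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "markers": _stage_markers,
    "preprocess": _stage_preprocess,
    "rctp": _stage_rctp,
    "snctp": _stage_snctp,
    "phenotypes": _stage_phenotypes,
    "associate": _stage_associate,
    "mediate": _stage_mediate,
}
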