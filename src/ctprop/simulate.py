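"""Synthetic multi-study cohort generator with known ground truth.

Emulates the statistical structure the downstream analysis assumes:

* a labeled single-nucleus reference in which each of the 19 subclasses owns
  a disjoint block of marker genes enriched ``fold``-fold over background;
* multi-study bulk cohorts whose expected counts are mixtures of the subclass
  signatures weighted by subject-level proportions, with negative-binomial
  sampling, multiplicative log-normal batch effects, and log-linear technical
  covariate effects;
* nucleus-level cohorts drawn multinomially from the same true proportions;
* phenotypes (11 neuropathologies, longitudinal cognition, demographics)
  causally linked to the true proportions with configurable effect sizes.

Proportions follow a logistic-normal model: subject logits are Gaussian
around subclass base logits, disease status shifts the logits additively, and
proportions are the softmax. With the default subject logit SD of 1, a
planted logit shift of b corresponds to a standardized group difference of
approximately b SD units on the latent scale, which is what the association
models estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import CountMatrix
from .taxonomy import Taxonomy, default_taxonomy

PATHOLOGIES = (
    "amyloid",
    "diffuse_plaques",
    "neuritic_plaques",
    "phf_tau",
    "tangles",
    "braak_score",
    "gross_infarcts",
    "atherosclerosis",
    "alpha_synuclein",
    "tdp43",
    "hippocampal_sclerosis",
)

#: The three measures averaged into the global AD pathology score.
GLOBAL_PATHOLOGY_COMPONENTS = ("diffuse_plaques", "neuritic_plaques", "tangles")

AMYLOID_TAU_PATHOLOGIES = (
    "amyloid",
    "diffuse_plaques",
    "neuritic_plaques",
    "phf_tau",
    "tangles",
    "braak_score",
)

#: 17 cognitive tests in 5 domains.
COGNITIVE_DOMAINS = {
    "episodic_memory": ["em1", "em2", "em3", "em4"],
    "semantic_memory": ["sm1", "sm2", "sm3", "sm4"],
    "working_memory": ["wm1", "wm2", "wm3"],
    "perceptual_speed": ["ps1", "ps2", "ps3"],
    "visuospatial": ["vs1", "vs2", "vs3"],
}


class GeneratorError(ValueError):
    pass


# --------------------------------------------------------------------------
# defaults: base composition, AD shifts, phenotype couplings
# --------------------------------------------------------------------------

_BASE_PROPORTIONS = {
    "LAMP5": 0.020, "PAX6": 0.008, "SST": 0.035, "VIP": 0.030, "PVALB": 0.040,
    "IT": 0.200, "L4 IT": 0.050, "L5 6 IT Car3": 0.015, "L5 6 NP": 0.012,
    "L5 ET": 0.008, "L6 CT": 0.040, "L6b": 0.015,
    "Astrocyte": 0.150, "Oligodendrocyte": 0.250, "OPC": 0.040,
    "Microglia": 0.050, "Endothelial": 0.020, "Pericyte": 0.009, "VLMC": 0.008,
}

#: Default disease shifts on the logit scale: interneuron and IT deficits,
#: mild non-neuronal relative gains.
DEFAULT_EFFECT_SIZES = {
    "LAMP5": -0.20, "PAX6": -0.10, "SST": -0.50, "VIP": -0.15, "PVALB": -0.25,
    "IT": -0.40, "L4 IT": -0.20, "L5 6 IT Car3": 0.10, "L5 6 NP": -0.15,
    "L5 ET": 0.0, "L6 CT": -0.20, "L6b": 0.10,
    "Astrocyte": 0.15, "Oligodendrocyte": 0.10, "OPC": 0.05,
    "Microglia": 0.10, "Endothelial": 0.0, "Pericyte": 0.05, "VLMC": 0.10,
}

DEFAULT_COGNITION_MODEL = dict(
    slope_mean=-0.05, slope_sd=0.03,
    slope_sst=0.02, slope_it=0.03, slope_path=-0.03,
    intercept_sst=0.10, intercept_it=0.20, intercept_path=-0.25,
    intercept_sd=0.30,
)


def default_pathology_loadings(taxonomy: Taxonomy) -> pd.DataFrame:
    """Linear loadings of standardized subclass logits on each pathology.

    By default only SST is loaded, negatively, on the amyloid- and
    tau-related measures; every other entry is 0.
    """
    m = pd.DataFrame(
        0.0, index=list(PATHOLOGIES), columns=list(taxonomy.subclasses)
    )
    for p in AMYLOID_TAU_PATHOLOGIES:
        m.loc[p, "SST"] = -0.45
    return m


@dataclass
class StudySpec:
    name: str
    regions: tuple[str, ...]
    n_cases: int
    n_controls: int
    n_other: int = 0
    shared_subjects: bool = True
    region_n: dict[str, int] | None = None  # per-region subject subsample

    @property
    def n_subjects(self) -> int:
        return self.n_cases + self.n_controls + self.n_other


@dataclass
class StudyDesign:
    studies: list[StudySpec]
    n_batches: int = 3

    def validate(self) -> None:
        if not self.studies:
            raise GeneratorError("design needs at least one study")
        for s in self.studies:
            if s.n_cases < 0 or s.n_controls < 0 or s.n_other < 0:
                raise GeneratorError(f"negative group size in study {s.name}")
            if not s.regions:
                raise GeneratorError(f"study {s.name} has no regions")

    @property
    def n_subjects(self) -> int:
        return sum(s.n_subjects for s in self.studies)


def default_design(scale: float = 1.0) -> StudyDesign:
    """Three-study design echoing the real cohort structure at desk scale:
    one large single-region study with 'other' subjects, one multi-region
    study with shared subjects, and one single-region case/control study."""
    f = lambda n: max(2, int(round(n * scale)))
    return StudyDesign(
        studies=[
            StudySpec("rosmap_like", ("DLPFC",), f(100), f(100), f(40)),
            StudySpec("msbb_like", ("FP", "STG"), f(40), f(40), 0),
            StudySpec("mayo_like", ("TCX",), f(40), f(40), 0),
        ]
    )


@dataclass
class SyntheticTruth:
    """Everything the generators know and the analysis must recover."""

    taxonomy: Taxonomy
    signatures: pd.DataFrame                 # subclass x gene
    marker_genes: dict[str, list[str]]
    base_logits: pd.Series
    logit_sd: float
    effect_sizes: pd.Series                  # logit-scale AD shift
    pathology_loadings: pd.DataFrame         # pathology x subclass
    cognition_model: dict
    seed: int
    subjects: pd.DataFrame | None = None     # per-subject metadata
    true_logits: pd.DataFrame | None = None  # subject x subclass
    true_proportions: pd.DataFrame | None = None

    def require_subjects(self) -> pd.DataFrame:
        if self.subjects is None:
            raise GeneratorError("truth has no subjects; run draw_subjects first")
        return self.subjects


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with Var = mu + dispersion * mu^2 (gamma-Poisson)."""
    mu = np.maximum(mu, 1e-12)
    if dispersion <= 1e-12:
        return rng.poisson(mu)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam)


# --------------------------------------------------------------------------
# reference generator
# --------------------------------------------------------------------------

def generate_reference(
    taxonomy: Taxonomy | None = None,
    n_nuclei_per_type: int = 200,
    n_genes: int = 2000,
    marker_frac: float = 0.01,
    fold: float = 32.0,
    dispersion: float = 0.2,
    library_size: float = 20_000.0,
    logit_sd: float = 1.0,
    effect_sizes: dict[str, float] | None = None,
    pathology_loadings: pd.DataFrame | None = None,
    cognition_model: dict | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, SyntheticTruth]:
    """Generate a labeled single-nucleus reference and the study truth.

    Each subclass owns a disjoint block of ``round(marker_frac * n_genes)``
    designated marker genes whose signature expression is ``fold`` times the
    gene's background level. Nucleus counts are negative binomial around the
    library-scaled signature. Returns (nuclei x genes counts, labels, truth).
    """
    taxonomy = taxonomy or default_taxonomy()
    if n_nuclei_per_type <= 0 or n_genes <= 0:
        raise GeneratorError("n_nuclei_per_type and n_genes must be positive")
    if fold < 1:
        raise GeneratorError("fold must be >= 1")
    n_mark = int(round(marker_frac * n_genes))
    if n_mark < 1:
        raise GeneratorError("marker_frac * n_genes must be >= 1")
    if n_mark * taxonomy.n_subclasses > n_genes:
        raise GeneratorError("marker blocks exceed the gene universe")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(mean=np.log(5.0), sigma=1.0, size=n_genes)

    sig = np.tile(base, (taxonomy.n_subclasses, 1))
    marker_genes: dict[str, list[str]] = {}
    for i, sub in enumerate(taxonomy.subclasses):
        block = slice(i * n_mark, (i + 1) * n_mark)
        if fold > 1:
            sig[i, block] = base[block] * fold
            marker_genes[sub] = genes[block]
        else:
            marker_genes[sub] = []
    signatures = pd.DataFrame(sig, index=list(taxonomy.subclasses), columns=genes)

    counts = np.empty((taxonomy.n_subclasses * n_nuclei_per_type, n_genes), dtype=np.int64)
    labels = []
    for i, sub in enumerate(taxonomy.subclasses):
        mu = library_size * sig[i] / sig[i].sum()
        block = _nb_draw(rng, np.tile(mu, (n_nuclei_per_type, 1)), dispersion)
        counts[i * n_nuclei_per_type:(i + 1) * n_nuclei_per_type] = block
        labels += [sub] * n_nuclei_per_type

    nucleus_ids = [f"n{i:06d}" for i in range(counts.shape[0])]
    ref = pd.DataFrame(counts, index=nucleus_ids, columns=genes)
    lab = pd.Series(labels, index=nucleus_ids, name="subclass")

    base_logits = pd.Series(
        {k: np.log(v) for k, v in _BASE_PROPORTIONS.items()}
    ).loc[list(taxonomy.subclasses)]
    eff = dict(DEFAULT_EFFECT_SIZES)
    if effect_sizes:
        eff.update(effect_sizes)
    truth = SyntheticTruth(
        taxonomy=taxonomy,
        signatures=signatures,
        marker_genes=marker_genes,
        base_logits=base_logits,
        logit_sd=logit_sd,
        effect_sizes=pd.Series(eff).loc[list(taxonomy.subclasses)],
        pathology_loadings=(
            pathology_loadings
            if pathology_loadings is not None
            else default_pathology_loadings(taxonomy)
        ),
        cognition_model=dict(cognition_model or DEFAULT_COGNITION_MODEL),
        seed=seed,
    )
    return ref, lab, truth


# --------------------------------------------------------------------------
# subject and bulk cohort generators
# --------------------------------------------------------------------------

_GROUP_SHIFT = {"control": 0.0, "ad": 1.0, "other": 0.5}


def draw_subjects(truth: SyntheticTruth, design: StudyDesign, seed: int = 0) -> SyntheticTruth:
    """Draw per-subject proportion vectors and demographics for a design.

    Subject logits = base logits + N(0, logit_sd) + group multiplier x AD
    effect sizes; proportions are the row-wise softmax. AD cases get the full
    shift, controls none, 'other' subjects (not meeting either criterion)
    half. Fills ``subjects``, ``true_logits`` and ``true_proportions``.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    subs = list(truth.taxonomy.subclasses)
    rows, logits = [], []
    for study in design.studies:
        groups = (["ad"] * study.n_cases + ["control"] * study.n_controls
                  + ["other"] * study.n_other)
        for i, grp in enumerate(groups):
            sid = f"{study.name}_s{i:04d}"
            shift = _GROUP_SHIFT[grp] * truth.effect_sizes.to_numpy()
            lg = (truth.base_logits.to_numpy()
                  + rng.normal(0.0, truth.logit_sd, len(subs)) + shift)
            logits.append(lg)
            rows.append(dict(
                subject_id=sid, study=study.name, group=grp,
                ad=1.0 if grp == "ad" else (0.0 if grp == "control" else np.nan),
                age_at_death=float(np.clip(rng.normal(85, 6), 60, 105)),
                age_baseline=float(np.clip(rng.normal(78, 6), 55, 100)),
                sex=int(rng.integers(0, 2)),
                education=float(np.clip(rng.normal(16, 3), 6, 25)),
                pmi=float(np.clip(rng.lognormal(np.log(8.0), 0.5), 1, 48)),
                apoe4=int(rng.binomial(2, 0.2)),
            ))
    subjects = pd.DataFrame(rows).set_index("subject_id", drop=False)
    lg = pd.DataFrame(np.array(logits), index=subjects.index, columns=subs)
    ex = np.exp(lg.to_numpy() - lg.to_numpy().max(axis=1, keepdims=True))
    props = pd.DataFrame(ex / ex.sum(axis=1, keepdims=True),
                         index=subjects.index, columns=subs)
    return replace(truth, subjects=subjects, true_logits=lg, true_proportions=props)


def generate_bulk_cohort(
    truth: SyntheticTruth,
    design: StudyDesign,
    library_size: float = 2e6,
    dispersion: float = 0.05,
    batch_sd: float = 0.1,
    cov_effect_sd: float = 0.02,
    seed: int = 0,
) -> tuple[dict[str, CountMatrix], pd.DataFrame, SyntheticTruth]:
    """Generate one CountMatrix per (study, region) plus sample metadata.

    Expected count of gene g in sample i is proportional to
    sum_k p_ik * s_gk, scaled to ``library_size``, multiplied by a log-normal
    per-(gene, batch) effect (SD ``batch_sd``) and by log-linear effects of
    the standardized technical covariates (per-gene coefficient SD
    ``cov_effect_sd``), then sampled negative-binomially. Samples of the same
    subject in different regions share the subject's true proportion vector.
    """
    rng = np.random.default_rng(seed)
    if truth.subjects is None:
        truth = draw_subjects(truth, design, seed=int(rng.integers(2**31)))
    subjects = truth.require_subjects()
    genes = list(truth.signatures.columns)
    sig = truth.signatures.to_numpy()  # subclass x gene

    gamma = {c: rng.normal(0.0, cov_effect_sd, len(genes))
             for c in ("rin", "pmi", "pct_mapped", "pct_usable")}
    batch_offsets: dict[tuple[str, int], np.ndarray] = {}

    datasets: dict[str, CountMatrix] = {}
    meta_rows = []
    for study in design.studies:
        study_subjects = subjects[subjects.study == study.name]
        if study_subjects.empty:
            continue
        if study.shared_subjects or len(study.regions) == 1:
            region_pools = {r: study_subjects for r in study.regions}
        else:
            chunks = np.array_split(
                rng.permutation(len(study_subjects)), len(study.regions))
            region_pools = {
                r: study_subjects.iloc[np.sort(ch)]
                for r, ch in zip(study.regions, chunks)
            }
        for region in study.regions:
            pool = region_pools[region]
            n_region = (study.region_n or {}).get(region, len(pool))
            take = pool.iloc[
                rng.choice(len(pool), size=min(n_region, len(pool)), replace=False)
            ].sort_index()
            props = truth.true_proportions.loc[take.index].to_numpy()
            expected = props @ sig  # samples x genes
            expected = expected / expected.sum(axis=1, keepdims=True) * library_size

            n = len(take)
            batch = rng.integers(0, design.n_batches, n)
            rin = rng.normal(7.0, 0.5, n)
            pct_mapped = rng.normal(85.0, 3.0, n)
            pct_usable = rng.normal(70.0, 5.0, n)
            pmi = take.pmi.to_numpy()

            log_mu = np.log(expected)
            for b in np.unique(batch):
                key = (study.name, int(b))
                if key not in batch_offsets:
                    batch_offsets[key] = rng.normal(0.0, batch_sd, len(genes))
                log_mu[batch == b] += batch_offsets[key]
            for name, vals in (("rin", rin), ("pmi", pmi),
                               ("pct_mapped", pct_mapped),
                               ("pct_usable", pct_usable)):
                z = (vals - vals.mean()) / (vals.std() + 1e-12)
                log_mu += np.outer(z, gamma[name])

            counts = _nb_draw(rng, np.exp(log_mu), dispersion)
            sample_ids = [f"{study.name}_{region}_{sid}" for sid in take.index]
            key = f"{study.name}_{region}"
            cov = pd.DataFrame(dict(
                subject_id=take.index, study=study.name, region=region,
                dataset=key, ad=take.ad.to_numpy(), group=take.group.to_numpy(),
                age_at_death=take.age_at_death.to_numpy(),
                sex=take.sex.to_numpy(),
                batch=[f"{study.name}_b{b}" for b in batch],
                rin=rin, pmi=pmi, pct_mapped=pct_mapped, pct_usable=pct_usable,
            ), index=sample_ids)
            datasets[key] = CountMatrix(
                pd.DataFrame(counts.T, index=genes, columns=sample_ids),
                dataset=key, covariates=cov,
            )
            meta_rows.append(cov)
    metadata = pd.concat(meta_rows)
    return datasets, metadata, truth


def generate_sn_cohort(
    truth: SyntheticTruth,
    n_subjects: int,
    nuclei_per_subject: tuple[int, int] = (800, 2000),
    seed: int = 0,
) -> pd.DataFrame:
    """Nucleus annotation table (subject_id, nucleus_id, subclass).

    Per subject, subclass labels are drawn multinomially from the subject's
    true proportion vector; nucleus totals are uniform over the given range.
    """
    subjects = truth.require_subjects()
    if subjects.empty:
        raise GeneratorError("empty subject set")
    rng = np.random.default_rng(seed)
    take = subjects.index[
        rng.choice(len(subjects), size=min(n_subjects, len(subjects)), replace=False)
    ].sort_values()
    lo, hi = nuclei_per_subject
    subs = list(truth.taxonomy.subclasses)
    rows = []
    for sid in take:
        n = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        counts = rng.multinomial(n, truth.true_proportions.loc[sid].to_numpy())
        labels = np.repeat(np.arange(len(subs)), counts)
        rng.shuffle(labels)
        for j, li in enumerate(labels):
            rows.append((sid, f"{sid}_n{j:05d}", subs[li]))
    return pd.DataFrame(rows, columns=["subject_id", "nucleus_id", "subclass"])


def generate_nucleus_gene_expression(
    truth: SyntheticTruth,
    annotations: pd.DataFrame,
    gene: str,
    library_size: float = 20_000.0,
    dispersion: float = 0.3,
    ad_log_shift: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.Series:
    """Per-nucleus counts for one gene, NB around the subclass signature.

    ``ad_log_shift`` optionally shifts the log mean within given subclasses
    for nuclei from AD subjects, planting within-type expression change that
    is independent of proportions.
    """
    if gene not in truth.signatures.columns:
        raise GeneratorError(f"gene {gene!r} not in signature universe")
    rng = np.random.default_rng(seed)
    subjects = truth.require_subjects()
    sig = truth.signatures
    mu_by_sub = {
        s: library_size * sig.loc[s, gene] / sig.loc[s].sum()
        for s in truth.taxonomy.subclasses
    }
    ad = subjects.ad.reindex(annotations.subject_id).fillna(0.0).to_numpy()
    mu = np.array([mu_by_sub[s] for s in annotations.subclass])
    if ad_log_shift:
        for sub, shift in ad_log_shift.items():
            mask = (annotations.subclass.to_numpy() == sub) & (ad == 1.0)
            mu[mask] *= np.exp(shift)
    counts = _nb_draw(rng, mu, dispersion)
    return pd.Series(counts, index=annotations.nucleus_id.to_numpy(), name=gene)


# --------------------------------------------------------------------------
# phenotype generator
# --------------------------------------------------------------------------

def generate_phenotypes(
    truth: SyntheticTruth,
    n_visits: int = 8,
    noise_sd: float = 0.25,
    pathology_noise_sd: float = 0.9,
    ad_pathology_shift: float = 1.2,
    test_noise_sd: float = 0.3,
    seed: int = 0,
):
    """Generate pathology, longitudinal cognition and raw test scores.

    Pathologies are linear in the standardized subclass logits via
    ``truth.pathology_loadings`` plus a direct disease shift and Gaussian
    noise; higher values mean worse pathology. Cognitive trajectories are
    linear per subject: intercept and annual slope each load on standardized
    SST and IT logits and on global pathology per ``truth.cognition_model``.
    Returns a PhenotypeTable (cross-sectional, longitudinal, raw tests).
    """
    from .phenotypes import PhenotypeTable  # local import to avoid a cycle

    if n_visits < 2:
        raise GeneratorError("n_visits must be >= 2: slopes are undefined otherwise")
    rng = np.random.default_rng(seed)
    subjects = truth.require_subjects().copy()
    n = len(subjects)
    z = (truth.true_logits - truth.true_logits.mean()) / truth.true_logits.std(ddof=0)

    load = truth.pathology_loadings
    group_mult = subjects.group.map(_GROUP_SHIFT).to_numpy()
    path = {}
    for p in PATHOLOGIES:
        val = z.to_numpy() @ load.loc[p].to_numpy()
        val = val + ad_pathology_shift * group_mult + rng.normal(0, pathology_noise_sd, n)
        path[p] = val
    path_df = pd.DataFrame(path, index=subjects.index)

    gpath = path_df[list(GLOBAL_PATHOLOGY_COMPONENTS)].mean(axis=1)
    zg = ((gpath - gpath.mean()) / (gpath.std(ddof=0) + 1e-12)).to_numpy()
    cm = truth.cognition_model
    z_sst, z_it = z["SST"].to_numpy(), z["IT"].to_numpy()
    slope = (cm["slope_mean"] + cm["slope_sst"] * z_sst + cm["slope_it"] * z_it
             + cm["slope_path"] * zg + rng.normal(0, cm["slope_sd"], n))
    intercept = (cm["intercept_sst"] * z_sst + cm["intercept_it"] * z_it
                 + cm["intercept_path"] * zg + rng.normal(0, cm["intercept_sd"], n))

    years = np.arange(n_visits, dtype=float)
    long_rows = []
    composite = np.empty((n, n_visits))
    for v, t in enumerate(years):
        composite[:, v] = intercept + slope * t + rng.normal(0, noise_sd, n)
    for i, sid in enumerate(subjects.index):
        for v, t in enumerate(years):
            long_rows.append((sid, v, t, composite[i, v]))
    longitudinal = pd.DataFrame(
        long_rows, columns=["subject_id", "visit", "years", "composite"]
    )

    # raw test scores on arbitrary scales: test = m_j + a_j * (composite + noise)
    test_rng = np.random.default_rng(truth.seed + 1)  # fixed scales per truth
    tests = [t for ts in COGNITIVE_DOMAINS.values() for t in ts]
    scales = {t: (test_rng.normal(20, 5), test_rng.uniform(2, 6)) for t in tests}
    test_cols = {}
    for t in tests:
        m_j, a_j = scales[t]
        noise = rng.normal(0, test_noise_sd, composite.shape)
        test_cols[t] = (m_j + a_j * (composite + noise)).ravel()
    test_df = pd.DataFrame(test_cols)
    test_df.insert(0, "subject_id", np.repeat(subjects.index.to_numpy(), n_visits))
    test_df.insert(1, "visit", np.tile(np.arange(n_visits), n))
    test_df.insert(2, "years", np.tile(years, n))

    cross = subjects.copy()
    for p in PATHOLOGIES:
        cross[p] = path_df[p]
    cross["cognition_at_death"] = composite[:, -1]
    zt = (path_df.phf_tau - path_df.phf_tau.mean()) / path_df.phf_tau.std(ddof=0)
    cross["braak_stage"] = np.clip(np.round(3 + 1.2 * zt), 0, 6).astype(int)
    zn = (path_df.neuritic_plaques - path_df.neuritic_plaques.mean()) / \
        path_df.neuritic_plaques.std(ddof=0)
    cross["cerad"] = pd.cut(
        zn, [-np.inf, -0.5, 0.0, 0.7, np.inf],
        labels=["none", "sparse", "moderate", "frequent"],
    ).astype(str)
    cross["cog_impaired"] = cross["cognition_at_death"] < -0.6
    cross["cdr"] = np.where(
        cross.cog_impaired, rng.choice([1.0, 2.0, 3.0], n), rng.choice([0.0, 0.5], n)
    )
    return PhenotypeTable(cross=cross, longitudinal=longitudinal, tests=test_df)


# --------------------------------------------------------------------------
# lightweight latent-score tables for model calibration studies
# --------------------------------------------------------------------------

def simulate_score_table(
    design: StudyDesign,
    effect: float = 0.0,
    logit_sd: float = 1.0,
    measurement_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Stacked per-sample latent-score table for one cell type.

    Bypasses count simulation: each subject carries one latent level
    (N(0, logit_sd) plus ``effect`` for AD cases); each of the subject's
    regional samples observes it with independent N(0, measurement_sd) noise,
    z-scored within dataset. Used for calibration studies of the mega-model,
    where the quantity of interest is the model's error control rather than
    the deconvolution path.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for study in design.studies:
        groups = (["ad"] * study.n_cases + ["control"] * study.n_controls
                  + ["other"] * study.n_other)
        for i, grp in enumerate(groups):
            sid = f"{study.name}_s{i:04d}"
            latent = rng.normal(0, logit_sd) + _GROUP_SHIFT[grp] * effect
            age = float(rng.normal(85, 6))
            sex = int(rng.integers(0, 2))
            pmi = float(np.clip(rng.lognormal(np.log(8.0), 0.5), 1, 48))
            for region in study.regions:
                rows.append(dict(
                    sample_id=f"{study.name}_{region}_{sid}", subject_id=sid,
                    study=study.name, dataset=f"{study.name}_{region}",
                    group=grp,
                    ad=1.0 if grp == "ad" else (0.0 if grp == "control" else np.nan),
                    age_at_death=age, sex=sex, pmi=pmi,
                    score=latent + rng.normal(0, measurement_sd),
                ))
    df = pd.DataFrame(rows)
    df["score"] = df.groupby("dataset")["score"].transform(
        lambda s: (s - s.mean()) / s.std(ddof=0)
    )
    return df
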