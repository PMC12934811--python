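"""Synthetic multi-study drug-screen generator with known ground truth.

Emulates the structure of heterogeneous ex vivo screening efforts: several
studies with partially overlapping drug panels and study-specific dose designs
(including single-dose libraries), monotone Hill-type ground-truth curves,
tissue×mechanism sensitivity effects, mutation-driven effects, a metastatic
resistance shift, cell-line-vs-ex-vivo class shifts, affine study batch
effects on the viability scale, and matched mutation/expression/gene-set
outputs. Every draw is a deterministic function of the config seed.

Ground-truth curves follow a descending Hill law with top fixed at 1:

    v(c) = bottom + (1 - bottom) / (1 + 10^(slope * (log10 c - log10 IC50)))

and all class/mutation/tissue effects act additively on log10 IC50, so the
true curves remain monotone non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .screen_data import DrugAnnotation, SampleAnnotation, ScreenDataset

TISSUES = [
    "lung", "breast", "pancreas", "bowel", "skin", "brain", "blood", "liver",
    "ovary", "kidney", "bone", "prostate",
]
DISEASES = [
    "LUAD", "BRCA", "PAAD", "COADREAD", "MEL", "GBM", "AML", "HCC",
    "OVT", "RCC", "OS", "PRAD",
]
MECHANISMS = [
    "microtubule inhibitor", "proteasome inhibitor", "MEK inhibitor",
    "topoisomerase inhibitor", "PI3K inhibitor", "HDAC inhibitor",
    "EGFR inhibitor", "BCL2 inhibitor", "CDK inhibitor", "DNA synthesis inhibitor",
]
GENES = ["TP53", "KRAS", "BRAF", "FLT3", "NPM1", "EGFR", "PIK3CA", "PTEN"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the generator. Defaults are the package's
    "paper-shaped small" screen: 6 studies of 30 samples, 120 drugs across 10
    mechanism classes, 8 tissues, 5-dose curves with one single-dose study."""

    n_studies: int = 6
    samples_per_study: int = 30
    n_drugs: int = 120
    n_tissues: int = 8
    n_mechanisms: int = 10
    doses_per_curve: int = 5
    n_single_dose_studies: int = 1
    panel_fraction: float = 0.5
    hill_slope_range: tuple = (0.7, 2.0)
    ic50_log10_range: tuple = (-2.0, 1.0)
    bottom_range: tuple = (0.0, 0.3)
    tissue_mech_effect_sd: float = 0.0
    planted_effects: tuple = (
        (0, 0, -1.2), (1, 2, -1.2), (2, 4, -1.2),
        (3, 6, -1.2), (4, 8, -1.2), (5, 9, -1.2),
    )  # (tissue index, mechanism index, log10 IC50 shift); negative = sensitive
    mutation_effect_table: tuple = (("KRAS", 2, -0.8), ("TP53", 7, 0.8))
    mutation_prevalence: float = 0.3
    met_fraction: float = 0.15
    met_resistance_shift: float = 0.4
    cellline_studies: tuple = ()
    cellline_class_shift_table: tuple = ((0, -0.8), (6, 0.8))
    latent_dim: int = 4
    latent_scale: float = 0.45
    sample_ic50_sd: float = 0.25
    batch_offset_sd: float = 0.05
    batch_scale_sd: float = 0.08
    noise_sd: float = 0.05
    n_genes: int = 60
    n_pathways: int = 5
    genes_per_pathway: int = 10
    pathway_coupling: float = 1.0
    expression_noise_sd: float = 0.4
    seed: int = 1

    def __post_init__(self):
        for name in (
            "tissue_mech_effect_sd", "batch_offset_sd", "batch_scale_sd",
            "noise_sd", "sample_ic50_sd", "expression_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.samples_per_study < 1:
            raise ConfigError("samples_per_study must be >= 1")
        if not (0 < self.panel_fraction <= 1):
            raise ConfigError("panel_fraction must be in (0, 1]")
        if self.seed is None:
            raise ConfigError("seed is mandatory")

    def with_(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """True generative state: per-(sample, drug) Hill parameters, study batch
    affine transforms, sample latent factors, and the mutation matrix."""

    sample_ids: list
    drug_ids: list
    study_of_sample: dict
    log10_ic50: np.ndarray       # (n_samples, n_drugs)
    slope: np.ndarray            # (n_drugs,)
    bottom: np.ndarray           # (n_drugs,)
    batch_offset: dict           # study -> additive viability offset
    batch_scale: dict            # study -> multiplicative viability scale
    latent: np.ndarray           # (n_samples, latent_dim)
    mech_loadings: np.ndarray    # (n_mechanisms, latent_dim)
    mutations: np.ndarray        # (n_samples, n_genes) binary
    gene_names: list
    mechanism_of_drug: dict

    def _idx(self, sample_id: str, drug_id: str):
        return self.sample_ids.index(sample_id), self.drug_ids.index(drug_id)

    def true_viability(self, sample_id: str, drug_id: str, log10_conc) -> np.ndarray:
        i, j = self._idx(sample_id, drug_id)
        x = np.asarray(log10_conc, float)
        b = self.bottom[j]
        return b + (1.0 - b) / (
            1.0 + 10.0 ** (self.slope[j] * (x - self.log10_ic50[i, j]))
        )

    def true_auc(self, sample_id: str, drug_id: str, lo: float, hi: float, n: int = 200) -> float:
        x = np.linspace(lo, hi, n)
        v = self.true_viability(sample_id, drug_id, x)
        return float(np.trapezoid(v, x) / (hi - lo))


def _study_ids(cfg: SyntheticConfig) -> list[str]:
    return [f"study_{k}" for k in range(cfg.n_studies)]


def simulate_cohort(cfg: SyntheticConfig):
    """Sample annotations plus latent factors, deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    tissues = TISSUES[: cfg.n_tissues]
    diseases = DISEASES[: cfg.n_tissues]
    samples: dict[str, SampleAnnotation] = {}
    latent = []
    for k, study in enumerate(_study_ids(cfg)):
        is_cl = k in cfg.cellline_studies
        for s in range(cfg.samples_per_study):
            sid = f"{study}_s{s:03d}"
            t = s % cfg.n_tissues  # balanced tissue assignment
            is_met = bool(rng.random() < cfg.met_fraction)
            met_site = None
            if is_met:
                met_site = tissues[int(rng.integers(0, cfg.n_tissues))]
            z = rng.normal(size=cfg.latent_dim)
            tmb = max(0, int(round(20.0 + 10.0 * z[0] + rng.normal(0, 2.0))))
            samples[sid] = SampleAnnotation(
                sample_id=sid,
                study_id=study,
                oncotree_code=diseases[t],
                primary_site=tissues[t],
                metastatic_site=met_site,
                is_metastasis=is_met,
                model_type="cell_line" if is_cl else ("PDC" if s % 2 == 0 else "PDO"),
                tmb=tmb,
            )
            latent.append(z)
    return samples, np.array(latent)


def make_drug_annotations(cfg: SyntheticConfig) -> dict[str, DrugAnnotation]:
    mechs = MECHANISMS[: cfg.n_mechanisms]
    diseases = DISEASES[: cfg.n_tissues]
    drugs = {}
    for j in range(cfg.n_drugs):
        did = f"drug_{j:03d}"
        mech = mechs[j % cfg.n_mechanisms]
        # standard-of-care flag for the disease planted as sensitive to this class
        soc = {
            diseases[t]
            for (t, m, shift) in cfg.planted_effects
            if m == j % cfg.n_mechanisms and shift < 0 and t < cfg.n_tissues
        }
        drugs[did] = DrugAnnotation(
            drug_id=did,
            canonical_name=did,
            mechanisms=[mech],
            targets={mech.split()[0].upper()},
            soc_diseases=soc,
        )
    return drugs


def simulate_true_curves(
    cfg: SyntheticConfig,
    cohort: Mapping[str, SampleAnnotation],
    latent: np.ndarray,
    drugs: Mapping[str, DrugAnnotation],
) -> GroundTruth:
    """Ground-truth Hill parameters for every (sample, drug) pair.

    log10 IC50 decomposes additively into drug base potency, tissue×mechanism
    effect, mutation effects, metastatic resistance shift, cell-line class
    shift, a low-rank sample-latent contribution and idiosyncratic noise.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    sample_ids = list(cohort)
    drug_ids = list(drugs)
    n_s, n_d = len(sample_ids), len(drug_ids)
    mech_idx = np.array([j % cfg.n_mechanisms for j in range(n_d)])

    base = rng.uniform(*cfg.ic50_log10_range, size=n_d)
    slope = rng.uniform(*cfg.hill_slope_range, size=n_d)
    bottom = rng.uniform(*cfg.bottom_range, size=n_d)

    tissue_mech = rng.normal(0.0, cfg.tissue_mech_effect_sd, size=(cfg.n_tissues, cfg.n_mechanisms))
    for t, m, shift in cfg.planted_effects:
        if t < cfg.n_tissues and m < cfg.n_mechanisms:
            tissue_mech[t, m] += shift

    gene_names = (GENES * ((cfg.n_genes // len(GENES)) + 1))[: cfg.n_genes]
    gene_names = [g if gene_names[:i].count(g) == 0 else f"{g}_{gene_names[:i].count(g)}"
                  for i, g in enumerate(gene_names)]
    mutations = (rng.random((n_s, cfg.n_genes)) < cfg.mutation_prevalence).astype(float)
    mut_effect = np.zeros((cfg.n_genes, cfg.n_mechanisms))
    for gene, m, shift in cfg.mutation_effect_table:
        if gene in gene_names and m < cfg.n_mechanisms:
            mut_effect[gene_names.index(gene), m] = shift

    cl_shift = np.zeros(cfg.n_mechanisms)
    for m, shift in cfg.cellline_class_shift_table:
        if m < cfg.n_mechanisms:
            cl_shift[m] = shift

    mech_loadings = rng.normal(size=(cfg.n_mechanisms, cfg.latent_dim)) / np.sqrt(cfg.latent_dim)

    tissues = TISSUES[: cfg.n_tissues]
    t_of = np.array([tissues.index(cohort[s].primary_site) for s in sample_ids])
    is_met = np.array([cohort[s].is_metastasis for s in sample_ids], float)
    is_cl = np.array([cohort[s].model_type == "cell_line" for s in sample_ids], float)

    ic50 = (
        base[None, :]
        + tissue_mech[t_of][:, mech_idx]
        + mutations @ mut_effect[:, mech_idx]
        + cfg.met_resistance_shift * is_met[:, None]
        + cl_shift[mech_idx][None, :] * is_cl[:, None]
        + cfg.latent_scale * (latent @ mech_loadings.T)[:, mech_idx]
        + rng.normal(0.0, cfg.sample_ic50_sd, size=(n_s, n_d))
    )

    studies = _study_ids(cfg)
    batch_offset = {s: float(rng.normal(0.0, cfg.batch_offset_sd)) for s in studies}
    batch_scale = {
        s: float(np.clip(1.0 + rng.normal(0.0, cfg.batch_scale_sd), 0.5, 1.5))
        for s in studies
    }
    return GroundTruth(
        sample_ids=sample_ids,
        drug_ids=drug_ids,
        study_of_sample={s: cohort[s].study_id for s in sample_ids},
        log10_ic50=ic50,
        slope=slope,
        bottom=bottom,
        batch_offset=batch_offset,
        batch_scale=batch_scale,
        latent=latent,
        mech_loadings=mech_loadings,
        mutations=mutations,
        gene_names=gene_names,
        mechanism_of_drug={d: MECHANISMS[j % cfg.n_mechanisms] for j, d in enumerate(drug_ids)},
    )


def emit_dataset(cfg: SyntheticConfig, truth: GroundTruth, cohort: Mapping[str, SampleAnnotation],
                 drugs: Mapping[str, DrugAnnotation]) -> ScreenDataset:
    """Observed screen: per-study panels and dose designs, affine batch effects
    on the viability scale, Gaussian noise, clipped to [0, 2]."""
    rng = np.random.default_rng(cfg.seed + 2)
    studies = _study_ids(cfg)
    n_panel = max(1, int(round(cfg.panel_fraction * cfg.n_drugs)))
    if n_panel > cfg.n_drugs:
        raise ConfigError("panel size exceeds number of drugs")
    single_dose = set(studies[cfg.n_studies - cfg.n_single_dose_studies:]) if cfg.n_single_dose_studies else set()

    drug_index = {d: j for j, d in enumerate(truth.drug_ids)}
    rows = []
    for study in studies:
        panel = sorted(rng.choice(truth.drug_ids, size=n_panel, replace=False))
        dose_jitter = rng.uniform(-0.25, 0.25)
        for sid in truth.sample_ids:
            if truth.study_of_sample[sid] != study:
                continue
            i = truth.sample_ids.index(sid)
            for did in panel:
                j = drug_index[did]
                center = truth.log10_ic50[i, j] * 0 + np.mean(cfg.ic50_log10_range)
                if study in single_dose:
                    logc = np.array([center + dose_jitter])
                else:
                    logc = np.linspace(center - 1.8, center + 1.8, cfg.doses_per_curve) + dose_jitter
                true_v = truth.true_viability(sid, did, logc)
                obs = (
                    truth.batch_scale[study] * true_v
                    + truth.batch_offset[study]
                    + rng.normal(0.0, cfg.noise_sd, size=logc.shape)
                )
                obs = np.clip(obs, 0.0, 2.0)
                for c, v in zip(10.0 ** logc, obs):
                    rows.append((study, sid, did, c, v))
    rec = pd.DataFrame(rows, columns=["study_id", "sample_id", "drug_id", "concentration_uM", "viability"])
    return ScreenDataset(rec, samples=cohort, drugs=drugs)


def simulate_omics(cfg: SyntheticConfig, truth: GroundTruth):
    """Mutation table, expression matrix and gene sets matched to the cohort.

    The first pathway's activity is coupled to the first configured
    mutation-effect gene, so genomic status, expression programs and drug
    response share a common axis — the structure probed downstream.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    n_s = len(truth.sample_ids)
    mut_rows = [
        {"sample_id": truth.sample_ids[i], "gene": truth.gene_names[g], "deleterious": 1}
        for i in range(n_s)
        for g in range(cfg.n_genes)
        if truth.mutations[i, g] > 0
    ]
    mutation_table = pd.DataFrame(mut_rows, columns=["sample_id", "gene", "deleterious"])

    activities = rng.normal(size=(cfg.n_pathways, n_s))
    coupled_gene = cfg.mutation_effect_table[0][0] if cfg.mutation_effect_table else None
    if coupled_gene in truth.gene_names:
        g0 = truth.gene_names.index(coupled_gene)
        activities[0] += cfg.pathway_coupling * truth.mutations[:, g0]

    expr_genes = [f"EXPR{g:03d}" for g in range(cfg.n_pathways * cfg.genes_per_pathway)]
    gene_sets = {}
    loadings = rng.uniform(0.6, 1.2, size=len(expr_genes))
    log_expr = np.zeros((len(expr_genes), n_s))
    for p in range(cfg.n_pathways):
        members = expr_genes[p * cfg.genes_per_pathway:(p + 1) * cfg.genes_per_pathway]
        gene_sets[f"PATHWAY_{p}"] = list(members)
        for gi, gname in enumerate(members):
            row = p * cfg.genes_per_pathway + gi
            log_expr[row] = (
                3.0
                + 0.8 * loadings[row] * activities[p]
                + rng.normal(0.0, cfg.expression_noise_sd, size=n_s)
            )
    expression = pd.DataFrame(np.exp(log_expr), index=expr_genes, columns=truth.sample_ids)
    return mutation_table, expression, gene_sets, activities


def simulate_screen(cfg: SyntheticConfig):
    """Convenience wrapper: cohort -> truth -> observed dataset.

    Returns (ScreenDataset, GroundTruth)."""
    cohort, latent = simulate_cohort(cfg)
    drugs = make_drug_annotations(cfg)
    truth = simulate_true_curves(cfg, cohort, latent, drugs)
    ds = emit_dataset(cfg, truth, cohort, drugs)
    return ds, truth
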