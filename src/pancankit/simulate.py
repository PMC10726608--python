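"""Synthetic TCGA-shaped cohorts with planted, recorded effects.

The generator emulates the layer inventory of a real pan-cancer bundle
(expression, clinical, TMB, MSI, immune cell ratios, immune scores,
promoter methylation, gene families, gene-set catalogs) so every
analysis in the toolkit can be exercised and validated offline.

Model, in brief: per-gene baseline log2(TPM+1) means are drawn once
from a normal distribution; samples add independent Gaussian noise.
Differential expression is planted as a mean shift on the log2 scale in
the tumor samples of one cancer.  TMB/MSI couple to planted genes
through a Gaussian copula on the shared latent noise, so the Pearson
correlation approaches the requested target.  Survival times are
exponential with per-sample log-hazard equal to the planted log hazard
ratio times the standardized gene expression, under independent uniform
administrative censoring.  Promoter betas couple to expression through
a logistic transform of the same copula.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import stats
from .cohort import Cohort, TUMOR, NORMAL

__all__ = ["CancerArm", "CohortSpec", "TruthRecord", "generate_cohort",
           "reference_fixture", "REFERENCE_SEED"]

REFERENCE_SEED = 20240917

CELL_TYPES = ["B_cells", "CD4_T_cells", "CD8_T_cells", "NK_cells",
              "Monocytes", "Macrophages", "Dendritic_cells", "Neutrophils"]

FAMILIES = {
    "checkpoint": ["PDCD1", "CD274", "CTLA4", "LAG3", "HAVCR2", "TIGIT"],
    "chemokine": ["CCL2", "CCL5", "CXCL9", "CXCL10", "CXCL12"],
    "chemokine_receptor": ["CCR2", "CCR5", "CXCR3", "CXCR4"],
    "immunostimulator": ["CD80", "CD86", "ICOS", "TNFRSF9", "CD40"],
    "immunoinhibitor": ["IL10", "TGFB1", "IDO1", "VSIR", "BTLA"],
}


@dataclass
class CancerArm:
    code: str
    n_tumor: int
    n_normal: int
    n_paired: int = 0


@dataclass
class PlantedDE:
    gene: str
    cancer: str
    log2fc: float


@dataclass
class PlantedMetricCorr:
    gene: str
    cancer: str
    metric: str          # "TMB" | "MSI"
    target_r: float


@dataclass
class PlantedHazard:
    gene: str
    cancer: str
    log_hr: float


@dataclass
class PlantedMethylationCorr:
    gene: str
    cancer: str
    target_r: float      # expression vs promoter beta


@dataclass
class PlantedCoexpression:
    gene_a: str          # index gene (keeps its own draw)
    gene_b: str          # coupled gene
    cancer: str
    target_r: float


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort.

    Baseline expression: per-gene means ~ N(baseline_mean, between_gene_sd),
    per-sample noise sd ``noise_sd``, all on the log2(TPM+1) scale.
    """

    cancers: list
    n_genes: int
    seed: int
    baseline_mean: float = 4.0
    between_gene_sd: float = 1.5
    noise_sd: float = 1.0
    censoring_rate: float = 0.3
    planted_de: list = field(default_factory=list)
    planted_metric_corr: list = field(default_factory=list)
    planted_hazard: list = field(default_factory=list)
    planted_methylation_corr: list = field(default_factory=list)
    planted_coexpression: list = field(default_factory=list)
    gene_names: list | None = None
    methylation_genes: list | None = None
    families: dict = field(default_factory=dict)
    catalogs: dict = field(default_factory=dict)
    stromal_signature: list = field(default_factory=list)
    immune_signature: list = field(default_factory=list)

    def validate(self) -> None:
        for arm in self.cancers:
            if arm.n_paired > min(arm.n_tumor, arm.n_normal):
                raise ValueError(
                    f"{arm.code}: n_paired={arm.n_paired} exceeds "
                    f"min(n_tumor, n_normal)={min(arm.n_tumor, arm.n_normal)}")
            if arm.n_tumor <= 0:
                raise ValueError(f"{arm.code}: n_tumor must be positive")
        for plant in (self.planted_metric_corr + self.planted_methylation_corr
                      + self.planted_coexpression):
            if not -1.0 < plant.target_r < 1.0:
                raise ValueError(f"target_r must lie in (-1, 1): {plant}")


@dataclass
class TruthRecord:
    """Planted effects with their realized (empirical) values."""

    de: list = field(default_factory=list)
    metric_corr: list = field(default_factory=list)
    hazard: list = field(default_factory=list)
    methylation_corr: list = field(default_factory=list)
    coexpression: list = field(default_factory=list)
    seed: int = 0

    def to_yaml(self, path) -> None:
        payload = {k: [dict(e) for e in v] if isinstance(v, list) else v
                   for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)


def _barcodes(arm: CancerArm) -> tuple[list, list, list]:
    """Tumor barcodes, normal barcodes, patient ids (synthetic grammar)."""
    n_patients = arm.n_tumor + arm.n_normal - arm.n_paired
    patients = [f"SYNT-{arm.code}-{i:04d}" for i in range(n_patients)]
    tumor_patients = patients[: arm.n_tumor]
    # paired patients come first so they contribute both samples
    normal_patients = patients[: arm.n_paired] + patients[arm.n_tumor:]
    tumor = [f"{p}-01A" for p in tumor_patients]
    normal = [f"{p}-11A" for p in normal_patients]
    return tumor, normal, patients


def generate_cohort(spec: CohortSpec) -> tuple[Cohort, TruthRecord]:
    """Draw a full multi-layer cohort from a :class:`CohortSpec`."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    genes = list(spec.gene_names) if spec.gene_names is not None else \
        [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]
    if len(genes) != spec.n_genes:
        raise ValueError("gene_names length must equal n_genes")
    gene_idx = {g: i for i, g in enumerate(genes)}

    sample_ids, patients, groups, cancers_of = [], [], [], []
    for arm in spec.cancers:
        tumor, normal, _ = _barcodes(arm)
        for bc in tumor:
            sample_ids.append(bc); groups.append(TUMOR); cancers_of.append(arm.code)
            patients.append("-".join(bc.split("-")[:3]))
        for bc in normal:
            sample_ids.append(bc); groups.append(NORMAL); cancers_of.append(arm.code)
            patients.append("-".join(bc.split("-")[:3]))
    ann = pd.DataFrame({"patient_id": patients, "group": groups,
                        "cancer_type": cancers_of},
                       index=pd.Index(sample_ids, name="sample_id"))
    n_samples = len(ann)

    gene_means = rng.normal(spec.baseline_mean, spec.between_gene_sd,
                            size=spec.n_genes)
    gene_means = np.clip(gene_means, 0.5, None)
    latent = rng.standard_normal((n_samples, spec.n_genes))

    is_tumor = (ann["group"] == TUMOR).to_numpy()
    cancer_arr = ann["cancer_type"].to_numpy()

    # co-expression plants rewrite the coupled gene's latent column
    for plant in spec.planted_coexpression:
        rows = np.flatnonzero(cancer_arr == plant.cancer)
        rho = plant.target_r
        eps = rng.standard_normal(len(rows))
        latent[rows, gene_idx[plant.gene_b]] = (
            rho * latent[rows, gene_idx[plant.gene_a]]
            + np.sqrt(1 - rho**2) * eps)

    values = gene_means[None, :] + spec.noise_sd * latent
    for plant in spec.planted_de:
        rows = (cancer_arr == plant.cancer) & is_tumor
        values[rows, gene_idx[plant.gene]] += plant.log2fc
    values = np.clip(values, 0.0, None)
    # log2(TPM+1) invariant: no gene may be zero everywhere
    dead = (values == 0).all(axis=0)
    values[0, dead] = 0.01
    expr = pd.DataFrame(values, index=ann.index, columns=genes)

    # ---- clinical -------------------------------------------------------
    uniq_patients = list(dict.fromkeys(patients))
    n_pat = len(uniq_patients)
    age = np.clip(rng.normal(62, 10, n_pat), 30, 90).round(1)
    gender = rng.choice(["male", "female"], size=n_pat)
    stage = rng.choice(["I", "II", "III", "IV"], size=n_pat,
                       p=[0.25, 0.35, 0.25, 0.15])
    clinical = pd.DataFrame({"age": age, "gender": gender, "stage": stage},
                            index=pd.Index(uniq_patients, name="patient_id"))

    # ---- survival -------------------------------------------------------
    lam0 = 1.0 / 1000.0          # baseline hazard, per day
    log_hazard = np.zeros(n_pat)
    pat_pos = {p: i for i, p in enumerate(uniq_patients)}
    for plant in spec.planted_hazard:
        rows = np.flatnonzero((cancer_arr == plant.cancer) & is_tumor)
        col = values[rows, gene_idx[plant.gene]]
        z = (col - col.mean()) / col.std()
        for r, zval in zip(rows, z):
            log_hazard[pat_pos[patients[r]]] = plant.log_hr * zval
    lam = lam0 * np.exp(log_hazard)
    t_event = rng.exponential(1.0 / lam)
    if spec.censoring_rate > 0:
        # administrative window solved for ~30% censoring at the baseline
        # hazard and rescaled for other rates (approximate)
        c_max = 3.2 / lam0 * (0.3 / spec.censoring_rate)
        t_cens = rng.uniform(0, c_max, n_pat)
    else:
        t_cens = np.full(n_pat, np.inf)
    clinical["os_time"] = np.minimum(t_event, t_cens).round(2)
    clinical["os_event"] = (t_event <= t_cens).astype(int)

    # ---- TMB / MSI (tumor samples) --------------------------------------
    tumor_rows = np.flatnonzero(is_tumor)
    tumor_ids = ann.index[tumor_rows]
    metric_latent = {"TMB": rng.standard_normal(len(tumor_rows)),
                     "MSI": rng.standard_normal(len(tumor_rows))}
    for plant in spec.planted_metric_corr:
        mask = cancer_arr[tumor_rows] == plant.cancer
        rho = plant.target_r
        z_gene = latent[tumor_rows[mask], gene_idx[plant.gene]]
        eps = rng.standard_normal(mask.sum())
        metric_latent[plant.metric][mask] = (rho * z_gene
                                             + np.sqrt(1 - rho**2) * eps)
    tmb = np.maximum(0.0, 10.0 + 3.0 * metric_latent["TMB"])
    msi = np.maximum(0.0, 1.0 + 0.3 * metric_latent["MSI"])
    metrics = {"TMB": pd.Series(tmb, index=tumor_ids, name="TMB"),
               "MSI": pd.Series(msi, index=tumor_ids, name="MSI")}

    # ---- immune cell ratios (tumor samples) -----------------------------
    dirichlet = rng.gamma(2.0, 1.0, size=(len(tumor_rows), len(CELL_TYPES)))
    dirichlet /= dirichlet.sum(axis=1, keepdims=True)
    immune_ratio = pd.DataFrame(dirichlet, index=tumor_ids, columns=CELL_TYPES)

    # ---- immune scores via ssGSEA of the two signatures -----------------
    immune_score = pd.DataFrame()
    if spec.stromal_signature and spec.immune_signature:
        immune_score = stats.estimate_scores(
            expr, spec.stromal_signature, spec.immune_signature)

    # ---- promoter methylation (tumor samples) ---------------------------
    methylation = pd.DataFrame()
    meth_genes = spec.methylation_genes
    if meth_genes:
        base_logit = np.log(0.4 / 0.6)
        meth_latent = rng.standard_normal((len(meth_genes), len(tumor_rows)))
        planted = {(p.gene, p.cancer): p.target_r
                   for p in spec.planted_methylation_corr}
        for gi, g in enumerate(meth_genes):
            for (gene, cancer), rho in planted.items():
                if gene != g:
                    continue
                mask = cancer_arr[tumor_rows] == cancer
                z_gene = latent[tumor_rows[mask], gene_idx[g]]
                eps = rng.standard_normal(mask.sum())
                meth_latent[gi, mask] = rho * z_gene + np.sqrt(1 - rho**2) * eps
        beta = 1.0 / (1.0 + np.exp(-(base_logit + 0.9 * meth_latent)))
        methylation = pd.DataFrame(beta, index=pd.Index(meth_genes, name="gene"),
                                   columns=tumor_ids)

    cohort = Cohort(expression=expr, annotations=ann, clinical=clinical,
                    metrics=metrics, immune_ratio=immune_ratio,
                    immune_score=immune_score, methylation=methylation,
                    families=dict(spec.families), catalogs=dict(spec.catalogs))

    truth = _realize_truth(spec, cohort)
    return cohort, truth


def _realize_truth(spec: CohortSpec, cohort: Cohort) -> TruthRecord:
    """Measure each planted effect back from the generated cohort."""
    truth = TruthRecord(seed=spec.seed)
    expr = cohort.expression
    ann = cohort.annotations
    for p in spec.planted_de:
        in_cancer = ann["cancer_type"] == p.cancer
        t = expr.loc[in_cancer & (ann["group"] == TUMOR), p.gene]
        n = expr.loc[in_cancer & (ann["group"] == NORMAL), p.gene]
        realized = float(t.mean() - n.mean()) if len(n) else float("nan")
        truth.de.append({"gene": p.gene, "cancer": p.cancer,
                         "log2fc": p.log2fc, "realized_log2fc": realized,
                         "n_tumor": int(len(t)), "n_normal": int(len(n))})
    for p in spec.planted_metric_corr:
        samples = cohort.samples_of(p.cancer, TUMOR)
        x = expr.loc[samples, p.gene]
        y = cohort.metrics[p.metric].loc[samples]
        r = stats.correlation(x, y).effect
        truth.metric_corr.append({"gene": p.gene, "cancer": p.cancer,
                                  "metric": p.metric, "target_r": p.target_r,
                                  "realized_r": float(r), "n": int(len(x))})
    for p in spec.planted_hazard:
        truth.hazard.append({"gene": p.gene, "cancer": p.cancer,
                             "log_hr": p.log_hr})
    for p in spec.planted_methylation_corr:
        samples = cohort.samples_of(p.cancer, TUMOR)
        cols = cohort.methylation.columns.intersection(samples)
        r = stats.correlation(expr.loc[cols, p.gene],
                              cohort.methylation.loc[p.gene, cols]).effect
        truth.methylation_corr.append(
            {"gene": p.gene, "cancer": p.cancer, "target_r": p.target_r,
             "realized_r": float(r), "n": int(len(cols))})
    for p in spec.planted_coexpression:
        samples = cohort.samples_of(p.cancer, TUMOR)
        r = stats.correlation(expr.loc[samples, p.gene_a],
                              expr.loc[samples, p.gene_b]).effect
        truth.coexpression.append(
            {"gene_a": p.gene_a, "gene_b": p.gene_b, "cancer": p.cancer,
             "target_r": p.target_r, "realized_r": float(r),
             "n": int(len(samples))})
    return truth


# ---------------------------------------------------------------------------
# packaged reference fixture
# ---------------------------------------------------------------------------


def reference_spec(seed: int = REFERENCE_SEED) -> CohortSpec:
    """The study-condition cohort used across the test suite.

    Four cancers, two of them with more than 20 tumor/normal pairs, 500
    genes including five immune gene families and two ssGSEA
    signatures, plus toy GO/KEGG/hallmark catalogs.  Planted effects:
    one differential gene (log2FC 2 in COAD), TMB and MSI couplings in
    BRCA (n=400 tumors), a hazard gene (log HR 0.7, BRCA), a promoter
    methylation anticorrelation (-0.5, BRCA), and co-expression modules
    for DEG/GSEA/co-expression panels.
    """
    n_genes = 500
    family_genes = [g for fam in FAMILIES.values() for g in fam]
    base = [f"G{i:04d}" for i in range(1, n_genes - len(family_genes) + 1)]
    genes = base + family_genes

    stromal = [f"G{i:04d}" for i in range(401, 421)]
    immune = [f"G{i:04d}" for i in range(421, 441)]

    coexp_module = [f"G{i:04d}" for i in range(51, 61)]
    rng = np.random.default_rng(seed + 1)  # catalog composition only

    def pick(n, exclude=()):
        pool = [g for g in base if g not in set(exclude)]
        return sorted(rng.choice(pool, size=n, replace=False).tolist())

    catalogs = {
        "go": {
            "GO_COEXP_MODULE": coexp_module,
            "GO_RANDOM_A": pick(12, coexp_module),
            "GO_RANDOM_B": pick(15, coexp_module),
            "GO_RANDOM_C": pick(10, coexp_module),
        },
        "kegg": {
            "KEGG_APOPTOSIS": pick(15),
            "KEGG_RANDOM_A": pick(12),
            "KEGG_RANDOM_B": pick(18),
        },
        "hallmark": {"HALLMARK_DNA_REPAIR": pick(20)},
    }

    coexpression = [PlantedCoexpression("G0050", g, "COAD", 0.7)
                    for g in coexp_module]
    coexpression.append(PlantedCoexpression("G0070", "G0071", "BRCA", 0.6))
    # couple G0080 to part of the immune signature so immune-score
    # correlations have a recoverable sign
    coexpression += [PlantedCoexpression("G0080", g, "BRCA", 0.5)
                     for g in immune[:8]]

    return CohortSpec(
        cancers=[CancerArm("BRCA", 400, 60, 30),
                 CancerArm("COAD", 60, 40, 25),
                 CancerArm("CHOL", 35, 12, 8),
                 CancerArm("LUAD", 50, 10, 3)],
        n_genes=n_genes,
        seed=seed,
        planted_de=[PlantedDE("G0010", "COAD", 2.0),
                    PlantedDE("G0011", "CHOL", 3.0)],
        planted_metric_corr=[PlantedMetricCorr("G0020", "BRCA", "TMB", 0.6),
                             PlantedMetricCorr("G0021", "BRCA", "MSI", 0.5)],
        planted_hazard=[PlantedHazard("G0030", "BRCA", 0.7)],
        planted_methylation_corr=[PlantedMethylationCorr("G0040", "BRCA", -0.5)],
        planted_coexpression=coexpression,
        gene_names=genes,
        methylation_genes=[f"G{i:04d}" for i in range(1, 101)],
        families=dict(FAMILIES),
        catalogs=catalogs,
        stromal_signature=stromal,
        immune_signature=immune,
    )


@functools.lru_cache(maxsize=1)
def reference_fixture() -> tuple[Cohort, TruthRecord]:
    """Generate (and cache) the reference cohort; treat it as read-only."""
    return generate_cohort(reference_spec())
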