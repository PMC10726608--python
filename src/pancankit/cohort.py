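"""Multi-layer cohort data model.

A :class:`Cohort` bundles aligned omic layers keyed by TCGA-style sample
barcodes: a samples x genes expression matrix on the log2(TPM+1) scale
with per-sample annotations (cancer type, tumor/normal group, patient),
per-patient clinical data, per-sample scalar metrics (TMB, MSI), immune
cell ratios, stromal/immune/ESTIMATE scores, promoter methylation beta
values, a registry of immune-related gene families, and named gene-set
catalogs.  Layers are aligned lazily at analysis time by intersecting
sample identifiers, so partial cohorts are legal.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"

LAYER_NAMES = ("tpm", "meta", "tmb", "msi", "immu_ratio", "immuscore",
               "promoter_methy")

FAMILY_NAMES = ("checkpoint", "chemokine", "chemokine_receptor",
                "immunostimulator", "immunoinhibitor")


class CohortError(ValueError):
    """Raised on unknown layers, cancer codes, genes or set names."""


@dataclass
class QueryDescriptor:
    """Resolution of a user query into a single gene or a gene set."""

    name: str
    kind: str                      # "gene" | "set"
    members: list                  # members present in the expression matrix
    absent: list = field(default_factory=list)

    @property
    def is_set(self) -> bool:
        return self.kind == "set"


@dataclass
class Cohort:
    """Aligned multi-omic cohort.

    expression        samples x genes DataFrame, log2(TPM+1)
    annotations       per-sample DataFrame: cancer_type, group, patient_id
    clinical          per-patient DataFrame: age, gender, stage, os_time, os_event
    metrics           {"TMB"|"MSI": Series indexed by sample}
    immune_ratio      samples x cell types, proportions in [0, 1]
    immune_score      samples x {Stromal, Immune, ESTIMATE}
    methylation       genes x samples promoter beta values in [0, 1]
    families          family name -> ordered gene list
    catalogs          catalog name -> {set name -> gene list}
    """

    expression: pd.DataFrame
    annotations: pd.DataFrame
    clinical: pd.DataFrame = field(default_factory=pd.DataFrame)
    metrics: dict = field(default_factory=dict)
    immune_ratio: pd.DataFrame = field(default_factory=pd.DataFrame)
    immune_score: pd.DataFrame = field(default_factory=pd.DataFrame)
    methylation: pd.DataFrame = field(default_factory=pd.DataFrame)
    families: dict = field(default_factory=dict)
    catalogs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        expr = self.expression
        ann = self.annotations
        if not expr.index.equals(ann.index):
            raise CohortError("expression and annotation sample ids differ")
        if expr.columns.duplicated().any():
            raise CohortError("duplicated gene symbols in the expression matrix")
        vals = expr.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise CohortError("expression values must be finite and >= 0")
        if vals.size and (vals == 0).all(axis=0).any():
            raise CohortError("expression contains an all-zero gene")
        triples = ann[["patient_id", "group", "cancer_type"]]
        if triples.duplicated().any():
            raise CohortError("duplicated (patient, group, cancer) sample")
        for name, series in self.metrics.items():
            if not np.isfinite(series.to_numpy(dtype=float)).all():
                raise CohortError(f"non-finite values in metric {name}")
        if len(self.immune_ratio):
            r = self.immune_ratio.to_numpy(dtype=float)
            if ((r < 0) | (r > 1)).any():
                raise CohortError("immune cell ratios must lie in [0, 1]")
        if len(self.methylation):
            b = self.methylation.to_numpy(dtype=float)
            ok = np.isnan(b) | ((b >= 0) & (b <= 1))
            if not ok.all():
                raise CohortError("methylation betas must lie in [0, 1] or be missing")
        for fam, genes in self.families.items():
            if not genes:
                raise CohortError(f"gene family {fam!r} is empty")
            if len(set(genes)) != len(genes):
                raise CohortError(f"duplicate symbols in family {fam!r}")

    # -- convenience selectors --------------------------------------------

    @property
    def cancer_types(self) -> list:
        return sorted(self.annotations["cancer_type"].unique())

    def samples_of(self, cancer: str | None = None,
                   group: str | None = None) -> pd.Index:
        ann = self.annotations
        mask = pd.Series(True, index=ann.index)
        if cancer is not None:
            if cancer not in set(ann["cancer_type"]):
                raise CohortError(
                    f"unknown cancer code {cancer!r}; known: {self.cancer_types}")
            mask &= ann["cancer_type"] == cancer
        if group is not None:
            mask &= ann["group"] == group
        return ann.index[mask]

    def tumor_expression(self, cancer: str | None = None) -> pd.DataFrame:
        return self.expression.loc[self.samples_of(cancer, TUMOR)]

    def paired_patients(self, cancer: str) -> list:
        """Patients with both a tumor and a normal sample in this cancer."""
        ann = self.annotations[self.annotations["cancer_type"] == cancer]
        by_group = ann.groupby("patient_id")["group"].agg(set)
        return sorted(by_group.index[by_group.apply(
            lambda s: TUMOR in s and NORMAL in s)])


# ---------------------------------------------------------------------------
# Table-1-style extraction
# ---------------------------------------------------------------------------


def extract_layer(cohort: Cohort, layer: str, cancer: str | None = None,
                  paired_only: bool = False) -> pd.DataFrame:
    """Extract one cohort layer, optionally restricted to a cancer type.

    With ``paired_only`` the result is restricted to patients having both
    a tumor and a normal sample, ordered so that tumor/normal pairs
    align (all tumor rows first, then the matching normal rows in the
    same patient order).  The cohort itself is never modified.
    """
    if layer not in LAYER_NAMES:
        raise CohortError(f"unknown layer {layer!r}; expected one of {LAYER_NAMES}")
    ann = cohort.annotations
    if cancer is not None and cancer not in set(ann["cancer_type"]):
        raise CohortError(
            f"unknown cancer code {cancer!r}; known: {cohort.cancer_types}")

    if layer in ("tpm", "meta"):
        samples = cohort.samples_of(cancer)
        if paired_only:
            if cancer is None:
                raise CohortError("paired_only extraction requires a cancer code")
            patients = cohort.paired_patients(cancer)
            sub = ann.loc[samples]
            tumor = [sub.index[(sub["patient_id"] == p) & (sub["group"] == TUMOR)][0]
                     for p in patients]
            normal = [sub.index[(sub["patient_id"] == p) & (sub["group"] == NORMAL)][0]
                      for p in patients]
            samples = pd.Index(tumor + normal)
        if layer == "tpm":
            return cohort.expression.loc[samples].copy()
        merged = ann.loc[samples].merge(
            cohort.clinical, left_on="patient_id", right_index=True, how="left")
        merged.index = samples
        return merged
    if paired_only:
        raise CohortError(f"layer {layer!r} carries no tumor/normal group labels")
    if layer in ("tmb", "msi"):
        name = layer.upper()
        if name not in cohort.metrics:
            raise CohortError(f"metric layer {name} not present in this cohort")
        series = cohort.metrics[name]
        if cancer is not None:
            series = series.loc[series.index.intersection(cohort.samples_of(cancer))]
        return series.to_frame(name)
    table = {"immu_ratio": cohort.immune_ratio,
             "immuscore": cohort.immune_score,
             "promoter_methy": cohort.methylation}[layer]
    if not len(table):
        raise CohortError(f"layer {layer!r} not present in this cohort")
    if cancer is None:
        return table.copy()
    wanted = cohort.samples_of(cancer)
    if layer == "promoter_methy":  # genes x samples orientation
        return table[table.columns.intersection(wanted)].copy()
    return table.loc[table.index.intersection(wanted)].copy()


def list_cancers(cohort: Cohort, paired_min_pairs: int = 20) -> pd.DataFrame:
    """Per-cancer sample summary with a paired-analysis eligibility flag.

    A cancer is pair-eligible when its tumor/normal pair count is
    strictly greater than ``paired_min_pairs``.
    """
    rows = []
    for cancer in cohort.cancer_types:
        ann = cohort.annotations[cohort.annotations["cancer_type"] == cancer]
        n_tumor = int((ann["group"] == TUMOR).sum())
        n_normal = int((ann["group"] == NORMAL).sum())
        n_pairs = len(cohort.paired_patients(cancer))
        rows.append({"cancer": cancer, "n_tumor": n_tumor, "n_normal": n_normal,
                     "n_pairs": n_pairs,
                     "pair_eligible": n_pairs > paired_min_pairs})
    return pd.DataFrame(rows).set_index("cancer")


def resolve_gene_or_set(cohort: Cohort, query: str) -> QueryDescriptor:
    """Resolve a query string to a single gene or a catalog gene set."""
    if query in cohort.expression.columns:
        return QueryDescriptor(name=query, kind="gene", members=[query])
    for catalog in cohort.catalogs.values():
        if query in catalog:
            members = list(catalog[query])
            present = [g for g in members if g in cohort.expression.columns]
            absent = [g for g in members if g not in cohort.expression.columns]
            if not present:
                raise CohortError(
                    f"gene set {query!r} has no member in the expression matrix")
            return QueryDescriptor(name=query, kind="set",
                                   members=present, absent=absent)
    universe = list(cohort.expression.columns) + [
        s for cat in cohort.catalogs.values() for s in cat]
    nearest = difflib.get_close_matches(query, universe, n=3)
    raise CohortError(
        f"{query!r} is neither a gene nor a loaded gene set"
        + (f"; nearest matches: {nearest}" if nearest else ""))


def query_scores(cohort: Cohort, query: str,
                 samples: pd.Index | None = None) -> tuple[pd.Series, QueryDescriptor]:
    """Per-sample score for a query: the gene column, or the set mean."""
    desc = resolve_gene_or_set(cohort, query)
    expr = cohort.expression if samples is None else cohort.expression.loc[samples]
    if desc.kind == "gene":
        return expr[desc.name].copy(), desc
    return expr[desc.members].mean(axis=1), desc
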