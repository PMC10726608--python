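"""Cancer-type-specific analyses.

Grouped expression of a gene or gene-set score (tumor/normal, paired,
two or three age groups, gender, stage), diagnostic ROC, differential
expression on a high/low median split followed by preranked GSEA,
gene-gene and gene-methylation correlation, co-expression panels with
hypergeometric enrichment, Kaplan-Meier survival on an expression or
methylation median split, and gene-term bipartite networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .cohort import Cohort, CohortError, TUMOR, NORMAL, list_cancers, query_scores

AGE_CUTOFF = 65          # years, the two-group age split
GROUPINGS = ("tumor_normal", "paired", "age2", "age3", "gender", "stage")

__all__ = ["grouped_expression", "diagnostic_roc", "deg_and_gsea",
           "gene_gene_correlation", "gene_methylation_correlation",
           "coexpression_panel", "survival_by_level", "term_network",
           "GroupedExpressionResult", "TermNetwork"]


@dataclass
class GroupedExpressionResult:
    grouping: str
    groups: dict                 # label -> np.ndarray of scores
    test: stats.TestResult | None
    n_dropped: int
    drop_reason: str = ""
    query: str = ""
    cancer: str = ""

    @property
    def group_sizes(self) -> dict:
        return {k: len(v) for k, v in self.groups.items()}


@dataclass
class TermNetwork:
    genes: list
    terms: list                  # [(term, q), ...] all passing the threshold
    edges: list                  # (gene, term) membership pairs
    ora: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(self.genes, bipartite="gene")
        g.add_nodes_from([t for t, _ in self.terms], bipartite="term")
        g.add_edges_from(self.edges)
        return g

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["gene", "term"])


def _age_of(cohort: Cohort, samples: pd.Index) -> pd.Series:
    patients = cohort.annotations.loc[samples, "patient_id"]
    age = cohort.clinical["age"].reindex(patients)
    age.index = samples
    return age


def grouped_expression(cohort: Cohort, cancer: str, query: str,
                       grouping: str, paired_min_pairs: int = 20,
                       age_cutoff: float = AGE_CUTOFF) -> GroupedExpressionResult:
    """Gene or gene-set expression grouped by clinical structure.

    age2 splits tumor samples at ``age_cutoff`` years; age3 uses age
    tertiles; stage labels arrive already normalized to I/II/III/IV.
    Two groups run a rank test (Mann-Whitney / paired signed-rank),
    three or more run Kruskal-Wallis.  Samples missing the grouping
    variable are dropped and counted.
    """
    if grouping not in GROUPINGS:
        raise CohortError(f"unknown grouping {grouping!r}; one of {GROUPINGS}")
    scores, desc = query_scores(cohort, query)
    ann = cohort.annotations
    in_cancer = ann["cancer_type"] == cancer
    if not in_cancer.any():
        raise CohortError(f"unknown cancer code {cancer!r}")
    n_dropped, reason = 0, ""

    if grouping == "tumor_normal":
        tumor = scores[in_cancer & (ann["group"] == TUMOR)]
        normal = scores[in_cancer & (ann["group"] == NORMAL)]
        _require_sizes({"tumor": tumor, "normal": normal})
        test = stats.mann_whitney(tumor.to_numpy(), normal.to_numpy())
        groups = {"tumor": tumor.to_numpy(), "normal": normal.to_numpy()}
    elif grouping == "paired":
        summary = list_cancers(cohort, paired_min_pairs)
        if not summary.loc[cancer, "pair_eligible"]:
            raise CohortError(
                f"{cancer} has {summary.loc[cancer, 'n_pairs']} pairs; paired "
                f"analysis requires more than {paired_min_pairs}")
        sub = ann[in_cancer]
        t_vals, n_vals = [], []
        for patient in cohort.paired_patients(cancer):
            t = sub.index[(sub["patient_id"] == patient) & (sub["group"] == TUMOR)][0]
            n = sub.index[(sub["patient_id"] == patient) & (sub["group"] == NORMAL)][0]
            t_vals.append(scores[t])
            n_vals.append(scores[n])
        t_vals, n_vals = np.asarray(t_vals), np.asarray(n_vals)
        test = stats.wilcoxon_signed_rank(t_vals - n_vals)
        groups = {"tumor": t_vals, "normal": n_vals}
    else:
        samples = ann.index[in_cancer & (ann["group"] == TUMOR)]
        vals = scores[samples]
        if grouping in ("age2", "age3"):
            age = _age_of(cohort, samples)
            keep = age.notna()
            n_dropped, reason = int((~keep).sum()), "missing age"
            vals, age = vals[keep], age[keep]
            if not len(vals):
                raise CohortError("age is missing for every tumor sample")
            if grouping == "age2":
                groups = {f"<{age_cutoff:g}": vals[age < age_cutoff].to_numpy(),
                          f">={age_cutoff:g}": vals[age >= age_cutoff].to_numpy()}
            else:
                t1, t2 = np.quantile(age, [1 / 3, 2 / 3])
                groups = {"young": vals[age <= t1].to_numpy(),
                          "middle": vals[(age > t1) & (age <= t2)].to_numpy(),
                          "old": vals[age > t2].to_numpy()}
        elif grouping == "gender":
            gender = cohort.clinical["gender"].reindex(
                ann.loc[samples, "patient_id"])
            gender.index = samples
            keep = gender.isin(["male", "female"])
            n_dropped, reason = int((~keep).sum()), "missing gender"
            vals = vals[keep]
            gender = gender[keep]
            groups = {g: vals[gender == g].to_numpy()
                      for g in ("female", "male")}
        else:  # stage
            stage = cohort.clinical["stage"].reindex(
                ann.loc[samples, "patient_id"])
            stage.index = samples
            keep = stage.isin(["I", "II", "III", "IV"])
            n_dropped, reason = int((~keep).sum()), "missing/unusable stage"
            vals = vals[keep]
            stage = stage[keep]
            groups = {s: vals[stage == s].to_numpy()
                      for s in ("I", "II", "III", "IV") if (stage == s).any()}
        _require_sizes(groups)
        if len(groups) < 2:
            raise CohortError(f"grouping {grouping!r} yields a single group")
        if len(groups) == 2:
            a, b = groups.values()
            test = stats.mann_whitney(a, b)
        else:
            test = stats.kruskal_wallis(list(groups.values()))
    return GroupedExpressionResult(grouping=grouping, groups=groups, test=test,
                                   n_dropped=n_dropped, drop_reason=reason,
                                   query=desc.name, cancer=cancer)


def _require_sizes(groups: dict, minimum: int = 2) -> None:
    for label, vals in groups.items():
        if len(vals) < minimum:
            raise CohortError(
                f"group {label!r} has {len(vals)} samples (< {minimum})")


def diagnostic_roc(cohort: Cohort, cancer: str, gene: str) -> stats.ROCResult:
    """ROC of a single gene's expression with tumor as the positive class."""
    scores, _ = query_scores(cohort, gene)
    ann = cohort.annotations
    in_cancer = ann["cancer_type"] == cancer
    if not in_cancer.any():
        raise CohortError(f"unknown cancer code {cancer!r}")
    tumor = scores[in_cancer & (ann["group"] == TUMOR)]
    normal = scores[in_cancer & (ann["group"] == NORMAL)]
    if not len(tumor) or not len(normal):
        raise CohortError(f"{cancer} lacks a tumor or a normal class")
    values = np.concatenate([tumor.to_numpy(), normal.to_numpy()])
    labels = np.r_[np.ones(len(tumor), dtype=bool),
                   np.zeros(len(normal), dtype=bool)]
    return stats.roc_auc(values, labels)


def deg_and_gsea(cohort: Cohort, cancer: str, gene: str, catalog_name: str,
                 n_perm: int = 1000, seed: int | None = None,
                 q_threshold: float = 0.05, top_n: int = 20):
    """DEGs on the gene's median split, then preranked GSEA on log2FC.

    Returns (deg_table, gsea_table, heatmap_payload).  The heatmap
    payload holds the top ``top_n`` genes by |log2FC| among those with
    q < ``q_threshold`` (empty, with a warning flag, when none passes).
    """
    if catalog_name not in cohort.catalogs:
        raise CohortError(
            f"catalog {catalog_name!r} not loaded; supply a GMT file "
            f"(known: {sorted(cohort.catalogs)})")
    samples = cohort.samples_of(cancer, TUMOR)
    if len(samples) < 8:
        raise CohortError(f"{cancer}: need >= 8 tumor samples, got {len(samples)}")
    expr = cohort.expression.loc[samples]
    index = expr[gene]
    deg = stats.deg_high_low(expr, index, exclude=gene)
    ranking = deg["log2fc"]
    gsea = stats.preranked_gsea(ranking, cohort.catalogs[catalog_name],
                                n_perm=n_perm, seed=seed)
    passing = deg[deg["q"] < q_threshold]
    top = passing.reindex(passing["log2fc"].abs()
                          .sort_values(ascending=False).index)[:top_n]
    heatmap = {"genes": list(top.index),
               "matrix": expr[list(top.index)] if len(top) else pd.DataFrame(),
               "split_gene": gene,
               "warning": None if len(top) else
               f"no gene passes q < {q_threshold}"}
    return deg, gsea, heatmap


def gene_gene_correlation(cohort: Cohort, cancer: str, gene_a: str,
                          gene_b: str, method: str = "pearson",
                          density: bool = False):
    """Tumor-sample correlation of two genes, with a scatter payload.

    The ``density`` flag only toggles a 2-D density layer in the plot
    spec; the statistics are unchanged.
    """
    samples = cohort.samples_of(cancer, TUMOR)
    for g in (gene_a, gene_b):
        if g not in cohort.expression.columns:
            raise CohortError(f"gene {g!r} not in the expression matrix")
    x = cohort.expression.loc[samples, gene_a]
    y = cohort.expression.loc[samples, gene_b]
    res = stats.correlation(x.to_numpy(), y.to_numpy(), method=method)
    slope, intercept = np.polyfit(x.to_numpy(), y.to_numpy(), 1)
    payload = {"x": x, "y": y, "xlabel": gene_a, "ylabel": gene_b,
               "slope": float(slope), "intercept": float(intercept),
               "density": bool(density), "r": res.effect, "p": res.p}
    return payload, res


def gene_methylation_correlation(cohort: Cohort, cancer: str, gene: str,
                                 method: str = "pearson", min_n: int = 5):
    """Correlation of expression vs promoter beta on overlapping tumors."""
    if gene not in cohort.methylation.index:
        raise CohortError(f"gene {gene!r} has no promoter methylation row")
    samples = cohort.samples_of(cancer, TUMOR)
    overlap = samples.intersection(cohort.methylation.columns)
    beta = cohort.methylation.loc[gene, overlap].dropna()
    overlap = beta.index
    if len(overlap) < min_n:
        raise CohortError(
            f"only {len(overlap)} tumor samples with methylation (< {min_n})")
    x = cohort.expression.loc[overlap, gene]
    res = stats.correlation(x.to_numpy(), beta.to_numpy(), method=method)
    payload = {"x": x, "y": beta, "xlabel": f"{gene} expression",
               "ylabel": f"{gene} promoter beta", "density": False,
               "r": res.effect, "p": res.p}
    return payload, res


def coexpression_panel(cohort: Cohort, cancer: str, gene: str,
                       top_n: int = 20, q_threshold: float = 0.05,
                       catalog_name: str | None = None):
    """Genes co-expressed with an index gene, plus enrichment of them.

    Pearson r of every other gene against the index across tumor
    samples, BH across genes; the strongest ``top_n`` positive and
    ``top_n`` negative correlates with q < ``q_threshold`` are kept.
    ORA uses the tested genes (not the genome) as background.
    """
    samples = cohort.samples_of(cancer, TUMOR)
    if len(samples) < 8:
        raise CohortError(f"{cancer}: need >= 8 tumor samples, got {len(samples)}")
    expr = cohort.expression.loc[samples]
    if gene not in expr.columns:
        raise CohortError(f"gene {gene!r} not in the expression matrix")
    x = expr[gene].to_numpy()
    rows = []
    for other in expr.columns:
        if other == gene:
            continue
        y = expr[other].to_numpy()
        if np.ptp(y) == 0:
            continue
        res = stats.correlation(x, y)
        rows.append({"gene": other, "r": res.effect, "p": res.p})
    corr = pd.DataFrame(rows).set_index("gene")
    corr["q"] = stats.benjamini_hochberg(corr["p"].to_numpy())
    sig = corr[corr["q"] < q_threshold]
    positive = sig[sig["r"] > 0].nlargest(top_n, "r")
    negative = sig[sig["r"] < 0].nsmallest(top_n, "r")
    selected = pd.concat([positive, negative])
    ora = pd.DataFrame()
    warning = None
    if not len(selected):
        warning = f"no gene passes q < {q_threshold}"
    elif catalog_name is not None:
        if catalog_name not in cohort.catalogs:
            raise CohortError(f"catalog {catalog_name!r} not loaded")
        ora = stats.hypergeometric_ora(list(selected.index),
                                       cohort.catalogs[catalog_name],
                                       background=list(corr.index))
    heatmap = {"genes": list(selected.index),
               "matrix": expr[list(selected.index)] if len(selected) else
               pd.DataFrame(),
               "index_gene": gene, "warning": warning}
    return corr, selected, ora, heatmap


def survival_by_level(cohort: Cohort, cancer: str, gene: str,
                      layer: str = "expression", min_samples: int = 10):
    """KM curves and log-rank test for a median split of one gene's level.

    ``layer`` selects expression (log2 TPM) or promoter methylation
    beta.  Ties at the median go to the low group, so group sizes
    differ by at most one when values are distinct.
    """
    if layer not in ("expression", "methylation"):
        raise CohortError(f"unknown layer {layer!r}")
    samples = cohort.samples_of(cancer, TUMOR)
    if layer == "expression":
        if gene not in cohort.expression.columns:
            raise CohortError(f"gene {gene!r} not in the expression matrix")
        level = cohort.expression.loc[samples, gene]
    else:
        if gene not in cohort.methylation.index:
            raise CohortError(f"gene {gene!r} has no promoter methylation row")
        level = cohort.methylation.loc[
            gene, samples.intersection(cohort.methylation.columns)].dropna()
    patients = cohort.annotations.loc[level.index, "patient_id"]
    clin = cohort.clinical.reindex(patients)[["os_time", "os_event"]]
    clin.index = level.index
    keep = clin.notna().all(axis=1)
    level, clin = level[keep], clin[keep]
    if len(level) < min_samples:
        raise CohortError(f"only {len(level)} usable samples (< {min_samples})")
    event = clin["os_event"].to_numpy(dtype=int)
    if event.sum() < 2:
        raise CohortError("fewer than 2 events; survival comparison impossible")
    high = (level > level.median()).to_numpy()
    time = clin["os_time"].to_numpy(dtype=float)
    curves = {"high": stats.km_estimate(time[high], event[high]),
              "low": stats.km_estimate(time[~high], event[~high])}
    test = stats.logrank(time, event, np.where(high, "high", "low"))
    return curves, test


def term_network(genes, catalog: dict, background,
                 q_threshold: float = 0.05) -> TermNetwork:
    """Bipartite gene-term network from hypergeometric enrichment.

    Nodes are the query genes and every term with BH q below the
    threshold; edges mark membership of a query gene in a linked term.
    An empty network (with the ORA table attached) is returned when no
    term passes.
    """
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise CohortError("empty gene query")
    ora = stats.hypergeometric_ora(genes, catalog, background)
    passing = ora[ora["q"] < q_threshold] if len(ora) else ora
    terms = [(row["term"], float(row["q"])) for _, row in passing.iterrows()]
    edges = []
    for term, _ in terms:
        members = set(catalog[term])
        edges += [(g, term) for g in genes if g in members]
    return TermNetwork(genes=genes, terms=terms, edges=edges, ora=ora)
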