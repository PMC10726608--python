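"""Pan-cancer analyses: per-cancer loops behind the pan-level figures.

Each operation returns a tidy result table (one row per cancer, BH
corrected across exactly those rows) together with a plot payload for
the renderer.  Correlations run on tumor samples only; group tests
require at least MIN_GROUP samples per group and correlations at least
MIN_CORR overlapping samples, with the thresholds recorded in the
table's metadata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import stats
from .cohort import Cohort, CohortError, TUMOR, NORMAL, list_cancers, query_scores

MIN_GROUP = 3     # smallest per-group n for two-sample tests
MIN_CORR = 5      # smallest n for correlation analyses

__all__ = ["pan_expression", "pan_metric_correlation", "pan_family_heatmap",
           "pan_immune_correlation", "pan_cox_forest"]


def _attach_q_and_stars(table: pd.DataFrame) -> pd.DataFrame:
    if len(table) and "p" in table.columns:
        table["q"] = stats.benjamini_hochberg(table["p"].to_numpy())
        table["stars"] = [stats.significance_stars(p) for p in table["p"]]
    return table


def pan_expression(cohort: Cohort, query: str, mode: str = "unpaired",
                   paired_min_pairs: int = 20) -> pd.DataFrame:
    """Per-cancer tumor/normal comparison of a gene or gene-set score.

    unpaired:   Mann-Whitney tumor vs normal, cancers with >= 3 per group
    paired:     Wilcoxon signed-rank, cancers with pair count > 20
    tumor_only: descriptive tumor distribution, no test
    """
    if mode not in ("unpaired", "paired", "tumor_only"):
        raise ValueError(f"unknown mode {mode!r}")
    scores, desc = query_scores(cohort, query)
    ann = cohort.annotations
    summary = list_cancers(cohort, paired_min_pairs)
    rows = []
    for cancer in cohort.cancer_types:
        in_cancer = ann["cancer_type"] == cancer
        tumor = scores[in_cancer & (ann["group"] == TUMOR)]
        normal = scores[in_cancer & (ann["group"] == NORMAL)]
        if mode == "tumor_only":
            if len(tumor) < 2:
                continue
            rows.append({"cancer": cancer, "effect": float(tumor.median()),
                         "mean": float(tumor.mean()), "n_tumor": len(tumor)})
            continue
        if mode == "unpaired":
            if len(tumor) < MIN_GROUP or len(normal) < MIN_GROUP:
                continue
            res = stats.mann_whitney(tumor.to_numpy(), normal.to_numpy())
            rows.append({"cancer": cancer, "effect": res.effect,
                         "statistic": res.statistic, "p": res.p,
                         "n_tumor": len(tumor), "n_normal": len(normal)})
        else:  # paired
            if not summary.loc[cancer, "pair_eligible"]:
                continue
            patients = cohort.paired_patients(cancer)
            sub = ann[in_cancer]
            diffs = []
            for patient in patients:
                t = sub.index[(sub["patient_id"] == patient)
                              & (sub["group"] == TUMOR)][0]
                n = sub.index[(sub["patient_id"] == patient)
                              & (sub["group"] == NORMAL)][0]
                diffs.append(scores[t] - scores[n])
            res = stats.wilcoxon_signed_rank(np.asarray(diffs))
            rows.append({"cancer": cancer, "effect": res.effect,
                         "statistic": res.statistic, "p": res.p,
                         "n_pairs": len(diffs)})
    table = pd.DataFrame(rows)
    if not len(table):
        raise CohortError(f"no cancer is eligible for mode {mode!r}")
    table = _attach_q_and_stars(table)
    table.attrs.update({"query": desc.name, "kind": desc.kind, "mode": mode,
                        "layer": "tpm", "min_group": MIN_GROUP,
                        "paired_min_pairs": paired_min_pairs})
    return table.set_index("cancer")


def pan_metric_correlation(cohort: Cohort, query: str, metric: str,
                           method: str = "pearson") -> pd.DataFrame:
    """Per-cancer correlation of a gene/set score with TMB or MSI.

    Tumor samples only; cancers with at least 5 overlapping samples.
    The table is the payload behind the radar chart (r per cancer with
    significance stars).
    """
    metric = metric.upper()
    if metric not in cohort.metrics:
        raise CohortError(f"metric layer {metric!r} not present in this cohort")
    scores, desc = query_scores(cohort, query)
    values = cohort.metrics[metric]
    rows = []
    for cancer in cohort.cancer_types:
        samples = cohort.samples_of(cancer, TUMOR).intersection(values.index)
        if len(samples) < MIN_CORR:
            continue
        res = stats.correlation(scores[samples], values[samples], method=method)
        rows.append({"cancer": cancer, "effect": res.effect,
                     "statistic": res.statistic, "p": res.p, "n": len(samples)})
    table = pd.DataFrame(rows)
    if not len(table):
        raise CohortError(f"no cancer has >= {MIN_CORR} samples with {metric}")
    table = _attach_q_and_stars(table)
    table.attrs.update({"query": desc.name, "kind": desc.kind, "metric": metric,
                        "method": method, "layer": metric.lower(),
                        "min_n": MIN_CORR})
    return table.set_index("cancer")


def pan_family_heatmap(cohort: Cohort, query: str, family: str,
                       method: str = "pearson", lowcol: str = "blue",
                       highcol: str = "red") -> dict:
    """Cancer x family-gene correlation grid for a gene/set query.

    Returns a payload with two aligned DataFrames (r and stars) in
    registry gene order, plus the requested heatmap colors.
    """
    if family not in cohort.families:
        raise CohortError(
            f"unknown family {family!r}; known: {sorted(cohort.families)}")
    genes = [g for g in cohort.families[family]
             if g in cohort.expression.columns]
    if not genes:
        raise CohortError(f"no member of family {family!r} in the expression matrix")
    scores, desc = query_scores(cohort, query)
    r = pd.DataFrame(index=cohort.cancer_types, columns=genes, dtype=float)
    p = pd.DataFrame(index=cohort.cancer_types, columns=genes, dtype=float)
    for cancer in cohort.cancer_types:
        samples = cohort.samples_of(cancer, TUMOR)
        if len(samples) < MIN_CORR:
            continue
        for gene in genes:
            res = stats.correlation(scores[samples],
                                    cohort.expression.loc[samples, gene],
                                    method=method)
            r.loc[cancer, gene] = res.effect
            p.loc[cancer, gene] = res.p
    stars = p.map(lambda v: "" if pd.isna(v) else stats.significance_stars(v))
    return {"r": r, "p": p, "stars": stars, "query": desc.name,
            "family": family, "method": method,
            "lowcol": lowcol, "highcol": highcol}


def pan_immune_correlation(cohort: Cohort, query: str,
                           layer: str = "cell_ratio",
                           shape: str = "heatmap",
                           method: str = "pearson") -> dict:
    """Cancer x cell-type (or x score) correlation of a gene/set query.

    ``layer`` is ``cell_ratio`` (immune cell proportions) or
    ``immune_score`` (Stromal/Immune/ESTIMATE).  ``shape`` only selects
    the rendering variant; the numbers are identical.
    """
    if layer not in ("cell_ratio", "immune_score"):
        raise CohortError(f"unknown immune layer {layer!r}")
    if shape not in ("heatmap", "triangle"):
        raise CohortError(f"unknown shape {shape!r}")
    table = cohort.immune_ratio if layer == "cell_ratio" else cohort.immune_score
    if not len(table):
        raise CohortError(f"layer {layer!r} not present in this cohort")
    scores, desc = query_scores(cohort, query)
    cols = list(table.columns)
    r = pd.DataFrame(index=cohort.cancer_types, columns=cols, dtype=float)
    p = pd.DataFrame(index=cohort.cancer_types, columns=cols, dtype=float)
    for cancer in cohort.cancer_types:
        samples = cohort.samples_of(cancer, TUMOR).intersection(table.index)
        if len(samples) < MIN_CORR:
            continue
        for col in cols:
            res = stats.correlation(scores[samples], table.loc[samples, col],
                                    method=method)
            r.loc[cancer, col] = res.effect
            p.loc[cancer, col] = res.p
    stars = p.map(lambda v: "" if pd.isna(v) else stats.significance_stars(v))
    return {"r": r, "p": p, "stars": stars, "query": desc.name,
            "layer": layer, "shape": shape, "method": method}


def pan_cox_forest(cohort: Cohort, gene: str, adjust_age: bool = False,
                   min_events: int = 10) -> pd.DataFrame:
    """Per-cancer Cox proportional-hazards fit of one gene.

    Expression is standardized within each cancer's tumor samples, so
    hazard ratios are per standard deviation and comparable across
    cancers.  Cancers with < ``min_events`` deaths, missing clinical
    rows, or failed fits are reported as skipped, never raised.
    """
    if gene not in cohort.expression.columns:
        raise CohortError(f"gene {gene!r} not in the expression matrix")
    rows, skipped = [], []
    for cancer in cohort.cancer_types:
        samples = cohort.samples_of(cancer, TUMOR)
        ann = cohort.annotations.loc[samples]
        clin = cohort.clinical.reindex(ann["patient_id"])
        clin.index = samples
        usable = clin[["os_time", "os_event"]].notna().all(axis=1)
        if adjust_age:
            usable &= clin["age"].notna()
        samples = samples[usable.to_numpy()]
        clin = clin.loc[samples]
        n_events = int(clin["os_event"].sum()) if len(clin) else 0
        if n_events < min_events:
            skipped.append({"cancer": cancer,
                            "reason": f"only {n_events} events (< {min_events})"})
            continue
        x = cohort.expression.loc[samples, gene].to_numpy()
        if np.ptp(x) == 0:
            skipped.append({"cancer": cancer, "reason": "constant expression"})
            continue
        x = (x - x.mean()) / x.std()
        try:
            res = stats.cox_fit(clin["os_time"].to_numpy(),
                                clin["os_event"].to_numpy(dtype=int), x,
                                age=clin["age"].to_numpy() if adjust_age else None)
        except ValueError as exc:
            skipped.append({"cancer": cancer, "reason": str(exc)})
            continue
        rows.append({"cancer": cancer, "hr": res.hr, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "p": res.p, "n": res.n,
                     "n_events": res.n_events})
    table = pd.DataFrame(rows)
    if not len(table):
        raise CohortError("no cancer could be fitted (see skip reasons)")
    table = _attach_q_and_stars(table)
    table.attrs.update({"query": gene, "adjust_age": adjust_age,
                        "min_events": min_events, "skipped": skipped,
                        "standardized": True})
    return table.set_index("cancer")
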