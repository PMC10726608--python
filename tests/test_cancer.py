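"""Cancer-type-specific analyses on the reference fixture."""

import numpy as np
import pandas as pd
import pytest

from pancankit import cancer as ca
from pancankit.cohort import CohortError


# ---------------------------------------------------------------------------
# grouped expression
# ---------------------------------------------------------------------------

def test_tumor_normal_grouping_recovers_plant(cohort, truth):
    plant = truth.de[0]
    res = ca.grouped_expression(cohort, plant["cancer"], plant["gene"],
                                "tumor_normal")
    assert res.test.effect > 0
    assert res.test.stars != "ns"
    assert res.test.method == "mann_whitney"


def test_paired_grouping_requires_eligibility(cohort):
    res = ca.grouped_expression(cohort, "COAD", "G0001", "paired")
    assert res.test.method == "wilcoxon_signed_rank"
    assert res.group_sizes == {"tumor": 25, "normal": 25}
    with pytest.raises(CohortError, match="pairs"):
        ca.grouped_expression(cohort, "CHOL", "G0001", "paired")


def test_age3_makes_three_groups_kruskal(cohort):
    res = ca.grouped_expression(cohort, "COAD", "G0001", "age3")
    assert len(res.groups) == 3
    assert res.test.method == "kruskal_wallis"
    assert sum(res.group_sizes.values()) + res.n_dropped == 60


def test_age2_splits_at_cutoff(cohort):
    res = ca.grouped_expression(cohort, "BRCA", "G0001", "age2")
    assert set(res.groups) == {"<65", ">=65"}
    assert sum(res.group_sizes.values()) + res.n_dropped == 400


def test_gender_two_groups(cohort):
    res = ca.grouped_expression(cohort, "BRCA", "G0001", "gender")
    assert set(res.groups) == {"male", "female"}


def test_stage_groups_collapse_substages(cohort):
    res = ca.grouped_expression(cohort, "BRCA", "G0001", "stage")
    assert set(res.groups) <= {"I", "II", "III", "IV"}
    assert len(res.groups) >= 3


def test_gene_set_query_same_structure(cohort):
    by_set = ca.grouped_expression(cohort, "COAD", "HALLMARK_DNA_REPAIR",
                                   "tumor_normal")
    by_gene = ca.grouped_expression(cohort, "COAD", "G0001", "tumor_normal")
    assert set(by_set.groups) == set(by_gene.groups)
    assert type(by_set.test) is type(by_gene.test)


def test_unknown_grouping(cohort):
    with pytest.raises(CohortError, match="grouping"):
        ca.grouped_expression(cohort, "COAD", "G0001", "zodiac")


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def test_roc_planted_diagnostic_gene(cohort):
    assert ca.diagnostic_roc(cohort, "CHOL", "G0011").auc >= 0.9


def test_roc_unplanted_gene_near_chance(cohort):
    auc = ca.diagnostic_roc(cohort, "BRCA", "G0005").auc
    assert 0.35 < auc < 0.65


def test_roc_label_inversion_symmetry(cohort):
    roc = ca.diagnostic_roc(cohort, "COAD", "G0010")
    # negating scores swaps the classes' roles
    from pancankit import stats
    ann = cohort.annotations
    mask = ann["cancer_type"] == "COAD"
    scores = cohort.expression.loc[mask, "G0010"]
    labels = (ann.loc[mask, "group"] == "tumor").to_numpy()
    inverted = stats.roc_auc(-scores.to_numpy(), labels)
    assert inverted.auc == pytest.approx(1 - roc.auc, abs=1e-12)


# ---------------------------------------------------------------------------
# DEG + GSEA
# ---------------------------------------------------------------------------

def test_deg_and_gsea_recover_coexpression_module(cohort):
    deg, gsea, heatmap = ca.deg_and_gsea(cohort, "COAD", "G0050", "go",
                                         n_perm=499, seed=13)
    row = gsea[gsea["set_name"] == "GO_COEXP_MODULE"].iloc[0]
    assert row["nes"] > 0
    assert row["fdr"] < 0.25
    assert "G0050" not in deg.index  # index gene excluded


def test_deg_and_gsea_deterministic(cohort):
    a = ca.deg_and_gsea(cohort, "COAD", "G0050", "go", n_perm=199, seed=2)[1]
    b = ca.deg_and_gsea(cohort, "COAD", "G0050", "go", n_perm=199, seed=2)[1]
    pd.testing.assert_frame_equal(a, b)


def test_deg_and_gsea_missing_catalog(cohort):
    with pytest.raises(CohortError, match="GMT"):
        ca.deg_and_gsea(cohort, "COAD", "G0050", "reactome", seed=1)


def test_deg_heatmap_empty_when_nothing_passes(cohort):
    _, _, heatmap = ca.deg_and_gsea(cohort, "COAD", "G0050", "go",
                                    n_perm=99, seed=5, q_threshold=0.0)
    assert heatmap["warning"] is not None
    assert len(heatmap["genes"]) == 0


# ---------------------------------------------------------------------------
# correlation panels
# ---------------------------------------------------------------------------

def test_gene_vs_itself(cohort):
    _, res = ca.gene_gene_correlation(cohort, "COAD", "G0001", "G0001")
    assert res.effect == 1.0


def test_density_flag_changes_nothing_statistical(cohort):
    _, plain = ca.gene_gene_correlation(cohort, "BRCA", "G0070", "G0071",
                                        density=False)
    payload, dens = ca.gene_gene_correlation(cohort, "BRCA", "G0070", "G0071",
                                             density=True)
    assert plain.effect == dens.effect and plain.p == dens.p
    assert payload["density"] is True


def test_planted_pair_recovered(cohort, truth):
    pair = [t for t in truth.coexpression
            if (t["gene_a"], t["gene_b"]) == ("G0070", "G0071")][0]
    _, res = ca.gene_gene_correlation(cohort, "BRCA", "G0070", "G0071")
    assert res.effect == pytest.approx(pair["target_r"], abs=0.1)


def test_methylation_anticorrelation_plant(cohort, truth):
    plant = truth.methylation_corr[0]
    _, res = ca.gene_methylation_correlation(cohort, plant["cancer"],
                                             plant["gene"])
    assert res.effect < 0
    assert res.stars != "ns"


def test_methylation_missing_gene(cohort):
    with pytest.raises(CohortError, match="methylation"):
        ca.gene_methylation_correlation(cohort, "BRCA", "G0400")


def test_coexpression_panel_finds_module(cohort):
    corr, selected, ora, heatmap = ca.coexpression_panel(
        cohort, "COAD", "G0050", catalog_name="go")
    module = {f"G{i:04d}" for i in range(51, 61)}
    assert module <= set(selected.index)
    assert "G0050" not in corr.index       # self-exclusion
    # ORA background is the tested-gene count, not the genome
    assert ora.iloc[0]["background_size"] == len(corr)


def test_coexpression_empty_panel_warns_not_errors(cohort):
    corr, selected, ora, heatmap = ca.coexpression_panel(
        cohort, "COAD", "G0001", q_threshold=1e-30)
    assert heatmap["warning"] is not None
    assert len(selected) == 0


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def test_survival_split_detects_hazard_plant(cohort, truth):
    plant = truth.hazard[0]
    curves, test = ca.survival_by_level(cohort, plant["cancer"],
                                        plant["gene"])
    assert test.stars != "ns"
    assert abs(test.n[0] - test.n[1]) <= 1
    for curve in curves.values():
        assert np.all(np.diff(curve.survival) <= 1e-12)


def test_survival_expression_and_methylation_share_code_path(cohort):
    by_expr = ca.survival_by_level(cohort, "BRCA", "G0030", "expression")
    by_meth = ca.survival_by_level(cohort, "BRCA", "G0030", "methylation")
    for curves, test in (by_expr, by_meth):
        assert set(curves) == {"high", "low"}
        assert 0 <= test.p <= 1


def test_survival_split_deterministic(cohort):
    a = ca.survival_by_level(cohort, "BRCA", "G0030")[1]
    b = ca.survival_by_level(cohort, "BRCA", "G0030")[1]
    assert a.statistic == b.statistic and a.n == b.n


# ---------------------------------------------------------------------------
# term networks
# ---------------------------------------------------------------------------

def test_network_tight_term():
    catalog = {"T": ["A", "B", "C", "D"], "U": ["E", "F", "G", "H", "I"]}
    background = [c for c in "ABCDEFGHIJKLMNOPQRST"]
    net = ca.term_network(["A", "B", "C", "D"], catalog, background)
    assert [t for t, _ in net.terms] == ["T"]
    assert len(net.edges) == 4
    assert all(e[1] == "T" for e in net.edges)


def test_network_single_gene_query(cohort):
    net = ca.term_network(["G0051"], cohort.catalogs["go"],
                          list(cohort.expression.columns), q_threshold=1.01)
    assert all(g == "G0051" for g, _ in net.edges)


def test_network_zero_threshold_is_empty(cohort):
    net = ca.term_network(["G0051", "G0052"], cohort.catalogs["go"],
                          list(cohort.expression.columns), q_threshold=0.0)
    assert net.terms == [] and net.edges == []
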