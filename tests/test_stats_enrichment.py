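"""ssGSEA/ESTIMATE, preranked GSEA, hypergeometric ORA and DEG splits."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pancankit import stats


def _profile(n=12, seed=0):
    rng = np.random.default_rng(seed)
    vals = np.sort(rng.uniform(1, 10, n))[::-1]
    return pd.Series(vals, index=[f"g{i:02d}" for i in range(n)])


@pytest.mark.parametrize("set_size", [2, 3])
def test_ssgsea_extremal_placements_exhaustive(set_size):
    """Top-ranked sets maximize the score over every possible placement."""
    profile = _profile()
    genes = list(profile.index)
    scores = {frozenset(c): stats.ssgsea_score(profile, c)
              for c in itertools.combinations(genes, set_size)}
    top = frozenset(genes[:set_size])
    bottom = frozenset(genes[-set_size:])
    assert scores[top] == max(scores.values())
    assert scores[bottom] == min(scores.values())


def test_ssgsea_monotone_transform_invariance():
    profile = _profile(seed=4)
    transformed = pd.Series(np.exp(profile.to_numpy() / 2.0),
                            index=profile.index)
    s = {"g00", "g05", "g11"}
    assert stats.ssgsea_score(profile, s) == \
        pytest.approx(stats.ssgsea_score(transformed, s), abs=1e-12)


def test_ssgsea_empty_intersection_errors():
    with pytest.raises(ValueError):
        stats.ssgsea_score(_profile(), {"absent"})


def test_estimate_additivity_and_order_invariance():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(rng.uniform(0, 8, (5, 30)),
                        index=[f"s{i}" for i in range(5)],
                        columns=[f"g{i:02d}" for i in range(30)])
    stromal, immune = set(expr.columns[:6]), set(expr.columns[6:12])
    table = stats.estimate_scores(expr, stromal, immune)
    np.testing.assert_allclose(table["ESTIMATE"],
                               table["Stromal"] + table["Immune"], atol=0)
    shuffled = expr[list(rng.permutation(expr.columns))]
    table2 = stats.estimate_scores(shuffled, stromal, immune)
    np.testing.assert_allclose(table.to_numpy(), table2.to_numpy(), atol=1e-12)


def test_estimate_monotone_in_signature_expression():
    rng = np.random.default_rng(2)
    expr = pd.DataFrame(rng.uniform(0, 8, (3, 40)),
                        index=["s0", "s1", "s2"],
                        columns=[f"g{i:02d}" for i in range(40)])
    immune = list(expr.columns[:5])
    boosted = expr.copy()
    boosted.loc["s1", immune] = boosted.to_numpy().max() + np.arange(5) + 1.0
    base = stats.estimate_scores(expr, set(expr.columns[30:35]), immune)
    up = stats.estimate_scores(boosted, set(expr.columns[30:35]), immune)
    assert up.loc["s1", "Immune"] > base.loc["s1", "Immune"]


# ---------------------------------------------------------------------------
# preranked GSEA
# ---------------------------------------------------------------------------

def _ranking(n=200, seed=0):
    rng = np.random.default_rng(seed)
    metric = np.sort(rng.normal(size=n))[::-1]
    return pd.Series(metric, index=[f"g{i:03d}" for i in range(n)])


def test_gsea_top_set_is_significant():
    ranking = _ranking()
    top10 = {g: list(ranking.index[:10]) for g in ["TOP"]}
    table = stats.preranked_gsea(ranking, top10, n_perm=999, seed=7)
    row = table.iloc[0]
    assert row["es"] > 0
    assert row["p"] <= 0.02
    assert np.sign(row["nes"]) == np.sign(row["es"])


def test_gsea_equal_metric_reduces_to_unweighted_ks():
    n = 50
    ranking = pd.Series(np.ones(n), index=[f"g{i:02d}" for i in range(n)])
    members = [f"g{i:02d}" for i in (0, 3, 17, 30, 44)]
    table = stats.preranked_gsea(ranking, {"S": members}, n_perm=10, seed=1)
    # independent unweighted KS oracle on the deterministic tie-break order
    order = sorted(ranking.index)  # equal metric: ties broken by symbol
    in_set = np.isin(order, members)
    running = np.cumsum(np.where(in_set, 1 / in_set.sum(),
                                 -1 / (n - in_set.sum())))
    expected = running[np.argmax(np.abs(running))]
    assert table.iloc[0]["es"] == pytest.approx(expected, abs=1e-12)


def test_gsea_deterministic_given_seed():
    ranking = _ranking(seed=3)
    catalog = {"A": list(ranking.index[5:20]), "B": list(ranking.index[50:70])}
    t1 = stats.preranked_gsea(ranking, catalog, n_perm=199, seed=11)
    t2 = stats.preranked_gsea(ranking, catalog, n_perm=199, seed=11)
    pd.testing.assert_frame_equal(t1, t2)


def test_gsea_skips_tiny_sets():
    ranking = _ranking()
    table = stats.preranked_gsea(ranking, {"tiny": [ranking.index[0]]},
                                 n_perm=19, seed=1)
    assert len(table) == 0


def test_gsea_es_matches_gseapy():
    """The weighted-KS enrichment score agrees with an independent
    implementation on identical rankings and sets."""
    gseapy = pytest.importorskip("gseapy")
    ranking = _ranking(n=100, seed=0)
    catalog = {"S": list(ranking.index[5:20]),
               "T": list(ranking.index[40:60])}
    ours = stats.preranked_gsea(ranking, catalog, n_perm=10, seed=1)
    rnk = pd.DataFrame({"gene": ranking.index, "score": ranking.to_numpy()})
    ref = gseapy.prerank(rnk=rnk, gene_sets=catalog, permutation_num=10,
                         seed=1, min_size=2, max_size=50, weight=1.0,
                         outdir=None, no_plot=True).res2d
    for _, row in ref.iterrows():
        mine = ours[ours["set_name"] == row["Term"]].iloc[0]
        assert mine["es"] == pytest.approx(float(row["ES"]), abs=1e-9)


def test_gsea_requires_seed():
    with pytest.raises(ValueError):
        stats.preranked_gsea(_ranking(), {"A": ["g000", "g001"]}, n_perm=9)


# ---------------------------------------------------------------------------
# hypergeometric ORA
# ---------------------------------------------------------------------------

def test_ora_single_point_tail():
    background = [f"g{i}" for i in range(20)]
    term = {"T": background[:5]}
    table = stats.hypergeometric_ora(background[:5], term, background)
    assert table.iloc[0]["p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)


def test_ora_disjoint_query():
    background = [f"g{i}" for i in range(20)]
    table = stats.hypergeometric_ora(background[10:15],
                                     {"T": background[:5]}, background)
    assert table.iloc[0]["p"] == 1.0


def test_ora_query_equals_background():
    background = [f"g{i}" for i in range(10)]
    table = stats.hypergeometric_ora(background, {"T": background[:4]},
                                     background)
    assert table.iloc[0]["p"] == 1.0


def test_ora_matches_exact_fraction_enumeration():
    rng = np.random.default_rng(6)
    background = [f"g{i}" for i in range(40)]
    term_genes = list(rng.choice(background, 12, replace=False))
    query = list(rng.choice(background, 9, replace=False))
    table = stats.hypergeometric_ora(query, {"T": term_genes}, background)
    k = len(set(query) & set(term_genes))
    exact = sum(Fraction(math.comb(12, i) * math.comb(28, 9 - i),
                         math.comb(40, 9)) for i in range(k, 10))
    assert table.iloc[0]["p"] == pytest.approx(float(exact), abs=1e-15)


def test_ora_empty_query_errors():
    with pytest.raises(ValueError):
        stats.hypergeometric_ora(["x"], {"T": ["g1"]}, ["g1", "g2"])


# ---------------------------------------------------------------------------
# DEG split
# ---------------------------------------------------------------------------

def test_deg_constant_gene_is_null():
    rng = np.random.default_rng(0)
    expr = pd.DataFrame(rng.normal(4, 1, (20, 3)),
                        index=[f"s{i}" for i in range(20)],
                        columns=["idx", "flat", "noise"])
    expr["flat"] = 2.5
    table = stats.deg_high_low(expr, expr["idx"], exclude="idx")
    assert table.loc["flat", "log2fc"] == 0.0
    assert table.loc["flat", "p"] == 1.0
    assert "idx" not in table.index


def test_deg_self_association_without_exclusion():
    rng = np.random.default_rng(1)
    expr = pd.DataFrame(rng.normal(4, 1, (30, 10)),
                        columns=[f"g{i}" for i in range(10)])
    table = stats.deg_high_low(expr, expr["g0"])
    top = table["log2fc"].abs().nlargest(3)
    assert "g0" in top.index


def test_deg_median_split_ties_to_low():
    expr = pd.DataFrame({"idx": [1.0, 2.0, 2.0, 2.0, 3.0, 3.0],
                         "g": [1, 2, 3, 4, 5, 6.0]})
    table = stats.deg_high_low(expr, expr["idx"], exclude="idx")
    # median 2: the three ties at the median fall into the low group
    assert table.loc["g", "n_high"] == 2
    assert table.loc["g", "n_low"] == 4
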