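"""Statistical primitives used by every analysis in the toolkit.

All tests and estimators here are implemented from their defining formulas:
rank tests (Mann-Whitney, Wilcoxon signed-rank, Kruskal-Wallis), BH
multiple-testing correction, Pearson/Spearman correlation, Cox
proportional-hazards partial likelihood with Efron tie handling,
Kaplan-Meier product-limit estimation, the log-rank test, ROC/AUC,
single-sample GSEA (ssGSEA) and the derived stromal/immune/ESTIMATE
infiltration scores, preranked GSEA with gene-label permutation nulls,
and the upper-tail hypergeometric over-representation test.

Only distribution functions (normal, t, chi-square) are delegated to
scipy; every statistic is computed here so it can be checked against
brute-force oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats as _spd

__all__ = [
    "TestResult",
    "CoxResult",
    "KMCurve",
    "ROCResult",
    "GSEAResult",
    "mann_whitney",
    "wilcoxon_signed_rank",
    "correlation",
    "kruskal_wallis",
    "benjamini_hochberg",
    "significance_stars",
    "cox_fit",
    "km_estimate",
    "logrank",
    "roc_auc",
    "gene_set_expression",
    "ssgsea_score",
    "estimate_scores",
    "preranked_gsea",
    "hypergeometric_ora",
    "deg_high_low",
]

_Z975 = 1.959963984540054  # 97.5% standard normal quantile


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    """Outcome of a hypothesis test.

    ``effect`` is context-dependent: a correlation coefficient r, a
    difference of log2 means (log2 fold change), a Kruskal-Wallis H, or
    an AUC.  ``n`` holds the group sizes that entered the test.
    """

    effect: float
    statistic: float
    p: float
    n: tuple
    method: str
    q: float | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    n_events: int
    converged: bool
    adjusted_for_age: bool
    coef: float = float("nan")
    se: float = float("nan")


@dataclass
class KMCurve:
    """Product-limit survival curve evaluated at the distinct event times."""

    times: np.ndarray          # ascending distinct event times
    survival: np.ndarray       # S(t) just after each event time
    at_risk: np.ndarray        # number at risk just before each event time
    n_events: np.ndarray       # deaths at each event time

    def survival_at(self, t: float) -> float:
        """S(t); S(0) = 1 by definition."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float | None
    leading_edge: list = field(default_factory=list)
    n_members: int = 0


# ---------------------------------------------------------------------------
# ranking helpers
# ---------------------------------------------------------------------------


def _midranks(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_counts(values: np.ndarray) -> np.ndarray:
    _, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    return counts


def _rank_sum_distribution(n_select: int, n_total: int) -> np.ndarray:
    """Counts of subsets of {1..n_total} of size n_select by rank sum.

    Dynamic-programming enumeration of the exact Wilcoxon rank-sum null.
    Index s of the returned array is the number of size-``n_select``
    subsets whose ranks sum to s.
    """
    max_sum = n_select * n_total
    table = np.zeros((n_select + 1, max_sum + 1), dtype=float)
    table[0, 0] = 1.0
    for rank in range(1, n_total + 1):
        for k in range(min(rank, n_select), 0, -1):
            table[k, rank:] += table[k - 1, : max_sum + 1 - rank]
    return table[n_select]


def _signed_rank_distribution(n: int) -> np.ndarray:
    """Counts of subsets of {1..n} by rank sum (exact W+ null, 2^n total)."""
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=float)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[:-rank]
        counts = counts + shifted
    return counts


def _two_sided_from_counts(counts: np.ndarray, stat: float) -> float:
    """Two-sided p = min(1, 2*min(P(T<=t), P(T>=t))) from an exact null."""
    total = counts.sum()
    idx_le = int(math.floor(stat + 1e-12))
    idx_ge = int(math.ceil(stat - 1e-12))
    p_le = counts[: idx_le + 1].sum() / total
    p_ge = counts[idx_ge:].sum() / total
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test on midranks.

    Exact p by enumeration of the rank-sum null when min(n_x, n_y) <= 8
    and there are no ties; otherwise a normal approximation with tie and
    continuity corrections.  The reported effect is the difference of
    group means (on whatever scale the inputs carry).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError(f"each group needs >= 2 values (got {nx} and {ny})")
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    rank_sum_x = ranks[:nx].sum()
    u = rank_sum_x - nx * (nx + 1) / 2.0
    ties = _tie_counts(combined)
    has_ties = np.any(ties > 1)
    n_total = nx + ny
    if min(nx, ny) <= 8 and not has_ties:
        # exact: distribution of the x rank sum over C(n, nx) labelings
        counts = _rank_sum_distribution(nx, n_total)
        p = _two_sided_from_counts(counts, rank_sum_x)
    else:
        mu = nx * ny / 2.0
        tie_term = (ties**3 - ties).sum() / (n_total * (n_total - 1)) if n_total > 1 else 0.0
        var = nx * ny / 12.0 * ((n_total + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (u - mu - 0.5 * np.sign(u - mu)) / math.sqrt(var) if u != mu else 0.0
            p = float(2.0 * _spd.norm.sf(abs(z)))
    return TestResult(
        effect=float(x.mean() - y.mean()),
        statistic=float(u),
        p=float(min(p, 1.0)),
        n=(nx, ny),
        method="mann_whitney",
    )


def wilcoxon_signed_rank(differences) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped.  Exact p by enumeration over the 2^n
    sign patterns when n <= 12 and |d| has no ties; otherwise normal
    approximation with tie correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero: degenerate pairing")
    if len(d) < 2:
        raise ValueError("need >= 2 nonzero differences")
    n = len(d)
    absd = np.abs(d)
    ranks = _midranks(absd)
    w_plus = ranks[d > 0].sum()
    ties = _tie_counts(absd)
    if n <= 12 and not np.any(ties > 1):
        counts = _signed_rank_distribution(n)
        p = _two_sided_from_counts(counts, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (ties**3 - ties).sum() / 48.0
        if var <= 0:
            p = 1.0
        else:
            z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / math.sqrt(var) if w_plus != mu else 0.0
            p = float(2.0 * _spd.norm.sf(abs(z)))
    return TestResult(
        effect=float(np.mean(d)),
        statistic=float(w_plus),
        p=float(min(p, 1.0)),
        n=(n,),
        method="wilcoxon_signed_rank",
    )


def correlation(x, y, method: str = "pearson") -> TestResult:
    """Pearson or Spearman correlation with a t-distributed two-sided p.

    Spearman is Pearson on midranks.  p comes from
    t = r * sqrt((n-2) / (1-r^2)) on n-2 degrees of freedom.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    if method == "spearman":
        x, y = _midranks(x), _midranks(y)
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / math.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t, p = math.inf, 0.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _spd.t.sf(abs(t), n - 2))
    return TestResult(effect=r, statistic=float(t), p=p, n=(n,), method=method)


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H test across >= 3 groups, chi-square p on k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("kruskal_wallis needs >= 3 groups; use mann_whitney for 2")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs >= 2 values")
    combined = np.concatenate(groups)
    n_total = len(combined)
    ranks = _midranks(combined)
    h = 0.0
    start = 0
    for g in groups:
        rsum = ranks[start : start + len(g)].sum()
        h += rsum * rsum / len(g)
        start += len(g)
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    ties = _tie_counts(combined)
    correction = 1.0 - (ties**3 - ties).sum() / (n_total**3 - n_total)
    if correction <= 0:
        h, p = 0.0, 1.0
    else:
        h /= correction
        p = float(_spd.chi2.sf(h, len(groups) - 1))
    return TestResult(
        effect=float(h), statistic=float(h), p=p,
        n=tuple(len(g) for g in groups), method="kruskal_wallis",
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, preserving input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


_STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Map a p-value to the conventional star label (strict thresholds)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must be in [0, 1], got {p}")
    for threshold, label in _STAR_THRESHOLDS:
        if p < threshold:
            return label
    return "ns"


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def _efron_loglik(beta, time, event, covs):
    """Efron-approximated Cox partial log-likelihood plus derivatives.

    Returns (loglik, gradient, negative Hessian a.k.a. information).
    """
    beta = np.asarray(beta, dtype=float)
    eta = covs @ beta
    # stabilize exp against overflow
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    p = covs.shape[1]
    ll = 0.0
    grad = np.zeros(p)
    info = np.zeros((p, p))
    event_times = np.unique(time[event == 1])
    for t in event_times:
        at_risk = time >= t
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        s0_r = w[at_risk].sum()
        s1_r = covs[at_risk].T @ w[at_risk]
        s2_r = (covs[at_risk] * w[at_risk, None]).T @ covs[at_risk]
        s0_d = w[dead].sum()
        s1_d = covs[dead].T @ w[dead]
        s2_d = (covs[dead] * w[dead, None]).T @ covs[dead]
        ll += eta[dead].sum()
        grad += covs[dead].sum(axis=0)
        for l in range(d):
            frac = l / d
            s0 = s0_r - frac * s0_d
            s1 = s1_r - frac * s1_d
            s2 = s2_r - frac * s2_d
            ll -= math.log(s0)
            grad -= s1 / s0
            info += s2 / s0 - np.outer(s1, s1) / (s0 * s0)
    return ll, grad, info


def cox_fit(time, event, x, age=None, adjust_age: bool | None = None) -> CoxResult:
    """Cox proportional-hazards fit for one gene, optionally age-adjusted.

    Newton-Raphson maximization of the Efron partial likelihood to a
    log-likelihood change below 1e-9 (at most 50 iterations).  The
    reported HR, CI, and Wald p always concern the gene covariate; age,
    when supplied, enters as a second continuous covariate.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(x, dtype=float)
    if adjust_age is None:
        adjust_age = age is not None
    if adjust_age and age is None:
        raise ValueError("adjust_age requires an age column")
    if np.any(time < 0):
        raise ValueError("negative survival time")
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events to fit (got {n_events})")
    if np.ptp(x) == 0:
        raise ValueError("gene covariate is constant: hazard ratio not identifiable")
    covs = x[:, None] if not adjust_age else np.column_stack([x, np.asarray(age, float)])
    beta = np.zeros(covs.shape[1])
    ll_prev, grad, info = _efron_loglik(beta, time, event, covs)
    converged = False
    for _ in range(50):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular information matrix in Cox fit") from exc
        # step-halving line search
        for halving in range(30):
            candidate = beta + step / (2**halving)
            ll_new, grad_new, info_new = _efron_loglik(candidate, time, event, covs)
            if ll_new >= ll_prev - 1e-12:
                break
        else:
            raise ValueError("Cox fit failed to improve the partial likelihood")
        beta, grad, info = candidate, grad_new, info_new
        if abs(ll_new - ll_prev) < 1e-9:
            converged = True
            ll_prev = ll_new
            break
        ll_prev = ll_new
    if not converged:
        raise ValueError("Cox fit did not converge in 50 Newton iterations")
    if abs(beta[0]) > 15:
        raise ValueError(
            "monotone partial likelihood (perfect separation): |beta| > 15"
        )
    cov_beta = np.linalg.inv(info)
    se = math.sqrt(cov_beta[0, 0])
    coef = float(beta[0])
    p = float(2.0 * _spd.norm.sf(abs(coef / se))) if se > 0 else 0.0
    return CoxResult(
        hr=math.exp(coef),
        ci_low=math.exp(coef - _Z975 * se),
        ci_high=math.exp(coef + _Z975 * se),
        p=p,
        n=len(time),
        n_events=n_events,
        converged=converged,
        adjusted_for_age=bool(adjust_age),
        coef=coef,
        se=se,
    )


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Censored-only input yields S identically 1 (no event times).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time < 0):
        raise ValueError("negative survival time")
    event_times = np.unique(time[event == 1])
    surv = np.empty(len(event_times))
    at_risk = np.empty(len(event_times), dtype=int)
    deaths = np.empty(len(event_times), dtype=int)
    s = 1.0
    for i, t in enumerate(event_times):
        n_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        s *= 1.0 - d / n_risk
        surv[i], at_risk[i], deaths[i] = s, n_risk, d
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk, n_events=deaths)


def logrank(time, event, group) -> TestResult:
    """Two-group log-rank test (observed minus expected, hypergeometric variance)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"logrank needs exactly 2 groups, got {len(labels)}")
    if event.sum() < 1:
        raise ValueError("no events observed")
    in_a = group == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        dead = (time == t) & (event == 1)
        d = int(dead.sum())
        d_a = int((dead & in_a).sum())
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if var <= 0:
        stat, p = 0.0, 1.0
    else:
        stat = o_minus_e * o_minus_e / var
        p = float(_spd.chi2.sf(stat, 1))
    return TestResult(
        effect=float(o_minus_e), statistic=float(stat), p=p,
        n=(int(in_a.sum()), int((~in_a).sum())), method="logrank",
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve over all distinct thresholds; AUC by the trapezoid rule.

    ``labels`` is truthy for the positive (tumor) class.  Ties in score
    contribute diagonal segments, so the trapezoid AUC equals the
    midrank Mann-Whitney identity U / (n_pos * n_neg).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="mergesort")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    # step only at distinct-score boundaries so ties form diagonals
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(~sorted_labels)
    distinct = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc, n_pos=n_pos, n_neg=n_neg)


# ---------------------------------------------------------------------------
# gene-set scoring
# ---------------------------------------------------------------------------


def gene_set_expression(expr: pd.DataFrame, genes) -> tuple[pd.Series, list]:
    """Per-sample mean expression of the gene-set members.

    ``expr`` is samples x genes on the log2(TPM+1) scale.  Returns the
    score series and the list of members absent from the matrix.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    present = [g for g in genes if g in expr.columns]
    absent = [g for g in genes if g not in expr.columns]
    if not present:
        raise ValueError("no gene-set member present in the expression matrix")
    return expr[present].mean(axis=1), absent


def ssgsea_score(values: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample GSEA enrichment score for one sample.

    Genes are ordered by decreasing expression with a deterministic
    tie-break (value, then symbol).  In-set positions accumulate
    normalized rank weights (N - position)^alpha; out-of-set positions
    accumulate uniformly.  The score is the sum of the running
    difference over all positions, so it depends only on the ranking.
    """
    gene_set = set(gene_set)
    genes = np.asarray(values.index)
    vals = values.to_numpy(dtype=float)
    in_set_all = np.isin(genes, list(gene_set))
    m = int(in_set_all.sum())
    if m == 0:
        raise ValueError("gene set does not intersect the expression profile")
    n = len(genes)
    if m == n:
        raise ValueError("gene set covers the whole profile; score undefined")
    order = np.lexsort((genes, -vals))
    in_set = in_set_all[order]
    positions = np.arange(n)
    weights = (n - positions).astype(float) ** alpha
    inc_in = np.where(in_set, weights, 0.0)
    inc_in /= inc_in.sum()
    inc_out = np.where(in_set, 0.0, 1.0 / (n - m))
    running = np.cumsum(inc_in - inc_out)
    return float(running.sum())


def estimate_scores(expr: pd.DataFrame, stromal_set, immune_set,
                    alpha: float = 0.25) -> pd.DataFrame:
    """Stromal, Immune and ESTIMATE infiltration scores per sample.

    Each signature is scored by ssGSEA on the sample's expression
    profile; ESTIMATE is defined as the sum Stromal + Immune.
    """
    stromal_set = set(stromal_set)
    immune_set = set(immune_set)
    rows = {}
    for sample in expr.index:
        profile = expr.loc[sample]
        s = ssgsea_score(profile, stromal_set, alpha=alpha)
        i = ssgsea_score(profile, immune_set, alpha=alpha)
        rows[sample] = (s, i, s + i)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["Stromal", "Immune", "ESTIMATE"])
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


def _gsea_es(metric_sorted: np.ndarray, in_set: np.ndarray):
    """Weighted KS enrichment score (exponent 1 on |metric|).

    Returns (es, index of the extremum, running sum).
    """
    n = len(metric_sorted)
    m = int(in_set.sum())
    weights = np.abs(metric_sorted)
    w_in = np.where(in_set, weights, 0.0)
    total = w_in.sum()
    if total <= 0:
        # all member metrics zero: fall back to unweighted steps
        w_in = in_set.astype(float)
        total = w_in.sum()
    inc = w_in / total - np.where(in_set, 0.0, 1.0 / (n - m))
    running = np.cumsum(inc)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), idx, running


def preranked_gsea(ranking: pd.Series, catalog: dict, n_perm: int = 1000,
                   seed: int | None = None) -> pd.DataFrame:
    """Preranked GSEA against a catalog of gene sets.

    The ranking metric is sorted decreasing; the enrichment score is the
    signed maximum deviation of the weighted Kolmogorov-Smirnov running
    sum.  The null is built from ``n_perm`` seeded gene-label
    permutations; p includes the +1 correction and NES normalizes by the
    mean |null ES| of matching sign.  Sets with < 2 members in the
    ranking are skipped.
    """
    if seed is None:
        raise ValueError("preranked_gsea requires an explicit seed")
    rng = np.random.default_rng(seed)
    genes = np.asarray(ranking.index)
    metric = ranking.to_numpy(dtype=float)
    order = np.lexsort((genes, -metric))
    genes_sorted = genes[order]
    metric_sorted = metric[order]
    n = len(genes_sorted)
    gene_pos = {g: i for i, g in enumerate(genes_sorted)}
    rows = []
    for set_name, members in catalog.items():
        pos = np.array(sorted(gene_pos[g] for g in set(members) if g in gene_pos),
                       dtype=int)
        m = len(pos)
        if m < 2 or m >= n:
            continue
        if 2 * m > n:
            continue  # ranking must be at least twice the set size
        in_set = np.zeros(n, dtype=bool)
        in_set[pos] = True
        es, idx, running = _gsea_es(metric_sorted, in_set)
        # gene-label permutation null
        null_es = np.empty(n_perm)
        for b in range(n_perm):
            perm_pos = rng.choice(n, size=m, replace=False)
            in_null = np.zeros(n, dtype=bool)
            in_null[perm_pos] = True
            null_es[b], _, _ = _gsea_es(metric_sorted, in_null)
        # p is computed within the matching-sign null pool (the classic
        # GSEA convention): conditioning only the numerator on sign would
        # compress p into (0, 1/2) and break null uniformity
        if es >= 0:
            same_sign = null_es[null_es >= 0]
            extreme = int((same_sign >= es).sum())
        else:
            same_sign = null_es[null_es < 0]
            extreme = int((same_sign <= es).sum())
        p = (1.0 + extreme) / (len(same_sign) + 1.0)
        denom = np.abs(same_sign).mean() if len(same_sign) else np.abs(null_es).mean()
        nes = es / denom if denom > 0 else 0.0
        if es >= 0:
            leading = [g for g in genes_sorted[: idx + 1] if in_set[gene_pos[g]]]
        else:
            leading = [g for g in genes_sorted[idx:] if in_set[gene_pos[g]]]
        rows.append(
            {"set_name": set_name, "es": es, "nes": nes, "p": p,
             "n_members": m, "leading_edge": ",".join(leading)}
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["fdr"] = benjamini_hochberg(table["p"].to_numpy())
    else:
        table = pd.DataFrame(
            columns=["set_name", "es", "nes", "p", "n_members", "leading_edge", "fdr"]
        )
    return table


def hypergeometric_ora(query, catalog: dict, background) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per term.

    The tail probability is computed exactly with integer binomial
    coefficients.  BH correction is applied across terms; each row
    reports the overlap genes.
    """
    background = set(background)
    query = set(query) & background
    if not query:
        raise ValueError("query is empty after intersecting with the background")
    big_m = len(background)
    n_query = len(query)
    rows = []
    for term, members in catalog.items():
        term_genes = set(members) & background
        big_k = len(term_genes)
        if big_k == 0:
            continue
        overlap = sorted(query & term_genes)
        k = len(overlap)
        upper = min(big_k, n_query)
        numer = sum(
            math.comb(big_k, i) * math.comb(big_m - big_k, n_query - i)
            for i in range(k, upper + 1)
        )
        p = float(Fraction(numer, math.comb(big_m, n_query)))
        rows.append(
            {"term": term, "k_overlap": k, "term_size": big_k,
             "query_size": n_query, "background_size": big_m,
             "p": min(p, 1.0), "overlap": ",".join(overlap)}
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = benjamini_hochberg(table["p"].to_numpy())
    else:
        table = pd.DataFrame(columns=["term", "k_overlap", "term_size", "query_size",
                                      "background_size", "p", "overlap", "q"])
    return table


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------


def deg_high_low(expr: pd.DataFrame, index: pd.Series,
                 exclude: str | None = None) -> pd.DataFrame:
    """Differential expression between high and low halves of an index.

    Samples are split at the median of ``index`` (ties go to the low
    group).  Per gene: log2FC = mean(high) - mean(low) on the stored
    log2 scale, p from the Mann-Whitney test, q from BH.  ``exclude``
    drops the index gene itself from the result.
    """
    index = index.loc[expr.index]
    if len(expr) < 4:
        raise ValueError("need >= 4 samples for a high/low split")
    median = float(index.median())
    high = index > median
    if high.sum() == 0 or (~high).sum() == 0:
        raise ValueError("degenerate median split: one group is empty")
    hi_expr = expr.loc[high]
    lo_expr = expr.loc[~high]
    rows = []
    for gene in expr.columns:
        if exclude is not None and gene == exclude:
            continue
        hv = hi_expr[gene].to_numpy()
        lv = lo_expr[gene].to_numpy()
        if np.ptp(np.concatenate([hv, lv])) == 0:
            rows.append({"gene": gene, "log2fc": 0.0, "statistic": float("nan"),
                         "p": 1.0})
            continue
        res = mann_whitney(hv, lv)
        rows.append({"gene": gene, "log2fc": res.effect,
                     "statistic": res.statistic, "p": res.p})
    table = pd.DataFrame(rows).set_index("gene")
    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    table["n_high"] = int(high.sum())
    table["n_low"] = int((~high).sum())
    return table
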