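"""Non-parametric statistical battery over the subject x phase feature table.

The feature table is a tidy DataFrame with one row per subject x phase and
columns ``subject``, ``group``, ``phase`` plus one column per index.  The
battery mirrors standard repeated-measures practice for short-term
autonomic studies:

* a normality screen (Lilliefors-corrected Kolmogorov-Smirnov plus a
  QQ-correlation summary) that is informational only — the pipeline always
  proceeds non-parametrically;
* Friedman's test across the four matched conditions with pairwise
  Wilcoxon signed-rank post-hocs, Bonferroni-corrected (x6), with the
  non-parametric effect size r = |Z|/sqrt(n);
* Mann-Whitney U tests between groups on task-minus-rest deltas;
* Spearman correlations of physiological deltas with subjective stress
  (SUDS) change and with cortisol percentage change 100*(t0 - t)/t0;
* Wilcoxon signed-rank tests of cortisol t1/t2 versus baseline.

Exact p-values are used for small samples (n <= 12, no ties); otherwise
the normal approximation with continuity correction.  An exact Friedman
p-value for small cohorts is available through dynamic-programming
enumeration of the per-subject rank permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "FriedmanResult", "normality_screen", "friedman_statistic",
    "friedman_exact_pvalue", "friedman_posthoc", "group_delta_test",
    "spearman_links", "cortisol_pct_change", "cortisol_change_test",
    "exclude_outliers",
]

PHASES = ("REST", "MIST", "MGT", "VS")
_EXACT_N_MAX = 12


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _phase_matrix(table, feature, scope="ALL", phases=PHASES):
    """Complete-case subject x phase matrix for one feature."""
    df = table if scope == "ALL" else table[table["group"] == scope]
    wide = df.pivot_table(index="subject", columns="phase", values=feature,
                          aggfunc="first")
    wide = wide.reindex(columns=list(phases)).dropna()
    return wide


def _signed_rank_z(diff):
    """Z statistic of the Wilcoxon signed-rank test (normal approximation
    with tie correction and continuity correction), computed on the
    non-zero differences."""
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 0
    ranks = sst.rankdata(np.abs(d))
    w_plus = float(np.sum(ranks[d > 0]))
    mu = n * (n + 1) / 4.0
    # tie correction
    _, counts = np.unique(ranks, return_counts=True)
    tie = np.sum(counts**3 - counts) / 48.0
    sd = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie)
    if sd == 0:
        return 0.0, n
    z = (w_plus - mu - 0.5 * np.sign(w_plus - mu)) / sd
    return float(z), n


def _wilcoxon_p(diff):
    """Two-sided signed-rank p: exact for n <= 12 without ties/zeros."""
    d = np.asarray(diff, dtype=float)
    nz = d[d != 0]
    if nz.size == 0:
        return 1.0
    exact_ok = (nz.size <= _EXACT_N_MAX and np.unique(np.abs(nz)).size == nz.size
                and nz.size == d.size)
    res = sst.wilcoxon(d, correction=True,
                       method="exact" if exact_ok else "approx")
    return float(res.pvalue)


def _mannwhitney_z(x, y):
    """Z of the Mann-Whitney U normal approximation with tie correction."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = x.size, y.size
    ranks = sst.rankdata(np.concatenate([x, y]))
    u1 = np.sum(ranks[:n1]) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    nt = n1 + n2
    _, counts = np.unique(ranks, return_counts=True)
    tie = np.sum(counts**3 - counts) / (nt * (nt - 1))
    sd = np.sqrt(n1 * n2 / 12.0 * (nt + 1 - tie))
    if sd == 0:
        return 0.0
    return float((u1 - mu - 0.5 * np.sign(u1 - mu)) / sd)


# ---------------------------------------------------------------------------
# normality screen
# ---------------------------------------------------------------------------

def normality_screen(values):
    """Lilliefors-corrected KS test plus a QQ-plot straightness summary.

    Informational only; returns a dict with the KS statistic and p-value
    and the correlation of the sample quantiles with the theoretical normal
    quantiles.  Degenerate (constant) input is flagged.
    """
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if x.size < 4 or np.ptp(x) == 0:
        return {"n": int(x.size), "degenerate": True,
                "ks_stat": np.nan, "p": np.nan, "qq_r": np.nan}
    stat, p = lilliefors(x, dist="norm")
    q = np.sort(x)
    theo = sst.norm.ppf((np.arange(1, x.size + 1) - 0.5) / x.size)
    qq_r = float(np.corrcoef(q, theo)[0, 1])
    return {"n": int(x.size), "degenerate": False,
            "ks_stat": float(stat), "p": float(p), "qq_r": qq_r}


# ---------------------------------------------------------------------------
# Friedman + post-hoc
# ---------------------------------------------------------------------------

def friedman_statistic(matrix):
    """Friedman chi-square statistic (midrank ties) of an n x k matrix."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    ranks = np.apply_along_axis(sst.rankdata, 1, m)
    rsum = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(rsum**2) - 3.0 * n * (k + 1)
    # tie correction (standard Friedman adjustment)
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    denom = 1.0 - ties / (n * k * (k**2 - 1))
    return float(stat / denom) if denom > 0 else 0.0


def friedman_exact_pvalue(matrix):
    """Exact Friedman p-value by enumerating per-subject rank permutations.

    Under the null every within-subject ordering is equally likely; the
    distribution of the rank-sum vector is built by dynamic programming
    over subjects (states are condition rank-sum tuples), which makes the
    full (k!)^n enumeration tractable for the small cohorts where an exact
    test matters.  Requires tie-free rows.
    """
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    for row in m:
        if np.unique(row).size != k:
            raise ValueError("exact Friedman p requires tie-free rows")
    obs = friedman_statistic(m)
    perms = list(permutations(range(1, k + 1)))
    states = {tuple([0] * k): 1.0}
    for _ in range(n):
        new = {}
        for state, cnt in states.items():
            for pm in perms:
                key = tuple(s + r for s, r in zip(state, pm))
                new[key] = new.get(key, 0.0) + cnt
        states = new
    total = float(len(perms)) ** n
    tail = 0.0
    const = 12.0 / (n * k * (k + 1))
    for rsum, cnt in states.items():
        stat = const * sum(r**2 for r in rsum) - 3.0 * n * (k + 1)
        if stat >= obs - 1e-9:
            tail += cnt
    return float(tail / total)


@dataclass
class FriedmanResult:
    feature: str
    scope: str
    n: int
    statistic: float
    p: float
    posthoc: list  # dicts: pair, p_raw, p_corrected, direction, r


def friedman_posthoc(table, feature, scope="ALL", alpha=0.05, method="chi2"):
    """Friedman test over the four matched conditions with Wilcoxon
    signed-rank post-hocs (Bonferroni x6) and effect sizes r = |Z|/sqrt(n).

    ``scope`` is "ALL" or a group label.  Subjects with incomplete phase
    data are dropped; fewer than 5 complete subjects is an error.  The
    post-hoc table is populated only when the omnibus test rejects at
    ``alpha``.  ``method`` "exact" uses the enumeration p-value (small n).
    """
    wide = _phase_matrix(table, feature, scope)
    n = len(wide)
    if n < 5:
        raise ValueError(f"need >= 5 complete subjects, got {n}")
    m = wide.to_numpy()
    stat = friedman_statistic(m)
    if method == "exact":
        p = friedman_exact_pvalue(m)
    else:
        p = float(sst.chi2.sf(stat, len(PHASES) - 1))
    posthoc = []
    if p < alpha:
        n_pairs = len(list(combinations(PHASES, 2)))
        for a, b in combinations(PHASES, 2):
            diff = m[:, PHASES.index(b)] - m[:, PHASES.index(a)]
            p_raw = _wilcoxon_p(diff)
            z, n_nz = _signed_rank_z(diff)
            r = abs(z) / np.sqrt(n_nz) if n_nz > 0 else 0.0
            direction = "up" if np.median(diff) > 0 else (
                "down" if np.median(diff) < 0 else "none")
            posthoc.append({
                "pair": (a, b), "p_raw": p_raw,
                "p_corrected": min(1.0, p_raw * n_pairs),
                "direction": direction, "r": float(r), "n": int(n_nz),
            })
    return FriedmanResult(feature=feature, scope=scope, n=n,
                          statistic=stat, p=p, posthoc=posthoc)


# ---------------------------------------------------------------------------
# between-group tests on deltas
# ---------------------------------------------------------------------------

def group_delta_test(table, feature, task):
    """Mann-Whitney U test between groups on per-subject task - REST deltas."""
    if task not in PHASES[1:]:
        raise ValueError(f"task must be one of {PHASES[1:]}")
    wide = table.pivot_table(index=["subject", "group"], columns="phase",
                             values=feature, aggfunc="first").reset_index()
    wide = wide.dropna(subset=["REST", task])
    delta = wide[task] - wide["REST"]
    g1 = delta[wide["group"] == "STRESS"].to_numpy()
    g2 = delta[wide["group"] == "CONTROL"].to_numpy()
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be represented")
    pooled = np.concatenate([g1, g2])
    exact_ok = (min(g1.size, g2.size) <= _EXACT_N_MAX
                and np.unique(pooled).size == pooled.size)
    res = sst.mannwhitneyu(g1, g2, alternative="two-sided",
                           method="exact" if exact_ok else "asymptotic")
    z = _mannwhitney_z(g1, g2)
    r = abs(z) / np.sqrt(g1.size + g2.size)
    return {"task": task, "feature": feature, "n": (int(g1.size), int(g2.size)),
            "U": float(res.statistic), "p": float(res.pvalue), "r": float(r),
            "median_delta": (float(np.median(g1)), float(np.median(g2)))}


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def cortisol_pct_change(t0, t):
    """Cortisol percentage variation from baseline: 100 * (t0 - t) / t0."""
    t0 = np.asarray(t0, dtype=float)
    t = np.asarray(t, dtype=float)
    return 100.0 * (t0 - t) / t0


def spearman_links(deltas, covariate):
    """Spearman rank correlation (average-rank tie handling) between a
    physiological delta and a covariate (SUDS change or cortisol % change).

    A constant covariate yields a missing correlation.
    """
    x = np.asarray(deltas, dtype=float)
    y = np.asarray(covariate, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3 or np.ptp(y) == 0 or np.ptp(x) == 0:
        return {"rho": np.nan, "p": np.nan, "n": int(x.size)}
    rho, p = sst.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": int(x.size)}


def exclude_outliers(values, k=3.0):
    """Mask values larger than mean + k * SD (the rule used before the
    cortisol correlation stage)."""
    x = np.asarray(values, dtype=float)
    lim = np.nanmean(x) + k * np.nanstd(x)
    return x <= lim


# ---------------------------------------------------------------------------
# cortisol response
# ---------------------------------------------------------------------------

def cortisol_change_test(cortisol, groups=None):
    """Wilcoxon signed-rank tests of cortisol at t1 and t2 versus t0.

    ``cortisol`` is an (n, 3) array of per-subject (t0, t1, t2); ``groups``
    an optional length-n label sequence for per-group sub-tests.  Returns
    a dict keyed by (scope, comparison) with p and effect size r.
    """
    c = np.asarray(cortisol, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("cortisol must be (n, 3): columns t0, t1, t2")
    scopes = {"ALL": np.ones(len(c), dtype=bool)}
    if groups is not None:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            scopes[str(g)] = groups == g
    out = {}
    for scope, mask in scopes.items():
        for j, name in ((1, "t1-t0"), (2, "t2-t0")):
            diff = c[mask, j] - c[mask, 0]
            p = _wilcoxon_p(diff)
            z, n_nz = _signed_rank_z(diff)
            r = abs(z) / np.sqrt(n_nz) if n_nz else 0.0
            out[(scope, name)] = {"p": float(p), "r": float(r), "n": int(mask.sum())}
    return out
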