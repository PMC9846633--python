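"""Population statistics for pair summaries.

Nonparametric location comparisons (Mann-Whitney / Wilcoxon), Spearman
correlation with a t-statistic p-value, the Conover squared-ranks test of
equal variance, an exact 1-D two-cluster K-means, and the bootstrap inertia
test of bimodality used on failure-rate distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["StatResult", "BimodalityResult", "group_compare",
           "conover_variance_test", "spearman_corr", "kmeans_1d_k2",
           "bootstrap_bimodality"]


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    two_sided: bool = True
    extra: dict = field(default_factory=dict)


@dataclass
class BimodalityResult:
    observed_inertia: float
    cluster_means: tuple[float, float]
    dispersion_explained: float
    bootstrap_inertias: np.ndarray
    p_one_sided: float
    n_draws_per_rep: int
    n_reps: int
    seed: int | None


def group_compare(x: np.ndarray, y: np.ndarray, paired: bool = False) -> StatResult:
    """Two-sided Mann-Whitney (unpaired) or Wilcoxon signed-rank (paired)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if min(x.size, y.size) < 3:
        raise ValueError("need at least 3 values per group")
    if paired:
        if x.size != y.size:
            raise ValueError("paired comparison requires equal lengths")
        d = x - y
        if np.all(d == 0):
            return StatResult("wilcoxon", np.nan, np.nan, (x.size, y.size),
                              extra={"flag": "all_differences_zero"})
        res = stats.wilcoxon(x, y, alternative="two-sided")
        name = "wilcoxon"
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        name = "mannwhitney"
    return StatResult(name, float(res.statistic), float(res.pvalue),
                      (x.size, y.size))


def conover_variance_test(x: np.ndarray, y: np.ndarray,
                          method: str = "normal",
                          n_perm: int = 10000,
                          rng: np.random.Generator | int | None = None
                          ) -> StatResult:
    """Conover squared-ranks test of equal variance (two-sided).

    Absolute deviations from the group means are ranked jointly, the ranks
    squared, and the statistic is their sum in the first group.  The default
    uses the tie-corrected normal approximation; ``method='permutation'``
    evaluates the same statistic against ``n_perm`` random permutations
    (useful at small n and as an internal cross-check).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if min(n, m) < 5:
        raise ValueError("need at least 5 values per group")
    dev = np.concatenate([np.abs(x - x.mean()), np.abs(y - y.mean())])
    if np.all(dev == 0):
        raise ValueError("zero within-group deviation everywhere")
    s = stats.rankdata(dev) ** 2
    t_obs = float(s[:n].sum())
    N = n + m
    s_bar = s.mean()
    var_t = n * m / (N * (N - 1.0)) * (np.sum(s ** 2) - N * s_bar ** 2)
    if method == "normal":
        if var_t <= 0:
            raise ValueError("degenerate squared-ranks variance")
        z = (t_obs - n * s_bar) / np.sqrt(var_t)
        p = 2.0 * stats.norm.sf(abs(z))
        return StatResult("conover_squared_ranks", z, float(min(p, 1.0)), (n, m))
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    gen = np.random.default_rng(rng)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = s[gen.permutation(N)[:n]].sum()
    center = n * s_bar
    p = (np.sum(np.abs(null - center) >= abs(t_obs - center)) + 1) / (n_perm + 1)
    return StatResult("conover_squared_ranks_perm", t_obs, float(p), (n, m))


def spearman_corr(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Spearman rho with two-sided p from the t-transform (n - 2 df).

    When significant at 0.05 the least-squares slope of y on x is reported in
    ``extra['slope']`` (the convention for reporting significant
    correlations).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 5:
        raise ValueError("need paired samples with n >= 5")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return StatResult("spearman", np.nan, np.nan, (x.size,),
                          extra={"flag": "constant_input"})
    rho, p = stats.spearmanr(x, y)
    extra = {}
    if p < 0.05:
        extra["slope"] = float(np.polyfit(x, y, 1)[0])
    return StatResult("spearman", float(rho), float(p), (x.size,), extra=extra)


# ---------------------------------------------------------------------------
# exact 1-D two-cluster K-means and the bootstrap bimodality test
# ---------------------------------------------------------------------------


def _split_inertias(sorted_rows: np.ndarray) -> np.ndarray:
    """Within-cluster sum of squares for every contiguous split of sorted rows.

    ``sorted_rows`` has shape (reps, n), each row sorted ascending.  Returns
    shape (reps, n - 1): the WSS when the first cluster holds the j + 1
    smallest values.  The optimal 2-partition in 1-D is always a contiguous
    split of the sorted values, so the row-minimum is the exact K-means
    inertia.
    """
    r, n = sorted_rows.shape
    c1 = np.cumsum(sorted_rows, axis=1)
    c2 = np.cumsum(sorted_rows ** 2, axis=1)
    sizes = np.arange(1, n)
    left_s1, left_s2 = c1[:, :-1], c2[:, :-1]
    tot_s1, tot_s2 = c1[:, -1:], c2[:, -1:]
    right_s1 = tot_s1 - left_s1
    right_s2 = tot_s2 - left_s2
    wss = (left_s2 - left_s1 ** 2 / sizes) \
        + (right_s2 - right_s1 ** 2 / (n - sizes))
    return np.maximum(wss, 0.0)


def kmeans_1d_k2(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Exact two-cluster K-means of a 1-D sample.

    Scans every contiguous split of the sorted values (provably optimal in
    1-D).  Returns ``(assignment, inertia, dispersion_explained)`` where the
    assignment is 0 for the low cluster, 1 for the high cluster, in the
    original order, and ``dispersion_explained = 1 - WSS/TSS`` (1.0 when the
    total dispersion is zero).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 values")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    wss = _split_inertias(xs[None, :])[0]
    j = int(np.argmin(wss))
    inertia = float(wss[j])
    assignment = np.zeros(n, dtype=int)
    assignment[order[j + 1:]] = 1
    tss = float(np.sum((x - x.mean()) ** 2))
    dispersion = 1.0 - inertia / tss if tss > 0 else 1.0
    return assignment, inertia, dispersion


def cluster_means(values: np.ndarray, assignment: np.ndarray
                  ) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    return (float(values[assignment == 0].mean()),
            float(values[assignment == 1].mean()))


def bootstrap_bimodality(reference: np.ndarray, observed: np.ndarray,
                         n_draws: int | None = None, n_reps: int = 10000,
                         seed: int | None = None) -> BimodalityResult:
    """Bootstrap test: is the observed K-means inertia unusually small?

    Draws ``n_draws`` values with replacement from ``reference`` ``n_reps``
    times, computes the exact two-cluster inertia of each draw, and reports
    ``p = (#{bootstrap inertia <= observed inertia} + 1) / (n_reps + 1)``
    (one-sided: small observed inertia = tightly separated clusters =
    bimodality beyond what resampling the reference produces).
    ``n_draws`` defaults to the observed sample size.
    """
    ref = np.asarray(reference, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if n_draws is None:
        n_draws = obs.size
    if n_draws < 4:
        raise ValueError("need at least 4 draws per replicate")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    assignment, inertia, dispersion = kmeans_1d_k2(obs)
    means = cluster_means(obs, assignment)
    if np.all(ref == ref[0]):
        warnings.warn("degenerate reference (all values equal); p = 1",
                      stacklevel=2)
        return BimodalityResult(inertia, means, dispersion,
                                np.zeros(n_reps), 1.0, n_draws, n_reps, seed)
    rng = np.random.default_rng(seed)
    draws = rng.choice(ref, size=(n_reps, n_draws), replace=True)
    draws.sort(axis=1)
    boot = _split_inertias(draws).min(axis=1)
    p = (float(np.sum(boot <= inertia)) + 1.0) / (n_reps + 1.0)
    return BimodalityResult(observed_inertia=inertia, cluster_means=means,
                            dispersion_explained=dispersion,
                            bootstrap_inertias=boot, p_one_sided=p,
                            n_draws_per_rep=n_draws, n_reps=n_reps, seed=seed)
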