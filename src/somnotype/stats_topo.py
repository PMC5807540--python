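"""Group statistics on channel topographies.

Unpaired Student t-tests (sample- and summary-based), Spearman rank
correlations, and a statistical non-parametric mapping (SnPM) supra-threshold
cluster permutation test: per-channel two-sample t-maps are thresholded at a
cluster-forming t (default: the two-tailed critical value at α = 0.05 for the
design's degrees of freedom), adjacency-connected components are formed
separately for positive and negative t, and each cluster's statistic (mass
Σ|t|, or size) is referred to the permutation distribution of the maximum
cluster statistic over random relabelings of group membership — the standard
family-wise-error-controlling max-statistic construction.

The permutation engine evaluates all relabelings in a vectorised batch:
per-channel t-maps for every permutation at once, then connected components
by iterative minimum-label propagation over the adjacency matrix, which
converges in at most the cluster diameter iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .io_formats import AdjacencyGraph


def critical_t(alpha: float, df: float) -> float:
    """Two-tailed Student critical value."""
    return float(sps.t.ppf(1.0 - alpha / 2.0, df))


def unpaired_t(a, b) -> tuple[float, float, float]:
    """Pooled-variance two-sample Student t; returns (t, df, p).

    Degenerate zero-variance input yields t = 0, p = 1 for equal means and
    signed infinity with p = 0 otherwise.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if sp2 == 0:
        if a.mean() == b.mean():
            return 0.0, float(df), 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), float(df), 0.0
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(df), float(res.pvalue)


def t_from_summary(mean_a: float, se_a: float, n_a: int,
                   mean_b: float, se_b: float, n_b: int
                   ) -> tuple[float, float, float]:
    """Two-sample t from group means and standard errors (Welch form).

    t = (mean_a − mean_b) / sqrt(se_a² + se_b²) with Welch–Satterthwaite
    degrees of freedom; lets printed summary tables be re-tested directly.
    """
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    va, vb = se_a ** 2, se_b ** 2
    t = (mean_a - mean_b) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return t, df, p


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-tailed p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired vectors of length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class ClusterResult:
    channels: list[str]
    sign: int           # +1: group A > group B
    stat: float         # cluster mass Σ|t| or size
    p: float            # FWER-corrected

    @property
    def size(self) -> int:
        return len(self.channels)


def _tmap_batch(data: np.ndarray, idx_a: np.ndarray, n_a: int, n_b: int
                ) -> np.ndarray:
    """Pooled-variance t-maps for a batch of relabelings.

    data: (n_subjects, n_channels); idx_a: (n_perm, n_a) row indices assigned
    to group A.  Returns (n_perm, n_channels).
    """
    n = n_a + n_b
    total = data.sum(axis=0)
    total_sq = (data ** 2).sum(axis=0)
    sum_a = data[idx_a].sum(axis=1)                   # (n_perm, n_ch)
    sumsq_a = (data[idx_a] ** 2).sum(axis=1)
    sum_b = total - sum_a
    sumsq_b = total_sq - sumsq_a
    mean_a, mean_b = sum_a / n_a, sum_b / n_b
    ss_a = sumsq_a - n_a * mean_a ** 2
    ss_b = sumsq_b - n_b * mean_b ** 2
    sp2 = (ss_a + ss_b) / (n - 2)
    denom = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / denom
    return np.where(denom == 0, 0.0, t)


def _max_cluster_stat_batch(tmaps: np.ndarray, adj: np.ndarray,
                            t_thresh: float, stat: str) -> np.ndarray:
    """Maximum cluster statistic per permutation, both signs.

    Connected components among supra-threshold channels of a common sign via
    iterative minimum-label propagation on the boolean adjacency matrix.
    """
    n_perm, n_ch = tmaps.shape
    out = np.zeros(n_perm)
    weights = np.abs(tmaps) if stat == "mass" else np.ones_like(tmaps)
    nbr = [np.nonzero(adj[c])[0] for c in range(n_ch)]
    for sign in (1, -1):
        supra = (sign * tmaps) > t_thresh
        active = np.nonzero(supra.any(axis=1))[0]
        if len(active) == 0:
            continue
        sup = supra[active]
        labels = np.where(sup, np.arange(n_ch)[None, :], n_ch).astype(np.int32)
        # propagate the minimum label through supra neighbours to convergence
        while True:
            new = labels.copy()
            for c in range(n_ch):
                nb = nbr[c]
                if len(nb) == 0:
                    continue
                cand = labels[:, nb].min(axis=1)
                upd = sup[:, c] & (cand < new[:, c])
                new[upd, c] = cand[upd]
            new = np.where(sup, new, n_ch)
            if np.array_equal(new, labels):
                break
            labels = new
        w = np.where(sup, weights[active], 0.0)
        key = labels + (np.arange(len(active), dtype=np.int64)[:, None] * (n_ch + 1))
        sums = np.zeros(len(active) * (n_ch + 1))
        np.add.at(sums, key.ravel(), w.ravel())
        sums = sums.reshape(len(active), n_ch + 1)[:, :n_ch]
        out[active] = np.maximum(out[active], sums.max(axis=1))
    return out


def _clusters_single(tmap: np.ndarray, neighbors: list[list[int]],
                     t_thresh: float, stat: str) -> list[tuple[list[int], int, float]]:
    """Connected supra-threshold clusters of one observed t-map (BFS)."""
    clusters = []
    for sign in (1, -1):
        supra = (sign * tmap) > t_thresh
        seen = np.zeros(len(tmap), bool)
        for start in np.nonzero(supra)[0]:
            if seen[start]:
                continue
            comp = [int(start)]
            seen[start] = True
            queue = [int(start)]
            while queue:
                c = queue.pop()
                for nb in neighbors[c]:
                    if supra[nb] and not seen[nb]:
                        seen[nb] = True
                        comp.append(nb)
                        queue.append(nb)
            val = float(np.abs(tmap[comp]).sum()) if stat == "mass" else float(len(comp))
            clusters.append((sorted(comp), sign, val))
    return clusters


def snpm_cluster_test(group_a: np.ndarray, group_b: np.ndarray,
                      adjacency: AdjacencyGraph,
                      t_thresh: float | None = None,
                      n_perm: int = 65536,
                      seed: int | np.random.Generator = 0,
                      stat: str = "mass",
                      exact: bool = False) -> list[ClusterResult]:
    """Supra-threshold cluster permutation test between two subject groups.

    Parameters
    ----------
    group_a, group_b : (n_subjects, n_channels) per-subject topographies.
    adjacency : channel adjacency used to form clusters.
    t_thresh : cluster-forming threshold; default is the two-tailed critical
        t at α = 0.05 for ``n_a + n_b − 2`` degrees of freedom.
    n_perm : number of relabelings in the null (the observed labeling is
        always one of them).  ``exact=True`` enumerates all distinct
        relabelings instead (feasible only for tiny designs).
    stat : "mass" (Σ|t| within the cluster) or "size" (channel count).

    Returns the observed clusters (both signs) with FWER-corrected p-values:
    the proportion of null maxima at least as large as the cluster statistic.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("groups must be 2-D with a common channel axis")
    n_a, n_b = a.shape[0], b.shape[0]
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    n_ch = a.shape[1]
    if len(adjacency.labels) != n_ch:
        raise ValueError("adjacency size does not match channel count")
    if stat not in ("mass", "size"):
        raise ValueError("stat must be 'mass' or 'size'")
    if t_thresh is None:
        t_thresh = critical_t(0.05, n_a + n_b - 2)
    if t_thresh <= 0:
        raise ValueError("t_thresh must be positive")
    if n_perm < 100 and not exact:
        import warnings

        warnings.warn("fewer than 100 permutations gives a coarse null",
                      stacklevel=2)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = np.concatenate([a, b], axis=0)
    n = n_a + n_b
    observed_idx = np.arange(n_a)

    if exact:
        idx_a = np.array(list(combinations(range(n), n_a)), dtype=np.intp)
    else:
        idx_a = np.empty((n_perm, n_a), dtype=np.intp)
        idx_a[0] = observed_idx
        for k in range(1, n_perm):
            idx_a[k] = rng.permutation(n)[:n_a]

    tmaps = _tmap_batch(data, idx_a, n_a, n_b)
    t_obs = _tmap_batch(data, observed_idx[None, :], n_a, n_b)[0]
    null_max = _max_cluster_stat_batch(tmaps, adjacency.matrix(), t_thresh, stat)

    results = []
    for comp, sign, val in _clusters_single(t_obs, adjacency.neighbors(),
                                            t_thresh, stat):
        p = float(np.mean(null_max >= val))
        results.append(ClusterResult(
            channels=[adjacency.labels[i] for i in comp],
            sign=sign, stat=val, p=p))
    results.sort(key=lambda c: c.p)
    return results


def cluster_mean(topo: np.ndarray, labels: list[str],
                 cluster_channels: list[str]) -> np.ndarray:
    """Per-subject mean of the topography over a cluster's channels.

    ``topo`` is (n_subjects, n_channels) aligned with ``labels``; the result
    feeds Spearman correlations against behavioural scores.
    """
    if not cluster_channels:
        raise ValueError("empty cluster")
    index = {lb: i for i, lb in enumerate(labels)}
    missing = [c for c in cluster_channels if c not in index]
    if missing:
        raise ValueError(f"cluster channels not in topography: {missing}")
    cols = [index[c] for c in cluster_channels]
    return np.asarray(topo, float)[:, cols].mean(axis=1)
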