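"""Permutation and rank-based inference utilities.

Cluster-based permutation tests on time-frequency maps, per-location
permutation t-tests with Benjamini-Hochberg FDR correction, Wilcoxon
signed-rank post hoc contrasts with family-wise adjustment, rank-sum
tests with effect size, and Spearman correlation.  All permutation
procedures are deterministic given a seed and use the add-one p-value
estimator (1 + b) / (1 + m), which cannot return zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Cluster",
    "ClusterResult",
    "MapTestResult",
    "PosthocResult",
    "cluster_permutation_tfr",
    "permutation_ttest_maps",
    "posthoc_paired",
    "spearman",
    "wilcoxon_ranksum_effect",
]

# 4-connectivity in the (freq, time) lattice.
_STRUCTURE = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _paired_t(diffs: np.ndarray) -> np.ndarray:
    """One-sample t over axis 0 (subjects), elementwise elsewhere."""
    n = diffs.shape[0]
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def _independent_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t over axis 0."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1 / na + 1 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.where(denom == 0, 0.0, t)


@dataclass
class Cluster:
    mask: np.ndarray  # boolean over the (freq, time) grid
    mass: float  # sum of member t-values (signed)
    p: float  # permutation-corrected


@dataclass
class ClusterResult:
    t_map: np.ndarray
    clusters: list[Cluster]
    n_permutations: int
    cluster_alpha: float

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]


def _find_clusters(t_map: np.ndarray, t_crit: float) -> list[tuple[np.ndarray, float]]:
    """Signed supra-threshold 4-connected clusters and their masses."""
    out = []
    for sign in (+1, -1):
        mask = sign * t_map >= t_crit
        labels, n = ndimage.label(mask, structure=_STRUCTURE)
        for lab in range(1, n + 1):
            m = labels == lab
            out.append((m, float(t_map[m].sum())))
    return out


def _max_mass(t_map: np.ndarray, t_crit: float) -> float:
    best = 0.0
    for sign in (+1, -1):
        mask = sign * t_map >= t_crit
        labels, n = ndimage.label(mask, structure=_STRUCTURE)
        if n:
            sums = ndimage.sum_labels(t_map, labels, index=np.arange(1, n + 1))
            best = max(best, float(np.abs(sums).max()))
    return best


def cluster_permutation_tfr(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    paired: bool,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> ClusterResult:
    """Cluster-based permutation test between two sets of z-maps.

    Parameters
    ----------
    maps_a, maps_b : ndarray, shape (n_subjects, n_freqs, n_times)
        Per-subject maps.  Paired comparisons require equal sizes with
        matched subject order; the null is built from subject-level
        sign flips of the differences.  Independent comparisons shuffle
        group labels.
    cluster_alpha : float
        Two-sided elementwise p threshold forming clusters; converted
        to a t threshold from the appropriate t distribution.
    n_perm : int
        Number of random permutations (a warning is issued below 100).

    Returns
    -------
    ClusterResult with the observed t-map and each cluster's mass and
    permutation-corrected p (tail probability of the null maximum
    absolute cluster mass).
    """
    maps_a = np.asarray(maps_a, dtype=float)
    maps_b = np.asarray(maps_b, dtype=float)
    if maps_a.shape[1:] != maps_b.shape[1:]:
        raise ValueError("mismatched map grids")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; corrected p-values are coarse")
    rng = np.random.default_rng(seed)

    if paired:
        if maps_a.shape[0] != maps_b.shape[0]:
            raise ValueError("paired sets must have equal numbers of subjects")
        diffs = maps_a - maps_b
        n = diffs.shape[0]
        t_crit = float(sstats.t.ppf(1 - cluster_alpha / 2, n - 1))
        t_obs = _paired_t(diffs)
        null = np.empty(n_perm)
        flat = diffs.reshape(n, -1)
        sumsq = (flat**2).sum(axis=0)
        for p in range(n_perm):
            signs = rng.choice((-1.0, 1.0), size=n)
            mean = (signs @ flat) / n
            var = (sumsq - n * mean**2) / (n - 1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t_p = mean / np.sqrt(var / n)
            t_p = np.nan_to_num(t_p).reshape(t_obs.shape)
            null[p] = _max_mass(t_p, t_crit)
    else:
        na = maps_a.shape[0]
        pooled = np.concatenate([maps_a, maps_b], axis=0)
        dof = pooled.shape[0] - 2
        t_crit = float(sstats.t.ppf(1 - cluster_alpha / 2, dof))
        t_obs = _independent_t(maps_a, maps_b)
        null = np.empty(n_perm)
        for p in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            t_p = _independent_t(pooled[perm[:na]], pooled[perm[na:]])
            null[p] = _max_mass(t_p, t_crit)

    clusters = [
        Cluster(mask=m, mass=mass, p=(1 + int(np.sum(null >= abs(mass)))) / (n_perm + 1))
        for m, mass in _find_clusters(t_obs, t_crit)
    ]
    clusters.sort(key=lambda c: abs(c.mass), reverse=True)
    return ClusterResult(
        t_map=t_obs, clusters=clusters, n_permutations=n_perm, cluster_alpha=cluster_alpha
    )


@dataclass
class MapTestResult:
    t: np.ndarray
    p: np.ndarray  # per-location permutation p
    q: np.ndarray  # Benjamini-Hochberg adjusted
    mask: np.ndarray  # q < alpha
    alpha: float


def permutation_ttest_maps(
    values_a: np.ndarray,
    values_b: np.ndarray,
    paired: bool,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> MapTestResult:
    """Per-location permutation t-tests with FDR correction.

    ``values_a`` / ``values_b`` have shape (n_subjects, n_locations);
    the same permutations are applied to every location and per-location
    p-values come from each location's own permutation null of |t|.
    """
    a = np.atleast_2d(np.asarray(values_a, dtype=float))
    b = np.atleast_2d(np.asarray(values_b, dtype=float))
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("mismatched location grids")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values are coarse")
    rng = np.random.default_rng(seed)

    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired sets must have equal numbers of subjects")
        d = a - b
        n = d.shape[0]
        t_obs = _paired_t(d)
        sumsq = (d**2).sum(axis=0)
        signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
        mean = signs @ d / n
        var = (sumsq[None, :] - n * mean**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = mean / np.sqrt(var / n)
        t_null = np.nan_to_num(t_null)
    else:
        na = a.shape[0]
        pooled = np.concatenate([a, b], axis=0)
        t_obs = _independent_t(a, b)
        t_null = np.empty((n_perm, a.shape[1]))
        for p in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            t_null[p] = _independent_t(pooled[perm[:na]], pooled[perm[na:]])

    exceed = (np.abs(t_null) >= np.abs(t_obs)[None, :]).sum(axis=0)
    p_vals = (1 + exceed) / (n_perm + 1)
    _, q_vals, _, _ = multipletests(p_vals, method="fdr_bh")
    return MapTestResult(t=t_obs, p=p_vals, q=q_vals, mask=q_vals < alpha, alpha=alpha)


@dataclass
class PosthocResult:
    pairs: list[tuple[str, str]]
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    method: str
    small_sample: bool = False


def posthoc_paired(
    values: dict[str, np.ndarray],
    pairs: list[tuple[str, str]],
    method: str = "holm",
) -> PosthocResult:
    """Wilcoxon signed-rank contrasts between condition pairs, adjusted
    across the tested family.

    ``values`` maps condition name to a per-subject vector (matched
    order across conditions).  Identical paired samples give p = 1.
    Fewer than 5 informative pairs triggers the exact-test region flag.
    """
    p_raw = []
    small = False
    for c1, c2 in pairs:
        x, y = np.asarray(values[c1], float), np.asarray(values[c2], float)
        if x.shape != y.shape:
            raise ValueError(f"conditions {c1!r}/{c2!r} have mismatched lengths")
        nonzero = int(np.sum(x != y))
        if nonzero < 5:
            small = True
        if nonzero == 0:
            p_raw.append(1.0)
            continue
        res = sstats.wilcoxon(x, y, zero_method="wilcox", method="auto")
        p_raw.append(float(res.pvalue))
    p_raw = np.array(p_raw)
    _, p_adj, _, _ = multipletests(p_raw, method=method)
    return PosthocResult(
        pairs=list(pairs), p_raw=p_raw, p_adjusted=np.minimum(p_adj, 1.0),
        method=method, small_sample=small,
    )


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties; p from the t
    approximation.  Raises on constant input, where rho is undefined."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho is undefined for a constant vector")
    res = sstats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def wilcoxon_ranksum_effect(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum test with the effect size r = |Z| / sqrt(N).

    Uses the tie-corrected normal approximation for Z; N is the total
    sample size.  Returns (p, r)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sstats.rankdata(combined)
    r1 = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    # Tie correction to the rank-sum variance.
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 1.0, 0.0
    z = (r1 - mu) / np.sqrt(var)
    p = 2 * sstats.norm.sf(abs(z))
    r = abs(z) / np.sqrt(n)
    return float(p), float(r)
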