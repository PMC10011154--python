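"""Cluster-based permutation test for paired ERD/ERS condition contrasts.

The test controls the family-wise error of the bin-wise paired t-map over
the channel x frequency x time grid:

1.  average each participant's trial maps per condition;
2.  compute the paired t statistic per bin;
3.  keep bins beyond the 2.5th / 97.5th t-distribution quantiles;
4.  group kept bins into maximal connected clusters (neighboring channels,
    consecutive frequency bins, consecutive time bins — no diagonals),
    positive and negative excursions separately;
5.  score each cluster by the sum of its t values (cluster mass);
6.  build the null by repeatedly sign-flipping each participant's
    difference map (within-participant condition exchange) and recording
    the maximum absolute cluster mass;
7.  a cluster's p-value is the fraction of the null at or above its
    absolute mass, with the (1 + exceedances) / (1 + n_perm) estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from .erds import ERDSMap
from .montage import Montage, DEFAULT_MONTAGE


@dataclass(frozen=True)
class ClusterConfig:
    n_permutations: int = 5000
    seed: int = 0
    alpha_threshold: float = 0.05  # two-sided bin-selection quantile
    alpha: float = 0.05            # cluster-level significance
    exhaustive: bool = False       # enumerate all sign patterns instead


@dataclass
class Cluster:
    bins: np.ndarray   # (k, 3) array of (channel, frequency, time) indices
    mass: float
    sign: int
    p_value: float | None = None

    @property
    def size(self) -> int:
        return len(self.bins)


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_distribution: np.ndarray
    n_permutations: int
    seed: int | None
    t_map: np.ndarray
    df: int
    alpha: float

    @property
    def significant(self) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value is not None
                and c.p_value < self.alpha]


def channel_adjacency(montage: Montage = DEFAULT_MONTAGE,
                      scale: float = 1.3) -> np.ndarray:
    """Boolean channel neighbor matrix from head-plane distances."""
    return montage.neighbor_matrix(scale)


def paired_t_map(diffs: np.ndarray) -> np.ndarray:
    """Bin-wise one-sample t over participant difference maps.

    ``diffs`` is (n_participants, ...).  Bins with zero variance across
    participants get t = 0 (they carry no paired evidence).
    """
    n = diffs.shape[0]
    if n < 2:
        raise ValueError("need at least two participants")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def _grid_edges(mask: np.ndarray, chan_adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edge list (flat indices) between True bins adjacent in one dimension."""
    n_ch, n_f, n_t = mask.shape
    flat = np.arange(mask.size).reshape(mask.shape)
    rows, cols = [], []

    def add(a_idx, b_idx, pair_mask):
        rows.append(a_idx[pair_mask])
        cols.append(b_idx[pair_mask])

    if n_t > 1:
        add(flat[:, :, :-1], flat[:, :, 1:], mask[:, :, :-1] & mask[:, :, 1:])
    if n_f > 1:
        add(flat[:, :-1, :], flat[:, 1:, :], mask[:, :-1, :] & mask[:, 1:, :])
    a_ch, b_ch = np.where(np.triu(chan_adj, 1))
    for a, b in zip(a_ch, b_ch):
        add(flat[a], flat[b], mask[a] & mask[b])
    if rows:
        return np.concatenate([r.ravel() for r in rows]), np.concatenate(
            [c.ravel() for c in cols]
        )
    return np.empty(0, int), np.empty(0, int)


def _connected_clusters(mask: np.ndarray, chan_adj: np.ndarray) -> list[np.ndarray]:
    """Maximal connected components of True bins; each as (k, 3) indices."""
    node_flat = np.flatnonzero(mask)
    if node_flat.size == 0:
        return []
    compact = -np.ones(mask.size, int)
    compact[node_flat] = np.arange(node_flat.size)
    r, c = _grid_edges(mask, chan_adj)
    graph = sparse.coo_matrix(
        (np.ones(r.size), (compact[r], compact[c])),
        shape=(node_flat.size, node_flat.size),
    )
    n_comp, labels = connected_components(graph, directed=False)
    coords = np.column_stack(np.unravel_index(node_flat, mask.shape))
    return [coords[labels == k] for k in range(n_comp)]


def threshold_clusters(
    t_map: np.ndarray,
    df: int,
    chan_adj: np.ndarray,
    alpha_threshold: float = 0.05,
) -> list[Cluster]:
    """Signed supra-threshold clusters of a t-map.

    Bins above the (1 - alpha/2) quantile or below the alpha/2 quantile of
    the t distribution with ``df`` degrees of freedom are clustered,
    positive and negative excursions separately.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    t_crit = float(stats.t.ppf(1.0 - alpha_threshold / 2.0, df))
    clusters: list[Cluster] = []
    for sign, mask in ((1, t_map > t_crit), (-1, t_map < -t_crit)):
        for bins in _connected_clusters(mask, chan_adj):
            mass = float(t_map[tuple(bins.T)].sum())
            clusters.append(Cluster(bins=bins, mass=mass, sign=sign))
    clusters.sort(key=lambda c: -abs(c.mass))
    return clusters


def _max_cluster_mass(t_map: np.ndarray, t_crit: float,
                      chan_adj: np.ndarray) -> float:
    best = 0.0
    for mask in (t_map > t_crit, t_map < -t_crit):
        for bins in _connected_clusters(mask, chan_adj):
            best = max(best, abs(float(t_map[tuple(bins.T)].sum())))
    return best


def _t_from_signs(diffs2d: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t-maps for many sign patterns at once.

    ``diffs2d`` is (n, bins); ``signs`` is (n_perm, n) of +-1.  Uses the
    invariance of sum(d^2) under sign flips to avoid recomputing variances
    from scratch.
    """
    n = diffs2d.shape[0]
    mean = signs @ diffs2d / n
    sumsq = (diffs2d**2).sum(axis=0)
    var = np.maximum(sumsq / n - mean**2, 0.0) * (n / (n - 1))
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
    return t


def permutation_null(
    diffs: np.ndarray,
    chan_adj: np.ndarray,
    config: ClusterConfig = ClusterConfig(),
) -> np.ndarray:
    """Null distribution of the maximum absolute cluster mass.

    Each permutation flips the sign of each participant's difference map
    independently (within-participant condition exchange).  With
    ``config.exhaustive`` all 2^n patterns are enumerated instead of
    Monte-Carlo sampling.
    """
    n = diffs.shape[0]
    shape = diffs.shape[1:]
    diffs2d = diffs.reshape(n, -1)
    df = n - 1
    t_crit = float(stats.t.ppf(1.0 - config.alpha_threshold / 2.0, df))

    if config.exhaustive:
        signs = np.array(list(product((-1.0, 1.0), repeat=n)))
    else:
        if config.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        rng = np.random.default_rng(config.seed)
        signs = rng.choice([-1.0, 1.0], size=(config.n_permutations, n))
    t_all = _t_from_signs(diffs2d, signs)
    return np.array(
        [_max_cluster_mass(t.reshape(shape), t_crit, chan_adj) for t in t_all]
    )


def cluster_pvalues(clusters: list[Cluster], null: np.ndarray) -> list[Cluster]:
    """Attach permutation p-values: p = (1 + #{null >= |mass|}) / (1 + N)."""
    if null.size == 0:
        raise ValueError("empty null distribution")
    for c in clusters:
        exceed = int(np.sum(null >= abs(c.mass) - 1e-12))
        c.p_value = (1 + exceed) / (1 + null.size)
    return clusters


def _as_stack(maps: list[ERDSMap] | np.ndarray) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        return maps
    first = maps[0]
    for m in maps[1:]:
        if not first.same_grid(m):
            raise ValueError("participant maps must share one grid")
    return np.stack([m.values for m in maps])


def run_cluster_test(
    maps_a: list[ERDSMap] | np.ndarray,
    maps_b: list[ERDSMap] | np.ndarray,
    chan_adj: np.ndarray | None = None,
    config: ClusterConfig = ClusterConfig(),
) -> ClusterResult:
    """Full paired cluster permutation test on per-participant maps.

    ``maps_a`` / ``maps_b`` hold one trial-averaged map per participant
    (same participants, same order).  Arrays may be (n, channels, freqs,
    times); a channel-only topographic test is the special case of
    singleton frequency/time axes.
    """
    a = _as_stack(maps_a)
    b = _as_stack(maps_b)
    if a.shape != b.shape:
        raise ValueError("conditions must have identical map stacks")
    while a.ndim < 4:  # allow (n, ch) or (n, ch, t) inputs
        a = a[..., None]
        b = b[..., None]
    diffs = a - b
    n = diffs.shape[0]
    if chan_adj is None:
        chan_adj = channel_adjacency()
    if chan_adj.shape[0] != diffs.shape[1]:
        raise ValueError("adjacency size does not match channel count")

    t_map = paired_t_map(diffs)
    clusters = threshold_clusters(t_map, n - 1, chan_adj, config.alpha_threshold)
    null = permutation_null(diffs, chan_adj, config)
    clusters = cluster_pvalues(clusters, null)
    return ClusterResult(
        clusters=clusters, null_distribution=null,
        n_permutations=len(null), seed=None if config.exhaustive else config.seed,
        t_map=t_map, df=n - 1, alpha=config.alpha,
    )


def band_topography_test(
    maps_a: list[ERDSMap],
    maps_b: list[ERDSMap],
    band: str,
    interval: tuple[float, float],
    chan_adj: np.ndarray | None = None,
    config: ClusterConfig = ClusterConfig(),
) -> ClusterResult:
    """Per-band topographic variant: cluster over channels only, after
    averaging each participant's map over the band and MI interval."""
    from .erds import band_summary

    a = np.stack([band_summary(m, band, interval) for m in maps_a])
    b = np.stack([band_summary(m, band, interval) for m in maps_b])
    return run_cluster_test(a, b, chan_adj, config)
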