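"""Cluster-based permutation testing for channel × time(–frequency) data.

Nonparametric family-wise error control in the Maris–Oostenveld style:
bin-wise two-sample t statistics are thresholded at a cluster-forming level,
suprathreshold bins are grouped into connected clusters (grid adjacency
along time/frequency plus a channel-neighborhood graph), each cluster is
scored by its mass (sum of t values), and the observed masses are compared
with the distribution of the maximum cluster mass under random relabelings
of the condition labels.

Bins live on a (n_channels, *grid_shape) lattice; the implementation is
shared by the ERP (channels × time) and ERSP (channels × frequency × time)
analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse, stats as sstats
from scipy.sparse.csgraph import connected_components


@dataclass
class Cluster:
    bins: np.ndarray     # flat indices into the (n_ch, *grid) lattice
    mass: float          # sum of t values over member bins
    p_value: float
    sign: int            # +1 / −1


@dataclass
class ClusterResult:
    clusters: list
    alpha: float
    n_permutations: int
    t_threshold: float
    shape: tuple                      # (n_channels, *grid_shape)
    t_map: np.ndarray = field(repr=False, default=None)
    null_max: np.ndarray = field(repr=False, default=None)

    @property
    def significant(self) -> list:
        return [c for c in self.clusters if c.p_value < self.alpha]

    def significant_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, bool).ravel()
        for c in self.significant:
            mask[c.bins] = True
        return mask.reshape(self.shape)


def _pooled_t(sum_a, sumsq_a, sum_b, sumsq_b, na, nb):
    """Pooled-variance two-sample t from per-group sums; degenerate-variance
    bins get t = 0 so they never enter cluster formation."""
    ma = sum_a / na
    mb = sum_b / nb
    va = (sumsq_a - na * ma**2) / (na - 1)
    vb = (sumsq_b - nb * mb**2) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / denom
    t[~np.isfinite(t)] = 0.0
    return t


def _grid_components(members: np.ndarray, shape: tuple, chan_pairs):
    """Connected components among ``members`` (sorted flat indices) under
    orthogonal grid adjacency within a channel plus channel-graph adjacency
    at the same grid point. Returns a component label per member."""
    n_m = len(members)
    if n_m <= 1:
        return np.zeros(n_m, int)
    grid_shape = shape[1:]
    g = int(np.prod(grid_shape))
    multi = np.unravel_index(members, shape)

    rows, cols = [], []

    def add_edges(cand_flat, valid):
        src = np.flatnonzero(valid)
        if not len(src):
            return
        pos = np.searchsorted(members, cand_flat[src])
        ok = (pos < n_m) & (members[np.minimum(pos, n_m - 1)] == cand_flat[src])
        rows.extend(src[ok])
        cols.extend(pos[ok])

    # neighbors along each grid axis (same channel)
    strides = []
    s = 1
    for size in reversed(grid_shape):
        strides.append(s)
        s *= size
    strides = strides[::-1]
    for axis, size in enumerate(grid_shape):
        coord = multi[axis + 1]
        add_edges(members + strides[axis], coord + 1 < size)

    # channel neighbors at the same grid point
    ch = multi[0]
    for c1, c2 in chan_pairs:
        sel = ch == c1
        add_edges(members + (c2 - c1) * g, sel)

    graph = sparse.coo_matrix(
        (np.ones(len(rows), bool), (rows, cols)), shape=(n_m, n_m))
    _, labels = connected_components(graph, directed=False)
    return labels


def _max_cluster_mass(t_flat, thresh, shape, chan_pairs):
    out = 0.0
    for sign in (1, -1):
        members = np.flatnonzero(sign * t_flat > thresh)
        if not len(members):
            continue
        labels = _grid_components(members, shape, chan_pairs)
        masses = np.bincount(labels, weights=np.abs(t_flat[members]))
        out = max(out, float(masses.max()))
    return out


def _clusters_of(t_flat, thresh, shape, chan_pairs):
    clusters = []
    for sign in (1, -1):
        members = np.flatnonzero(sign * t_flat > thresh)
        if not len(members):
            continue
        labels = _grid_components(members, shape, chan_pairs)
        for lab in range(labels.max() + 1):
            bins = members[labels == lab]
            clusters.append(Cluster(bins=bins,
                                    mass=float(t_flat[bins].sum()),
                                    p_value=1.0, sign=sign))
    return clusters


def _adjacency_pairs(channel_adjacency, n_ch):
    if channel_adjacency is None:
        return []
    adj = np.asarray(channel_adjacency, bool)
    if adj.shape != (n_ch, n_ch):
        raise ValueError("channel adjacency must be (n_channels, n_channels)")
    i, j = np.nonzero(np.triu(adj, 1))
    # undirected: register both directions so edge lookup sees every pair
    return list(zip(i, j)) + list(zip(j, i))


def cluster_permutation(a, b, *, channel_adjacency=None, alpha: float = 0.05,
                        cluster_alpha: float = 0.05, n_perm: int = 1000,
                        seed=None, chunk: int = 64) -> ClusterResult:
    """Two-sample cluster permutation test.

    Parameters
    ----------
    a, b
        Observation arrays shaped (n_obs, n_channels, *grid_shape); trials
    	or participants are the unit of exchange.
    channel_adjacency
        Boolean channel-neighborhood matrix, or None for no cross-channel
        clustering (each channel its own strip).
    alpha
        Cluster significance level (reported, and used by
        ``ClusterResult.significant``).
    cluster_alpha
        Point-wise two-tailed level defining the cluster-forming t threshold.
    n_perm
        Number of random relabelings; the achievable p floor is
        1/(n_perm + 1).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.ndim < 3 or b.ndim < 3 or a.shape[1:] != b.shape[1:]:
        raise ValueError("a and b must be (n_obs, n_channels, *grid) with "
                         "matching bin shapes")
    na, nb = a.shape[0], b.shape[0]
    if na < 2 or nb < 2:
        raise ValueError("need at least 2 observations per condition")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} gives a coarse p-value resolution",
                      stacklevel=2)

    shape = a.shape[1:]
    chan_pairs = _adjacency_pairs(channel_adjacency, shape[0])
    X = np.concatenate([a.reshape(na, -1), b.reshape(nb, -1)], axis=0)
    Xsq = X**2
    n = na + nb
    tot = X.sum(axis=0)
    tot_sq = Xsq.sum(axis=0)
    df = n - 2
    thresh = sstats.t.ppf(1.0 - cluster_alpha / 2.0, df)

    t_obs = _pooled_t(X[:na].sum(axis=0), Xsq[:na].sum(axis=0),
                      tot - X[:na].sum(axis=0), tot_sq - Xsq[:na].sum(axis=0),
                      na, nb)
    clusters = _clusters_of(t_obs, thresh, shape, chan_pairs)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    done = 0
    while done < n_perm:
        k = min(chunk, n_perm - done)
        sel = np.zeros((k, n), bool)
        for r in range(k):
            sel[r, rng.permutation(n)[:na]] = True
        sum_a = sel @ X
        sumsq_a = sel @ Xsq
        t_perm = _pooled_t(sum_a, sumsq_a, tot - sum_a, tot_sq - sumsq_a, na, nb)
        for r in range(k):
            null_max[done + r] = _max_cluster_mass(t_perm[r], thresh, shape,
                                                   chan_pairs)
        done += k

    for c in clusters:
        c.p_value = float((1 + np.sum(null_max >= abs(c.mass))) / (n_perm + 1))
    clusters.sort(key=lambda c: c.p_value)
    return ClusterResult(clusters=clusters, alpha=alpha, n_permutations=n_perm,
                         t_threshold=float(thresh), shape=shape, t_map=t_obs,
                         null_max=null_max)
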