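"""Comparative analysis of repertoires via Jensen-Shannon distance.

For two fitted clone size laws P and Q the Jensen-Shannon divergence

    JSD(P, Q) = 1/2 [ sum_i P_i ln(P_i/M_i) + sum_i Q_i ln(Q_i/M_i) ],
    M = (P + Q)/2,

is symmetric, bounded by ln 2, and defined even when the supports differ.
Pairwise JSD matrices feed Ward hierarchical clustering and non-metric MDS
for cohort-level visualization.  Spliced fits are compared with the
discrete sum, Pareto comparator fits with the continuous (integral)
generalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .desponds import DespondsResults
from .distributions import SplicedDistribution

__all__ = [
    "jsd_discrete",
    "jsd_continuous",
    "DistanceMatrix",
    "pairwise_distances",
    "cluster_samples",
    "cut_clusters",
    "embed_mds",
    "linkage_to_newick",
]

LN2 = math.log(2.0)


def _as_distribution(obj) -> SplicedDistribution:
    if isinstance(obj, SplicedDistribution):
        return obj
    dist = getattr(obj, "distribution", None)
    if isinstance(dist, SplicedDistribution):
        return dist
    raise TypeError("expected a SplicedDistribution or a spliced fit result")


def _js_terms(p, q):
    m = 0.5 * (p + q)
    out = 0.0
    for a in (p, q):
        pos = a > 0.0
        out += float(a[pos] @ np.log(a[pos] / m[pos]))
    return 0.5 * out


def _support_grid(x_lo, x_hi, head_cap, blocks_per_octave):
    """Integer head [x_lo, head_end] plus geometric block edges out to x_hi."""
    head_end = min(x_hi, head_cap)
    head = np.arange(x_lo, head_end + 1, dtype=np.int64)
    if head_end >= x_hi:
        return head, None
    n_oct = math.log2(x_hi / head_end)
    k = max(1, math.ceil(n_oct * blocks_per_octave))
    edges = np.unique(np.ceil(
        head_end * 2.0 ** (np.arange(1, k + 1) / blocks_per_octave)
    ).astype(np.int64))
    edges = edges[edges > head_end]
    if edges.size == 0 or edges[-1] < x_hi:
        edges = np.append(edges, x_hi)
    return head, edges


def jsd_discrete(P, Q, sqrt=False, tail_tol=1e-10, blocks_per_octave=16,
                 head_cap=1 << 21):
    """Jensen-Shannon divergence between two spliced (or discrete) models.

    Both pmfs are evaluated on the integer support from 1 out to the point
    where each model's remaining tail mass drops below ``tail_tol`` and
    renormalized there.  For very heavy tails the far tail (beyond
    ``head_cap``) is aggregated into fine geometric blocks (CDF-difference
    masses, ``blocks_per_octave`` per doubling); the divergence between the
    block-aggregated laws differs from the dense sum only by the within-block
    variation of the log-ratio, which is negligible at this resolution.

    Set ``sqrt=True`` for the square root (the true metric).
    """
    P, Q = _as_distribution(P), _as_distribution(Q)
    x_hi = max(P.support_upper(tail_tol), Q.support_upper(tail_tol))
    x_hi = max(x_hi, P.u, Q.u)
    head, edges = _support_grid(1, int(x_hi), head_cap, blocks_per_octave)

    p = P.pmf(head)
    q = Q.pmf(head)
    if edges is not None:
        lo = np.concatenate(([head[-1]], edges[:-1])).astype(float)
        hi = edges.astype(float)
        p = np.concatenate([p, np.maximum(P.cdf(hi) - P.cdf(lo), 0.0)])
        q = np.concatenate([q, np.maximum(Q.cdf(hi) - Q.cdf(lo), 0.0)])
    p = p / p.sum()
    q = q / q.sum()
    val = min(max(_js_terms(p, q), 0.0), LN2)
    return math.sqrt(val) if sqrt else val


def _as_pareto(obj):
    if isinstance(obj, DespondsResults):
        return float(obj.u), float(obj.alpha_d)
    u, a = obj
    return float(u), float(a)


def jsd_continuous(P, Q, sqrt=False, epsrel=1e-8):
    """Continuous-law Jensen-Shannon divergence between two Pareto tail fits.

    The Eq-for-discrete sum is traded for an integral over the union support
    [min(u_P, u_Q), inf); each density is 0 below its own threshold.  Between
    the two thresholds only one density is positive, so that piece is the
    closed form (ln 2)/2 * mass; the remainder uses adaptive quadrature.
    """
    (u1, a1), (u2, a2) = _as_pareto(P), _as_pareto(Q)

    def pdf(x, u, a):
        return a * u ** a / x ** (a + 1.0) if x >= u else 0.0

    lo, hi = min(u1, u2), max(u1, u2)
    val = 0.0
    if hi > lo:
        # only the lower-threshold density is positive on [lo, hi)
        ul, al = (u1, a1) if u1 < u2 else (u2, a2)
        val += 0.5 * LN2 * (-np.expm1(al * math.log(ul / hi)))

    def integrand(x):
        f = pdf(x, u1, a1)
        g = pdf(x, u2, a2)
        m = 0.5 * (f + g)
        out = 0.0
        if f > 0:
            out += f * math.log(f / m)
        if g > 0:
            out += g * math.log(g / m)
        return 0.5 * out

    tail, _ = integrate.quad(integrand, hi, np.inf, epsrel=epsrel, limit=200)
    val += tail
    val = min(max(val, 0.0), LN2)
    return math.sqrt(val) if sqrt else val


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric pairwise distance matrix with zero diagonal."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        labels = tuple(self.labels)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(labels):
            raise ValueError("values must be square and match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValueError("diagonal must be exactly 0")
        if np.any(v < 0.0):
            raise ValueError("distances must be nonnegative")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self):
        return len(self.labels)

    def condensed(self):
        return squareform(self.values, checks=False)

    def to_dataframe(self):
        return pd.DataFrame(self.values, index=list(self.labels),
                            columns=list(self.labels))


def pairwise_distances(fits, method="spliced", sqrt=False, **jsd_kwargs):
    """Pairwise distance matrix over a labeled cohort of fits.

    method:
      - ``spliced``: discrete JSD between spliced model fits
      - ``desponds``: continuous JSD between Pareto comparator fits
      - ``estimator-euclidean``: Euclidean distance between per-sample
        statistic vectors (``fits`` is then a mapping label -> vector or a
        DataFrame with one row per sample)
    """
    if method == "estimator-euclidean":
        if isinstance(fits, pd.DataFrame):
            labels = [str(i) for i in fits.index]
            mat = fits.to_numpy(dtype=float)
        else:
            labels = list(fits.keys())
            mat = np.asarray([np.asarray(fits[k], dtype=float) for k in labels])
        diff = mat[:, None, :] - mat[None, :, :]
        vals = np.sqrt((diff ** 2).sum(axis=-1))
        np.fill_diagonal(vals, 0.0)
        return DistanceMatrix(tuple(labels), vals)

    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least 2 fits")
    if method == "spliced":
        objs = [_as_distribution(f) for f in fits]
        dist_fn = lambda a, b: jsd_discrete(a, b, sqrt=sqrt, **jsd_kwargs)
    elif method == "desponds":
        objs = [_as_pareto(f) for f in fits]
        dist_fn = lambda a, b: jsd_continuous(a, b, sqrt=sqrt)
    else:
        raise ValueError("unknown method %r" % method)

    labels = []
    for f in fits:
        lab = getattr(getattr(getattr(f, "model", None), "sample", None), "label", None)
        labels.append(lab if lab else "sample%d" % len(labels))
    n = len(objs)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = dist_fn(objs[i], objs[j])
    return DistanceMatrix(tuple(labels), vals)


def cluster_samples(dm: DistanceMatrix, method="ward"):
    """Agglomerative clustering (Ward linkage on the given dissimilarities).

    Returns a scipy linkage matrix; pair with ``dm.labels`` for dendrograms
    and ``linkage_to_newick`` for export.
    """
    return hierarchy.linkage(dm.condensed(), method=method)


def cut_clusters(linkage, k):
    """Flat cluster labels (1..k) from a linkage matrix."""
    return hierarchy.fcluster(linkage, t=k, criterion="maxclust")


def embed_mds(dm: DistanceMatrix, dims=2, seed=0, n_init=4, max_iter=300):
    """Non-metric MDS embedding of a distance matrix.

    Returns ``(coords, stress)`` where coords is an (n, dims) array in the
    order of ``dm.labels`` and stress is the normalized stress-1.
    """
    if dm.n < 3:
        raise ValueError("MDS needs at least 3 samples")
    from sklearn.manifold import MDS

    kwargs = dict(
        n_components=dims,
        random_state=seed,
        n_init=n_init,
        max_iter=max_iter,
        normalized_stress="auto",
    )
    try:
        mds = MDS(metric="precomputed", metric_mds=False, init="random", **kwargs)
    except TypeError:  # older scikit-learn spelling
        mds = MDS(dissimilarity="precomputed", metric=False, **kwargs)
    coords = mds.fit_transform(dm.values)
    return coords, float(mds.stress_)


def linkage_to_newick(linkage, labels: Sequence[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick tree with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return "%s:%g" % (labels[node.id], length)
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return "(%s,%s):%g" % (left, right, length)

    return "(%s,%s);" % (rec(tree.left, tree.dist), rec(tree.right, tree.dist))
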