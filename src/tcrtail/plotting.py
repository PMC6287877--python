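"""Plotting hooks: per-sample fit diagnostics and cohort views.

Matplotlib is imported lazily so the core package works without a display
stack; pass an existing Axes to compose figures.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_fit", "plot_profile", "plot_dendrogram", "plot_mds"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_fit(result, ax=None, n_points=200):
    """Rank-frequency (log-log) view of the data with the fitted survival curve.

    The cross marks the fitted threshold; the curve is the model's P(X >= x)
    scaled to the number of clonotypes.
    """
    ax = _ax(ax)
    s = result.model.sample
    counts = np.sort(s.counts)[::-1]
    ranks = np.arange(1, counts.size + 1)
    ax.loglog(counts, ranks, ".", color="0.6", ms=3, label="data")
    dist = result.distribution
    xs = np.unique(np.geomspace(1, counts.max(), n_points).astype(int))
    surv = 1.0 - dist.cdf(xs - 1)
    ax.loglog(xs, np.maximum(surv * s.n, 0.5), "-", color="C0", label="fit")
    u = result.u
    ax.plot([u], [max((s.counts >= u).sum(), 0.5)], "x", color="C3", ms=10,
            label="threshold")
    ax.set_xlabel("clone size (reads)")
    ax.set_ylabel("number of clones at or above size")
    ax.legend(frameon=False)
    ax.set_title(s.label or "clone size distribution")
    return ax


def plot_profile(result, ax=None):
    """Profile log-likelihood over the candidate thresholds."""
    ax = _ax(ax)
    prof = result.profile[result.profile["converged"]]
    ax.plot(prof["u"], prof["loglik"], ".-", color="C0")
    ax.axvline(result.u, color="C3", ls="--", label="selected u")
    ax.set_xlabel("candidate threshold u")
    ax.set_ylabel("profile log-likelihood")
    ax.legend(frameon=False)
    return ax


def plot_dendrogram(linkage, labels, ax=None):
    """Ward dendrogram of a cohort distance matrix."""
    from scipy.cluster import hierarchy

    ax = _ax(ax)
    hierarchy.dendrogram(linkage, labels=list(labels), ax=ax)
    ax.set_ylabel("Jensen-Shannon distance")
    return ax


def plot_mds(coords, labels, ax=None):
    """Scatter of the first two MDS coordinates with sample labels."""
    ax = _ax(ax)
    coords = np.asarray(coords)
    ax.scatter(coords[:, 0], coords[:, 1], s=25)
    for (x, y), lab in zip(coords, labels):
        ax.annotate(str(lab), (x, y), fontsize=8,
                    textcoords="offset points", xytext=(4, 2))
    ax.set_xlabel("MDS 1")
    ax.set_ylabel("MDS 2")
    return ax
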