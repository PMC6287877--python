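"""Maximum-likelihood fitting of the spliced bulk-tail model.

The threshold ``u`` is chosen by profile likelihood: for each candidate
threshold (every unique observed clone size at or above an upper sample
quantile, 0.75 by default), the tail fraction is the plug-in
``phi = n_u / n``, the bulk (truncated discrete Gamma) and tail (discrete
GPD) parameters are maximized independently — the likelihood factorizes
across the two components given ``u`` — and the candidate maximizing the
full profile likelihood L_p(u) wins.  Ties go to the smallest threshold
(the larger tail).

Usage follows the Model -> fit() -> Results convention::

    model = SplicedThresholdModel(sample)
    res = model.fit()
    res.summary()
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

from .distributions import (
    XI_EXPONENTIAL_CUTOFF,
    DiscreteGamma,
    DiscreteGPD,
    SplicedDistribution,
)
from .sample import CloneSizeSample

__all__ = [
    "SplicedThresholdModel",
    "SplicedThresholdResults",
    "fit_spliced",
    "candidate_thresholds",
    "fit_given_threshold",
]

_BIG = 1e12


def candidate_thresholds(sample, quantile=0.75, min_tail=10, min_bulk=10):
    """Candidate thresholds: unique observed sizes at or above the sample quantile.

    Candidates must leave at least ``min_tail`` clones at/above and
    ``min_bulk`` clones below, and be >= 2 (a non-empty bulk).
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    counts = sample.counts
    values, mult = sample.unique_counts()
    if values.size == 1:
        raise ValueError(
            "all clone sizes are identical (size %d): no spliced bulk/tail "
            "structure to fit" % values[0]
        )
    q = np.quantile(counts, quantile)
    n = counts.size
    # clones at/above each unique value (values sorted ascending)
    tail_sizes = n - np.concatenate(([0], np.cumsum(mult)[:-1]))
    bulk_sizes = n - tail_sizes
    ok = (values >= max(q, 2)) & (tail_sizes >= min_tail) & (bulk_sizes >= min_bulk)
    cands = values[ok]
    if cands.size == 0:
        raise ValueError(
            "no admissible threshold candidates (sample too small or too "
            "concentrated around a single size)"
        )
    return cands


def _bulk_terms(a, b, ivals, u, include_zero):
    """(Z_bulk, pmf at ivals) for the truncated discrete Gamma.

    Uses a dense regularized-incomplete-gamma grid on 0..u when the bulk
    values are dense in {1..u-1}, point evaluations otherwise.
    """
    if u + 1 <= 2 * ivals.size + 16:
        ginc = special.gammainc(a, b * np.arange(0.0, u + 1.0))
        g_lo, g_hi, g_u, g_1 = ginc[ivals], ginc[ivals + 1], ginc[u], ginc[1]
    else:
        g_lo = special.gammainc(a, b * ivals)
        g_hi = special.gammainc(a, b * (ivals + 1.0))
        g_u = float(special.gammainc(a, b * u))
        g_1 = float(special.gammainc(a, b))
    z = g_u - (0.0 if include_zero else g_1)
    pm = g_hi - g_lo
    # far in the Gamma upper tail the lower-incomplete difference cancels;
    # recompute those entries from the complement
    tiny = pm < 1e-10
    if np.any(tiny):
        xv = ivals[tiny].astype(float)
        pm = pm.copy()
        pm[tiny] = special.gammaincc(a, b * xv) - special.gammaincc(a, b * (xv + 1.0))
    return z, pm


def _bulk_nll_value(a, b, ivals, wts, u, include_zero, wsum):
    z, pm = _bulk_terms(a, b, ivals, u, include_zero)
    if not z > 0 or np.any(pm <= 0.0) or not np.all(np.isfinite(pm)):
        return _BIG, None
    return float(wsum * math.log(z) - wts @ np.log(pm)), (z, pm)


def _gamma_cdf_dlogb(xs, a, b):
    """d gammainc(a, b x) / d log b = b x (b x)^(a-1) e^(-b x) / Gamma(a)."""
    xs = np.asarray(xs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = np.exp(a * np.log(np.maximum(b * xs, 1e-300)) - b * xs
                     - special.gammaln(a))
    return np.where(xs > 0, out, 0.0)


def _bulk_nll(params, ivals, wts, u, include_zero):
    """Objective with gradient: analytic in log beta, forward-diff in log alpha."""
    log_a, log_b = params
    if abs(log_a) > 30 or abs(log_b) > 30:
        return _BIG, np.zeros(2)
    a, b = math.exp(log_a), math.exp(log_b)
    wsum = wts.sum()
    f, aux = _bulk_nll_value(a, b, ivals, wts, u, include_zero, wsum)
    if aux is None:
        return _BIG, np.zeros(2)
    z, pm = aux
    dz = _gamma_cdf_dlogb(u, a, b) - (0.0 if include_zero
                                      else _gamma_cdf_dlogb(1.0, a, b))
    dpm = _gamma_cdf_dlogb(ivals + 1.0, a, b) - _gamma_cdf_dlogb(ivals, a, b)
    grad_b = float(wsum * dz / z - wts @ (dpm / pm))
    h = 1e-6
    f2, _ = _bulk_nll_value(a * math.exp(h), b, ivals, wts, u, include_zero, wsum)
    grad_a = (f2 - f) / h if f2 < _BIG else 0.0
    return f, np.array([grad_a, grad_b])


def _gpd_surv_and_grads(z, sigma, xi):
    """Survival t^(-1/xi) at z=(x-u)/sigma with d/dlog sigma and d/dxi."""
    if abs(xi) < XI_EXPONENTIAL_CUTOFF:
        s = np.exp(-z)
        return s, z * s, 0.5 * z * z * s
    t = 1.0 + xi * z
    ok = t > 0.0
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        logt = np.where(ok, np.log1p(xi * z), np.inf)
        s = np.where(ok, np.exp(-logt / xi), 0.0)
        ds_dlogsig = np.where(ok, z * np.exp(-(1.0 / xi + 1.0) * logt), 0.0)
        ds_dxi = np.where(ok, s * (logt / xi ** 2 - z / (xi * np.maximum(t, 1e-300))), 0.0)
    return s, ds_dlogsig, ds_dxi


def _tail_nll(params, vals, wts, u):
    """Discrete-GPD negative log-likelihood on counts >= u, with gradient."""
    log_s, xi = params
    if abs(log_s) > 30 or abs(xi) > 50:
        return _BIG, np.zeros(2)
    sigma = math.exp(log_s)
    z0 = (vals - u) / sigma
    z1 = (vals + 1 - u) / sigma
    s0, d0_sig, d0_xi = _gpd_surv_and_grads(z0, sigma, xi)
    if xi < 0 and np.any(s0 <= 0.0):
        return _BIG, np.zeros(2)  # upper bound below an observation
    s1, d1_sig, d1_xi = _gpd_surv_and_grads(z1, sigma, xi)
    g = s0 - s1
    if np.any(g <= 0.0) or not np.all(np.isfinite(g)):
        return _BIG, np.zeros(2)
    f = float(-(wts @ np.log(g)))
    grad_sig = float(-(wts @ ((d0_sig - d1_sig) / g)))
    grad_xi = float(-(wts @ ((d0_xi - d1_xi) / g)))
    return f, np.array([grad_sig, grad_xi])


def _minimize(fun, starts, args, warm_first=False):
    """Bounded quasi-Newton from deterministic starts; best finite result.

    With ``warm_first`` the first start (a warm start from the neighbouring
    threshold candidate) is trusted when it converges to a finite optimum;
    the remaining starts are fallbacks only.
    """
    best = None
    for i, x0 in enumerate(starts):
        res = optimize.minimize(fun, x0, args=args, method="L-BFGS-B", jac=True)
        if best is None or res.fun < best.fun:
            best = res
        if warm_first and i == 0 and res.success and res.fun < _BIG:
            break
    return best


def _moment_gamma_start(vals, wts):
    m = float((vals * wts).sum() / wts.sum())
    v = float((wts * (vals - m) ** 2).sum() / wts.sum())
    v = max(v, 0.25)
    a = max(m * m / v, 1e-3)
    b = max(m / v, 1e-6)
    return (math.log(a), math.log(b))


def _hill_start(vals, wts, u):
    logs = float(wts @ np.log(vals / u))
    if logs <= 0:
        return None
    alpha_d = float(wts.sum()) / logs
    sigma = max(u / alpha_d, 1e-6)
    return (math.log(sigma), 1.0 / alpha_d)


def fit_given_threshold(sample, u, bulk_includes_zero=False, warm=None):
    """Maximize the spliced likelihood with the threshold fixed at ``u``.

    Returns ``(SplicedDistribution, loglik, converged, warm_params)``.
    ``phi`` is the plug-in n_u/n; bulk and tail are optimized independently.
    ``warm`` may carry ``(bulk_params, tail_params)`` extra starting points.
    """
    values, mult = sample.unique_counts()
    return _fit_threshold_core(values, mult, sample.n, int(u),
                               bulk_includes_zero, warm)


def _fit_threshold_core(values, mult, n, u, bulk_includes_zero, warm):
    in_tail = values >= u
    bvals, bwts = values[~in_tail].astype(np.int64), mult[~in_tail].astype(float)
    tvals, twts = values[in_tail].astype(float), mult[in_tail].astype(float)
    n_u = int(twts.sum())
    n_b = n - n_u
    if n_u == 0 or n_b == 0:
        raise ValueError("threshold u=%d leaves an empty bulk or tail" % u)
    phi = n_u / n

    bulk_starts = [_moment_gamma_start(bvals, bwts), (0.0, math.log(0.5))]
    tail_starts = [(math.log(max(np.mean(tvals) - u, 1.0)), 0.5)]
    hill = _hill_start(tvals, twts, u)
    if hill is not None:
        tail_starts.insert(0, hill)
    warm_first = warm is not None
    if warm_first:
        wb, wt = warm
        if wb is not None:
            bulk_starts.insert(0, wb)
        if wt is not None:
            tail_starts.insert(0, wt)

    bres = _minimize(_bulk_nll, bulk_starts, (bvals, bwts, u, bulk_includes_zero),
                     warm_first=warm_first)
    tres = _minimize(_tail_nll, tail_starts, (tvals, twts, float(u)),
                     warm_first=warm_first)
    converged = bool(bres.success and tres.success and bres.fun < _BIG and tres.fun < _BIG)

    alpha, beta = math.exp(bres.x[0]), math.exp(bres.x[1])
    sigma, xi = math.exp(tres.x[0]), float(tres.x[1])
    dist = SplicedDistribution(
        bulk=DiscreteGamma(alpha, beta),
        tail=DiscreteGPD(int(u), sigma, xi),
        phi=phi,
        bulk_includes_zero=bulk_includes_zero,
    )
    loglik = (
        n_b * math.log1p(-phi)
        - bres.fun
        + n_u * math.log(phi)
        - tres.fun
    )
    return dist, float(loglik), converged, (tuple(bres.x), tuple(tres.x))


class SplicedThresholdModel:
    """Spliced discrete Gamma / discrete GPD model of a clone size sample.

    Parameters
    ----------
    sample : CloneSizeSample or array-like of positive integers
    bulk_includes_zero : bool
        If True, normalize the bulk over {0, ..., u-1} (the literal
        right-truncated form); default truncates at 1 since observed clone
        sizes are counts >= 1.
    min_tail, min_bulk : int
        Minimum clones required in each component for a candidate threshold.
    """

    def __init__(self, sample, bulk_includes_zero=False, min_tail=10, min_bulk=10):
        if not isinstance(sample, CloneSizeSample):
            sample = CloneSizeSample(np.asarray(sample))
        self.sample = sample
        self.bulk_includes_zero = bool(bulk_includes_zero)
        self.min_tail = int(min_tail)
        self.min_bulk = int(min_bulk)

    def candidate_thresholds(self, quantile=0.75):
        return candidate_thresholds(
            self.sample, quantile=quantile,
            min_tail=self.min_tail, min_bulk=self.min_bulk,
        )

    def fit(self, quantile=0.75):
        """Profile-likelihood fit over the candidate threshold grid."""
        cands = self.candidate_thresholds(quantile=quantile)
        values, mult = self.sample.unique_counts()
        n = self.sample.n
        rows = []
        best = None
        warm = None
        for u in cands:
            try:
                dist, ll, conv, warm_params = _fit_threshold_core(
                    values, mult, n, int(u), self.bulk_includes_zero, warm,
                )
            except (ValueError, FloatingPointError) as exc:  # pragma: no cover
                warnings.warn("candidate u=%d skipped: %s" % (u, exc))
                rows.append((int(u), -math.inf, False))
                continue
            warm = warm_params
            rows.append((int(u), ll, conv))
            if conv and (best is None or ll > best[1]):
                best = (dist, ll)
        if best is None:
            raise RuntimeError(
                "no candidate threshold admitted a converged fit; "
                "profile trace: %r" % rows
            )
        profile = pd.DataFrame(rows, columns=["u", "loglik", "converged"])
        dist, ll = best
        return SplicedThresholdResults(self, dist, ll, profile)


@dataclass
class SplicedThresholdResults:
    """Fitted spliced model: estimates, log-likelihood, and the profile trace."""

    model: SplicedThresholdModel
    distribution: SplicedDistribution
    llf: float
    profile: pd.DataFrame

    @property
    def params(self) -> pd.Series:
        d = self.distribution
        return pd.Series(
            {
                "u": float(d.tail.u),
                "alpha": d.bulk.alpha,
                "beta": d.bulk.beta,
                "sigma": d.tail.sigma,
                "xi": d.tail.xi,
                "phi": d.phi,
            }
        )

    @property
    def u(self) -> int:
        return self.distribution.tail.u

    @property
    def xi(self) -> float:
        return self.distribution.tail.xi

    @property
    def n_u(self) -> int:
        return self.model.sample.n_at_or_above(self.u)

    @property
    def converged(self) -> bool:
        return bool(self.profile.loc[self.profile["u"] == self.u, "converged"].iloc[0])

    def to_dict(self) -> dict:
        s = self.model.sample
        return {
            "label": s.label,
            "n": s.n,
            "total_reads": s.total_reads,
            "u": int(self.u),
            "alpha": self.distribution.bulk.alpha,
            "beta": self.distribution.bulk.beta,
            "sigma": self.distribution.tail.sigma,
            "xi": self.distribution.tail.xi,
            "phi": self.distribution.phi,
            "loglik": self.llf,
            "bulk_includes_zero": self.distribution.bulk_includes_zero,
            "profile": [
                {"u": int(r.u), "loglik": float(r.loglik), "converged": bool(r.converged)}
                for r in self.profile.itertuples()
            ],
        }

    def summary(self) -> str:
        s = self.model.sample
        lines = [
            "Spliced threshold model (discrete Gamma bulk / discrete GPD tail)",
            "=" * 66,
            f"Sample: {s.label or '<unlabeled>'}   clonotypes: {s.n}   reads: {s.total_reads}",
            f"Threshold candidates evaluated: {len(self.profile)}",
            "-" * 66,
            f"  threshold u        {self.u:>12d}",
            f"  bulk shape alpha   {self.distribution.bulk.alpha:>12.6g}",
            f"  bulk rate beta     {self.distribution.bulk.beta:>12.6g}",
            f"  tail scale sigma   {self.distribution.tail.sigma:>12.6g}",
            f"  tail shape xi      {self.distribution.tail.xi:>12.6g}",
            f"  tail fraction phi  {self.distribution.phi:>12.6g}",
            f"  log-likelihood     {self.llf:>12.6f}",
            "=" * 66,
        ]
        return "\n".join(lines)

    def simulate(self, n_clones, rng):
        """Draw a synthetic repertoire of ``n_clones`` from the fitted law."""
        return CloneSizeSample(self.distribution.rvs(n_clones, rng),
                               label=self.model.sample.label + "_sim")


def fit_spliced(sample, quantile=0.75, **kwargs):
    """Convenience wrapper: build the model and fit in one call."""
    return SplicedThresholdModel(sample, **kwargs).fit(quantile=quantile)
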