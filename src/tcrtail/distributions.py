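"""Discrete Gamma, discrete generalized Pareto, and the spliced bulk-tail model.

Clone sizes are read counts, so all three laws live on the integers.  Each
discrete law is the quantized analog of its continuous parent: for interval
length d = 1,

    Pr(X = x) = Psi(x + 1) - Psi(x),

where Psi is the continuous distribution function.  The spliced model glues a
(truncated) discrete Gamma *bulk* below an integer threshold ``u`` to a
discrete generalized Pareto (GPD) *tail* at and above ``u``, with a fraction
``phi`` of the probability mass assigned to the tail.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

__all__ = [
    "DiscreteGamma",
    "DiscreteGPD",
    "SplicedDistribution",
    "gpd_cdf_continuous",
    "gpd_sf_continuous",
]

# Below this |xi| the GPD power form is numerically unusable; use the
# exponential (xi -> 0) limit instead.
XI_EXPONENTIAL_CUTOFF = 1e-8


def _as_int_array(x):
    arr = np.asarray(x)
    if arr.dtype.kind == "f":
        if not np.all(np.isfinite(arr)) or not np.all(arr == np.floor(arr)):
            raise ValueError("expected integer-valued input")
        arr = arr.astype(np.int64)
    elif arr.dtype.kind not in "iu":
        raise ValueError("expected integer-valued input")
    return arr


def gpd_sf_continuous(x, u, sigma, xi):
    """Survival function of the continuous GPD, stable for xi near 0.

    Returns ``(1 + xi (x-u)/sigma)^(-1/xi)`` (0 beyond the xi<0 upper bound,
    1 below ``u``), switching to ``exp(-(x-u)/sigma)`` when |xi| is tiny.
    """
    z = (np.asarray(x, dtype=float) - u) / sigma
    z = np.maximum(z, 0.0)
    if abs(xi) < XI_EXPONENTIAL_CUTOFF:
        return np.exp(-z)
    t = 1.0 + xi * z
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = np.where(t > 0.0, np.exp(-np.log1p(xi * z) / xi), 0.0)
    return out


def gpd_cdf_continuous(x, u, sigma, xi):
    """Distribution function of the continuous GPD(u, sigma, xi)."""
    return 1.0 - gpd_sf_continuous(x, u, sigma, xi)


@dataclass(frozen=True)
class DiscreteGamma:
    """Quantized Gamma(alpha, beta) on {0, 1, 2, ...}.

    ``alpha`` is the shape, ``beta`` the rate.  The pmf is
    ``[gammainc(alpha, beta (x+1)) - gammainc(alpha, beta x)] / Gamma(alpha)``,
    i.e. the law of floor(Y) for Y ~ Gamma(alpha, beta).
    """

    alpha: float
    beta: float

    def __post_init__(self):
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("DiscreteGamma requires alpha > 0 and beta > 0")

    def pmf(self, x):
        x = _as_int_array(x)
        if np.any(x < 0):
            raise ValueError("discrete Gamma support is x >= 0")
        lo = special.gammainc(self.alpha, self.beta * x)
        hi = special.gammainc(self.alpha, self.beta * (x + 1))
        return hi - lo

    def cdf(self, x):
        x = _as_int_array(x)
        out = special.gammainc(self.alpha, self.beta * np.maximum(x + 1, 0))
        return np.where(x < 0, 0.0, out)

    def quantile_table(self, upper):
        """Cumulative probabilities on {0, ..., upper} for inverse-CDF draws."""
        xs = np.arange(upper + 1)
        return xs, self.cdf(xs)

    def rvs(self, size, rng, tail_tol=1e-12):
        """Inverse-CDF sampling on a support truncated where tail mass < tail_tol."""
        upper = int(stats.gamma.ppf(1.0 - tail_tol, self.alpha, scale=1.0 / self.beta)) + 1
        xs, cum = self.quantile_table(upper)
        v = rng.random(size)
        return xs[np.searchsorted(cum, v, side="left")]


@dataclass(frozen=True)
class DiscreteGPD:
    """Quantized generalized Pareto on integers at and above the threshold ``u``.

    pmf(x) = S(x) - S(x+1) with S the continuous GPD survival function.
    Support: {u, u+1, ...} for xi >= 0; {u, ..., floor(u - sigma/xi)} for
    xi < 0.
    """

    u: int
    sigma: float
    xi: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError("DiscreteGPD requires sigma > 0")
        if float(self.u) != int(self.u):
            raise ValueError("threshold u must be an integer")
        object.__setattr__(self, "u", int(self.u))

    @property
    def support_max(self):
        """Largest integer with positive mass; inf when xi >= 0 (or xi ~ 0)."""
        if self.xi >= 0 or abs(self.xi) < XI_EXPONENTIAL_CUTOFF:
            return math.inf
        bound = self.u - self.sigma / self.xi
        m = math.floor(bound)
        # when the continuous bound is itself an integer the pmf at it is 0
        if m == bound:
            m -= 1
        return m

    def _sf(self, x):
        return gpd_sf_continuous(x, self.u, self.sigma, self.xi)

    def pmf(self, x):
        x = _as_int_array(x)
        out = self._sf(x) - self._sf(x + 1)
        return np.where(x < self.u, 0.0, out)

    def logpmf(self, x):
        with np.errstate(divide="ignore"):
            return np.log(self.pmf(x))

    def cdf(self, x):
        x = _as_int_array(x)
        return np.where(x < self.u, 0.0, 1.0 - self._sf(x + 1))

    def sf(self, x):
        """P(X > x) for integer x; equals the continuous survival at x+1."""
        x = _as_int_array(x)
        return np.where(x < self.u, 1.0, self._sf(x + 1))

    def quantile(self, p):
        """Smallest support integer whose CDF reaches p (Galois inverse of cdf)."""
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p must lie in [0, 1]")
        if np.any(p == 1.0):
            if self.xi >= 0:
                raise ValueError("quantile(1) is unbounded when xi >= 0")
        scalar = p.ndim == 0
        p = np.atleast_1d(p)
        if abs(self.xi) < XI_EXPONENTIAL_CUTOFF:
            z = -self.sigma * np.log1p(-p)
        else:
            with np.errstate(over="ignore"):
                z = self.sigma / self.xi * np.expm1(-self.xi * np.log1p(-p))
        x = self.u + np.maximum(0, np.ceil(z) - 1).astype(np.int64)
        # one-step float corrections around the closed form
        for _ in range(2):
            too_high = (x > self.u) & (self.cdf(x - 1) >= p)
            x = np.where(too_high, x - 1, x)
            too_low = self.cdf(x) < p
            x = np.where(too_low, x + 1, x)
        if self.xi < 0 and math.isfinite(self.support_max):
            x = np.minimum(x, self.support_max)
        return x[0] if scalar else x

    def rvs(self, size, rng):
        return self.quantile(rng.random(size))

    def truncation_point(self, tail_tol=1e-12):
        """Integer x such that P(X > x) < tail_tol (closed form, no fixed cap)."""
        if self.xi < 0 and math.isfinite(self.support_max):
            return int(self.support_max)
        return int(self.quantile(min(1.0 - tail_tol, 1.0 - 1e-16))) + 1


@dataclass(frozen=True)
class SplicedDistribution:
    """Discrete Gamma bulk below ``u`` spliced to a discrete GPD tail at ``u``.

    With tail mass fraction ``phi`` and censoring interval d = 1:

        f(x) = (1 - phi) h(x) / Z_bulk   for lo <= x <= u - 1
        f(x) = phi g(x)                  for x >= u

    where by default the bulk is additionally left-truncated at 1 (clone
    sizes are counts >= 1), so Z_bulk = H(u-1) - h(0).  Setting
    ``bulk_includes_zero=True`` keeps the literal right-truncated-only
    normalizer Z_bulk = H(u-1).
    """

    bulk: DiscreteGamma
    tail: DiscreteGPD
    phi: float
    bulk_includes_zero: bool = False
    d: int = field(default=1, init=False)

    def __post_init__(self):
        if not (0.0 <= self.phi <= 1.0):
            raise ValueError("phi must lie in [0, 1]")
        if self.phi < 1.0 and self.tail.u < 2:
            raise ValueError("tail threshold u must be >= 2 so the bulk is non-empty")

    @property
    def u(self):
        return self.tail.u

    @property
    def _bulk_lo(self):
        return 0 if self.bulk_includes_zero else 1

    @property
    def _z_bulk(self):
        z = float(self.bulk.cdf(self.u - 1))
        if not self.bulk_includes_zero:
            z -= float(self.bulk.cdf(0))
        return z

    def pmf(self, x):
        x = _as_int_array(x)
        out = np.zeros(np.shape(x), dtype=float)
        lo = self._bulk_lo
        in_bulk = (x >= lo) & (x <= self.u - 1)
        in_tail = x >= self.u
        if self.phi < 1.0 and np.any(in_bulk):
            out = np.where(
                in_bulk,
                (1.0 - self.phi) * self.bulk.pmf(np.maximum(x, 0)) / self._z_bulk,
                out,
            )
        if self.phi > 0.0:
            out = np.where(in_tail, self.phi * self.tail.pmf(np.maximum(x, self.u)), out)
        return out if out.shape else float(out)

    def logpmf(self, x):
        with np.errstate(divide="ignore"):
            return np.log(self.pmf(x))

    def cdf(self, x):
        x = _as_int_array(x)
        lo = self._bulk_lo
        bulk_part = (self.bulk.cdf(np.clip(x, lo - 1, self.u - 1)) -
                     (0.0 if self.bulk_includes_zero else float(self.bulk.cdf(0))))
        bulk_part = np.maximum(bulk_part, 0.0)
        below = (1.0 - self.phi) * bulk_part / self._z_bulk if self.phi < 1.0 else np.zeros_like(bulk_part)
        above = 1.0 - self.phi + self.phi * self.tail.cdf(np.maximum(x, self.u))
        out = np.where(x >= self.u, above, below)
        return out if out.shape else float(out)

    def loglik(self, counts):
        """Sum of log pmf over clone sizes; -inf if any observation has zero mass."""
        counts = _as_int_array(counts)
        if counts.size == 0:
            raise ValueError("empty sample")
        if np.any(counts < 1):
            raise ValueError("clone sizes must be >= 1")
        p = self.pmf(counts)
        if np.any(p <= 0.0):
            return -math.inf
        return float(np.sum(np.log(p)))

    def support_upper(self, tail_tol=1e-12):
        """Integer beyond which remaining mass < tail_tol (tail-driven)."""
        if self.phi == 0.0:
            return self.u - 1
        return self.tail.truncation_point(tail_tol=min(1.0, tail_tol / max(self.phi, tail_tol)))

    def rvs(self, size, rng):
        """Mixture draw: Bernoulli(phi) tail indicator, then inverse-CDF in each part."""
        is_tail = rng.random(size) < self.phi
        out = np.empty(size, dtype=np.int64)
        n_tail = int(is_tail.sum())
        n_bulk = size - n_tail
        if n_bulk:
            lo = self._bulk_lo
            xs = np.arange(lo, self.u)
            probs = self.bulk.pmf(xs)
            cum = np.cumsum(probs) / probs.sum()
            v = rng.random(n_bulk)
            out[~is_tail] = xs[np.searchsorted(cum, v, side="left")]
        if n_tail:
            out[is_tail] = self.tail.rvs(n_tail, rng)
        return out
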