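"""Synthetic repertoires from the spliced model, factorial cohort designs,
and read downsampling.

The default :class:`SimulationDesign` is a 48-sample full factorial over
bulk shape alpha in {3, 5, 10}, tail shape xi in {0.25, 0.5, 0.75, 1.1} and
tail fraction phi in {0.1, 0.15, 0.2, 0.25}, with bulk rate beta = 0.15 and
n = 20,000 clonotypes per sample.  In each cell the threshold is the Gamma
quantile u = floor(Q_{alpha,beta}(1 - phi)) and the GPD scale is
sigma = alpha/beta (the bulk Gamma mean), so that the tail begins where the
bulk's upper phi-fraction would end and has a scale commensurate with the
bulk.  This grid spans light to very heavy tails and small to large
expanded-clone fractions, the regimes seen across real repertoires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .distributions import DiscreteGamma, DiscreteGPD, SplicedDistribution
from .sample import CloneSizeSample

__all__ = [
    "SimulationDesign",
    "generate_repertoire",
    "build_design_cohort",
    "downsample_reads",
    "equalize_depth",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def generate_repertoire(model: SplicedDistribution, n_clones: int, seed,
                        label: str = "") -> CloneSizeSample:
    """Draw ``n_clones`` independent clone sizes from a spliced model.

    Each clone is tail with probability phi (discrete GPD inverse-CDF draw)
    and bulk otherwise (truncated discrete Gamma inverse-CDF table).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = _rng(seed)
    counts = model.rvs(int(n_clones), rng)
    return CloneSizeSample(counts, label=label)


@dataclass(frozen=True)
class SimulationDesign:
    """Full-factorial cohort design over (alpha, xi, phi) at fixed beta.

    ``sigma_rule`` maps (alpha, beta) to the GPD scale; the default is the
    bulk Gamma mean alpha/beta.  The threshold in each cell is
    u = floor(Q_{alpha,beta}(1 - phi)).
    """

    alpha_grid: Sequence[float] = (3.0, 5.0, 10.0)
    xi_grid: Sequence[float] = (0.25, 0.5, 0.75, 1.1)
    phi_grid: Sequence[float] = (0.1, 0.15, 0.2, 0.25)
    beta: float = 0.15
    n_clones: int = 20_000
    seed: int = 0
    sigma_rule: Union[str, Callable[[float, float], float]] = "mean"

    @property
    def size(self) -> int:
        return len(self.alpha_grid) * len(self.xi_grid) * len(self.phi_grid)

    def sigma(self, alpha: float) -> float:
        if callable(self.sigma_rule):
            return float(self.sigma_rule(alpha, self.beta))
        if self.sigma_rule == "mean":
            return alpha / self.beta
        if self.sigma_rule == "product":
            return alpha * self.beta
        raise ValueError("unknown sigma_rule %r" % (self.sigma_rule,))

    def threshold(self, alpha: float, phi: float) -> int:
        return int(np.floor(stats.gamma.ppf(1.0 - phi, alpha, scale=1.0 / self.beta)))

    def cells(self):
        """Iterate (alpha, xi, phi) in deterministic grid order."""
        for a in self.alpha_grid:
            for x in self.xi_grid:
                for p in self.phi_grid:
                    yield float(a), float(x), float(p)

    def cell_model(self, alpha: float, xi: float, phi: float) -> SplicedDistribution:
        u = self.threshold(alpha, phi)
        if u < 2:
            raise ValueError(
                "design cell (alpha=%g, xi=%g, phi=%g) yields threshold u=%d < 2"
                % (alpha, xi, phi, u)
            )
        return SplicedDistribution(
            bulk=DiscreteGamma(alpha, self.beta),
            tail=DiscreteGPD(u, self.sigma(alpha), xi),
            phi=phi,
        )


def build_design_cohort(design: SimulationDesign):
    """One sample per grid cell; per-cell seeds spawned from the design seed.

    Labels encode the generating parameters; each sample's ``meta`` carries
    them numerically (keys alpha, xi, phi, u, sigma, beta, cell_seed).
    """
    ss = np.random.SeedSequence(design.seed)
    children = ss.spawn(design.size)
    cohort = []
    for (alpha, xi, phi), child in zip(design.cells(), children):
        model = design.cell_model(alpha, xi, phi)
        label = "a%g_xi%g_phi%g" % (alpha, xi, phi)
        rng = np.random.default_rng(child)
        counts = model.rvs(design.n_clones, rng)
        meta = {
            "alpha": alpha, "xi": xi, "phi": phi,
            "u": model.tail.u, "sigma": model.tail.sigma, "beta": design.beta,
            "design_seed": design.seed,
        }
        cohort.append(CloneSizeSample(counts, label=label, meta=meta))
    return cohort


def downsample_reads(sample: CloneSizeSample, target_reads: int, seed) -> CloneSizeSample:
    """Subsample reads without replacement to exactly ``target_reads``.

    The retained reads per clonotype follow the multivariate hypergeometric
    law across clones; clonotypes reduced to zero reads are dropped (they
    would be unobserved at the lower depth).
    """
    total = sample.total_reads
    if not 1 <= target_reads <= total:
        raise ValueError(
            "target_reads must be in [1, %d], got %d" % (total, target_reads)
        )
    if target_reads == total:
        return sample
    rng = _rng(seed)
    new = rng.multivariate_hypergeometric(
        sample.counts, int(target_reads), method="marginals"
    )
    kept = new[new > 0]
    meta = dict(sample.meta)
    meta["downsampled_from"] = total
    return CloneSizeSample(kept, label=sample.label, meta=meta)


def equalize_depth(cohort, depth: Optional[int] = None, seed=0):
    """Downsample every sample in a cohort to a common read depth.

    ``depth`` defaults to the cohort minimum total reads (samples already at
    that depth pass through unchanged).  Returns ``(cohort, depth)``.
    """
    cohort = list(cohort)
    if not cohort:
        raise ValueError("empty cohort")
    if depth is None:
        depth = min(s.total_reads for s in cohort)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(cohort))
    out = []
    for s, child in zip(cohort, children):
        if s.total_reads == depth:
            out.append(s)
        else:
            out.append(downsample_reads(s, depth, np.random.default_rng(child)))
    return out, int(depth)
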