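# tcrtail

Model-based analysis of T cell receptor (TCR) repertoire clone size
distributions.

## The problem

High-throughput TCR sequencing yields, for each sample, a vector of *clone
sizes*: the number of reads observed for each distinct clonotype.  These
distributions are heavy-tailed — a handful of clones expanded by an active
immune response dominate a sea of rare clonotypes — but the power-law
behaviour only holds above some clone size threshold.  One-number summaries
(richness, Shannon entropy, clonality) are sensitive to sequencing depth,
and fitting a pure power law discards everything below its threshold.

`tcrtail` models the **whole** clone size distribution with a *spliced
threshold model*: a discretized Gamma "bulk" for the small clones and a
discrete generalized Pareto distribution (GPD) "tail" for the expanded
clones, joined at an integer threshold *u* that is estimated from the data.
With tail mass fraction φ and censoring interval d = 1,

```
f(x) = (1 − φ) h(x | α, β) / H(u − 1 | α, β)   for x ≤ u − 1
f(x) = φ g(x | u, σ, ξ)                         for x ≥ u
```

where `h`/`H` are the pmf/CDF of the discrete Gamma(α, β) and `g` the pmf of
the discrete GPD(u, σ, ξ), each obtained from its continuous parent Ψ via
`Pr(X = x) = Ψ(x + 1) − Ψ(x)`.  Estimation is by profile likelihood: every
unique clone size at or above the 75% sample quantile is tried as the
threshold; given *u*, φ is the plug-in fraction n_u/n and (α, β), (σ, ξ)
are maximized independently; the threshold maximizing the profile
likelihood L_p(u) wins.

Why these quantities are worth estimating:

- **ξ (tail shape)** measures how dominated the repertoire is by expanded
  clones: ξ is inversely related to the shape α_d of the classical type-I
  Pareto tail model (a Pareto(u, α_d) is exactly a GPD with σ = u/α_d,
  ξ = 1/α_d), and by the GPD threshold-stability property ξ is invariant to
  sequencing depth even though *u* shrinks with it.
- **u (threshold)** marks the clone size above which expansion is
  attributable to active immune response — an objective, depth-adaptive
  cutoff for selecting clonotypes for downstream motif or gene-usage work.
- **the stimulated fraction**: reads carried by clones of size ≥ û over all
  reads, a scalar measure of how much of the repertoire is engaged.

For cohort comparisons the package computes pairwise Jensen-Shannon
distances between fitted models, Ward hierarchical clustering, and
non-metric MDS embeddings.  A KS-threshold type-I Pareto comparator fit,
the standard ecological estimators, a spliced-model simulator, and
hypergeometric read downsampling round out the toolbox.

## Worked example

```python
import numpy as np
from tcrtail import (SimulationDesign, SplicedThresholdModel,
                     generate_repertoire, clonality, proportion_stimulated,
                     fit_desponds)

design = SimulationDesign(seed=1)                    # factorial study design
model = design.cell_model(3.0, 0.5, 0.15)            # alpha=3, xi=0.5, phi=0.15
sample = generate_repertoire(model, 20_000, 42, label="example")
res = SplicedThresholdModel(sample).fit()
print(res.summary())
```

```
Spliced threshold model (discrete Gamma bulk / discrete GPD tail)
==================================================================
Sample: example   clonotypes: 20000   reads: 484553
Threshold candidates evaluated: 259
------------------------------------------------------------------
  threshold u                  31
  bulk shape alpha        2.99466
  bulk rate beta         0.149386
  tail scale sigma        20.8897
  tail shape xi          0.515751
  tail fraction phi       0.14895
  log-likelihood     -78525.000247
==================================================================
```

The generating cell had u = 31, α = 3, β = 0.15, σ = 20, ξ = 0.5, φ = 0.15:
every parameter is recovered closely, and the selected threshold is exact.
Continuing,

```python
print("clonality:", round(clonality(sample), 4))                  # 0.0488
print("stimulated:", round(proportion_stimulated(sample, res.u), 4))  # 0.4479
cmp = fit_desponds(sample)   # Pareto comparator, KS threshold selection
print(cmp.u, cmp.alpha_d)    # 84, 1.812  (implied xi = 1/alpha_d = 0.552)
```

The comparator reads the same heavy tail (ξ ≈ 0.55) but anchors its
threshold much higher (84 vs 31) and models nothing below it — the
motivation for the spliced model.  `pairwise_distances`,
`cluster_samples` and `embed_mds` take collections of fits from here to
cohort-level pictures; `tcrtail --help` exposes the same workflows as a
command line (`simulate`, `fit`, `desponds`, `diversity`, `compare`,
`downsample`).

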