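"""Ecological diversity estimators and the threshold-derived stimulation statistic.

Given clone frequencies p_i = count_i / total_reads:

    richness   S = number of unique clonotypes
    entropy    H = -sum p_i ln p_i            (nats)
    clonality  C = 1 - H / ln S               (1 - Pielou's evenness)

``proportion_stimulated`` is the fraction of all reads carried by clones at
or above a size threshold — with the threshold taken from a spliced-model
fit, it estimates the share of the repertoire actively engaged in immune
response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .sample import CloneSizeSample

__all__ = [
    "richness",
    "shannon",
    "clonality",
    "proportion_stimulated",
    "DiversityEstimates",
    "diversity_estimates",
    "diversity_table",
]


def _counts(sample):
    if isinstance(sample, CloneSizeSample):
        return sample.counts
    return CloneSizeSample(np.asarray(sample)).counts


def richness(sample) -> int:
    """Number of unique clonotypes observed."""
    return int(_counts(sample).size)


def shannon(sample, base: Optional[float] = None) -> float:
    """Shannon entropy of the clone frequencies; nats unless ``base`` given."""
    c = _counts(sample).astype(float)
    p = c / c.sum()
    h = float(-(p @ np.log(p)))
    if base is not None:
        h /= math.log(base)
    return h


def clonality(sample) -> float:
    """1 - Pielou's evenness: 0 for a uniform repertoire, 1 for one clone.

    A single-clonotype sample is defined as fully clonal (C = 1); the ratio
    H/ln S is 0/0 there and the dominated-repertoire limit is 1.
    """
    s = richness(sample)
    if s == 1:
        return 1.0
    return 1.0 - shannon(sample) / math.log(s)


def proportion_stimulated(sample, u: int) -> float:
    """Reads in clones of size >= u as a fraction of all reads."""
    if u < 1:
        raise ValueError("threshold u must be >= 1")
    c = _counts(sample)
    return float(c[c >= u].sum() / c.sum())


@dataclass(frozen=True)
class DiversityEstimates:
    richness: int
    shannon: float
    clonality: float
    prop_stimulated: Optional[float] = None


def diversity_estimates(sample, threshold: Optional[int] = None) -> DiversityEstimates:
    """All estimators for one sample; ``prop_stimulated`` only with a threshold."""
    return DiversityEstimates(
        richness=richness(sample),
        shannon=shannon(sample),
        clonality=clonality(sample),
        prop_stimulated=None if threshold is None else proportion_stimulated(sample, threshold),
    )


def diversity_table(samples, thresholds=None) -> pd.DataFrame:
    """One row per sample with the four statistics.

    ``thresholds`` maps sample label -> threshold (or is a sequence aligned
    with ``samples``); omitted thresholds leave ``prop_stimulated`` NaN.
    """
    rows = []
    for i, s in enumerate(samples):
        u = None
        if thresholds is not None:
            if isinstance(thresholds, dict):
                u = thresholds.get(s.label)
            else:
                u = thresholds[i]
        est = diversity_estimates(s, threshold=u)
        rows.append(
            {
                "label": s.label,
                "richness": est.richness,
                "shannon": est.shannon,
                "clonality": est.clonality,
                "prop_stimulated": (math.nan if est.prop_stimulated is None
                                    else est.prop_stimulated),
            }
        )
    return pd.DataFrame(rows)
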