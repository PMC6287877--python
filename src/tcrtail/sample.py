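"""Container for a sample repertoire: one read count per clonotype."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CloneSizeSample"]


@dataclass(frozen=True)
class CloneSizeSample:
    """Clone sizes (reads per clonotype) for one sample.

    The order of ``counts`` carries no meaning: every statistic and fit in
    this package is invariant to permutations of the vector.
    """

    counts: np.ndarray
    label: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.dtype.kind == "f":
            if not np.all(arr == np.floor(arr)):
                raise ValueError("clone sizes must be integers")
            arr = arr.astype(np.int64)
        elif arr.dtype.kind not in "iu":
            raise ValueError("clone sizes must be integers")
        else:
            arr = arr.astype(np.int64)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("counts must be a non-empty 1-d vector")
        if np.any(arr < 1):
            raise ValueError("every clone size must be >= 1")
        object.__setattr__(self, "counts", arr)

    @property
    def n(self) -> int:
        """Number of clonotypes."""
        return int(self.counts.size)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())

    def unique_counts(self):
        """(sorted unique sizes, multiplicities) — the counts-of-counts view."""
        cached = self.__dict__.get("_unique")
        if cached is None:
            cached = np.unique(self.counts, return_counts=True)
            object.__setattr__(self, "_unique", cached)
        return cached

    def n_at_or_above(self, u: int) -> int:
        return int(np.count_nonzero(self.counts >= u))

    def relabel(self, label: str) -> "CloneSizeSample":
        return CloneSizeSample(self.counts, label=label, meta=dict(self.meta))
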