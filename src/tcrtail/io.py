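"""Readers and writers: clone tables, fit records, distance matrices, cohorts.

Clone counts come in as either a plain two-column TSV (clonotype label,
read count) or an AIRR-style rearrangement TSV, in which case reads are
aggregated per clonotype key (junction by default) over the duplicate-count
column.  Fit records round-trip through JSON text bit-exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .sample import CloneSizeSample
from .compare import DistanceMatrix

__all__ = [
    "read_clone_table",
    "write_clone_table",
    "write_fit",
    "read_fit",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_cohort",
    "read_cohort",
]

log = logging.getLogger("tcrtail")

AIRR_KEY_CANDIDATES = ("junction_aa", "junction", "cdr3_aa", "cdr3")
AIRR_COUNT_COLUMN = "duplicate_count"


def _validate_counts(keys, counts, path):
    counts = pd.to_numeric(counts, errors="coerce")
    bad = counts.isna() | (counts != counts.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            "%s: row %d has a non-integer count (%r)" % (path, row + 1, counts.iloc[row])
        )
    counts = counts.astype(np.int64)
    nonpos = counts <= 0
    if nonpos.any():
        row = int(np.flatnonzero(nonpos.to_numpy())[0])
        raise ValueError(
            "%s: row %d (clonotype %r) has count %d <= 0"
            % (path, row + 1, keys.iloc[row], counts.iloc[row])
        )
    return counts


def _aggregate(keys, counts, path):
    df = pd.DataFrame({"key": keys.astype(str), "count": counts})
    if df["key"].duplicated().any():
        ndup = int(df["key"].duplicated().sum())
        log.warning("%s: %d duplicate clonotype keys summed", path, ndup)
    agg = df.groupby("key", sort=False)["count"].sum()
    return agg


def read_clone_table(path, format="two_column_tsv", key_column=None,
                     count_column=AIRR_COUNT_COLUMN, label=None) -> CloneSizeSample:
    """Read one sample's clone sizes from a TSV file.

    ``format='two_column_tsv'``: clonotype label then count, optional header.
    ``format='airr_tsv'``: AIRR rearrangement table; reads are summed per
    clonotype key over ``count_column``.
    """
    path = Path(path)
    if label is None:
        label = path.stem
    if format == "two_column_tsv":
        try:
            df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                             comment="#", skip_blank_lines=True)
        except pd.errors.EmptyDataError:
            raise ValueError("%s: empty clone table" % path) from None
        if df.shape[1] < 2:
            raise ValueError("%s: expected 2 tab-separated columns" % path)
        # tolerate a header line (second field non-numeric)
        if pd.to_numeric(df.iloc[0, 1], errors="coerce") != pd.to_numeric(
                df.iloc[0, 1], errors="coerce"):
            df = df.iloc[1:].reset_index(drop=True)
        if df.empty:
            raise ValueError("%s: no data rows" % path)
        counts = _validate_counts(df.iloc[:, 0], df.iloc[:, 1], path)
        agg = _aggregate(df.iloc[:, 0], counts, path)
    elif format == "airr_tsv":
        try:
            df = pd.read_csv(path, sep="\t", dtype=str)
        except pd.errors.EmptyDataError:
            raise ValueError("%s: empty clone table" % path) from None
        if count_column not in df.columns:
            raise ValueError("%s: missing count column %r" % (path, count_column))
        if key_column is None:
            for cand in AIRR_KEY_CANDIDATES:
                if cand in df.columns:
                    key_column = cand
                    break
            else:
                raise ValueError(
                    "%s: no clonotype key column among %r"
                    % (path, AIRR_KEY_CANDIDATES)
                )
        elif key_column not in df.columns:
            raise ValueError("%s: missing key column %r" % (path, key_column))
        if df.empty:
            raise ValueError("%s: no data rows" % path)
        counts = _validate_counts(df[key_column], df[count_column], path)
        agg = _aggregate(df[key_column], counts, path)
    else:
        raise ValueError("unknown format %r" % format)
    return CloneSizeSample(agg.to_numpy(), label=label,
                           meta={"source": str(path), "format": format})


def write_clone_table(sample: CloneSizeSample, path):
    """Write a sample as a two-column TSV (synthetic clonotype keys)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, c in enumerate(sample.counts):
            fh.write("clone%06d\t%d\n" % (i, c))


def write_fit(result, path):
    """Serialize a fit result (spliced or comparator) as JSON text."""
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=1)
        fh.write("\n")


def read_fit(path) -> dict:
    """Read a fit record written by :func:`write_fit` (parameters bit-exact)."""
    with open(path) as fh:
        return json.load(fh)


def fit_record_to_distribution(record: dict):
    """Rebuild a SplicedDistribution from a spliced fit record."""
    from .distributions import DiscreteGamma, DiscreteGPD, SplicedDistribution

    return SplicedDistribution(
        bulk=DiscreteGamma(record["alpha"], record["beta"]),
        tail=DiscreteGPD(int(record["u"]), record["sigma"], record["xi"]),
        phi=record["phi"],
        bulk_includes_zero=record.get("bulk_includes_zero", False),
    )


def write_distance_matrix(dm: DistanceMatrix, path):
    dm.to_dataframe().to_csv(path, sep="\t", index_label="sample")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(tuple(df.index), df.to_numpy(dtype=float))


def write_cohort(cohort, directory, manifest_name="manifest.tsv"):
    """Write per-sample two-column TSVs plus a manifest of labels and params."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort:
        fname = "%s.tsv" % s.label
        write_clone_table(s, directory / fname)
        row = {"label": s.label, "file": fname,
               "n": s.n, "total_reads": s.total_reads}
        row.update({k: v for k, v in s.meta.items() if np.isscalar(v)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(directory / manifest_name, sep="\t", index=False)


def read_cohort(directory, manifest_name="manifest.tsv"):
    directory = Path(directory)
    manifest = pd.read_csv(directory / manifest_name, sep="\t")
    cohort = []
    for r in manifest.itertuples():
        s = read_clone_table(directory / r.file, label=r.label)
        meta = {k: getattr(r, k) for k in manifest.columns
                if k not in ("label", "file")}
        cohort.append(CloneSizeSample(s.counts, label=r.label, meta=meta))
    return cohort
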