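"""sRNA cluster class assignment, RPM normalization, and size profiles.

Class assignment resolves clusters hitting several annotated loci by a
fixed class precedence (miRNA > cis_NAT > trans_NAT > TAS/PHAS > lncRNA >
tRNA_like > TE_repeat > other) with maximal overlap, then lexicographic
feature id, breaking ties within a class.  A maximal-overlap-first mode
is also available.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .catalog import CLASS_PRECEDENCE, LocusCatalog

_RANK = {cls: i for i, cls in enumerate(CLASS_PRECEDENCE)}


def assign_class(
    cluster_intervals: pd.DataFrame,
    catalog: LocusCatalog,
    mode: Literal["precedence", "maximal_overlap"] = "precedence",
) -> pd.Series:
    """Map each cluster to exactly one RNA class.

    ``cluster_intervals`` needs columns (cluster, chrom, start, end) in the
    catalog's 0-based half-open coordinates.  Unmatched clusters are
    labeled "other".
    """
    required = {"cluster", "chrom", "start", "end"}
    missing = required - set(cluster_intervals.columns)
    if missing:
        raise ValueError(f"cluster table missing columns: {sorted(missing)}")

    trees: dict[str, IntervalTree] = {}
    for f in catalog:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)

    labels = {}
    for row_number, row in enumerate(cluster_intervals.itertuples(index=False), start=1):
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise ValueError(
                f"record {row_number}: cluster {row.cluster} has invalid interval "
                f"[{start}, {end})"
            )
        hits = []
        for iv in trees.get(str(row.chrom), IntervalTree()).overlap(start, end):
            f = iv.data
            ov = f.overlap(start, end)
            if ov > 0:
                hits.append((f, ov))
        if not hits:
            labels[row.cluster] = "other"
            continue
        if mode == "precedence":
            best = min(hits, key=lambda h: (_RANK[h[0].rna_class], -h[1], h[0].id))
        else:
            best = min(hits, key=lambda h: (-h[1], _RANK[h[0].rna_class], h[0].id))
        labels[row.cluster] = best[0].rna_class
    return pd.Series(labels, name="rna_class")


def rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million: each sample column rescaled to sum to 1e6."""
    depth = counts.sum(axis=0)
    zero = depth[depth <= 0]
    if len(zero):
        raise ValueError(f"zero-depth sample(s): {list(zero.index)}")
    return counts.astype(float) / depth * 1e6


def size_distribution(read_length_table: pd.DataFrame,
                      lengths: tuple[int, ...] = (20, 21, 22, 23, 24)) -> pd.DataFrame:
    """Per-sample 20-24 nt size profile in RPM units.

    ``read_length_table``: rows indexed by read length (nt, within 15-35),
    columns are samples, values are mapped-read counts.  Normalization is
    by each sample's total mapped reads, so the profile sums to the RPM of
    the 20-24 nt window.
    """
    idx = read_length_table.index.astype(int)
    if (idx < 15).any() or (idx > 35).any():
        raise ValueError("read lengths must lie within 15-35 nt")
    total = read_length_table.sum(axis=0).astype(float)
    window = read_length_table.reindex(list(lengths), fill_value=0)
    profile = window.astype(float) / total * 1e6
    profile.index.name = "length"
    return profile


def class_direction_summary(de_results: pd.DataFrame,
                            classes: pd.Series) -> pd.DataFrame:
    """Count up/down DE features per RNA class per time point.

    ``de_results`` needs columns (feature, time, status); ``classes`` maps
    feature id -> rna_class.
    """
    de = de_results[de_results["status"].isin(["up", "down"])].copy()
    if de.empty:
        return pd.DataFrame(columns=["rna_class", "time", "up", "down"])
    de["rna_class"] = de["feature"].map(classes).fillna("other")
    tally = (
        de.groupby(["rna_class", "time", "status"], observed=True)
        .size()
        .unstack("status", fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
        .reset_index()
    )
    tally.columns.name = None
    return tally.astype({"up": np.int64, "down": np.int64})
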