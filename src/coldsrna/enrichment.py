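"""Over-representation analysis of gene sets against user-supplied term maps.

One-sided hypergeometric (Fisher) upper-tail p per term, BH-corrected
across the reported terms.  Term maps are generic (gene -> term), so any
GO-like ontology snapshot can be supplied; no DAG handling or term
propagation is attempted.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def enrich(
    gene_set: Iterable[str],
    term_map: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` per term.

    ``term_map`` maps term id -> genes; all genes must lie in
    ``background``.  Returns one row per term with k >= 1, columns
    (term, k, K, n, N, p, p_adj), sorted by p (ties by term id).
    """
    background = set(background)
    if not background:
        raise ValueError("background must be nonempty")
    genes = set(gene_set)
    if not genes <= background:
        raise ValueError("gene_set must be a subset of the background")
    n, big_n = len(genes), len(background)
    rows = []
    for term, members in term_map.items():
        members = set(members)
        if not members <= background:
            raise ValueError(f"term {term!r} has genes outside the background")
        big_k = len(members)
        k = len(genes & members)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        rows.append({"term": term, "k": k, "K": big_k, "n": n, "N": big_n,
                     "p": min(p, 1.0)})
    result = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if len(result):
        result["p_adj"] = bh_adjust(result["p"].to_numpy())
        result = result.sort_values(["p", "term"], kind="mergesort",
                                    ignore_index=True)
    else:
        result["p_adj"] = pd.Series(dtype=float)
    return result


def read_term_map(path: str | os.PathLike) -> dict[str, set[str]]:
    """Two-column (gene, term) TSV or GMT (term, description, genes...)."""
    term_map: dict[str, set[str]] = {}
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        is_gmt = str(path).endswith(".gmt") or len(first.rstrip("\n").split("\t")) > 2
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or fields == [""]:
                continue
            if is_gmt:
                term, _desc, *genes = fields
                term_map.setdefault(term, set()).update(g for g in genes if g)
            else:
                gene, term = fields[0], fields[1]
                term_map.setdefault(term, set()).add(gene)
    return term_map


def detected_background(de_mrna: pd.DataFrame, threshold: float = 5.0) -> set[str]:
    """Expression-aware default background: genes with base mean >= threshold
    at any analyzed time point."""
    detected = de_mrna[de_mrna["base_mean"] >= threshold]
    return set(detected["feature"])
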