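"""Correlation classification of miRNA:mRNA and NAT pairs, and detection
of the classical nat-siRNA regulon.

miRNA:mRNA pairs (the miRNA must be DE) fall into exactly one category
per time point: ``inverse`` (opposite directions, either way round),
``same_up``, ``same_down``, ``partner_unchanged`` or
``partner_undetected``.

NAT pairs with a DE siRNA cluster get an unordered two-transcript status
pattern drawn with arrows: both up (up_up), one up / rest unchanged or
undetected (up_flat), one down / rest flat (down_flat), both flat
(flat_flat), or anticorrelated (up_down).

The classical nat-siRNA regulon is the stimulus-induced case: the siRNA
cluster significantly up and one transcript (the driver) significantly
up while its partner goes down.  Two modes are exposed because strict
+/-2-fold on the partner excludes weak but clearly negative responses:

* ``relaxed`` (default): driver FC >= 2 with adjusted p <= 0.05 and the
  partner's fold change merely negative;
* ``strict``: additionally partner FC <= -2 with adjusted p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd

PAIR_CATEGORIES = ("inverse", "same_up", "same_down",
                   "partner_unchanged", "partner_undetected")

NAT_PATTERNS = ("up_up", "up_flat", "down_flat", "flat_flat", "up_down")

PATTERN_GLYPHS = {
    "up_up": "↑↑",
    "up_flat": "↑─",
    "down_flat": "↓─",
    "flat_flat": "──",
    "up_down": "↑↓",
}


def classify_mirna_pair(mirna_status: str, target_status: str) -> str:
    """Table-style category for one (DE miRNA, target) pair."""
    if mirna_status not in ("up", "down"):
        raise ValueError(
            f"miRNA status must be 'up' or 'down' (got {mirna_status!r}); "
            "prefilter to DE miRNAs"
        )
    if target_status == "undetected":
        return "partner_undetected"
    if target_status == "unchanged":
        return "partner_unchanged"
    if target_status not in ("up", "down"):
        raise ValueError(f"unknown target status {target_status!r}")
    if mirna_status == target_status:
        return "same_up" if mirna_status == "up" else "same_down"
    return "inverse"


@dataclass(frozen=True)
class NatPairRecord:
    pair_id: str
    kind: str  # "cis" or "trans"
    status_1: str
    status_2: str
    sirna_status: str  # "up" or "down"
    pattern: str
    classical: bool


def classify_nat_pair(
    pair_id: str,
    kind: str,
    status_1: Optional[str],
    status_2: Optional[str],
    sirna_status: str,
) -> NatPairRecord:
    """Pattern for one NAT pair whose siRNA cluster is DE.

    Missing transcript statuses are treated as undetected (flagged by the
    stored status value).
    """
    if sirna_status not in ("up", "down"):
        raise ValueError("siRNA cluster must be DE (status up or down)")
    s1 = status_1 if status_1 in ("up", "down", "unchanged", "undetected") else "undetected"
    s2 = status_2 if status_2 in ("up", "down", "unchanged", "undetected") else "undetected"
    statuses = {s1, s2}
    if statuses == {"up", "down"}:
        pattern = "up_down"
    elif "up" in statuses:
        pattern = "up_up" if statuses == {"up"} else "up_flat"
    elif "down" in statuses:
        # a both-down pair has no dedicated bin; it joins the down-involving one
        pattern = "down_flat"
    else:
        pattern = "flat_flat"
    classical = pattern == "up_down" and sirna_status == "up"
    return NatPairRecord(pair_id, kind, s1, s2, sirna_status, pattern, classical)


def detect_classical_regulon(
    fc_1: float,
    padj_1: float,
    fc_2: float,
    padj_2: float,
    sirna_fc: float,
    sirna_padj: float,
    mode: Literal["strict", "relaxed"] = "relaxed",
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
) -> bool:
    """Does a NAT pair follow the classical nat-siRNA regulon?

    Fold changes are on the signed linear scale the field reports
    (FC >= 2 up, FC <= -2 down).  The siRNA cluster must be
    significantly up; one transcript (the driver) significantly up; and
    the partner's fold change negative (relaxed) or significantly at or
    below -``fc_threshold`` (strict).
    """
    if not (sirna_fc >= fc_threshold and sirna_padj <= alpha):
        return False
    for driver_fc, driver_p, partner_fc, partner_p in (
        (fc_1, padj_1, fc_2, padj_2),
        (fc_2, padj_2, fc_1, padj_1),
    ):
        if not (driver_fc >= fc_threshold and driver_p <= alpha):
            continue
        if mode == "relaxed":
            if partner_fc < 0:
                return True
        else:
            if partner_fc <= -fc_threshold and partner_p <= alpha:
                return True
    return False


def classify_mirna_pair_table(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Apply the category rule to a join of DE miRNAs with their targets
    (columns mirna, transcript, time, mirna_status, target_status)."""
    out = pair_table.copy()
    out["category"] = [
        classify_mirna_pair(m, t)
        for m, t in zip(out["mirna_status"], out["target_status"])
    ]
    return out


def tally_categories(classified: pd.DataFrame) -> pd.DataFrame:
    """Category x time-point counts (every eligible pair counted once)."""
    tally = (
        classified.groupby(["category", "time"], observed=True)
        .size()
        .unstack("time", fill_value=0)
        .reindex(PAIR_CATEGORIES, fill_value=0)
    )
    tally.columns.name = None
    return tally.astype(np.int64)


def classify_nat_pairs_from_de(
    catalog,
    de_srna: pd.DataFrame,
    de_mrna: pd.DataFrame,
) -> pd.DataFrame:
    """Classify every catalog NAT pair whose siRNA cluster is DE.

    The pair's siRNA cluster is looked up as ``<pair id>_sirna`` in the
    sRNA results; transcript statuses come from the mRNA results.
    """
    srna_idx = de_srna.set_index(["feature", "time"])
    mrna_idx = de_mrna.set_index(["feature", "time"])
    times = sorted(de_srna["time"].unique())
    rows = []
    for kind in ("cis", "trans"):
        for a, b in catalog.nat_pairs(kind):
            pid = a.id[:-1] if a.id.endswith("a") else a.id
            cluster = f"{pid}_sirna"
            for tp in times:
                key = (cluster, tp)
                if key not in srna_idx.index:
                    continue
                sirna_status = str(srna_idx.loc[key, "status"])
                if sirna_status not in ("up", "down"):
                    continue

                def _status(fid: str) -> Optional[str]:
                    k = (fid, tp)
                    return str(mrna_idx.loc[k, "status"]) if k in mrna_idx.index else None

                rec = classify_nat_pair(pid, kind, _status(a.id), _status(b.id),
                                        sirna_status)
                rows.append({
                    "pair": pid, "kind": kind, "time": tp,
                    "transcript_1": a.id, "transcript_2": b.id,
                    "status_1": rec.status_1, "status_2": rec.status_2,
                    "sirna_status": rec.sirna_status, "pattern": rec.pattern,
                    "classical": rec.classical,
                })
    return pd.DataFrame(
        rows,
        columns=["pair", "kind", "time", "transcript_1", "transcript_2",
                 "status_1", "status_2", "sirna_status", "pattern", "classical"],
    )


def detect_regulons_from_de(
    catalog,
    de_srna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    mode: Literal["strict", "relaxed"] = "relaxed",
) -> pd.DataFrame:
    """Run the classical-regulon rule on every catalog NAT pair x time point."""
    srna_idx = de_srna.set_index(["feature", "time"])
    mrna_idx = de_mrna.set_index(["feature", "time"])
    times = sorted(de_srna["time"].unique())
    rows = []
    for kind in ("cis", "trans"):
        for a, b in catalog.nat_pairs(kind):
            pid = a.id[:-1] if a.id.endswith("a") else a.id
            cluster = f"{pid}_sirna"
            for tp in times:
                keys = [(cluster, tp), (a.id, tp), (b.id, tp)]
                if not all(k in srna_idx.index or k in mrna_idx.index for k in keys):
                    continue
                if (cluster, tp) not in srna_idx.index:
                    continue
                if (a.id, tp) not in mrna_idx.index or (b.id, tp) not in mrna_idx.index:
                    continue
                sr = srna_idx.loc[(cluster, tp)]
                t1 = mrna_idx.loc[(a.id, tp)]
                t2 = mrna_idx.loc[(b.id, tp)]
                classical = detect_classical_regulon(
                    fc_1=signed_fc(float(t1["log2fc"])),
                    padj_1=float(t1["p_adj"]),
                    fc_2=signed_fc(float(t2["log2fc"])),
                    padj_2=float(t2["p_adj"]),
                    sirna_fc=signed_fc(float(sr["log2fc"])),
                    sirna_padj=float(sr["p_adj"]),
                    mode=mode,
                )
                rows.append({"pair": pid, "kind": kind, "time": tp,
                             "classical": classical})
    return pd.DataFrame(rows, columns=["pair", "kind", "time", "classical"])


def load_example_regulon_table() -> pd.DataFrame:
    """Curated example: published per-pair fold changes for cold-induced
    cis-NAT pairs whose nat-siRNA clusters were all significantly
    upregulated.

    Columns: time, gene_a, fc_a, padj_a, gene_b, fc_b, padj_b, sirna_fc,
    sirna_padj.  Significance is encoded at the decision boundary: the
    source reports which transcripts pass |FC| >= 2 with BH p <= 0.05, so
    those carry padj 0.05 and the rest 1.0; every siRNA cluster carries
    (fc, padj) = (2.0, 0.05), the minimal values that satisfy the
    upregulation criterion.
    """
    from importlib import resources

    with resources.files("coldsrna.data").joinpath(
            "cis_nat_regulon_examples.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def count_classical(table: pd.DataFrame,
                    mode: Literal["strict", "relaxed"] = "relaxed") -> pd.Series:
    """Per-time-point counts of pairs passing the classical-regulon rule
    on a fold-change table shaped like :func:`load_example_regulon_table`."""
    flags = [
        detect_classical_regulon(
            fc_1=row.fc_a, padj_1=row.padj_a, fc_2=row.fc_b, padj_2=row.padj_b,
            sirna_fc=row.sirna_fc, sirna_padj=row.sirna_padj, mode=mode)
        for row in table.itertuples(index=False)
    ]
    out = table.loc[flags].groupby("time").size()
    return out.reindex(sorted(table["time"].unique()), fill_value=0)


def signed_fc(log2fc: float) -> float:
    """Signed linear fold change as the field prints it: 2^|lfc| with the
    sign of the log fold change (4 -> FC 4 up, -4 -> FC -4 down)."""
    if not np.isfinite(log2fc):
        return float("nan")
    magnitude = 2.0 ** abs(log2fc)
    return magnitude if log2fc >= 0 else -magnitude
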