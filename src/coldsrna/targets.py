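"""psRNATarget-style miRNA target prediction.

The expectation score is a penalty sum over the antiparallel miRNA:site
duplex: perfect Watson-Crick pair 0, G:U wobble 0.5, mismatch 1.0, with
penalties doubled in the seed region (miRNA positions 2-13 from the 5'
end).  Lower is better; 0 is a perfect reverse complement.  The core
scorer is ungapped: every transcript window of miRNA length is scored
and windows at or under the expectation cutoff are reported, reduced to
the best-scoring window among overlapping ones (ties -> leftmost).

Target-site accessibility (the energy to unpair the site, UPE) is
consumed from a precomputed table and used only as a filter; it is never
computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

EXPECTATION_CUTOFF = 2.5
UPE_MAX = 25.0

SEED_START, SEED_END = 2, 13  # miRNA positions (1-based, 5'->3') with doubled penalty
CENTRAL = (9, 10, 11)  # all paired -> cleavage, else translational inhibition

MATCH = 0.0
WOBBLE = 0.5
MISMATCH = 1.0

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
_VALID = set("ACGU")


def _normalize(seq: str, what: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{what} contains non-nucleotide symbols: {sorted(bad)}")
    return seq


def _pair_penalty(mirna_base: str, target_base: str) -> float:
    """Penalty for one antiparallel position (target read 5'->3')."""
    if _COMPLEMENT[mirna_base] == target_base:
        return MATCH
    if (mirna_base, target_base) in (("G", "U"), ("U", "G")):
        return WOBBLE
    return MISMATCH


@dataclass(frozen=True)
class TargetHit:
    """One miRNA -> transcript site (transcript coordinates, 0-based half-open)."""

    mirna: str
    transcript: str
    target_start: int
    target_end: int
    expectation: float
    inhibition: str  # "cleavage" or "translation"
    upe: Optional[float] = None
    alignment: Optional[tuple[str, str, str]] = None


def score_duplex(mirna_seq: str, site_seq: str) -> tuple[float, tuple[str, str, str]]:
    """Expectation score for a miRNA against a same-length site (both 5'->3').

    Returns (expectation, alignment) where the alignment triple renders
    the miRNA 3'->5' over a match line (``|`` pair, ``o`` wobble, space
    mismatch) over the target 5'->3'.
    """
    m = _normalize(mirna_seq, "miRNA sequence")
    s = _normalize(site_seq, "site sequence")
    if len(m) != len(s):
        raise ValueError("site length must equal miRNA length for the core scorer")
    total = 0.0
    marks = []
    # miRNA position p (1-based from its 5' end) faces site index len-p
    for p in range(1, len(m) + 1):
        mb = m[p - 1]
        tb = s[len(s) - p]
        pen = _pair_penalty(mb, tb)
        if SEED_START <= p <= SEED_END:
            pen *= 2.0
        total += pen
        marks.append("|" if pen == 0 else ("o" if _is_wobble(mb, tb) else " "))
    alignment = (m[::-1], "".join(marks[::-1]), s)
    return total, alignment


def _is_wobble(mb: str, tb: str) -> bool:
    return (mb, tb) in (("G", "U"), ("U", "G"))


def _central_paired(mirna: str, site: str) -> bool:
    for p in CENTRAL:
        if p > len(mirna):
            return False
        if _pair_penalty(mirna[p - 1], site[len(site) - p]) == MISMATCH:
            return False
    return True


def find_targets(
    mirnas: Mapping[str, str],
    transcripts: Mapping[str, str],
    cutoff: float = EXPECTATION_CUTOFF,
    upe_table: Optional[pd.DataFrame] = None,
    upe_max: float = UPE_MAX,
) -> list[TargetHit]:
    """All miRNA target sites with expectation <= cutoff.

    ``upe_table`` (optional): columns (mirna, transcript, position, upe)
    keyed on the hit's target start; hits whose tabulated UPE exceeds
    ``upe_max`` are removed, hits without a table entry are kept.
    """
    if not mirnas or not transcripts:
        raise ValueError("mirnas and transcripts must be nonempty")
    upe_lookup: dict[tuple[str, str, int], float] = {}
    if upe_table is not None:
        for row in upe_table.itertuples(index=False):
            upe_lookup[(row.mirna, row.transcript, int(row.position))] = float(row.upe)

    hits: list[TargetHit] = []
    for mid, mseq in mirnas.items():
        m = _normalize(mseq, f"miRNA {mid}")
        for tid, tseq in transcripts.items():
            t = _normalize(tseq, f"transcript {tid}")
            if len(t) < len(m):
                logger.info("transcript %s shorter than miRNA %s; skipped", tid, mid)
                continue
            windows = []
            for start in range(len(t) - len(m) + 1):
                site = t[start:start + len(m)]
                score, alignment = score_duplex(m, site)
                if score <= cutoff:
                    windows.append((start, score, site, alignment))
            for start, score, site, alignment in _reduce_overlaps(windows, len(m)):
                upe = upe_lookup.get((mid, tid, start))
                if upe is not None and upe > upe_max:
                    continue
                hits.append(
                    TargetHit(
                        mirna=mid,
                        transcript=tid,
                        target_start=start,
                        target_end=start + len(m),
                        expectation=score,
                        inhibition=("cleavage" if _central_paired(m, site)
                                    else "translation"),
                        upe=upe,
                        alignment=alignment,
                    )
                )
    return hits


def _reduce_overlaps(windows: list[tuple], length: int) -> list[tuple]:
    """Greedy reduction of overlapping windows to the best-scoring one
    (ties broken leftmost)."""
    chosen: list[tuple] = []
    for win in sorted(windows, key=lambda w: (w[1], w[0])):
        if all(abs(win[0] - c[0]) >= length for c in chosen):
            chosen.append(win)
    return sorted(chosen, key=lambda w: w[0])


def hits_to_frame(hits: Iterable[TargetHit]) -> pd.DataFrame:
    rows = [
        {
            "mirna": h.mirna,
            "transcript": h.transcript,
            "target_start": h.target_start,
            "target_end": h.target_end,
            "expectation": h.expectation,
            "inhibition": h.inhibition,
            "upe": h.upe,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["mirna", "transcript", "target_start", "target_end",
                 "expectation", "inhibition", "upe"],
    )


def render_alignments(hits: Iterable[TargetHit]) -> str:
    """3-line text blocks (miRNA 3'->5', match line, target 5'->3')."""
    blocks = []
    for h in hits:
        if h.alignment is None:
            continue
        top, mid, bot = h.alignment
        blocks.append(
            f">{h.mirna} vs {h.transcript} @ {h.target_start} "
            f"expectation={h.expectation:g}\n"
            f"miRNA  3' {top} 5'\n"
            f"          {mid}\n"
            f"target 5' {bot} 3'\n"
        )
    return "\n".join(blocks)


def join_targets_to_de(
    hits: pd.DataFrame, de_mirna: pd.DataFrame, de_mrna: pd.DataFrame
) -> pd.DataFrame:
    """One row per (DE miRNA, target, time point) carrying both statuses.

    Non-DE miRNAs are excluded; targets missing from the mRNA DE table are
    reported as ``partner_undetected`` status with NaN fold change, and
    the count of unjoined hits is logged.
    """
    de_m = de_mirna[de_mirna["status"].isin(["up", "down"])]
    if de_m.empty or hits.empty:
        return pd.DataFrame(
            columns=["mirna", "transcript", "time", "mirna_log2fc", "mirna_status",
                     "target_log2fc", "target_status"]
        )
    joined = de_m.merge(hits[["mirna", "transcript"]].drop_duplicates(),
                        left_on="feature", right_on="mirna")
    mrna_idx = de_mrna.set_index(["feature", "time"])
    rows = []
    unjoined = 0
    for r in joined.itertuples(index=False):
        key = (r.transcript, r.time)
        if key in mrna_idx.index:
            tgt = mrna_idx.loc[key]
            tgt_lfc, tgt_status = float(tgt["log2fc"]), str(tgt["status"])
        else:
            unjoined += 1
            tgt_lfc, tgt_status = float("nan"), "undetected"
        rows.append(
            {
                "mirna": r.feature,
                "transcript": r.transcript,
                "time": r.time,
                "mirna_log2fc": r.log2fc,
                "mirna_status": r.status,
                "target_log2fc": tgt_lfc,
                "target_status": tgt_status,
            }
        )
    if unjoined:
        logger.warning("%d hit(s) had no mRNA DE record; treated as undetected",
                       unjoined)
    return pd.DataFrame(rows)
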