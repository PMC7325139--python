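"""Readers and writers for the on-disk formats.

Dialects: GFF3 is 1-based closed on disk and converted to the package's
0-based half-open internal coordinates; FASTA is wrapped at 80 columns;
TSVs are UTF-8 with a header row and '.' for missing values.
"""

from __future__ import annotations

import os
from typing import Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .catalog import Feature, LocusCatalog

MISSING = "."


class FormatError(ValueError):
    """A malformed record in an input file (carries the line number)."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | os.PathLike) -> LocusCatalog:
    """Read a locus catalog from GFF3 (1-based closed -> 0-based half-open)."""
    features = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                gf = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(f"malformed GFF3 record: {exc}", lineno) from exc
            if gf.end < gf.start:
                raise FormatError(f"end < start for feature at {gf.seqid}", lineno)
            attrs = gf.attributes
            fid = attrs.get("ID", [None])[0]
            if fid is None:
                raise FormatError("missing ID attribute", lineno)
            rna_class = attrs.get("rna_class", ["other"])[0]
            partner = attrs.get("partner_id", [None])[0]
            family = attrs.get("family", [None])[0]
            features.append(
                Feature(
                    id=fid,
                    chrom=gf.seqid,
                    start=gf.start - 1,
                    end=gf.end,
                    strand=gf.strand if gf.strand in ("+", "-") else "+",
                    rna_class=rna_class,
                    partner_id=partner,
                    family=family,
                )
            )
    return LocusCatalog(features=features)


def write_gff3(catalog: LocusCatalog, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in catalog:
            attrs = [f"ID={f.id}", f"rna_class={f.rna_class}"]
            if f.partner_id is not None:
                attrs.append(f"partner_id={f.partner_id}")
            if f.family is not None:
                attrs.append(f"family={f.family}")
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        "coldsrna",
                        "region",
                        str(f.start + 1),
                        str(f.end),
                        MISSING,
                        f.strand,
                        MISSING,
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# TSV tables


def read_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Counts TSV: feature rows x sample columns, nonnegative integers."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.has_duplicates:
        raise FormatError("duplicate feature ids in count table")
    if (counts.values < 0).any():
        raise FormatError("negative values in count table")
    return counts.astype("int64")


def write_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts.to_csv(path, sep="\t", index_label="feature")


REQUIRED_DESIGN_COLUMNS = ("sample", "condition", "time", "replicate")


def read_design(path: str | os.PathLike) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FormatError(f"design sheet missing required columns: {missing}")
    return design


def write_design(design: pd.DataFrame, path: str | os.PathLike) -> None:
    design.to_csv(path, sep="\t", index=False)


def write_table(table: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index, na_rep=MISSING)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[MISSING])


# ---------------------------------------------------------------------------
# Truth files (flat key\tvalue text)


def write_truth(records: Mapping[str, list[str]], path: str | os.PathLike) -> None:
    """Each key maps to a list of tab-joined record strings."""
    with open(path, "w") as fh:
        for key in sorted(records):
            for value in records[key]:
                fh.write(f"{key}\t{value}\n")


def read_truth(path: str | os.PathLike) -> dict[str, list[str]]:
    records: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            key, _, value = line.partition("\t")
            records.setdefault(key, []).append(value)
    return records
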