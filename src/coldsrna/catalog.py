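"""Locus catalog: genomic features typed by RNA class, with NAT pairings.

Coordinates are 0-based half-open internally; GFF3 round-tripping in
:mod:`coldsrna.io` converts to/from the 1-based closed on-disk dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

RNA_CLASSES = (
    "miRNA",
    "cis_NAT",
    "trans_NAT",
    "lncRNA",
    "TAS",
    "PHAS",
    "tRNA_like",
    "TE_repeat",
    "other",
)

#: Precedence used when an sRNA cluster overlaps loci of several classes
#: (highest wins). "other" never wins over an annotated class.
CLASS_PRECEDENCE = (
    "miRNA",
    "cis_NAT",
    "trans_NAT",
    "TAS",
    "PHAS",
    "lncRNA",
    "tRNA_like",
    "TE_repeat",
    "other",
)


@dataclass(frozen=True)
class Feature:
    """One catalog feature (locus or transcript)."""

    id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # "+" or "-"
    rna_class: str
    partner_id: Optional[str] = None
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.id}: invalid strand {self.strand!r}")
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"feature {self.id}: unknown rna_class {self.rna_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int, chrom: Optional[str] = None) -> int:
        """Overlap length with a 0-based half-open interval (0 if disjoint)."""
        if chrom is not None and chrom != self.chrom:
            return 0
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class LocusCatalog:
    """Collection of typed features with symmetric NAT pairings."""

    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {f.id: f for f in self.features}
        if len(self._by_id) != len(self.features):
            raise ValueError("duplicate feature ids in catalog")
        self.validate()

    def validate(self) -> None:
        for f in self.features:
            if f.partner_id is None:
                continue
            partner = self._by_id.get(f.partner_id)
            if partner is None:
                raise ValueError(f"feature {f.id}: dangling partner {f.partner_id}")
            if partner.partner_id != f.id:
                raise ValueError(f"partner link {f.id}<->{f.partner_id} not symmetric")
            if f.rna_class == "cis_NAT":
                if f.strand == partner.strand:
                    raise ValueError(f"cis-NAT pair {f.id}/{partner.id} on same strand")
                if f.overlap(partner.start, partner.end, partner.chrom) == 0:
                    raise ValueError(f"cis-NAT pair {f.id}/{partner.id} does not overlap")
            if f.rna_class == "trans_NAT":
                if f.overlap(partner.start, partner.end, partner.chrom) > 0:
                    raise ValueError(f"trans-NAT pair {f.id}/{partner.id} overlaps")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[Feature]:
        return iter(self.features)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._by_id

    def get(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def by_class(self, rna_class: str) -> list[Feature]:
        return [f for f in self.features if f.rna_class == rna_class]

    def nat_pairs(self, kind: str) -> list[tuple[Feature, Feature]]:
        """Unique (A, B) partner pairs of the given kind ('cis' or 'trans')."""
        cls = {"cis": "cis_NAT", "trans": "trans_NAT"}[kind]
        pairs = []
        seen: set[str] = set()
        for f in self.features:
            if f.rna_class != cls or f.partner_id is None or f.id in seen:
                continue
            partner = self._by_id[f.partner_id]
            seen.update((f.id, partner.id))
            pairs.append((f, partner))
        return pairs

    @classmethod
    def from_features(cls, features: Iterable[Feature]) -> "LocusCatalog":
        return cls(features=list(features))
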