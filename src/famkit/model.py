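"""Core domain types shared across the toolkit.

Coordinate convention: genomic intervals are 1-based and fully closed
(start and end are both included), matching the annotation tables the
readers consume. All interval arithmetic in the package states this
convention explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from famkit.errors import FamkitError, UndefinedRatioError

#: Reserved sentinel for genes not placed on any chromosome. A free
#: chromosome label is any other non-empty string ("Ca1".."Ca8", ...).
UNPLACED = "UNPLACED"

_DNA_ALPHABET = set("ACGTRYSWKMBDHVN")
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class GeneRecord:
    """One row of a gene-family annotation table."""

    name: str
    locus_id: str
    protein_id: str
    chromosome: str
    start: int | None
    end: int | None
    strand: str  # "+", "-", or "." (unknown)
    protein_length: int
    pi: float
    mol_wt: float  # kilodaltons
    exon_count: int
    isoform_count: int

    def __post_init__(self) -> None:
        if self.chromosome == UNPLACED:
            if self.start is not None or self.end is not None:
                raise FamkitError(
                    f"{self.name}: unplaced record must not carry coordinates"
                )
        else:
            if self.start is None or self.end is None:
                raise FamkitError(f"{self.name}: placed record requires coordinates")
            if self.start > self.end:
                raise FamkitError(f"{self.name}: start > end ({self.start} > {self.end})")
        if self.protein_length <= 0:
            raise FamkitError(f"{self.name}: protein_length must be positive")
        if self.exon_count < 1:
            raise FamkitError(f"{self.name}: exon_count must be >= 1")
        if self.isoform_count < 1:
            raise FamkitError(f"{self.name}: isoform_count must be >= 1")
        if self.strand not in {"+", "-", "."}:
            raise FamkitError(f"{self.name}: invalid strand {self.strand!r}")

    @property
    def placed(self) -> bool:
        return self.chromosome != UNPLACED


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or amino-acid sequence."""

    id: str
    seq: str
    kind: str = "dna"  # "dna" | "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise FamkitError("sequence record requires a non-empty id")
        if not self.seq:
            raise FamkitError(f"{self.id}: empty sequence")
        alphabet = _DNA_ALPHABET if self.kind == "dna" else _PROTEIN_ALPHABET
        bad = set(self.seq.upper()) - alphabet - {"-"}
        if bad:
            raise FamkitError(
                f"{self.id}: residues {sorted(bad)} not in {self.kind} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Motif:
    """A named IUPAC nucleotide pattern."""

    name: str
    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise FamkitError(f"motif {self.name!r}: empty pattern")
        from famkit.cre import IUPAC_SETS  # local import avoids a cycle

        for i, sym in enumerate(self.pattern.upper(), start=1):
            if sym not in IUPAC_SETS:
                raise FamkitError(
                    f"motif {self.name!r}: invalid IUPAC code {sym!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.pattern)


# Selection modes for duplicate gene pairs.
POSITIVE = "positive"
PURIFYING_OR_DRIFT = "purifying_or_drift"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class DuplicatePair:
    """A duplicated gene pair with substitution-rate statistics.

    ``ratio`` is Ka/Ks and is ``None`` (flagged, not fabricated) when
    Ks = 0; ``time_mya`` is the Ks-based divergence time in million
    years; ``mode`` is the selection-mode call.
    """

    gene_a: str
    gene_b: str
    ka: float
    ks: float
    ratio: float | None = None
    time_mya: float | None = None
    mode: str | None = None

    def __post_init__(self) -> None:
        if self.ka < 0 or self.ks < 0:
            raise FamkitError(f"{self.gene_a}/{self.gene_b}: Ka and Ks must be >= 0")
        if self.time_mya is not None and self.time_mya < 0:
            raise FamkitError(f"{self.gene_a}/{self.gene_b}: negative divergence time")

    @property
    def ratio_defined(self) -> bool:
        return self.ks > 0

    def require_ratio(self) -> float:
        if not self.ratio_defined or self.ratio is None or math.isnan(self.ratio):
            raise UndefinedRatioError(
                f"{self.gene_a}/{self.gene_b}: Ka/Ks undefined (Ks = 0)"
            )
        return self.ratio


_DOMAIN_ORDER = ("B3", "AUX_RESP", "III", "IV")


@dataclass(frozen=True)
class DomainAnnotation:
    """Residue spans (1-based, inclusive) of the conserved subdomains.

    Valid spans are non-overlapping and ordered B3 < AUX_RESP < III < IV
    where present.
    """

    protein_id: str
    spans: Mapping[str, tuple[int, int]]
    source: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.spans) - set(_DOMAIN_ORDER)
        if unknown:
            raise FamkitError(f"{self.protein_id}: unknown domains {sorted(unknown)}")
        prev_end = 0
        for dom in _DOMAIN_ORDER:
            if dom not in self.spans:
                continue
            s, e = self.spans[dom]
            if s < 1 or e < s:
                raise FamkitError(f"{self.protein_id}: bad span for {dom}: ({s}, {e})")
            if s <= prev_end:
                raise FamkitError(
                    f"{self.protein_id}: domain {dom} overlaps or precedes an earlier domain"
                )
            prev_end = e

    def has(self, domain: str) -> bool:
        return domain in self.spans


@dataclass
class Fixture:
    """A packaged, hand-curated transcription of a printed table."""

    name: str
    payload: list = field(default_factory=list)
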