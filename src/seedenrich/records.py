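"""Core sequence records for miRNA target-site analysis.

Mature miRNAs are held in the RNA alphabet (5'->3'); 3'UTRs are held in the
DNA alphabet in mRNA sense (5'->3'), the convention of UTR FASTA exports.
All site matching is done in DNA space after normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "SequenceAlphabetError",
    "SequenceLengthError",
    "MatureMiRNA",
    "UTRRecord",
    "SiteMatch",
    "UTRPool",
    "normalize_rna",
    "normalize_dna",
    "reverse_complement_dna",
    "SITE_TYPES",
]

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_CHARS = frozenset("ACGU")
# IUPAC nucleotide codes tolerated in UTR input; ambiguity codes never match a seed.
_DNA_CHARS = frozenset("ACGTRYSWKMBDHVN")


class SequenceAlphabetError(ValueError):
    """Sequence contains characters outside the accepted nucleotide alphabet."""


class SequenceLengthError(ValueError):
    """Sequence is too short for the requested operation."""


def normalize_rna(sequence: str) -> str:
    """Uppercase a miRNA sequence and map T->U; reject non-ACGU characters."""
    seq = sequence.strip().upper().replace("T", "U")
    bad = set(seq) - _RNA_CHARS
    if bad:
        raise SequenceAlphabetError(
            f"invalid miRNA characters {sorted(bad)!r}; expected ACGU (T accepted)"
        )
    return seq


def normalize_dna(sequence: str) -> str:
    """Uppercase a UTR sequence and map U->T; reject non-IUPAC characters."""
    seq = sequence.strip().upper().replace("U", "T")
    bad = set(seq) - _DNA_CHARS
    if bad:
        raise SequenceAlphabetError(
            f"invalid UTR characters {sorted(bad)!r}; expected IUPAC DNA codes"
        )
    return seq


def reverse_complement_dna(sequence: str) -> str:
    return sequence.translate(_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatureMiRNA:
    """A named mature miRNA sequence, 5'->3', RNA alphabet.

    The seed is nucleotides 2-8 (1-based, inclusive), the region whose
    Watson-Crick complement in a 3'UTR defines the canonical site types.
    """

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("miRNA name must be non-empty")
        seq = normalize_rna(self.sequence)
        if len(seq) < 8:
            raise SequenceLengthError(
                f"miRNA {self.name!r} is {len(seq)} nt; need >= 8 nt to define a seed"
            )
        object.__setattr__(self, "sequence", seq)

    @property
    def seed(self) -> str:
        """Seed region: positions 2-8 of the mature sequence (length 7)."""
        return self.sequence[1:8]


@dataclass(frozen=True)
class UTRRecord:
    """One gene's 3'UTR in mRNA sense, DNA alphabet."""

    gene_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        seq = normalize_dna(self.sequence)
        if len(seq) < 1:
            raise SequenceLengthError(f"UTR for {self.gene_id!r} is empty")
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteMatch:
    """One predicted miRNA recognition element in a 3'UTR.

    Coordinates are 0-based, half-open, on the UTR (mRNA sense).
    """

    gene_id: str
    mirna_name: str
    start: int
    end: int
    site_type: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        width = self.end - self.start
        expected = 8 if self.site_type == "8mer" else 7
        if width != expected:
            raise ValueError(
                f"{self.site_type} site must span {expected} nt, got {width}"
            )
        if self.start < 0:
            raise ValueError("site start must be >= 0")


class UTRPool:
    """An ordered collection of UTRRecords with unique gene ids."""

    def __init__(self, records: Iterable[UTRRecord] = ()) -> None:
        self._records: dict[str, UTRRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: UTRRecord) -> None:
        if record.gene_id in self._records:
            raise ValueError(f"duplicate gene_id {record.gene_id!r} in UTR pool")
        self._records[record.gene_id] = record

    def __getitem__(self, gene_id: str) -> UTRRecord:
        try:
            return self._records[gene_id]
        except KeyError:
            raise KeyError(f"gene_id {gene_id!r} not present in UTR pool") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._records

    def __iter__(self) -> Iterator[UTRRecord]:
        return iter(self._records.values())

    def __len__(self) -> int:
        return len(self._records)

    @property
    def gene_ids(self) -> list[str]:
        return list(self._records)

    def subset(self, gene_ids: Iterable[str]) -> "UTRPool":
        return UTRPool(self[g] for g in gene_ids)
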