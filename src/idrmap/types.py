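"""Core domain types shared by every analysis stage.

All coordinates held by these types are 0-based half-open: residue and
nucleotide intervals ``[start, end)``, genomic bp intervals likewise.
File readers in :mod:`idrmap.io` perform the (single) conversion from the
1-based inclusive conventions of GFF3 and the TSV dialects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: the 20 standard amino acids plus the ambiguity letter X
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
#: nucleotides accepted in coding sequences; N counts as non-GC
NT_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """An input file violates its declared dialect."""


class PairingError(ValueError):
    """A protein/CDS pair is incompatible (length mismatch or missing mate)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: an amino-acid sequence without stop symbol."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise FormatError(
                f"protein {self.id!r}: illegal residue letters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsRecord:
    """Spliced coding sequence paired to a protein by identical id."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"CDS {self.id!r}: empty sequence")
        bad = set(self.sequence) - NT_ALPHABET
        if bad:
            raise FormatError(f"CDS {self.id!r}: illegal bases {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(eq=False)
class DisorderMask:
    """Per-residue binary disorder call for one protein.

    ``calls[i]`` is True when residue ``i`` (0-based) is predicted
    disordered.  The vector length must equal the protein length.
    """

    protein_id: str
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=bool)
        if self.calls.ndim != 1:
            raise FormatError(f"mask {self.protein_id!r}: calls must be 1-D")

    def __len__(self) -> int:
        return int(self.calls.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DisorderMask):
            return NotImplemented
        return self.protein_id == other.protein_id and np.array_equal(
            self.calls, other.calls
        )


@dataclass(frozen=True)
class Segment:
    """A maximal run of disordered residues, ``[start, end)`` on the protein."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"segment {self.protein_id!r}: bad interval [{self.start},{self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DomainAnnotation:
    """A structural-domain hit on a protein, residue interval ``[start, end)``."""

    protein_id: str
    domain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"domain {self.domain_id!r} on {self.protein_id!r}: "
                f"bad interval [{self.start},{self.end})"
            )


@dataclass(frozen=True)
class GeneLocus:
    """Genomic placement of one gene, bp interval ``[start, end)``."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    protein_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneticMapInterval:
    """One empirically mapped chromosome fragment and its genetic length in cM."""

    chromosome: str
    start: int
    end: int
    cm: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"map interval {self.chromosome}:{self.start}-{self.end}: empty"
            )
        if self.cm < 0:
            raise FormatError(
                f"map interval {self.chromosome}:{self.start}-{self.end}: "
                f"negative cM {self.cm}"
            )

    @property
    def length_mb(self) -> float:
        return (self.end - self.start) / 1e6


@dataclass(frozen=True)
class ParalogPair:
    """An unordered pair of protein ids related by duplication (or speciation)."""

    id_a: str
    id_b: str

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise FormatError(f"paralog pair with identical members {self.id_a!r}")
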