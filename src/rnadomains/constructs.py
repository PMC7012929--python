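"""Sequence bookkeeping, in-vitro transcript construction and dosing arithmetic.

Everything user-facing here is 1-based and inclusive, matching the
"250-302"-style coordinates used in molecular-biology figure legends.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "RnaSequence",
    "TranscriptConstruct",
    "DosingSpec",
    "interval_length",
    "subfragment",
    "reverse_complement_to_rna",
    "build_t7_construct",
    "equivalent_concentration",
    "mass_concentration",
    "read_fasta",
    "write_fasta",
]

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

#: Mean residue mass used for molar <-> mass conversions, g/mol per
#: nucleotide residue of single-stranded RNA (conventional value for an
#: internal NMP residue; the true figure varies slightly with composition).
DEFAULT_RESIDUE_MASS = 320.5

# Accept both ASCII '-' and the typographic minus that figure legends use.
_STRAND_MINUS = {"-", "−", "–"}
_INTERVAL_RE = re.compile(
    r"^(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)"
    r"(?:\((?P<strand>[+\-−–])\))?$"
)


class IntervalParseError(ValueError):
    """Raised when an interval string cannot be parsed."""


class AlphabetError(ValueError):
    """Raised on residues outside the expected alphabet."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval such as ``chr6:151937260-151937915(-)``."""

    chrom: str
    start: int
    end: int
    strand: Literal["+", "-"] = "+"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        """Parse ``chrom:start-end`` with an optional ``(+)``/``(-)`` suffix."""
        m = _INTERVAL_RE.match(text.strip())
        if m is None:
            raise IntervalParseError(
                f"cannot parse interval {text!r}: expected 'chrom:start-end(strand)'"
            )
        strand = m.group("strand") or "+"
        if strand in _STRAND_MINUS:
            strand = "-"
        try:
            return cls(m.group("chrom"), int(m.group("start")), int(m.group("end")), strand)
        except ValueError as exc:
            raise IntervalParseError(f"invalid interval {text!r}: {exc}") from exc

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"

    def to_bed_fields(self) -> tuple[str, int, int, str]:
        """Return (chrom, chromStart, chromEnd, strand) in 0-based half-open BED convention."""
        return self.chrom, self.start - 1, self.end, self.strand


def interval_length(interval: GenomicInterval | str) -> int:
    """Length in nucleotides of a 1-based inclusive interval (end - start + 1)."""
    if isinstance(interval, str):
        interval = GenomicInterval.parse(interval)
    return len(interval)


def _normalize_rna(residues: str) -> str:
    s = residues.upper().replace("T", "U")
    bad = set(s) - RNA_ALPHABET
    if bad:
        raise AlphabetError(
            f"invalid residue(s) {sorted(bad)}: RNA alphabet is A, C, G, U "
            "(T is accepted and converted)"
        )
    return s


@dataclass(frozen=True)
class RnaSequence:
    """An identified RNA sequence over {A, C, G, U}, positions 1-based.

    ``T`` (DNA templates) and lower case are silently normalized on
    construction.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", _normalize_rna(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def subfragment(seq: RnaSequence, start: int, end: int) -> RnaSequence:
    """Residues ``start..end`` inclusive (1-based), as a new sequence.

    The fragment id records the coordinates, e.g. ``Eleanor2[320-447]``.
    """
    if not (1 <= start <= end <= len(seq)):
        raise IndexError(
            f"fragment {start}-{end} out of range for sequence of length {len(seq)}"
        )
    return RnaSequence(id=f"{seq.id}[{start}-{end}]", residues=seq.residues[start - 1 : end])


_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement_to_rna(dna: str, id: str = "rc") -> RnaSequence:
    """Reverse-complement a DNA string and transcribe it to RNA (T -> U).

    Used to obtain the RNA encoded on the minus strand of a genomic
    reference sequence.
    """
    s = dna.upper()
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise AlphabetError(f"invalid DNA residue(s) {sorted(bad)}: expected A, C, G, T")
    rc = s.translate(_DNA_COMPLEMENT)[::-1]
    return RnaSequence(id=id, residues=rc.replace("T", "U"))


#: 3'-terminal trinucleotide left on a run-off T7 transcript after template
#: linearization with each blunt-cutting enzyme.
ENZYME_THREE_PRIME = {"EcoRV": "GAC", "NruI": "UCG"}
T7_FIVE_PRIME = "GGG"


@dataclass(frozen=True)
class TranscriptConstruct:
    """A run-off T7 in-vitro transcript: GGG + insert + enzyme-derived 3' end."""

    insert: RnaSequence
    five_prime_addition: str
    three_prime_addition: str

    @property
    def full_sequence(self) -> RnaSequence:
        return RnaSequence(
            id=f"{self.insert.id}|T7",
            residues=self.five_prime_addition + self.insert.residues + self.three_prime_addition,
        )

    def __len__(self) -> int:
        return len(self.insert) + len(self.five_prime_addition) + len(self.three_prime_addition)


def build_t7_construct(insert: RnaSequence, enzyme: str) -> TranscriptConstruct:
    """Model the termini of a T7 run-off transcript.

    T7 initiation from the promoter adds ``GGG`` at the 5' end; run-off at a
    blunt restriction site leaves ``GAC`` (EcoRV) or ``UCG`` (NruI) at the 3'
    end, so the transcript is always 6 nt longer than the insert.
    """
    if len(insert) == 0:
        raise ValueError("insert must be non-empty")
    try:
        tail = ENZYME_THREE_PRIME[enzyme]
    except KeyError:
        raise ValueError(
            f"unknown linearization enzyme {enzyme!r}; expected one of "
            f"{sorted(ENZYME_THREE_PRIME)}"
        ) from None
    return TranscriptConstruct(
        insert=insert, five_prime_addition=T7_FIVE_PRIME, three_prime_addition=tail
    )


@dataclass(frozen=True)
class DosingSpec:
    """A concentration-equivalence rule anchored to a reference RNA.

    ``equimolar_nucleotides`` matches the total molar amount of nucleotide
    residues; ``equal_mass`` matches the mass concentration.  Under a single
    mean residue mass the two reduce to the same length ratio, so both modes
    return ``reference_concentration * reference_length / target_length``.
    """

    reference_length: int
    reference_concentration: float  # uM
    mode: Literal["equimolar_nucleotides", "equal_mass"] = "equimolar_nucleotides"
    residue_mass: float = DEFAULT_RESIDUE_MASS  # g/mol per residue

    def __post_init__(self) -> None:
        if self.reference_length < 1:
            raise ValueError(f"reference_length must be >= 1, got {self.reference_length}")
        if self.reference_concentration <= 0:
            raise ValueError(
                f"reference_concentration must be > 0, got {self.reference_concentration}"
            )
        if self.mode not in ("equimolar_nucleotides", "equal_mass"):
            raise ValueError(f"unknown dosing mode {self.mode!r}")
        if self.residue_mass <= 0:
            raise ValueError(f"residue_mass must be > 0, got {self.residue_mass}")


def equivalent_concentration(spec: DosingSpec, target_length: int) -> float:
    """Molar concentration (uM) of a target RNA equivalent to the reference.

    In ``equimolar_nucleotides`` mode the product concentration x length (the
    nucleotide molarity) is conserved; in ``equal_mass`` mode the mass
    concentration is conserved, which under a common mean residue mass gives
    the identical length-ratio formula.
    """
    if target_length < 1:
        raise ValueError(f"target_length must be >= 1, got {target_length}")
    return spec.reference_concentration * spec.reference_length / target_length


def mass_concentration(spec: DosingSpec) -> float:
    """Mass concentration (ng/ul) of the reference RNA itself.

    ng/ul = uM x length x residue mass / 1000; used e.g. to dose a
    homopolymer sold by weight at the same mass concentration as a molar
    reference.
    """
    return spec.reference_concentration * spec.reference_length * spec.residue_mass / 1000.0


class FastaParseError(ValueError):
    """Raised on malformed FASTA input."""


def read_fasta(path: str | Path, rna: bool = True) -> list[RnaSequence]:
    """Read a (multi-record) FASTA file.

    With ``rna=True`` (default) T is converted to U and lower case upcased;
    residues outside the alphabet raise :class:`AlphabetError`.
    """
    path = Path(path)
    records: list[RnaSequence] = []
    with path.open() as handle:
        first = handle.readline()
        if first and not first.startswith(">") and first.strip():
            raise FastaParseError(f"{path}:1: sequence data before first FASTA header")
        handle.seek(0)
        for rec in SeqIO.parse(handle, "fasta"):
            residues = str(rec.seq)
            if not rna:
                residues = residues.upper()
            records.append(RnaSequence(id=rec.id, residues=residues))
    return records


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    """Write sequences as unwrapped FASTA records."""
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    with Path(path).open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=None)
        writer.write_file(records)
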