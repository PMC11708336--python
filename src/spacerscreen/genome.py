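"""Coordinate, strand, and transcription-region semantics.

All coordinates in this package are 0-based, half-open ``[start, end)``
intervals on the plus strand of a replicon.  A "minus-strand" spacer is a
spacer whose sequence is identical to the reverse complement of the
plus-strand substring over its interval; its crRNA (equal in sequence to the
spacer) therefore base-pairs with transcripts read off the plus strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PLUS = "+"
MINUS = "-"

_DNA_RE = re.compile(r"^[ACGT]*$")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, context: str = "sequence") -> None:
    """Raise ``ValueError`` naming the first offending position if ``seq``
    contains characters outside {A, C, G, T}."""
    if not _DNA_RE.match(seq):
        for i, ch in enumerate(seq):
            if ch not in "ACGT":
                raise ValueError(
                    f"{context} contains non-ACGT character {ch!r} at position {i}"
                )


class UnmappedSpacerError(ValueError):
    """Raised when an operation requires a spacer mapped to a given genome."""


@dataclass(frozen=True)
class OperonRegion:
    """A transcribed interval with the strand of its mRNA and the time
    (minutes post-infection) at which its promoter fires.

    ``strand`` is the genome strand whose sequence equals the mRNA.
    """

    start: int
    end: int
    strand: str
    activation_time: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"operon {self.name!r}: start {self.start} >= end {self.end}")
        if self.activation_time < 0:
            raise ValueError(f"operon {self.name!r}: negative activation_time")
        if self.strand not in (PLUS, MINUS):
            raise ValueError(f"operon {self.name!r}: strand must be '+' or '-'")

    def __contains__(self, position: int) -> bool:
        return self.start <= position < self.end

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeAnnotation:
    """A replicon sequence plus an operon map defining what is transcribed when."""

    name: str
    sequence: str
    operons: list[OperonRegion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        validate_dna(self.sequence, f"genome {self.name!r}")
        for op in self.operons:
            if op.start < 0 or op.end > self.length:
                raise ValueError(
                    f"operon {op.name!r} [{op.start},{op.end}) outside genome "
                    f"{self.name!r} of length {self.length}"
                )
        # same-strand operons must not overlap
        for strand in (PLUS, MINUS):
            ops = sorted(
                (o for o in self.operons if o.strand == strand), key=lambda o: o.start
            )
            for a, b in zip(ops, ops[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"operons {a.name!r} and {b.name!r} overlap on strand {strand}"
                    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def operon_at(self, position: int) -> OperonRegion | None:
        """The operon whose interval contains ``position``, or None."""
        for op in self.operons:
            if position in op:
                return op
        return None

    def subsequence(self, start: int, end: int, strand: str = PLUS) -> str:
        """Sequence of ``[start, end)`` as read on ``strand``."""
        sub = self.sequence[start:end]
        return sub if strand == PLUS else reverse_complement(sub)


@dataclass(frozen=True)
class SpacerRecord:
    """A spacer with its placement on a source replicon.

    ``strand`` is the genome strand to which the spacer sequence is identical;
    ``source`` is the replicon name, or ``"unmapped"``.
    """

    sequence: str
    source: str = "unmapped"
    start: int = -1
    end: int = -1
    strand: str = PLUS
    duplicate: bool = False

    @property
    def mapped(self) -> bool:
        return self.source != "unmapped"

    @property
    def midpoint(self) -> int:
        """Integer midpoint; a tie at a region boundary falls downstream
        because intervals are half-open."""
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return len(self.sequence)


UNTRANSCRIBED = "untranscribed"


def _require_mapped(spacer: SpacerRecord, genome: GenomeAnnotation) -> None:
    if not spacer.mapped or spacer.source != genome.name:
        raise UnmappedSpacerError(
            f"spacer {spacer.sequence[:12]}... is not mapped to genome {genome.name!r} "
            f"(source={spacer.source!r})"
        )


def region_of(spacer: SpacerRecord, genome: GenomeAnnotation) -> str:
    """Label of the operon containing the spacer midpoint, else "untranscribed".

    The midpoint rule gives straddling spacers a single deterministic region.
    """
    _require_mapped(spacer, genome)
    op = genome.operon_at(spacer.midpoint)
    return op.name if op is not None else UNTRANSCRIBED


def is_targeting(spacer: SpacerRecord, genome: GenomeAnnotation) -> bool:
    """True iff the spacer's crRNA can base-pair with a transcript: its
    midpoint lies inside an operon and its strand is opposite to the operon's
    mRNA strand."""
    _require_mapped(spacer, genome)
    op = genome.operon_at(spacer.midpoint)
    return op is not None and spacer.strand != op.strand


def spacer_sequence_from_genome(
    genome: GenomeAnnotation, start: int, end: int, strand: str
) -> str:
    """Reconstruct a spacer sequence from its placement."""
    return genome.subsequence(start, end, strand)


# ---------------------------------------------------------------------------
# FASTA / BED-like TSV I/O

def read_genome_fasta(path: str | Path, operons: Iterable[OperonRegion] = ()) -> GenomeAnnotation:
    """Read the first record of a FASTA file as a GenomeAnnotation."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return GenomeAnnotation(name=record.id, sequence=str(record.seq), operons=list(operons))


def write_genome_fasta(genome: GenomeAnnotation, path: str | Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.name, description="")
    SeqIO.write([record], str(path), "fasta")


OPERON_TSV_COLUMNS = ["replicon", "start", "end", "name", "activation_time", "strand"]


def read_operon_tsv(path: str | Path, replicon: str | None = None) -> list[OperonRegion]:
    """Read a BED-like operon TSV (0-based half-open coordinates)."""
    df = pd.read_csv(path, sep="\t", comment="#", names=OPERON_TSV_COLUMNS, header=0)
    if replicon is not None:
        df = df[df["replicon"] == replicon]
    return [
        OperonRegion(
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            activation_time=float(r.activation_time),
            name=str(r.name),
        )
        for r in df.itertuples(index=False)
    ]


def write_operon_tsv(
    genome: GenomeAnnotation, path: str | Path, header_comment: str | None = None
) -> None:
    """Write the operon map as a BED-like TSV (0-based half-open)."""
    rows = [
        {
            "replicon": genome.name,
            "start": op.start,
            "end": op.end,
            "name": op.name,
            "activation_time": op.activation_time,
            "strand": op.strand,
        }
        for op in genome.operons
    ]
    df = pd.DataFrame(rows, columns=OPERON_TSV_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open\n")
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index=False)
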