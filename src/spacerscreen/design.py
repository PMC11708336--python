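"""Tiling spacer library design and 90-nt oligo construction.

A tiling library places a spacer of length ``k`` every ``step`` nucleotides
along the plus strand of a replicon; minus-strand spacers are the reverse
complements of the same windows, so both strands share one coordinate grid.
Each spacer is embedded in a synthesizable oligo:

    priming_left + bsai_left + left_repeat_homology
        + spacer + right_repeat_homology + bsai_right + priming_right

The BsaI sites (GGTCTC) are oriented so that Golden Gate digestion releases
the spacer flanked by repeat-homology overhangs; the plus- and minus-strand
schemes carry distinct priming sequences so the two sub-pools can be
amplified separately.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import (
    PLUS,
    MINUS,
    GenomeAnnotation,
    SpacerRecord,
    reverse_complement,
    validate_dna,
)

BSAI_SITE = "GGTCTC"

#: Default direct repeat shipped with the package.  The repeat of the
#: S. epidermidis type III-A array used in the screens is not public in the
#: sources this package draws on, so this is a synthetic stand-in: 30 nt,
#: non-palindromic, free of BsaI sites and of near-repeats of itself.
DEFAULT_REPEAT = "GATCAACGTACCTTAGCACGGCTCAAGTTA"


@dataclass(frozen=True)
class FlankScheme:
    """The five fixed segments surrounding a spacer in an oligo."""

    priming_left: str
    bsai_left: str
    left_repeat_homology: str
    right_repeat_homology: str
    bsai_right: str
    priming_right: str

    @property
    def total_flank_length(self) -> int:
        return (
            len(self.priming_left)
            + len(self.bsai_left)
            + len(self.left_repeat_homology)
            + len(self.right_repeat_homology)
            + len(self.bsai_right)
            + len(self.priming_right)
        )


def _default_schemes() -> dict[str, FlankScheme]:
    # Flank lengths 5+6+17 (left) and 17+6+4 (right) put a 35-nt spacer in a
    # 90-nt oligo.  Repeat-homology arms are the repeat's outermost segments,
    # mimicking the repeat-spacer-repeat junction created on integration.
    left_arm = DEFAULT_REPEAT[-17:]
    right_arm = DEFAULT_REPEAT[:17]
    return {
        PLUS: FlankScheme(
            priming_left="ACCTC",
            bsai_left=BSAI_SITE,
            left_repeat_homology=left_arm,
            right_repeat_homology=right_arm,
            bsai_right=reverse_complement(BSAI_SITE),
            priming_right="TGCA",
        ),
        MINUS: FlankScheme(
            priming_left="TTGCA",
            bsai_left=BSAI_SITE,
            left_repeat_homology=left_arm,
            right_repeat_homology=right_arm,
            bsai_right=reverse_complement(BSAI_SITE),
            priming_right="GCAT",
        ),
    }


@dataclass
class LibraryDesignConfig:
    spacer_length: int = 35
    step: int = 2
    strands: str = "both"  # both | plus | minus
    flank_schemes: dict[str, FlankScheme] = field(default_factory=_default_schemes)
    oligo_length: int | None = 90  # None disables the length check

    def __post_init__(self) -> None:
        if self.spacer_length < 15:
            raise ValueError("spacer_length must be >= 15")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.strands not in ("both", "plus", "minus"):
            raise ValueError("strands must be 'both', 'plus' or 'minus'")

    @property
    def selected_strands(self) -> list[str]:
        return {"both": [PLUS, MINUS], "plus": [PLUS], "minus": [MINUS]}[self.strands]


@dataclass
class SpacerLibrary:
    design: LibraryDesignConfig
    records: list[SpacerRecord]
    oligos: list[str]

    def __len__(self) -> int:
        return len(self.records)


def expected_record_count(genome_length: int, k: int, step: int, n_strands: int) -> int:
    """Closed-form spacer count: per strand, floor((L - k) / step) + 1."""
    return n_strands * ((genome_length - k) // step + 1)


def build_oligo(spacer: SpacerRecord, cfg: LibraryDesignConfig) -> str:
    """Assemble the synthesis oligo for one spacer.

    With an empty flank scheme the oligo degenerates to the bare spacer
    (pass-through mode); set ``oligo_length=None`` to permit that.
    """
    scheme = cfg.flank_schemes.get(spacer.strand)
    if scheme is None:
        raise ValueError(f"no flank scheme defined for strand {spacer.strand!r}")
    oligo = (
        scheme.priming_left
        + scheme.bsai_left
        + scheme.left_repeat_homology
        + spacer.sequence
        + scheme.right_repeat_homology
        + scheme.bsai_right
        + scheme.priming_right
    )
    if cfg.oligo_length is not None and len(oligo) != cfg.oligo_length:
        raise ValueError(
            f"flank scheme for strand {spacer.strand!r} yields a "
            f"{len(oligo)}-nt oligo, expected {cfg.oligo_length}"
        )
    return oligo


def design_tiling_library(
    genome: GenomeAnnotation, cfg: LibraryDesignConfig | None = None
) -> SpacerLibrary:
    """Design a tiling spacer library over ``genome``.

    Spacers start at plus-strand positions 0, step, 2*step, ... <= L - k on
    every selected strand; a minus-strand spacer over ``[p, p+k)`` is the
    reverse complement of the plus-strand window.  Spacer sequences occurring
    more than once in the design are kept but flagged as duplicates.
    """
    cfg = cfg or LibraryDesignConfig()
    k = cfg.spacer_length
    L = genome.length
    if L < k:
        raise ValueError(f"genome length {L} is shorter than spacer length {k}")
    validate_dna(genome.sequence, f"genome {genome.name!r}")

    records: list[SpacerRecord] = []
    for strand in cfg.selected_strands:
        for start in range(0, L - k + 1, cfg.step):
            window = genome.sequence[start : start + k]
            seq = window if strand == PLUS else reverse_complement(window)
            records.append(
                SpacerRecord(
                    sequence=seq, source=genome.name, start=start, end=start + k,
                    strand=strand,
                )
            )

    seen = Counter(r.sequence for r in records)
    records = [
        replace(r, duplicate=seen[r.sequence] > 1) if seen[r.sequence] > 1 else r
        for r in records
    ]
    oligos = [build_oligo(r, cfg) for r in records]
    return SpacerLibrary(design=cfg, records=records, oligos=oligos)


def extract_spacer_from_oligo(oligo: str, scheme: FlankScheme) -> str:
    """Substring between the repeat-homology arms of an oligo (round-trip check)."""
    left = len(scheme.priming_left) + len(scheme.bsai_left) + len(scheme.left_repeat_homology)
    right = len(scheme.right_repeat_homology) + len(scheme.bsai_right) + len(scheme.priming_right)
    return oligo[left : len(oligo) - right]


# ---------------------------------------------------------------------------
# Manifest / FASTA I/O

MANIFEST_COLUMNS = ["id", "replicon", "start", "end", "strand", "spacer_seq", "oligo_seq", "duplicate"]


def spacer_id(record: SpacerRecord) -> str:
    strand_tag = "p" if record.strand == PLUS else "m"
    return f"{record.source}:{record.start}-{record.end}:{strand_tag}"


def write_library_manifest(library: SpacerLibrary, path: str | Path) -> None:
    rows = [
        {
            "id": spacer_id(r),
            "replicon": r.source,
            "start": r.start,
            "end": r.end,
            "strand": r.strand,
            "spacer_seq": r.sequence,
            "oligo_seq": oligo,
            "duplicate": int(r.duplicate),
        }
        for r, oligo in zip(library.records, library.oligos)
    ]
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open\n")
        df.to_csv(fh, sep="\t", index=False)


def read_library_manifest(path: str | Path) -> list[SpacerRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        SpacerRecord(
            sequence=str(r.spacer_seq),
            source=str(r.replicon),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            duplicate=bool(r.duplicate),
        )
        for r in df.itertuples(index=False)
    ]


def write_oligo_fasta(library: SpacerLibrary, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(oligo), id=spacer_id(r), description="")
        for r, oligo in zip(library.records, library.oligos)
    ]
    SeqIO.write(records, str(path), "fasta")
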