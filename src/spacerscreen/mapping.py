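"""Mapping of acquired spacers to replicons and single-nucleotide RPM
coverage maps.

Acquired spacers are exact (or near-exact) copies of their protospacer, so
the mapper is a transparent k-mer-seeded exact/near-exact search: every
position of each replicon's plus strand is indexed by its k-mer; a spacer is
probed in both orientations with pigeonhole seeds (``max_mismatches + 1``
disjoint seeds guarantee at least one exact seed hit for any placement
within the mismatch budget), and candidate placements are verified by
full-length Hamming comparison.  A spacer with a single best placement is
``unique``; equally good placements at more than one locus make it
``ambiguous``; no placement within the budget leaves it ``unaligned``.

RPM tracks accumulate each uniquely aligned spacer's read count over every
position of its interval on its strand, then divide by (total uniquely
aligned reads across all replicons / 10^6) — "reads per million total
aligned reads" at single-nucleotide resolution.  Ambiguous spacers are
tallied but excluded from the tracks so no position is double-counted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .extract import CountTable
from .genome import MINUS, PLUS, GenomeAnnotation, reverse_complement

UNIQUE = "unique"
AMBIGUOUS = "ambiguous"
UNALIGNED = "unaligned"

DEFAULT_SEED_LENGTH = 11


@dataclass(frozen=True)
class SpacerAlignment:
    spacer: str
    status: str
    replicon: str | None = None
    start: int = -1
    end: int = -1
    strand: str = PLUS
    mismatches: int = -1
    reason: str = ""


class KmerIndex:
    """Exact k-mer positions over the plus strands of a set of replicons."""

    def __init__(self, replicons: list[GenomeAnnotation], seed_length: int = DEFAULT_SEED_LENGTH):
        if not replicons:
            raise ValueError("at least one replicon is required")
        self.seed_length = seed_length
        self.replicons = {g.name: g for g in replicons}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for g in replicons:
            seq = g.sequence
            for p in range(len(seq) - seed_length + 1):
                self._index.setdefault(seq[p : p + seed_length], []).append((g.name, p))

    def seed_hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _placements_for_oriented(
    index: KmerIndex, oriented: str, strand: str, max_mm: int
) -> list[tuple[str, int, str, int]]:
    """Candidate (replicon, start, strand, mismatches) for one orientation.

    ``oriented`` is the sequence as it would read on the plus strand.
    """
    k = index.seed_length
    n_seeds = max_mm + 1
    length = len(oriented)
    offsets = [i * k for i in range(n_seeds)]
    hits: dict[tuple[str, int], int] = {}
    for off in offsets:
        for name, pos in index.seed_hits(oriented[off : off + k]):
            start = pos - off
            genome = index.replicons[name]
            if start < 0 or start + length > genome.length:
                continue
            key = (name, start)
            if key in hits:
                continue
            mm = _hamming(genome.sequence[start : start + length], oriented)
            if mm <= max_mm:
                hits[key] = mm
    return [(name, start, strand, mm) for (name, start), mm in hits.items()]


def map_spacers(
    table: CountTable,
    replicons: list[GenomeAnnotation],
    max_mismatches: int = 0,
    index: KmerIndex | None = None,
) -> list[SpacerAlignment]:
    """Place every distinct spacer of ``table`` on both strands of every replicon."""
    index = index or KmerIndex(replicons)
    needed = (max_mismatches + 1) * index.seed_length
    alignments = []
    for spacer in sorted(table.counts):
        if len(spacer) < needed:
            alignments.append(
                SpacerAlignment(
                    spacer=spacer, status=UNALIGNED,
                    reason=f"shorter than {needed} nt required for seeding",
                )
            )
            continue
        candidates = _placements_for_oriented(index, spacer, PLUS, max_mismatches)
        candidates += _placements_for_oriented(
            index, reverse_complement(spacer), MINUS, max_mismatches
        )
        if not candidates:
            alignments.append(
                SpacerAlignment(spacer=spacer, status=UNALIGNED, reason="no placement")
            )
            continue
        best_mm = min(c[3] for c in candidates)
        best = [c for c in candidates if c[3] == best_mm]
        if len(best) > 1:
            alignments.append(SpacerAlignment(spacer=spacer, status=AMBIGUOUS, mismatches=best_mm))
        else:
            name, start, strand, mm = best[0]
            alignments.append(
                SpacerAlignment(
                    spacer=spacer, status=UNIQUE, replicon=name,
                    start=start, end=start + len(spacer), strand=strand, mismatches=mm,
                )
            )
    return alignments


@dataclass
class AcquisitionProfile:
    """Strand-separated single-nucleotide RPM tracks plus source tallies."""

    rpm: dict[str, dict[str, np.ndarray]]  # replicon -> strand -> per-position RPM
    aligned_reads: dict[str, int]  # replicon -> uniquely aligned read count
    ambiguous_reads: int
    unaligned_reads: int
    total_aligned: int

    def source_fractions(self) -> dict[str, float]:
        """Percent of uniquely aligned spacer reads per replicon."""
        if self.total_aligned == 0:
            return {name: float("nan") for name in self.aligned_reads}
        return {
            name: 100.0 * n / self.total_aligned for name, n in self.aligned_reads.items()
        }


def position_coverage_rpm(
    alignments: list[SpacerAlignment],
    table: CountTable,
    replicons: list[GenomeAnnotation],
) -> AcquisitionProfile:
    """Accumulate per-position RPM from unique alignments.

    Each unique alignment carrying count ``c`` adds ``c`` to every position of
    its interval on its strand; tracks are then divided by
    ``total uniquely aligned reads / 10^6``.
    """
    raw = {
        g.name: {PLUS: np.zeros(g.length), MINUS: np.zeros(g.length)} for g in replicons
    }
    aligned = {g.name: 0 for g in replicons}
    ambiguous = unaligned = 0
    for aln in alignments:
        c = table.counts.get(aln.spacer, 0)
        if aln.status == UNIQUE:
            raw[aln.replicon][aln.strand][aln.start : aln.end] += c
            aligned[aln.replicon] += c
        elif aln.status == AMBIGUOUS:
            ambiguous += c
        else:
            unaligned += c
    total = sum(aligned.values())
    if total == 0:
        raise ValueError("no uniquely aligned spacers")
    scale = total / 1e6
    rpm = {name: {s: v / scale for s, v in tracks.items()} for name, tracks in raw.items()}
    return AcquisitionProfile(
        rpm=rpm, aligned_reads=aligned, ambiguous_reads=ambiguous,
        unaligned_reads=unaligned, total_aligned=total,
    )


def source_fractions(
    alignments: list[SpacerAlignment],
    table: CountTable,
    replicons: list[GenomeAnnotation],
) -> dict[str, float]:
    """Percent of uniquely aligned spacer reads per replicon."""
    return position_coverage_rpm(alignments, table, replicons).source_fractions()


# ---------------------------------------------------------------------------
# I/O

def write_rpm_tsv(profile: AcquisitionProfile, path: str | Path) -> None:
    """Wiggle-style long TSV (replicon, position, strand, rpm); zeros omitted."""
    frames = []
    for name, tracks in profile.rpm.items():
        for strand, vals in tracks.items():
            nz = np.flatnonzero(vals)
            frames.append(
                pd.DataFrame(
                    {"replicon": name, "position": nz, "strand": strand, "rpm": vals[nz]}
                )
            )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["replicon", "position", "strand", "rpm"]
    )
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based; zero-RPM positions omitted\n")
        df.to_csv(fh, sep="\t", index=False)


def write_source_summary(profile: AcquisitionProfile, path: str | Path) -> None:
    summary = {
        "source_fractions_percent": profile.source_fractions(),
        "aligned_reads": profile.aligned_reads,
        "ambiguous_reads": profile.ambiguous_reads,
        "unaligned_reads": profile.unaligned_reads,
        "total_aligned": profile.total_aligned,
    }
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
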