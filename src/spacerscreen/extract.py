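"""Spacer recovery from CRISPR-array amplicon reads.

Amplicons of an expanded CRISPR array have the structure
``... DR spacer DR spacer DR ...`` where DR is the direct repeat.  Every
maximal stretch flanked by two DR matches contributes one spacer, and
consecutive spacers share the DR between them, so an array read
``DR S1 DR S2 DR`` yields both S1 and S2.

DR occurrences are located by full-length Hamming comparison (no indels),
with a configurable mismatch tolerance; overlapping candidate windows are
resolved greedily left-to-right, lowest mismatch count first (leftmost on
ties).  Reads are scanned in both orientations by default and hits from the
reverse-complement scan are reported in the forward amplicon orientation.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .genome import reverse_complement, validate_dna


@dataclass
class ExtractionConfig:
    repeat_seq: str
    max_repeat_mismatches: int = 1
    spacer_len_bounds: tuple[int, int] = (20, 50)
    search_both_orientations: bool = True

    def __post_init__(self) -> None:
        validate_dna(self.repeat_seq, "repeat_seq")
        if len(self.repeat_seq) < 12:
            raise ValueError("repeat_seq must be at least 12 nt")
        lo, hi = self.spacer_len_bounds
        if lo > hi:
            raise ValueError("spacer_len_bounds min must be <= max")


@dataclass
class CountTable:
    """Per-sample spacer -> read-count mapping with totals."""

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)
    total_reads: int = 0
    total_extracted: int = 0
    skipped_repeat_longer_than_read: int = 0
    skipped_bad_length: int = 0

    def add(self, spacer: str, n: int = 1) -> None:
        self.counts[spacer] = self.counts.get(spacer, 0) + n
        self.total_extracted += n

    def __len__(self) -> int:
        return len(self.counts)


def detected_unique_spacers(table: CountTable, min_count: int = 1) -> int:
    """Number of distinct spacer sequences seen at least ``min_count`` times."""
    return sum(1 for c in table.counts.values() if c >= min_count)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_repeat_occurrences(read: str, repeat: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """All non-overlapping DR placements in ``read`` as (position, mismatches).

    Candidate windows within ``max_mm`` Hamming distance are enumerated with a
    vectorized sliding-window comparison, then thinned greedily left-to-right
    taking the lowest-mismatch (leftmost on ties) window of each overlapping
    cluster.
    """
    L, R = len(read), len(repeat)
    if L < R:
        return []
    arr = _encode(read)
    windows = np.lib.stride_tricks.sliding_window_view(arr, R)
    mismatches = (windows != repeat).sum(axis=1)
    positions = np.flatnonzero(mismatches <= max_mm)
    if positions.size == 0:
        return []
    candidates = [(int(p), int(mismatches[p])) for p in positions]

    selected: list[tuple[int, int]] = []
    i = 0
    while i < len(candidates):
        # cluster: all candidates overlapping the current leftmost one
        j = i
        cluster_end = candidates[i][0] + R
        while j + 1 < len(candidates) and candidates[j + 1][0] < cluster_end:
            j += 1
        best = min(candidates[i : j + 1], key=lambda c: (c[1], c[0]))
        selected.append(best)
        # drop everything overlapping the selected window
        i = j + 1
        sel_end = best[0] + R
        while i < len(candidates) and candidates[i][0] < sel_end:
            i += 1
    return selected


def spacers_in_read(read: str, cfg: ExtractionConfig) -> tuple[list[str], int]:
    """Spacers flanked by two DR matches in one read.

    Returns ``(spacers, n_length_filtered)``; spacers from the
    reverse-complement scan are already in forward amplicon orientation.
    """
    repeat = _encode(cfg.repeat_seq)
    max_mm = cfg.max_repeat_mismatches
    lo, hi = cfg.spacer_len_bounds

    def scan(seq: str) -> tuple[list[str], int]:
        occ = find_repeat_occurrences(seq, repeat, max_mm)
        out, filtered = [], 0
        for (p1, _), (p2, _) in zip(occ, occ[1:]):
            s = seq[p1 + len(cfg.repeat_seq) : p2]
            if lo <= len(s) <= hi:
                out.append(s)
            elif len(s) > 0:
                filtered += 1
        return out, filtered

    spacers, filtered = scan(read)
    if cfg.search_both_orientations:
        rc_spacers, rc_filtered = scan(reverse_complement(read))
        spacers += rc_spacers
        filtered += rc_filtered
    return spacers, filtered


def extract_spacers(
    reads: Iterable[str], cfg: ExtractionConfig, sample_id: str = "sample"
) -> CountTable:
    """Aggregate spacer counts over an iterable of read sequences."""
    table = CountTable(sample_id=sample_id)
    rlen = len(cfg.repeat_seq)
    for read in reads:
        table.total_reads += 1
        if len(read) < rlen:
            table.skipped_repeat_longer_than_read += 1
            continue
        spacers, filtered = spacers_in_read(read.upper(), cfg)
        table.skipped_bad_length += filtered
        for s in spacers:
            table.add(s)
    return table


def iter_fastq_sequences(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (plain or gzip, Phred+33).

    A malformed record raises ``ValueError`` carrying the record index.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    index = 0
    with opener(path, "rt") as handle:
        try:
            for _title, seq, _qual in FastqGeneralIterator(handle):
                index += 1
                yield seq
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record at index {index}: {exc}") from exc


def extract_spacers_fastq(
    path: str | Path, cfg: ExtractionConfig, sample_id: str | None = None
) -> CountTable:
    """Run extraction over a FASTQ file."""
    sample_id = sample_id or Path(path).stem
    return extract_spacers(iter_fastq_sequences(path), cfg, sample_id=sample_id)


# ---------------------------------------------------------------------------
# I/O

def write_count_table(table: CountTable, path: str | Path, summary_path: str | Path | None = None) -> None:
    df = pd.DataFrame(
        sorted(table.counts.items()), columns=["spacer_seq", "count"]
    )
    with open(path, "w") as fh:
        fh.write(f"# sample: {table.sample_id}\n")
        df.to_csv(fh, sep="\t", index=False)
    if summary_path is not None:
        summary = {
            "sample_id": table.sample_id,
            "total_reads": table.total_reads,
            "total_extracted": table.total_extracted,
            "unique_spacers": len(table),
            "skipped_repeat_longer_than_read": table.skipped_repeat_longer_than_read,
            "skipped_bad_length": table.skipped_bad_length,
        }
        Path(summary_path).write_text(json.dumps(summary, indent=2) + "\n")


def read_count_table(path: str | Path, sample_id: str | None = None) -> CountTable:
    df = pd.read_csv(path, sep="\t", comment="#")
    counts = dict(zip(df["spacer_seq"].astype(str), df["count"].astype(int)))
    table = CountTable(sample_id=sample_id or Path(path).stem, counts=counts)
    table.total_extracted = int(sum(counts.values()))
    table.total_reads = table.total_extracted
    return table
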