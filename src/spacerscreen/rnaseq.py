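"""Time-course RNA-seq coverage: per-million normalization and early/late
operon calling.

The early/late promoter structure of a phage genome is recovered from stepped
coverage with a change-point rule: a position is "on" at a timepoint when its
smoothed normalized coverage exceeds ``threshold_factor`` times a baseline
estimate, taken as the smallest per-strand genome-wide median across
timepoints (the quietest timepoint; the per-timepoint median itself is not a
usable baseline because late in infection most of the genome is transcribed).
Each position's activation time is the earliest timepoint at which it is on;
maximal runs of constant activation time at least ``min_region`` long become
operons, so adjacent early and late regions are split at the activation
change-point.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import MINUS, PLUS, OperonRegion

Strand = str
#: timepoint (minutes) -> strand -> per-position values
CoverageValues = dict[float, dict[Strand, np.ndarray]]


@dataclass
class CoverageProfile:
    replicon: str
    length: int
    values: CoverageValues = field(default_factory=dict)
    is_normalized: bool = False

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.values)

    def total(self, timepoint: float) -> float:
        return float(sum(v.sum() for v in self.values[timepoint].values()))

    def normalized(self) -> "CoverageProfile":
        """Scale each timepoint so its total over both strands is 10^6."""
        if self.is_normalized:
            return self
        out: CoverageValues = {}
        for t in self.timepoints:
            total = self.total(t)
            if total <= 0:
                raise ValueError(
                    f"timepoint {t} of {self.replicon!r} has zero total coverage"
                )
            out[t] = {s: v * (1e6 / total) for s, v in self.values[t].items()}
        return CoverageProfile(
            replicon=self.replicon, length=self.length, values=out, is_normalized=True
        )


def normalize_coverage(raw: CoverageProfile) -> CoverageProfile:
    """Per-million scaling per timepoint (alias for ``CoverageProfile.normalized``)."""
    return raw.normalized()


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="same")


def call_operons(
    cov: CoverageProfile,
    threshold_factor: float = 5.0,
    smoothing_window: int = 501,
    min_region: int = 500,
    early_label: str = "early",
    late_label: str = "late",
) -> list[OperonRegion]:
    """Call transcribed regions and their activation times from a time course.

    Returns operons named ``early``/``late`` (suffixed when several share a
    tier): a region is early when it activates at the first timepoint of the
    course.  All-zero coverage yields an empty list.
    """
    if len(cov.timepoints) < 2:
        raise ValueError("operon calling needs at least 2 timepoints")
    if all(cov.total(t) == 0 for t in cov.timepoints):
        return []
    norm = cov.normalized()
    timepoints = norm.timepoints

    regions: list[OperonRegion] = []
    for strand in (PLUS, MINUS):
        if not all(strand in norm.values[t] for t in timepoints):
            continue
        smoothed = {t: _smooth(norm.values[t][strand], smoothing_window) for t in timepoints}
        # baseline: the quietest timepoint's genome-wide median on this strand
        baseline = min(float(np.median(norm.values[t][strand])) for t in timepoints)
        threshold = threshold_factor * baseline

        # per-position activation index: earliest timepoint the position is on
        activation_idx = np.full(norm.length, -1, dtype=np.int64)
        for i, t in reversed(list(enumerate(timepoints))):
            activation_idx[smoothed[t] > threshold] = i

        # maximal runs of constant activation time
        boundaries = np.flatnonzero(np.diff(activation_idx) != 0) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [norm.length]])
        for s, e in zip(starts, ends):
            idx = activation_idx[s]
            if idx < 0 or (e - s) < min_region:
                continue
            act = timepoints[idx]
            regions.append(
                OperonRegion(
                    start=int(s), end=int(e), strand=strand,
                    activation_time=float(act), name="",
                )
            )

    if not regions:
        return []
    first_t = min(cov.timepoints)
    named: list[OperonRegion] = []
    counts = {early_label: 0, late_label: 0}
    for op in sorted(regions, key=lambda o: (o.start, o.strand)):
        tier = early_label if op.activation_time == first_t else late_label
        counts[tier] += 1
        suffix = f"_{counts[tier]}" if counts[tier] > 1 else ""
        named.append(
            OperonRegion(
                start=op.start, end=op.end, strand=op.strand,
                activation_time=op.activation_time, name=tier + suffix,
            )
        )
    # de-duplicate suffixes: if a tier occurs more than once, suffix all of them
    for tier, n in counts.items():
        if n > 1:
            named = [
                OperonRegion(
                    start=o.start, end=o.end, strand=o.strand,
                    activation_time=o.activation_time,
                    name=(f"{tier}_1" if o.name == tier else o.name),
                )
                for o in named
            ]
    return named


# ---------------------------------------------------------------------------
# TSV I/O (long format: position, strand, timepoint, count)

def write_coverage_tsv(cov: CoverageProfile, path: str | Path) -> None:
    frames = []
    for t in cov.timepoints:
        for strand, vals in cov.values[t].items():
            nz = np.flatnonzero(vals)
            frames.append(
                pd.DataFrame(
                    {
                        "position": nz,
                        "strand": strand,
                        "timepoint": t,
                        "count": vals[nz],
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["position", "strand", "timepoint", "count"]
    )
    with open(path, "w") as fh:
        fh.write(f"# replicon: {cov.replicon}\n# length: {cov.length}\n")
        fh.write("# coordinates: 0-based; zero-count positions omitted\n")
        df.to_csv(fh, sep="\t", index=False)


def read_coverage_tsv(path: str | Path) -> CoverageProfile:
    replicon, length = "unknown", None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if line.startswith("# replicon:"):
                replicon = line.split(":", 1)[1].strip()
            elif line.startswith("# length:"):
                length = int(line.split(":", 1)[1].strip())
    df = pd.read_csv(path, sep="\t", comment="#")
    if length is None:
        length = int(df["position"].max()) + 1 if len(df) else 0
    values: CoverageValues = {}
    for (t, strand), sub in df.groupby(["timepoint", "strand"]):
        arr = np.zeros(length)
        arr[sub["position"].to_numpy(dtype=int)] = sub["count"].to_numpy(dtype=float)
        values.setdefault(float(t), {})[str(strand)] = arr
    for t in values:
        for strand in (PLUS, MINUS):
            values[t].setdefault(strand, np.zeros(length))
    return CoverageProfile(replicon=replicon, length=length, values=values)
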