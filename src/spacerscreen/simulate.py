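"""Synthetic data emulating a genome-tiling type III-A spacer screen.

The generator produces every input the pipeline consumes: a phage-like
genome with an early (PE) and late (PL) operon, a tiling spacer library,
count tables and repeat-flanked amplicon reads before and after phage
selection, naive-acquisition amplicons mixing phage- and plasmid-derived
spacers, and stepped time-course RNA-seq coverage.

Selection is modeled as a single effective multinomial reweighting per
timepoint: post-infection expected frequencies are proportional to
``f_t0(s) * w(s)**rounds``, where ``w`` is a relative fitness determined by
what the spacer targets and the host genotype.  The shipped genotype presets
(wild type, dcsm6, cas10HD, cas10HD/dcsm6) are calibration artifacts chosen
to reproduce the qualitative enrichment geography of the screens — early
minus-strand spacers enriched in the wild type, PE-downstream spacers
depleted without Csm6 activity, and a mild late-over-early inversion when
the Cas10 ssDNase is dead — never measured values.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; fixed seed means byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .design import DEFAULT_REPEAT, LibraryDesignConfig, SpacerLibrary, design_tiling_library
from .extract import CountTable
from .genome import (
    MINUS,
    PLUS,
    GenomeAnnotation,
    OperonRegion,
    SpacerRecord,
    is_targeting,
    region_of,
)
from .rnaseq import CoverageProfile

GENOTYPES = ("WT", "dcsm6", "cas10HD", "cas10HD_dcsm6")

#: Relative fitness per (genotype, spacer class).  Classes: "nontargeting"
#: (plus-strand or untranscribed spacers — no crRNA/transcript pairing),
#: "PE_upstream"/"PE_downstream" (targeting the early operon's first/second
#: half), "PL" (targeting the late operon), "other" (targeting any other
#: operon).  Values are calibration artifacts (see module docstring).
FITNESS_PRESETS: dict[str, dict[str, float]] = {
    "WT": {"nontargeting": 0.5, "PE_upstream": 5.0, "PE_downstream": 5.0, "PL": 0.7, "other": 1.0},
    "dcsm6": {"nontargeting": 0.5, "PE_upstream": 5.0, "PE_downstream": 0.4, "PL": 0.3, "other": 1.0},
    "cas10HD": {"nontargeting": 1.0, "PE_upstream": 0.78, "PE_downstream": 0.78, "PL": 1.96, "other": 1.0},
    "cas10HD_dcsm6": {"nontargeting": 1.0, "PE_upstream": 1.0, "PE_downstream": 1.0, "PL": 1.0, "other": 1.0},
}

#: Phage-vs-plasmid acquisition odds per genotype; the phage fraction is
#: theta / (1 + theta).  WT and cas10HD are calibrated to the observed 97.96%
#: and 0.94% phage-derived fractions; dcsm6 is WT-like.
ACQUISITION_ODDS: dict[str, float] = {"WT": 48.0, "dcsm6": 24.0, "cas10HD": 0.0095, "cas10HD_dcsm6": 0.0095}


@dataclass
class SimulationConfig:
    seed: int = 0
    genome_length: int = 40_000
    #: (name, start, end, strand, activation_time); the default plan places a
    #: plus-strand early operon over [1000, 15000) firing at 5 min and a late
    #: operon over [15000, 40000) firing at 15 min.
    operon_plan: list[tuple[str, int, int, str, float]] = field(
        default_factory=lambda: [
            ("PE", 1_000, 15_000, PLUS, 5.0),
            ("PL", 15_000, 40_000, PLUS, 15.0),
        ]
    )
    spacer_length: int = 35
    step: int = 2
    genotype: str = "WT"
    read_depth: int = 1_000_000
    per_base_error_rate: float = 0.0
    repeat_seq: str = DEFAULT_REPEAT
    #: multiplicative gamma dispersion of t0 abundances (shape parameter;
    #: larger = more even library; CV = 1/sqrt(shape))
    t0_dispersion_shape: float = 20.0
    #: lognormal sigma of spacer-level fitness noise (0 disables)
    fitness_noise_sd: float = 0.3
    #: effective selection rounds per post-infection timepoint
    selection_rounds: dict[str, float] = field(
        default_factory=lambda: {"t5h": 1.0, "t24h": 1.5}
    )
    #: phage-vs-plasmid acquisition odds; None uses the genotype preset
    acquisition_odds: float | None = None
    rnaseq_timepoints: tuple[float, ...] = (5.0, 15.0, 30.0)
    rnaseq_baseline: float = 2.0
    rnaseq_amplitude: float = 50.0
    #: 3'-decay of coverage along an operon, per nt
    rnaseq_decay_per_nt: float = 1e-5

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}; choose from {GENOTYPES}")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic generator for a named substream.

        Stream names are folded in with a CRC so ordering of calls never
        matters and outputs are platform-stable."""
        tag = zlib.crc32(stream.encode()) & 0x7FFFFFFF
        return np.random.default_rng(np.random.SeedSequence((self.seed, tag)))


def simulate_genome(cfg: SimulationConfig, name: str = "phage_sim") -> GenomeAnnotation:
    """Uniform-random ACGT genome of the configured length and operon plan."""
    operons = [
        OperonRegion(start=s, end=e, strand=st, activation_time=t, name=n)
        for (n, s, e, st, t) in cfg.operon_plan
    ]
    for op in operons:
        if op.end > cfg.genome_length:
            raise ValueError(f"operon {op.name!r} extends past genome length {cfg.genome_length}")
    rng = cfg.rng(f"genome:{name}")
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, cfg.genome_length)])
    return GenomeAnnotation(name=name, sequence=seq, operons=operons)


def spacer_fitness_class(spacer: SpacerRecord, genome: GenomeAnnotation) -> str:
    """Fitness class of a spacer: what its crRNA can target, and where."""
    if not is_targeting(spacer, genome):
        return "nontargeting"
    region = region_of(spacer, genome)
    op = genome.operon_at(spacer.midpoint)
    if region == "PE":
        half = (op.start + op.end) // 2
        return "PE_upstream" if spacer.midpoint < half else "PE_downstream"
    if region == "PL":
        return "PL"
    return "other"


def fitness_weights(
    library: SpacerLibrary,
    genome: GenomeAnnotation,
    cfg: SimulationConfig,
    override: np.ndarray | None = None,
) -> np.ndarray:
    """Per-spacer relative fitness: preset value for the spacer's class times
    optional lognormal spacer-level noise.  ``override`` replaces the preset
    lookup with explicit per-spacer weights."""
    if override is not None:
        base = np.asarray(override, dtype=float)
        if len(base) != len(library.records):
            raise ValueError("override length must match the library")
    else:
        preset = FITNESS_PRESETS[cfg.genotype]
        classes = [spacer_fitness_class(r, genome) for r in library.records]
        missing = {c for c in classes if c not in preset}
        if missing:
            raise ValueError(f"fitness preset {cfg.genotype!r} missing classes {sorted(missing)}")
        base = np.array([preset[c] for c in classes], dtype=float)
    if cfg.fitness_noise_sd > 0:
        rng = cfg.rng("fitness_noise")
        base = base * rng.lognormal(mean=0.0, sigma=cfg.fitness_noise_sd, size=len(base))
    if np.any(base <= 0):
        raise ValueError("all fitness weights must be positive")
    return base


def simulate_screen(
    library: SpacerLibrary,
    genome: GenomeAnnotation,
    cfg: SimulationConfig,
    fitness_override: np.ndarray | None = None,
) -> dict[str, CountTable]:
    """Multinomially sampled count tables for t0 and the post-infection timepoints.

    t0 abundances are near-uniform with gamma dispersion; each post timepoint
    draws from frequencies proportional to ``q0 * w**rounds``.
    """
    n = len(library.records)
    seqs = [r.sequence for r in library.records]
    rng = cfg.rng("screen")
    if np.isfinite(cfg.t0_dispersion_shape):
        q0 = rng.gamma(shape=cfg.t0_dispersion_shape, scale=1.0 / cfg.t0_dispersion_shape, size=n)
        q0 /= q0.sum()
    else:  # infinite shape: an exactly even library
        q0 = np.full(n, 1.0 / n)
    w = fitness_weights(library, genome, cfg, override=fitness_override)

    tables: dict[str, CountTable] = {}
    counts0 = rng.multinomial(cfg.read_depth, q0)
    tables["t0"] = _counts_to_table("t0", seqs, counts0)
    for sample, rounds in cfg.selection_rounds.items():
        q = q0 * np.power(w, rounds)
        q /= q.sum()
        tables[sample] = _counts_to_table(sample, seqs, rng.multinomial(cfg.read_depth, q))
    return tables


def _counts_to_table(sample_id: str, seqs: list[str], counts: np.ndarray) -> CountTable:
    table = CountTable(sample_id=sample_id)
    total = 0
    for s, c in zip(seqs, counts):
        c = int(c)
        if c > 0:
            table.counts[s] = table.counts.get(s, 0) + c
            total += c
    table.total_extracted = total
    table.total_reads = total
    return table


# ---------------------------------------------------------------------------
# Amplicon read emission

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < error_rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def write_amplicon_fastq(
    table: CountTable,
    path: str | Path,
    cfg: SimulationConfig,
    stream: str = "amplicons",
) -> int:
    """Emit one ``DR + spacer + DR`` read per counted spacer occurrence.

    Reads are written in a deterministic shuffled order with substitution
    errors at the configured per-base rate; returns the number of reads.
    """
    rng = cfg.rng(f"fastq:{stream}")
    spacers = np.array(sorted(table.counts), dtype=object)
    reps = np.array([table.counts[s] for s in spacers])
    pool = np.repeat(spacers, reps)
    rng.shuffle(pool)
    dr = cfg.repeat_seq
    with open(path, "w") as fh:
        for i, spacer in enumerate(pool):
            read = _mutate(dr + spacer + dr, cfg.per_base_error_rate, rng)
            fh.write(f"@{stream}_{i}\n{read}\n+\n{'I' * len(read)}\n")
    return len(pool)


# ---------------------------------------------------------------------------
# Naive acquisition

def simulate_plasmid(cfg: SimulationConfig, name: str = "pCRISPR_sim", length: int = 7_000) -> GenomeAnnotation:
    """Random plasmid replicon (no operon map needed for acquisition mapping)."""
    rng = cfg.rng(f"genome:{name}")
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])
    return GenomeAnnotation(name=name, sequence=seq)


def _acquisition_position_weights(genome: GenomeAnnotation, cfg: SimulationConfig, k: int) -> np.ndarray:
    """Per-(strand, start) sampling weights over a replicon.

    Row 0 holds plus-strand spacers, row 1 minus-strand.  For genotypes with
    active Cas10 immunity (WT, dcsm6) minus-strand protospacers inside the
    early operon are strongly favoured — those spacers let their host survive
    — with the dcsm6 preset further skewed toward the PE-upstream half.
    """
    n = genome.length - k + 1
    if n <= 0:
        raise ValueError("replicon shorter than spacer length")
    weights = np.ones((2, n))
    pe = next((op for op in genome.operons if op.name == "PE"), None)
    if pe is not None and cfg.genotype in ("WT", "dcsm6"):
        mid = np.arange(n) + k // 2
        inside = (mid >= pe.start) & (mid < pe.end)
        weights[1, inside] = 10.0
        if cfg.genotype == "dcsm6":
            downstream = inside & (mid >= (pe.start + pe.end) // 2)
            weights[1, downstream] = 1.5
        weights[0, :] *= 0.3
    total = weights.sum()
    if total <= 0:
        raise ValueError("degenerate acquisition weight vector")
    return weights / total


def simulate_acquisition(
    cfg: SimulationConfig,
    phage: GenomeAnnotation,
    plasmid: GenomeAnnotation,
    n_reads: int = 10_000,
    path: str | Path | None = None,
) -> CountTable:
    """Acquisition amplicons: each survivor contributes one new spacer drawn
    from the phage with probability theta/(1+theta), else from the plasmid,
    at a position drawn from the per-position weight vector.

    Returns the planted spacer counts; if ``path`` is given the reads are
    also written as ``DR + spacer + DR`` FASTQ.
    """
    theta = cfg.acquisition_odds if cfg.acquisition_odds is not None else ACQUISITION_ODDS[cfg.genotype]
    if theta <= 0:
        raise ValueError("acquisition odds theta must be positive")
    rng = cfg.rng("acquisition")
    k = cfg.spacer_length
    p_phage = theta / (1.0 + theta)
    table = CountTable(sample_id=f"acquisition_{cfg.genotype}")
    weight_cache = {
        phage.name: _acquisition_position_weights(phage, cfg, k),
        plasmid.name: np.ones((2, plasmid.length - k + 1)),
    }
    weight_cache[plasmid.name] /= weight_cache[plasmid.name].sum()
    n_phage = int(rng.binomial(n_reads, p_phage))
    for genome, n_src in ((phage, n_phage), (plasmid, n_reads - n_phage)):
        if n_src == 0:
            continue
        w = weight_cache[genome.name]
        draws = rng.choice(w.size, size=n_src, p=w.ravel())
        for flat in draws:
            strand_idx, start = divmod(int(flat), w.shape[1])
            seq = genome.subsequence(start, start + k, PLUS if strand_idx == 0 else MINUS)
            table.add(seq)
    table.total_reads = n_reads
    if path is not None:
        write_amplicon_fastq(table, path, cfg, stream="acquisition")
    return table


# ---------------------------------------------------------------------------
# RNA-seq

def simulate_rnaseq(cfg: SimulationConfig, genome: GenomeAnnotation) -> CoverageProfile:
    """Stepped Poisson coverage: baseline everywhere on both strands, plus
    amplitude (with 3'-decay) over each operon active by the timepoint, on
    the operon's mRNA strand."""
    rng = cfg.rng("rnaseq")
    L = genome.length
    values = {}
    for t in cfg.rnaseq_timepoints:
        lam = {PLUS: np.full(L, cfg.rnaseq_baseline), MINUS: np.full(L, cfg.rnaseq_baseline)}
        for op in genome.operons:
            if op.activation_time <= t:
                offsets = np.arange(op.length)
                if op.strand == MINUS:
                    offsets = offsets[::-1]
                lam[op.strand][op.start : op.end] += cfg.rnaseq_amplitude * np.exp(
                    -cfg.rnaseq_decay_per_nt * offsets
                )
        values[float(t)] = {s: rng.poisson(lam[s]).astype(float) for s in (PLUS, MINUS)}
    return CoverageProfile(replicon=genome.name, length=L, values=values)


def default_library(genome: GenomeAnnotation, cfg: SimulationConfig) -> SpacerLibrary:
    """Tiling library matching the simulation's spacer length and step."""
    return design_tiling_library(
        genome, LibraryDesignConfig(spacer_length=cfg.spacer_length, step=cfg.step)
    )
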