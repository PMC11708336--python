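"""Stage orchestration: simulate a complete fixture directory, run the
screen-enrichment path (extract -> frequencies -> enrichment -> annotate ->
summarize), and run the acquisition path (extract -> map -> RPM tracks).

Every stage writes plain-text outputs plus a run manifest recording the
package version, a config hash, the seed, and input checksums, so a rerun on
identical inputs is byte-identical and auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .design import write_library_manifest, write_oligo_fasta, read_library_manifest
from .enrich import annotate_enrichment, compute_enrichment, group_stats, write_enrichment_tsv
from .extract import (
    CountTable,
    ExtractionConfig,
    extract_spacers_fastq,
    read_count_table,
    write_count_table,
)
from .genome import GenomeAnnotation, read_genome_fasta, read_operon_tsv, write_genome_fasta, write_operon_tsv
from .mapping import map_spacers, position_coverage_rpm, write_rpm_tsv, write_source_summary
from .rnaseq import read_coverage_tsv, write_coverage_tsv
from .simulate import (
    SimulationConfig,
    default_library,
    simulate_acquisition,
    simulate_genome,
    simulate_plasmid,
    simulate_rnaseq,
    simulate_screen,
    write_amplicon_fastq,
)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"[{stage}] {cause}")


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _require(path: str | Path, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"missing input: {p}")
    return p


def write_run_manifest(outdir: Path, stage: str, params: dict, inputs: list[Path]) -> None:
    manifest = {
        "tool": "spacerscreen",
        "version": __version__,
        "stage": stage,
        "parameters": params,
        "config_hash": hashlib.sha256(
            json.dumps(params, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
        "input_checksums": {str(p): _file_checksum(p) for p in inputs},
    }
    (outdir / f"run_manifest_{stage}.json").write_text(json.dumps(manifest, indent=2) + "\n")


def simulate_fixture(cfg: SimulationConfig, outdir: str | Path, fastq_depth: int | None = None) -> dict[str, Path]:
    """Write a complete synthetic fixture: genome FASTA, operon TSV, library
    manifest and oligo FASTA, per-sample amplicon FASTQ, RNA-seq coverage
    TSV, acquisition FASTQ, and a provenance JSON.

    ``fastq_depth`` caps the number of reads emitted per FASTQ sample (count
    tables keep the configured full depth); useful for desk-scale fixtures.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(cfg)
    plasmid = simulate_plasmid(cfg)
    library = default_library(genome, cfg)

    paths = {
        "genome": outdir / "genome.fasta",
        "plasmid": outdir / "plasmid.fasta",
        "operons": outdir / "operons.tsv",
        "manifest": outdir / "library_manifest.tsv",
        "oligos": outdir / "library_oligos.fasta",
        "coverage": outdir / "rnaseq_coverage.tsv",
        "acquisition_fastq": outdir / "acquisition.fastq",
        "provenance": outdir / "provenance.json",
    }
    write_genome_fasta(genome, paths["genome"])
    write_genome_fasta(plasmid, paths["plasmid"])
    write_operon_tsv(genome, paths["operons"])
    write_library_manifest(library, paths["manifest"])
    write_oligo_fasta(library, paths["oligos"])

    tables = simulate_screen(library, genome, cfg)
    for sample, table in tables.items():
        if fastq_depth is not None and table.total_extracted > fastq_depth:
            table = _downsample(table, fastq_depth, cfg, sample)
        fq = outdir / f"{sample}.fastq"
        write_amplicon_fastq(table, fq, cfg, stream=sample)
        paths[f"fastq_{sample}"] = fq

    cov = simulate_rnaseq(cfg, genome)
    write_coverage_tsv(cov, paths["coverage"])
    simulate_acquisition(cfg, genome, plasmid, path=paths["acquisition_fastq"])

    provenance = {"tool": "spacerscreen", "version": __version__, "config": asdict(cfg)}
    paths["provenance"].write_text(json.dumps(provenance, indent=2, default=str) + "\n")
    return paths


def _downsample(table: CountTable, depth: int, cfg: SimulationConfig, sample: str) -> CountTable:
    import numpy as np

    rng = cfg.rng(f"downsample:{sample}")
    seqs = sorted(table.counts)
    counts = np.array([table.counts[s] for s in seqs])
    sub = rng.multivariate_hypergeometric(counts, depth)
    out = CountTable(sample_id=table.sample_id)
    for s, c in zip(seqs, sub):
        if c > 0:
            out.counts[s] = int(c)
            out.total_extracted += int(c)
    out.total_reads = out.total_extracted
    return out


def run_screen(
    pre_fastq: str | Path,
    post_fastqs: dict[str, str | Path],
    manifest_path: str | Path,
    genome_path: str | Path,
    operons_path: str | Path,
    repeat_seq: str,
    outdir: str | Path,
    zero_policy: str = "na",
) -> dict[str, Path]:
    """Extraction through group summaries for one screen sample set."""
    stage = "screen"
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = [_require(pre_fastq, stage), _require(manifest_path, stage),
              _require(genome_path, stage), _require(operons_path, stage)]
    for p in post_fastqs.values():
        inputs.append(_require(p, stage))

    ecfg = ExtractionConfig(repeat_seq=repeat_seq)
    genome = read_genome_fasta(genome_path)
    genome.operons.extend(read_operon_tsv(operons_path, replicon=genome.name))
    manifest = read_library_manifest(manifest_path)

    pre = extract_spacers_fastq(pre_fastq, ecfg, sample_id="t0")
    if pre.total_extracted == 0:
        raise PipelineError(stage, f"no spacers extracted from {pre_fastq}")
    write_count_table(pre, outdir / "counts_t0.tsv", outdir / "counts_t0.summary.json")

    outputs: dict[str, Path] = {"counts_t0": outdir / "counts_t0.tsv"}
    summaries = []
    for sample, fq in sorted(post_fastqs.items()):
        post = extract_spacers_fastq(fq, ecfg, sample_id=sample)
        if post.total_extracted == 0:
            raise PipelineError(stage, f"no spacers extracted from {fq}")
        write_count_table(post, outdir / f"counts_{sample}.tsv", outdir / f"counts_{sample}.summary.json")
        enr = annotate_enrichment(
            compute_enrichment(post, pre, zero_policy=zero_policy), manifest, genome
        )
        enr_path = outdir / f"enrichment_{sample}.tsv"
        write_enrichment_tsv(enr, enr_path, header_comment=f"sample: {sample} vs t0")
        outputs[f"enrichment_{sample}"] = enr_path
        gs = group_stats(enr[enr["targeting"]], group_col="region")
        gs.insert(0, "sample", sample)
        summaries.append(gs)

    summary = pd.concat(summaries, ignore_index=True)
    summary_path = outdir / "group_summary.tsv"
    with open(summary_path, "w") as fh:
        fh.write("# mean/SD of post/pre enrichment over targeting spacers, by region\n")
        summary.to_csv(fh, sep="\t", index=False)
    outputs["group_summary"] = summary_path
    write_run_manifest(
        outdir, stage,
        {"repeat_seq": repeat_seq, "zero_policy": zero_policy}, inputs,
    )
    return outputs


def run_acquisition(
    fastq: str | Path,
    phage_path: str | Path,
    plasmid_path: str | Path,
    repeat_seq: str,
    outdir: str | Path,
    max_mismatches: int = 0,
) -> dict[str, Path]:
    """Extraction through RPM maps and source fractions for acquisition reads."""
    stage = "acquisition"
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = [_require(fastq, stage), _require(phage_path, stage), _require(plasmid_path, stage)]

    ecfg = ExtractionConfig(repeat_seq=repeat_seq)
    table = extract_spacers_fastq(fastq, ecfg, sample_id="acquisition")
    if table.total_extracted == 0:
        raise PipelineError(stage, "no spacers extracted")
    write_count_table(table, outdir / "acquisition_counts.tsv", outdir / "acquisition_counts.summary.json")

    replicons = [read_genome_fasta(phage_path), read_genome_fasta(plasmid_path)]
    alignments = map_spacers(table, replicons, max_mismatches=max_mismatches)
    profile = position_coverage_rpm(alignments, table, replicons)
    write_rpm_tsv(profile, outdir / "acquisition_rpm.tsv")
    write_source_summary(profile, outdir / "acquisition_sources.json")
    write_run_manifest(
        outdir, stage, {"repeat_seq": repeat_seq, "max_mismatches": max_mismatches}, inputs
    )
    return {
        "counts": outdir / "acquisition_counts.tsv",
        "rpm": outdir / "acquisition_rpm.tsv",
        "sources": outdir / "acquisition_sources.json",
    }


def run_rnaseq(coverage_path: str | Path, outdir: str | Path, threshold_factor: float = 5.0,
               smoothing_window: int = 501, min_region: int = 500) -> Path:
    """Call early/late operons from a coverage TSV; emits the operon TSV
    consumed by the screen stage."""
    from .rnaseq import call_operons

    stage = "rnaseq"
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cov = read_coverage_tsv(_require(coverage_path, stage))
    regions = call_operons(cov, threshold_factor=threshold_factor,
                           smoothing_window=smoothing_window, min_region=min_region)
    genome = GenomeAnnotation(name=cov.replicon, sequence="A" * cov.length, operons=regions)
    out = Path(outdir) / "called_operons.tsv"
    write_operon_tsv(genome, out, header_comment="called from time-course coverage")
    write_run_manifest(outdir, stage, {"threshold_factor": threshold_factor,
                                       "smoothing_window": smoothing_window,
                                       "min_region": min_region},
                       [Path(coverage_path)])
    return out
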