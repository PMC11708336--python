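# spacerscreen

Analysis toolkit for **genome-tiling CRISPR type III-A spacer screens**
against staphylococcal phages — the experiment in which a plasmid library of
tens of thousands of spacers, tiling both strands of a phage genome every
few nucleotides, is introduced into *S. aureus* carrying a type III-A
CRISPR-Cas system, the culture is infected, and deep sequencing of the
CRISPR arrays before and after infection reveals which crRNAs let their host
survive.

The package covers the full computational path of such a screen:

- **Library design** — tile `k`-nt spacers every `step` nt on both strands
  and emit the 90-nt synthesis oligo for each (universal priming sites, BsaI
  sites for Golden Gate cloning, and direct-repeat homology arms around the
  spacer).
- **Spacer extraction** — recover spacers from amplicon FASTQ reads as every
  sequence flanked by two direct-repeat (DR) matches, with a Hamming
  mismatch tolerance; an array read `DR·S1·DR·S2·DR` yields both spacers.
- **Enrichment statistics** — per-spacer frequencies `f_t(s) = c_t(s)/N_t`,
  enrichment ratios `E_t(s) = f_t(s)/f_t0(s)`, annotation by targeted operon
  and strand, group means ± SD, Welch's unequal-variance *t*-test, and
  Pearson correlation of enrichment against transcript abundance.
- **Acquisition mapping** — place newly acquired spacers on phage and
  plasmid replicons with a transparent k-mer-seeded exact/near-exact mapper
  and build strand-separated, single-nucleotide RPM coverage tracks
  (reads per million total aligned reads) plus per-source fractions.
- **Operon calling** — recover the phage's early/late promoter structure
  (PE ≈ 1–15 kb active within 5 min of infection, PL ≈ 15–40 kb active
  between 5 and 15 min) from stepped time-course RNA-seq coverage with a
  smoothing + threshold change-point rule.
- **Synthetic data** — a seeded generator that emulates the whole
  experiment (genome, library, multinomial selection with genotype-dependent
  fitness, amplicon reads with substitution errors, acquisition reads,
  Poisson RNA-seq coverage), so every stage is testable end to end without
  any external download.

## Worked example

Simulate a wild-type screen over a 40-kb genome with a 2,000-spacer tiling
library and compare spacers targeting early (PE) vs late (PL) transcripts
(`examples/03_screen_enrichment.py`):

```text
PE-targeting: n=350, mean enrichment 3.66 +/- 1.21
PL-targeting: n=625, mean enrichment 0.52 +/- 0.16
Welch's t-test: t=48.3, df=356, p=1.91e-158
```

Spacers whose crRNA pairs with early transcripts are strongly enriched
(their hosts clear the infection and keep dividing), while spacers against
late transcripts trigger a Csm6-mediated growth arrest and fail to expand —
the defining geography of the wild-type screen. Switching the genotype
preset changes the outcome; with the Cas10 nuclease-dead preset, acquisition
sources flip (`examples/04_acquisition_map.py`):

```text
WT       phage-derived:  98.10%   plasmid-derived:   1.90%
cas10HD  phage-derived:   0.86%   plasmid-derived:  99.14%
```

Each script in `examples/` exercises one capability (design, extraction,
enrichment, acquisition mapping, operon calling) in a few lines; a thin CLI
mirrors the same stages:

```bash
spacerscreen demo --seed 1 --out demo_run/     # simulate + run every stage
spacerscreen design --genome ref.fa --k 35 --step 2 --out lib/
spacerscreen extract --fastq run.fastq --repeat <DR sequence> --out counts.tsv
```

## Layout

```
src/spacerscreen/
  genome.py     coordinates, strands, operons, region/targeting semantics
  design.py     tiling library + oligo construction
  extract.py    DR-flanked spacer extraction from FASTQ
  enrich.py     frequencies, enrichment ratios, group statistics
  mapping.py    k-mer spacer mapper + RPM coverage tracks
  rnaseq.py     coverage normalization + operon calling
  stats.py      Welch's t-test, Pearson correlation
  simulate.py   the synthetic experiment generator
  pipeline.py   stage orchestration; cli.py  command-line surface
```

See `docs/methods.md` for the underlying models, parameter defaults, and
known limitations.
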