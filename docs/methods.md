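# Methods

This note documents the models and conventions behind `spacerscreen`: what
each stage computes, the defaults and why, what the synthetic generator does
and does not emulate, and the numerical choices a maintainer would want
written down.

## Coordinates, strands, and targeting

All intervals are 0-based, half-open `[start, end)` on the plus strand of a
replicon. A *minus-strand spacer* is one whose sequence equals the reverse
complement of the plus-strand substring over its interval. The crRNA is
taken equal in sequence to the spacer, so a spacer **targets** a transcript
exactly when (i) its midpoint lies inside an operon and (ii) its strand is
opposite to the operon's mRNA strand — the crRNA can then base-pair with the
transcript, which is what arms the Cas10-Csm complex. Region membership uses
the integer midpoint `(start + end) // 2`; because intervals are half-open,
a midpoint landing exactly on a boundary belongs to the downstream region,
giving straddling spacers a deterministic single label. Operon boundaries
are inputs (BED-like TSV), not constants: the early/late promoter switch of
a real phage is only known to within a few kilobases.

## Library design

Spacers of length `k` (default 35 nt, a canonical type III-A spacer size;
configurable) start at positions `0, step, 2·step, … ≤ L − k` on each
selected strand, so the per-strand count is `floor((L − k)/step) + 1`.
Minus-strand spacers reuse the plus-strand coordinate grid (they are reverse
complements of the same windows), which keeps coordinates symmetric and
reproducible. Genomic repeats produce duplicate spacer sequences; these are
kept but flagged, and downstream annotation treats them as unplaceable.

Each spacer is embedded in a 90-nt oligo:

```
priming_left(5) + GGTCTC(6) + repeat_homology(17)
    + spacer(35) + repeat_homology(17) + GAGACC(6) + priming_right(4)
```

BsaI sites are oriented so Golden Gate digestion releases the spacer with
repeat-homology overhangs; plus- and minus-strand schemes carry distinct
priming sequences so the two sub-pools can be PCR-amplified without
cross-hybridization. The shipped repeat (`design.DEFAULT_REPEAT`, 30 nt) is
a synthetic stand-in chosen to be non-palindromic, free of BsaI sites, and
without near-repeats of itself; the repeat of the actual *S. epidermidis*
type III-A array is not public in the sources this package draws on, and
every function that needs a repeat takes it as a parameter.

## Spacer extraction

Direct-repeat occurrences in a read are found by full-length Hamming
comparison over every window (vectorized sliding-window compare), with a
default tolerance of 1 mismatch — substitutions dominate on the MiSeq-class
data this models, so no indel alignment is attempted. Overlapping candidate
windows are resolved greedily left-to-right, lowest mismatch count first,
leftmost on ties; the gap between consecutive selected repeats is a spacer
if its length is within bounds (default 20–50 nt). Consecutive spacers share
the repeat between them, so expanded arrays yield all their spacers. Reads
are scanned in both orientations by default and reverse-complement hits are
canonicalized to the forward amplicon orientation; with a non-palindromic
repeat the two scans never double-count (a repeat within mismatch tolerance
of its own reverse complement could, which is why the shipped default was
screened against that).

Spacers are counted as exact strings, with no error-correction clustering:
at step 2 the designed grid separates neighbours by ≥ 2 nt, and clustering
would blur it. Base qualities are ignored.

## Enrichment statistics

Frequencies are computed over the spacers extracted in each sample (not over
the designed manifest): `f(s) = c(s)/N`. The enrichment ratio is
`E_t(s) = f_t(s)/f_t0(s)`. Spacers absent at t0 get `NA` and are excluded
from group statistics — detection and selection are reported separately — or
a shared pseudocount `α` (default 0.5) can be applied to both samples, which
converges to the NA-policy values as `α → 0` for detected spacers. Group
summaries (mean ± SD, Welch's *t*) are on the natural enrichment scale, as
is conventional for these screens; a log-scale option exists.

Enrichment-vs-expression correlation summarizes each spacer's expression as
the mean per-position normalized coverage over its interval on the mRNA
strand (the strand opposite the spacer), then computes Pearson's *r* over
spacers with finite enrichment.

## Statistics

`stats.welch_t_test` computes `t = (m_x − m_y)/√(s_x²/n_x + s_y²/n_y)` with
Welch–Satterthwaite degrees of freedom and a two-sided p-value from the
regularized incomplete beta function, `p = I_{ν/(ν+t²)}(ν/2, ½)`. Sample
SDs use the n−1 denominator. Two zero-variance samples with equal means
return the degenerate `t=0, p=1`; unequal means with zero variance raise.
`stats.pearson_r` is the plain covariance formula with results clamped to
[−1, 1] against rounding.

## Acquisition mapping

Acquired spacers are copies of their protospacer, so the default mapper is
exact (`max_mismatches=0`), with a documented near-exact mode (pigeonhole
seeding: `m+1` disjoint 11-mers guarantee a seed hit for any placement with
≤ m mismatches, each candidate verified by full-length Hamming comparison).
A single best placement is `unique`; equal-best placements at more than one
locus are `ambiguous` and excluded from coverage tracks (tallied instead) so
single-nucleotide maps never double-count; no placement is `unaligned`.

RPM tracks add each unique alignment's read count to every position of its
interval on its strand, then divide by (total uniquely aligned reads across
**all** replicons / 10⁶) — "per million total aligned reads". This yields
the conservation identity `Σ_positions RPM(replicon) = 10⁶ · k̄ ·
(reads_replicon/reads_total)` with `k̄` the count-weighted mean aligned
spacer length, which the tests verify to 1e−9.

## Operon calling from time-course coverage

Raw per-position counts are normalized per timepoint to a total of 10⁶ over
both strands, absorbing depth differences between timepoints. Calling then
proceeds per strand:

1. smooth each timepoint's normalized track with a moving average
   (default window 501 nt);
2. estimate the baseline as the **smallest** per-timepoint genome-wide
   median on that strand, and set the threshold to `threshold_factor`
   (default 5) times it. The per-timepoint median itself is not a usable
   baseline: late in infection most of a phage genome is transcribed, so the
   median at a late timepoint sits at the transcribed level and would
   suppress every call. The quietest timepoint's median estimates the
   untranscribed background instead;
3. assign each position the earliest timepoint at which its smoothed value
   exceeds the threshold (its activation time);
4. maximal runs of constant activation time at least `min_region`
   (default 500 nt) long become operons. Segmenting at activation-time
   change-points, rather than merging all above-threshold positions, is what
   separates adjacent early and late operons once both are transcribed.

The thresholds make calling invariant to rescaling any single timepoint, and
lowering `threshold_factor` can only grow regions (the baseline does not
depend on the factor). Boundary accuracy is limited by the smoothing window:
recovered edges land within about half a window of a planted step. This rule
is a reproducible, parameterized formalization of what is usually done by
inspection of coverage plots; it is not a TSS-resolution method.

## The synthetic experiment

The generator exists so that every pipeline stage has inputs with known
ground truth. Its defaults describe the modeled experiment: a 40-kb
uniform-random genome with a plus-strand early operon [1000, 15000) firing
at 5 min and a late operon [15000, 40000) firing at 15 min; 35-nt spacers
every 2 nt on both strands; 10⁶ reads per sample; amplicons of the form
`DR·spacer·DR` with configurable substitution errors; RNA-seq timepoints at
5/15/30 min with Poisson noise around `baseline + amplitude ·
1[operon active by t]` (baseline 2, amplitude 50), plus a mild 3′-decay
(10⁻⁵ per nt) standing in for the lower downstream abundance of long early
transcripts.

**Selection model.** Infection, lysis, arrest and regrowth are deliberately
collapsed into one effective relative fitness per spacer: post-infection
expected frequencies are `∝ f_t0(s) · w(s)^rounds` (rounds 1.0 at 5 h, 1.5
at 24 h), sampled multinomially. Count ratios — the pipeline's only
observable — constrain nothing beyond relative fitness, so explicit
population dynamics would add parameters without adding testable structure.
t0 abundances are near-uniform with gamma dispersion (shape 20, CV ≈ 22%),
and spacer-level lognormal fitness noise (σ = 0.3, giving group CVs around
0.3, in line with the spread such screens report) makes group SDs realistic.

**Genotype presets.** The fitness tables are calibration artifacts chosen to
reproduce the qualitative selection geography of the screens, and are
flagged as such; they are not measurements. Classes are: `nontargeting`
(plus-strand or untranscribed spacers), `PE_upstream`/`PE_downstream` (the
early operon's two halves), `PL`, and `other`.

| genotype | nontargeting | PE_up | PE_down | PL | reading |
|---|---|---|---|---|---|
| WT | 0.5 | 5.0 | 5.0 | 0.7 | early-targeting hosts expand; late-targeting arrest |
| dcsm6 | 0.5 | 5.0 | 0.4 | 0.3 | PE-downstream spacers need Csm6 and are lost |
| cas10HD | 1.0 | 0.78 | 0.78 | 1.96 | no expansion; mild late-over-early inversion |
| cas10HD_dcsm6 | 1.0 | 1.0 | 1.0 | 1.0 | no defense at all: neutral |

The cas10HD values use the reported group means of that screen as relative
weights, so the simulated ordering and significance direction match, though
absolute simulated means depend on the library composition through `w̄`.

**Acquisition.** Each survivor contributes one new spacer, phage-derived
with probability `θ/(1+θ)` (WT θ=48 → 97.96% phage; cas10HD θ=0.0095 →
0.94%; dcsm6 θ=24, a WT-like value chosen here), at a position drawn from a
per-position weight vector that favours minus-strand protospacers in the
early operon when Cas10 immunity is active (10×; dcsm6 down-weights the
PE-downstream half to 1.5×) and down-weights the plus strand (0.3×).

**What passing tests do and do not show.** The generator plants exactly the
structure the pipeline is built to detect: substitution-only errors, exact
amplicon structure, single-mode selection, step-shaped transcription. Tests
passing on it demonstrate that the algorithms recover planted truth under
the modeled noise; they say nothing about PCR chimeras, indel-rich reads,
strand-biased coverage artifacts, copy-number drift of the library plasmid,
or escape-mutant dynamics, none of which are simulated.

## Problem sizes in the shipped tests

The test suite runs the full logic at reduced scale, as its own design
choice: screens of 400–2,000 spacers at depths of 3·10⁵–10⁶ reads (the
directional genotype comparisons use 2,000 spacers), extraction fidelity on
10⁵ reads, selection-law recovery over 100 replicate screens at depth 10⁶,
operon-boundary recovery over 50 randomized 40-kb simulations, and 10⁴ null
simulations for the Welch calibration. All statistical assertions use
3-standard-error bands (or the stated closed-form tolerances) so they are
stable under the fixed seeds.

## Known limitations

- No paired-end merging, adapter trimming, demultiplexing, or quality-aware
  extraction; inputs are assumed pre-processed.
- The mapper is ungapped; a protospacer spanning a deletion would be missed.
- Operon calling assumes block-like operons with a shared baseline; nested
  promoters or graded activation are out of scope.
- Spacer-level enrichment significance (per-spacer tests across thousands of
  spacers) is deliberately absent: the screens report group-level contrasts,
  and no dispersion model for per-spacer counts is fit here.
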