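"""The synthetic screen generator: determinism, planted-truth recovery,
and the genotype presets' qualitative selection geography."""

import numpy as np
import pytest

from spacerscreen.enrich import annotate_enrichment, compute_enrichment, correlate_with_expression, summarize_groups
from spacerscreen.genome import MINUS, PLUS
from spacerscreen.simulate import (
    ACQUISITION_ODDS,
    FITNESS_PRESETS,
    SimulationConfig,
    default_library,
    simulate_acquisition,
    simulate_genome,
    simulate_plasmid,
    simulate_rnaseq,
    simulate_screen,
    spacer_fitness_class,
    write_amplicon_fastq,
)


def preset_cfg(genotype="WT", seed=40, **kw):
    defaults = dict(
        seed=seed, genotype=genotype, genome_length=8000,
        operon_plan=[("PE", 200, 3000, PLUS, 5.0), ("PL", 3000, 8000, PLUS, 15.0)],
        step=20, read_depth=300_000,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestDeterminism:
    def test_fixed_seed_reproduces_genome_and_counts(self):
        cfg = preset_cfg(seed=41)
        g1, g2 = simulate_genome(cfg), simulate_genome(cfg)
        assert g1.sequence == g2.sequence
        lib = default_library(g1, cfg)
        t1 = simulate_screen(lib, g1, cfg)
        t2 = simulate_screen(lib, g1, cfg)
        assert all(t1[k].counts == t2[k].counts for k in t1)

    def test_different_seeds_differ(self):
        a = simulate_genome(preset_cfg(seed=42))
        b = simulate_genome(preset_cfg(seed=43))
        assert a.sequence != b.sequence

    def test_fastq_emission_is_byte_identical(self, tmp_path):
        cfg = preset_cfg(seed=44, read_depth=2000)
        g = simulate_genome(cfg)
        lib = default_library(g, cfg)
        t0 = simulate_screen(lib, g, cfg)["t0"]
        p1, p2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
        write_amplicon_fastq(t0, p1, cfg)
        write_amplicon_fastq(t0, p2, cfg)
        assert p1.read_bytes() == p2.read_bytes()


class TestGenome:
    def test_default_plan_matches_early_late_layout(self):
        cfg = SimulationConfig(seed=45)
        g = simulate_genome(cfg)
        assert g.length == 40_000
        pe, pl = g.operons
        assert (pe.start, pe.end, pe.activation_time) == (1000, 15_000, 5.0)
        assert (pl.start, pl.end, pl.activation_time) == (15_000, 40_000, 15.0)

    def test_gc_fraction_of_large_genome_near_half(self):
        cfg = SimulationConfig(seed=46, genome_length=100_000, operon_plan=[])
        g = simulate_genome(cfg)
        gc = (g.sequence.count("G") + g.sequence.count("C")) / g.length
        assert abs(gc - 0.5) < 3 * np.sqrt(0.25 / g.length)

    def test_operon_outside_genome_rejected(self):
        cfg = SimulationConfig(seed=47, genome_length=1000,
                               operon_plan=[("PE", 0, 2000, PLUS, 5.0)])
        with pytest.raises(ValueError, match="past genome length"):
            simulate_genome(cfg)


class TestFitnessClasses:
    def test_classes_partition_the_library(self):
        cfg = preset_cfg()
        g = simulate_genome(cfg)
        lib = default_library(g, cfg)
        classes = {spacer_fitness_class(r, g) for r in lib.records}
        assert classes <= {"nontargeting", "PE_upstream", "PE_downstream", "PL"}
        assert "PE_upstream" in classes and "PL" in classes

    def test_presets_cover_all_classes(self):
        for genotype, preset in FITNESS_PRESETS.items():
            assert set(preset) == {"nontargeting", "PE_upstream", "PE_downstream", "PL", "other"}

    def test_override_length_mismatch_is_an_error(self):
        cfg = preset_cfg()
        g = simulate_genome(cfg)
        lib = default_library(g, cfg)
        with pytest.raises(ValueError, match="length"):
            simulate_screen(lib, g, cfg, fitness_override=np.ones(3))


def screen_enrichment(cfg):
    g = simulate_genome(cfg)
    lib = default_library(g, cfg)
    tables = simulate_screen(lib, g, cfg)
    enr = compute_enrichment(tables["t5h"], tables["t0"])
    return annotate_enrichment(enr, lib.records, g), g


class TestPresetGeography:
    def test_wild_type_enriches_early_minus_strand_spacers(self):
        enr, _ = screen_enrichment(preset_cfg("WT", seed=48))
        t = enr[enr["targeting"]]
        pe = t[t["region"] == "PE"]["enrichment"].dropna()
        pl = t[t["region"] == "PL"]["enrichment"].dropna()
        plus = enr[(enr["strand"] == "+")]["enrichment"].dropna()
        assert pe.mean() > pl.mean()
        assert pe.mean() > plus.mean()

    def test_cas10hd_inverts_to_mild_late_enrichment(self):
        enr, _ = screen_enrichment(preset_cfg("cas10HD", seed=49))
        t = enr[enr["targeting"]]
        a, b, res = summarize_groups(
            t, {"region": "PL"}, {"region": "PE"}, "PL", "PE"
        )
        assert a.mean > b.mean
        assert res.p < 0.05

    def test_dcsm6_depletes_pe_downstream_spacers(self):
        cfg = preset_cfg("dcsm6", seed=50)
        enr, g = screen_enrichment(cfg)
        pe = g.operons[0]
        half = (pe.start + pe.end) // 2
        t = enr[enr["targeting"] & (enr["region"] == "PE")]
        mid = (t["start"] + t["start"] + 35) // 2
        up = t[mid < half]["enrichment"].dropna()
        down = t[mid >= half]["enrichment"].dropna()
        assert up.mean() > down.mean()


class TestAcquisition:
    def test_extreme_odds_give_all_phage_reads(self):
        cfg = preset_cfg(seed=51, acquisition_odds=1e9)
        g, p = simulate_genome(cfg), simulate_plasmid(cfg)
        table = simulate_acquisition(cfg, g, p, n_reads=300)
        assert all(s in g.sequence or s in _rc_space(g) for s in table.counts)

    def test_wild_type_odds_recover_calibrated_phage_fraction(self):
        cfg = preset_cfg("WT", seed=52)
        g, p = simulate_genome(cfg), simulate_plasmid(cfg)
        n = 10_000
        table = simulate_acquisition(cfg, g, p, n_reads=n)
        phage_reads = sum(
            c for s, c in table.counts.items() if s in g.sequence or s in _rc_space(g)
        )
        theta = ACQUISITION_ODDS["WT"]
        expected = theta / (1 + theta)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(phage_reads / n - expected) < 3 * se

    def test_nonpositive_odds_rejected(self):
        cfg = preset_cfg(seed=53, acquisition_odds=0.0)
        g, p = simulate_genome(cfg), simulate_plasmid(cfg)
        with pytest.raises(ValueError, match="positive"):
            simulate_acquisition(cfg, g, p, n_reads=10)


def _rc_space(genome):
    from spacerscreen.genome import reverse_complement

    return reverse_complement(genome.sequence)


class TestRnaseqSimulation:
    def test_zero_amplitude_gives_flat_poisson_baseline(self):
        cfg = preset_cfg(seed=54, rnaseq_amplitude=0.0)
        g = simulate_genome(cfg)
        cov = simulate_rnaseq(cfg, g)
        vals = cov.values[5.0]["+"]
        assert abs(vals.mean() - cfg.rnaseq_baseline) < 3 * np.sqrt(cfg.rnaseq_baseline / len(vals))

    def test_early_operon_elevated_at_five_minutes(self):
        cfg = preset_cfg(seed=55)
        g = simulate_genome(cfg)
        cov = simulate_rnaseq(cfg, g)
        t5 = cov.values[5.0]["+"]
        inside = t5[200:3000].mean()
        outside = t5[3000:].mean()
        assert inside - outside > 0.8 * cfg.rnaseq_amplitude * 0.9

    def test_late_operon_gains_coverage_only_after_five_minutes(self):
        cfg = preset_cfg(seed=56)
        g = simulate_genome(cfg)
        cov = simulate_rnaseq(cfg, g)
        pl5 = cov.values[5.0]["+"][3000:].mean()
        pl15 = cov.values[15.0]["+"][3000:].mean()
        assert pl5 < cfg.rnaseq_baseline * 1.5
        assert pl15 > pl5 + 0.5 * cfg.rnaseq_amplitude


def test_enrichment_tracks_expression_when_fitness_proportional_to_it():
    """Fitness set proportional to 5-minute transcript abundance yields a
    strong positive enrichment-expression correlation."""
    cfg = preset_cfg("WT", seed=57, fitness_noise_sd=0.0, read_depth=500_000)
    g = simulate_genome(cfg)
    lib = default_library(g, cfg)
    cov = simulate_rnaseq(cfg, g)
    norm = cov.normalized()
    w = []
    for r in lib.records:
        mrna = "-" if r.strand == "+" else "+"
        w.append(0.2 + float(np.mean(norm.values[5.0][mrna][r.start : r.end])))
    tables = simulate_screen(lib, g, cfg, fitness_override=np.array(w))
    enr = compute_enrichment(tables["t5h"], tables["t0"])
    r, n = correlate_with_expression(enr, cov, 5.0, lib.records, g)
    assert n > 100
    assert r > 0.5
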