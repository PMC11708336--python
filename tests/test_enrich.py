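"""Frequencies, enrichment ratios, group summaries, expression correlation."""

import math

import numpy as np
import pandas as pd
import pytest

from spacerscreen.enrich import (
    annotate_enrichment,
    compute_enrichment,
    compute_frequencies,
    correlate_with_expression,
    group_stats,
    summarize_groups,
)
from spacerscreen.extract import CountTable
from spacerscreen.simulate import (
    SimulationConfig,
    default_library,
    simulate_rnaseq,
    simulate_screen,
)


def table(sample_id, counts):
    return CountTable(sample_id=sample_id, counts=dict(counts))


class TestFrequencies:
    def test_two_spacer_arithmetic(self):
        assert compute_frequencies(table("s", {"A": 90, "B": 10})) == {"A": 0.9, "B": 0.1}

    def test_single_spacer(self):
        assert compute_frequencies(table("s", {"A": 1})) == {"A": 1.0}

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        counts = {f"s{i}": int(c) for i, c in enumerate(rng.integers(1, 1000, 500))}
        freqs = compute_frequencies(table("s", counts))
        assert math.fsum(freqs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_table_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            compute_frequencies(table("s", {}))


class TestEnrichment:
    def test_identical_tables_give_unit_enrichment(self):
        t = table("x", {"A": 10, "B": 20, "C": 5})
        enr = compute_enrichment(t, t)
        assert np.allclose(enr["enrichment"], 1.0)

    def test_hand_arithmetic(self):
        enr = compute_enrichment(table("post", {"A": 90, "B": 10}), table("pre", {"A": 50, "B": 50}))
        by = dict(zip(enr["spacer_seq"], enr["enrichment"]))
        assert by == pytest.approx({"A": 1.8, "B": 0.2})

    def test_absent_at_t0_is_na_under_default_policy(self):
        enr = compute_enrichment(table("post", {"A": 5, "B": 95}), table("pre", {"A": 0, "B": 100}))
        by = dict(zip(enr["spacer_seq"], enr["enrichment"]))
        assert np.isnan(by["A"]) and by["B"] == pytest.approx(0.95 / 1.0)

    def test_pseudocount_converges_to_na_policy_for_detected_spacers(self):
        pre = table("pre", {"A": 40, "B": 60, "C": 0})
        post = table("post", {"A": 70, "B": 20, "C": 10})
        exact = compute_enrichment(post, pre)
        for alpha in (1.0, 0.1, 0.01, 0.001):
            approx = compute_enrichment(post, pre, zero_policy="pseudocount", pseudocount=alpha)
            merged = exact.merge(approx, on="spacer_seq", suffixes=("_na", "_pc"))
            detected = merged[merged["count_pre_na"] > 0]
            err = np.abs(detected["enrichment_pc"] - detected["enrichment_na"]).max()
            if alpha <= 0.001:
                assert err < 1e-3
        # and the pseudocount path gives the absent spacer a finite ratio
        assert np.isfinite(approx["enrichment"]).all()

    def test_unknown_zero_policy_rejected(self):
        t = table("x", {"A": 1})
        with pytest.raises(ValueError):
            compute_enrichment(t, t, zero_policy="bogus")


class TestGroupSummaries:
    def test_identical_groups_give_t0_p1(self):
        enr = pd.DataFrame(
            {
                "spacer_seq": list("abcdef"),
                "enrichment": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                "region": ["PE"] * 3 + ["PL"] * 3,
            }
        )
        a, b, res = summarize_groups(enr, {"region": "PE"}, {"region": "PL"}, "PE", "PL")
        assert res.t == 0 and res.p == pytest.approx(1.0)
        assert a.n == b.n == 3

    def test_mean_sd_and_welch_match_closed_form(self):
        enr = pd.DataFrame(
            {
                "spacer_seq": list("abcdef"),
                "enrichment": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "region": ["PE"] * 3 + ["PL"] * 3,
            }
        )
        a, b, res = summarize_groups(enr, {"region": "PE"}, {"region": "PL"}, "PE", "PL")
        assert (a.mean, a.sd) == (pytest.approx(2.0), pytest.approx(1.0))
        assert (b.mean, b.sd) == (pytest.approx(5.0), pytest.approx(1.0))
        # closed form: t = (2-5)/sqrt(1/3+1/3) = -3/sqrt(2/3)
        assert res.t == pytest.approx(-3 / math.sqrt(2 / 3))
        assert res.df == pytest.approx(4.0)

    def test_na_enrichments_are_excluded(self):
        enr = pd.DataFrame(
            {
                "spacer_seq": list("abcd"),
                "enrichment": [1.0, np.nan, 2.0, 3.0],
                "region": ["PE", "PE", "PE", "PL"],
            }
        )
        gs = group_stats(enr)
        assert gs.set_index("group").loc["PE", "n"] == 2

    def test_small_group_rejected_for_test(self):
        enr = pd.DataFrame(
            {"spacer_seq": list("abc"), "enrichment": [1.0, 2.0, 3.0], "region": ["PE", "PL", "PL"]}
        )
        with pytest.raises(ValueError, match="n >= 2"):
            summarize_groups(enr, {"region": "PE"}, {"region": "PL"})


class TestSelectionProperties:
    def test_neutral_null_centred_on_unit_enrichment(self, small_genome):
        cfg = SimulationConfig(
            seed=5, genome_length=small_genome.length, step=10,
            read_depth=200_000, fitness_noise_sd=0.0,
        )
        lib = default_library(small_genome, cfg)
        n = len(lib.records)
        tables = simulate_screen(lib, small_genome, cfg, fitness_override=np.ones(n))
        enr = compute_enrichment(tables["t5h"], tables["t0"])
        vals = enr["enrichment"].dropna()
        se = vals.std() / np.sqrt(len(vals))
        assert abs(vals.mean() - 1.0) < 3 * se
        frac_up = (vals > 1).mean()
        assert abs(frac_up - 0.5) < 3 * np.sqrt(0.25 / len(vals))

    def test_planted_fitness_follows_one_round_selection_law(self, small_genome):
        cfg = SimulationConfig(
            seed=6, genome_length=small_genome.length, step=10,
            read_depth=500_000, fitness_noise_sd=0.0,
            t0_dispersion_shape=float("inf"),
            selection_rounds={"t5h": 1.0},
        )
        lib = default_library(small_genome, cfg)
        n = len(lib.records)
        w = np.ones(n)
        w[0] = 10.0
        tables = simulate_screen(lib, small_genome, cfg, fitness_override=w)
        enr = compute_enrichment(tables["t5h"], tables["t0"])
        by = dict(zip(enr["spacer_seq"], enr["enrichment"]))
        expected = 10.0 / w.mean()
        observed = by[lib.records[0].sequence]
        # multinomial noise at this depth keeps the estimate within a few percent
        assert observed == pytest.approx(expected, rel=0.1)


class TestExpressionCorrelation:
    def test_proportional_and_antiproportional_vectors(self, small_genome):
        cfg = SimulationConfig(seed=7, genome_length=small_genome.length, step=50)
        cov = simulate_rnaseq(cfg, small_genome)
        lib = default_library(small_genome, cfg)
        minus = [r for r in lib.records if r.strand == "-"][:12]
        norm = cov.normalized()
        expr = [
            float(np.mean(norm.values[5.0]["+"][r.start : r.end])) for r in minus
        ]
        enr = pd.DataFrame(
            {"spacer_seq": [r.sequence for r in minus], "enrichment": expr}
        )
        r, n = correlate_with_expression(enr, cov, 5.0, minus, small_genome)
        assert n == len(minus) and r == pytest.approx(1.0)
        enr["enrichment"] = [-e + 100 for e in expr]
        r, _ = correlate_with_expression(enr, cov, 5.0, minus, small_genome)
        assert r == pytest.approx(-1.0)

    def test_too_few_spacers_is_an_error(self, small_genome):
        cfg = SimulationConfig(seed=8, genome_length=small_genome.length)
        cov = simulate_rnaseq(cfg, small_genome)
        enr = pd.DataFrame({"spacer_seq": ["AAA"], "enrichment": [1.0]})
        with pytest.raises(ValueError, match="need >= 3"):
            correlate_with_expression(enr, cov, 5.0, [], small_genome)


def test_annotation_labels_region_strand_and_targeting(small_genome):
    cfg = SimulationConfig(seed=9, genome_length=small_genome.length, step=100)
    lib = default_library(small_genome, cfg)
    counts = CountTable(sample_id="t", counts={r.sequence: 10 for r in lib.records})
    enr = annotate_enrichment(compute_enrichment(counts, counts), lib.records, small_genome)
    known = enr[enr["region"] != "unmapped"]
    assert len(known) > 0
    minus_in_operon = known[(known["strand"] == "-") & (known["region"] != "untranscribed")]
    assert minus_in_operon["targeting"].all()
    plus_rows = known[known["strand"] == "+"]
    assert not plus_rows["targeting"].any()
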