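"""Windowed frequency profiles, cumulative curves, subclass counting and
species summaries."""

import numpy as np
import pytest

from g4scan import (
    AnchoredMatch,
    SyntheticConfig,
    cumulative_distribution,
    frequency_profile,
    generate_flank_set,
    percent_positive,
    species_summary,
    subclass_count,
    tes_strand_insert_profile,
)


def up(gene, coord, span=15, strand="non-template"):
    return AnchoredMatch(gene, "TSS", "upstream", coord, span, strand)


def down(gene, coord, span=15, strand="non-template"):
    return AnchoredMatch(gene, "TES", "downstream", coord, span, strand)


class TestFrequencyProfile:
    def test_single_match_single_window(self):
        p = frequency_profile([up("g", -50)], n_sequences=100)
        assert p.frequencies[-1] == 1.0  # window -100..-1
        assert np.all(p.frequencies[:-1] == 0)

    def test_five_matches_in_one_window(self):
        matches = [up(f"g{i}", -101 - 10 * i) for i in range(5)]
        p = frequency_profile(matches, n_sequences=50)
        # -200..-101 is the second window from the anchor
        assert p.frequencies[-2] == 10.0
        assert p.counts.sum() == 5

    def test_empty_input_all_zero(self):
        p = frequency_profile([], 10, anchor="TSS", side="upstream")
        assert np.all(p.counts == 0) and len(p.counts) == 50

    def test_count_conservation(self):
        matches = [up(f"g{i}", -(i % 4900) - 20) for i in range(200)]
        p = frequency_profile(matches, n_sequences=77)
        assert p.counts.sum() == 200
        assert np.allclose(p.frequencies * 77 / 100, p.counts)

    def test_strand_scope_additivity(self):
        matches = [up("a", -10), up("b", -700, strand="template"), up("c", -1500)]
        both = frequency_profile(matches, 10)
        nt = frequency_profile(matches, 10, strand_scope="non-template")
        t = frequency_profile(matches, 10, strand_scope="template")
        assert np.all(both.counts == nt.counts + t.counts)

    def test_invariance_under_reordering(self):
        matches = [up("a", -10), up("b", -700), up("c", -1500)]
        p1 = frequency_profile(matches, 10)
        p2 = frequency_profile(list(reversed(matches)), 10)
        assert np.all(p1.counts == p2.counts)

    def test_partial_last_window_flagged(self):
        p = frequency_profile([up("g", -50)], 10, window=300, flank_len=5000)
        assert p.partial_last
        assert p.window_starts[0] == -5000 and p.window_ends[0] == -4801

    def test_errors(self):
        with pytest.raises(ValueError, match="n_sequences"):
            frequency_profile([up("g", -50)], 0)
        with pytest.raises(ValueError, match="mixed"):
            frequency_profile([up("g", -50), down("g", 50)], 10)
        with pytest.raises(ValueError, match="strand_scope"):
            frequency_profile([], 10, strand_scope="sense")


class TestTesInsertProfile:
    def test_single_non_template_match(self):
        nt, t = tes_strand_insert_profile([down("g", 30)], 100)
        assert nt.window == 20 and t.window == 20
        assert nt.counts[1] == 1 and nt.counts.sum() == 1  # window +21..+40
        assert np.all(t.counts == 0)

    def test_strand_swap_symmetry(self):
        matches = [down("a", 30), down("b", 500, strand="template"), down("c", 999)]
        swapped = [
            AnchoredMatch(
                a.gene_id,
                a.anchor,
                a.side,
                a.coord,
                a.span,
                "template" if a.strand_class == "non-template" else "non-template",
            )
            for a in matches
        ]
        nt1, t1 = tes_strand_insert_profile(matches, 10)
        nt2, t2 = tes_strand_insert_profile(swapped, 10)
        assert np.all(nt1.counts == t2.counts) and np.all(t1.counts == nt2.counts)

    def test_empty_input(self):
        nt, t = tes_strand_insert_profile([], 10)
        assert np.all(nt.counts == 0) and np.all(t.counts == 0) and len(nt.counts) == 50

    def test_distal_matches_filtered(self):
        nt, _ = tes_strand_insert_profile([down("g", 1001), down("g", 1000)], 10)
        assert nt.counts.sum() == 1


class TestCumulativeDistribution:
    def test_hand_enumerated_three_motifs(self):
        anchored = [
            up("A", -24),
            up("A", -300, strand="template"),
            up("B", -150),
        ]
        c = cumulative_distribution(anchored, ["A", "B"], 400)
        pct = c.cum_positive_pct
        assert pct[22] == 0 and pct[23] == 50.0 and pct[148] == 50.0
        assert pct[149] == 100.0 and pct[-1] == 100.0
        steps = np.flatnonzero(np.diff(c.cum_motifs)) + 2  # distances where count rises
        assert list(steps) == [24, 150, 300]

    def test_no_motifs(self):
        c = cumulative_distribution([], ["A", "B"], 100)
        assert np.all(c.cum_motifs == 0) and np.all(c.cum_positive_pct == 0)

    def test_saturation(self):
        anchored = [up(g, -15) for g in "ABCD"]
        c = cumulative_distribution(anchored, list("ABCD"), 100)
        assert np.all(c.cum_positive_pct[14:] == 100.0)
        assert np.all(c.cum_positive_pct[:14] == 0.0)

    def test_non_decreasing(self):
        rng = np.random.default_rng(1)
        anchored = [up(f"g{i%37}", -int(c)) for i, c in enumerate(rng.integers(20, 4800, 300))]
        c = cumulative_distribution(anchored, [f"g{i}" for i in range(40)], 5000)
        assert np.all(np.diff(c.cum_motifs) >= 0)
        assert np.all(np.diff(c.cum_positive_pct) >= 0)
        assert c.cum_motifs[-1] == 300

    def test_endpoint_equals_percent_positive(self):
        anchored = [up("A", -24), up("B", -4999, span=10)]
        curve = cumulative_distribution(anchored, list("ABCD"), 5000)
        assert percent_positive(anchored, list("ABCD"), 5000) == curve.cum_positive_pct[-1]
        assert curve.cum_positive_pct[-1] == 50.0

    def test_errors(self):
        with pytest.raises(ValueError, match="missing"):
            cumulative_distribution([up("Z", -24)], ["A"], 100)
        with pytest.raises(ValueError, match="empty"):
            percent_positive([], [], 100)
        with pytest.raises(ValueError, match="upstream"):
            cumulative_distribution([down("A", 24)], ["A"], 100)


class TestSubclassCount:
    def test_examples(self):
        assert subclass_count(["GGGTGGGTGGGTGGG"]) == 1
        assert subclass_count(["GGGTTGGGTGGGTGGG"]) == 0
        assert subclass_count(["GGGGTGGGTGGGTGGG"]) == 0
        assert subclass_count(["GGGTGGGTGGGTGGG", "GGGAGGGCGGGTGGG", "GGG"]) == 2


class TestSpeciesSummary:
    def test_density_ordering_and_extremes(self):
        dense = SyntheticConfig(
            n_genes=150, flank_len=1000, upstream_rate=1e-3, sides=("upstream",), seed=3
        )
        sparse = SyntheticConfig(
            n_genes=150, flank_len=1000, upstream_rate=1e-4, sides=("upstream",), seed=4
        )
        none = SyntheticConfig(
            n_genes=30, flank_len=1000, upstream_rate=0.0, upstream_fold=0.0, sides=("upstream",), seed=5
        )
        sets = [
            (name, generate_flank_set(cfg)[0])
            for name, cfg in [("dense", dense), ("sparse", sparse), ("barren", none)]
        ]
        df = species_summary(sets)
        assert list(df.species) == ["dense", "sparse", "barren"]
        assert df.percent_positive[0] > df.percent_positive[1] > df.percent_positive[2]
        assert df.percent_positive[2] == 0.0

    def test_all_planted_is_100(self):
        cfg = SyntheticConfig(
            n_genes=25, flank_len=1000, fixed_upstream_coord=-100, sides=("upstream",), seed=6
        )
        flanks, _ = generate_flank_set(cfg)
        df = species_summary([("sp", flanks)])
        assert df.percent_positive[0] == 100.0 and df.n_genes[0] == 25

    def test_duplicate_label_rejected(self):
        cfg = SyntheticConfig(n_genes=5, flank_len=500, sides=("upstream",), seed=7)
        flanks, _ = generate_flank_set(cfg)
        with pytest.raises(ValueError, match="duplicate"):
            species_summary([("a", flanks), ("a", flanks)])
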