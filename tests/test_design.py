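"""Reduction digestion, size selection, fragment/spacing statistics and
design comparison."""

import math

import numpy as np
import pytest

from restfrag import (
    ContractError,
    Fragment,
    InputError,
    LibraryDesign,
    SizeWindow,
    compare_designs,
    digest,
    distance_summary,
    effective_length,
    find_sites,
    genetic_distance,
    get_enzyme,
    interfragment_distances,
    randomness_test,
    reduce_fragments,
    run_design,
    size_select,
)

from conftest import random_dna

TAQI = get_enzyme("TaqI")
MSEI = get_enzyme("MseI")


def frag(start, end, flanking=("TaqI", "TaqI"), seq_id="s"):
    return Fragment(seq_id, start, end, flanking)


class TestReduce:
    def test_fragment_with_site_removed(self):
        seq = "CGATTAAT"
        assert reduce_fragments([frag(0, 8)], seq, [MSEI]) == []

    def test_fragment_without_site_retained(self):
        seq = "CGAGGCCT"  # contains HaeIII GGCC but not MseI TTAA
        assert reduce_fragments([frag(0, 8)], seq, [MSEI]) == [frag(0, 8)]

    def test_empty_reduction_set_is_identity(self):
        frags = [frag(0, 4), frag(4, 8)]
        assert reduce_fragments(frags, "CGATTAAT", []) == frags

    def test_site_must_lie_fully_inside_fragment(self):
        # TTAA straddles the boundary at 6: neither fragment contains it whole
        seq = "CCCCCT" + "TAACCC"
        frags = [frag(0, 6), frag(6, 12)]
        assert reduce_fragments(frags, seq, [MSEI]) == frags

    def test_monotone_in_reduction_set(self, rng):
        seq = random_dna(rng, 30_000)
        frags = digest(seq, TAQI)
        sets = [[], [MSEI], [MSEI, get_enzyme("ApoI")],
                [MSEI, get_enzyme("ApoI"), get_enzyme("BstUI")]]
        counts = [len(reduce_fragments(frags, seq, s)) for s in sets]
        assert counts == sorted(counts, reverse=True)


class TestSizeSelect:
    def test_inclusive_bounds_cutpoint(self):
        w = SizeWindow(80, 100)
        assert size_select([frag(0, 80)], w) == [frag(0, 80)]
        assert size_select([frag(0, 101)], w) == []

    def test_filled_convention_adds_overhang_per_enzyme_end(self):
        f = frag(0, 96, ("TaqI", "TaqI"))
        assert effective_length(f, "filled") == 100  # +2 per filled CG overhang
        assert size_select([f], SizeWindow(80, 100), "filled") == [f]

    def test_terminus_ends_add_nothing(self):
        f = frag(0, 96, ("TERMINUS", "TaqI"))
        assert effective_length(f, "filled") == 98

    def test_monotone_in_window(self, rng):
        seq = random_dna(rng, 30_000)
        frags = digest(seq, TAQI)
        narrow = len(size_select(frags, SizeWindow(85, 95)))
        wide = len(size_select(frags, SizeWindow(80, 100)))
        wider = len(size_select(frags, SizeWindow(60, 120)))
        assert narrow <= wide <= wider


class TestRunDesign:
    @staticmethod
    def _five_fragment_genome():
        # six TaqI sites spaced so the five interior cut-to-cut fragments are
        # exactly 90 bp and free of TTAA; terminal fragments fall outside
        # the window.
        filler = ("ACG" * 29)[:86]  # no T: cannot contain TCGA or TTAA
        seq = "A" * 10 + ("TCGA" + filler) * 5 + "TCGA" + "AA"
        return seq

    def test_constructed_fixture_counts_five(self):
        seq = self._five_fragment_genome()
        design = LibraryDesign(TAQI, (MSEI,), SizeWindow(80, 100))
        frags, stats = run_design([("chr", seq)], design)
        assert stats.count == 5
        assert all(f.end - f.start == 90 for f in frags)
        assert stats.cumulative_bp == 450

    def test_no_site_genome(self):
        design = LibraryDesign(TAQI, (), SizeWindow(1, 100))
        frags, stats = run_design([("chr", "ACGGACGGAC")], design)
        assert stats.count == 1  # whole sequence, length 10, inside window

    def test_empty_genome_rejected(self):
        with pytest.raises(InputError):
            run_design([], LibraryDesign(TAQI))

    def test_retained_are_subset_of_digest(self, rng):
        seq = random_dna(rng, 20_000)
        design = LibraryDesign(TAQI, (MSEI,), SizeWindow(50, 200))
        frags, _ = run_design([("c", seq)], design)
        full = set(digest(seq, TAQI, seq_id="c"))
        assert set(frags) <= full

    def test_gc_excludes_ambiguous_bases(self):
        seq = "GCNNNNAT"  # one fragment; GC over unambiguous bases = 2/4
        design = LibraryDesign(TAQI, (), SizeWindow(1, 100))
        _, stats = run_design([("c", seq)], design)
        assert stats.gc_fraction == pytest.approx(0.5)

    def test_window_counts_match_renewal_expectation(self, rng):
        """On i.i.d. genomes the number of digest fragments in a size window
        follows the analytic renewal expectation n*p^2*(1-p)^(L-7) summed
        over the window (p = per-position TaqI match probability), within
        3 standard errors over 100 seeded replicates."""
        n, p = 50_000, 0.25**4
        lo, hi = 80, 100
        expected = n * p * p * sum((1 - p) ** (L - 7) for L in range(lo, hi + 1))
        counts = []
        for _ in range(100):
            seq = random_dna(rng, n)
            counts.append(len(size_select(digest(seq, TAQI), SizeWindow(lo, hi))))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / math.sqrt(len(counts))
        assert abs(mean - expected) <= 3 * se


class TestDistances:
    def test_gap_mode(self):
        frs = [frag(0, 10), frag(20, 30), frag(50, 60)]
        assert interfragment_distances(frs, "gap") == [10, 20]

    def test_start_to_start_and_midpoint(self):
        frs = [frag(0, 10), frag(20, 30)]
        assert interfragment_distances(frs, "start_to_start") == [20]
        assert interfragment_distances(frs, "midpoint") == [20]

    def test_single_fragment_empty(self):
        assert interfragment_distances([frag(0, 10)], "gap") == []

    def test_never_spans_sequences(self):
        frs = [frag(0, 10, seq_id="a"), frag(50, 60, seq_id="b")]
        assert interfragment_distances(frs, "gap") == []

    def test_overlap_rejected(self):
        with pytest.raises(ContractError):
            interfragment_distances([frag(0, 10), frag(5, 20)], "gap")

    def test_summary_examples(self):
        d = distance_summary([10, 20, 30])
        assert d.median == 20 and d.max == 30 and d.n == 3
        const = distance_summary([7] * 100)
        assert const.p5 == const.p25 == const.median == const.p75 == const.p95 == 7

    def test_summary_linear_interpolation(self):
        d = distance_summary(list(range(1, 100)))
        assert d.p25 == pytest.approx(25.5)
        assert d.p75 == pytest.approx(74.5)

    def test_summary_empty_rejected(self):
        with pytest.raises(InputError):
            distance_summary([])


class TestRandomness:
    def test_clustered_placement_rejected(self, rng):
        starts = np.sort(rng.choice(5_000, size=200, replace=False))
        frs = [frag(int(s), int(s) + 1) for s in starts]
        r = randomness_test(frs, 1_000_000)
        assert r.dispersion_index > 10
        assert r.dispersion_p < 0.001

    def test_periodic_placement_zero_dispersion(self):
        frs = [frag(i * 1000 + 5, i * 1000 + 6) for i in range(100)]
        r = randomness_test(frs, 100_000)
        assert r.dispersion_index == 0.0

    def test_underpowered_rejected(self):
        with pytest.raises(InputError):
            randomness_test([frag(0, 10)] * 5, 1000)

    def test_sequence_length_contract(self):
        frs = [frag(i * 10, i * 10 + 5) for i in range(20)]
        with pytest.raises(ContractError):
            randomness_test(frs, 100)


class TestGeneticDistance:
    @pytest.mark.parametrize(
        "kb,rate,cm",
        [(7.75, 15.7, 0.12), (234, 15.7, 3.67), (0, 15.7, 0.0)],
    )
    def test_conversion(self, kb, rate, cm):
        assert round(genetic_distance(kb, rate), 2) == cm

    def test_negative_rejected(self):
        with pytest.raises(InputError):
            genetic_distance(-1, 15.7)


class TestCompareDesigns:
    def test_reduction_monotonicity_across_designs(self, rng):
        seq = random_dna(rng, 60_000)
        apoi, bstui = get_enzyme("ApoI"), get_enzyme("BstUI")
        w = SizeWindow(80, 100)
        designs = [
            ("T/A", LibraryDesign(TAQI, (apoi,), w)),
            ("T/M", LibraryDesign(TAQI, (MSEI,), w)),
            ("T/AMB", LibraryDesign(TAQI, (apoi, MSEI, bstui), w)),
        ]
        table = compare_designs([("c", seq)], designs).set_index("design")
        assert (
            table.loc["T/AMB", "count"]
            <= min(table.loc["T/A", "count"], table.loc["T/M", "count"])
        )

    def test_scheme_row_counts_two_per_rad_site(self, rng):
        spacer = "".join(rng.choice(list("AT"), size=25))
        seq = spacer + ("CCTGCAGG" + spacer) * 62
        assert len(find_sites(seq, "CCTGCAGG")) == 62
        table = compare_designs(
            [("c", seq)], [], scheme_enzymes=[get_enzyme("SbfI")]
        )
        assert table.loc[0, "count"] == 124

    def test_empty_reduction_full_window_equals_digest(self, rng):
        seq = random_dna(rng, 10_000)
        design = LibraryDesign(TAQI, (), SizeWindow(1, 10**9))
        table = compare_designs([("c", seq)], [design])
        assert table.loc[0, "count"] == len(digest(seq, TAQI))

    def test_windows_override_sweeps_designs(self, rng):
        seq = random_dna(rng, 30_000)
        design = LibraryDesign(TAQI, (MSEI,))
        wins = [SizeWindow(80, 100), SizeWindow(180, 200)]
        table = compare_designs([("c", seq)], [design], windows=wins)
        assert list(table["min_bp"]) == [80, 180]


class TestLibraryDesignValidation:
    def test_reduction_enzyme_equal_to_enzyme1_rejected(self):
        with pytest.raises(InputError):
            LibraryDesign(TAQI, (get_enzyme("TaqI"),))

    def test_isoschizomer_of_enzyme1_rejected(self):
        with pytest.raises(InputError):
            LibraryDesign(MSEI, (get_enzyme("TruI"),))

    def test_scheme_enzyme_rejected_as_enzyme1(self):
        with pytest.raises(InputError):
            LibraryDesign(get_enzyme("SbfI"))
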