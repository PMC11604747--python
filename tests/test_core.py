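"""Collinearity metrics: matching, correspondence, orientation, coherence,
misplacement."""

import math

import pytest
from hypothesis import given, strategies as st

from collinearity_qc import (
    CollinearityQCError,
    ConfigError,
    NoSharedGenesError,
    correspondence_table,
    find_misplacements,
    gap_divergence,
    infer_orientation,
    match_genes,
    summarize_chromosome,
)
from conftest import make_annotation, make_matched


def genes_on(seq, ids, start=1, length=1000, gap=1000, reverse=False):
    """Lay out ids consecutively on one sequence; optionally in reverse order."""
    order = list(reversed(ids)) if reverse else list(ids)
    out = []
    cur = start
    for gid in order:
        out.append((gid, seq, cur, cur + length - 1))
        cur += length + gap
    return out


class TestMatchGenes:
    def test_identity_matches_every_gene(self, identity_matched, identity_genes):
        assert len(identity_matched) == len(identity_genes)
        assert not identity_matched.ref_only and not identity_matched.tgt_only

    def test_missing_target_genes_land_in_ref_only(self):
        ref = genes_on("chr1", [f"g{i}" for i in range(10)])
        tgt = [g for g in ref if g[0] not in ("g3", "g7")]
        matched = make_matched(ref, tgt)
        assert len(matched) == 8
        assert matched.ref_only == {"g3", "g7"}
        assert not matched.tgt_only

    def test_disjoint_id_universes_raise(self):
        ref = make_annotation("reference", genes_on("chr1", ["a", "b"]))
        tgt = make_annotation("target", genes_on("sc1", ["x", "y"]))
        with pytest.raises(NoSharedGenesError, match="no shared gene identifiers"):
            match_genes(ref, tgt)

    def test_matching_is_order_independent(self):
        ref = genes_on("chr1", ["a", "b", "c"])
        tgt = genes_on("sc1", ["c", "a", "b"])
        m1 = make_matched(ref, tgt)
        m2 = make_matched(list(reversed(ref)), tgt)
        assert m1.pairs.keys() == m2.pairs.keys()
        assert all(m1.pairs[k] == m2.pairs[k] for k in m1.pairs)


class TestCorrespondence:
    def test_identity_one_sequence_per_chromosome(self, identity_matched):
        table = correspondence_table(identity_matched)
        assert all(list(row) == [chrom] for chrom, row in table.items())

    def test_split_chromosome_counts_each_contig(self):
        ref = genes_on("chrA", [f"a{i}" for i in range(6)]) + \
              genes_on("chrB", [f"b{i}" for i in range(4)])
        tgt = (genes_on("ctg1", ["a0", "a1"]) + genes_on("ctg2", ["a2", "a3"])
               + genes_on("ctg3", ["a4", "a5"]) + genes_on("ctg4", [f"b{i}" for i in range(4)]))
        table = correspondence_table(make_matched(ref, tgt))
        assert len(table["chrA"]) == 3 and len(table["chrB"]) == 1

    def test_fused_chromosomes_share_one_scaffold(self):
        ref = genes_on("chrA", ["a0", "a1"]) + genes_on("chrB", ["b0", "b1"])
        tgt = genes_on("sc1", ["a0", "a1", "b0", "b1"])
        matched = make_matched(ref, tgt)
        table = correspondence_table(matched)
        assert list(table["chrA"]) == ["sc1"] and list(table["chrB"]) == ["sc1"]
        assert sum(sum(row.values()) for row in table.values()) == len(matched)


def orientation_fixture(tgt_starts):
    """Matched set with one group whose target starts are as given."""
    n = len(tgt_starts)
    ref = genes_on("chr1", [f"g{i}" for i in range(n)])
    tgt = [(f"g{i}", "sc1", s, s + 10) for i, s in enumerate(tgt_starts)]
    return make_matched(ref, tgt)


class TestOrientation:
    def test_strictly_ascending_is_forward(self):
        call = infer_orientation(orientation_fixture([10, 20, 30, 40]), "chr1", "sc1")
        assert call.call == "forward" and call.frac_ascending == 1.0

    def test_nine_of_ten_steps_ascending_is_forward_at_exact_threshold(self):
        starts = [i * 100 for i in range(1, 12)]
        starts[5], starts[6] = starts[6], starts[5]  # one descending step
        call = infer_orientation(orientation_fixture(starts), "chr1", "sc1")
        assert call.n_comparisons == 10
        assert call.frac_ascending == pytest.approx(0.9)
        assert call.call == "forward"  # "at least 90%" is inclusive

    def test_eight_of_ten_steps_ascending_is_unclear(self):
        starts = [i * 100 for i in range(1, 12)]
        starts[2], starts[3] = starts[3], starts[2]
        starts[7], starts[8] = starts[8], starts[7]
        call = infer_orientation(orientation_fixture(starts), "chr1", "sc1")
        assert call.frac_ascending == pytest.approx(0.8)
        assert call.call == "unclear"

    def test_single_gene_group_is_single(self):
        call = infer_orientation(orientation_fixture([100]), "chr1", "sc1")
        assert call.call == "single" and call.n_comparisons == 0

    def test_all_tied_starts_are_single(self):
        call = infer_orientation(orientation_fixture([100, 100, 100]), "chr1", "sc1")
        assert call.call == "single"

    def test_ties_excluded_from_both_fractions(self):
        # steps: +, 0, + -> 2 comparisons, both ascending
        call = infer_orientation(orientation_fixture([10, 20, 20, 30]), "chr1", "sc1")
        assert call.n_comparisons == 2
        assert call.frac_ascending == 1.0 and call.call == "forward"

    def test_unknown_group_raises(self):
        with pytest.raises(CollinearityQCError):
            infer_orientation(orientation_fixture([10, 20]), "chr1", "nope")

    @given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=2,
                    max_size=8, unique=True))
    def test_fractions_match_brute_force_and_reversal_swaps_them(self, starts):
        call = infer_orientation(orientation_fixture(starts), "chr1", "sc1")
        ups = sum(1 for a, b in zip(starts, starts[1:]) if b > a)
        downs = sum(1 for a, b in zip(starts, starts[1:]) if b < a)
        assert call.n_comparisons == ups + downs
        assert call.frac_ascending == pytest.approx(ups / (ups + downs))
        assert call.frac_descending == pytest.approx(downs / (ups + downs))
        rev = infer_orientation(orientation_fixture(starts[::-1]), "chr1", "sc1")
        assert rev.frac_ascending == pytest.approx(call.frac_descending)
        assert rev.frac_descending == pytest.approx(call.frac_ascending)
        swap = {"forward": "reverse", "reverse": "forward", "unclear": "unclear"}
        assert rev.call == swap[call.call]


def adjacency_fixture(ref_gaps, tgt_gaps, length=100):
    """One chromosome whose reference and target gap sequences are given."""
    def lay(seq, gaps):
        out, cur = [], 1
        for i in range(len(gaps) + 1):
            out.append((f"g{i}", seq, cur, cur + length - 1))
            if i < len(gaps):
                cur += length + gaps[i]
        return out
    return make_matched(lay("chr1", ref_gaps), lay("sc1", tgt_gaps))


class TestGapDivergence:
    def test_identity_is_fully_coherent(self, identity_matched):
        comparisons = gap_divergence(identity_matched)
        assert comparisons and all(c.divergence == 0 and c.coherent for c in comparisons)

    def test_hand_computed_divergences_and_strictness(self):
        comparisons = gap_divergence(adjacency_fixture([1000, 2000], [1400, 2600]),
                                     threshold=500)
        assert [c.divergence for c in comparisons] == [400, 600]
        assert [c.coherent for c in comparisons] == [True, False]

    def test_divergence_equal_to_threshold_is_not_coherent(self):
        (c,) = gap_divergence(adjacency_fixture([1000], [1500]), threshold=500)
        assert c.divergence == 500 and c.coherent is False

    def test_pair_on_different_target_sequences_is_broken(self):
        ref = genes_on("chr1", ["g0", "g1", "g2"])
        tgt = genes_on("sc1", ["g0", "g1"]) + genes_on("sc2", ["g2"])
        comparisons = gap_divergence(make_matched(ref, tgt))
        assert [c.status for c in comparisons] == ["compared", "broken"]
        broken = comparisons[1]
        assert broken.tgt_gap is None and broken.divergence is None and broken.coherent is None

    def test_unmatched_genes_do_not_break_the_chain(self):
        ref = genes_on("chr1", ["g0", "g1", "g2"], length=100, gap=50)
        tgt = [g for g in genes_on("sc1", ["g0", "g1", "g2"], length=100, gap=50)
               if g[0] != "g1"]
        (c,) = gap_divergence(make_matched(ref, tgt))
        assert (c.gene_a, c.gene_b) == ("g0", "g2")
        assert c.ref_gap == c.tgt_gap == 200  # spans the unmatched gene
        assert c.divergence == 0

    def test_overlapping_genes_have_negative_signed_gaps(self):
        ref = [("g0", "chr1", 1, 100), ("g1", "chr1", 51, 150)]
        tgt = [("g0", "sc1", 1, 100), ("g1", "sc1", 81, 180)]
        (c,) = gap_divergence(make_matched(ref, tgt))
        assert c.ref_gap == -50 and c.tgt_gap == -20 and c.divergence == 30

    def test_negative_threshold_rejected(self, identity_matched):
        with pytest.raises(ConfigError):
            gap_divergence(identity_matched, threshold=-1)

    @given(st.lists(st.integers(min_value=0, max_value=5000), min_size=1, max_size=6),
           st.data())
    def test_divergence_symmetric_in_genome_roles(self, ref_gaps, data):
        tgt_gaps = data.draw(st.lists(st.integers(min_value=0, max_value=5000),
                                      min_size=len(ref_gaps), max_size=len(ref_gaps)))
        fwd = gap_divergence(adjacency_fixture(ref_gaps, tgt_gaps))
        rev = gap_divergence(adjacency_fixture(tgt_gaps, ref_gaps))
        assert [c.divergence for c in fwd] == [c.divergence for c in rev]


class TestMisplacements:
    def test_mono_chromosomal_targets_yield_nothing(self, identity_matched):
        assert find_misplacements(identity_matched) == []

    def test_minority_genes_reported_with_dominant_fraction(self):
        ref = genes_on("chr2", [f"a{i}" for i in range(20)]) + \
              genes_on("chr3", [f"b{i}" for i in range(7)])
        tgt = genes_on("ctg1", [f"a{i}" for i in range(20)] + [f"b{i}" for i in range(7)])
        records = find_misplacements(make_matched(ref, tgt))
        assert len(records) == 7
        assert {r.gene_id for r in records} == {f"b{i}" for i in range(7)}
        assert all(r.dominant_chrom == "chr2" for r in records)
        assert records[0].dominant_fraction == pytest.approx(20 / 27)

    def test_even_split_breaks_tie_lexicographically(self):
        ref = genes_on("chrA", [f"a{i}" for i in range(10)]) + \
              genes_on("chrB", [f"b{i}" for i in range(10)])
        tgt = genes_on("sc1", [f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)])
        records = find_misplacements(make_matched(ref, tgt))
        assert {r.gene_id for r in records} == {f"b{i}" for i in range(10)}
        assert all(r.dominant_chrom == "chrA" for r in records)

    def test_records_sorted_by_target_seq_then_ref_start(self):
        ref = (genes_on("chrA", ["a0", "a1", "a2"]) + genes_on("chrB", ["b0", "b1"])
               + genes_on("chrC", ["c0"]))
        tgt = (genes_on("sc1", ["a0", "a1", "a2", "b1"])
               + genes_on("sc2", ["b0", "c0"]))
        records = find_misplacements(make_matched(ref, tgt))
        assert [(r.gene_id, r.target_seq) for r in records] == \
            [("b1", "sc1"), ("c0", "sc2")]


class TestSummarizeChromosome:
    def test_identity_summary(self, identity_matched):
        rep = summarize_chromosome(identity_matched, "chrA")
        assert list(rep.correspondence) == ["chrA"]
        assert [c.call for c in rep.orientations] == ["forward"]
        assert rep.coherent_fraction == 1.0
        assert rep.n_broken == 0 and rep.misplacements == []

    def test_wholly_inverted_chromosome_is_reverse_and_coherent(self):
        ids = [f"g{i}" for i in range(6)]
        ref = genes_on("chr1", ids, gap=500)
        tgt = genes_on("sc1", ids, gap=500, reverse=True)
        rep = summarize_chromosome(make_matched(ref, tgt), "chr1")
        assert [c.call for c in rep.orientations] == ["reverse"]
        assert rep.coherent_fraction == 1.0  # reversal preserves adjacent gaps

    def test_split_chromosome_has_one_broken_adjacency(self):
        ids = [f"g{i}" for i in range(6)]
        ref = genes_on("chr1", ids)
        tgt = genes_on("ctg1", ids[:3]) + genes_on("ctg2", ids[3:])
        rep = summarize_chromosome(make_matched(ref, tgt), "chr1")
        assert len(rep.correspondence) == 2
        assert rep.n_broken == 1

    def test_no_compared_pairs_gives_nan_fraction(self):
        ref = genes_on("chr1", ["g0", "g1"])
        tgt = genes_on("sc1", ["g0"]) + genes_on("sc2", ["g1"])
        rep = summarize_chromosome(make_matched(ref, tgt), "chr1")
        assert math.isnan(rep.coherent_fraction)

    def test_unknown_chromosome_error_lists_available(self, identity_matched):
        with pytest.raises(CollinearityQCError, match="chrA, chrB"):
            summarize_chromosome(identity_matched, "chrZ")


@given(
    assignment=st.lists(
        st.tuples(st.sampled_from(["chr1", "chr2", "chr3"]),
                  st.sampled_from(["sc1", "sc2", "sc3", "sc4"])),
        min_size=1, max_size=40,
    )
)
def test_correspondence_counts_partition_the_matched_genes(assignment):
    """Every matched gene lands in exactly one (chromosome, scaffold) cell."""
    ref, tgt = [], []
    by_seq_count = {}
    for i, (chrom, scaf) in enumerate(assignment):
        r = by_seq_count.setdefault(("r", chrom), 0)
        t = by_seq_count.setdefault(("t", scaf), 0)
        ref.append((f"g{i}", chrom, 1 + 2000 * r, 1000 + 2000 * r))
        tgt.append((f"g{i}", scaf, 1 + 2000 * t, 1000 + 2000 * t))
        by_seq_count[("r", chrom)] += 1
        by_seq_count[("t", scaf)] += 1
    matched = make_matched(ref, tgt)
    table = correspondence_table(matched)
    assert sum(sum(row.values()) for row in table.values()) == len(matched)
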