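"""CSS chaining against exhaustive enumeration, thresholds, summaries,
triangulation."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import chain_oracle
from synmap import synthetic_data as sd
from synmap.formats_io import GeneticMapTable
from synmap.macrosynteny import (
    SyntenicBlock,
    SyntenyThresholds,
    derive_genetic_threshold,
    derive_physical_threshold,
    detect_css,
    detect_css_between_maps,
    genes_in_window,
    project_multiway,
    summarize,
)
from synmap.orthology import ASSIGNMENT_COLUMNS


def make_inputs(markers):
    """markers: (id, lg, cM, chrom, bp, status). Returns (assignments, map)."""
    adf = pd.DataFrame(
        [
            (m, status, chrom if status == "single_locus" else None,
             bp if status == "single_locus" else math.nan, 1e-30, 1)
            for m, lg, cm, chrom, bp, status in markers
        ],
        columns=list(ASSIGNMENT_COLUMNS),
    )
    mdf = pd.DataFrame(
        [(m, lg, cm) for m, lg, cm, *_ in markers],
        columns=["marker", "linkage_group", "cM"],
    )
    return adf, GeneticMapTable(mdf)


class TestThresholdDerivation:
    def test_gene_window_on_grapevine_scale_genome(self):
        # 200 genes on a 475 Mb / 30,434-gene genome span ~3.12 Mb
        assert derive_physical_threshold(475e6, 30_434, 200) == pytest.approx(
            3.122e6, rel=1e-3
        )

    def test_inverse_gives_gene_count_of_a_window(self):
        genes = genes_in_window(3.2e6, 475e6, 30_434)
        assert genes == pytest.approx(205.0, abs=0.1)
        assert round(genes, -2) == 200

    def test_small_exact_case_and_linearity(self):
        assert derive_physical_threshold(1e6, 1000, 1) == 1000
        assert derive_physical_threshold(1e6, 1000, 2) == 2 * derive_physical_threshold(
            1e6, 1000, 1
        )

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            derive_physical_threshold(475e6, 0, 200)

    def test_one_percent_of_map_with_floor_policy(self):
        assert derive_genetic_threshold(1463, 0.01) == pytest.approx(14.63)
        assert derive_genetic_threshold(1463, 0.01, floor_to_int=True) == 14
        assert derive_genetic_threshold(1349, 0.01) == pytest.approx(13.49)
        assert derive_genetic_threshold(100, 0.0) == 0


class TestDetectCss:
    def test_three_markers_within_gaps_form_one_block(self):
        adf, gmap = make_inputs(
            [
                ("m1", "A", 0.0, "chr1", 1.0e6, "single_locus"),
                ("m2", "A", 5.0, "chr1", 1.5e6, "single_locus"),
                ("m3", "A", 10.0, "chr1", 2.0e6, "single_locus"),
            ]
        )
        (block,) = detect_css(adf, gmap)
        assert block.n_syntenic == 3
        assert block.span_query == 10.0
        assert block.span_target == 1.0e6

    def test_target_gap_violation_leaves_no_block(self):
        adf, gmap = make_inputs(
            [
                ("m1", "A", 0.0, "chr1", 1.0e6, "single_locus"),
                ("m2", "A", 5.0, "chr1", 40.0e6, "single_locus"),
                ("m3", "A", 10.0, "chr1", 2.0e6, "single_locus"),
            ]
        )
        assert detect_css(adf, gmap) == []

    def test_query_gap_splits_into_two_blocks_matching_oracle(self):
        rows = []
        for i in range(12):
            cm = i * 2.0 if i < 6 else 13.0 + i * 2.0  # 13 cM jump at position 6
            rows.append((f"m{i:02d}", "A", cm, "chr1", 0.5e6 * i, "single_locus"))
        adf, gmap = make_inputs(rows)
        blocks = detect_css(adf, gmap)
        assert [b.n_syntenic for b in blocks] == [6, 6]
        q = gmap.df["cM"].to_numpy()
        t = adf["pos"].to_numpy()
        oracle = chain_oracle(q, t, 12.0, 3.2e6, 3)
        assert [tuple(range(0, 6)), tuple(range(6, 12))] == oracle

    def test_inversion_inside_block_does_not_break_it(self):
        adf, gmap = make_inputs(
            [
                ("m1", "A", 0.0, "chr1", 1.0e6, "single_locus"),
                ("m2", "A", 4.0, "chr1", 3.0e6, "single_locus"),
                ("m3", "A", 8.0, "chr1", 2.0e6, "single_locus"),
                ("m4", "A", 12.0, "chr1", 4.0e6, "single_locus"),
            ]
        )
        (block,) = detect_css(adf, gmap)
        assert block.n_syntenic == 4

    def test_orientation_invariance_under_coordinate_reversal(self):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(20):
            rows.append(
                (f"m{i:02d}", "A", float(i * 3), "chr1", float(rng.uniform(0, 30e6)), "single_locus")
            )
        adf, gmap = make_inputs(rows)
        fwd = detect_css(adf, gmap)
        flipped = adf.copy()
        flipped["pos"] = 30e6 - flipped["pos"]
        rev = detect_css(flipped, gmap)
        assert [{m for m, _q, _t in b.members} for b in fwd] == [
            {m for m, _q, _t in b.members} for b in rev
        ]

    def test_interspersed_markers_counted_but_not_chain_breaking(self):
        adf, gmap = make_inputs(
            [
                ("m1", "A", 0.0, "chr1", 1.0e6, "single_locus"),
                ("x1", "A", 2.0, "chr9", 50.0e6, "single_locus"),  # elsewhere
                ("x2", "A", 3.0, None, math.nan, "absent"),
                ("m2", "A", 5.0, "chr1", 1.5e6, "single_locus"),
                ("x3", "A", 6.0, None, math.nan, "multi_locus"),  # not counted
                ("m3", "A", 10.0, "chr1", 2.0e6, "single_locus"),
            ]
        )
        blocks = detect_css(adf, gmap)
        main = [b for b in blocks if b.target_chrom == "chr1"]
        assert len(main) == 1
        assert main[0].n_syntenic == 3
        assert main[0].n_interspersed == 2

    def test_optional_interspersed_limit_breaks_chains(self):
        rows = [("m1", "A", 0.0, "chr1", 1.0e6, "single_locus")]
        for i in range(4):
            rows.append((f"x{i}", "A", 2.0 + i * 0.5, "chr9", 50.0e6 + i * 1e5, "single_locus"))
        rows += [
            ("m2", "A", 5.0, "chr1", 1.5e6, "single_locus"),
            ("m3", "A", 7.0, "chr1", 1.8e6, "single_locus"),
            ("m4", "A", 10.0, "chr1", 2.0e6, "single_locus"),
        ]
        adf, gmap = make_inputs(rows)
        th = SyntenyThresholds(max_interspersed=2)
        chained = [b for b in detect_css(adf, gmap, th) if b.target_chrom == "chr1"]
        assert [b.n_syntenic for b in chained] == [3]  # m1 cut off by the foreign run

    def test_unmapped_single_locus_marker_is_skipped(self, caplog):
        adf, gmap = make_inputs(
            [
                ("m1", "A", 0.0, "chr1", 1.0e6, "single_locus"),
                ("m2", "A", 5.0, "chr1", 1.5e6, "single_locus"),
                ("m3", "A", 10.0, "chr1", 2.0e6, "single_locus"),
            ]
        )
        extra = pd.DataFrame(
            [("ghost", "single_locus", "chr1", 1.7e6, 1e-30, 1)],
            columns=list(ASSIGNMENT_COLUMNS),
        )
        adf = pd.concat([adf, extra], ignore_index=True)
        with caplog.at_level("WARNING"):
            (block,) = detect_css(adf, gmap)
        assert block.n_syntenic == 3
        assert any("ghost" in r.message for r in caplog.records)


@st.composite
def chain_instance(draw):
    n = draw(st.integers(min_value=2, max_value=15))
    q = sorted(
        draw(
            st.lists(
                st.floats(min_value=0, max_value=60, allow_nan=False),
                min_size=n,
                max_size=n,
            )
        )
    )
    t = draw(
        st.lists(
            st.floats(min_value=0, max_value=2.5e7, allow_nan=False),
            min_size=n,
            max_size=n,
        )
    )
    min_markers = draw(st.sampled_from([2, 3, 4]))
    return q, t, min_markers


class TestChainOracleEquivalence:
    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(chain_instance())
    def test_greedy_chaining_equals_exhaustive_enumeration(self, instance):
        q, t, min_markers = instance
        rows = [
            (f"m{i:02d}", "A", q[i], "chr1", t[i], "single_locus") for i in range(len(q))
        ]
        adf, gmap = make_inputs(rows)
        th = SyntenyThresholds(min_markers=min_markers)
        blocks = detect_css(adf, gmap, th)
        got = sorted(tuple(sorted(m for m, _q, _t in b.members)) for b in blocks)
        # oracle works on the cM-sorted order used by the detector
        order = sorted(range(len(q)), key=lambda i: (q[i], f"m{i:02d}"))
        qo = np.array([q[i] for i in order])
        to = np.array([t[i] for i in order])
        expected = sorted(
            tuple(sorted(f"m{order[k]:02d}" for k in run))
            for run in chain_oracle(qo, to, th.max_gap_query_cM, th.max_gap_target_bp, min_markers)
        )
        assert got == expected

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(chain_instance(), st.floats(min_value=1.0, max_value=3.0))
    def test_enlarging_gaps_never_drops_chained_markers(self, instance, factor):
        q, t, min_markers = instance
        rows = [
            (f"m{i:02d}", "A", q[i], "chr1", t[i], "single_locus") for i in range(len(q))
        ]
        adf, gmap = make_inputs(rows)
        small = SyntenyThresholds(min_markers=min_markers)
        large = SyntenyThresholds(
            min_markers=min_markers,
            max_gap_query_cM=small.max_gap_query_cM * factor,
            max_gap_target_bp=small.max_gap_target_bp * factor,
        )
        n_small = sum(b.n_syntenic for b in detect_css(adf, gmap, small))
        n_large = sum(b.n_syntenic for b in detect_css(adf, gmap, large))
        assert n_large >= n_small

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(chain_instance())
    def test_raising_min_markers_never_adds_blocks(self, instance):
        q, t, _ = instance
        rows = [
            (f"m{i:02d}", "A", q[i], "chr1", t[i], "single_locus") for i in range(len(q))
        ]
        adf, gmap = make_inputs(rows)
        n_blocks = [
            len(detect_css(adf, gmap, SyntenyThresholds(min_markers=mm)))
            for mm in (2, 3, 4)
        ]
        assert n_blocks == sorted(n_blocks, reverse=True)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(chain_instance())
    def test_no_marker_in_two_blocks(self, instance):
        q, t, min_markers = instance
        rows = [
            (f"m{i:02d}", "A", q[i], "chr1", t[i], "single_locus") for i in range(len(q))
        ]
        adf, gmap = make_inputs(rows)
        blocks = detect_css(adf, gmap, SyntenyThresholds(min_markers=min_markers))
        members = [m for b in blocks for m, _q, _t in b.members]
        assert len(members) == len(set(members))
        assert len(members) <= int((adf["status"] == "single_locus").sum())


class TestBetweenMaps:
    def test_shared_markers_chain_with_per_map_thresholds(self):
        a = GeneticMapTable(
            pd.DataFrame(
                [("m1", "A", 0.0), ("m2", "A", 5.0), ("m3", "A", 10.0), ("m4", "A", 40.0)],
                columns=["marker", "linkage_group", "cM"],
            )
        )
        b = GeneticMapTable(
            pd.DataFrame(
                [("m1", "T2", 3.0), ("m2", "T2", 9.0), ("m3", "T2", 15.0), ("m4", "T2", 20.0)],
                columns=["marker", "linkage_group", "cM"],
            )
        )
        blocks = detect_css_between_maps(a, b, max_gap_a_cM=12.0, max_gap_b_cM=14.0)
        assert len(blocks) == 1  # m4 breaks on the 30 cM query gap
        assert blocks[0].n_syntenic == 3
        assert blocks[0].target_unit == "cM"


class TestSummarize:
    def _blocks(self):
        b1 = SyntenicBlock(
            "A~c1~1", "A", "c1", [("m1", 0.0, 0.0), ("m2", 4.0, 1e6), ("m3", 8.0, 2e6)]
        )
        b2 = SyntenicBlock(
            "B~c2~1",
            "B",
            "c2",
            [(f"n{i}", float(2 * i), float(i * 5e5)) for i in range(5)],
        )
        return [b1, b2]

    def test_mean_and_max_markers_per_block(self):
        s = summarize(self._blocks())
        assert s.mean_markers_per_css == 4.0
        assert s.max_markers_per_css == 5
        assert s.n_css == 2

    def test_mean_adjacent_distance_single_block(self):
        (b1, _b2) = self._blocks()
        s = summarize([b1])
        assert s.mean_adjacent_gap_query == pytest.approx(4.0)
        assert s.mean_adjacent_gap_target == pytest.approx(1e6)

    def test_empty_block_list_gives_zero_summary(self):
        s = summarize([])
        assert s.n_css == 0
        assert s.mean_markers_per_css == 0.0

    def test_pooled_vs_per_block_adjacent_means(self):
        blocks = self._blocks()
        pooled = summarize(blocks, adjacent="pooled")
        per_block = summarize(blocks, adjacent="per_block")
        # block gaps: [4,4] and [2,2,2,2] -> pooled (4*2+2*4)/6, per-block (4+2)/2
        assert pooled.mean_adjacent_gap_query == pytest.approx(16 / 6)
        assert per_block.mean_adjacent_gap_query == pytest.approx(3.0)

    def test_simulated_dataset_summary_matches_direct_recount(self):
        anc = sd.simulate_ancestor(3, 15, seed=61)
        a, b, truth = sd.evolve(anc, n_events_per_lineage=2, seed=62)
        gmap = sd.project_genetic(a, seed=63)
        from synmap.orthology import assign

        hits = sd.emit_hits(truth, sd.placements(b), seed=64)
        assignments, _ = assign(hits, query_ids=a.marker_ids())
        blocks = detect_css(assignments, gmap)
        s = summarize(blocks, assignments)
        assert s.n_css == len(blocks)
        assert s.n_orthologous_markers == int(
            (assignments["status"] == "single_locus").sum()
        )
        sizes = [b.n_syntenic for b in blocks]
        assert s.mean_markers_per_css == pytest.approx(np.mean(sizes))
        gaps = [g for b in blocks for g in b.adjacent_gaps()[0]]
        assert s.mean_adjacent_gap_query == pytest.approx(np.mean(gaps))


class TestProjectMultiway:
    def _block(self, bid, chrom, lo, hi):
        return SyntenicBlock(
            bid, "A", chrom, [("x" + bid, 0.0, lo), ("y" + bid, 1.0, hi), ("z" + bid, 2.0, (lo + hi) / 2)]
        )

    def test_overlap_and_jaccard(self):
        a = self._block("a1", "chr4", 1e6, 5e6)
        c = self._block("c1", "chr4", 3e6, 8e6)
        overlaps, _cov = project_multiway([a], [c], {"chr4": 10e6})
        row = overlaps.iloc[0]
        assert row["overlap_bp"] == pytest.approx(2e6)
        assert row["jaccard"] == pytest.approx(2 / 7)

    def test_disjoint_blocks_overlap_zero(self):
        a = self._block("a1", "chr4", 1e6, 2e6)
        c = self._block("c1", "chr4", 5e6, 8e6)
        overlaps, _cov = project_multiway([a], [c], {"chr4": 10e6})
        assert overlaps.iloc[0]["overlap_bp"] == 0.0

    def test_coverage_union_and_zero_flag(self):
        a = self._block("a1", "chr4", 0, 4e6)
        c = self._block("c1", "chr4", 2e6, 6e6)
        _ov, cov = project_multiway([a], [c], {"chr4": 12e6, "chr5": 5e6})
        cov = cov.set_index("chrom")
        assert cov.loc["chr4", "covered_bp"] == pytest.approx(6e6)
        assert cov.loc["chr4", "fraction"] == pytest.approx(0.5)
        assert bool(cov.loc["chr5", "zero_coverage"]) is True

    def test_conserved_ancestral_segment_overlaps_on_reference(self):
        """Two query lineages retaining an ancestral segment should produce
        pairwise blocks that overlap on the shared reference genome."""
        from synmap.orthology import assign

        anc = sd.simulate_ancestor(3, 15, seed=71)
        genomes, _ev, _par = sd.evolve_multi(anc, 3, n_events_per_lineage=0, seed=72)
        qa, tb, qc = genomes
        truth_ab = sd.build_truth(anc, qa, tb)
        truth_cb = sd.build_truth(anc, qc, tb)
        place = sd.placements(tb)
        map_a = sd.project_genetic(qa, seed=73)
        map_c = sd.project_genetic(qc, seed=74)
        assign_a, _ = assign(sd.emit_hits(truth_ab, place, seed=75), query_ids=qa.marker_ids())
        assign_c, _ = assign(sd.emit_hits(truth_cb, place, seed=76), query_ids=qc.marker_ids())
        blocks_ab = detect_css(assign_a, map_a)
        blocks_cb = detect_css(assign_c, map_c)
        lengths = {c.name: c.length_bp for c in tb.chromosomes}
        overlaps, cov = project_multiway(blocks_ab, blocks_cb, lengths)
        # with no rearrangement both lineages keep every ancestral chromosome
        same = overlaps[overlaps["chrom_ab"] == overlaps["chrom_cb"]]
        assert (same["overlap_bp"] > 0).all()
        assert (~cov["zero_coverage"]).all()
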