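"""Cycles parsing, complexity scoring, content calls, element densities."""

import math

import pytest

from ecdnakit.amplicon import (
    AmpliconDecomposition,
    AmpliconPath,
    GeneAnnotation,
    amplicon_complexity,
    classify_amplicon_content,
    element_density,
    parse_cycles,
    write_cycles,
)
from ecdnakit.errors import DataError, FormatError, UndefinedResultError
from ecdnakit.genome_profile import CNSegment


def decomp(n_seg, cyclic_weights, residual=0.0, seg_len=10_000):
    """Helper: decomposition with given cyclic path length*copy weights."""
    segments = [
        CNSegment("chr1", i * seg_len, (i + 1) * seg_len, 10.0) for i in range(n_seg)
    ]
    paths = [
        AmpliconPath(str(i + 1), True, seg_len, w / seg_len)
        for i, w in enumerate(cyclic_weights)
    ]
    return AmpliconDecomposition("a", segments, paths, residual)


class TestParseCycles:
    def test_conservation_zero_residual(self, tmp_path):
        path = tmp_path / "a.cycles"
        path.write_text(
            "Segment\t1\tchr1\t0\t10000\t8\n"
            "Cycle=1;Copy_count=8;Segments=1+\n"
        )
        d = parse_cycles(path)
        assert d.residual_weight == 0.0
        assert d.n_seg == 1 and d.paths[0].is_cyclic

    def test_hand_computed_weights(self, tmp_path):
        # segments: 10 kb at CN 10, 5 kb at CN 4 -> total weight 120,000
        # cyclic path over seg1 at copy 8 -> 80,000; linear path over seg2
        # at copy 4 -> 20,000; residual = 120,000 - 100,000 = 20,000
        path = tmp_path / "a.cycles"
        path.write_text(
            "Segment\t1\tchr1\t0\t10000\t10\n"
            "Segment\t2\tchr1\t20000\t25000\t4\n"
            "Cycle=1;Copy_count=8;Segments=1+\n"
            "Cycle=2;Copy_count=4;Segments=0+,2+,0-\n"
        )
        d = parse_cycles(path)
        cyclic = [p for p in d.paths if p.is_cyclic]
        linear = [p for p in d.paths if not p.is_cyclic]
        assert cyclic[0].weight == 80_000
        assert linear[0].weight == 20_000
        assert d.residual_weight == 20_000

    def test_dangling_segment_id(self, tmp_path):
        path = tmp_path / "a.cycles"
        path.write_text(
            "Segment\t1\tchr1\t0\t10000\t8\n"
            "Cycle=1;Copy_count=8;Segments=1+,7-\n"
        )
        with pytest.raises(FormatError, match="unknown segment"):
            parse_cycles(path)

    def test_round_trip(self, tmp_path):
        src = tmp_path / "a.cycles"
        src.write_text(
            "Segment\t1\tchr1\t0\t10000\t10\n"
            "Segment\t2\tchr1\t20000\t25000\t4\n"
            "Cycle=1;Copy_count=8;Segments=1+,2-\n"
            "Cycle=2;Copy_count=4;Segments=0+,2+,0-\n"
        )
        d1 = parse_cycles(src)
        dst = tmp_path / "b.cycles"
        write_cycles(d1, dst)
        d2 = parse_cycles(dst)
        assert d1.segments == d2.segments
        assert d1.paths == d2.paths
        assert d1.residual_weight == d2.residual_weight


class TestComplexity:
    def test_single_cycle_single_segment_is_zero(self):
        assert amplicon_complexity(decomp(1, [10_000.0])) == pytest.approx(0.0)

    def test_two_equal_paths_two_segments(self):
        # log10(2) + 2 * (-0.5 log10 0.5) = 0.60206
        score = amplicon_complexity(decomp(2, [5_000.0, 5_000.0]))
        assert score == pytest.approx(0.60206, abs=1e-5)

    def test_path_plus_residual(self):
        # log10(3) - 0.8 log10 0.8 - 0.2 log10 0.2 = 0.694443...
        score = amplicon_complexity(decomp(3, [8_000.0], residual=2_000.0))
        expected = math.log10(3) - 0.8 * math.log10(0.8) - 0.2 * math.log10(0.2)
        assert score == pytest.approx(expected, abs=1e-12)
        assert score == pytest.approx(0.69444, abs=1e-4)

    @pytest.mark.parametrize("n1,n2", [(1, 2), (2, 5), (5, 17)])
    def test_monotone_in_segment_count(self, n1, n2):
        weights = [4_000.0, 6_000.0]
        assert amplicon_complexity(decomp(n2, weights)) > amplicon_complexity(
            decomp(n1, weights)
        )

    def test_entropy_maximal_at_equal_weights(self):
        equal = amplicon_complexity(decomp(2, [5_000.0, 5_000.0]))
        skewed = amplicon_complexity(decomp(2, [9_000.0, 1_000.0]))
        single = amplicon_complexity(decomp(2, [10_000.0]))
        assert equal > skewed > single
        assert single == pytest.approx(math.log10(2))

    def test_zero_weight_undefined(self):
        d = AmpliconDecomposition(
            "a", [CNSegment("chr1", 0, 100, 1.0)],
            [AmpliconPath("1", False, 100, 1.0)], 0.0,
        )
        with pytest.raises(UndefinedResultError):
            amplicon_complexity(d)


class TestContentCalls:
    def test_oncogene_precedence_keeps_immune_list(self, toy_annotation):
        call = classify_amplicon_content([("chr1", 900, 3_200)], toy_annotation)
        assert call.subclass == "oncogenic"
        assert call.oncogenes == ["ONC1"]
        assert call.immune_genes == ["IMM1"]

    def test_immune_only(self, toy_annotation):
        call = classify_amplicon_content([("chr1", 2_400, 3_100)], toy_annotation)
        assert call.subclass == "immunomodulatory"

    def test_other_coding(self, toy_annotation):
        call = classify_amplicon_content([("chr1", 4_100, 4_900)], toy_annotation)
        assert call.subclass == "other_coding"

    def test_regulatory_only(self, toy_annotation):
        call = classify_amplicon_content([("chr1", 5_900, 6_200)], toy_annotation)
        assert call.subclass == "regulatory_only"
        assert call.element_counts["enhancer"] == 1

    def test_no_coding_genes(self, toy_annotation):
        call = classify_amplicon_content([("chr1", 100_000, 200_000)], toy_annotation)
        assert call.subclass == "no_coding_genes"

    def test_order_independent(self, toy_annotation):
        reversed_ann = GeneAnnotation(
            genes=list(reversed(toy_annotation.genes)),
            oncogenes=toy_annotation.oncogenes,
            immune_sets=toy_annotation.immune_sets,
            elements=list(reversed(toy_annotation.elements)),
        )
        intervals = [("chr1", 900, 7_200)]
        a = classify_amplicon_content(intervals, toy_annotation)
        b = classify_amplicon_content(intervals, reversed_ann)
        assert (a.subclass, a.genes, a.oncogenes) == (b.subclass, b.genes, b.oncogenes)

    def test_empty_intervals_rejected(self, toy_annotation):
        with pytest.raises(DataError):
            classify_amplicon_content([], toy_annotation)


class TestElementDensity:
    def test_unit_arithmetic(self, toy_annotation):
        dens = element_density([("chr1", 5_000, 7_000)], toy_annotation)
        # 2,000 bp span = 0.002 Mb; 1 enhancer, 1 promoter -> 500 per Mb
        assert dens["enhancer"] == pytest.approx(500.0)
        assert dens["promoter"] == pytest.approx(500.0)

    def test_no_elements(self, toy_annotation):
        dens = element_density([("chr3", 0, 1_000_000)], toy_annotation)
        assert all(v == 0.0 for v in dens.values())

    def test_straddling_element_counted_once(self, toy_annotation):
        # enhancer at 6,000-6,100 straddles the amplicon boundary at 6,050
        dens = element_density(
            [("chr1", 5_000, 6_050), ("chr1", 6_050, 7_000)], toy_annotation
        )
        assert dens["enhancer"] == pytest.approx(500.0)

    def test_inverse_span_scaling(self, toy_annotation):
        short = element_density([("chr1", 5_000, 7_000)], toy_annotation)
        double = element_density([("chr1", 5_000, 7_000), ("chr2", 0, 2_000)], toy_annotation)
        assert double["enhancer"] == pytest.approx(short["enhancer"] / 2)

    def test_zero_span_rejected(self, toy_annotation):
        with pytest.raises(DataError):
            element_density([], toy_annotation)
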