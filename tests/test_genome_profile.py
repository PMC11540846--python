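"""Copy-number profile metrics: seeding, wGII, WGD, SV burden and filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecdnakit.errors import DataError, FormatError, UndefinedResultError
from ecdnakit.genome_profile import (
    Arm,
    CNSegment,
    SampleProfile,
    SVRecord,
    call_wgd,
    filter_svs,
    find_seed_intervals,
    read_seg,
    sv_burden,
    wgii,
    write_seg,
)


def seg(chrom, start, end, cn):
    return CNSegment(chrom, start, end, cn)


class TestReadSeg:
    def test_sorted_round_trip(self, tmp_path):
        path = tmp_path / "x.seg"
        segs = {"s1": [seg("chr1", 0, 100, 2.0), seg("chr1", 100, 300, 5.0),
                       seg("chr2", 0, 50, 2.0)]}
        write_seg(segs, path)
        assert read_seg(path) == segs

    def test_overlap_rejected(self, tmp_path):
        path = tmp_path / "x.seg"
        path.write_text(
            "sample\tchrom\tstart\tend\ttotal_cn\n"
            "s1\tchr1\t0\t100\t2\ns1\tchr1\t50\t150\t3\n"
        )
        with pytest.raises(FormatError, match="overlap"):
            read_seg(path)

    def test_end_le_start_rejected(self, tmp_path):
        path = tmp_path / "x.seg"
        path.write_text("sample\tchrom\tstart\tend\ttotal_cn\ns1\tchr1\t100\t100\t2\n")
        with pytest.raises(FormatError):
            read_seg(path)

    def test_negative_cn_rejected(self):
        with pytest.raises(FormatError):
            seg("chr1", 0, 10, -1.0)

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "x.seg"
        path.write_text("sample\tchrom\tstart\tend\ttotal_cn\n")
        assert read_seg(path) == {}


def _fixture_profile():
    """Six segments, one designed failure per seed criterion (ploidy 3).

    s1: qualifies, 60 kb span -> focal. s2: 49 kb, fails length.
    s3: CN 4.4, fails the 4.5 floor. s4: CN 5.5, fails 2x ploidy (=6).
    s5: CN 9 on an arm with median 8, fails the +2.5 arm criterion.
    s6: qualifies but spans 25 Mb -> seed yet non-focal.
    """
    segments = [
        seg("chr1", 0, 60_000, 10.0),          # s1
        seg("chr1", 100_000, 149_000, 10.0),   # s2
        seg("chr1", 200_000, 260_000, 4.4),    # s3
        seg("chr1", 300_000, 360_000, 5.5),    # s4
        seg("chr2", 0, 60_000, 9.0),           # s5
        seg("chr1", 1_000_000, 26_000_000, 10.0),  # s6
    ]
    prof = SampleProfile(
        sample="s1", purity=0.5, ploidy=3.0, segments=segments,
        arms=[Arm("chr1", 0, 30_000_000, "1p"), Arm("chr2", 0, 1_000_000, "2p")],
        arm_medians={"1p": 2.0, "2p": 8.0},
    )
    return prof


class TestSeedIntervals:
    def test_single_qualifying_segment_focal(self):
        prof = SampleProfile(
            "s", 0.5, 2.0, [seg("chr1", 0, 60_000, 10.0)],
            arms=[Arm("chr1", 0, 60_000, "1p")], arm_medians={"1p": 2.0},
        )
        (iv,) = find_seed_intervals(prof)
        assert (iv.chrom, iv.start, iv.end, iv.focal) == ("chr1", 0, 60_000, True)

    def test_short_segment_rejected(self):
        prof = SampleProfile(
            "s", 0.5, 2.0, [seg("chr1", 0, 49_000, 10.0)],
            arms=[Arm("chr1", 0, 49_000, "1p")], arm_medians={"1p": 2.0},
        )
        assert find_seed_intervals(prof) == []

    def test_six_segment_fixture_brute_force(self):
        prof = _fixture_profile()
        out = find_seed_intervals(prof)
        # independent per-criterion audit
        expected = []
        for s in sorted(prof.segments, key=lambda x: (x.chrom, x.start)):
            arm = next(a for a in prof.arms if a.chrom == s.chrom)
            ok = (
                (s.end - s.start) > 50_000
                and s.total_cn > 4.5
                and s.total_cn > 2 * prof.ploidy
                and s.total_cn >= prof.arm_medians[arm.name] + 2.5
            )
            if ok:
                expected.append((s.chrom, s.start, s.end))
        assert [(i.chrom, i.start, i.end) for i in out] == expected
        assert len(out) == 2
        focal_flags = {(i.start): i.focal for i in out}
        assert focal_flags[0] is True           # 60 kb
        assert focal_flags[1_000_000] is False  # 25 Mb exceeds focal window

    def test_monotone_under_uniform_cn_gain(self):
        prof = _fixture_profile()
        before = {(i.chrom, i.start, i.end) for i in find_seed_intervals(prof)}
        gained = SampleProfile(
            prof.sample, prof.purity, prof.ploidy,
            [seg(s.chrom, s.start, s.end, s.total_cn + 2.0) for s in prof.segments],
            arms=prof.arms,
            arm_medians={k: v + 2.0 for k, v in prof.arm_medians.items()},
        )
        after = {(i.chrom, i.start, i.end) for i in find_seed_intervals(gained)}
        for chrom, start, end in before:
            assert any(c == chrom and s <= start and e >= end for c, s, e in after)

    def test_abutting_segments_merge(self):
        prof = SampleProfile(
            "s", 0.5, 2.0,
            [seg("chr1", 0, 60_000, 10.0), seg("chr1", 60_000, 130_000, 12.0)],
            arms=[Arm("chr1", 0, 130_000, "1p")], arm_medians={"1p": 2.0},
        )
        (iv,) = find_seed_intervals(prof)
        assert (iv.start, iv.end, iv.max_cn) == (0, 130_000, 12.0)


class TestWgii:
    def test_all_segments_at_ploidy(self):
        segs = [seg("chr1", 0, 1000, 2.0), seg("chr2", 0, 500, 2.0)]
        assert wgii(segs, median_ploidy=2.0) == 0.0

    def test_one_of_two_chromosomes_gained(self):
        segs = [seg("chr1", 0, 1000, 3.0), seg("chr2", 0, 1000, 2.0)]
        assert wgii(segs, median_ploidy=2.0) == pytest.approx(0.5)

    def test_brute_force_recount_toy_genome(self):
        """1-bp recount oracle on a ~10-kb four-chromosome toy genome."""
        rng = np.random.default_rng(42)
        chroms = {"chr1": 3000, "chr2": 2500, "chr3": 2000, "chr4": 2500}
        segs = []
        for chrom, length in chroms.items():
            cuts = np.sort(rng.choice(np.arange(1, length), size=3, replace=False))
            bounds = [0, *cuts.tolist(), length]
            for a, b in zip(bounds, bounds[1:]):
                segs.append(seg(chrom, a, b, float(rng.choice([1.0, 2.0, 2.4, 3.0, 5.0]))))
        ploidy = 2.0
        got = wgii(segs, median_ploidy=ploidy)
        fractions = []
        for chrom, length in chroms.items():
            per_bp = np.zeros(length)
            for s in segs:
                if s.chrom == chrom:
                    per_bp[s.start:s.end] = np.rint(s.total_cn)
            fractions.append(np.mean(per_bp != np.rint(ploidy)))
        assert got == pytest.approx(np.mean(fractions), abs=1e-12)

    @given(
        split=st.integers(min_value=1, max_value=999),
        cn=st.floats(min_value=0, max_value=10, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_segment_splitting(self, split, cn):
        whole = [seg("chr1", 0, 1000, cn), seg("chr2", 0, 800, 3.0)]
        parts = [
            seg("chr1", 0, split, cn), seg("chr1", split, 1000, cn),
            seg("chr2", 0, 800, 3.0),
        ]
        assert wgii(whole, median_ploidy=2.0) == pytest.approx(
            wgii(parts, median_ploidy=2.0), abs=1e-12
        )

    def test_default_median_ploidy_is_weighted_median(self):
        # 60% of bases at CN 4, 40% at CN 2 -> median ploidy 4
        segs = [seg("chr1", 0, 600, 4.0), seg("chr1", 600, 1000, 2.0)]
        assert wgii(segs) == pytest.approx(0.4)

    def test_sex_chromosomes_excluded_by_default(self):
        segs = [seg("chr1", 0, 1000, 2.0), seg("chrX", 0, 1000, 5.0)]
        assert wgii(segs, median_ploidy=2.0) == 0.0

    def test_no_segments_undefined(self):
        with pytest.raises(UndefinedResultError):
            wgii([], median_ploidy=2.0)

    def test_bounds(self):
        segs = [seg("chr1", 0, 1000, 8.0)]
        assert 0.0 <= wgii(segs, median_ploidy=2.0) <= 1.0


class TestWgdAndBurden:
    @pytest.mark.parametrize(
        "ploidy,expected", [(2.71, True), (2.7, False), (2.0, False), (3.4, True)]
    )
    def test_wgd_strict_threshold(self, ploidy, expected):
        assert call_wgd(ploidy) is expected

    @pytest.mark.parametrize(
        "count,size,expected",
        [(0, 1_000_000, 0.0), (100, 100_000_000, 1.0), (31, 3_100_000_000, 0.01)],
    )
    def test_sv_burden_per_megabase(self, count, size, expected):
        assert sv_burden(count, size) == pytest.approx(expected)

    def test_sv_burden_invalid_genome(self):
        with pytest.raises(DataError):
            sv_burden(1, 0)


def _sv(sv_type="DUP", length=5000, quality=30.0, depth_ratio=1.0, mapq0=0.0):
    return SVRecord(sv_type, length, quality, depth_ratio, mapq0)


class TestFilterSvs:
    def test_quality_rule(self):
        kept, removed = filter_svs([_sv(quality=29.0)])
        assert kept == [] and removed[0][1] == ["quality<30"]

    def test_clean_record_kept(self):
        kept, removed = filter_svs([_sv(quality=30.0)])
        assert len(kept) == 1 and removed == []

    def test_one_record_per_rule(self):
        records = [
            _sv(quality=29.0),                      # quality < 30
            _sv(depth_ratio=3.5),                   # normal depth > 3x
            _sv(sv_type="DEL", length=20_000, quality=35.0),  # large DEL
            _sv(sv_type="INS", length=500, mapq0=0.5),        # small + MAPQ0
            _sv(),                                  # clean
        ]
        kept, removed = filter_svs(records)
        assert len(kept) == 1 and len(removed) == 4
        fired = [reasons for _, reasons in removed]
        assert all(len(r) == 1 for r in fired)
        # brute-force audit of which rule fired for each removed record
        assert fired[0] == ["quality<30"]
        assert fired[1] == ["normal_depth>3x"]
        assert fired[2] == ["deldup_length_remove_large"]
        assert fired[3] == ["mapq0>0.4"]

    def test_partition_property(self):
        records = [_sv(quality=q) for q in (10.0, 29.9, 30.0, 50.0)]
        kept, removed = filter_svs(records)
        assert len(kept) + len(removed) == len(records)
        assert not (set(map(id, kept)) & set(map(id, (r for r, _ in removed))))

    def test_inverted_large_deldup_direction(self):
        small = _sv(sv_type="DEL", length=5_000, quality=40.0)
        large = _sv(sv_type="DEL", length=50_000, quality=40.0)
        kept, removed = filter_svs([small, large], large_deldup_direction="remove_small")
        assert kept == [large] and removed[0][0] is small

    def test_empty_input(self):
        assert filter_svs([]) == ([], [])

    def test_bnd_without_length_ignores_length_rules(self):
        kept, removed = filter_svs([SVRecord("BND", None, 40.0, 1.0, 0.9)])
        assert len(kept) == 1
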