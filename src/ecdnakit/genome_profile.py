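"""Copy-number profiles, focal-amplification seeding and instability metrics.

Coordinates are 0-based half-open (BED/SEG convention) throughout; VCF I/O
converts from 1-based.

The focal-amplification seeding rule mirrors the AmpliconArchitect-style
seeding used in pan-cancer ecDNA surveys: a segment seeds if it is longer
than 50 kb, has total copy number above 4.5, above twice the sample ploidy,
and at least 2.5 copies above the median arm-level copy number. Qualifying
segments are merged into maximal runs and tagged *focal* when the merged
span lies within 50 kb - 20 Mb.

wGII (weighted genome instability index) is the per-chromosome-averaged
fraction of covered bases whose rounded copy state differs from the rounded
median ploidy; whole-genome duplication is called at ploidy > 2.7; SV burden
is structural variants per megabase. SV post-filters follow Manta-style
somatic filtering (quality < 30, normal depth > 3x chromosomal mean near a
break-end, large DEL/DUP, high MAPQ0 fraction near small variants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, UndefinedResultError

SEG_COLUMNS = ["sample", "chrom", "start", "end", "total_cn"]

#: Default thresholds (surfaced so a config file can override any of them).
SEED_MIN_LENGTH = 50_000
SEED_MIN_CN = 4.5
SEED_PLOIDY_FACTOR = 2.0
SEED_ARM_EXTRA = 2.5
FOCAL_MIN = 50_000
FOCAL_MAX = 20_000_000
WGD_PLOIDY = 2.7
SV_MIN_QUALITY = 30.0
SV_DELDUP_MAX_LENGTH = 10_000
SV_SMALL_LENGTH = 1_000
SV_MAX_MAPQ0_FRACTION = 0.4
SV_MAX_NORMAL_DEPTH_RATIO = 3.0

SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass(frozen=True)
class CNSegment:
    """One total-copy-number segment of a sample's genome."""

    chrom: str
    start: int
    end: int
    total_cn: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(
                f"segment {self.chrom}:{self.start}-{self.end} has end <= start"
            )
        if self.total_cn < 0:
            raise FormatError(f"negative copy number {self.total_cn}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Arm:
    """A chromosome arm (or any background window for arm-level medians)."""

    chrom: str
    start: int
    end: int
    name: str


@dataclass(frozen=True)
class SeedInterval:
    """A merged run of seed-qualifying segments."""

    chrom: str
    start: int
    end: int
    focal: bool
    max_cn: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SVRecord:
    """A structural-variant call with the annotations the post-filters use."""

    sv_type: str  # DEL, DUP, INV, BND, INS
    length: int | None  # absent for BND
    somatic_quality: float
    normal_depth_ratio: float  # normal depth near break-ends / chromosomal mean
    mapq0_fraction: float

    def __post_init__(self) -> None:
        if self.somatic_quality < 0:
            raise FormatError("somatic quality must be >= 0")
        if not 0.0 <= self.mapq0_fraction <= 1.0:
            raise FormatError("MAPQ0 fraction must lie in [0,1]")


@dataclass
class SampleProfile:
    """Per-sample copy-number context for instability metrics and seeding."""

    sample: str
    purity: float
    ploidy: float
    segments: list[CNSegment]
    sv_count: int = 0
    genome_size: int = 0
    arm_medians: dict[str, float] = field(default_factory=dict)
    arms: list[Arm] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise DataError(f"purity {self.purity} outside (0,1]")
        if self.ploidy <= 0:
            raise DataError(f"ploidy {self.ploidy} must be positive")


def read_seg(path) -> dict[str, list[CNSegment]]:
    """Read a SEG TSV (sample, chrom, start, end, total_cn) into segments.

    Segments are returned sorted by (chrom, start) per sample. Overlapping
    segments within a sample are rejected; an empty file with a valid header
    yields an empty mapping.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"SEG file {path} missing columns {missing}")
    out: dict[str, list[CNSegment]] = {}
    for sample, grp in df.groupby("sample", sort=True):
        segs = sorted(
            (
                CNSegment(str(r.chrom), int(r.start), int(r.end), float(r.total_cn))
                for r in grp.itertuples()
            ),
            key=lambda s: (s.chrom, s.start),
        )
        for a, b in zip(segs, segs[1:]):
            if a.chrom == b.chrom and b.start < a.end:
                raise FormatError(
                    f"overlapping segments in sample {sample}: "
                    f"{a.chrom}:{a.start}-{a.end} and {b.chrom}:{b.start}-{b.end}"
                )
        out[str(sample)] = segs
    return out


def write_seg(segments_by_sample: dict[str, list[CNSegment]], path) -> None:
    rows = [
        (sample, s.chrom, s.start, s.end, s.total_cn)
        for sample in sorted(segments_by_sample)
        for s in segments_by_sample[sample]
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_arms_bed(path) -> list[Arm]:
    """Read arm definitions from a 4-column BED (chrom, start, end, name)."""
    arms = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"arm BED line needs 4 columns: {line!r}")
            arms.append(Arm(parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return arms


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Smallest value whose cumulative weight reaches half the total."""
    order = np.argsort(values, kind="stable")
    v, w = np.asarray(values, float)[order], np.asarray(weights, float)[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def arm_medians(segments: list[CNSegment], arms: list[Arm]) -> dict[str, float]:
    """Length-weighted median total CN of segments overlapping each arm."""
    out: dict[str, float] = {}
    for arm in arms:
        vals, weights = [], []
        for seg in segments:
            if seg.chrom != arm.chrom:
                continue
            ov = min(seg.end, arm.end) - max(seg.start, arm.start)
            if ov > 0:
                vals.append(seg.total_cn)
                weights.append(ov)
        if vals:
            out[arm.name] = _weighted_median(np.array(vals), np.array(weights))
    return out


def whole_chrom_arms(segments: list[CNSegment]) -> list[Arm]:
    """One arm spanning each chromosome's covered extent (toy-genome default)."""
    bounds: dict[str, tuple[int, int]] = {}
    for s in segments:
        lo, hi = bounds.get(s.chrom, (s.start, s.end))
        bounds[s.chrom] = (min(lo, s.start), max(hi, s.end))
    return [Arm(c, lo, hi, c) for c, (lo, hi) in sorted(bounds.items())]


def _arm_for(seg: CNSegment, arms: list[Arm]) -> Arm | None:
    mid = (seg.start + seg.end) // 2
    for arm in arms:
        if arm.chrom == seg.chrom and arm.start <= mid < arm.end:
            return arm
    return None


def find_seed_intervals(
    profile: SampleProfile,
    *,
    min_length: int = SEED_MIN_LENGTH,
    min_cn: float = SEED_MIN_CN,
    ploidy_factor: float = SEED_PLOIDY_FACTOR,
    arm_extra: float = SEED_ARM_EXTRA,
    focal_min: int = FOCAL_MIN,
    focal_max: int = FOCAL_MAX,
) -> list[SeedInterval]:
    """Maximal merged runs of segments passing all four seed criteria.

    A segment qualifies when length > ``min_length`` AND total_cn >
    ``min_cn`` AND total_cn > ``ploidy_factor`` x ploidy AND total_cn >=
    arm median + ``arm_extra``. Abutting qualifying segments are merged;
    each merged interval is tagged focal when its span lies within
    [``focal_min``, ``focal_max``].
    """
    arms = profile.arms or whole_chrom_arms(profile.segments)
    medians = profile.arm_medians or arm_medians(profile.segments, arms)
    if not medians:
        raise DataError("arm medians unavailable: profile has no covered arms")

    qualifying = []
    for seg in sorted(profile.segments, key=lambda s: (s.chrom, s.start)):
        arm = _arm_for(seg, arms)
        if arm is None or arm.name not in medians:
            raise DataError(f"no arm median for segment {seg.chrom}:{seg.start}")
        if (
            seg.length > min_length
            and seg.total_cn > min_cn
            and seg.total_cn > ploidy_factor * profile.ploidy
            and seg.total_cn >= medians[arm.name] + arm_extra
        ):
            qualifying.append(seg)

    merged: list[list[CNSegment]] = []
    for seg in qualifying:
        if merged and merged[-1][-1].chrom == seg.chrom and seg.start <= merged[-1][-1].end:
            merged[-1].append(seg)
        else:
            merged.append([seg])
    out = []
    for run in merged:
        start, end = run[0].start, run[-1].end
        span = end - start
        out.append(
            SeedInterval(
                chrom=run[0].chrom,
                start=start,
                end=end,
                focal=focal_min <= span <= focal_max,
                max_cn=max(s.total_cn for s in run),
            )
        )
    return out


def wgii(
    profile_or_segments,
    median_ploidy: float | None = None,
    *,
    exclude_chroms: frozenset[str] = SEX_CHROMS,
) -> float:
    """Weighted genome instability index in [0, 1].

    Per chromosome, the fraction of covered bases whose rounded total CN
    differs from the rounded median ploidy; wGII is the unweighted mean of
    the per-chromosome fractions. Rounding is half-to-even on both sides.
    ``median_ploidy`` defaults to the length-weighted median of segment CN
    over the included chromosomes. Uncovered bases are excluded entirely;
    sex chromosomes are excluded by default.
    """
    segments = (
        profile_or_segments.segments
        if isinstance(profile_or_segments, SampleProfile)
        else list(profile_or_segments)
    )
    segments = [s for s in segments if s.chrom not in exclude_chroms]
    if not segments:
        raise UndefinedResultError("wGII undefined: no segments")
    if median_ploidy is None:
        median_ploidy = _weighted_median(
            np.array([s.total_cn for s in segments]),
            np.array([s.length for s in segments]),
        )
    target = float(np.rint(median_ploidy))
    fractions = []
    for chrom in sorted({s.chrom for s in segments}):
        chrom_segs = [s for s in segments if s.chrom == chrom]
        covered = sum(s.length for s in chrom_segs)
        aberrant = sum(
            s.length for s in chrom_segs if float(np.rint(s.total_cn)) != target
        )
        fractions.append(aberrant / covered)
    return float(np.mean(fractions))


def call_wgd(ploidy: float, threshold: float = WGD_PLOIDY) -> bool:
    """Whole-genome duplication call: strictly ploidy > 2.7."""
    if ploidy <= 0:
        raise DataError(f"ploidy {ploidy} must be positive")
    return ploidy > threshold


def sv_burden(sv_count: int, genome_size: int) -> float:
    """Structural variants per megabase of genome."""
    if genome_size <= 0:
        raise DataError(f"genome size {genome_size} must be positive")
    if sv_count < 0:
        raise DataError("SV count must be non-negative")
    return sv_count / (genome_size / 1e6)


def filter_svs(
    records: list[SVRecord],
    *,
    min_quality: float = SV_MIN_QUALITY,
    max_normal_depth_ratio: float = SV_MAX_NORMAL_DEPTH_RATIO,
    deldup_max_length: int = SV_DELDUP_MAX_LENGTH,
    small_length: int = SV_SMALL_LENGTH,
    max_mapq0_fraction: float = SV_MAX_MAPQ0_FRACTION,
    large_deldup_direction: str = "remove_large",
) -> tuple[list[SVRecord], list[tuple[SVRecord, list[str]]]]:
    """Apply somatic SV post-filters; return (kept, removed-with-reasons).

    Rules: normal depth near a break-end > 3x the chromosomal mean;
    somatic quality < 30; DEL/DUP with length > 10 kb (direction
    configurable via ``large_deldup_direction`` in {"remove_large",
    "remove_small"}); variants < 1 kb with MAPQ0 fraction > 0.4. Every
    removed record carries the full list of rules it triggered.
    """
    if large_deldup_direction not in ("remove_large", "remove_small"):
        raise DataError(f"unknown direction {large_deldup_direction!r}")
    kept, removed = [], []
    for rec in records:
        reasons = []
        if rec.normal_depth_ratio > max_normal_depth_ratio:
            reasons.append(f"normal_depth>{max_normal_depth_ratio:g}x")
        if rec.somatic_quality < min_quality:
            reasons.append(f"quality<{min_quality:g}")
        if rec.sv_type in ("DEL", "DUP") and rec.length is not None:
            large = rec.length > deldup_max_length
            if (large and large_deldup_direction == "remove_large") or (
                not large and large_deldup_direction == "remove_small"
            ):
                reasons.append(f"deldup_length_{large_deldup_direction}")
        if (
            rec.length is not None
            and rec.length < small_length
            and rec.mapq0_fraction > max_mapq0_fraction
        ):
            reasons.append(f"mapq0>{max_mapq0_fraction:g}")
        if reasons:
            removed.append((rec, reasons))
        else:
            kept.append(rec)
    return kept, removed
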