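"""Amplicon cycle decompositions, complexity scoring and content calls.

Cycles-file dialect
-------------------
A text format per amplicon, one record per line:

``Segment\t<id>\t<chrom>\t<start>\t<end>\t<total_cn>``
    A copy-number segment of the amplicon (0-based half-open).

``Cycle=<id>;Copy_count=<float>;Segments=<sid><sign>,...``
    A path through the segments, e.g. ``Segments=1+,2-``. A path is cyclic
    iff it does not start and end with the ``0+``/``0-`` sentinels that mark
    linear (non-cyclic) paths.

Path length is the summed span of its listed segments (sentinels excluded,
repeats counted). The residual weight is the length-weighted copy number of
the segments not explained by any path:
``max(0, sum(len_s * cn_s) - sum(len_p * copies_p))``.

Complexity score
----------------
With cyclic-path weights ``w_i = length_i * copy_count_i``, residual ``r``
and total ``W = sum_i w_i + r``, the score is

``log10(n_seg) + sum_i(-f_i log10 f_i) + (-f_r log10 f_r)``

where ``f_i = w_i / W`` and ``f_r = r / W`` (0 log 0 taken as 0). The first
term counts segments; the entropy terms capture the diversity of the cyclic
decomposition and of the mass left unexplained by cycles. A single-segment,
single-cycle amplicon with no residual scores exactly 0.

Content classification
----------------------
Amplicons are subclassified with the fixed precedence oncogenic >
immunomodulatory > other_coding > regulatory_only > no_coding_genes, using
>= 1 bp of overlap between an annotation interval and any amplicon interval.
Immune-gene co-amplification on oncogenic amplicons is retained in the call.
"""

from __future__ import annotations

import math
import os
import re
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .errors import DataError, FormatError, UndefinedResultError
from .genome_profile import CNSegment

_CYCLE_RE = re.compile(
    r"^Cycle=(?P<id>[^;]+);Copy_count=(?P<copies>[^;]+);Segments=(?P<segs>.+)$"
)

SUBCLASSES = (
    "oncogenic",
    "immunomodulatory",
    "other_coding",
    "regulatory_only",
    "no_coding_genes",
)

ELEMENT_TYPES = ("enhancer", "promoter", "lncRNA")


@dataclass(frozen=True)
class AmpliconPath:
    path_id: str
    is_cyclic: bool
    length: int
    copy_count: float
    #: ordered signed segment ids, e.g. ("1+", "2-"); sentinels excluded
    segment_tokens: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise FormatError(f"path {self.path_id} has non-positive length")
        if self.copy_count < 0:
            raise FormatError(f"path {self.path_id} has negative copy count")

    @property
    def weight(self) -> float:
        return self.length * self.copy_count


@dataclass
class AmpliconDecomposition:
    """Segments plus cyclic/non-cyclic paths for one amplicon."""

    amplicon_id: str
    segments: list[CNSegment]
    paths: list[AmpliconPath]
    residual_weight: float = 0.0

    def __post_init__(self) -> None:
        if not self.segments:
            raise FormatError(f"amplicon {self.amplicon_id} has no segments")
        if self.residual_weight < 0:
            raise FormatError("residual weight must be non-negative")

    @property
    def n_seg(self) -> int:
        return len(self.segments)

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        return [(s.chrom, s.start, s.end) for s in self.segments]

    @property
    def span(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass(frozen=True)
class GeneRecord:
    chrom: str
    start: int
    end: int
    name: str
    coding: bool = True


@dataclass(frozen=True)
class RegulatoryElement:
    chrom: str
    start: int
    end: int
    element_type: str  # enhancer / promoter / lncRNA


@dataclass
class GeneAnnotation:
    """Genes, oncogene list, immune gene sets and regulatory elements."""

    genes: list[GeneRecord]
    oncogenes: frozenset[str] = frozenset()
    immune_sets: dict[str, frozenset[str]] = field(default_factory=dict)
    elements: list[RegulatoryElement] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._gene_trees: dict[str, IntervalTree] = {}
        for g in self.genes:
            self._gene_trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g
            )
        self._element_trees: dict[str, IntervalTree] = {}
        for e in self.elements:
            if e.element_type not in ELEMENT_TYPES:
                raise FormatError(f"unknown element type {e.element_type!r}")
            self._element_trees.setdefault(e.chrom, IntervalTree()).addi(
                e.start, e.end, e
            )

    @property
    def immune_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.immune_sets.values():
            out |= s
        return frozenset(out)

    def genes_overlapping(self, intervals) -> list[GeneRecord]:
        hits: dict[str, GeneRecord] = {}
        for chrom, start, end in intervals:
            tree = self._gene_trees.get(chrom)
            if tree is None:
                continue
            for iv in tree.overlap(start, end):
                hits[iv.data.name] = iv.data
        return sorted(hits.values(), key=lambda g: (g.chrom, g.start, g.name))

    def elements_overlapping(self, intervals) -> list[RegulatoryElement]:
        hits = set()
        for chrom, start, end in intervals:
            tree = self._element_trees.get(chrom)
            if tree is None:
                continue
            hits |= {iv.data for iv in tree.overlap(start, end)}
        return sorted(hits, key=lambda e: (e.chrom, e.start, e.element_type))


@dataclass
class AmpliconContentCall:
    amplicon_id: str
    subclass: str
    genes: list[str]
    oncogenes: list[str]
    immune_genes: list[str]
    element_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.subclass not in SUBCLASSES:
            raise DataError(f"unknown subclass {self.subclass!r}")


def parse_cycles(path) -> AmpliconDecomposition:
    """Parse one cycles-dialect file into an :class:`AmpliconDecomposition`."""
    segments: dict[str, CNSegment] = {}
    raw_paths: list[tuple[str, float, list[str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("Segment"):
                parts = line.split("\t")
                if len(parts) != 6:
                    raise FormatError(f"{path}:{lineno}: Segment line needs 6 fields")
                _, sid, chrom, start, end, cn = parts
                segments[sid] = CNSegment(chrom, int(start), int(end), float(cn))
            elif line.startswith("Cycle"):
                m = _CYCLE_RE.match(line)
                if m is None:
                    raise FormatError(f"{path}:{lineno}: malformed Cycle line")
                raw_paths.append(
                    (m["id"], float(m["copies"]), m["segs"].split(","))
                )
            else:
                raise FormatError(f"{path}:{lineno}: unrecognized line {line!r}")
    if not segments:
        raise FormatError(f"{path}: no Segment lines")

    paths = []
    for pid, copies, tokens in raw_paths:
        is_cyclic = not (tokens[0][:-1] == "0" and tokens[-1][:-1] == "0")
        length = 0
        members = []
        for tok in tokens:
            sid, sign = tok[:-1], tok[-1]
            if sign not in "+-":
                raise FormatError(f"{path}: bad segment token {tok!r} in cycle {pid}")
            if sid == "0":
                continue
            if sid not in segments:
                raise FormatError(f"{path}: cycle {pid} references unknown segment {sid}")
            length += segments[sid].length
            members.append(tok)
        paths.append(AmpliconPath(pid, is_cyclic, length, copies, tuple(members)))

    total_cn_weight = sum(s.length * s.total_cn for s in segments.values())
    explained = sum(p.weight for p in paths)
    residual = max(0.0, total_cn_weight - explained)
    amplicon_id = os.path.splitext(os.path.basename(str(path)))[0]
    return AmpliconDecomposition(
        amplicon_id=amplicon_id,
        segments=[segments[k] for k in sorted(segments, key=lambda x: (segments[x].chrom, segments[x].start))],
        paths=paths,
        residual_weight=residual,
    )


def write_cycles(decomp: AmpliconDecomposition, path) -> None:
    """Write the cycles dialect (bit-exact round trip with parse_cycles)."""
    with open(path, "w") as fh:
        for i, s in enumerate(decomp.segments, 1):
            fh.write(f"Segment\t{i}\t{s.chrom}\t{s.start}\t{s.end}\t{s.total_cn!r}\n")
        for p in decomp.paths:
            if not p.segment_tokens:
                raise DataError(
                    f"path {p.path_id} lacks segment tokens; cannot serialize"
                )
            segs = ",".join(p.segment_tokens)
            if not p.is_cyclic:
                segs = f"0+,{segs},0-"
            fh.write(f"Cycle={p.path_id};Copy_count={p.copy_count!r};Segments={segs}\n")


def _entropy_term(f: float) -> float:
    if f < 0 or f > 1 + 1e-12:
        raise DataError(f"weight fraction {f} outside [0,1]")
    return 0.0 if f <= 0 else -f * math.log10(f)


def amplicon_complexity(decomp: AmpliconDecomposition) -> float:
    """Three-term log10 complexity score (see module docstring)."""
    cyclic_weights = [p.weight for p in decomp.paths if p.is_cyclic]
    total = sum(cyclic_weights) + decomp.residual_weight
    if total <= 0:
        raise UndefinedResultError(
            f"amplicon {decomp.amplicon_id}: zero total cyclic+residual weight"
        )
    score = math.log10(decomp.n_seg)
    for w in cyclic_weights:
        score += _entropy_term(w / total)
    score += _entropy_term(decomp.residual_weight / total)
    return score


def classify_amplicon_content(
    intervals, annotation: GeneAnnotation, amplicon_id: str = "amplicon"
) -> AmpliconContentCall:
    """Subclassify an amplicon's gene/element content (fixed precedence)."""
    intervals = list(intervals)
    if not intervals:
        raise DataError("amplicon has no intervals")
    genes = annotation.genes_overlapping(intervals)
    gene_names = [g.name for g in genes]
    oncs = sorted(set(gene_names) & annotation.oncogenes)
    immune = sorted(set(gene_names) & annotation.immune_genes)
    coding = [g.name for g in genes if g.coding]
    elements = annotation.elements_overlapping(intervals)
    counts = {t: 0 for t in ELEMENT_TYPES}
    for e in elements:
        counts[e.element_type] += 1

    if oncs:
        subclass = "oncogenic"
    elif immune:
        subclass = "immunomodulatory"
    elif coding:
        subclass = "other_coding"
    elif any(counts.values()):
        subclass = "regulatory_only"
    else:
        subclass = "no_coding_genes"
    return AmpliconContentCall(
        amplicon_id=amplicon_id,
        subclass=subclass,
        genes=gene_names,
        oncogenes=oncs,
        immune_genes=immune,
        element_counts=counts,
    )


def element_density(intervals, annotation: GeneAnnotation) -> dict[str, float]:
    """Regulatory elements per megabase of amplicon span, by element type.

    An element straddling an amplicon boundary counts once; the span is the
    summed length of the amplicon intervals.
    """
    intervals = list(intervals)
    span = sum(end - start for _, start, end in intervals)
    if span <= 0:
        raise DataError("amplicon span must be positive")
    counts = {t: 0 for t in ELEMENT_TYPES}
    for e in annotation.elements_overlapping(intervals):
        counts[e.element_type] += 1
    mb = span / 1e6
    return {t: c / mb for t, c in counts.items()}


def read_genes_bed(path) -> list[GeneRecord]:
    """BED: chrom, start, end, name[, coding-flag (1/0, default 1)]."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"gene BED line needs >=4 columns: {line!r}")
            coding = True if len(parts) < 5 else parts[4] not in ("0", "false")
            out.append(GeneRecord(parts[0], int(parts[1]), int(parts[2]), parts[3], coding))
    return out


def read_elements_bed(path) -> list[RegulatoryElement]:
    """BED: chrom, start, end, element_type in {enhancer, promoter, lncRNA}."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"element BED line needs 4 columns: {line!r}")
            out.append(RegulatoryElement(parts[0], int(parts[1]), int(parts[2]), parts[3]))
    return out


def read_gene_list(path) -> frozenset[str]:
    with open(path) as fh:
        return frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )


def read_gmt(path) -> dict[str, frozenset[str]]:
    """GMT gene sets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return sets


def write_gmt(sets: dict[str, frozenset[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tecdnakit\t{genes}\n")
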