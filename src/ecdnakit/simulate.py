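"""Synthetic tumour cohorts with known ecDNA content and mutation timing.

The generator emulates the data model of a whole-genome-sequenced tumour
carrying an ecDNA focal amplification:

* a toy three-chromosome genome with a background copy state near the
  sample ploidy and one (or more) high-copy focal amplicon per tumour;
* somatic SNVs inside the amplicon whose multiplicity is either the full
  focal copy number (pre-formation era: the mutation was amplified with
  the locus) or a low value (post-formation era), with expected VAF
  m * p / (p * CPNfocal + (1 - p) * CPNnorm);
* binomial read sampling at Poisson-distributed depth around ~100x (an
  infinite-depth flag emits exact VAFs for oracle tests);
* 96-channel trinucleotide spectra drawn from era-specific mixtures over a
  synthetic Dirichlet reference signature set.

Every random draw flows from a single integer seed, and a TruthLedger
records the generating era, signature and multiplicity of every mutation
so recovery rates can be measured against ground truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .amplicon import (
    AmpliconDecomposition,
    AmpliconPath,
    GeneAnnotation,
    GeneRecord,
    RegulatoryElement,
    write_cycles,
    write_gmt,
)
from .channels import N_CHANNELS, ref_alt
from .errors import DataError
from .genome_profile import CNSegment, write_seg
from .signatures import SignatureModel, write_signatures_tsv
from .timing import MutationObservation, expected_vaf
from .vcfio import write_mutations_vcf

#: Toy genome used by the simulator (chromosome -> length in bp).
TOY_GENOME: dict[str, int] = {
    "chr1": 60_000_000,
    "chr2": 50_000_000,
    "chr3": 40_000_000,
}

TRUTH_COLUMNS = ["sample", "mutation_id", "era", "signature", "multiplicity", "channel"]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the cohort the analysis modules were designed around:
    tumour purity 0.10-0.95, ploidy ~2-4, focal amplicons at copy number
    far above ploidy, ~100x tumour depth, and era-specific signature
    mixtures that differ between pre- and post-formation mutations.
    """

    n_samples: int = 10
    purity_range: tuple[float, float] = (0.10, 0.95)
    ploidy_range: tuple[float, float] = (2.0, 4.0)
    depth_mean: float = 100.0
    cpn_focal_range: tuple[float, float] = (10.0, 60.0)
    n_mut_per_amplicon: int = 100
    era_mixtures: tuple[tuple[float, ...], tuple[float, ...]] = (
        (0.7, 0.2, 0.1),
        (0.1, 0.2, 0.7),
    )
    fraction_pre: float = 0.5
    seed: int = 0
    infinite_depth: bool = False
    n_amplicons: int = 1
    amplicon_probability: float = 1.0
    regions_per_patient: int = 1
    signature_concentration: float = 0.5

    def __post_init__(self) -> None:
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise DataError("purity_range must lie within (0,1]")
        if self.depth_mean <= 0:
            raise DataError("depth_mean must be positive")
        if not 0 <= self.fraction_pre <= 1:
            raise DataError("fraction_pre must lie in [0,1]")
        pre, post = self.era_mixtures
        if len(pre) != len(post):
            raise DataError("era mixtures must cover the same signatures")
        for mix in (pre, post):
            if abs(sum(mix) - 1.0) > 1e-9 or any(w < 0 for w in mix):
                raise DataError("each era mixture must be a simplex (sum 1)")
        if self.n_amplicons < 1 or self.n_amplicons > len(TOY_GENOME):
            raise DataError(f"n_amplicons must be in 1..{len(TOY_GENOME)}")
        if self.n_samples < 0:
            raise DataError("n_samples must be >= 0")

    @property
    def n_signatures(self) -> int:
        return len(self.era_mixtures[0])

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["purity_range"] = list(self.purity_range)
        d["ploidy_range"] = list(self.ploidy_range)
        d["cpn_focal_range"] = list(self.cpn_focal_range)
        d["era_mixtures"] = [list(m) for m in self.era_mixtures]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("purity_range", "ploidy_range", "cpn_focal_range"):
            if key in d:
                d[key] = tuple(d[key])
        if "era_mixtures" in d:
            d["era_mixtures"] = tuple(tuple(m) for m in d["era_mixtures"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def simulate_reference_signatures(
    n_signatures: int, seed: int = 0, concentration: float = 0.5
) -> SignatureModel:
    """Synthetic Dirichlet-style reference signatures (rows sum to 1).

    Low concentration (default 0.5) yields spiky, mutually dissimilar
    spectra, mimicking the distinctness of curated reference signatures.
    Deterministic for a fixed seed. A real signatures x 96 TSV can be
    supplied instead via :func:`ecdnakit.signatures.read_signatures_tsv`.
    """
    if n_signatures < 1:
        raise DataError("n_signatures must be >= 1")
    rng = np.random.default_rng(seed)
    R = rng.dirichlet(np.full(N_CHANNELS, concentration), size=n_signatures)
    names = tuple(f"SBS_SYN{i + 1}" for i in range(n_signatures))
    return SignatureModel(names, R)


@dataclass
class SimulatedTumour:
    sample: str
    patient: str
    purity: float
    ploidy: float
    depth_mean: float
    segments: list[CNSegment]
    decompositions: list[AmpliconDecomposition]
    mutations: list[MutationObservation]
    truth: pd.DataFrame

    @property
    def has_ecdna(self) -> bool:
        return bool(self.decompositions)


def _draw_multiplicity(rng, era: str, cpn_focal: float) -> float:
    if era == "pre":
        return cpn_focal
    # post mutations sit clearly below the 0.8*CPNfocal pre threshold
    hi = max(1, math.ceil(cpn_focal / 4))
    return float(rng.integers(1, hi + 1))


def simulate_tumour(
    config: SimulationConfig,
    sample_index: int,
    model: SignatureModel,
) -> SimulatedTumour:
    """One synthetic tumour: CN segments, decompositions, SNVs and truth."""
    if model.n_signatures != config.n_signatures:
        raise DataError("signature model does not match era mixtures")
    rng = np.random.default_rng([config.seed, sample_index])
    sample = f"S{sample_index:03d}"
    patient = f"P{sample_index // config.regions_per_patient:03d}"
    purity = float(rng.uniform(*config.purity_range))
    ploidy = float(rng.uniform(*config.ploidy_range))
    base_cn = float(max(1, round(ploidy)))

    has_amplicons = rng.random() < config.amplicon_probability
    chroms = list(TOY_GENOME)
    amp_chroms = (
        [str(c) for c in rng.choice(chroms, size=config.n_amplicons, replace=False)]
        if has_amplicons
        else []
    )

    segments: list[CNSegment] = []
    decompositions: list[AmpliconDecomposition] = []
    mutations: list[MutationObservation] = []
    truth_rows: list[tuple] = []
    mixtures = np.array(config.era_mixtures, dtype=float)

    for chrom in chroms:
        length = TOY_GENOME[chrom]
        if chrom not in amp_chroms:
            segments.append(CNSegment(chrom, 0, length, base_cn))
            continue
        cpn_focal = float(rng.uniform(*config.cpn_focal_range))
        amp_len = int(rng.uniform(5e5, 3e6))
        start = int(rng.uniform(5e6, length - 5e6 - amp_len))
        end = start + amp_len
        segments.append(CNSegment(chrom, 0, start, base_cn))
        amp_seg = CNSegment(chrom, start, end, cpn_focal)
        segments.append(amp_seg)
        segments.append(CNSegment(chrom, end, length, base_cn))

        amp_id = f"{sample}_amp_{chrom}"
        decompositions.append(
            AmpliconDecomposition(
                amplicon_id=amp_id,
                segments=[amp_seg],
                paths=[
                    AmpliconPath(
                        path_id="1",
                        is_cyclic=True,
                        length=amp_len,
                        copy_count=cpn_focal,
                        segment_tokens=("1+",),
                    )
                ],
                residual_weight=0.0,
            )
        )

        n_mut = config.n_mut_per_amplicon
        positions = np.sort(rng.choice(amp_len, size=n_mut, replace=False)) + start
        eras = np.where(rng.random(n_mut) < config.fraction_pre, "pre", "post")
        for i, (pos, era) in enumerate(zip(positions, eras)):
            m = _draw_multiplicity(rng, era, cpn_focal)
            vaf_exp = expected_vaf(m, purity, cpn_focal, 2.0)
            if config.infinite_depth:
                depth = int(round(config.depth_mean))
                vaf = vaf_exp
            else:
                depth = max(1, int(rng.poisson(config.depth_mean)))
                vaf = rng.binomial(depth, vaf_exp) / depth
            sig_idx = int(rng.choice(model.n_signatures, p=mixtures[0 if era == "pre" else 1]))
            channel = int(rng.choice(N_CHANNELS, p=model.R[sig_idx])) + 1
            ref, alt = ref_alt(channel)
            mut_id = f"{amp_id}_m{i:04d}"
            mutations.append(
                MutationObservation(
                    sample=sample,
                    mutation_id=mut_id,
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    vaf=float(vaf),
                    depth=depth,
                    channel=channel,
                    purity=purity,
                    cpn_focal=cpn_focal,
                    cpn_norm=2.0,
                )
            )
            truth_rows.append(
                (sample, mut_id, era, model.names[sig_idx], m, channel)
            )

    return SimulatedTumour(
        sample=sample,
        patient=patient,
        purity=purity,
        ploidy=ploidy,
        depth_mean=config.depth_mean,
        segments=segments,
        decompositions=decompositions,
        mutations=mutations,
        truth=pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS),
    )


def simulate_annotation(seed: int = 0) -> GeneAnnotation:
    """Synthetic gene/oncogene/immune-set/element annotation of the toy genome.

    Genes tile every 400 kb; every 8th gene is an oncogene; two immune gene
    sets of ~110 genes each are drawn from the non-oncogenes (large enough
    to survive the default ORA minimum set size of 100); enhancers,
    promoters and lncRNAs tile at staggered intervals.
    """
    genes: list[GeneRecord] = []
    idx = 0
    for chrom, length in TOY_GENOME.items():
        for pos in range(200_000, length - 220_000, 400_000):
            genes.append(GeneRecord(chrom, pos, pos + 20_000, f"GENE{idx:04d}", True))
            idx += 1
    oncogenes = frozenset(g.name for i, g in enumerate(genes) if i % 8 == 0)
    non_onc = [g.name for g in genes if g.name not in oncogenes]
    rng = np.random.default_rng([seed, 9_999])
    immune_sets = {
        "GO:0002698": frozenset(rng.choice(non_onc, size=110, replace=False)),
        "GO:0001909": frozenset(rng.choice(non_onc, size=110, replace=False)),
    }
    elements: list[RegulatoryElement] = []
    for chrom, length in TOY_GENOME.items():
        for pos in range(450_000, length - 2_000, 900_000):
            elements.append(RegulatoryElement(chrom, pos, pos + 1_500, "enhancer"))
        for pos in range(350_000, length - 1_000, 700_000):
            elements.append(RegulatoryElement(chrom, pos, pos + 800, "promoter"))
        for pos in range(750_000, length - 6_000, 1_500_000):
            elements.append(RegulatoryElement(chrom, pos, pos + 5_000, "lncRNA"))
    return GeneAnnotation(genes, oncogenes, immune_sets, elements)


@dataclass
class SimulatedCohort:
    config: SimulationConfig
    signatures: SignatureModel
    tumours: list[SimulatedTumour]
    annotation: GeneAnnotation

    @property
    def truth(self) -> pd.DataFrame:
        frames = [t.truth for t in self.tumours if len(t.truth)]
        if not frames:
            return pd.DataFrame(columns=TRUTH_COLUMNS)
        return pd.concat(frames, ignore_index=True)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate a full cohort (signatures, tumours and annotation)."""
    model = simulate_reference_signatures(
        config.n_signatures, seed=config.seed, concentration=config.signature_concentration
    )
    tumours = [simulate_tumour(config, i, model) for i in range(config.n_samples)]
    return SimulatedCohort(config, model, tumours, simulate_annotation(config.seed))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_annotation(annotation: GeneAnnotation, directory) -> dict[str, str]:
    os.makedirs(directory, exist_ok=True)
    paths = {
        "genes": os.path.join(directory, "genes.bed"),
        "oncogenes": os.path.join(directory, "oncogenes.txt"),
        "immune_sets": os.path.join(directory, "immune_sets.gmt"),
        "elements": os.path.join(directory, "elements.bed"),
    }
    with open(paths["genes"], "w") as fh:
        for g in annotation.genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t{int(g.coding)}\n")
    with open(paths["oncogenes"], "w") as fh:
        for name in sorted(annotation.oncogenes):
            fh.write(name + "\n")
    write_gmt(annotation.immune_sets, paths["immune_sets"])
    with open(paths["elements"], "w") as fh:
        for e in annotation.elements:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\t{e.element_type}\n")
    return paths


def write_cohort(cohort: SimulatedCohort, directory) -> dict:
    """Write a cohort directory and return its manifest (also saved as JSON).

    Layout: per-sample ``<sid>.vcf``, ``<sid>.seg``, ``<sid>.<amp>.cycles``;
    cohort-level ``metadata.tsv`` (purity, ploidy), ``truth.tsv``,
    ``signatures.tsv``, ``annotation/`` and ``config.yaml``. The manifest
    lists every file with a SHA-256 checksum.
    """
    os.makedirs(directory, exist_ok=True)
    rel = lambda p: os.path.relpath(p, directory)
    samples: dict[str, dict] = {}
    meta_rows = []
    for t in cohort.tumours:
        vcf_path = os.path.join(directory, f"{t.sample}.vcf")
        write_mutations_vcf(
            t.mutations, vcf_path, contigs=TOY_GENOME,
            exact_vaf=cohort.config.infinite_depth,
        )
        seg_path = os.path.join(directory, f"{t.sample}.seg")
        write_seg({t.sample: t.segments}, seg_path)
        cycles_paths = []
        for d in t.decompositions:
            cpath = os.path.join(directory, f"{d.amplicon_id}.cycles")
            write_cycles(d, cpath)
            cycles_paths.append(rel(cpath))
        samples[t.sample] = {
            "patient": t.patient,
            "vcf": rel(vcf_path),
            "seg": rel(seg_path),
            "cycles": cycles_paths,
        }
        meta_rows.append(
            (t.sample, t.patient, t.purity, t.ploidy, t.depth_mean, 0)
        )

    meta_path = os.path.join(directory, "metadata.tsv")
    pd.DataFrame(
        meta_rows,
        columns=["sample", "patient", "purity", "ploidy", "depth_mean", "sv_count"],
    ).to_csv(meta_path, sep="\t", index=False, float_format="%.10g")

    truth_path = os.path.join(directory, "truth.tsv")
    cohort.truth.to_csv(truth_path, sep="\t", index=False, float_format="%.10g")

    sig_path = os.path.join(directory, "signatures.tsv")
    write_signatures_tsv(cohort.signatures, sig_path)

    ann_paths = write_annotation(cohort.annotation, os.path.join(directory, "annotation"))

    config_path = os.path.join(directory, "config.yaml")
    with open(config_path, "w") as fh:
        yaml.safe_dump(cohort.config.to_dict(), fh, sort_keys=True)

    manifest = {
        "seed": cohort.config.seed,
        "samples": samples,
        "metadata": rel(meta_path),
        "truth": rel(truth_path),
        "signatures": rel(sig_path),
        "annotation": {k: rel(v) for k, v in ann_paths.items()},
        "config": rel(config_path),
    }
    all_files = sorted(
        [meta_path, truth_path, sig_path, config_path]
        + list(ann_paths.values())
        + [os.path.join(directory, s["vcf"]) for s in samples.values()]
        + [os.path.join(directory, s["seg"]) for s in samples.values()]
        + [os.path.join(directory, c) for s in samples.values() for c in s["cycles"]]
    )
    manifest["checksums"] = {rel(p): _sha256(p) for p in all_files}
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
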