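"""Cohort orchestration: run every stage over a cohort directory.

A cohort directory is described by a ``manifest.json`` (as produced by
:func:`ecdnakit.simulate.write_cohort`, or assembled by hand for real data)
listing per-sample VCF/SEG/cycles paths, cohort metadata (purity, ploidy),
a reference-signature TSV and annotation files. ``run_pipeline`` applies,
in order: the purity floor, instability metrics and focal seeding, amplicon
complexity and content classification, mutation timing and signature
timing, and gene-set enrichment, then writes a deterministic report bundle
(TSVs plus one JSON summary). Output is a pure function of the manifest
contents, configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import amplicon as amp
from . import enrichment as enr
from . import genome_profile as gp
from . import signatures as sig
from . import timing as tm
from .errors import DataError, FormatError
from .vcfio import read_mutations_vcf

MIN_PURITY = 0.10

STAGES = ("instability", "amplicon", "timing", "enrich")


@dataclass
class PipelineConfig:
    """Every printed threshold, surfaced with its default."""

    min_purity: float = MIN_PURITY
    seed_min_length: int = gp.SEED_MIN_LENGTH
    seed_min_cn: float = gp.SEED_MIN_CN
    seed_ploidy_factor: float = gp.SEED_PLOIDY_FACTOR
    seed_arm_extra: float = gp.SEED_ARM_EXTRA
    focal_min: int = gp.FOCAL_MIN
    focal_max: int = gp.FOCAL_MAX
    wgd_ploidy: float = gp.WGD_PLOIDY
    sv_min_quality: float = gp.SV_MIN_QUALITY
    pre_threshold: float = tm.PRE_THRESHOLD
    literal_multiplicity: bool = False
    min_timing_samples: int = tm.MIN_TIMING_SAMPLES
    min_set_size: int = enr.MIN_SET_SIZE
    q_threshold: float = enr.Q_THRESHOLD
    q_direction: str = "less"
    n_permutations: int = enr.N_PERMUTATIONS
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass(frozen=True)
class MultiRegionStatus:
    patient: str
    n_regions: int
    n_detected: int
    status: str  # clonal / regional / absent / present
    indeterminate: bool  # single-region patients: clonality unknowable


def multiregion_status(patient: str, detections: list[bool]) -> MultiRegionStatus:
    """Clonal / regional / absent call from per-region ecDNA detections.

    Clonal means detected in all of >= 2 regions; regional means detected
    in a proper nonempty subset. Single-region patients report the region's
    own status ("present"/"absent") with ``indeterminate=True``.
    """
    if not detections:
        raise DataError(f"patient {patient}: zero regions")
    n, k = len(detections), sum(bool(d) for d in detections)
    if n == 1:
        return MultiRegionStatus(patient, 1, k, "present" if k else "absent", True)
    if k == n:
        status = "clonal"
    elif k > 0:
        status = "regional"
    else:
        status = "absent"
    return MultiRegionStatus(patient, n, k, status, False)


@dataclass
class CohortManifest:
    root: str
    samples: dict[str, dict]  # sample -> {patient, vcf, seg, cycles: [...]}
    metadata: pd.DataFrame  # indexed by sample
    signatures_path: str
    annotation: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def path(self, rel: str) -> str:
        return os.path.join(self.root, rel)

    @classmethod
    def load(cls, directory) -> "CohortManifest":
        mpath = os.path.join(directory, "manifest.json")
        if not os.path.exists(mpath):
            raise FormatError(f"no manifest.json under {directory}")
        with open(mpath) as fh:
            m = json.load(fh)
        meta = pd.read_csv(os.path.join(directory, m["metadata"]), sep="\t").set_index(
            "sample"
        )
        manifest = cls(
            root=str(directory),
            samples=m["samples"],
            metadata=meta,
            signatures_path=m["signatures"],
            annotation=m.get("annotation", {}),
            seed=int(m.get("seed", 0)),
        )
        for sid, entry in manifest.samples.items():
            for p in [entry["vcf"], entry["seg"], *entry["cycles"]]:
                if not os.path.exists(manifest.path(p)):
                    raise FormatError(f"manifest references missing file {p}")
        return manifest

    def load_annotation(self) -> amp.GeneAnnotation | None:
        if not self.annotation:
            return None
        return amp.GeneAnnotation(
            genes=amp.read_genes_bed(self.path(self.annotation["genes"])),
            oncogenes=amp.read_gene_list(self.path(self.annotation["oncogenes"])),
            immune_sets=amp.read_gmt(self.path(self.annotation["immune_sets"])),
            elements=amp.read_elements_bed(self.path(self.annotation["elements"])),
        )


def _write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def _round(x: float, nd: int = 10):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else round(float(x), nd)


def run_pipeline(
    manifest: CohortManifest,
    config: PipelineConfig | None = None,
    out_dir="results",
    stages: tuple[str, ...] = STAGES,
) -> dict[str, str]:
    """Run the requested stages and write the report bundle.

    Returns a mapping of report-section name to output path. Samples below
    the purity floor are excluded with a logged reason and the run
    continues. All randomness (the enrichment permutations) flows from
    ``config.seed``.
    """
    config = config or PipelineConfig()
    os.makedirs(out_dir, exist_ok=True)
    outputs: dict[str, str] = {}
    log_lines: list[str] = []

    # --- purity floor -----------------------------------------------------
    included, exclusions = [], []
    for sample in sorted(manifest.samples):
        purity = float(manifest.metadata.loc[sample, "purity"])
        if purity < config.min_purity:
            exclusions.append((sample, f"purity {purity:g} < {config.min_purity:g}"))
            log_lines.append(f"EXCLUDE {sample}: purity {purity:g} below floor")
        else:
            included.append(sample)
    excl_path = os.path.join(out_dir, "exclusions.tsv")
    _write_tsv(pd.DataFrame(exclusions, columns=["sample", "reason"]), excl_path)
    outputs["exclusions"] = excl_path

    # --- load per-sample inputs ------------------------------------------
    annotation = manifest.load_annotation()
    model = sig.read_signatures_tsv(manifest.path(manifest.signatures_path))
    profiles: dict[str, gp.SampleProfile] = {}
    decomps: dict[str, list[amp.AmpliconDecomposition]] = {}
    for sample in included:
        entry = manifest.samples[sample]
        segs = gp.read_seg(manifest.path(entry["seg"])).get(sample, [])
        meta = manifest.metadata.loc[sample]
        profiles[sample] = gp.SampleProfile(
            sample=sample,
            purity=float(meta["purity"]),
            ploidy=float(meta["ploidy"]),
            segments=segs,
            sv_count=int(meta.get("sv_count", 0)),
            genome_size=sum(s.length for s in segs),
        )
        decomps[sample] = [amp.parse_cycles(manifest.path(c)) for c in entry["cycles"]]

    # --- instability ------------------------------------------------------
    if "instability" in stages:
        rows = []
        for sample in included:
            prof = profiles[sample]
            seeds = gp.find_seed_intervals(
                prof,
                min_length=config.seed_min_length,
                min_cn=config.seed_min_cn,
                ploidy_factor=config.seed_ploidy_factor,
                arm_extra=config.seed_arm_extra,
                focal_min=config.focal_min,
                focal_max=config.focal_max,
            )
            rows.append(
                {
                    "sample": sample,
                    "purity": prof.purity,
                    "ploidy": prof.ploidy,
                    "wgd": gp.call_wgd(prof.ploidy, config.wgd_ploidy),
                    "wgii": gp.wgii(prof),
                    "sv_burden_per_mb": gp.sv_burden(prof.sv_count, prof.genome_size),
                    "n_seed_intervals": len(seeds),
                    "n_focal": sum(1 for s in seeds if s.focal),
                }
            )
        path = os.path.join(out_dir, "instability.tsv")
        _write_tsv(pd.DataFrame(rows), path)
        outputs["instability"] = path

    # --- amplicon complexity & content ------------------------------------
    content_calls: dict[str, amp.AmpliconContentCall] = {}
    if "amplicon" in stages:
        rows = []
        for sample in included:
            for d in decomps[sample]:
                row = {
                    "sample": sample,
                    "amplicon_id": d.amplicon_id,
                    "n_seg": d.n_seg,
                    "span_bp": d.span,
                    "complexity": amp.amplicon_complexity(d),
                }
                if annotation is not None:
                    call = amp.classify_amplicon_content(
                        d.intervals, annotation, d.amplicon_id
                    )
                    content_calls[d.amplicon_id] = call
                    dens = amp.element_density(d.intervals, annotation)
                    row.update(
                        subclass=call.subclass,
                        genes=",".join(call.genes),
                        oncogenes=",".join(call.oncogenes),
                        immune_genes=",".join(call.immune_genes),
                        enhancers_per_mb=dens["enhancer"],
                        promoters_per_mb=dens["promoter"],
                        lncRNAs_per_mb=dens["lncRNA"],
                    )
                rows.append(row)
        path = os.path.join(out_dir, "amplicons.tsv")
        _write_tsv(pd.DataFrame(rows), path)
        outputs["amplicons"] = path

    # --- timing -----------------------------------------------------------
    timing_table = pd.DataFrame(columns=["sample", "mutation_id", "channel", "cpn_mut", "status"])
    if "timing" in stages:
        mut_rows = []
        calls_by_sample: dict[str, list[tm.TimingCall]] = {}
        for sample in included:
            segs_amp = [s for d in decomps[sample] for s in d.segments]

            def lookup(chrom, pos, _segs=segs_amp):
                for s in _segs:
                    if s.chrom == chrom and s.start <= pos < s.end:
                        return s.total_cn
                return None

            inside, _outside = read_mutations_vcf(
                manifest.path(manifest.samples[sample]["vcf"]),
                sample,
                profiles[sample].purity,
                lookup,
            )
            calls = tm.time_mutations(
                inside,
                pre_threshold=config.pre_threshold,
                literal=config.literal_multiplicity,
            )
            calls_by_sample[sample] = calls
            for m, c in zip(inside, calls):
                mut_rows.append(
                    {
                        "sample": sample,
                        "mutation_id": m.mutation_id,
                        "channel": m.channel,
                        "cpn_mut": c.cpn_mut,
                        "status": c.status,
                    }
                )
        timing_table = pd.DataFrame(
            mut_rows, columns=["sample", "mutation_id", "channel", "cpn_mut", "status"]
        )
        path = os.path.join(out_dir, "timing_mutations.tsv")
        _write_tsv(timing_table, path)
        outputs["timing_mutations"] = path

        # exposures by NNLS on each sample's full channel counts
        counts = {
            sample: sig.channel_counts(
                timing_table.loc[timing_table["sample"] == sample, "channel"]
            )
            for sample in included
        }
        counts_df = pd.DataFrame.from_dict(counts, orient="index")
        exposures = sig.fit_exposures_nnls(counts_df, model) if included else None
        fitted = model.with_exposures(exposures) if exposures is not None else model

        classified = timing_table[timing_table["status"].isin(["pre", "post"])]
        sig_table = tm.signature_timing_test(
            classified, fitted, min_samples=config.min_timing_samples
        ) if len(classified) else pd.DataFrame(
            columns=["median_difference", "p_value", "n_samples"]
        ).rename_axis("signature")
        per_sample, per_signature = tm.timing_report(calls_by_sample, sig_table)
        path = os.path.join(out_dir, "timing_samples.tsv")
        _write_tsv(per_sample, path)
        outputs["timing_samples"] = path
        path = os.path.join(out_dir, "signature_timing.tsv")
        per_signature.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs["signature_timing"] = path

    # --- enrichment -------------------------------------------------------
    if "enrich" in stages and annotation is not None:
        incidence = {}
        for sample in included:
            for d in decomps[sample]:
                genes = frozenset(
                    g.name for g in annotation.genes_overlapping(d.intervals)
                )
                incidence[d.amplicon_id] = genes
        enrichment_out: dict = {"n_amplicons": len(incidence)}
        if incidence:
            matrix = enr.AmpliconGeneMatrix(incidence)
            target = frozenset(annotation.oncogenes) & matrix.pool
            if target:
                res = enr.oncogene_enrichment_permutation(
                    matrix, target, n_perm=config.n_permutations, seed=config.seed
                )
                enrichment_out.update(
                    observed_proportion=_round(res.observed_proportion),
                    null_mean=_round(res.null_mean),
                    null_sd=_round(res.null_sd),
                    p_value=_round(res.p_value),
                    n_permutations=res.n_permutations,
                    seed=res.seed,
                )
            else:
                enrichment_out["note"] = "no oncogene observed on any amplicon"
                log_lines.append("ENRICH skipped permutation: empty target set")
        path = os.path.join(out_dir, "enrichment.json")
        with open(path, "w") as fh:
            json.dump(enrichment_out, fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs["enrichment"] = path

        # ORA of genes on non-oncogenic amplicons against the immune sets
        query = set()
        for amp_id, call in sorted(content_calls.items()):
            if call.subclass != "oncogenic":
                query.update(call.genes)
        background = frozenset(g.name for g in annotation.genes)
        if query:
            ora = enr.fisher_ora(
                frozenset(query) & background,
                annotation.immune_sets,
                background,
                min_set_size=config.min_set_size,
                q_threshold=config.q_threshold,
                q_direction=config.q_direction,
            )
        else:
            ora = pd.DataFrame(
                columns=["set_id", "set_size", "overlap", "p_value", "q_value", "significant"]
            )
            log_lines.append("ORA skipped: empty query gene list")
        path = os.path.join(out_dir, "ora.tsv")
        _write_tsv(ora, path)
        outputs["ora"] = path

    # --- multiregion status ----------------------------------------------
    by_patient: dict[str, list[bool]] = {}
    for sample in included:
        patient = str(manifest.samples[sample].get("patient", sample))
        detected = any(
            any(p.is_cyclic for p in d.paths) for d in decomps[sample]
        )
        by_patient.setdefault(patient, []).append(detected)
    mr_rows = [
        dataclasses.asdict(multiregion_status(patient, dets))
        for patient, dets in sorted(by_patient.items())
    ]
    path = os.path.join(out_dir, "multiregion.tsv")
    _write_tsv(
        pd.DataFrame(
            mr_rows, columns=["patient", "n_regions", "n_detected", "status", "indeterminate"]
        ),
        path,
    )
    outputs["multiregion"] = path

    # --- summary + log ----------------------------------------------------
    summary = {
        "n_samples_input": len(manifest.samples),
        "n_samples_included": len(included),
        "n_samples_excluded": len(exclusions),
        "n_patients": len(by_patient),
        "ecdna_detected_fraction": _round(
            float(np.mean([any(dets) for dets in by_patient.values()]))
        )
        if by_patient
        else None,
        "stages": list(stages),
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": {k: os.path.basename(v) for k, v in sorted(outputs.items())},
    }
    path = os.path.join(out_dir, "summary.json")
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["summary"] = path

    log_path = os.path.join(out_dir, "pipeline.log")
    with open(log_path, "w") as fh:
        for line in log_lines:
            fh.write(line + "\n")
    outputs["log"] = log_path
    return outputs
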