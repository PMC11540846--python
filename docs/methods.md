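# Methods

This note documents the models, parameter choices and numerical conventions
behind ecdnakit, and what the synthetic-cohort tests do and do not
demonstrate about real data.

## Coordinates and formats

All intervals are 0-based half-open internally (BED/SEG convention); VCF
I/O converts from 1-based positions. SEG files are TSVs with columns
`sample, chrom, start, end, total_cn`. Cycle decompositions use a
documented text dialect: `Segment` lines carry `(id, chrom, start, end,
total_cn)` and `Cycle` lines carry `(id, copy_count, ordered signed
segment ids)`, with `0+`/`0−` sentinels marking non-cyclic (linear) paths.
The per-segment copy number column is required because the residual weight
— the length-weighted copy mass unexplained by any path — cannot be
computed without it. Trinucleotide channels follow the conventional
pyrimidine-centred SBS96 order (`A[C>A]A` … `T[T>G]T`), indexed 1–96, and
travel in VCFs as the integer `TNC` INFO tag.

## Focal-amplification seeding

A copy-number segment seeds a candidate focal amplification when **all** of
the following hold: length > 50 kb; total CN > 4.5; total CN > 2 × sample
ploidy; total CN ≥ arm-level median CN + 2.5. Qualifying abutting segments
are merged into maximal runs, and a merged interval is tagged *focal* when
its span lies within [50 kb, 20 Mb]. The four criteria are combined with
AND; users who prefer the looser two-criterion rule (CN floor and ploidy
multiple only) can pass `arm_extra=-inf` and `min_cn` alone. Arm
boundaries come from a BED file; when none is supplied each chromosome's
covered extent is treated as a single arm, which is the right behaviour
for the simulator's toy genome. Arm medians are length-weighted medians of
segment CN (smallest value reaching half the cumulative weight).

## wGII, WGD and SV burden

wGII is computed per chromosome as the fraction of covered bases whose
rounded total CN differs from the rounded median ploidy, then averaged
(unweighted) over chromosomes. Rounding is half-to-even on both the
segment CN and the median ploidy. The median ploidy defaults to the
length-weighted median of segment CN; a caller with an external ploidy
estimate can pass it explicitly. Uncovered bases are excluded from both
numerator and denominator, and sex chromosomes are excluded by default
(configurable) since hemizygosity would otherwise inflate the index.
Whole-genome duplication is a strict threshold call at ploidy > 2.7. SV
burden is `sv_count / (genome_size / 1e6)`.

SV post-filters remove calls with: somatic quality < 30; normal-sample
depth near a break-end > 3× the chromosomal mean; DEL/DUP length > 10 kb;
variants < 1 kb with MAPQ0 read fraction > 0.4. Every removed record
carries the list of rules it triggered, and kept ∪ removed partitions the
input. Removing *large* deletions/duplications is unusual for somatic
filtering, so the direction of that one rule is configurable
(`remove_large`, the default, or `remove_small`).

## Amplicon complexity

With cyclic-path weights `w_i = length_i × copy_count_i`, residual `r` and
total `W = Σ w_i + r`, the score is
`log10(n_seg) + Σ_i(−f_i log10 f_i) + (−f_r log10 f_r)` with `0·log 0 ≡ 0`.
The first term grows with structural fragmentation; the entropy terms are
zero when a single cyclic decomposition explains all copy mass and maximal
when mass is spread evenly across paths and residual. A single-segment,
single-cycle, zero-residual amplicon scores exactly 0. Only cyclic paths
and the residual enter the entropy normalization; linear paths reduce the
residual when the decomposition is parsed but do not contribute entropy
terms themselves. The log base (10) and the Shannon-entropy reading of the
normalized length-weighted copy numbers are this package's normative
definition of the three-term score.

## ecDNA content subclassification

Precedence is fixed to make calls deterministic: oncogenic (≥1 oncogene
overlaps) > immunomodulatory (≥1 immune-set gene) > other-coding >
regulatory-only (≥1 enhancer/promoter/lncRNA and no genes) >
no-coding-genes. Overlap means ≥1 bp between an annotation interval and
any amplicon interval; no fractional-overlap threshold is applied. Immune
genes co-amplified on oncogenic amplicons are retained as a field of the
call rather than changing the subclass. Oncogene and immune-set lists are
user inputs (gene lists differ substantially in inclusivity; the choice
materially changes the oncogenic fraction), with toy lists shipped for
tests. Element densities divide the count of distinct overlapping elements
by the summed amplicon span in Mb, so an element straddling a boundary
counts once.

## Mutation multiplicity and timing

The forward model for a mutation on `m` of `CPNfocal` amplified copies in
a tumour of purity `p` with normal-cell local copy number `CPNnorm` is
`VAF = m·p / (p·CPNfocal + (1−p)·CPNnorm)`; the implemented inversion is
`CPNmut = VAF·(1/p)·(p·CPNfocal + CPNnorm·(1−p))`, the standard
allele-balance read-depth inversion, which recovers `CPNmut = CPNfocal`
exactly at `VAF = 1, p = 1`. An alternative parenthesization that applies
the purity correction only to the focal term is retained behind
`literal=True` for audit, but it is dimensionally inconsistent (it does
not reduce to the clonal limit) and is never used by the pipeline.
Classification is strict: pre iff `CPNmut > 0.8·CPNfocal`; post iff
`CPNmut < 0.8·CPNfocal` and `CPNmut > CPNnorm/2`; exact boundary equality
and everything at or below `CPNnorm/2` is unclassified and excluded from
downstream catalogues. `CPNnorm` defaults to 2 (autosomes) and is
overridable per locus. A noise-free inferred multiplicity above `CPNfocal`
indicates inconsistent inputs and raises; when timing noisy cohort data
the cap is disabled because binomial sampling legitimately pushes
single-mutation estimates above `CPNfocal`.

## Signature attribution and timing

The attribution posterior multiplies the sample exposure by the reference
signature weight and normalizes:
`P(s|c,j) = E_{j,s}R_{s,c} / Σ_{s'}E_{j,s'}R_{s',c}`. The posterior is
invariant to positive rescaling of `E_j`, so normalized and raw exposures
are interchangeable; channels with zero total likelihood raise an
unattributable-mutation error and are excluded. Argmax ties break to the
lowest signature index. Exposures are inputs; for synthetic
self-containment a helper fits them by non-negative least squares on the
sample's 96-channel counts (adequate here because the synthetic reference
signatures are nearly orthogonal; NNLS on real, collinear reference sets
is noticeably less stable than dedicated refitting tools).

The signature-timing test computes, per sample with ≥1 pre and ≥1 post
mutation, the mean attribution posterior over pre mutations minus the mean
over post mutations, and reports the across-sample median of that paired
difference per signature, with a paired Wilcoxon signed-rank p-value.
Means over mutations (rather than pooled posterior mass) are the default
aggregation; the two coincide for equal-size classes. Zero differences are
dropped (Wilcoxon convention); the exact null distribution is used for
n ≤ 25 and the normal approximation with continuity correction beyond,
falling back to the approximation if the exact path rejects ties. Fewer
than `min_samples` (default 5) eligible samples yields NA statistics
rather than an unstable test. Samples are treated independently;
multi-region samples of one tumour are not aggregated before testing.

## Enrichment statistics

The permutation test draws `|target|` genes uniformly **without
replacement** from the pool of genes observed on ≥1 amplicon, recomputes
the fraction of amplicons containing ≥1 drawn gene, and reports
`p = (1 + #{perm ≥ observed}) / (n_perm + 1)` — the +1 correction keeps
Monte-Carlo p-values off zero, with floor `1/(n_perm+1)` at the default
10,000 permutations. ORA uses a one-sided Fisher exact test (enrichment
direction; two-sided available), excludes sets smaller than 100 genes
(after restriction to the background), and adjusts across surviving sets
with Benjamini–Hochberg. Significance defaults to `q < 0.001`; the
direction of the comparison is configurable because the threshold's
conventional reading is "less than".

## Synthetic cohort: what it emulates and what it does not

Each simulated tumour has a three-chromosome toy genome (60/50/40 Mb), a
background copy state at the rounded ploidy, and (by default) one ecDNA
amplicon of 0.5–3 Mb at copy number drawn from 10–60 — far above ploidy,
as real ecDNA is. Purity is uniform on 0.10–0.95 and ploidy on 2–4. Each
amplicon receives 100 SNVs; an SNV is pre-era with probability 0.5, in
which case its multiplicity equals the focal copy number, or post-era with
multiplicity uniform on {1, …, ⌈CPNfocal/4⌉} so that post mutations sit
clearly below the 0.8 threshold and recovery rates are interpretable.
Depth is Poisson around 100× (the tumour-sequencing target the data model
emulates; the depth distribution itself is this package's choice) with
binomial alt-read sampling; an infinite-depth flag emits exact VAFs for
oracle tests. Channels are drawn from era-specific mixtures over synthetic
Dirichlet reference signatures (concentration 0.5, giving spiky, mutually
dissimilar spectra); real reference sets can be supplied as a
signatures × 96 TSV. All draws flow from one integer seed via per-sample
seed sequences, making cohort files byte-identical across runs.

The generator does **not** simulate reads (no BAM/FASTQ), SV breakpoint
sequences, subclonal copy-number evolution, multi-chromosomal amplicons,
or mutational hotspots. Passing recovery tests on this cohort therefore
demonstrates the correctness of the inference given the stated VAF and
spectrum models — not robustness to segmentation error, purity
misestimation, subclonality or mapping artefacts in real tumours.

## Problem sizes and determinism

The shipped tests and the acceptance script use deliberately small
problems — cohorts of 1–50 samples, 40–1,000 mutations per amplicon,
10,000 permutations, 10-kb brute-force wGII genomes — chosen so every
oracle can be recomputed exhaustively or at 1-bp resolution alongside the
implementation. Pipeline outputs are pure functions of (inputs, config,
seed): floats are serialized with fixed formats, JSON keys are sorted, and
no timestamps enter reports, so report bundles are byte-identical across
reruns.

## Known limitations

* Amplicon membership of a mutation is decided by position-in-interval
  against the decomposition's segments; mutations inside a seed interval
  but outside any decomposition segment are not timed.
* The clonal/regional multi-region classification uses the all-or-subset
  rule; with one sequenced region clonality is reported as indeterminate.
* ORA takes gene sets as flat files (GMT); no ontology-graph propagation
  is performed.
* The ecDNA/BFB/linear discrimination of amplicon reconstruction tools is
  out of scope: cycle decompositions are inputs, and any cyclic path is
  treated as evidence of circular (ecDNA-like) structure.
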