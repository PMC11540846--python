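"""Mutation timing relative to ecDNA formation.

A somatic SNV inside a focal amplification sits on some number of the
amplified copies (its *multiplicity*, CPNmut). Mutations that predate
amplification were copied onto every amplicon copy (CPNmut close to the
focal copy number CPNfocal); mutations arising afterwards sit on a subset
(low CPNmut). Multiplicity is inferred from the variant allele frequency by
the standard allele-balance inversion

    CPNmut = VAF * (1/p) * (p * CPNfocal + CPNnorm * (1 - p))

with tumour purity p and normal-cell local copy number CPNnorm (2 on
autosomes). Classification uses strict thresholds: *pre* when CPNmut >
0.8 * CPNfocal, *post* when CPNmut < 0.8 * CPNfocal and CPNmut >
CPNnorm / 2, otherwise *unclassified* (boundary equality included).

Signature timing compares, per sample and signature, the mean attribution
posterior over pre-classified mutations with the mean over post-classified
mutations, and reports the across-sample median paired difference with a
paired Wilcoxon signed-rank p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .channels import channel_index
from .errors import DataError
from .signatures import SignatureModel, signature_posteriors

PRE_THRESHOLD = 0.8
DEFAULT_CPN_NORM = 2.0
MIN_TIMING_SAMPLES = 5


@dataclass
class MutationObservation:
    """One somatic SNV with its VAF and copy-number context."""

    sample: str
    mutation_id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    vaf: float
    depth: int
    channel: int  # 1..96
    purity: float
    cpn_focal: float
    cpn_norm: float = DEFAULT_CPN_NORM
    cpn_mut: float | None = field(default=None)

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise DataError(f"VAF {self.vaf} outside [0,1]")
        if not 0.0 < self.purity <= 1.0:
            raise DataError(f"purity {self.purity} outside (0,1]")
        if self.cpn_focal <= 0:
            raise DataError("CPNfocal must be positive")
        if self.cpn_norm < 0:
            raise DataError("CPNnorm must be non-negative")
        self.channel = channel_index(self.channel)


@dataclass(frozen=True)
class TimingCall:
    mutation_id: str
    status: str  # pre / post / unclassified
    cpn_mut: float


def mutational_multiplicity(
    vaf: float,
    purity: float,
    cpn_focal: float,
    cpn_norm: float = DEFAULT_CPN_NORM,
    *,
    literal: bool = False,
    cap_tolerance: float = 1e-6,
) -> float:
    """Infer CPNmut from VAF, purity and the local copy-number context.

    ``literal=True`` evaluates the alternative parenthesization
    ``VAF*(1/p)*(p*CPNfocal) + CPNnorm*(1-p)`` for audit; the default is the
    allele-balance inversion documented in the module docstring. A result
    exceeding CPNfocal beyond ``cap_tolerance`` (relative) is flagged as a
    suspect input via :class:`DataError`.
    """
    if purity <= 0:
        raise DataError(f"purity {purity} must be positive")
    if cpn_focal <= 0:
        raise DataError("CPNfocal must be positive")
    if literal:
        return vaf * (1.0 / purity) * (purity * cpn_focal) + cpn_norm * (1.0 - purity)
    m = vaf * (1.0 / purity) * (purity * cpn_focal + cpn_norm * (1.0 - purity))
    if m > cpn_focal * (1.0 + cap_tolerance) + cap_tolerance:
        raise DataError(
            f"CPNmut {m:.4g} exceeds CPNfocal {cpn_focal:.4g}: inconsistent input"
        )
    return m


def expected_vaf(
    multiplicity: float, purity: float, cpn_focal: float, cpn_norm: float = DEFAULT_CPN_NORM
) -> float:
    """Forward VAF model: m*p / (p*CPNfocal + (1-p)*CPNnorm)."""
    denom = purity * cpn_focal + (1.0 - purity) * cpn_norm
    if denom <= 0:
        raise DataError("non-positive total read-backing copy number")
    vaf = multiplicity * purity / denom
    if vaf > 1.0 + 1e-12:
        raise DataError(
            f"multiplicity {multiplicity} with purity {purity} implies VAF {vaf:.4g} > 1"
        )
    return min(vaf, 1.0)


def classify_timing(
    cpn_mut: float,
    cpn_focal: float,
    cpn_norm: float = DEFAULT_CPN_NORM,
    pre_threshold: float = PRE_THRESHOLD,
) -> str:
    """Classify a mutation as pre / post / unclassified (strict thresholds)."""
    if cpn_focal <= 0:
        raise DataError("CPNfocal must be positive")
    upper = pre_threshold * cpn_focal
    if cpn_mut > upper:
        return "pre"
    if cpn_mut < upper and cpn_mut > cpn_norm / 2.0:
        return "post"
    return "unclassified"


def time_mutations(
    mutations: list[MutationObservation],
    *,
    pre_threshold: float = PRE_THRESHOLD,
    literal: bool = False,
) -> list[TimingCall]:
    """Multiplicity + classification for a list of observations (in order)."""
    calls = []
    for m in mutations:
        m.cpn_mut = mutational_multiplicity(
            m.vaf, m.purity, m.cpn_focal, m.cpn_norm, literal=literal,
            cap_tolerance=np.inf,
        )
        calls.append(
            TimingCall(
                m.mutation_id,
                classify_timing(m.cpn_mut, m.cpn_focal, m.cpn_norm, pre_threshold),
                m.cpn_mut,
            )
        )
    return calls


@dataclass(frozen=True)
class SignatureTimingResult:
    signature: str
    median_difference: float  # median over samples of mean(pre) - mean(post)
    p_value: float
    n_samples: int


def _wilcoxon_p(diffs: np.ndarray) -> float:
    """Paired signed-rank p; zeros dropped; exact for n<=25 else normal."""
    diffs = diffs[diffs != 0]
    if len(diffs) == 0:
        return float("nan")
    method = "exact" if len(diffs) <= 25 else "approx"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = wilcoxon(diffs, zero_method="wilcox", correction=True, method=method)
    except ValueError:
        res = wilcoxon(diffs, zero_method="wilcox", correction=True, method="approx")
    return float(res.pvalue)


def signature_timing_test(
    mutations: pd.DataFrame,
    model: SignatureModel,
    *,
    min_samples: int = MIN_TIMING_SAMPLES,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Which signatures act early vs late relative to ecDNA formation.

    ``mutations`` needs columns ``sample``, ``channel`` and ``status``
    ("pre"/"post"; others ignored). For each eligible sample (>=1 pre and
    >=1 post mutation) and signature s, A = aggregate posterior P(s) over
    pre mutations and B over post; the statistic is median_samples(A - B)
    with a paired Wilcoxon signed-rank p-value. Signatures (here: the whole
    table) with fewer than ``min_samples`` eligible samples are reported
    with NaN statistics. ``aggregate`` is "mean" (per-mutation average) or
    "pooled" (total posterior mass normalized by mutation count — identical
    to mean; retained for API explicitness).

    Returns a DataFrame indexed by signature with columns
    ``median_difference``, ``p_value``, ``n_samples``.
    """
    if aggregate not in ("mean", "pooled"):
        raise DataError(f"unknown aggregate {aggregate!r}")
    per_sample_diffs: dict[str, np.ndarray] = {}
    for sample, grp in mutations.groupby("sample", sort=True):
        pre = grp[grp["status"] == "pre"]
        post = grp[grp["status"] == "post"]
        if len(pre) == 0 or len(post) == 0:
            continue

        def _agg(rows) -> np.ndarray | None:
            posts = []
            for ch in rows["channel"]:
                try:
                    posts.append(signature_posteriors(ch, sample, model))
                except DataError:
                    continue  # unattributable mutation: excluded
            if not posts:
                return None
            return np.mean(posts, axis=0)

        a, b = _agg(pre), _agg(post)
        if a is None or b is None:
            continue
        per_sample_diffs[sample] = a - b

    n = len(per_sample_diffs)
    result = pd.DataFrame(
        index=pd.Index(model.names, name="signature"),
        columns=["median_difference", "p_value", "n_samples"],
    )
    result["n_samples"] = n
    if n == 0:
        warnings.warn("no samples with both pre and post mutations", stacklevel=2)
        return result.astype({"median_difference": float, "p_value": float})
    diffs = np.vstack(list(per_sample_diffs.values()))  # samples x signatures
    if n < min_samples:
        result["median_difference"] = np.nan
        result["p_value"] = np.nan
        return result.astype(float)
    result["median_difference"] = np.median(diffs, axis=0)
    result["p_value"] = [_wilcoxon_p(diffs[:, s]) for s in range(diffs.shape[1])]
    return result.astype(float)


def timing_report(
    calls_by_sample: dict[str, list[TimingCall]],
    signature_table: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic per-sample and per-signature summary tables.

    Returns ``(per_sample, per_signature)``; per-sample rows carry counts
    of pre/post/unclassified calls. Rerunning on identical inputs yields
    byte-identical TSV serializations.
    """
    rows = []
    for sample in sorted(calls_by_sample):
        calls = calls_by_sample[sample]
        counts = {"pre": 0, "post": 0, "unclassified": 0}
        for c in calls:
            counts[c.status] += 1
        rows.append(
            {
                "sample": sample,
                "n_mutations": len(calls),
                "n_pre": counts["pre"],
                "n_post": counts["post"],
                "n_unclassified": counts["unclassified"],
            }
        )
    per_sample = pd.DataFrame(
        rows, columns=["sample", "n_mutations", "n_pre", "n_post", "n_unclassified"]
    )
    if signature_table is None:
        signature_table = pd.DataFrame(
            columns=["median_difference", "p_value", "n_samples"]
        ).rename_axis("signature")
    return per_sample, signature_table.sort_index()
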