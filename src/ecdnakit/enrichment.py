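"""Gene-set statistics: permutation enrichment and Fisher/BH ORA.

The oncogene-enrichment permutation test asks whether amplicons carry genes
from a target set (e.g. oncogenes) more often than expected for a random
gene set of the same size drawn from the pool of genes ever observed on an
amplicon. The observed statistic is the fraction of amplicons containing at
least one target gene; the empirical p-value uses the standard +1
correction, p = (1 + #{permutation >= observed}) / (n_perm + 1), so it is
never exactly zero and is bounded below by 1/(n_perm+1).

Over-representation analysis (ORA) compares a query gene list against
predefined gene sets with a one-sided Fisher exact test (enrichment
direction) and Benjamini-Hochberg adjustment across the surviving sets;
sets smaller than ``min_set_size`` (default 100) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .errors import DataError

N_PERMUTATIONS = 10_000
MIN_SET_SIZE = 100
Q_THRESHOLD = 0.001


@dataclass
class AmpliconGeneMatrix:
    """Amplicon -> gene incidence plus the pool of ever-amplified genes."""

    incidence: dict[str, frozenset[str]]  # amplicon id -> genes on it
    pool: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        observed = frozenset().union(*self.incidence.values()) if self.incidence else frozenset()
        if not self.pool:
            self.pool = observed
        elif not observed <= self.pool:
            raise DataError("pool must contain every gene with any incidence")

    @property
    def n_amplicons(self) -> int:
        return len(self.incidence)


@dataclass(frozen=True)
class EnrichmentResult:
    observed_proportion: float
    null_mean: float
    null_sd: float
    p_value: float
    n_permutations: int
    seed: int


def proportion_with_target(
    matrix: AmpliconGeneMatrix, target_set: frozenset[str]
) -> float:
    """Fraction of amplicons containing >= 1 gene from the target set."""
    if matrix.n_amplicons == 0:
        raise DataError("empty amplicon-gene matrix")
    hits = sum(1 for genes in matrix.incidence.values() if genes & target_set)
    return hits / matrix.n_amplicons


def oncogene_enrichment_permutation(
    matrix: AmpliconGeneMatrix,
    target_set,
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
) -> EnrichmentResult:
    """Permutation test of target-gene enrichment on amplicons.

    Each permutation draws ``len(target_set)`` genes uniformly without
    replacement from the pool and recomputes the proportion of amplicons
    carrying >= 1 sampled gene. Deterministic for a fixed seed.
    """
    target = frozenset(target_set)
    if not target <= matrix.pool:
        raise DataError("target set must be a subset of the gene pool")
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    if matrix.n_amplicons == 0:
        raise DataError("empty amplicon-gene matrix")
    observed = proportion_with_target(matrix, target)
    pool = np.array(sorted(matrix.pool))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    amplicon_gene_sets = [genes for _, genes in sorted(matrix.incidence.items())]
    k = len(target)
    for i in range(n_perm):
        draw = frozenset(rng.choice(pool, size=k, replace=False))
        hits = sum(1 for genes in amplicon_gene_sets if genes & draw)
        null[i] = hits / matrix.n_amplicons
    p = (1 + int(np.sum(null >= observed))) / (n_perm + 1)
    return EnrichmentResult(
        observed_proportion=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_perm > 1 else 0.0,
        p_value=p,
        n_permutations=n_perm,
        seed=seed,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_ora(
    query,
    gene_sets: dict[str, frozenset[str]],
    background,
    *,
    min_set_size: int = MIN_SET_SIZE,
    q_threshold: float = Q_THRESHOLD,
    alternative: str = "greater",
    q_direction: str = "less",
) -> pd.DataFrame:
    """One-sided Fisher over-representation analysis with BH adjustment.

    For each gene set S (restricted to the background) with |S| >=
    ``min_set_size``, tests whether the query hits S more often than
    expected under the hypergeometric null. ``q_direction`` sets the
    significance rule (``"less"``: q < threshold — the conventional
    reading; ``"greater"`` retained for audit of the literal text).
    Returns a DataFrame with columns set_id, set_size, overlap, p_value,
    q_value, significant, sorted by p then set_id.
    """
    query = frozenset(query)
    background = frozenset(background)
    if not query:
        raise DataError("empty query gene list")
    if not query <= background:
        raise DataError("query must be a subset of the background")
    if q_direction not in ("less", "greater"):
        raise DataError(f"unknown q_direction {q_direction!r}")

    rows = []
    n_bg, n_q = len(background), len(query)
    for set_id in sorted(gene_sets):
        genes = gene_sets[set_id] & background
        if len(genes) < min_set_size:
            continue
        k = len(query & genes)
        table = [
            [k, n_q - k],
            [len(genes) - k, n_bg - len(genes) - (n_q - k)],
        ]
        _, p = fisher_exact(table, alternative=alternative)
        rows.append((set_id, len(genes), k, float(p)))
    table_df = pd.DataFrame(rows, columns=["set_id", "set_size", "overlap", "p_value"])
    if len(table_df):
        table_df["q_value"] = bh_adjust(table_df["p_value"])
        if q_direction == "less":
            table_df["significant"] = table_df["q_value"] < q_threshold
        else:
            table_df["significant"] = table_df["q_value"] > q_threshold
        table_df = table_df.sort_values(["p_value", "set_id"]).reset_index(drop=True)
    else:
        table_df["q_value"] = pd.Series(dtype=float)
        table_df["significant"] = pd.Series(dtype=bool)
    return table_df
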