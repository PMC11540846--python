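"""Oncogene-enrichment permutation test and Fisher/BH over-representation.

The permutation test compares the fraction of amplicons carrying a target
gene against random same-size gene sets drawn from the pool of genes ever
seen on an amplicon; ORA tests a query gene list against predefined sets.
"""

from ecdnakit import AmpliconGeneMatrix, fisher_ora, oncogene_enrichment_permutation

matrix = AmpliconGeneMatrix(
    {
        "amp1": frozenset({"MYC_like", "g1"}),
        "amp2": frozenset({"MYC_like"}),
        "amp3": frozenset({"g2", "g3"}),
        "amp4": frozenset({"g4"}),
    },
    pool=frozenset({"MYC_like", "g1", "g2", "g3", "g4", "g5", "g6", "g7"}),
)
res = oncogene_enrichment_permutation(matrix, {"MYC_like"}, n_perm=10_000, seed=1)
print(f"observed proportion = {res.observed_proportion:.3f}")
print(f"null mean = {res.null_mean:.3f}, empirical p = {res.p_value:.4f}")

background = frozenset(f"g{i}" for i in range(400))
immune_set = {"GO:demo": frozenset(f"g{i}" for i in range(120))}
query = frozenset(f"g{i}" for i in range(25))
table = fisher_ora(query, immune_set, background)
print(table.to_string(index=False))

# The permutation p is the (+1-corrected) fraction of random gene sets that
# match or beat the observed amplicon hit rate; the ORA q-value is the
# BH-adjusted one-sided Fisher p for over-representation of the query.
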