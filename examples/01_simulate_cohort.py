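"""Simulate a small synthetic tumour cohort and inspect its ground truth.

Builds five tumours, each carrying one high-copy ecDNA amplicon, and prints
the per-sample purity, ploidy, amplicon copy number and the pre/post era
split of the simulated mutations.
"""

from ecdnakit import SimulationConfig, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_samples=5, seed=7))

print("sample  purity  ploidy  CPNfocal  n_mut  pre  post")
for t in cohort.tumours:
    cf = t.decompositions[0].segments[0].total_cn
    eras = t.truth["era"].value_counts()
    print(
        f"{t.sample}  {t.purity:6.2f}  {t.ploidy:6.2f}  {cf:8.1f}  "
        f"{len(t.mutations):5d}  {eras.get('pre', 0):3d}  {eras.get('post', 0):4d}"
    )

# CPNfocal is the copy number of the amplified locus; pre-era mutations sit
# on every amplicon copy (multiplicity == CPNfocal), post-era on a few.
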