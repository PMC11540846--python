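"""Time mutations relative to ecDNA formation from their VAFs.

Inverts the allele-balance model CPNmut = VAF * (1/p) * (p*CPNfocal +
CPNnorm*(1-p)) and applies the strict pre (> 0.8 x CPNfocal) / post
(< 0.8 x CPNfocal and > CPNnorm/2) thresholds.
"""

from ecdnakit import classify_timing, expected_vaf, mutational_multiplicity

purity, cpn_focal, cpn_norm = 0.5, 20.0, 2.0
print(f"purity={purity}, CPNfocal={cpn_focal}, CPNnorm={cpn_norm}")
print("true_m    VAF   inferred_m  call")
for true_m in (20.0, 12.0, 4.0, 1.0, 0.4):
    vaf = expected_vaf(true_m, purity, cpn_focal, cpn_norm)
    m = mutational_multiplicity(vaf, purity, cpn_focal, cpn_norm)
    call = classify_timing(m, cpn_focal, cpn_norm)
    print(f"{true_m:6.1f}  {vaf:5.3f}  {m:10.3f}  {call}")

# A mutation on all 20 amplicon copies (m = CPNfocal) predates formation;
# low-multiplicity mutations arose afterwards; multiplicities at or below
# CPNnorm/2 are left unclassified rather than forced into an era.
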