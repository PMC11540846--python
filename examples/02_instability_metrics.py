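"""Genome-instability metrics: focal seeding, wGII, WGD and SV burden.

Builds a copy-number profile by hand, finds the focal-amplification seed
intervals (length > 50 kb, CN > 4.5, CN > 2x ploidy, CN >= arm median +
2.5, tagged focal within 50 kb - 20 Mb) and prints the instability metrics.
"""

from ecdnakit import CNSegment, SampleProfile, call_wgd, find_seed_intervals, sv_burden, wgii

segments = [
    CNSegment("chr1", 0, 30_000_000, 2.0),
    CNSegment("chr1", 30_000_000, 31_500_000, 25.0),  # 1.5 Mb amplicon
    CNSegment("chr1", 31_500_000, 60_000_000, 2.0),
    CNSegment("chr2", 0, 50_000_000, 3.0),            # whole-chromosome gain
]
profile = SampleProfile("demo", purity=0.6, ploidy=2.1, segments=segments)

for iv in find_seed_intervals(profile):
    print(f"seed interval {iv.chrom}:{iv.start}-{iv.end}  CN={iv.max_cn:g}  focal={iv.focal}")

print(f"wGII = {wgii(profile):.4f}")          # fraction of genome off the median ploidy
print(f"WGD  = {call_wgd(profile.ploidy)}")   # ploidy > 2.7 would be a duplication
print(f"SV burden = {sv_burden(44, sum(s.length for s in segments)):.2f} per Mb")

# The 1.5 Mb CN-25 segment seeds (every criterion holds) and is focal; the
# chr2 gain inflates wGII (half the assayed genome sits off-ploidy) but is
# far too large to seed a focal amplification.
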