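"""Amplicon complexity scoring and ecDNA content subclassification.

Parses a cycles-dialect decomposition, scores its structural complexity
(log10 segment count plus the entropy of cyclic-path and residual weights)
and classifies a toy amplicon's gene content.
"""

import tempfile

from ecdnakit import amplicon_complexity, classify_amplicon_content, parse_cycles
from ecdnakit.amplicon import GeneAnnotation, GeneRecord, RegulatoryElement

cycles_text = (
    "Segment\t1\tchr7\t54000000\t55000000\t30.0\n"
    "Segment\t2\tchr7\t55200000\t55600000\t30.0\n"
    "Cycle=1;Copy_count=20;Segments=1+,2-\n"
    "Cycle=2;Copy_count=10;Segments=0+,1+,0-\n"
)
with tempfile.NamedTemporaryFile("w", suffix=".cycles", delete=False) as fh:
    fh.write(cycles_text)

decomp = parse_cycles(fh.name)
print(f"n_seg={decomp.n_seg}  residual weight={decomp.residual_weight:g}")
print(f"complexity = {amplicon_complexity(decomp):.4f}")

annotation = GeneAnnotation(
    genes=[GeneRecord("chr7", 54_500_000, 54_600_000, "EGFR_like", True)],
    oncogenes=frozenset({"EGFR_like"}),
    elements=[RegulatoryElement("chr7", 55_300_000, 55_301_000, "enhancer")],
)
call = classify_amplicon_content(decomp.intervals, annotation, decomp.amplicon_id)
print(f"subclass = {call.subclass}; oncogenes = {call.oncogenes}")

# Complexity grows with the number of segments and the diversity of cyclic
# and unexplained copy mass; a single clean cycle over one segment scores 0.
# The amplicon is called oncogenic because it overlaps an oncogene.
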