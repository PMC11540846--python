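"""Minimal somatic-SNV VCF I/O.

Writing emits a small VCF 4.2 with INFO keys AF (variant allele frequency),
DP (depth), AO (alt read count, omitted for noise-free records) and TNC
(trinucleotide channel index 1..96). Reading goes through cyvcf2; when AO
and DP are present the VAF is recomputed exactly as AO/DP, avoiding float
round-off from the text representation.
"""

from __future__ import annotations

from cyvcf2 import VCF

from .errors import FormatError
from .timing import DEFAULT_CPN_NORM, MutationObservation

_HEADER = """\
##fileformat=VCFv4.2
##source=ecdnakit
{contigs}##INFO=<ID=AF,Number=A,Type=Float,Description="Variant allele frequency in tumour reads">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at the site">
##INFO=<ID=AO,Number=1,Type=Integer,Description="Alternate-allele read count">
##INFO=<ID=TNC,Number=1,Type=Integer,Description="Trinucleotide channel index (1-96, pyrimidine-centred SBS96 order)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_mutations_vcf(
    mutations: list[MutationObservation],
    path,
    contigs: dict[str, int] | None = None,
    exact_vaf: bool = False,
) -> None:
    """Write observations as a sorted single-sample VCF.

    ``exact_vaf=True`` marks noise-free records: AO is omitted so readers
    take the VAF from AF verbatim.
    """
    contig_lines = "".join(
        f"##contig=<ID={name},length={length}>\n"
        for name, length in (contigs or {}).items()
    )
    with open(path, "w") as fh:
        fh.write(_HEADER.format(contigs=contig_lines))
        for m in sorted(mutations, key=lambda m: (m.chrom, m.pos)):
            info = f"AF={m.vaf:.10g};DP={m.depth}"
            if not exact_vaf:
                info += f";AO={round(m.vaf * m.depth)}"
            info += f";TNC={m.channel}"
            fh.write(
                f"{m.chrom}\t{m.pos + 1}\t{m.mutation_id}\t{m.ref}\t{m.alt}"
                f"\t.\tPASS\t{info}\n"
            )


def read_mutations_vcf(
    path,
    sample: str,
    purity: float,
    cpn_lookup,
    cpn_norm: float = DEFAULT_CPN_NORM,
) -> tuple[list[MutationObservation], list[MutationObservation]]:
    """Read a somatic VCF into observations.

    ``cpn_lookup(chrom, pos0)`` returns the focal amplification copy number
    covering a 0-based position, or None outside amplicons. Returns
    ``(inside, outside)`` where records outside amplicons carry the normal
    copy number as a placeholder focal CN and are meant only for
    catalogue/exposure building, never timing.
    """
    inside, outside = [], []
    for v in VCF(str(path)):
        tnc = v.INFO.get("TNC")
        if tnc is None:
            raise FormatError(f"{path}: record {v.ID} lacks the TNC INFO tag")
        dp = int(v.INFO.get("DP", 0))
        ao = v.INFO.get("AO")
        if ao is not None and dp > 0:
            vaf = int(ao) / dp
        else:
            af = v.INFO.get("AF")
            if af is None:
                raise FormatError(f"{path}: record {v.ID} lacks AF and AO/DP")
            vaf = float(af[0]) if isinstance(af, (tuple, list)) else float(af)
        pos0 = v.POS - 1
        cn = cpn_lookup(v.CHROM, pos0)
        obs = MutationObservation(
            sample=sample,
            mutation_id=v.ID or f"{v.CHROM}:{v.POS}",
            chrom=v.CHROM,
            pos=pos0,
            ref=v.REF,
            alt=v.ALT[0] if v.ALT else ".",
            vaf=min(vaf, 1.0),
            depth=dp,
            channel=int(tnc),
            purity=purity,
            cpn_focal=cn if cn is not None else max(cpn_norm, 1.0),
            cpn_norm=cpn_norm,
        )
        (inside if cn is not None else outside).append(obs)
    return inside, outside
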