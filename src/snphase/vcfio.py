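"""VCF reading and writing.

Output records are written as text for byte-for-byte determinism; parsing
goes through pysam.  All positions are 0-based internally and converted to
1-based only at these boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import pysam

VCF_VERSION = "VCFv4.2"


@dataclass(frozen=True)
class TruthVariant:
    """A planted variant: VCF-style alleles anchored at ``pos`` (0-based)."""

    pos: int
    ref: str
    alt: str
    zygosity: str          # "het" | "hom_alt"
    vclass: str            # "SNP" | "INS" | "DEL"
    het_hap: int = 0       # for het variants: haplotype carrying the alt (1|2)


def _header(contig: str, length: int, sample: Optional[str],
            extra: Sequence[str] = ()) -> List[str]:
    lines = [f"##fileformat={VCF_VERSION}",
             f"##contig=<ID={contig},length={length}>"]
    lines.extend(extra)
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if sample:
        cols += f"\tFORMAT\t{sample}"
    lines.append(cols)
    return lines


def write_truth_vcf(path: str, contig: str, length: int,
                    variants: Iterable[TruthVariant],
                    sample: str = "truth") -> None:
    extra = [
        '##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines = _header(contig, length, sample, extra)
    for v in sorted(variants, key=lambda v: v.pos):
        gt = "0/1" if v.zygosity == "het" else "1/1"
        lines.append(f"{contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                     f"VC={v.vclass}\tGT\t{gt}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth_vcf(path: str) -> List[TruthVariant]:
    out: List[TruthVariant] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else rec.ref
            sample = rec.samples[0] if rec.samples else None
            gt = sample["GT"] if sample else (0, 1)
            zyg = "hom_alt" if gt == (1, 1) else "het"
            if len(rec.ref) == len(alt) == 1:
                vclass = "SNP"
            elif len(alt) > len(rec.ref):
                vclass = "INS"
            else:
                vclass = "DEL"
            vc = rec.info.get("VC")
            if vc:
                vclass = vc if isinstance(vc, str) else vc[0]
            out.append(TruthVariant(pos=rec.pos - 1, ref=rec.ref, alt=alt,
                                    zygosity=zyg, vclass=vclass))
    return out


def format_call_line(contig: str, pos: int, ref: str, alts: Sequence[str],
                     gt: str, qual: float, source: str) -> str:
    return (f"{contig}\t{pos + 1}\t.\t{ref}\t{','.join(alts)}\t{qual:.2f}\t"
            f"PASS\tSRC={source}\tGT:GQ\t{gt}:{int(round(qual))}")


def write_call_vcf(path: str, contig: str, length: int,
                   lines: Sequence[str], sample: str = "sample") -> None:
    extra = [
        '##INFO=<ID=SRC,Number=1,Type=String,Description='
        '"Model whose call was emitted (haplotype_model or pileup_model)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
    ]
    header = _header(contig, length, sample, extra)
    with open(path, "w") as fh:
        fh.write("\n".join(header + list(lines)) + "\n")
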