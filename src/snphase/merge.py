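"""Merging the two rounds' calls and evaluating against a truth set.

The merge rule: if the haplotype model's record at a site has quality
strictly greater than the threshold delta (default 14), its decision stands;
otherwise, if the pileup model's record has quality strictly greater than
delta, its call is emitted; otherwise the site is discarded as a likely
false positive.  Only SNP genotypes reach the output — pileup-model calls
whose allele pair involves I or D are suppressed, and a confident hom_ref
decision yields no record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .models import CallRecord
from .vcfio import TruthVariant, format_call_line, write_call_vcf


@dataclass(frozen=True)
class FinalCall:
    contig: str
    position: int              # 0-based
    ref: str
    alts: Tuple[str, ...]
    gt: str                    # "0/1", "1/1" or "1/2"
    quality: float
    source: str                # "haplotype_model" | "pileup_model"
    genotype: str              # canonical allele pair


def _as_final(record: CallRecord) -> Optional[FinalCall]:
    """A SNP FinalCall for a variant record, None for hom_ref or indel pairs."""
    if record.involves_indel or not record.is_variant:
        return None
    a, b = record.genotype[0], record.genotype[1]
    ref = record.ref_base
    if a == b:
        alts: Tuple[str, ...] = (a,)
        gt = "1/1"
    elif ref in (a, b):
        alts = (b if a == ref else a,)
        gt = "0/1"
    else:
        alts = (a, b)
        gt = "1/2"
    return FinalCall(contig=record.contig, position=record.position, ref=ref,
                     alts=alts, gt=gt, quality=record.quality,
                     source=record.source, genotype=record.genotype)


def merge_calls(hap: Optional[CallRecord], pile: Optional[CallRecord],
                delta: float = 14.0) -> Optional[FinalCall]:
    """Apply the two-round quality-threshold merge at one site."""
    if hap is None and pile is None:
        raise ValueError("at least one record must be present")
    if hap is not None and hap.quality > delta:
        return _as_final(hap)
    if pile is not None and pile.quality > delta:
        return _as_final(pile)
    return None


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    precision_defined: bool = True

    def as_dict(self) -> Dict[str, float]:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "precision": self.precision, "recall": self.recall,
                "f1": self.f1}


def _in_regions(pos: int, regions: Optional[Sequence[Tuple[int, int]]]) -> bool:
    if regions is None:
        return True
    return any(s <= pos < e for s, e in regions)


def classify_against_truth(calls: Sequence[FinalCall],
                           truth: Sequence[TruthVariant],
                           regions: Optional[Sequence[Tuple[int, int]]] = None,
                           contig: Optional[str] = None) -> EvalResult:
    """Site + genotype match within the confident regions; SNP truth only.

    TP requires the called allele pair to equal the truth genotype; a call
    at a truth site with the wrong genotype counts as both FP and FN.
    """
    if contig is not None:
        bad = {c.contig for c in calls if c.contig != contig}
        if bad:
            raise ValueError(f"calls on unexpected contig(s) {bad}, "
                             f"expected {contig}")
    truth_pairs: Dict[int, str] = {}
    for v in truth:
        if v.vclass != "SNP" or not _in_regions(v.pos, regions):
            continue
        pair = (v.ref + v.alt) if v.zygosity == "het" else (v.alt + v.alt)
        truth_pairs[v.pos] = "".join(sorted(pair))
    tp = fp = 0
    hit: Set[int] = set()
    for c in calls:
        if not _in_regions(c.position, regions):
            continue
        want = truth_pairs.get(c.position)
        if want is not None and "".join(sorted(c.genotype)) == want:
            tp += 1
            hit.add(c.position)
        else:
            fp += 1
    fn = len(truth_pairs) - len(hit)
    precision_defined = (tp + fp) > 0
    precision = tp / (tp + fp) if precision_defined else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return EvalResult(tp=tp, fp=fp, fn=fn, precision=precision, recall=recall,
                      f1=f1, precision_defined=precision_defined)


def write_final_vcf(path: str, contig: str, length: int,
                    calls: Sequence[FinalCall],
                    sample: str = "sample") -> None:
    """Final SNP-only VCF; calls must already be position-sorted."""
    positions = [c.position for c in calls]
    if positions != sorted(positions):
        raise ValueError("calls must be sorted by position")
    lines = [format_call_line(c.contig, c.position, c.ref, list(c.alts),
                              c.gt, c.quality, c.source) for c in calls]
    write_call_vcf(path, contig, length, lines, sample=sample)


def read_final_vcf(path: str) -> List[FinalCall]:
    import pysam
    out: List[FinalCall] = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            alts = tuple(rec.alts or ())
            gt_t = rec.samples[0]["GT"]
            gt = "/".join(str(g) for g in gt_t)
            alleles = [([rec.ref] + list(alts))[g] for g in gt_t]
            src = rec.info.get("SRC", "unknown")
            out.append(FinalCall(
                contig=rec.chrom, position=rec.pos - 1, ref=rec.ref,
                alts=alts, gt=gt, quality=float(rec.qual),
                source=src if isinstance(src, str) else src[0],
                genotype="".join(sorted(alleles))))
    return out
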