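"""Synthetic diploid genomes and error-perturbed long reads.

The simulator is the package's source of training and evaluation data: it
plants homozygous/heterozygous SNPs and short (1-5 bp) indels into a random
reference, derives the two haplotype sequences, and draws reads alternately
from the haplotypes with substitution/insertion/deletion errors injected per
base.  Reads are emitted at their true coordinates with exact CIGARs (no
external aligner), carry their haplotype of origin in the ``XH`` tag, and
base qualities are drawn from two Phred bands — higher for correct bases,
lower for erroneous ones — so quality features carry learnable signal.

What it does not emulate: pore-level signal, homopolymer-biased errors,
chimeric or clipped mappings, structural variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
import pysam

from .reads import D, TRUTH_HAP_TAG, AlignedRead, encode_bases
from .vcfio import TruthVariant, write_truth_vcf

_BASES = "ACGT"


@dataclass
class DiploidGenome:
    """Reference plus two derived haplotypes and the planted truth set."""

    contig: str
    reference: str
    hap1: str
    hap2: str
    # per-haplotype map: haplotype index -> reference position, -1 for
    # inserted bases that have no reference coordinate
    hap1_pos: np.ndarray
    hap2_pos: np.ndarray
    truth_variants: List[TruthVariant]
    seed: int

    def __len__(self) -> int:
        return len(self.reference)

    def hap(self, h: int) -> Tuple[str, np.ndarray]:
        return (self.hap1, self.hap1_pos) if h == 1 else (self.hap2, self.hap2_pos)

    def truth_snps(self) -> List[TruthVariant]:
        return [v for v in self.truth_variants if v.vclass == "SNP"]


@dataclass
class SimRead:
    """A simulated read with both its BAM fields and dense expansion."""

    aligned: AlignedRead
    seq: str
    quals: np.ndarray            # per-sequenced-base Phred
    cigartuples: List[Tuple[int, int]]


@dataclass
class SimulatedReadSet:
    contig: str
    reference_length: int
    coverage: float
    error_model: Tuple[float, float, float]   # (sub, ins, del) per base
    reads: List[SimRead]
    seed: int

    def aligned_reads(self) -> List[AlignedRead]:
        return [r.aligned for r in self.reads]


def _check_rate(name: str, value: float) -> None:
    if not np.isfinite(value) or not 0.0 <= value <= 0.1:
        raise ValueError(f"{name} must be finite and in [0, 0.1], got {value}")


def generate_diploid(length: int,
                     snp_rate: float = 0.001,
                     het_fraction: float = 2.0 / 3.0,
                     indel_rate: float = 0.0002,
                     seed: int = 0,
                     contig: str = "sim1") -> DiploidGenome:
    """Plant SNPs and short indels into a random reference.

    ``snp_rate`` defaults to one SNP per kilobase (the density typical of a
    human genome against its reference); ``het_fraction`` to 2/3 het, the
    human het:hom ratio of roughly 2:1.  Variants are kept at least two
    bases apart so alleles never overlap.
    """
    if length < 1000:
        raise ValueError("length must be >= 1000")
    _check_rate("snp_rate", snp_rate)
    _check_rate("indel_rate", indel_rate)
    if not np.isfinite(het_fraction) or not 0.0 <= het_fraction <= 1.0:
        raise ValueError("het_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)
    ref_codes = rng.integers(0, 4, size=length, dtype=np.int8)
    reference = "".join(_BASES[c] for c in ref_codes)

    snp_pos = np.flatnonzero(rng.random(length) < snp_rate)
    indel_pos = np.flatnonzero(rng.random(length) < indel_rate)
    events = sorted([(int(p), "SNP") for p in snp_pos]
                    + [(int(p), "INDEL") for p in indel_pos])

    variants: List[TruthVariant] = []
    last_end = -10
    for pos, kind in events:
        if pos < 10 or pos > length - 10:
            continue
        if pos < last_end + 2:
            continue
        ref_base = reference[pos]
        zyg = "het" if rng.random() < het_fraction else "hom_alt"
        het_hap = int(rng.integers(1, 3)) if zyg == "het" else 0
        if kind == "SNP":
            alt = _BASES[(ref_codes[pos] + rng.integers(1, 4)) % 4]
            variants.append(TruthVariant(pos, ref_base, alt, zyg, "SNP", het_hap))
            last_end = pos
        else:
            ilen = int(rng.integers(1, 6))
            if rng.random() < 0.5:     # insertion
                ins = "".join(_BASES[c] for c in rng.integers(0, 4, ilen))
                variants.append(TruthVariant(pos, ref_base, ref_base + ins,
                                             zyg, "INS", het_hap))
                last_end = pos
            else:                      # deletion of ilen bases after the anchor
                if pos + ilen >= length - 10:
                    continue
                ref_allele = reference[pos:pos + ilen + 1]
                variants.append(TruthVariant(pos, ref_allele, ref_base,
                                             zyg, "DEL", het_hap))
                last_end = pos + ilen

    hap_seqs: List[str] = []
    hap_maps: List[np.ndarray] = []
    by_pos: Dict[int, TruthVariant] = {v.pos: v for v in variants}
    for h in (1, 2):
        chars: List[str] = []
        pos_map: List[int] = []
        p = 0
        while p < length:
            v = by_pos.get(p)
            applies = v is not None and (v.zygosity == "hom_alt" or v.het_hap == h)
            if not applies:
                chars.append(reference[p])
                pos_map.append(p)
                p += 1
                continue
            if v.vclass == "SNP":
                chars.append(v.alt)
                pos_map.append(p)
                p += 1
            elif v.vclass == "INS":
                chars.append(reference[p])
                pos_map.append(p)
                for b in v.alt[1:]:
                    chars.append(b)
                    pos_map.append(-1)
                p += 1
            else:  # DEL: keep the anchor, skip the deleted bases
                chars.append(reference[p])
                pos_map.append(p)
                p += len(v.ref)
        hap_seqs.append("".join(chars))
        hap_maps.append(np.asarray(pos_map, dtype=np.int64))

    return DiploidGenome(contig=contig, reference=reference,
                         hap1=hap_seqs[0], hap2=hap_seqs[1],
                         hap1_pos=hap_maps[0], hap2_pos=hap_maps[1],
                         truth_variants=variants, seed=seed)


def _draw_quals(rng: np.random.Generator, n: int, error: bool) -> np.ndarray:
    """Phred qualities from two Beta-scaled bands (error vs correct base)."""
    if error:
        q = 2.0 + rng.beta(2.0, 4.0, size=n) * 15.0
    else:
        q = 5.0 + rng.beta(4.0, 2.0, size=n) * 25.0
    return np.round(q).astype(np.int16)


def simulate_reads(genome: DiploidGenome,
                   coverage: float = 16.0,
                   error_model: Tuple[float, float, float] = (0.04, 0.01, 0.01),
                   seed: int = 0,
                   read_length_mean: float = 5000.0,
                   min_read_length: int = 300) -> SimulatedReadSet:
    """Draw error-perturbed reads alternately from the two haplotypes."""
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    sub_rate, ins_rate, del_rate = error_model
    for name, r in zip(("sub", "ins", "del"), error_model):
        _check_rate(f"{name} rate", r)

    rng = np.random.default_rng(seed)
    length = len(genome)
    # reads may hang over the contig ends and are clipped, so the expected
    # covered length per read is L*length/(length+L-200); compensate
    n_reads = int(round(coverage * (length + read_length_mean - 200)
                        / read_length_mean))
    if n_reads == 0:
        import warnings
        warnings.warn("coverage too low for the contig: zero reads produced")

    hap_codes = {h: encode_bases(genome.hap(h)[0]) for h in (1, 2)}
    hap_maps = {h: genome.hap(h)[1] for h in (1, 2)}

    reads: List[SimRead] = []
    for idx in range(n_reads):
        h = 1 + idx % 2                       # alternate haplotypes
        codes, pos_map = hap_codes[h], hap_maps[h]
        hlen = len(codes)
        rl = max(min_read_length,
                 int(rng.gamma(4.0, read_length_mean / 4.0)))
        s = int(rng.integers(-(rl - 100), hlen - 100))
        i0, i1 = max(0, s), min(hlen, s + rl)
        if i1 - i0 < 50:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        mapq = int(rng.integers(40, 61))
        name = f"{genome.contig}_r{idx:06d}"

        n_cols = i1 - i0
        del_mask = rng.random(n_cols) < del_rate
        sub_mask = rng.random(n_cols) < sub_rate
        ins_mask = rng.random(n_cols) < ins_rate
        sub_shift = rng.integers(1, 4, size=n_cols)
        ins_lens = np.where(ins_mask, rng.geometric(0.6, size=n_cols), 0)
        q_hi = _draw_quals(rng, n_cols, error=False)
        q_lo = _draw_quals(rng, n_cols, error=True)

        seq_codes: List[int] = []
        seq_quals: List[int] = []
        cigar: List[List[int]] = []          # [op, len], op in BAM codes
        matches: List[Tuple[int, int, int]] = []   # (ref_pos, code, qual)
        insertions: Dict[int, int] = {}
        deletions: List[Tuple[int, int]] = []
        read_start = -1
        last_rp = -1

        def add_op(op: int, ln: int) -> None:
            if cigar and cigar[-1][0] == op:
                cigar[-1][1] += ln
            else:
                cigar.append([op, ln])

        def add_insertion(anchor: int, ln: int, k: int) -> None:
            add_op(1, ln)
            ins_codes = rng.integers(0, 4, size=ln)
            seq_codes.extend(int(c) for c in ins_codes)
            seq_quals.extend(int(q_lo[k]) for _ in range(ln))
            insertions[anchor] = insertions.get(anchor, 0) + ln

        for k in range(n_cols):
            rp = int(pos_map[i0 + k])
            if del_mask[k]:
                continue
            base = int(codes[i0 + k])
            is_err = bool(sub_mask[k])
            if is_err:
                base = (base + int(sub_shift[k])) % 4
            qual = int(q_lo[k]) if is_err else int(q_hi[k])
            if rp >= 0:
                if read_start < 0:
                    read_start = rp
                elif rp > last_rp + 1:
                    gap = rp - last_rp - 1
                    add_op(2, gap)
                    deletions.append((last_rp + 1, gap))
                add_op(0, 1)
                seq_codes.append(base)
                seq_quals.append(qual)
                matches.append((rp, base, qual))
                last_rp = rp
            else:
                if last_rp < 0:
                    continue                  # unanchored leading insertion
                add_insertion(last_rp, 1, k)
            if ins_lens[k] and last_rp >= 0:
                add_insertion(last_rp, int(ins_lens[k]), k)

        if read_start < 0 or not matches:
            continue
        end = last_rp + 1
        span = end - read_start
        syms = np.full(span, D, dtype=np.int8)
        quals = np.full(span, -1, dtype=np.int16)
        mp = np.asarray([m[0] for m in matches]) - read_start
        syms[mp] = [m[1] for m in matches]
        quals[mp] = [m[2] for m in matches]

        aligned = AlignedRead(name=name, strand=strand, mapq=mapq,
                              start=read_start, end=end, syms=syms,
                              quals=quals, insertions=insertions,
                              deletions=deletions, truth_haplotype=h)
        seq = "".join(_BASES[c] for c in seq_codes)
        reads.append(SimRead(aligned=aligned, seq=seq,
                             quals=np.asarray(seq_quals, dtype=np.int16),
                             cigartuples=[(op, ln) for op, ln in cigar]))

    reads.sort(key=lambda r: (r.aligned.start, r.aligned.name))
    return SimulatedReadSet(contig=genome.contig, reference_length=length,
                            coverage=coverage, error_model=error_model,
                            reads=reads, seed=seed)


def write_truth(genome: DiploidGenome, readset: SimulatedReadSet,
                out_prefix: str, fastq: bool = False) -> Dict[str, str]:
    """Write FASTA (+fai), sorted+indexed BAM, truth VCF and confident BED.

    Returns the mapping of artifact name to path.  With ``fastq=True`` the
    raw read sequences are additionally exported for external alignment.
    """
    paths = {"fasta": f"{out_prefix}.fa", "bam": f"{out_prefix}.bam",
             "vcf": f"{out_prefix}.vcf", "bed": f"{out_prefix}.bed"}

    with open(paths["fasta"], "w") as fh:
        fh.write(f">{genome.contig}\n")
        for i in range(0, len(genome), 60):
            fh.write(genome.reference[i:i + 60] + "\n")
    pysam.faidx(paths["fasta"])

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": genome.contig, "LN": len(genome)}]}
    with pysam.AlignmentFile(paths["bam"], "wb", header=header) as bam:
        for r in readset.reads:
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r.aligned.name
            a.query_sequence = r.seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals))
            a.flag = 16 if r.aligned.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = r.aligned.start
            a.mapping_quality = r.aligned.mapq
            a.cigartuples = r.cigartuples
            a.set_tag(TRUTH_HAP_TAG, r.aligned.truth_haplotype, "i")
            bam.write(a)
    pysam.index(paths["bam"])

    write_truth_vcf(paths["vcf"], genome.contig, len(genome),
                    genome.truth_variants)
    with open(paths["bed"], "w") as fh:
        fh.write(f"{genome.contig}\t0\t{len(genome)}\n")

    if fastq:
        paths["fastq"] = f"{out_prefix}.fastq"
        with open(paths["fastq"], "w") as fh:
            for r in readset.reads:
                fh.write(f"@{r.aligned.name}\n{r.seq}\n+\n"
                         + "".join(chr(q + 33) for q in r.quals) + "\n")
    return paths
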