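"""Read-backed phasing of het calls and haplotagging of reads.

High-quality heterozygous SNP calls from the first round are phased with a
lightweight minimum-error-correction (MEC) heuristic: sites that share
informative reads form a phase block (connected component); within a block
an initial left-to-right greedy orientation is refined by single-site flips
until no flip lowers the MEC cost, i.e. the total number of read-allele
conflicts after each read is assigned to its better haplotype.  The global
hap1/hap2 labelling of a block is fixed by the tie-break that the first
site's first (canonically ordered) allele goes to haplotype 1.  An external
phaser (e.g. WhatsHap) can substitute via the same PhasedSiteSet interface.

Haplotagging assigns every read to the haplotype whose alleles it matches
at strictly more phased sites; ties and reads covering no phased site stay
unphased.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .models import CallRecord
from .reads import BASE_CODE, AlignedRead


@dataclass(frozen=True)
class HetSite:
    position: int
    allele_a: str      # canonical order, allele_a < allele_b
    allele_b: str
    quality: float = 0.0


@dataclass
class PhasedSite:
    position: int
    allele_hap1: str
    allele_hap2: str
    block: int         # phase-set id: position of the block's first site


@dataclass
class PhasedSiteSet:
    sites: List[PhasedSite] = field(default_factory=list)
    quality_threshold: float = 14.0
    mec_cost: int = 0

    def __len__(self) -> int:
        return len(self.sites)

    def positions(self) -> List[int]:
        return [s.position for s in self.sites]

    def blocks(self) -> Dict[int, List[PhasedSite]]:
        out: Dict[int, List[PhasedSite]] = {}
        for s in self.sites:
            out.setdefault(s.block, []).append(s)
        return out


def select_het_sites(calls: Sequence[CallRecord],
                     qual_threshold: float = 14.0) -> List[HetSite]:
    """Het calls with quality >= threshold and two distinct base alleles."""
    out = []
    for c in calls:
        if c.zygosity != "het" or c.quality < qual_threshold:
            continue
        a, b = c.genotype[0], c.genotype[1]
        if a in BASE_CODE and b in BASE_CODE and a != b:
            out.append(HetSite(position=c.position, allele_a=a, allele_b=b,
                               quality=c.quality))
    out.sort(key=lambda s: s.position)
    return out


def _read_alleles(reads: Sequence[AlignedRead],
                  sites: Sequence[HetSite]) -> List[Dict[int, int]]:
    """Per read: site-index -> 0/1 for allele_a/allele_b (others ignored)."""
    site_pos = [s.position for s in sites]
    code_a = [BASE_CODE[s.allele_a] for s in sites]
    code_b = [BASE_CODE[s.allele_b] for s in sites]
    out: List[Dict[int, int]] = []
    for r in reads:
        alleles: Dict[int, int] = {}
        # sites overlapped by this read (site list is sorted)
        lo = int(np.searchsorted(site_pos, r.start))
        hi = int(np.searchsorted(site_pos, r.end))
        for si in range(lo, hi):
            sym = r.sym_at(site_pos[si])
            if sym == code_a[si]:
                alleles[si] = 0
            elif sym == code_b[si]:
                alleles[si] = 1
        out.append(alleles)
    return out


def mec_cost(read_alleles: Sequence[Dict[int, int]],
             orientation: Sequence[int]) -> int:
    """Conflicts after assigning each read to its better haplotype.

    ``orientation[s] = 0`` means site s's allele_a belongs to haplotype 1.
    """
    total = 0
    for alleles in read_alleles:
        mis1 = sum(1 for si, a in alleles.items() if a != orientation[si])
        mis2 = len(alleles) - mis1
        total += min(mis1, mis2)
    return total


def _components(n_sites: int,
                read_alleles: Sequence[Dict[int, int]]) -> List[List[int]]:
    parent = list(range(n_sites))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for alleles in read_alleles:
        keys = sorted(alleles)
        for x, y in zip(keys, keys[1:]):
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[max(rx, ry)] = min(rx, ry)
    comps: Dict[int, List[int]] = {}
    for s in range(n_sites):
        comps.setdefault(find(s), []).append(s)
    return [sorted(v) for _, v in sorted(comps.items())]


def phase_sites(reads: Sequence[AlignedRead],
                het_sites: Sequence[HetSite],
                quality_threshold: float = 14.0) -> PhasedSiteSet:
    """Greedy MEC phasing with single-site flip refinement."""
    sites = sorted(het_sites, key=lambda s: s.position)
    if not sites:
        return PhasedSiteSet(sites=[], quality_threshold=quality_threshold)
    read_alleles = _read_alleles(reads, sites)
    comps = _components(len(sites), read_alleles)

    orientation = np.zeros(len(sites), dtype=np.int64)
    for comp in comps:
        in_comp = set(comp)
        comp_reads = [a for a in read_alleles
                      if any(si in in_comp for si in a)]
        # greedy left-to-right: orient each site by the leaning of the reads
        # that cover it, given the sites oriented so far
        m1 = np.zeros(len(comp_reads))
        m2 = np.zeros(len(comp_reads))
        for si in comp:
            score = 0.0
            for ri, alleles in enumerate(comp_reads):
                a = alleles.get(si)
                if a is None:
                    continue
                lean = m1[ri] - m2[ri]
                score += lean if a == 0 else -lean
            o = 0 if score >= 0 else 1
            orientation[si] = o
            for ri, alleles in enumerate(comp_reads):
                a = alleles.get(si)
                if a is None:
                    continue
                if a == o:
                    m1[ri] += 1
                else:
                    m2[ri] += 1
        # refinement until no single-site flip or suffix flip (the classic
        # phase-switch move) lowers the MEC cost
        improved = True
        while improved:
            improved = False
            for si in comp:
                base_cost = mec_cost(comp_reads, orientation)
                orientation[si] ^= 1
                if mec_cost(comp_reads, orientation) < base_cost:
                    improved = True
                else:
                    orientation[si] ^= 1
            for start in range(1, len(comp)):
                suffix = comp[start:]
                base_cost = mec_cost(comp_reads, orientation)
                orientation[suffix] ^= 1
                if mec_cost(comp_reads, orientation) < base_cost:
                    improved = True
                else:
                    orientation[suffix] ^= 1
        # small blocks are cheap to solve exactly; enumerate with the first
        # site fixed (global swap symmetry) and keep the best orientation
        if 1 < len(comp) <= 12:
            rest = comp[1:]
            best = orientation[comp].copy()
            best_cost = mec_cost(comp_reads, orientation)
            for bits in range(2 ** len(rest)):
                for j, si in enumerate(rest):
                    orientation[si] = (bits >> j) & 1
                cost = mec_cost(comp_reads, orientation)
                if cost < best_cost:
                    best_cost = cost
                    best = orientation[comp].copy()
            orientation[comp] = best
        # block labelling tie-break: first site's first allele -> hap1
        if orientation[comp[0]] == 1:
            for si in comp:
                orientation[si] ^= 1

    phased: List[PhasedSite] = []
    for comp in comps:
        block = sites[comp[0]].position
        for si in comp:
            s = sites[si]
            if orientation[si] == 0:
                phased.append(PhasedSite(s.position, s.allele_a, s.allele_b, block))
            else:
                phased.append(PhasedSite(s.position, s.allele_b, s.allele_a, block))
    phased.sort(key=lambda s: s.position)
    return PhasedSiteSet(sites=phased, quality_threshold=quality_threshold,
                         mec_cost=mec_cost(read_alleles, orientation))


def haplotag_reads(reads: Sequence[AlignedRead],
                   phased: PhasedSiteSet) -> Dict[str, int]:
    """Assign each read to {1, 2} by majority allele match, else 0 (unphased).

    The partition is total over the input reads and deterministic; it is
    also written back onto each read's ``haplotype`` attribute.
    """
    positions = phased.positions()
    hap1 = {s.position: BASE_CODE[s.allele_hap1] for s in phased.sites}
    hap2 = {s.position: BASE_CODE[s.allele_hap2] for s in phased.sites}
    out: Dict[str, int] = {}
    for r in reads:
        m1 = m2 = 0
        lo = int(np.searchsorted(positions, r.start))
        hi = int(np.searchsorted(positions, r.end))
        for si in range(lo, hi):
            pos = positions[si]
            sym = r.sym_at(pos)
            if sym == hap1[pos]:
                m1 += 1
            elif sym == hap2[pos]:
                m2 += 1
        tag = 1 if m1 > m2 else (2 if m2 > m1 else 0)
        r.haplotype = tag
        out[r.name] = tag
    return out


def write_phased_vcf(path: str, contig: str, length: int,
                     phased: PhasedSiteSet) -> None:
    """Export phased het sites as a VCF with phase-set (PS) annotations."""
    lines = ["##fileformat=VCFv4.2",
             f"##contig=<ID={contig},length={length}>",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             '##FORMAT=<ID=PS,Number=1,Type=Integer,'
             'Description="Phase set">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample"]
    for ps in phased.sites:
        a, b = sorted((ps.allele_hap1, ps.allele_hap2))
        gt = "0|1" if ps.allele_hap1 == a else "1|0"
        lines.append(f"{contig}\t{ps.position + 1}\t.\t{a}\t{b}\t.\tPASS"
                     f"\t.\tGT:PS\t{gt}:{ps.block + 1}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_haplotagged_bam(in_bam: str, out_bam: str,
                          tags: Dict[str, int]) -> None:
    """Copy a BAM, attaching the haplotag partition as HP tags (1/2; reads
    tagged unphased carry no HP tag, following haplotagging convention)."""
    import pysam
    with pysam.AlignmentFile(in_bam, "rb") as src:
        with pysam.AlignmentFile(out_bam, "wb", template=src) as dst:
            for aln in src.fetch(until_eof=True):
                hp = tags.get(aln.query_name, 0)
                if hp:
                    aln.set_tag("HP", hp, "i")
                dst.write(aln)
    pysam.index(out_bam)


def split_by_haplotype(reads: Sequence[AlignedRead]
                       ) -> Tuple[List[AlignedRead], List[AlignedRead],
                                  List[AlignedRead], List[AlignedRead]]:
    """The four alignment subsets (original, hap1, hap2, unphased)."""
    hap1 = [r for r in reads if r.haplotype == 1]
    hap2 = [r for r in reads if r.haplotype == 2]
    unphased = [r for r in reads if r.haplotype == 0]
    return list(reads), hap1, hap2, unphased
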