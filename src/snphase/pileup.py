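"""Strand-aware pileup summaries and candidate-site search.

For every reference position the pileup records per-strand counts over
{A, C, G, T, I, D}, the maximum insertion/deletion fragment length (IMAX,
DMAX) and the depth.  Insertion events are counted once at their anchor
position (the aligned base immediately left of the insertion); every
reference position under a deletion contributes one D.  Depth counts all
reads whose alignment spans the position, including those with D there,
which keeps the alternative-allele frequency f_b <= 1 even when D is the
dominant allele.

A site b is a candidate when depth > d and
f_b = max alt-symbol count (pooled over strands) / depth > e,
both inequalities strict; defaults d=6, e=0.12.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np

from .reads import AlignedRead, load_reads

# pileup feature symbol order (differs from the read-symbol codes: the
# pileup alphabet interposes I before D)
PILEUP_SYMBOLS = "ACGTID"
I_IDX, D_IDX = 4, 5
_DEPTH_IDX = np.array([0, 1, 2, 3, 5])   # A,C,G,T,D span the position


@dataclass(frozen=True)
class PileupColumn:
    position: int
    ref_base: str
    counts: np.ndarray       # (2, 6): strand (fwd, rev) x symbol
    imax: np.ndarray         # (2,)
    dmax: np.ndarray         # (2,)
    depth: int


@dataclass(frozen=True)
class CandidateSite:
    contig: str
    position: int
    ref_base: str
    af: float
    depth: int


class Pileup:
    """Pileup over a contiguous interval, backed by dense arrays."""

    def __init__(self, contig: str, start: int, end: int,
                 reference: Optional[str] = None) -> None:
        if end <= start:
            raise ValueError("empty interval")
        self.contig = contig
        self.start = start
        self.end = end
        self.reference = reference
        n = end - start
        self.counts = np.zeros((n, 2, 6), dtype=np.int32)
        self.imax = np.zeros((n, 2), dtype=np.int32)
        self.dmax = np.zeros((n, 2), dtype=np.int32)

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def depth(self) -> np.ndarray:
        return self.counts[:, :, _DEPTH_IDX].sum(axis=(1, 2))

    def add_read(self, read: AlignedRead) -> None:
        s = max(self.start, read.start)
        e = min(self.end, read.end)
        if e <= s:
            return
        srow = 0 if read.strand == "+" else 1
        seg = read.syms[s - read.start:e - read.start].astype(np.int64)
        sym_idx = np.where(seg == 4, D_IDX, seg)   # read D code -> pileup D
        pos_idx = np.arange(s - self.start, e - self.start)
        ok = sym_idx >= 0
        np.add.at(self.counts, (pos_idx[ok], srow, sym_idx[ok]), 1)
        for anchor, ln in read.insertions.items():
            if self.start <= anchor < self.end:
                i = anchor - self.start
                self.counts[i, srow, I_IDX] += 1
                self.imax[i, srow] = max(self.imax[i, srow], ln)
        for ds, dl in read.deletions:
            lo, hi = max(ds, self.start), min(ds + dl, self.end)
            if hi > lo:
                i = np.arange(lo - self.start, hi - self.start)
                self.dmax[i, srow] = np.maximum(self.dmax[i, srow], dl)

    def ref_base(self, pos: int) -> str:
        if self.reference is None:
            return "N"
        return self.reference[pos]

    def column(self, pos: int) -> PileupColumn:
        if not self.start <= pos < self.end:
            raise IndexError(f"position {pos} outside [{self.start}, {self.end})")
        i = pos - self.start
        return PileupColumn(position=pos, ref_base=self.ref_base(pos),
                            counts=self.counts[i].copy(),
                            imax=self.imax[i].copy(), dmax=self.dmax[i].copy(),
                            depth=int(self.counts[i][:, _DEPTH_IDX].sum()))

    def columns(self) -> List[PileupColumn]:
        return [self.column(p) for p in range(self.start, self.end)]

    def feature_matrix(self) -> np.ndarray:
        """Per-position 16-vector: forward (C[A..T,I,D], IMAX, DMAX) then reverse."""
        n = len(self)
        out = np.zeros((n, 16), dtype=np.float64)
        for srow, off in ((0, 0), (1, 8)):
            out[:, off:off + 6] = self.counts[:, srow, :]
            out[:, off + 6] = self.imax[:, srow]
            out[:, off + 7] = self.dmax[:, srow]
        return out


def build_pileup(source: Union[str, Sequence[AlignedRead]], contig: str,
                 start: int, end: int, reference: Optional[str] = None,
                 min_mapq: int = 1) -> Pileup:
    """Build the pileup for ``contig:[start, end)`` from a BAM or reads."""
    if isinstance(source, str):
        reads: Sequence[AlignedRead] = load_reads(source, contig, start, end,
                                                  min_mapq=min_mapq)
    else:
        reads = source
    pile = Pileup(contig, start, end, reference=reference)
    for r in reads:
        pile.add_read(r)
    return pile


def find_candidates(pileup: Pileup, min_depth: int = 6,
                    min_af: float = 0.12) -> List[CandidateSite]:
    """Sites with depth > ``min_depth`` and f_b > ``min_af`` (both strict)."""
    if pileup.reference is None:
        raise ValueError("candidate search needs the reference sequence")
    pooled = pileup.counts.sum(axis=1)            # (n, 6)
    depth = pooled[:, _DEPTH_IDX].sum(axis=1)
    ref_codes = np.full(len(pileup), -1, dtype=np.int64)
    seg = pileup.reference[pileup.start:pileup.end]
    for j, base in enumerate("ACGT"):
        ref_codes[np.frombuffer(seg.upper().encode(), dtype=np.uint8)
                  == ord(base)] = j

    out: List[CandidateSite] = []
    candidate_mask = depth > min_depth
    for i in np.flatnonzero(candidate_mask):
        rc = ref_codes[i]
        alt_counts = [pooled[i, s] for s in range(6) if s != rc]
        af = max(alt_counts) / depth[i]
        if af > min_af:
            out.append(CandidateSite(contig=pileup.contig,
                                     position=pileup.start + int(i),
                                     ref_base=seg[i], af=float(af),
                                     depth=int(depth[i])))
    return out
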