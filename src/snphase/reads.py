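"""Aligned-read container and BAM ingestion.

A read is stored densely over its reference footprint: for every reference
position j in [start, end) the aligned symbol R[j] in {A, C, G, T, D} and the
base quality Q[j] (undefined, -1, under a deletion), together with the
mapping quality, strand, insertion events keyed by their anchor position
(the aligned base immediately left of the inserted sequence) and deletion
events.  This dense form makes pileup construction, feature imaging and
haplotagging simple array operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pysam

# symbol codes used throughout the package
A, C, G, T, D = 0, 1, 2, 3, 4
SYMBOLS = "ACGTD"
BASE_CODE = {"A": A, "C": C, "G": G, "T": T}
CODE_BASE = {v: k for k, v in BASE_CODE.items()}

# BAM auxiliary tags: truth haplotype written by the simulator, and the
# conventional haplotag assigned after phasing
TRUTH_HAP_TAG = "XH"
HAPLOTAG_TAG = "HP"


def encode_bases(seq: str) -> np.ndarray:
    """Map an ACGT string to int8 codes; other letters become -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in BASE_CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass
class AlignedRead:
    """One read's alignment expanded over its reference footprint."""

    name: str
    strand: str                      # "+" or "-"
    mapq: int
    start: int                       # reference, 0-based
    end: int                         # reference, half-open
    syms: np.ndarray                 # int8 codes, length end-start
    quals: np.ndarray                # int16 Phred, -1 under deletions
    insertions: Dict[int, int] = field(default_factory=dict)   # anchor -> length
    deletions: List[Tuple[int, int]] = field(default_factory=list)  # (start, length)
    haplotype: int = 0               # 0 = unphased / unknown, else 1 or 2
    truth_haplotype: int = 0         # simulator ground truth, 0 if unknown

    def __post_init__(self) -> None:
        if len(self.syms) != self.end - self.start:
            raise ValueError("symbol track length does not match [start, end)")

    def sym_at(self, pos: int) -> int:
        """Aligned symbol code at reference position, -1 outside the read."""
        if self.start <= pos < self.end:
            return int(self.syms[pos - self.start])
        return -1

    def qual_at(self, pos: int) -> int:
        if self.start <= pos < self.end:
            return int(self.quals[pos - self.start])
        return -1

    def overlaps(self, pos: int) -> bool:
        return self.start <= pos < self.end


def read_from_alignment(aln: pysam.AlignedSegment) -> AlignedRead:
    """Expand a pysam alignment into the dense per-position representation."""
    seq = aln.query_sequence
    if seq is None:
        raise ValueError(f"read {aln.query_name} has no sequence")
    qual = aln.query_qualities
    codes = encode_bases(seq)
    qarr = (np.asarray(qual, dtype=np.int16) if qual is not None
            else np.full(len(seq), 20, dtype=np.int16))

    start = aln.reference_start
    syms: List[np.ndarray] = []
    quals: List[np.ndarray] = []
    insertions: Dict[int, int] = {}
    deletions: List[Tuple[int, int]] = []
    qpos = 0
    rpos = start
    for op, length in aln.cigartuples or []:
        if op in (0, 7, 8):          # M, =, X
            syms.append(codes[qpos:qpos + length])
            quals.append(qarr[qpos:qpos + length])
            qpos += length
            rpos += length
        elif op == 1:                # I — anchored at the base to the left
            if rpos > start:
                anchor = rpos - 1
                insertions[anchor] = max(insertions.get(anchor, 0), length)
            qpos += length
        elif op == 2:                # D
            syms.append(np.full(length, D, dtype=np.int8))
            quals.append(np.full(length, -1, dtype=np.int16))
            deletions.append((rpos, length))
            rpos += length
        elif op == 3:                # N: treat like a deletion gap for footprint
            syms.append(np.full(length, D, dtype=np.int8))
            quals.append(np.full(length, -1, dtype=np.int16))
            rpos += length
        elif op == 4:                # S
            qpos += length
        # H (5) and P (6) consume nothing we track

    sym_track = (np.concatenate(syms) if syms
                 else np.zeros(0, dtype=np.int8))
    qual_track = (np.concatenate(quals) if quals
                  else np.zeros(0, dtype=np.int16))
    return AlignedRead(
        name=aln.query_name,
        strand="-" if aln.is_reverse else "+",
        mapq=aln.mapping_quality,
        start=start,
        end=rpos,
        syms=sym_track,
        quals=qual_track,
        insertions=insertions,
        deletions=deletions,
        haplotype=int(aln.get_tag(HAPLOTAG_TAG)) if aln.has_tag(HAPLOTAG_TAG) else 0,
        truth_haplotype=(int(aln.get_tag(TRUTH_HAP_TAG))
                         if aln.has_tag(TRUTH_HAP_TAG) else 0),
    )


def load_reads(
    bam_path: str,
    contig: str,
    start: Optional[int] = None,
    end: Optional[int] = None,
    min_mapq: int = 1,
) -> List[AlignedRead]:
    """Fetch primary alignments on ``contig`` as :class:`AlignedRead`.

    Secondary/supplementary alignments, unmapped records and reads below
    ``min_mapq`` are excluded (standard pileup hygiene).
    """
    out: List[AlignedRead] = []
    with pysam.AlignmentFile(bam_path, "rb") as bam:
        if contig not in bam.references:
            raise KeyError(f"contig {contig!r} not present in {bam_path}")
        for aln in bam.fetch(contig, start, end):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            out.append(read_from_alignment(aln))
    return out
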