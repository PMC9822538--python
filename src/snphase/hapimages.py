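"""Second-round feature images: combined 26-features over four alignment subsets.

At every reference position j and for a given read subset, the combined
feature T_j (length 26) concatenates
  counts          C_j^B, B in {A,C,G,T,D}                     (5)
  frequencies     F_j^B = C_j^B / sum_B C_j^B                 (5)
  base-qual sums  Q_j^B = sum_i Q_i[j] * [R_i[j]=B], B in ACGT (4)
  base-qual means U_j^B = Q_j^B / C_j^B                       (4)
  map-qual sums   M_j^B = sum_i M_i * [R_i[j]=B]              (4)
  map-qual means  V_j^B = M_j^B / C_j^B                       (4)
with mean terms defined as 0 where the count is 0, and all features 0 for
an empty subset.  Insertions are invisible here: the symbol alphabet is
{A, C, G, T, D}.

For a candidate b the short-range image stacks T_j over [b-w, b+w] and the
long-range image over the t nearest high-quality het sites on each side of
b plus b itself.  Each image is computed for the four alignment subsets
(original, haplotype 1, haplotype 2, unphased) and concatenated along the
channel axis: blocks 1-26 original, 27-52 hap1, 53-78 hap2, 79-104 unphased.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .reads import AlignedRead

N_COMBINED = 26
SUBSET_ORDER = ("original", "hap1", "hap2", "unphased")


class SubsetFeatures:
    """Per-position accumulators for one alignment subset over an interval."""

    def __init__(self, contig: str, start: int, end: int) -> None:
        self.contig = contig
        self.start = start
        self.end = end
        n = end - start
        self.counts = np.zeros((n, 5), dtype=np.float64)   # A,C,G,T,D
        self.qsum = np.zeros((n, 4), dtype=np.float64)
        self.msum = np.zeros((n, 4), dtype=np.float64)

    def add_read(self, read: AlignedRead) -> None:
        s = max(self.start, read.start)
        e = min(self.end, read.end)
        if e <= s:
            return
        seg = read.syms[s - read.start:e - read.start].astype(np.int64)
        pos = np.arange(s - self.start, e - self.start)
        ok = seg >= 0
        np.add.at(self.counts, (pos[ok], seg[ok]), 1.0)
        base = ok & (seg < 4)
        quals = read.quals[s - read.start:e - read.start].astype(np.float64)
        np.add.at(self.qsum, (pos[base], seg[base]), quals[base])
        np.add.at(self.msum, (pos[base], seg[base]), float(read.mapq))

    def rows(self, positions: np.ndarray) -> np.ndarray:
        """Combined 26-feature rows; out-of-interval positions are zero."""
        positions = np.asarray(positions, dtype=np.int64)
        out = np.zeros((len(positions), N_COMBINED), dtype=np.float64)
        inside = (positions >= self.start) & (positions < self.end)
        idx = positions[inside] - self.start
        c = self.counts[idx]
        q = self.qsum[idx]
        m = self.msum[idx]
        tot = c.sum(axis=1, keepdims=True)
        f = np.divide(c, tot, out=np.zeros_like(c), where=tot > 0)
        cb = c[:, :4]
        u = np.divide(q, cb, out=np.zeros_like(q), where=cb > 0)
        v = np.divide(m, cb, out=np.zeros_like(m), where=cb > 0)
        out[inside] = np.concatenate([c, f, q, u, m, v], axis=1)
        return out

    def vector(self, position: int) -> np.ndarray:
        return self.rows(np.array([position]))[0]


def build_subset_features(reads: Sequence[AlignedRead], contig: str,
                          start: int, end: int) -> SubsetFeatures:
    feats = SubsetFeatures(contig, start, end)
    for r in reads:
        feats.add_read(r)
    return feats


def combined_feature(reads: Sequence[AlignedRead], position: int,
                     contig: str = "") -> np.ndarray:
    """T_j for one subset at one position (26-vector; empty subset -> zeros)."""
    feats = build_subset_features(reads, contig, position, position + 1)
    return feats.vector(position)


@dataclass
class HaplotypeInput:
    """The two concatenated images fed to the haplotype model for one site."""

    contig: str
    site: int
    short_image: np.ndarray       # (2w+1, 104)
    long_image: np.ndarray        # (2t+1, 104)
    left_sites: Tuple[int, ...]   # chosen flanking het sites, genomic order
    right_sites: Tuple[int, ...]
    long_mask: np.ndarray         # (2t+1,) bool, False for zero-padded rows
    ref_base: str = "N"


def _stack_subsets(subsets: Sequence[SubsetFeatures],
                   positions: np.ndarray) -> np.ndarray:
    if len(subsets) != 4:
        raise ValueError("expected the four subsets "
                         f"{SUBSET_ORDER}, got {len(subsets)}")
    return np.concatenate([s.rows(positions) for s in subsets], axis=1)


def make_short_range_image(subsets: Sequence[SubsetFeatures], site: int,
                           w: int = 16) -> np.ndarray:
    """(2w+1) x 104 image over [site-w, site+w] in fixed subset order."""
    if w < 1:
        raise ValueError("flanking size w must be >= 1")
    positions = np.arange(site - w, site + w + 1)
    return _stack_subsets(subsets, positions)


def select_flanking_sites(het_sites: Sequence[int], site: int,
                          t: int = 5) -> Tuple[List[int], List[int]]:
    """The t nearest qualifying het sites strictly left/right of ``site``."""
    sites = np.asarray(sorted(het_sites), dtype=np.int64)
    lefts = sites[sites < site][-t:].tolist()
    rights = sites[sites > site][:t].tolist()
    return lefts, rights


def make_long_range_image(subsets: Sequence[SubsetFeatures], site: int,
                          het_sites: Sequence[int], t: int = 5,
                          contig: str = "", w: int = 16,
                          ref_base: str = "N") -> HaplotypeInput:
    """Build both images for ``site``; missing flank rows stay zero-masked."""
    lefts, rights = select_flanking_sites(het_sites, site, t)
    rows = np.zeros((2 * t + 1, 4 * N_COMBINED), dtype=np.float64)
    mask = np.zeros(2 * t + 1, dtype=bool)
    mask[t] = True
    positions = lefts + [site] + rights
    row_idx = (list(range(t - len(lefts), t)) + [t]
               + list(range(t + 1, t + 1 + len(rights))))
    rows[row_idx] = _stack_subsets(subsets, np.asarray(positions))
    mask[row_idx] = True
    short = make_short_range_image(subsets, site, w=w)
    return HaplotypeInput(contig=contig, site=site, short_image=short,
                          long_image=rows, left_sites=tuple(lefts),
                          right_sites=tuple(rights), long_mask=mask,
                          ref_base=ref_base)
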