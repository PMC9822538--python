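"""First-round pileup feature images.

The image of a candidate site b is a (2w+1) x 16 matrix: one row per
reference position in [b-w, b+w], eight forward-strand features
(C[A], C[C], C[G], C[T], C[I], C[D], IMAX, DMAX) followed by the same eight
computed from reverse-strand reads only.  Rows falling outside the contig
(or outside the built pileup) are zero so every image has a fixed shape.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .pileup import Pileup


@dataclass
class PileupImage:
    contig: str
    site: int
    w: int
    matrix: np.ndarray       # (2w+1, 16)
    ref_base: str = "N"

    @property
    def shape(self) -> Tuple[int, int]:
        return self.matrix.shape


def make_pileup_image(pileup: Pileup, site: int, w: int = 16,
                      normalize_depth: bool = False) -> PileupImage:
    """Slice the strand-split feature window centred on ``site``."""
    if w < 1:
        raise ValueError("flanking size w must be >= 1")
    if not pileup.start <= site < pileup.end:
        raise ValueError(f"site {site} outside the built pileup")
    mat = np.zeros((2 * w + 1, 16), dtype=np.float64)
    lo, hi = site - w, site + w + 1
    src_lo, src_hi = max(lo, pileup.start), min(hi, pileup.end)
    feats = pileup.feature_matrix()
    mat[src_lo - lo:src_hi - lo] = feats[src_lo - pileup.start:
                                         src_hi - pileup.start]
    if normalize_depth:
        depth = mat[:, [0, 1, 2, 3, 5]].sum(axis=1) + mat[:, [8, 9, 10, 11, 13]].sum(axis=1)
        nz = depth > 0
        mat[nz] = mat[nz] / depth[nz, None]
    return PileupImage(contig=pileup.contig, site=site, w=w, matrix=mat,
                       ref_base=pileup.ref_base(site))


def save_shard(path: str, images: Sequence[np.ndarray],
               keys: Sequence[Tuple[str, int]],
               meta: Optional[dict] = None) -> None:
    """Write feature images as a compressed shard keyed by (contig, position)."""
    arrays = {f"{c}:{p}": np.asarray(img) for (c, p), img in zip(keys, images)}
    arrays["__index__"] = np.frombuffer(
        json.dumps({"keys": [f"{c}:{p}" for c, p in keys],
                    "meta": meta or {}}).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_shard(path: str) -> Tuple[Dict[Tuple[str, int], np.ndarray], dict]:
    data = np.load(path)
    index = json.loads(bytes(data["__index__"]).decode())
    out: Dict[Tuple[str, int], np.ndarray] = {}
    for key in index["keys"]:
        contig, pos = key.rsplit(":", 1)
        out[(contig, int(pos))] = data[key]
    return out, index.get("meta", {})
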