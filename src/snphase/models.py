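"""The two genotyping networks, their label spaces and quality scores.

Round one (pileup model): two stacked bidirectional LSTM layers over the
(2w+1) x 16 pileup image; the middle time step of the tanh-activated
recurrent output feeds a dense layer and two softmax heads — 21 genotype
classes (unordered allele pairs over {A, C, G, T, I, D}) and 3 zygosity
classes.  Round two (haplotype model): the same recurrent block applied
separately to the (2w+1) x 104 short-range image and the (2t+1) x 104
long-range image, a dense layer combining both branch outputs, and heads of
10 (SNP-only genotype pairs) and 3 classes.

Both models are trained with the sum of label-smoothed cross-entropies of
the two heads and report a Phred-like quality, the smaller of the genotype
and zygosity scores, computed with the log-odds transform
q(P) = (10/ln 10) ln(P/(1-P)) clipped to [0, 60].  Because label smoothing s
bounds a converged softmax maximum at 1-s+s/K (0.905 for the 21-class head),
raw smoothed probabilities could never clear a Phred threshold of 14; the
heads are therefore temperature-calibrated after training (a single scalar
per model fitted against unsmoothed labels, Guo-style), which restores
meaningful high-confidence probabilities (see docs/methods.md).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .config import NetConfig, TrainConfig
from .nn import Adam, BiLSTM, Dense, Lookahead, smoothed_cross_entropy, softmax

logger = logging.getLogger(__name__)

# unordered allele pairs; symbol rank A < C < G < T < I < D
GENOTYPES_21 = ["AA", "AC", "AG", "AT", "CC", "CG", "CT", "GG", "GT", "TT",
                "AI", "AD", "CI", "CD", "GI", "GD", "TI", "TD", "II", "DD", "ID"]
GENOTYPES_10 = GENOTYPES_21[:10]
ZYGOSITIES = ["hom_ref", "hom_alt", "het"]
_RANK = {"A": 0, "C": 1, "G": 2, "T": 3, "I": 4, "D": 5}
_G21_INDEX = {g: i for i, g in enumerate(GENOTYPES_21)}
_G10_INDEX = {g: i for i, g in enumerate(GENOTYPES_10)}


def canonical_pair(a: str, b: str) -> str:
    """Unordered pair as its canonical class string (e.g. ('G','A') -> 'AG')."""
    x, y = sorted((a, b), key=_RANK.__getitem__)
    return x + y


def genotype_index(pair: str, n_classes: int = 21) -> int:
    idx = _G21_INDEX if n_classes == 21 else _G10_INDEX
    return idx[canonical_pair(pair[0], pair[1])]


def pair_of_index(i: int) -> str:
    return GENOTYPES_21[i]


def zygosity_of(pair: str, ref_base: str) -> str:
    a, b = pair[0], pair[1]
    if a == b:
        return "hom_ref" if a == ref_base else "hom_alt"
    return "het"


def log_odds(p: float) -> float:
    """Unclipped Phred-scaled log-odds (10/ln 10) ln(P/(1-P))."""
    eps = 1e-10
    p = min(max(float(p), eps), 1.0 - eps)
    return float((10.0 / np.log(10.0)) * np.log(p / (1.0 - p)))


def quality_score(p: float) -> float:
    """Phred-like log-odds score, q(0.5)=0, clipped to [0, 60]."""
    return float(np.clip(log_odds(p), 0.0, 60.0))


def smoothing_ceiling(n_classes: int, smoothing: float) -> float:
    """Max softmax probability a label-smoothed optimum can assign."""
    return 1.0 - smoothing + smoothing / n_classes


@dataclass
class CallRecord:
    """One site's prediction from either model."""

    contig: str
    position: int
    ref_base: str
    genotype: str                  # canonical pair, e.g. "AC"
    zygosity: str
    quality: float
    p_genotype: float              # P_g(L1)
    p_zygosity: float              # P_z(L2)
    genotype_probs: np.ndarray
    zygosity_probs: np.ndarray
    source: str = "pileup_model"

    @property
    def is_variant(self) -> bool:
        return self.zygosity != "hom_ref"

    @property
    def involves_indel(self) -> bool:
        return "I" in self.genotype or "D" in self.genotype


class TrainingError(ValueError):
    pass


# ---------------------------------------------------------------------------
# training-time augmentation
#
# The feature images are equivariant under any relabelling of the four bases
# (and, for the strand-split pileup image, under swapping the strands):
# permuting the base channels and mapping the genotype labels through the
# same permutation produces another equally likely training example.
# Randomising a permutation per batch multiplies the effective number of
# variant examples ~50-fold, which matters at desk-scale training-set sizes.

def _base_permutations() -> Tuple[List[Tuple[int, ...]], np.ndarray, np.ndarray]:
    from itertools import permutations
    perms = list(permutations(range(4)))
    bases = "ACGT"
    t21 = np.zeros((len(perms), 21), dtype=np.int64)
    t10 = np.zeros((len(perms), 10), dtype=np.int64)
    for k, pi in enumerate(perms):
        sym = {bases[i]: bases[pi[i]] for i in range(4)}
        sym.update({"I": "I", "D": "D"})
        for i, g in enumerate(GENOTYPES_21):
            t21[k, i] = _G21_INDEX[canonical_pair(sym[g[0]], sym[g[1]])]
        for i, g in enumerate(GENOTYPES_10):
            t10[k, i] = _G10_INDEX[canonical_pair(sym[g[0]], sym[g[1]])]
    return perms, t21, t10


_PERMS, _GMAP21, _GMAP10 = _base_permutations()


def _pileup_channel_source(pi: Tuple[int, ...], strand_swap: bool) -> np.ndarray:
    src = np.arange(16)
    for b in range(4):
        src[pi[b]] = b
        src[8 + pi[b]] = 8 + b
    if strand_swap:
        src = np.concatenate([src[8:], src[:8]])
    return src


def _combined_channel_source(pi: Tuple[int, ...], n_subsets: int = 4) -> np.ndarray:
    src = np.arange(n_subsets * 26)
    for s in range(n_subsets):
        base = s * 26
        for off, width in ((0, 5), (5, 5), (10, 4), (14, 4), (18, 4), (22, 4)):
            for b in range(4):
                src[base + off + pi[b]] = base + off + b
    return src


def pileup_augmenter(x: np.ndarray, yg: np.ndarray, yz: np.ndarray,
                     rng: np.random.Generator):
    k = int(rng.integers(len(_PERMS)))
    swap = bool(rng.integers(2))
    src = _pileup_channel_source(_PERMS[k], swap)
    return x[:, :, src], _GMAP21[k][yg], yz


def haplotype_augmenter(inputs, yg: np.ndarray, yz: np.ndarray,
                        rng: np.random.Generator):
    xs, xl = inputs
    k = int(rng.integers(len(_PERMS)))
    src = _combined_channel_source(_PERMS[k])
    return (xs[:, :, src], xl[:, :, src]), _GMAP10[k][yg], yz


# Deterministic transform subsets used to symmetrize inference: averaging
# head logits over a few base relabellings (plus, for the strand-split
# pileup image, strand swap) enforces the exact symmetry of the task at
# test time and reduces prediction variance.
_TTA_PERM_IDS = [0, 7, 16, 23]     # identity + 3 spread permutations


def _pileup_tta_transforms():
    out = []
    for k in _TTA_PERM_IDS:
        for swap in (False, True):
            out.append((_pileup_channel_source(_PERMS[k], swap), _GMAP21[k]))
    return out


def _combined_tta_transforms():
    return [(_combined_channel_source(_PERMS[k]), _GMAP10[k])
            for k in _TTA_PERM_IDS]


_PILEUP_TTA = _pileup_tta_transforms()
_COMBINED_TTA = _combined_tta_transforms()


ModelInput = Union[np.ndarray, Tuple[np.ndarray, np.ndarray]]


def _take(inputs: ModelInput, idx: np.ndarray) -> ModelInput:
    if isinstance(inputs, tuple):
        return tuple(x[idx] for x in inputs)  # type: ignore[return-value]
    return inputs[idx]


def _n_examples(inputs: ModelInput) -> int:
    return len(inputs[0]) if isinstance(inputs, tuple) else len(inputs)


class PileupNetwork:
    """First-round genotyper over the strand-split pileup image."""

    n_genotypes = 21
    n_zygosities = 3

    def __init__(self, config: Optional[NetConfig] = None, seq_len: int = 33,
                 in_channels: int = 16, seed: int = 0,
                 dtype: np.dtype = np.float32) -> None:
        self.config = config or NetConfig()
        self.seq_len = seq_len
        self.in_channels = in_channels
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        H = self.config.hidden_size
        self.l1 = BiLSTM(in_channels, H, rng, dtype=dtype)
        self.l2 = BiLSTM(2 * H, H, rng, dtype=dtype)
        self.fc = Dense(2 * H, self.config.fc_size, rng, dtype=dtype)
        self.head_g = Dense(self.config.fc_size, self.n_genotypes, rng,
                            scale=0.01, dtype=dtype)
        self.head_z = Dense(self.config.fc_size, self.n_zygosities, rng,
                            scale=0.01, dtype=dtype)
        self._layers = {"l1": self.l1, "l2": self.l2, "fc": self.fc,
                        "head_g": self.head_g, "head_z": self.head_z}
        self.temperature = 1.0     # post-hoc calibration, see fit_temperature
        self._a: Optional[np.ndarray] = None
        self._z: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 3 or x.shape[1] != self.seq_len or x.shape[2] != self.in_channels:
            raise ValueError(f"expected (B, {self.seq_len}, {self.in_channels}) "
                             f"input, got {x.shape}")
        x = np.log1p(x)        # compress counts/quality sums to O(1) scale
        a = np.tanh(self.l2.forward(self.l1.forward(x)))
        self._a = a
        mid = a[:, self.seq_len // 2]
        z = np.tanh(self.fc.forward(mid))
        self._z = z
        return self.head_g.forward(z), self.head_z.forward(z)

    def backward(self, dlg: np.ndarray, dlz: np.ndarray) -> None:
        assert self._a is not None and self._z is not None
        dz = self.head_g.backward(dlg) + self.head_z.backward(dlz)
        dmid = self.fc.backward(dz * (1.0 - self._z ** 2))
        da = np.zeros_like(self._a)
        da[:, self.seq_len // 2] = dmid
        self.l1.backward(self.l2.backward(da * (1.0 - self._a ** 2)))

    def param_items(self):
        out = []
        for name, layer in self._layers.items():
            out.extend(layer.param_items(name))
        return out

    def zero_grad(self) -> None:
        for layer in self._layers.values():
            layer.zero_grad()

    def predict_logits(self, x: np.ndarray, batch_size: int = 512
                       ) -> Tuple[np.ndarray, np.ndarray]:
        transforms = (_PILEUP_TTA if self.config.symmetrize_inference
                      else [(np.arange(16), np.arange(self.n_genotypes))])
        lgs, lzs = [], []
        for i in range(0, len(x), batch_size):
            xb = x[i:i + batch_size]
            lg_acc = lz_acc = 0.0
            for src, gmap in transforms:
                lg, lz = self.forward(xb[:, :, src])
                lg_acc = lg_acc + lg[:, gmap]
                lz_acc = lz_acc + lz
            lgs.append(lg_acc / len(transforms))
            lzs.append(lz_acc / len(transforms))
        if not lgs:
            return (np.zeros((0, self.n_genotypes)),
                    np.zeros((0, self.n_zygosities)))
        return np.concatenate(lgs), np.concatenate(lzs)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512
                      ) -> Tuple[np.ndarray, np.ndarray]:
        lg, lz = self.predict_logits(x, batch_size)
        t = self.temperature
        return softmax(lg / t), softmax(lz / t)

    # -- persistence ---------------------------------------------------
    def _meta(self) -> dict:
        return {"kind": "pileup", "seq_len": self.seq_len,
                "in_channels": self.in_channels, "seed": self.seed,
                "config": {"hidden_size": self.config.hidden_size,
                           "fc_size": self.config.fc_size,
                           "branch_fc_size": self.config.branch_fc_size,
                           "combine_size": self.config.combine_size,
                           "symmetrize_inference":
                               self.config.symmetrize_inference},
                "temperature": self.temperature,
                "format_version": 1}

    def save(self, path: str) -> None:
        arrays = {name: p for name, p, _ in self.param_items()}
        arrays["__meta__"] = np.frombuffer(
            json.dumps(self._meta()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    def load_weights(self, path: str) -> None:
        data = np.load(path)
        for name, p, _ in self.param_items():
            p[...] = data[name]


class HaplotypeNetwork:
    """Second-round genotyper combining short- and long-range images."""

    n_genotypes = 10
    n_zygosities = 3

    def __init__(self, config: Optional[NetConfig] = None,
                 short_len: int = 33, long_len: int = 11,
                 in_channels: int = 104, seed: int = 0,
                 branches: str = "both",
                 dtype: np.dtype = np.float32) -> None:
        if branches not in ("both", "short", "long"):
            raise ValueError("branches must be 'both', 'short' or 'long'")
        self.config = config or NetConfig()
        self.short_len = short_len
        self.long_len = long_len
        self.in_channels = in_channels
        self.seed = seed
        self.branches = branches
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        H = self.config.hidden_size
        bfc = self.config.branch_fc_size
        self._layers: Dict[str, object] = {}
        if branches in ("both", "short"):
            self.s1 = BiLSTM(in_channels, H, rng, dtype=dtype)
            self.s2 = BiLSTM(2 * H, H, rng, dtype=dtype)
            self.s_fc = Dense(2 * H, bfc, rng, dtype=dtype)
            self._layers.update({"s1": self.s1, "s2": self.s2, "s_fc": self.s_fc})
        if branches in ("both", "long"):
            self.h1 = BiLSTM(in_channels, H, rng, dtype=dtype)
            self.h2 = BiLSTM(2 * H, H, rng, dtype=dtype)
            self.h_fc = Dense(2 * H, bfc, rng, dtype=dtype)
            self._layers.update({"h1": self.h1, "h2": self.h2, "h_fc": self.h_fc})
        n_branch = 2 if branches == "both" else 1
        self.combine = Dense(n_branch * bfc, self.config.combine_size, rng,
                             dtype=dtype)
        self.head_g = Dense(self.config.combine_size, self.n_genotypes, rng,
                            scale=0.01, dtype=dtype)
        self.head_z = Dense(self.config.combine_size, self.n_zygosities, rng,
                            scale=0.01, dtype=dtype)
        self._layers.update({"combine": self.combine, "head_g": self.head_g,
                             "head_z": self.head_z})
        self.temperature = 1.0
        self._cache: dict = {}

    def _branch_forward(self, which: str, x: np.ndarray, seq_len: int
                        ) -> np.ndarray:
        l1, l2, fc = (getattr(self, f"{which}1"), getattr(self, f"{which}2"),
                      getattr(self, f"{which}_fc"))
        a = np.tanh(l2.forward(l1.forward(x)))
        mid = a[:, seq_len // 2]
        z = np.tanh(fc.forward(mid))
        self._cache[which] = (a, z)
        return z

    def _branch_backward(self, which: str, dz: np.ndarray, seq_len: int) -> None:
        l1, l2, fc = (getattr(self, f"{which}1"), getattr(self, f"{which}2"),
                      getattr(self, f"{which}_fc"))
        a, z = self._cache[which]
        dmid = fc.backward(dz * (1.0 - z ** 2))
        da = np.zeros_like(a)
        da[:, seq_len // 2] = dmid
        l1.backward(l2.backward(da * (1.0 - a ** 2)))

    def forward(self, inputs: Tuple[np.ndarray, np.ndarray]
                ) -> Tuple[np.ndarray, np.ndarray]:
        xs, xl = inputs
        xs = np.asarray(xs, dtype=self.dtype)
        xl = np.asarray(xl, dtype=self.dtype)
        if xs.shape[1:] != (self.short_len, self.in_channels):
            raise ValueError(f"short image must be (B, {self.short_len}, "
                             f"{self.in_channels}), got {xs.shape}")
        if xl.shape[1:] != (self.long_len, self.in_channels):
            raise ValueError(f"long image must be (B, {self.long_len}, "
                             f"{self.in_channels}), got {xl.shape}")
        xs = np.log1p(xs)      # same O(1) feature compression as round one
        xl = np.log1p(xl)
        outs = []
        if self.branches in ("both", "short"):
            outs.append(self._branch_forward("s", xs, self.short_len))
        if self.branches in ("both", "long"):
            outs.append(self._branch_forward("h", xl, self.long_len))
        joint = np.concatenate(outs, axis=1)
        u = np.tanh(self.combine.forward(joint))
        self._cache["u"] = u
        return self.head_g.forward(u), self.head_z.forward(u)

    def backward(self, dlg: np.ndarray, dlz: np.ndarray) -> None:
        u = self._cache["u"]
        du = self.head_g.backward(dlg) + self.head_z.backward(dlz)
        djoint = self.combine.backward(du * (1.0 - u ** 2))
        bfc = self.config.branch_fc_size
        col = 0
        if self.branches in ("both", "short"):
            self._branch_backward("s", djoint[:, col:col + bfc], self.short_len)
            col += bfc
        if self.branches in ("both", "long"):
            self._branch_backward("h", djoint[:, col:col + bfc], self.long_len)

    def param_items(self):
        out = []
        for name, layer in self._layers.items():
            out.extend(layer.param_items(name))  # type: ignore[attr-defined]
        return out

    def zero_grad(self) -> None:
        for layer in self._layers.values():
            layer.zero_grad()  # type: ignore[attr-defined]

    def predict_logits(self, inputs: Tuple[np.ndarray, np.ndarray],
                       batch_size: int = 512) -> Tuple[np.ndarray, np.ndarray]:
        xs, xl = inputs
        transforms = (_COMBINED_TTA if self.config.symmetrize_inference
                      else [(np.arange(xs.shape[2]),
                             np.arange(self.n_genotypes))])
        lgs, lzs = [], []
        for i in range(0, len(xs), batch_size):
            xsb, xlb = xs[i:i + batch_size], xl[i:i + batch_size]
            lg_acc = lz_acc = 0.0
            for src, gmap in transforms:
                lg, lz = self.forward((xsb[:, :, src], xlb[:, :, src]))
                lg_acc = lg_acc + lg[:, gmap]
                lz_acc = lz_acc + lz
            lgs.append(lg_acc / len(transforms))
            lzs.append(lz_acc / len(transforms))
        if not lgs:
            return (np.zeros((0, self.n_genotypes)),
                    np.zeros((0, self.n_zygosities)))
        return np.concatenate(lgs), np.concatenate(lzs)

    def predict_proba(self, inputs: Tuple[np.ndarray, np.ndarray],
                      batch_size: int = 512) -> Tuple[np.ndarray, np.ndarray]:
        lg, lz = self.predict_logits(inputs, batch_size)
        t = self.temperature
        return softmax(lg / t), softmax(lz / t)

    def _meta(self) -> dict:
        return {"kind": "haplotype", "short_len": self.short_len,
                "long_len": self.long_len, "in_channels": self.in_channels,
                "seed": self.seed, "branches": self.branches,
                "config": {"hidden_size": self.config.hidden_size,
                           "fc_size": self.config.fc_size,
                           "branch_fc_size": self.config.branch_fc_size,
                           "combine_size": self.config.combine_size,
                           "symmetrize_inference":
                               self.config.symmetrize_inference},
                "temperature": self.temperature,
                "format_version": 1}

    def save(self, path: str) -> None:
        arrays = {name: p for name, p, _ in self.param_items()}
        arrays["__meta__"] = np.frombuffer(
            json.dumps(self._meta()).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    def load_weights(self, path: str) -> None:
        data = np.load(path)
        for name, p, _ in self.param_items():
            p[...] = data[name]


def load_model(path: str):
    """Reconstruct a saved network (pileup or haplotype) from a checkpoint."""
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    cfg = NetConfig(**meta["config"])
    if meta["kind"] == "pileup":
        model: Union[PileupNetwork, HaplotypeNetwork] = PileupNetwork(
            cfg, seq_len=meta["seq_len"], in_channels=meta["in_channels"],
            seed=meta["seed"])
    else:
        model = HaplotypeNetwork(cfg, short_len=meta["short_len"],
                                 long_len=meta["long_len"],
                                 in_channels=meta["in_channels"],
                                 seed=meta["seed"],
                                 branches=meta.get("branches", "both"))
    for name, p, _ in model.param_items():
        p[...] = data[name]
    model.temperature = float(meta.get("temperature", 1.0))
    return model


def rebalance_indices(is_negative: np.ndarray, max_ratio: float,
                      rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Cap the hom_ref : variant imbalance by downsampling hom_ref examples.

    Keeps every variant example and a seeded without-replacement sample of
    at most ``max_ratio`` negatives per positive; ``max_ratio <= 0`` keeps
    everything.
    """
    is_negative = np.asarray(is_negative, dtype=bool)
    n_neg, n_pos = int(is_negative.sum()), int((~is_negative).sum())
    idx = np.arange(len(is_negative))
    if max_ratio <= 0 or n_pos == 0 or n_neg <= max_ratio * n_pos:
        return idx
    rng = rng or np.random.default_rng(0)
    keep_neg = rng.choice(idx[is_negative], size=int(max_ratio * n_pos),
                          replace=False)
    return np.sort(np.concatenate([idx[~is_negative], keep_neg]))


def train_model(model, inputs: ModelInput, labels_g: np.ndarray,
                labels_z: np.ndarray, tcfg: TrainConfig,
                sample_indices: Optional[np.ndarray] = None,
                augment=None) -> List[float]:
    """Optimise both heads; returns the per-epoch mean total loss.

    ``augment``, if given, is applied per batch: a callable
    (inputs, yg, yz, rng) -> (inputs, yg, yz) drawing a random
    label-preserving transform such as :func:`pileup_augmenter`.
    """
    n = _n_examples(inputs)
    if n == 0:
        raise TrainingError("empty training set")
    if np.unique(labels_g).size < 2:
        raise TrainingError("training set contains a single genotype class")
    rng = np.random.default_rng(tcfg.seed)
    opt: Union[Adam, Lookahead] = Adam(model.param_items(), lr=tcfg.learning_rate)
    if tcfg.lookahead:
        opt = Lookahead(opt, k=tcfg.lookahead_k, alpha=tcfg.lookahead_alpha)
    pool = np.arange(n) if sample_indices is None else np.asarray(sample_indices)
    history: List[float] = []
    for _ in range(tcfg.epochs):
        perm = rng.permutation(pool)
        losses = []
        for i in range(0, len(perm), tcfg.batch_size):
            idx = perm[i:i + tcfg.batch_size]
            xb, ygb, yzb = _take(inputs, idx), labels_g[idx], labels_z[idx]
            if augment is not None:
                xb, ygb, yzb = augment(xb, ygb, yzb, rng)
            model.zero_grad()
            lg, lz = model.forward(xb)
            loss_g, dlg = smoothed_cross_entropy(lg, ygb, tcfg.label_smoothing)
            loss_z, dlz = smoothed_cross_entropy(lz, yzb, tcfg.label_smoothing)
            model.backward(dlg, dlz)
            opt.step()
            losses.append(loss_g + loss_z)
        history.append(float(np.mean(losses)))
    return history


def fit_temperature(model, inputs: ModelInput, labels_g: np.ndarray,
                    labels_z: np.ndarray,
                    grid: Optional[np.ndarray] = None) -> float:
    """Post-hoc confidence calibration with a single shared temperature.

    Label smoothing regularises training but leaves the softmax maxima
    pinned near 1-s+s/K, which makes Phred-style quality thresholds
    unusable.  Following standard temperature scaling, this picks the
    scalar T minimising the (unsmoothed) negative log-likelihood of the
    given labels under logits/T, summed over both heads, and stores it on
    ``model.temperature``.  Deterministic; typically T < 1 (sharpening).
    """
    lg, lz = model.predict_logits(inputs)
    if grid is None:
        grid = np.geomspace(0.05, 3.0, 80)
    best_t, best_nll = 1.0, np.inf
    idx = np.arange(len(labels_g))
    for t in grid:
        pg = softmax(lg / t)
        pz = softmax(lz / t)
        nll = (-np.log(np.clip(pg[idx, labels_g], 1e-12, None)).mean()
               - np.log(np.clip(pz[idx, labels_z], 1e-12, None)).mean())
        if nll < best_nll:
            best_nll, best_t = nll, float(t)
    model.temperature = best_t
    return best_t


def call_records(model, inputs: ModelInput, contig: str,
                 positions: Sequence[int], ref_bases: Sequence[str],
                 source: Optional[str] = None) -> List[CallRecord]:
    """Run inference and assemble one :class:`CallRecord` per site.

    The genotype head is authoritative: zygosity is recomputed from the
    predicted allele pair and the reference base, and a disagreement with
    the zygosity head's argmax is logged but not propagated.
    """
    pg, pz = model.predict_proba(inputs)
    if source is None:
        source = ("pileup_model" if model.n_genotypes == 21
                  else "haplotype_model")
    out: List[CallRecord] = []
    for k, (pos, ref) in enumerate(zip(positions, ref_bases)):
        ig = int(np.argmax(pg[k]))
        iz = int(np.argmax(pz[k]))
        pair = pair_of_index(ig)
        zyg = zygosity_of(pair, ref)
        if zyg != ZYGOSITIES[iz]:
            logger.debug("head disagreement at %s:%d: genotype %s implies %s, "
                         "zygosity head says %s", contig, pos + 1, pair, zyg,
                         ZYGOSITIES[iz])
        qg = quality_score(float(pg[k, ig]))
        qz = quality_score(float(pz[k, iz]))
        out.append(CallRecord(contig=contig, position=int(pos), ref_base=ref,
                              genotype=pair, zygosity=zyg,
                              quality=min(qg, qz),
                              p_genotype=float(pg[k, ig]),
                              p_zygosity=float(pz[k, iz]),
                              genotype_probs=pg[k], zygosity_probs=pz[k],
                              source=source))
    return out
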