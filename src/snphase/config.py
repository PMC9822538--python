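"""Configuration containers for the two-round caller.

Defaults follow the method's reference operating point: candidate filters
d=6 / e=0.12, pileup flank w=16, long-range flank t=5 het sites per side,
het-selection quality 14 and merge threshold delta=14.  Two training
profiles are provided: ``full_profile`` carries the full-scale schedule
(large batches, hundreds of epochs, GPU-sized layers), ``desk_profile`` is
the CPU-scale schedule this package trains and tests with.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
import yaml


@dataclass
class CandidateConfig:
    """Candidate-site search thresholds (both strict inequalities)."""

    min_depth: int = 6        # retain site iff depth > min_depth
    min_af: float = 0.12      # retain site iff f_b > min_af
    min_mapq: int = 1         # reads with MAPQ below this are ignored in pileups


@dataclass
class ImageConfig:
    flank: int = 16           # w: pileup-image half window
    het_flank: int = 5        # t: het sites per side in the long-range image
    het_quality: float = 14.0  # quality floor for "high-quality" het sites
    normalize_depth: bool = False  # optional per-row depth normalisation (off: raw counts)


@dataclass
class NetConfig:
    hidden_size: int = 128    # BiLSTM hidden units per direction
    fc_size: int = 512        # width of the post-recurrent dense layer
    branch_fc_size: int = 256  # per-branch dense width (haplotype model)
    combine_size: int = 256   # width of the layer joining the two branches
    # average head logits over base-relabelling transforms at inference
    symmetrize_inference: bool = False


@dataclass
class TrainConfig:
    batch_size: int = 2000
    epochs: int = 200
    learning_rate: float = 1e-4
    label_smoothing: float = 0.1
    lookahead: bool = True
    lookahead_k: int = 5
    lookahead_alpha: float = 0.5
    # cap on the hom_ref : variant example imbalance fed to the optimiser;
    # 0 disables rebalancing
    max_negative_ratio: float = 0.0
    # per-batch base-relabelling (and strand-swap) augmentation
    augment: bool = False
    seed: int = 0


@dataclass
class MergeConfig:
    delta: float = 14.0       # round-merge quality threshold (strict >)
    second_round: str = "all"  # "all" or "low-qual-only"


@dataclass
class CallerConfig:
    candidates: CandidateConfig = field(default_factory=CandidateConfig)
    images: ImageConfig = field(default_factory=ImageConfig)
    pileup_net: NetConfig = field(default_factory=NetConfig)
    haplotype_net: NetConfig = field(default_factory=NetConfig)
    pileup_train: TrainConfig = field(default_factory=TrainConfig)
    haplotype_train: TrainConfig = field(default_factory=lambda: TrainConfig(
        batch_size=512, epochs=30, learning_rate=1e-5))
    merge: MergeConfig = field(default_factory=MergeConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CallerConfig":
        raw = yaml.safe_load(text) or {}
        return cls(
            candidates=CandidateConfig(**raw.get("candidates", {})),
            images=ImageConfig(**raw.get("images", {})),
            pileup_net=NetConfig(**raw.get("pileup_net", {})),
            haplotype_net=NetConfig(**raw.get("haplotype_net", {})),
            pileup_train=TrainConfig(**raw.get("pileup_train", {})),
            haplotype_train=TrainConfig(**raw.get("haplotype_train", {})),
            merge=MergeConfig(**raw.get("merge", {})),
        )


def full_profile() -> CallerConfig:
    """The full-scale (GPU-sized) operating point."""
    return CallerConfig()


def desk_profile(seed: int = 0) -> CallerConfig:
    """CPU-scale profile used by the bundled tests and examples.

    Smaller recurrent layers and a short, higher-learning-rate Adam schedule
    so both models train in minutes on one core; feature geometry and all
    calling thresholds are unchanged from the full profile.
    """
    cfg = CallerConfig()
    cfg.pileup_net = NetConfig(hidden_size=48, fc_size=128,
                               symmetrize_inference=True)
    cfg.haplotype_net = NetConfig(hidden_size=48, fc_size=128,
                                  branch_fc_size=96, combine_size=96,
                                  symmetrize_inference=True)
    cfg.pileup_train = TrainConfig(batch_size=128, epochs=60,
                                   learning_rate=3e-3, lookahead=False,
                                   max_negative_ratio=8.0, augment=True,
                                   seed=seed)
    cfg.haplotype_train = TrainConfig(batch_size=128, epochs=40,
                                      learning_rate=3e-3, lookahead=False,
                                      max_negative_ratio=8.0, augment=True,
                                      seed=seed)
    return cfg
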