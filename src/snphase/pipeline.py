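"""End-to-end orchestration of the two-round caller.

Stages: candidate search on the pileup -> first-round calls from the pileup
model -> selection and phasing of high-quality het SNPs -> haplotagging ->
four-subset short/long-range images -> second-round calls from the
haplotype model -> quality-threshold merge -> final SNP VCF.

Also provides the training orchestration (labels from a truth set, both
models trained in sequence, the second round on the haplotagged alignment
produced by the first) and a self-contained simulated train/evaluate
experiment used by the examples, the test-suite and the acceptance script.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import CallerConfig, desk_profile
from .hapimages import SubsetFeatures, build_subset_features
from .merge import FinalCall, classify_against_truth, merge_calls, write_final_vcf
from .models import (CallRecord, HaplotypeNetwork, PileupNetwork, ZYGOSITIES,
                     call_records, canonical_pair, fit_temperature,
                     genotype_index, haplotype_augmenter, pileup_augmenter,
                     rebalance_indices, train_model, zygosity_of)
from .phase import (HetSite, PhasedSiteSet, haplotag_reads, phase_sites,
                    select_het_sites, split_by_haplotype)
from .pileup import CandidateSite, Pileup, build_pileup, find_candidates
from .reads import AlignedRead
from .sim import generate_diploid, simulate_reads
from .vcfio import TruthVariant

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# labels

def truth_pair_map(variants: Sequence[TruthVariant]) -> Dict[int, str]:
    """Reference position -> canonical truth allele pair (I/D symbols for
    insertion anchors and deleted positions)."""
    pairs: Dict[int, str] = {}
    for v in variants:
        het = v.zygosity == "het"
        if v.vclass == "SNP":
            pairs[v.pos] = (canonical_pair(v.ref, v.alt) if het
                            else canonical_pair(v.alt, v.alt))
        elif v.vclass == "INS":
            pairs[v.pos] = (canonical_pair(v.ref[0], "I") if het
                            else canonical_pair("I", "I"))
        else:  # DEL: v.ref spells the anchor plus the deleted bases
            for k, base in enumerate(v.ref[1:]):
                pairs[v.pos + 1 + k] = (canonical_pair(base, "D") if het
                                        else canonical_pair("D", "D"))
    return pairs


def candidate_labels(candidates: Sequence[CandidateSite],
                     pair_map: Dict[int, str]
                     ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(genotype-21 labels, zygosity labels, indel mask) per candidate."""
    yg = np.zeros(len(candidates), dtype=np.int64)
    yz = np.zeros(len(candidates), dtype=np.int64)
    indel = np.zeros(len(candidates), dtype=bool)
    for i, c in enumerate(candidates):
        pair = pair_map.get(c.position, canonical_pair(c.ref_base, c.ref_base))
        yg[i] = genotype_index(pair, 21)
        yz[i] = ZYGOSITIES.index(zygosity_of(pair, c.ref_base))
        indel[i] = "I" in pair or "D" in pair
    return yg, yz, indel


# ---------------------------------------------------------------------------
# feature assembly

def build_pileup_inputs(pileup: Pileup, candidates: Sequence[CandidateSite],
                        w: int = 16, normalize_depth: bool = False
                        ) -> np.ndarray:
    feats = pileup.feature_matrix()
    if normalize_depth:
        depth = feats[:, [0, 1, 2, 3, 5, 8, 9, 10, 11, 13]].sum(axis=1)
        nz = depth > 0
        feats = feats.copy()
        feats[nz] /= depth[nz, None]
    n = len(candidates)
    X = np.zeros((n, 2 * w + 1, 16), dtype=np.float32)
    for i, c in enumerate(candidates):
        lo, hi = c.position - w, c.position + w + 1
        src_lo, src_hi = max(lo, pileup.start), min(hi, pileup.end)
        X[i, src_lo - lo:src_hi - lo] = feats[src_lo - pileup.start:
                                              src_hi - pileup.start]
    return X


def build_haplotype_inputs(subsets: Sequence[SubsetFeatures],
                           candidates: Sequence[CandidateSite],
                           het_positions: Sequence[int],
                           w: int = 16, t: int = 5
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """Stacked (short, long) images for every candidate site."""
    n = len(candidates)
    Xs = np.zeros((n, 2 * w + 1, 104), dtype=np.float32)
    Xl = np.zeros((n, 2 * t + 1, 104), dtype=np.float32)
    het = np.asarray(sorted(het_positions), dtype=np.int64)
    for i, c in enumerate(candidates):
        b = c.position
        window = np.arange(b - w, b + w + 1)
        Xs[i] = np.concatenate([s.rows(window) for s in subsets], axis=1)
        lefts = het[het < b][-t:]
        rights = het[het > b][:t]
        rows = np.concatenate([lefts, [b], rights])
        row_idx = np.concatenate([np.arange(t - len(lefts), t), [t],
                                  np.arange(t + 1, t + 1 + len(rights))])
        block = np.concatenate([s.rows(rows) for s in subsets], axis=1)
        Xl[i, row_idx.astype(int)] = block
    return Xs, Xl


def phase_and_split(reads: Sequence[AlignedRead],
                    pileup_calls: Sequence[CallRecord],
                    cfg: CallerConfig
                    ) -> Tuple[List[HetSite], PhasedSiteSet,
                               Tuple[List[AlignedRead], ...]]:
    het = select_het_sites(pileup_calls, cfg.images.het_quality)
    phased = phase_sites(reads, het, cfg.images.het_quality)
    haplotag_reads(reads, phased)
    return het, phased, split_by_haplotype(reads)


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainedModels:
    pileup: PileupNetwork
    haplotype: HaplotypeNetwork
    config: CallerConfig


def train_models(reads: Sequence[AlignedRead], reference: str, contig: str,
                 truth_variants: Sequence[TruthVariant],
                 cfg: Optional[CallerConfig] = None,
                 branches: str = "both") -> Tuple[TrainedModels, Dict]:
    """Train both rounds on one labelled contig.

    The haplotype model is trained on the haplotagged alignment produced by
    the freshly trained pileup model, mirroring the deployment data flow.
    """
    cfg = cfg or desk_profile()
    w, t = cfg.images.flank, cfg.images.het_flank
    pile = build_pileup(reads, contig, 0, len(reference), reference=reference,
                        min_mapq=cfg.candidates.min_mapq)
    candidates = find_candidates(pile, cfg.candidates.min_depth,
                                 cfg.candidates.min_af)
    pair_map = truth_pair_map(truth_variants)
    yg, yz, indel = candidate_labels(candidates, pair_map)
    X = build_pileup_inputs(pile, candidates, w,
                            cfg.images.normalize_depth)

    pmodel = PileupNetwork(cfg.pileup_net, seq_len=2 * w + 1,
                           seed=cfg.pileup_train.seed)
    idx = rebalance_indices(yz == 0, cfg.pileup_train.max_negative_ratio,
                            np.random.default_rng(cfg.pileup_train.seed + 1))
    p_history = train_model(
        pmodel, X, yg, yz, cfg.pileup_train, sample_indices=idx,
        augment=pileup_augmenter if cfg.pileup_train.augment else None)
    p_temp = fit_temperature(pmodel, X, yg, yz)

    positions = [c.position for c in candidates]
    refs = [c.ref_base for c in candidates]
    p_records = call_records(pmodel, X, contig, positions, refs)
    het, phased, subsets_reads = phase_and_split(list(reads), p_records, cfg)
    subsets = [build_subset_features(rs, contig, 0, len(reference))
               for rs in subsets_reads]
    het_positions = [h.position for h in het]
    Xs, Xl = build_haplotype_inputs(subsets, candidates, het_positions, w, t)

    keep = ~indel                      # the 10-class space has no I/D
    yg10 = np.array([genotype_index(
        pair_map.get(c.position, canonical_pair(c.ref_base, c.ref_base)), 10)
        for c, k in zip(candidates, keep) if k], dtype=np.int64)
    hmodel = HaplotypeNetwork(cfg.haplotype_net, short_len=2 * w + 1,
                              long_len=2 * t + 1,
                              seed=cfg.haplotype_train.seed, branches=branches)
    idx2 = rebalance_indices(yz[keep] == 0,
                             cfg.haplotype_train.max_negative_ratio,
                             np.random.default_rng(cfg.haplotype_train.seed + 1))
    h_history = train_model(
        hmodel, (Xs[keep], Xl[keep]), yg10, yz[keep], cfg.haplotype_train,
        sample_indices=idx2,
        augment=haplotype_augmenter if cfg.haplotype_train.augment else None)
    h_temp = fit_temperature(hmodel, (Xs[keep], Xl[keep]), yg10, yz[keep])

    info = {"n_candidates": len(candidates),
            "n_variant_labels": int((yz != 0).sum()),
            "n_het_sites": len(het), "n_phase_blocks": len(phased.blocks()),
            "pileup_temperature": p_temp, "haplotype_temperature": h_temp,
            "pileup_loss": p_history, "haplotype_loss": h_history}
    return TrainedModels(pileup=pmodel, haplotype=hmodel, config=cfg), info


# ---------------------------------------------------------------------------
# inference

@dataclass
class PipelineResult:
    contig: str
    candidates: List[CandidateSite]
    pileup_records: Dict[int, CallRecord]
    het_sites: List[HetSite]
    phased: PhasedSiteSet
    haplotags: Dict[str, int]
    haplotype_records: Dict[int, CallRecord]
    final_calls: List[FinalCall]

    def counts(self) -> Dict[str, int]:
        return {"candidates": len(self.candidates),
                "het_sites": len(self.het_sites),
                "phase_blocks": len(self.phased.blocks()),
                "second_round_sites": len(self.haplotype_records),
                "final_calls": len(self.final_calls)}


def call_pipeline(reads: Sequence[AlignedRead], reference: str, contig: str,
                  models: TrainedModels) -> PipelineResult:
    """Run the full two-round pipeline on one contig's alignment."""
    cfg = models.config
    w, t = cfg.images.flank, cfg.images.het_flank
    reads = list(reads)
    pile = build_pileup(reads, contig, 0, len(reference), reference=reference,
                        min_mapq=cfg.candidates.min_mapq)
    candidates = find_candidates(pile, cfg.candidates.min_depth,
                                 cfg.candidates.min_af)
    positions = [c.position for c in candidates]
    refs = [c.ref_base for c in candidates]
    X = build_pileup_inputs(pile, candidates, w,
                            cfg.images.normalize_depth)
    p_records = call_records(models.pileup, X, contig, positions, refs)
    p_by_pos = {r.position: r for r in p_records}

    het, phased, subsets_reads = phase_and_split(reads, p_records, cfg)
    haplotags = {r.name: r.haplotype for r in reads}
    subsets = [build_subset_features(rs, contig, 0, len(reference))
               for rs in subsets_reads]

    if cfg.merge.second_round == "low-qual-only":
        second = [c for c in candidates
                  if p_by_pos[c.position].quality < cfg.merge.delta]
    else:
        second = list(candidates)
    het_positions = [h.position for h in het]
    Xs, Xl = build_haplotype_inputs(subsets, second, het_positions, w, t)
    h_records = call_records(
        models.haplotype, (Xs, Xl), contig,
        [c.position for c in second], [c.ref_base for c in second])
    h_by_pos = {r.position: r for r in h_records}

    finals: List[FinalCall] = []
    for c in candidates:
        fc = merge_calls(h_by_pos.get(c.position), p_by_pos.get(c.position),
                         cfg.merge.delta)
        if fc is not None:
            finals.append(fc)
    finals.sort(key=lambda f: f.position)

    result = PipelineResult(contig=contig, candidates=candidates,
                            pileup_records=p_by_pos, het_sites=het,
                            phased=phased, haplotags=haplotags,
                            haplotype_records=h_by_pos, final_calls=finals)
    logger.info("pipeline counts: %s", result.counts())
    return result


def single_model_calls(records: Dict[int, CallRecord], delta: float,
                       model: str) -> List[FinalCall]:
    """Final-style SNP calls from one round alone (for model comparison)."""
    out = []
    for pos in sorted(records):
        rec = records[pos]
        fc = (merge_calls(rec, None, delta) if model == "haplotype"
              else merge_calls(None, rec, delta))
        if fc is not None:
            out.append(fc)
    return out


def haplotag_accuracy(reads: Sequence[AlignedRead],
                      phased: PhasedSiteSet) -> float:
    """Fraction of tagged reads matching their true haplotype, allowing the
    arbitrary per-block hap1/hap2 labelling to be flipped per block."""
    site_block = {s.position: s.block for s in phased.sites}
    positions = sorted(site_block)
    per_block: Dict[int, List[bool]] = {}
    for r in reads:
        if r.haplotype == 0 or r.truth_haplotype == 0:
            continue
        lo = int(np.searchsorted(positions, r.start))
        if lo >= len(positions) or positions[lo] >= r.end:
            continue
        block = site_block[positions[lo]]
        per_block.setdefault(block, []).append(r.haplotype == r.truth_haplotype)
    total = correct = 0
    for flags in per_block.values():
        n_same = sum(flags)
        correct += max(n_same, len(flags) - n_same)
        total += len(flags)
    return correct / total if total else 0.0


# ---------------------------------------------------------------------------
# simulated train/evaluate experiment

def run_experiment(seed: int = 1,
                   cfg: Optional[CallerConfig] = None,
                   train_length: int = 200_000,
                   test_length: int = 50_000,
                   coverage: float = 16.0,
                   error_model: Tuple[float, float, float] = (0.04, 0.01, 0.01),
                   snp_rate: float = 0.001,
                   het_fraction: float = 2.0 / 3.0,
                   indel_rate: float = 0.0002,
                   branches: str = "both",
                   out_vcf: Optional[str] = None) -> Dict:
    """Simulate, train both models, and evaluate on a held-out contig.

    Returns per-model and merged precision/recall/F1 against the planted
    SNPs, haplotagging accuracy against the simulator's truth tags, and the
    stage counts.  Fully deterministic in ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s = [int(x % (2 ** 31)) for x in ss.generate_state(6)]
    cfg = cfg or desk_profile()
    cfg.pileup_train.seed = s[2]
    cfg.haplotype_train.seed = s[3]

    genome_tr = generate_diploid(train_length, snp_rate=snp_rate,
                                 het_fraction=het_fraction,
                                 indel_rate=indel_rate, seed=s[0],
                                 contig="train1")
    reads_tr = simulate_reads(genome_tr, coverage, error_model,
                              seed=s[1]).aligned_reads()
    models, train_info = train_models(reads_tr, genome_tr.reference, "train1",
                                      genome_tr.truth_variants, cfg,
                                      branches=branches)

    genome_te = generate_diploid(test_length, snp_rate=snp_rate,
                                 het_fraction=het_fraction,
                                 indel_rate=indel_rate, seed=s[4],
                                 contig="test1")
    reads_te = simulate_reads(genome_te, coverage, error_model,
                              seed=s[5]).aligned_reads()
    result = call_pipeline(reads_te, genome_te.reference, "test1", models)

    truth = genome_te.truth_variants
    delta = cfg.merge.delta
    ev_pile = classify_against_truth(
        single_model_calls(result.pileup_records, delta, "pileup"), truth)
    ev_hap = classify_against_truth(
        single_model_calls(result.haplotype_records, delta, "haplotype"), truth)
    ev_final = classify_against_truth(result.final_calls, truth)

    if out_vcf is not None:
        write_final_vcf(out_vcf, "test1", test_length, result.final_calls)

    return {
        "pileup_model": ev_pile.as_dict(),
        "haplotype_model": ev_hap.as_dict(),
        "merged": ev_final.as_dict(),
        "haplotag_accuracy": haplotag_accuracy(reads_te, result.phased),
        "counts": result.counts(),
        "train_info": train_info,
        "n_truth_snps": len(genome_te.truth_snps()),
        "models": models,
        "result": result,
    }
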