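"""Build a strand-aware pileup, search candidate SNP sites, image one site.

A site is a candidate when its depth exceeds 6 and its alternative-allele
frequency f_b = (max alt-symbol count) / depth exceeds 0.12 — the first
round's search rule.
"""

import snphase as sp

genome = sp.generate_diploid(50_000, seed=7)
reads = sp.simulate_reads(genome, coverage=16.0,
                          error_model=(0.04, 0.01, 0.01),
                          seed=8).aligned_reads()
pile = sp.build_pileup(reads, genome.contig, 0, len(genome),
                       reference=genome.reference)
cands = sp.find_candidates(pile, min_depth=6, min_af=0.12)

truth = {v.pos for v in genome.truth_snps()}
hits = sum(1 for c in cands if c.position in truth)
print(f"mean depth {pile.depth.mean():.1f}x, {len(cands)} candidate sites")
print(f"{hits}/{len(truth)} planted SNPs are candidates; the rest of the "
      f"candidates are sequencing-error pileups the genotyper must reject")

site = next(c for c in cands if c.position in truth)
img = sp.make_pileup_image(pile, site.position, w=16)
print(f"example candidate {site.position + 1} (ref {site.ref_base}, "
      f"f_b={site.af:.2f}, depth {site.depth}) -> image {img.shape}: "
      f"33 window rows x 16 strand-split count channels")
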