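"""Het-site selection, MEC phasing and haplotagging."""

import itertools

import numpy as np
import pytest

import snphase as sp
from snphase.phase import HetSite, _read_alleles, mec_cost

from conftest import make_read


def call(pos, genotype, zygosity, quality, ref="A"):
    return sp.CallRecord(contig="c", position=pos, ref_base=ref,
                         genotype=genotype, zygosity=zygosity,
                         quality=quality, p_genotype=0.9, p_zygosity=0.9,
                         genotype_probs=np.zeros(21),
                         zygosity_probs=np.zeros(3))


class TestSelectHetSites:
    def test_quality_threshold_is_inclusive(self):
        assert len(sp.select_het_sites([call(1, "AC", "het", 20.0)])) == 1
        assert len(sp.select_het_sites([call(1, "AC", "het", 14.0)])) == 1
        assert len(sp.select_het_sites([call(1, "AC", "het", 13.9)])) == 0

    def test_mixed_list_enumeration(self):
        calls = [call(1, "AC", "het", 20), call(2, "AG", "het", 15),
                 call(3, "CT", "het", 14), call(4, "GT", "het", 13),
                 call(5, "CC", "hom_alt", 50), call(6, "AA", "hom_ref", 50)]
        sites = sp.select_het_sites(calls)
        assert [s.position for s in sites] == [1, 2, 3]

    def test_indel_pairs_are_not_phaseable(self):
        assert sp.select_het_sites([call(1, "AI", "het", 30),
                                    call(2, "AD", "het", 30)]) == []

    def test_alleles_carried_from_genotype(self):
        (site,) = sp.select_het_sites([call(9, "GT", "het", 30)])
        assert (site.allele_a, site.allele_b) == ("G", "T")


def brute_force_mec(read_alleles, n_sites):
    best = None
    for bits in itertools.product((0, 1), repeat=n_sites):
        cost = mec_cost(read_alleles, list(bits))
        best = cost if best is None else min(best, cost)
    return best


def random_instance(rng, n_sites, n_reads, flip_rate=0.1):
    """Reads drawn from two complementary haplotypes with noisy alleles."""
    positions = np.sort(rng.choice(1000, size=n_sites, replace=False))
    sites = [HetSite(int(p), "A", "C") for p in positions]
    truth = rng.integers(0, 2, size=n_sites)
    reads = []
    for i in range(n_reads):
        hap = rng.integers(0, 2)
        lo = rng.integers(0, n_sites)
        hi = rng.integers(lo + 1, n_sites + 1)
        bases = []
        for s in range(lo, hi):
            a = truth[s] if hap == 0 else 1 - truth[s]
            if rng.random() < flip_rate:
                a = 1 - a
            bases.append("AC"[a])
        start = int(positions[lo])
        span = int(positions[hi - 1]) - start + 1
        track = ["A"] * span          # fill; only site positions matter
        for s in range(lo, hi):
            track[int(positions[s]) - start] = bases[s - lo]
        reads.append(make_read(start, "".join(track), name=f"r{i}"))
    return sites, reads


class TestPhaseSites:
    def test_conflict_free_instance_single_block(self):
        sites = [HetSite(10, "A", "C"), HetSite(20, "G", "T")]
        reads = [make_read(5, "A" * 5 + "A" + "A" * 9 + "G" + "A" * 5,
                           name="r1"),
                 make_read(5, "A" * 5 + "A" + "A" * 9 + "G" + "A" * 5,
                           name="r2"),
                 make_read(5, "A" * 5 + "C" + "A" * 9 + "T" + "A" * 5,
                           name="r3"),
                 make_read(5, "A" * 5 + "C" + "A" * 9 + "T" + "A" * 5,
                           name="r4")]
        phased = sp.phase_sites(reads, sites)
        assert len(phased.blocks()) == 1
        assert phased.mec_cost == 0
        # A travels with G, C with T; first site's first allele -> hap1
        assert phased.sites[0].allele_hap1 == "A"
        assert phased.sites[1].allele_hap1 == "G"

    def test_greedy_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            n_sites = int(rng.integers(2, 7))
            n_reads = int(rng.integers(2, 11))
            sites, reads = random_instance(rng, n_sites, n_reads)
            phased = sp.phase_sites(reads, sites)
            alleles = _read_alleles(reads, sites)
            assert phased.mec_cost == brute_force_mec(alleles, n_sites)

    def test_disconnected_clusters_become_separate_blocks(self):
        sites = [HetSite(10, "A", "C"), HetSite(500, "G", "T")]
        reads = [make_read(8, "AAAA", name="a"),
                 make_read(498, "AAGA", name="b")]
        phased = sp.phase_sites(reads, sites)
        assert len(phased.blocks()) == 2

    def test_zero_het_sites_degrade_gracefully(self):
        phased = sp.phase_sites([make_read(0, "AAAA")], [])
        assert len(phased) == 0
        tags = sp.haplotag_reads([make_read(0, "AAAA")], phased)
        assert list(tags.values()) == [0]

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(13)
        sites, reads = random_instance(rng, 5, 8)
        alleles = _read_alleles(reads, sites)
        orientation = [0, 1, 0, 0, 1]
        flipped = [1 - o for o in orientation]
        assert mec_cost(alleles, orientation) == mec_cost(alleles, flipped)

    def test_mec_upper_bound(self):
        rng = np.random.default_rng(17)
        sites, reads = random_instance(rng, 6, 10, flip_rate=0.3)
        phased = sp.phase_sites(reads, sites)
        alleles = _read_alleles(reads, sites)
        worst = sum(len(a) for a in alleles)
        assert 0 <= phased.mec_cost <= worst


class TestHaplotag:
    def _phased(self):
        return sp.PhasedSiteSet(sites=[
            sp.PhasedSite(10, "A", "C", 10),
            sp.PhasedSite(20, "G", "T", 10),
            sp.PhasedSite(30, "C", "A", 10)])

    def test_full_match_goes_to_hap1(self):
        r = make_read(5, "AAAAA" + "A" + "AAAAAAAAA" + "G" + "AAAAAAAAA"
                      + "C" + "AAAA")
        assert sp.haplotag_reads([r], self._phased())[r.name] == 1

    def test_no_overlap_is_unphased(self):
        r = make_read(100, "AAAA")
        assert sp.haplotag_reads([r], self._phased())[r.name] == 0

    def test_tie_votes_are_unphased(self):
        r = make_read(5, "AAAAA" + "A" + "AAAAAAAAA" + "T" + "AAAA")
        assert sp.haplotag_reads([r], self._phased())[r.name] == 0

    def test_partition_is_total_and_disjoint(self, reads_50k):
        phased = self._phased()
        tags = sp.haplotag_reads(list(reads_50k), phased)
        assert set(tags) == {r.name for r in reads_50k}
        groups = sp.split_by_haplotype(reads_50k)
        assert len(groups[1]) + len(groups[2]) + len(groups[3]) \
            == len(groups[0]) == len(reads_50k)


def test_phased_vcf_and_haplotagged_bam_exports(tmp_path, genome_50k,
                                                readset_50k):
    import pysam
    import snphase as sp_
    paths = sp_.write_truth(genome_50k, readset_50k, str(tmp_path / "t"))
    reads = sp_.load_reads(paths["bam"], genome_50k.contig)
    het = [HetSite(v.pos, *sorted((v.ref, v.alt)))
           for v in genome_50k.truth_snps() if v.zygosity == "het"][:20]
    phased = sp.phase_sites(reads, het)
    vcf_path = str(tmp_path / "phased.vcf")
    sp.write_phased_vcf(vcf_path, genome_50k.contig, len(genome_50k), phased)
    with pysam.VariantFile(vcf_path) as vf:
        recs = list(vf)
    assert len(recs) == len(phased)
    for rec in recs:
        gt = rec.samples[0]["GT"]
        assert sorted(gt) == [0, 1]
        assert rec.samples[0].phased
        assert rec.samples[0]["PS"] >= 1

    tags = sp.haplotag_reads(reads, phased)
    out_bam = str(tmp_path / "tagged.bam")
    sp.write_haplotagged_bam(paths["bam"], out_bam, tags)
    with pysam.AlignmentFile(out_bam) as bam:
        for aln in bam.fetch():
            want = tags[aln.query_name]
            if want:
                assert aln.get_tag("HP") == want
            else:
                assert not aln.has_tag("HP")


def test_haplotagging_recovers_truth_haplotypes(genome_50k, reads_50k):
    """With the planted het SNPs as the phased set, >=95% of assigned reads
    at 16x / 4% error match their true haplotype of origin."""
    sites = []
    for v in genome_50k.truth_snps():
        if v.zygosity != "het":
            continue
        h1 = v.alt if v.het_hap == 1 else v.ref
        h2 = v.alt if v.het_hap == 2 else v.ref
        sites.append(sp.PhasedSite(v.pos, h1, h2, 0))
    reads = [make_read(r.start,
                       "".join("ACGTD"[s] for s in r.syms),
                       name=r.name, truth_hap=r.truth_haplotype)
             for r in reads_50k]
    phased = sp.PhasedSiteSet(sites=sites)
    tags = sp.haplotag_reads(reads, phased)
    assigned = [r for r in reads if r.haplotype != 0]
    assert len(assigned) > 0.5 * len(reads)
    agree = sum(1 for r in assigned if r.haplotype == r.truth_haplotype)
    assert agree / len(assigned) >= 0.95
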