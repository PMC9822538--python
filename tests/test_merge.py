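"""Two-round merge rule, truth-set classification and final VCF output."""

import itertools

import numpy as np
import pysam
import pytest

import snphase as sp
from snphase.merge import _as_final
from snphase.models import GENOTYPES_10
from snphase.vcfio import TruthVariant


def rec(quality, genotype="AC", ref="A", source="pileup_model", pos=100):
    return sp.CallRecord(contig="c", position=pos, ref_base=ref,
                         genotype=genotype,
                         zygosity=sp.zygosity_of(genotype, ref),
                         quality=quality, p_genotype=0.9, p_zygosity=0.9,
                         genotype_probs=np.zeros(21),
                         zygosity_probs=np.zeros(3), source=source)


def hap(q, **kw):
    return rec(q, source="haplotype_model", **kw)


class TestMergeRule:
    def test_confident_haplotype_call_wins(self):
        out = sp.merge_calls(hap(20.0), rec(50.0), delta=14.0)
        assert out is not None and out.source == "haplotype_model"

    def test_fallback_to_confident_pileup_call(self):
        out = sp.merge_calls(hap(10.0), rec(16.0), delta=14.0)
        assert out is not None and out.source == "pileup_model"

    def test_both_low_discarded(self):
        assert sp.merge_calls(hap(10.0), rec(10.0), delta=14.0) is None

    def test_truth_table_over_presence_and_quality(self):
        states = {"high": 20.0, "low": 10.0, "absent": None}
        for hs, ps in itertools.product(states, states):
            h = hap(states[hs]) if states[hs] is not None else None
            p = rec(states[ps]) if states[ps] is not None else None
            if h is None and p is None:
                with pytest.raises(ValueError):
                    sp.merge_calls(h, p)
                continue
            out = sp.merge_calls(h, p, delta=14.0)
            if hs == "high":
                assert out is not None and out.source == "haplotype_model"
            elif ps == "high":
                assert out is not None and out.source == "pileup_model"
            else:
                assert out is None

    def test_boundary_quality_exactly_delta_discards(self):
        assert sp.merge_calls(hap(14.0), rec(14.0), delta=14.0) is None

    def test_confident_hom_ref_yields_no_record_and_shadows_pileup(self):
        out = sp.merge_calls(hap(30.0, genotype="AA", ref="A"), rec(30.0))
        assert out is None

    def test_pileup_indel_genotypes_suppressed(self):
        assert sp.merge_calls(None, rec(30.0, genotype="AD")) is None
        assert sp.merge_calls(None, rec(30.0, genotype="II")) is None

    def test_monotone_in_delta(self):
        pairs = [(hap(q1), rec(q2)) for q1 in (5, 15, 25)
                 for q2 in (5, 15, 25)]
        kept = [sum(sp.merge_calls(h, p, delta=d) is not None
                    for h, p in pairs) for d in (5, 10, 14, 20, 30)]
        assert kept == sorted(kept, reverse=True)


class TestGenotypeToVcf:
    @pytest.mark.parametrize("ref", "ACGT")
    @pytest.mark.parametrize("pair", GENOTYPES_10)
    def test_gt_mapping_enumeration(self, pair, ref):
        out = _as_final(rec(30.0, genotype=pair, ref=ref))
        a, b = pair[0], pair[1]
        if a == b == ref:
            assert out is None                     # hom_ref: no record
        elif a == b:
            assert out.gt == "1/1" and out.alts == (a,)
        elif ref in pair:
            alt = b if a == ref else a
            assert out.gt == "0/1" and out.alts == (alt,)
        else:
            assert out.gt == "1/2" and out.alts == (a, b)
        if out is not None:
            assert all(len(x) == 1 for x in out.alts)


TRUTH = [TruthVariant(9, "A", "C", "het", "SNP"),
         TruthVariant(19, "G", "T", "hom_alt", "SNP"),
         TruthVariant(29, "C", "A", "het", "SNP"),
         TruthVariant(39, "ACG", "A", "het", "DEL")]   # indel: not counted


def final(pos, ref, alt, gt="0/1", q=30.0):
    genotype = "".join(sorted(ref + alt)) if gt == "0/1" \
        else "".join(sorted(alt + alt))
    return sp.FinalCall(contig="c", position=pos, ref=ref, alts=(alt,),
                        gt=gt, quality=q, source="haplotype_model",
                        genotype=genotype)


class TestClassify:
    def test_perfect_calls(self):
        calls = [final(9, "A", "C"), final(19, "G", "T", gt="1/1")]
        ev = sp.classify_against_truth(calls, TRUTH[:2])
        assert (ev.tp, ev.fp, ev.fn) == (2, 0, 0)
        assert ev.precision == ev.recall == ev.f1 == 1.0

    def test_two_correct_one_spurious(self):
        calls = [final(9, "A", "C"), final(19, "G", "T", gt="1/1"),
                 final(50, "A", "G")]
        ev = sp.classify_against_truth(calls, TRUTH[:3])
        assert (ev.tp, ev.fp, ev.fn) == (2, 1, 1)
        assert ev.precision == pytest.approx(2 / 3)
        assert ev.recall == pytest.approx(2 / 3)

    def test_wrong_genotype_counts_fp_and_fn(self):
        ev = sp.classify_against_truth([final(9, "A", "C", gt="1/1")],
                                       TRUTH[:1])
        assert (ev.tp, ev.fp, ev.fn) == (0, 1, 1)

    def test_empty_call_set_flags_undefined_precision(self):
        ev = sp.classify_against_truth([], TRUTH[:2])
        assert ev.recall == 0.0
        assert ev.precision == 0.0
        assert not ev.precision_defined

    def test_regions_restrict_both_sides(self):
        calls = [final(9, "A", "C"), final(29, "C", "A")]
        ev = sp.classify_against_truth(calls, TRUTH, regions=[(0, 15)])
        assert (ev.tp, ev.fp, ev.fn) == (1, 0, 0)

    def test_contig_mismatch_raises(self):
        with pytest.raises(ValueError):
            sp.classify_against_truth([final(9, "A", "C")], TRUTH,
                                      contig="other")

    def test_indel_truth_is_excluded(self):
        ev = sp.classify_against_truth([], [TRUTH[3]])
        assert (ev.tp, ev.fp, ev.fn) == (0, 0, 0)


class TestVcfOutput:
    def test_zero_calls_header_only(self, tmp_path):
        path = str(tmp_path / "empty.vcf")
        sp.write_final_vcf(path, "c", 1000, [])
        with pysam.VariantFile(path) as vf:
            assert list(vf) == []

    def test_round_trip(self, tmp_path):
        calls = [final(9, "A", "C"), final(19, "G", "T", gt="1/1", q=21.5)]
        path = str(tmp_path / "calls.vcf")
        sp.write_final_vcf(path, "c", 1000, calls)
        back = sp.read_final_vcf(path)
        assert [(c.position, c.ref, c.alts, c.gt, c.genotype) for c in back] \
            == [(c.position, c.ref, c.alts, c.gt, c.genotype) for c in calls]
        assert back[1].quality == pytest.approx(21.5, abs=0.01)
        assert back[0].source == "haplotype_model"

    def test_unphased_genotype_separator(self, tmp_path):
        path = str(tmp_path / "c.vcf")
        sp.write_final_vcf(path, "c", 1000, [final(9, "A", "C")])
        body = [l for l in open(path) if not l.startswith("#")]
        assert "0/1" in body[0] and "|" not in body[0].split("\t")[9]

    def test_unsorted_calls_rejected(self, tmp_path):
        calls = [final(19, "G", "T"), final(9, "A", "C")]
        with pytest.raises(ValueError):
            sp.write_final_vcf(str(tmp_path / "x.vcf"), "c", 1000, calls)

    def test_het_nonref_writes_two_alts(self, tmp_path):
        c = sp.FinalCall(contig="c", position=5, ref="A", alts=("C", "G"),
                         gt="1/2", quality=30.0, source="pileup_model",
                         genotype="CG")
        path = str(tmp_path / "h.vcf")
        sp.write_final_vcf(path, "c", 1000, [c])
        with pysam.VariantFile(path) as vf:
            recs = list(vf)
        assert recs[0].alts == ("C", "G")
        assert recs[0].samples[0]["GT"] == (1, 2)
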