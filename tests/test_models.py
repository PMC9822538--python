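"""Genotyping networks: heads, label spaces, quality law, training behaviour."""

import numpy as np
import pytest

import snphase as sp
from snphase.config import NetConfig, TrainConfig
from snphase.models import (GENOTYPES_21, TrainingError, log_odds,
                            pair_of_index, rebalance_indices,
                            smoothing_ceiling)


@pytest.fixture(scope="module")
def tiny_pileup_net():
    return sp.PileupNetwork(NetConfig(hidden_size=8, fc_size=16), seq_len=9,
                            in_channels=16, seed=3)


@pytest.fixture(scope="module")
def tiny_hap_net():
    return sp.HaplotypeNetwork(NetConfig(hidden_size=8, fc_size=16,
                                         branch_fc_size=8, combine_size=8),
                               short_len=9, long_len=5, seed=3)


class TestHeads:
    def test_pileup_head_sizes(self, tiny_pileup_net):
        lg, lz = tiny_pileup_net.forward(np.zeros((2, 9, 16)))
        assert lg.shape == (2, 21)
        assert lz.shape == (2, 3)

    def test_haplotype_head_sizes(self, tiny_hap_net):
        lg, lz = tiny_hap_net.forward((np.zeros((2, 9, 104)),
                                       np.zeros((2, 5, 104))))
        assert lg.shape == (2, 10)
        assert lz.shape == (2, 3)

    def test_zero_image_yields_valid_distributions(self, tiny_pileup_net):
        pg, pz = tiny_pileup_net.predict_proba(np.zeros((3, 9, 16)))
        assert np.allclose(pg.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(pz.sum(axis=1), 1.0, atol=1e-6)
        assert (pg >= 0).all() and (pz >= 0).all()

    def test_shape_mismatch_raises(self, tiny_pileup_net, tiny_hap_net):
        with pytest.raises(ValueError):
            tiny_pileup_net.forward(np.zeros((2, 7, 16)))
        with pytest.raises(ValueError):
            tiny_hap_net.forward((np.zeros((2, 9, 104)),
                                  np.zeros((2, 7, 104))))


class TestQualityLaw:
    def test_symmetry_point(self):
        assert sp.quality_score(0.5) == 0.0

    def test_direct_evaluation(self):
        assert abs(sp.quality_score(0.9) - 10 * np.log10(9)) < 1e-9

    def test_clipping_contract(self):
        assert sp.quality_score(1 - 1e-12) == 60.0
        assert sp.quality_score(1e-12) == 0.0
        assert sp.quality_score(2.0) == 60.0     # out-of-range input clipped

    def test_strict_monotonicity(self):
        grid = np.linspace(0.01, 0.99, 1000)
        vals = [log_odds(p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_antisymmetry_before_clipping(self):
        for p in (0.6, 0.75, 0.9, 0.99):
            assert abs(log_odds(p) + log_odds(1 - p)) < 1e-9

    def test_smoothing_ceiling_values(self):
        assert abs(smoothing_ceiling(21, 0.1) - (0.9 + 0.1 / 21)) < 1e-12
        assert smoothing_ceiling(3, 0.0) == 1.0


class TestLabelSpace:
    @pytest.mark.parametrize("i", range(21))
    def test_pair_round_trip(self, i):
        pair = pair_of_index(i)
        assert sp.genotype_index(pair, 21) == i

    def test_canonicalisation(self):
        assert sp.canonical_pair("G", "A") == "AG"
        assert sp.canonical_pair("D", "I") == "ID"
        assert sp.canonical_pair("T", "I") == "TI"

    @pytest.mark.parametrize("pair,ref,want", [
        ("AA", "A", "hom_ref"), ("AA", "C", "hom_alt"), ("AC", "A", "het"),
        ("AC", "G", "het"), ("II", "A", "hom_alt"), ("AD", "A", "het"),
    ])
    def test_zygosity_consistency(self, pair, ref, want):
        assert sp.zygosity_of(pair, ref) == want


def _toy_training_set(n=200, seq_len=9, channels=16, n_classes=21, seed=0):
    """Separable toy images: class k gets a bump in channel k % channels."""
    rng = np.random.default_rng(seed)
    yg = rng.integers(0, n_classes, size=n)
    yz = yg % 3
    X = rng.random((n, seq_len, channels)).astype(np.float32)
    X[np.arange(n), seq_len // 2, yg % channels] += 6.0
    return X, yg, yz


class TestTraining:
    def test_initial_loss_matches_uniform_closed_form(self):
        X, yg, yz = _toy_training_set()
        net = sp.PileupNetwork(NetConfig(8, 16), seq_len=9, seed=0)
        cfg = TrainConfig(batch_size=200, epochs=1, learning_rate=0.0,
                          lookahead=False, seed=0)
        history = sp.train_model(net, X, yg, yz, cfg)
        # small-scale head init keeps the softmax near uniform at epoch 0
        assert abs(history[0] - (np.log(21) + np.log(3))) < 0.2

    def test_toy_set_overfits_to_high_accuracy(self):
        X, yg, yz = _toy_training_set()
        net = sp.PileupNetwork(NetConfig(16, 32), seq_len=9, seed=0)
        cfg = TrainConfig(batch_size=50, epochs=200, learning_rate=3e-3,
                          lookahead=False, seed=0)
        sp.train_model(net, X, yg, yz, cfg)
        pg, pz = net.predict_proba(X)
        assert (pg.argmax(1) == yg).mean() >= 0.99
        assert (pz.argmax(1) == yz).mean() >= 0.99

    def test_training_is_deterministic_under_fixed_seed(self):
        losses, weights = [], []
        for _ in range(2):
            X, yg, yz = _toy_training_set(n=60)
            net = sp.PileupNetwork(NetConfig(8, 16), seq_len=9, seed=1)
            cfg = TrainConfig(batch_size=30, epochs=5, learning_rate=1e-3,
                              seed=7)
            h = sp.train_model(net, X, yg, yz, cfg)
            losses.append(h[-1])
            weights.append(np.concatenate(
                [p.ravel() for _, p, _ in net.param_items()]))
        assert losses[0] == losses[1]
        assert np.array_equal(weights[0], weights[1])

    def test_degenerate_training_sets_raise(self):
        net = sp.PileupNetwork(NetConfig(8, 16), seq_len=9, seed=0)
        cfg = TrainConfig(epochs=1)
        with pytest.raises(TrainingError):
            sp.train_model(net, np.zeros((0, 9, 16)), np.zeros(0, int),
                           np.zeros(0, int), cfg)
        with pytest.raises(TrainingError):
            sp.train_model(net, np.zeros((5, 9, 16)), np.zeros(5, int),
                           np.zeros(5, int), cfg)

    def test_rebalance_caps_negative_ratio(self):
        is_neg = np.array([True] * 90 + [False] * 10)
        idx = rebalance_indices(is_neg, 4.0, np.random.default_rng(0))
        assert (~is_neg[idx]).sum() == 10
        assert is_neg[idx].sum() == 40
        assert len(np.unique(idx)) == len(idx)
        # no-op when already balanced
        assert len(rebalance_indices(is_neg, 100.0)) == 100


class TestCalibrationAndCalls:
    def test_temperature_sharpens_toward_unsmoothed_labels(self):
        X, yg, yz = _toy_training_set()
        net = sp.PileupNetwork(NetConfig(16, 32), seq_len=9, seed=0)
        cfg = TrainConfig(batch_size=50, epochs=150, learning_rate=3e-3,
                          lookahead=False, label_smoothing=0.1, seed=0)
        sp.train_model(net, X, yg, yz, cfg)
        before = net.predict_proba(X)[0].max(axis=1).mean()
        T = sp.fit_temperature(net, X, yg, yz)
        after = net.predict_proba(X)[0].max(axis=1).mean()
        assert T < 1.0
        assert after > before
        assert after > smoothing_ceiling(21, 0.1)

    def test_call_records_batch_order_invariance(self, tiny_pileup_net):
        rng = np.random.default_rng(4)
        X = rng.random((7, 9, 16))
        recs = sp.call_records(tiny_pileup_net, X, "c", range(7), "ACGTACG")
        perm = rng.permutation(7)
        recs_p = sp.call_records(tiny_pileup_net, X[perm], "c",
                                 np.arange(7)[perm],
                                 [("ACGTACG")[i] for i in perm])
        by_pos = {r.position: r for r in recs_p}
        for r in recs:
            other = by_pos[r.position]
            assert r.genotype == other.genotype
            assert r.quality == pytest.approx(other.quality, abs=1e-5)

    def test_record_quality_is_min_of_two_heads(self, tiny_pileup_net):
        rng = np.random.default_rng(5)
        X = rng.random((5, 9, 16))
        for r in sp.call_records(tiny_pileup_net, X, "c", range(5), "ACGTA"):
            assert r.quality == pytest.approx(
                min(sp.quality_score(r.p_genotype),
                    sp.quality_score(r.p_zygosity)), abs=1e-9)

    def test_save_load_round_trip(self, tmp_path, tiny_pileup_net,
                                  tiny_hap_net):
        rng = np.random.default_rng(6)
        tiny_pileup_net.temperature = 0.37
        path = str(tmp_path / "p.npz")
        tiny_pileup_net.save(path)
        loaded = sp.load_model(path)
        X = rng.random((3, 9, 16))
        for a, b in zip(loaded.predict_proba(X),
                        tiny_pileup_net.predict_proba(X)):
            assert np.array_equal(a, b)
        assert loaded.temperature == 0.37
        hpath = str(tmp_path / "h.npz")
        tiny_hap_net.save(hpath)
        hload = sp.load_model(hpath)
        pair = (rng.random((3, 9, 104)), rng.random((3, 5, 104)))
        for a, b in zip(hload.predict_proba(pair),
                        tiny_hap_net.predict_proba(pair)):
            assert np.array_equal(a, b)


class TestAugmentation:
    def test_pileup_augmentation_preserves_the_learning_problem(self):
        from snphase.models import pileup_augmenter
        rng = np.random.default_rng(7)
        x = rng.random((4, 9, 16))
        yg = np.array([sp.genotype_index("AC"), sp.genotype_index("AA"),
                       sp.genotype_index("AI"), sp.genotype_index("GT")])
        yz = np.array([2, 0, 2, 2])
        xa, yga, yza = pileup_augmenter(x, yg, yz, np.random.default_rng(12))
        assert xa.shape == x.shape
        assert np.array_equal(yza, yz)                 # zygosity invariant
        assert sorted(np.sort(xa, axis=None)) == sorted(np.sort(x, axis=None))
        # pair structure preserved: het stays het, hom stays hom, I stays
        for before, after in zip(yg, yga):
            b, a = GENOTYPES_21[before], GENOTYPES_21[after]
            assert (b[0] == b[1]) == (a[0] == a[1])
            assert ("I" in b) == ("I" in a)

    def test_identity_permutation_exists(self):
        from snphase.models import _GMAP21, _PERMS
        k = _PERMS.index((0, 1, 2, 3))
        assert np.array_equal(_GMAP21[k], np.arange(21))
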