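"""Loss terms: hand-computed cases, loop-oracle equivalence, gradient flow."""

import numpy as np
import pytest

from danisim.autograd import Tensor
from danisim.losses import (LossBundle, bce, loss_adv_brain, loss_adv_latent,
                            loss_rec, loss_reg, loss_total, loss_vox)
from danisim.nets import ModelConfig, build_models, generate_full_sequence
from danisim.prep import RegionSet

from .oracles import bce_ref, rec_ref, reg_ref, vox_ref


class _FixedLR:
    """Stub regressor with a constant prediction."""

    def __init__(self, value):
        self.value = value

    def predict(self, o, a, d):
        return 1.0 if a == o else self.value


def _region_set(masks):
    masks = [np.asarray(m, dtype=bool) for m in masks]
    return RegionSet(0, masks, [str(i) for i in range(len(masks))])


class TestReconstruction:
    def test_zero_when_outputs_equal_input(self):
        x = np.random.default_rng(0).uniform(size=(4, 4))
        assert loss_rec(x, [x.copy(), x.copy()], [0.9, 0.3]) == pytest.approx(0.0)

    def test_single_bin_hand_value(self):
        x = np.full((4, 4), 0.5)
        g = np.zeros((4, 4))
        assert loss_rec(x, [g], [1.0]) == pytest.approx(0.25)

    def test_linear_in_membership_weights(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=(3, 3))
        gs = [rng.uniform(size=(3, 3)) for _ in range(3)]
        mu = np.array([0.2, 0.5, 0.9])
        assert loss_rec(x, gs, 2 * mu) == pytest.approx(2 * loss_rec(x, gs, mu))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            loss_rec(np.zeros((2, 2)), [np.zeros((2, 2))], [0.5, 0.5])


class TestVoxelMonotonicity:
    def test_constant_sequence_is_free(self):
        g = [np.full((3, 3), 0.4)] * 4
        for a in range(4):
            assert loss_vox(g, a) == pytest.approx(0.0)

    def test_scalar_hand_value(self):
        g = [np.array([[1.0]]), np.array([[0.5]]), np.array([[0.2]])]
        assert loss_vox(g, 1) == pytest.approx(0.17)

    def test_boundary_bin_with_compliant_suffix_is_free(self):
        g0 = np.random.default_rng(2).uniform(0.5, 1.0, size=(3, 3))
        g = [g0, g0 - 0.1, g0.copy()]  # max of later == g0 element-wise
        assert loss_vox(g, 0) == pytest.approx(0.0)

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            loss_vox([np.zeros((2, 2))] * 3, 3)


class TestRegionalProgression:
    def test_zero_when_ratios_match_predictions(self):
        mask = np.ones((4, 4), dtype=bool)
        g1 = np.full((4, 4), 0.5)
        target = 0.9
        s1 = g1.sum() + 0.1
        # choose g2 so that (sum2 + eps) / (sum1 + eps) == target exactly
        g2 = np.full((4, 4), (target * s1 - 0.1) / 16)
        rset = _region_set([mask])
        val = loss_reg([g1, g2], 0, 1, rset, [_FixedLR(target)], [70.0, 75.0])
        assert val == pytest.approx(0.0, abs=1e-15)

    def test_single_term_hand_value(self):
        mask = np.ones((4, 4), dtype=bool)
        g1 = np.full((4, 4), 50.0 / 16)
        g2 = np.full((4, 4), 40.0 / 16)
        rset = _region_set([mask])
        val = loss_reg([g1, g2], 0, 1, rset, [_FixedLR(0.9)], [70.0, 75.0])
        expected = 16.0 * (0.9 - 40.1 / 50.1) ** 2   # s_q = 16 voxels, R(A-1) = 1
        assert val == pytest.approx(expected, abs=1e-12)

    def test_size_weighting_matches_loop_oracle_with_scaled_sizes(self):
        """The s_q factor is linear: k-fold sizes give a k-fold loss."""
        rng = np.random.default_rng(3)
        gs = [rng.uniform(size=(4, 4)) for _ in range(2)]
        mask = rng.uniform(size=(4, 4)) > 0.5
        base = reg_ref(gs, 0, 1, [mask], [mask.sum()],
                       lambda q, o, a, d: 0.85, [70, 72])
        scaled = reg_ref(gs, 0, 1, [mask], [3 * mask.sum()],
                         lambda q, o, a, d: 0.85, [70, 72])
        assert scaled == pytest.approx(3 * base, rel=1e-12)

    def test_missing_regressor_is_configuration_error(self):
        mask = np.ones((2, 2), dtype=bool)
        with pytest.raises(ValueError, match="regressor count"):
            loss_reg([np.zeros((2, 2))] * 2, 0, 0, _region_set([mask]),
                     [], [70, 72])


class TestAdversarial:
    def test_uninformative_discriminator_costs_two_log_two(self):
        half = lambda batch: np.full((len(batch), 1), 0.5)
        d_loss, g_term = loss_adv_brain(half, np.zeros((4, 1, 2, 2)),
                                        np.zeros((4, 1, 2, 2)))
        assert d_loss == pytest.approx(2 * np.log(2), abs=1e-12)
        assert g_term == pytest.approx(np.log(2), abs=1e-12)

    def test_perfect_discriminator_costs_nothing(self):
        db = lambda batch: (np.ones((len(batch), 1)) if batch.sum() > 0
                            else np.zeros((len(batch), 1)))
        d_loss, _ = loss_adv_brain(db, np.ones((3, 1, 2, 2)),
                                   np.zeros((3, 1, 2, 2)))
        assert d_loss < 1e-5

    def test_generator_term_decreases_as_fakes_fool(self):
        vals = [bce(np.full((4, 1), p), 1.0) for p in (0.2, 0.5, 0.9)]
        assert vals[0] > vals[1] > vals[2]

    def test_latent_pair_equilibrium_and_minimal_batch(self):
        half = lambda batch: np.full((len(batch), 1), 0.5)
        d_loss, e_term = loss_adv_latent(half, np.zeros((1, 5)), np.zeros((1, 5)))
        assert d_loss == pytest.approx(2 * np.log(2))
        assert e_term == pytest.approx(np.log(2))

    def test_empty_batch_rejected(self):
        half = lambda batch: np.full((len(batch), 1), 0.5)
        with pytest.raises(ValueError):
            loss_adv_brain(half, np.zeros((0, 1, 2, 2)), np.zeros((1, 1, 2, 2)))


class TestTotal:
    def test_weighted_sum_and_annihilation(self):
        bundle = LossBundle(rec=5.0, vox=2.0, reg=1.0, db=3.0, dz=4.0)
        zeros = dict.fromkeys(("reg", "vox", "b", "z", "rec"), 0.0)
        assert loss_total(bundle, zeros) == 0.0
        ones = dict.fromkeys(("reg", "vox", "b", "z", "rec"), 1.0)
        assert loss_total(bundle, ones) == pytest.approx(15.0)

    def test_negative_weight_rejected(self):
        bundle = LossBundle(1, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            loss_total(bundle, {"reg": -1.0, "vox": 0, "b": 0, "z": 0, "rec": 0})


class TestLoopOracleEquivalence:
    """Vectorized losses match naive loop references to 1e-10 on tiny inputs."""

    @pytest.mark.parametrize("seed", range(5))
    def test_reconstruction(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(1, 4)
        x = rng.uniform(size=(4, 4))
        gs = [rng.uniform(size=(4, 4)) for _ in range(a)]
        mu = rng.uniform(0.1, 1.0, size=a)
        assert loss_rec(x, gs, mu) == pytest.approx(rec_ref(x, gs, mu),
                                                    abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_voxel(self, seed):
        rng = np.random.default_rng(seed + 10)
        n = int(rng.integers(2, 4))
        gs = [rng.uniform(size=(3, 4)) for _ in range(n)]
        for a in range(n):
            assert loss_vox(gs, a) == pytest.approx(vox_ref(gs, a), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_regional(self, seed):
        rng = np.random.default_rng(seed + 20)
        n = int(rng.integers(2, 4))
        gs = [rng.uniform(size=(4, 4)) for _ in range(n)]
        masks = [rng.uniform(size=(4, 4)) > 0.4 for _ in range(2)]
        masks = [m if m.any() else ~m for m in masks]
        preds = rng.uniform(0.7, 1.0, size=2)
        rset = _region_set(masks)
        regs = [_FixedLR(p) for p in preds]
        ages = np.sort(rng.uniform(60, 90, size=n))
        a = int(rng.integers(0, n))
        got = loss_reg(gs, a, 1, rset, regs, ages)
        want = reg_ref(gs, a, 1, masks, [m.sum() for m in masks],
                       lambda q, o, t, d: regs[q].predict(o, t, d), ages)
        assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_cross_entropy(self, seed):
        rng = np.random.default_rng(seed + 30)
        p = rng.uniform(0.01, 0.99, size=(6, 1))
        for target in (0.0, 1.0):
            assert bce(p, target) == pytest.approx(bce_ref(p, target),
                                                   abs=1e-10)

    def test_batch_order_invariance(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.1, 0.9, size=(8, 1))
        assert bce(p, 1.0) == pytest.approx(bce(p[::-1].copy(), 1.0), abs=1e-12)


class TestGradientFlow:
    """Every loss reaches the parameters it is meant to train."""

    @pytest.fixture(scope="class")
    def setup(self):
        cfg = ModelConfig(image_size=16, latent_dim=6, n_age_bins=3,
                          base_channels=4, seed=3)
        models = build_models(cfg)
        rng = np.random.default_rng(0)
        x = Tensor(rng.uniform(size=(2, 1, 16, 16)))
        z = models.encoder(x)
        seq = generate_full_sequence(models, z, np.array([1, 2]))
        return cfg, models, x, z, seq

    def _has_grad(self, net):
        return any(p.grad is not None and np.abs(p.grad).max() > 0
                   for p in net.parameters())

    def test_reconstruction_reaches_encoder_and_generator(self, setup):
        cfg, models, x, z, seq = setup
        target = np.random.default_rng(1).uniform(size=(3, 2, 16, 16))
        ((seq - target) ** 2).mean().backward()
        assert self._has_grad(models.encoder) and self._has_grad(models.generator)
        for _, net in models.named_nets():
            net.zero_grad()

    def test_voxel_loss_reaches_generator(self, setup):
        cfg, models, x, z, seq = setup
        g_list = [seq[i, 0] for i in range(cfg.n_age_bins)]
        loss_vox(g_list, 1).backward()
        assert self._has_grad(models.generator)
        for _, net in models.named_nets():
            net.zero_grad()

    def test_regional_loss_reaches_generator(self, setup):
        cfg, models, x, z, seq = setup
        mask = np.zeros((16, 16), dtype=bool)
        mask[4:12, 4:12] = True
        rset = _region_set([mask])
        g_list = [seq[i, 0] for i in range(cfg.n_age_bins)]
        loss_reg(g_list, 0, 1, rset, [_FixedLR(0.9)], [65.0, 70.0, 75.0]).backward()
        assert self._has_grad(models.generator)
        for _, net in models.named_nets():
            net.zero_grad()

    def test_adversarial_pairs_reach_their_networks(self, setup):
        cfg, models, x, z, seq = setup
        d_loss, g_term = loss_adv_brain(models.db, x,
                                        Tensor(seq.data[0][:, None]))
        d_loss.backward()
        assert self._has_grad(models.db)
        for _, net in models.named_nets():
            net.zero_grad()
        _, e_term = loss_adv_latent(models.dz, Tensor(np.zeros((2, 6))), z)
        e_term.backward()
        assert self._has_grad(models.encoder) and self._has_grad(models.dz)
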