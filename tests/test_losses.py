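"""Loss functions against closed forms and brute-force oracles."""
import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from vangan import losses as L
from vangan.nn import Tensor

RNG = np.random.default_rng(777)


def brute_ssim(a, b, params):
    """Independent SSIM oracle: explicit per-window formula evaluation."""
    k = params.window_size
    ax = np.arange(k) - (k - 1) / 2.0
    g1 = np.exp(-0.5 * (ax / params.sigma) ** 2)
    g1 /= g1.sum()
    w = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
    wins_a = sliding_window_view(a, (k, k, k))
    wins_b = sliding_window_view(b, (k, k, k))
    c1, c2 = params.c1, params.c2
    vals = []
    for ia in np.ndindex(wins_a.shape[:3]):
        wa, wb = wins_a[ia], wins_b[ia]
        mu_a = (w * wa).sum()
        mu_b = (w * wb).sum()
        var_a = (w * wa * wa).sum() - mu_a ** 2
        var_b = (w * wb * wb).sum() - mu_b ** 2
        cov = (w * wa * wb).sum() - mu_a * mu_b
        vals.append(((2 * mu_a * mu_b + c1) * (2 * cov + c2))
                    / ((mu_a ** 2 + mu_b ** 2 + c1)
                       * (var_a + var_b + c2)))
    return float(np.mean(vals))


class TestCycleLosses:
    def test_l1_identity_is_zero(self):
        x = RNG.normal(size=(4, 4, 4))
        assert L.cycle_forward_l1(x, x).item() == 0.0

    def test_l1_constant_offset(self):
        x = np.zeros((4, 4, 4))
        assert L.cycle_forward_l1(x, x + 0.5).item() == pytest.approx(0.5)

    def test_l1_matches_elementwise_sum(self):
        a, b = RNG.normal(size=(2, 4, 4, 4))
        expected = np.abs(b - a).sum() / a.size
        assert L.cycle_forward_l1(a, b).item() == pytest.approx(expected,
                                                                rel=1e-6)

    def test_bce_near_zero_at_confident_truth(self):
        y = np.ones((4, 4, 4))
        assert L.cycle_backward_bce(y, y - 1e-7).item() < 1e-6

    def test_bce_half_probability_is_ln2(self):
        y = np.ones((4, 4, 4))
        p = np.full((4, 4, 4), 0.5)
        assert L.cycle_backward_bce(y, p).item() == pytest.approx(np.log(2),
                                                                  rel=1e-6)

    def test_bce_matches_per_voxel_formula(self):
        y = (RNG.random((4, 4, 4)) > 0.5).astype(float)
        p = RNG.uniform(0.01, 0.99, size=(4, 4, 4))
        expected = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert L.cycle_backward_bce(y, p).item() == pytest.approx(expected,
                                                                  rel=1e-6)

    def test_signed_mapping_round_trip(self):
        y01 = (RNG.random((4, 4, 4)) > 0.5).astype(float)
        signed = y01 * 2 - 1
        direct = L.cycle_backward_bce(y01, np.clip(y01, 0.2, 0.8))
        mapped = L.cycle_backward_bce(signed, np.clip(y01, 0.2, 0.8) * 2 - 1,
                                      signed=True)
        assert mapped.item() == pytest.approx(direct.item(), rel=1e-6)


class TestSSIM:
    def test_identical_images_score_one(self):
        a = RNG.normal(size=(16, 16, 16))
        assert L.ssim(a, a).item() == pytest.approx(1.0, abs=1e-9)

    def test_constant_images_closed_form(self):
        c1v, c2v = 0.3, -0.6
        p = L.SSIMParams()
        expected = (2 * c1v * c2v + p.c1) / (c1v ** 2 + c2v ** 2 + p.c1)
        got = L.ssim(np.full((12, 12, 12), c1v),
                     np.full((12, 12, 12), c2v), p).item()
        assert got == pytest.approx(expected, abs=1e-9)

    def test_matches_per_window_oracle(self):
        p = L.SSIMParams()
        a = RNG.normal(size=(16, 16, 16))
        b = a + 0.3 * RNG.normal(size=(16, 16, 16))
        assert L.ssim(a.astype(np.float64), b.astype(np.float64), p).item() \
            == pytest.approx(brute_ssim(a, b, p), abs=1e-6)

    def test_symmetry(self):
        a, b = RNG.normal(size=(2, 12, 12, 12))
        assert L.ssim(a, b).item() == pytest.approx(L.ssim(b, a).item(),
                                                    abs=1e-9)

    def test_reconstruction_loss_is_one_minus_ssim(self):
        a, b = RNG.normal(size=(2, 12, 12, 12))
        assert L.reconstruction_loss(a, b).item() == pytest.approx(
            1.0 - L.ssim(a, b).item(), abs=1e-9)

    def test_reconstruction_identity_is_zero(self):
        a = RNG.normal(size=(12, 12, 12))
        assert L.reconstruction_loss(a, a).item() == pytest.approx(0.0,
                                                                   abs=1e-7)


class TestSoftSkeleton:
    def test_zero_volume_stays_zero(self):
        v = np.zeros((8, 8, 8))
        assert L.soft_skeleton(v).data.sum() == 0.0

    def test_never_exceeds_input(self):
        v = RNG.random((8, 8, 8))
        sk = L.soft_skeleton(v).data[0, ..., 0]
        assert np.all(sk <= v + 1e-6)

    def test_thin_line_survives(self):
        v = np.zeros((7, 7, 7))
        v[1:6, 3, 3] = 1.0
        sk = L.soft_skeleton(v, L.SoftSkeletonParams(3)).data[0, ..., 0]
        assert np.all(sk[2:5, 3, 3] > 0)


class TestDiceFamily:
    def test_identity_binary_masks(self):
        y = np.zeros((12, 12, 12))
        y[3:9, 5:7, 5:7] = 1.0
        assert L.soft_dice(y, y).item() > 0.999
        assert L.soft_cldice(y, y, L.SoftSkeletonParams(6)).item() > 0.99

    def test_disjoint_supports_score_near_zero(self):
        a = np.zeros((8, 8, 8))
        b = np.zeros((8, 8, 8))
        a[:2], b[6:] = 1.0, 1.0
        bound = 1.0 / (a.sum() + b.sum() + 1.0)
        assert L.soft_dice(a, b).item() <= bound + 1e-9

    def test_soft_dice_matches_formula(self):
        y = RNG.random((8, 8, 8))
        p = RNG.random((8, 8, 8))
        expected = (2 * (y * p).sum() + 1) / (y.sum() + p.sum() + 1)
        assert L.soft_dice(y, p).item() == pytest.approx(expected, rel=1e-6)

    def test_soft_cldice_matches_formula(self):
        y = RNG.random((8, 8, 8))
        p = RNG.random((8, 8, 8))
        k = L.SoftSkeletonParams(4)
        sk_p = L.soft_skeleton(p, k).data[0, ..., 0]
        sk_y = L.soft_skeleton(y, k).data[0, ..., 0]
        tprec = ((sk_p * y).sum() + 1) / (sk_p.sum() + 1)
        tsens = ((sk_y * p).sum() + 1) / (sk_y.sum() + 1)
        expected = 2 * tprec * tsens / (tprec + tsens)
        assert L.soft_cldice(y, p, k).item() == pytest.approx(expected,
                                                              rel=1e-5)


class TestTopologyLoss:
    def test_identity_is_near_zero(self):
        y = np.zeros((10, 10, 10))
        y[2:8, 4:6, 4:6] = 1.0
        assert L.topology_loss(y, y,
                               skel_params=L.SoftSkeletonParams(4)).item() \
            < 0.01

    def test_alpha_zero_reduces_to_soft_dice_loss(self):
        y, p = RNG.random((2, 6, 6, 6))
        w = L.LossWeights(alpha=0.0)
        expected = 1.0 - L.soft_dice(y, p).item()
        assert L.topology_loss(y, p, w).item() == pytest.approx(expected,
                                                                rel=1e-7)

    def test_weighted_combination_arithmetic(self):
        # alpha=0.5 with component scores 0.8 (dice) and 0.6 (cldice)
        # must combine to 0.5*0.2 + 0.5*0.4 = 0.3
        alpha = 0.5
        combined = (1 - alpha) * (1 - 0.8) + alpha * (1 - 0.6)
        assert combined == pytest.approx(0.3)


class TestAdversarial:
    def test_perfect_discriminator_scores_zero(self):
        assert L.lsgan_d_loss(np.ones((4, 4)), np.zeros((4, 4))).item() == 0.0

    def test_perfect_generator_scores_zero(self):
        assert L.lsgan_g_loss(np.ones((4, 4))).item() == 0.0

    def test_half_logits_arithmetic(self):
        half = np.full((4, 4), 0.5)
        assert L.lsgan_d_loss(half, half).item() == pytest.approx(0.25)

    def test_totals_compose_weighted_terms(self):
        comps = {"g_adv": Tensor(0.2), "f_adv": Tensor(0.1),
                 "cycle_bce": Tensor(0.1), "topo": Tensor(0.1),
                 "cycle_l1": Tensor(0.3), "rec": Tensor(0.2)}
        tg, tf = L.total_generator_losses(comps, L.LossWeights())
        assert tg.item() == pytest.approx(0.2 + 10 * 0.1 + 5 * 0.1)
        assert tf.item() == pytest.approx(0.1 + 10 * 0.3 + 5 * 0.2)

    def test_zero_weights_leave_adversarial_terms(self):
        comps = {k: Tensor(v) for k, v in
                 [("g_adv", 0.4), ("f_adv", 0.3), ("cycle_bce", 9.0),
                  ("topo", 9.0), ("cycle_l1", 9.0), ("rec", 9.0)]}
        tg, tf = L.total_generator_losses(comps, L.LossWeights(0.5, 0, 0))
        assert tg.item() == pytest.approx(0.4)
        assert tf.item() == pytest.approx(0.3)


class TestGradients:
    @pytest.mark.parametrize("loss", [
        lambda t, r: L.cycle_forward_l1(r, t),
        lambda t, r: L.cycle_backward_bce(
            Tensor((r.data > 0).astype(np.float64)), t.sigmoid()),
        lambda t, r: L.ssim(r, t, L.SSIMParams(window_size=3)),
        lambda t, r: L.topology_loss(
            Tensor(np.clip(r.data, 0, 1)), t.sigmoid(),
            skel_params=L.SoftSkeletonParams(2)),
    ], ids=["l1", "bce", "ssim", "topology"])
    def test_autodiff_matches_finite_differences(self, loss):
        ref = Tensor(RNG.normal(size=(3, 3, 3)))
        x = RNG.normal(size=(3, 3, 3))

        def f(arr):
            return float(loss(Tensor(arr), ref).data)

        t = Tensor(x.copy(), requires_grad=True)
        loss(t, ref).backward()
        grad = np.zeros_like(x)
        eps = 1e-5
        it = np.nditer(x, flags=["multi_index"])
        while not it.finished:
            i = it.multi_index
            orig = x[i]
            x[i] = orig + eps
            fp = f(x)
            x[i] = orig - eps
            fm = f(x)
            x[i] = orig
            grad[i] = (fp - fm) / (2 * eps)
            it.iternext()
        denom = np.max(np.abs(grad)) + 1e-12
        assert np.max(np.abs(t.grad.reshape(grad.shape) - grad)) / denom \
            < 1e-3

    def test_losses_finite_and_nonnegative_on_random_inputs(self):
        y = RNG.random((6, 6, 6))
        p = RNG.random((6, 6, 6))
        x = RNG.normal(size=(12, 12, 12))
        xr = RNG.normal(size=(12, 12, 12))
        values = [
            L.cycle_forward_l1(x, xr).item(),
            L.cycle_backward_bce(y, np.clip(p, 1e-4, 1 - 1e-4)).item(),
            L.reconstruction_loss(x, xr).item(),
            L.topology_loss(y, p,
                            skel_params=L.SoftSkeletonParams(2)).item(),
            L.lsgan_d_loss(x[:2, :2, 0], xr[:2, :2, 0]).item(),
            L.lsgan_g_loss(x[:2, :2, 0]).item(),
        ]
        assert all(np.isfinite(v) and v >= 0 for v in values)
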