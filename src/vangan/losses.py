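"""Loss functions for cycle-consistent adversarial vessel segmentation.

The translation model uses two generators (G: imaging -> segmentation,
F: segmentation -> imaging) and two least-squares PatchGAN discriminators.
Each generator minimises the cycle-consistency terms of the reconstruction
it produces:

* forward cycle  x -> G(x) -> F(G(x)):  L1 + structural-similarity (SSIM)
  reconstruction loss, charged to F;
* backward cycle y -> F(y) -> G(F(y)):  voxelwise binary cross-entropy plus
  a topology term combining soft-Dice and soft-clDice, charged to G.

The weighted totals are ``L = L_GAN(G) + L_GAN(F) + lambda*(L1 + BCE)
+ eta*(L_rec + L_topo)`` with defaults alpha=0.5, lambda=10, eta=5.

All losses accept either numpy arrays or autodiff tensors; expectations are
realised as arithmetic means over voxels and batch.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import functional as F
from .nn.tensor import Tensor

__all__ = ["LossWeights", "SSIMParams", "SoftSkeletonParams",
           "signed_to_unit", "cycle_forward_l1", "cycle_backward_bce",
           "ssim", "reconstruction_loss", "soft_skeleton", "soft_dice",
           "soft_cldice", "topology_loss", "lsgan_d_loss", "lsgan_g_loss",
           "total_generator_losses"]

BCE_EPS = 1e-7


@dataclass
class LossWeights:
    """Objective weights: alpha balances Dice vs clDice inside the topology
    term; lam scales cycle consistency; eta scales reconstruction/topology."""
    alpha: float = 0.5
    lam: float = 10.0
    eta: float = 5.0

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0 or self.eta < 0:
            raise ValueError("lambda and eta must be >= 0")


@dataclass
class SSIMParams:
    """Gaussian-window SSIM parameters. ``dynamic_range`` is the pixel value
    span L (2 for data normalised to [-1, 1])."""
    window_size: int = 11
    sigma: float = 1.5
    dynamic_range: float = 2.0

    @property
    def c1(self) -> float:
        return (0.01 * self.dynamic_range) ** 2

    @property
    def c2(self) -> float:
        return (0.03 * self.dynamic_range) ** 2


@dataclass
class SoftSkeletonParams:
    iterations: int = 10

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def _as_volume_tensor(v) -> Tensor:
    """Wrap input as a (N, C, D, H, W) tensor without copying graphs."""
    t = v if isinstance(v, Tensor) else Tensor(np.asarray(v))
    if t.ndim == 3:
        t = t.reshape((1,) + t.shape + (1,))
    elif t.ndim == 4:
        t = t.reshape(t.shape + (1,))
    elif t.ndim != 5:
        raise ValueError(f"expected a 3-5D volume, got ndim {t.ndim}")
    return t


def _check_same_shape(a: Tensor, b: Tensor) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def signed_to_unit(v):
    """Affine map from the [-1, 1] data range to [0, 1] probabilities."""
    if isinstance(v, Tensor):
        return (v + 1.0) * 0.5
    return (np.asarray(v) + 1.0) * 0.5


def cycle_forward_l1(x, x_rec) -> Tensor:
    """Mean absolute error between an image and its cycle reconstruction."""
    x, x_rec = _as_volume_tensor(x), _as_volume_tensor(x_rec)
    _check_same_shape(x, x_rec)
    return (x_rec - x).abs().mean()


def cycle_backward_bce(y, y_rec, signed: bool = False) -> Tensor:
    """Mean binary cross-entropy between a mask and its reconstruction.

    With ``signed=True`` both inputs are first mapped from [-1, 1] to
    [0, 1]; predictions are clipped to [eps, 1-eps].
    """
    y, y_rec = _as_volume_tensor(y), _as_volume_tensor(y_rec)
    _check_same_shape(y, y_rec)
    if signed:
        y, y_rec = signed_to_unit(y), signed_to_unit(y_rec)
    p = y_rec.clip(BCE_EPS, 1.0 - BCE_EPS)
    yd = y if isinstance(y, Tensor) else Tensor(y)
    return -(yd * p.log() + (1.0 - yd) * (1.0 - p).log()).mean()


def _gaussian_1d(size: int, sigma: float, dtype) -> np.ndarray:
    ax = np.arange(size, dtype=np.float64) - (size - 1) / 2.0
    g1 = np.exp(-0.5 * (ax / sigma) ** 2)
    return (g1 / g1.sum()).astype(dtype)


def ssim(a, b, params: SSIMParams | None = None) -> Tensor:
    """Mean local SSIM index under a sliding 3-D Gaussian window.

    Local means/variances/covariance are Gaussian-weighted over valid window
    positions; the SSIM map is averaged to a scalar in [-1, 1].
    """
    params = params or SSIMParams()
    a, b = _as_volume_tensor(a), _as_volume_tensor(b)
    _check_same_shape(a, b)
    if min(a.shape[1:4]) < params.window_size:
        raise ValueError("volume smaller than the SSIM window")
    k = params.window_size
    g1 = _gaussian_1d(k, params.sigma, a.data.dtype)
    c = a.shape[-1]
    eye = np.eye(c, dtype=a.data.dtype)
    # separable Gaussian window: one 1-D depthwise pass per spatial axis
    kernels = [Tensor(np.einsum("k,cf->kcf", g1, eye).reshape(shape))
               for shape in ((k, 1, 1, c, c), (1, k, 1, c, c),
                             (1, 1, k, c, c))]
    c1, c2 = params.c1, params.c2

    def _filt(t: Tensor) -> Tensor:
        for w in kernels:
            t = F.conv3d(t, w)
        return t

    mu_a, mu_b = _filt(a), _filt(b)
    mu_aa, mu_bb, mu_ab = mu_a * mu_a, mu_b * mu_b, mu_a * mu_b
    var_a = _filt(a * a) - mu_aa
    var_b = _filt(b * b) - mu_bb
    cov = _filt(a * b) - mu_ab
    num = (2.0 * mu_ab + c1) * (2.0 * cov + c2)
    den = (mu_aa + mu_bb + c1) * (var_a + var_b + c2)
    return (num / den).mean()


def reconstruction_loss(x, x_rec, params: SSIMParams | None = None) -> Tensor:
    """1 - SSIM, in [0, 2]."""
    return 1.0 - ssim(x, x_rec, params)


def soft_skeleton(v, params: SoftSkeletonParams | None = None) -> Tensor:
    """Differentiable morphological skeleton via iterated soft erosion and
    opening (min/max pooling); values never exceed the input."""
    params = params or SoftSkeletonParams()
    img = _as_volume_tensor(v)
    skel = (img - F.soft_open(img)).relu()
    for _ in range(params.iterations):
        img = F.soft_erode(img)
        delta = (img - F.soft_open(img)).relu()
        skel = skel + (delta - skel * delta).relu()
    return skel


def soft_dice(y, y_pred, smooth: float = 1.0) -> Tensor:
    """Soft Dice overlap in [0, 1] with additive smoothing."""
    y, y_pred = _as_volume_tensor(y), _as_volume_tensor(y_pred)
    _check_same_shape(y, y_pred)
    inter = (y * y_pred).sum()
    return (2.0 * inter + smooth) / (y.sum() + y_pred.sum() + smooth)


def soft_cldice(y, y_pred, skel_params: SoftSkeletonParams | None = None,
                smooth: float = 1.0) -> Tensor:
    """Soft centreline-Dice: harmonic mean of topology precision and
    sensitivity measured through soft skeletons."""
    y, y_pred = _as_volume_tensor(y), _as_volume_tensor(y_pred)
    _check_same_shape(y, y_pred)
    skel_pred = soft_skeleton(y_pred, skel_params)
    skel_true = soft_skeleton(y, skel_params)
    tprec = ((skel_pred * y).sum() + smooth) / (skel_pred.sum() + smooth)
    tsens = ((skel_true * y_pred).sum() + smooth) / (skel_true.sum() + smooth)
    return 2.0 * tprec * tsens / (tprec + tsens)


def topology_loss(y, y_rec, weights: LossWeights | None = None,
                  skel_params: SoftSkeletonParams | None = None,
                  signed: bool = False) -> Tensor:
    """(1-alpha)(1 - softDice) + alpha(1 - softclDice) on [0, 1] volumes."""
    weights = weights or LossWeights()
    if signed:
        y, y_rec = signed_to_unit(_as_volume_tensor(y)), \
            signed_to_unit(_as_volume_tensor(y_rec))
    a = weights.alpha
    loss = (1.0 - a) * (1.0 - soft_dice(y, y_rec))
    if a > 0.0:
        loss = loss + a * (1.0 - soft_cldice(y, y_rec, skel_params))
    return loss


def lsgan_d_loss(real_logits, fake_logits) -> Tensor:
    """Least-squares discriminator loss: 0.5 E[(D(real)-1)^2] + 0.5 E[D(fake)^2]."""
    r = real_logits if isinstance(real_logits, Tensor) else Tensor(real_logits)
    f = fake_logits if isinstance(fake_logits, Tensor) else Tensor(fake_logits)
    return 0.5 * ((r - 1.0) ** 2.0).mean() + 0.5 * (f ** 2.0).mean()


def lsgan_g_loss(fake_logits) -> Tensor:
    """Least-squares generator loss: E[(D(fake)-1)^2]."""
    f = fake_logits if isinstance(fake_logits, Tensor) else Tensor(fake_logits)
    return ((f - 1.0) ** 2.0).mean()


def total_generator_losses(components: dict, weights: LossWeights | None = None):
    """Combine per-generator totals.

    ``components`` keys: ``g_adv`` (adversarial loss of G's output),
    ``f_adv``, ``cycle_bce``, ``topo``, ``cycle_l1``, ``rec``.  Returns
    ``(total_G, total_F)`` where each total contains only the cycle terms of
    the reconstruction that generator produces.
    """
    w = weights or LossWeights()
    total_g = components["g_adv"] + w.lam * components["cycle_bce"] \
        + w.eta * components["topo"]
    total_f = components["f_adv"] + w.lam * components["cycle_l1"] \
        + w.eta * components["rec"]
    return total_g, total_f
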