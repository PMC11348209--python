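"""Unpaired adversarial training orchestration.

One training step updates, in order, the two discriminators (least-squares
loss on noisy real/fake inputs) and then the two generators.  Under the
default ``per_generator`` loss split each generator owns the cycle terms
of the reconstruction it produces -- G (imaging -> segmentation) minimises
its adversarial term plus lambda*BCE + eta*topology on y -> F(y) -> G(F(y)),
while F minimises its adversarial term plus lambda*L1 + eta*(1 - SSIM) on
x -> G(x) -> F(G(x)) -- so G's segmentations are penalised only
adversarially on the forward cycle.  ``joint`` restores the classic
coupled cycle loss for baseline comparisons.

Schedules follow the published recipe: Adam(lr 2e-4, betas 0.5/0.9) for
200 epochs with linear decay to zero from epoch 100, discriminator input
noise with variance 0.1*(1 - i/epochs), per-weight gradient-norm clipping
at 100, global batch 2, Z-axis rotation augmentation and vessel-biased
sampling of segmentation patches (90% of empty draws are resampled).
"""
from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import losses as L
from .networks import (DiscriminatorConfig, GeneratorConfig,
                       PatchGANDiscriminator, ResUNetGenerator)
from .nn import Adam, Tensor

__all__ = ["TrainConfig", "noise_sigma", "learning_rate", "split_dataset",
           "sample_seg_volume", "augment", "TrainingDiverged", "Trainer"]


class TrainingDiverged(RuntimeError):
    def __init__(self, record: Dict[str, float]):
        super().__init__(f"non-finite loss encountered: {record}")
        self.record = record


@dataclass
class TrainConfig:
    epochs: int = 200
    steps_per_epoch: int = 100
    batch_size: int = 2
    lr0: float = 2e-4
    adam_moments: Tuple[float, float] = (0.5, 0.9)
    decay_start_epoch: int = 100
    clip_norm: float = 100.0
    noise_variance0: float = 0.1
    vessel_bias_prob: float = 0.9
    patch_shape: Tuple[int, int, int] = (128, 128, 128)
    test_frac: float = 0.1
    val_frac: float = 0.2
    # architecture
    gen_levels: int = 4
    gen_base_filters: int = 16
    disc_base_filters: int = 64
    # loss composition
    alpha: float = 0.5
    lam: float = 10.0
    eta: float = 5.0
    skeleton_iters: int = 10
    ssim_window: int = 11
    loss_split: str = "per_generator"   # or "joint"
    # ablation switches
    use_disc_noise: bool = True
    use_rec_loss: bool = True
    use_topo_loss: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.vessel_bias_prob <= 1.0:
            raise ValueError("vessel_bias_prob must be in [0, 1]")
        if not self.decay_start_epoch < self.epochs:
            raise ValueError("decay_start_epoch must be < epochs")
        if self.loss_split not in ("per_generator", "joint"):
            raise ValueError("loss_split must be 'per_generator' or 'joint'")

    @property
    def weights(self) -> L.LossWeights:
        return L.LossWeights(self.alpha, self.lam, self.eta)


def noise_sigma(epoch: int, cfg: TrainConfig) -> float:
    """Annealed discriminator-noise std: variance v0*(1 - i/epochs)."""
    if not 0 <= epoch <= cfg.epochs:
        raise ValueError("epoch outside the training range")
    var = cfg.noise_variance0 * (1.0 - epoch / cfg.epochs)
    return math.sqrt(max(var, 0.0))


def learning_rate(epoch: int, cfg: TrainConfig) -> float:
    """Constant until the decay start, then linear to zero at the end."""
    if epoch <= cfg.decay_start_epoch:
        return cfg.lr0
    frac = (cfg.epochs - epoch) / (cfg.epochs - cfg.decay_start_epoch)
    return cfg.lr0 * max(frac, 0.0)


def split_dataset(n: int, seed: int, test_frac: float = 0.1,
                  val_frac: float = 0.2
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic (train, val, test) index split.

    ``test_frac`` of the data is held out first; the remainder is split
    (1 - val_frac)/val_frac with the integer remainder going to validation
    (10 volumes -> 1 test / 7 train / 2 val).
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = int(round(test_frac * n))
    rest = n - n_test
    n_train = int((1.0 - val_frac) * rest)
    test = perm[:n_test]
    train = perm[n_test:n_test + n_train]
    val = perm[n_test + n_train:]
    return np.sort(train), np.sort(val), np.sort(test)


def _has_foreground(patch: np.ndarray) -> bool:
    return bool((np.asarray(patch) > 0).any())


def sample_seg_volume(pool: Sequence, rng: np.random.Generator,
                      vessel_bias_prob: float = 0.9,
                      max_retries: int = 100) -> np.ndarray:
    """Vessel-biased draw from the segmentation pool.

    An empty draw is accepted with probability ``1 - vessel_bias_prob``
    and resampled otherwise, up to ``max_retries`` redraws.
    """
    if not len(pool):
        raise ValueError("empty segmentation pool")
    patch = pool[int(rng.integers(len(pool)))]
    for _ in range(max_retries):
        if _has_foreground(getattr(patch, "values", patch)):
            return patch
        if rng.random() >= vessel_bias_prob:
            return patch
        patch = pool[int(rng.integers(len(pool)))]
    return patch


ROTATION_SET = (0.0, 0.5 * np.pi, np.pi, 1.5 * np.pi, 2.0 * np.pi)


def augment(patch: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Lossless rotation about the Z axis, sampled from
    {0, pi/2, pi, 3pi/2, 2pi} (the identity appears twice, as printed in
    the recipe, so it is twice as likely as any other rotation)."""
    angle = ROTATION_SET[int(rng.integers(len(ROTATION_SET)))]
    quarter_turns = int(round(angle / (0.5 * np.pi))) % 4
    return np.rot90(patch, k=quarter_turns, axes=(0, 1)) \
        if quarter_turns else patch


def _random_patch(volume: np.ndarray, shape: Tuple[int, int, int],
                  rng: np.random.Generator) -> np.ndarray:
    starts = []
    for ext, w in zip(volume.shape, shape):
        if ext < w:
            raise ValueError(f"volume extent {ext} smaller than patch {w}")
        starts.append(0 if ext == w else int(rng.integers(ext - w + 1)))
    sx, sy, sz = starts
    return volume[sx:sx + shape[0], sy:sy + shape[1], sz:sz + shape[2]]


class Trainer:
    """Holds the four networks, their optimisers and the loss log."""

    def __init__(self, cfg: TrainConfig | None = None):
        self.cfg = cfg or TrainConfig()
        c = self.cfg
        gcfg = GeneratorConfig(levels=c.gen_levels,
                               base_filters=c.gen_base_filters)
        dcfg = DiscriminatorConfig(base_filters=c.disc_base_filters)
        ss = np.random.SeedSequence(c.seed)
        seeds = ss.generate_state(5)
        self.G = ResUNetGenerator(replace(gcfg, seed=int(seeds[0])))
        self.F = ResUNetGenerator(replace(gcfg, seed=int(seeds[1])))
        self.D_X = PatchGANDiscriminator(replace(dcfg, seed=int(seeds[2])))
        self.D_Y = PatchGANDiscriminator(replace(dcfg, seed=int(seeds[3])))
        self.rng = np.random.default_rng(int(seeds[4]))
        betas = c.adam_moments
        self.opt_g = Adam(self.G.parameters(), c.lr0, betas,
                          clip_norm=c.clip_norm)
        self.opt_f = Adam(self.F.parameters(), c.lr0, betas,
                          clip_norm=c.clip_norm)
        self.opt_dx = Adam(self.D_X.parameters(), c.lr0, betas,
                           clip_norm=c.clip_norm)
        self.opt_dy = Adam(self.D_Y.parameters(), c.lr0, betas,
                           clip_norm=c.clip_norm)
        self.history: List[Dict[str, float]] = []
        self.epoch = 0

    # -- single optimisation step -------------------------------------
    def train_step(self, batch_x: np.ndarray, batch_y: np.ndarray,
                   epoch: Optional[int] = None) -> Dict[str, float]:
        """One update of D_X, D_Y, G and F on a batch of patches.

        ``batch_x``: imaging patches in [-1, 1], shape (N, D, H, W);
        ``batch_y``: segmentation patches in {0, 1}, same shape.
        """
        c = self.cfg
        epoch = self.epoch if epoch is None else epoch
        sigma = noise_sigma(epoch, c) if c.use_disc_noise else 0.0
        lr = learning_rate(epoch, c)
        for opt in (self.opt_g, self.opt_f, self.opt_dx, self.opt_dy):
            opt.lr = lr

        x = Tensor(np.asarray(batch_x, np.float32)[..., None])
        y01 = np.asarray(batch_y, np.float32)[..., None]
        y = Tensor(y01 * 2.0 - 1.0)  # segmentation domain lives in [-1, 1]

        fake_y = self.G(x)
        fake_x = self.F(y)

        # discriminators on detached fakes
        d_y_loss = L.lsgan_d_loss(
            self.D_Y(y, sigma, self.rng),
            self.D_Y(fake_y.detach(), sigma, self.rng))
        d_x_loss = L.lsgan_d_loss(
            self.D_X(x, sigma, self.rng),
            self.D_X(fake_x.detach(), sigma, self.rng))
        (d_y_loss + d_x_loss).backward()
        self.opt_dy.step()
        self.opt_dx.step()
        self._zero_all()

        # generators
        g_adv = L.lsgan_g_loss(self.D_Y(fake_y, sigma, self.rng))
        f_adv = L.lsgan_g_loss(self.D_X(fake_x, sigma, self.rng))
        inner_to_F = fake_y.detach() if c.loss_split == "per_generator" \
            else fake_y
        inner_to_G = fake_x.detach() if c.loss_split == "per_generator" \
            else fake_x
        x_rec = self.F(inner_to_F)
        y_rec = self.G(inner_to_G)
        y_rec01 = L.signed_to_unit(y_rec)
        cyc_l1 = L.cycle_forward_l1(x, x_rec)
        cyc_bce = L.cycle_backward_bce(Tensor(y01), y_rec01)
        zero = Tensor(np.zeros(()))
        rec = L.reconstruction_loss(
            x, x_rec, L.SSIMParams(window_size=c.ssim_window)) \
            if c.use_rec_loss else zero
        topo = L.topology_loss(
            Tensor(y01), y_rec01, c.weights,
            L.SoftSkeletonParams(c.skeleton_iters)) \
            if c.use_topo_loss else zero
        total_g = g_adv + c.lam * cyc_bce + c.eta * topo
        total_f = f_adv + c.lam * cyc_l1 + c.eta * rec
        (total_g + total_f).backward()
        self.opt_g.step()
        self.opt_f.step()
        self._zero_all()

        record = {
            "epoch": float(epoch), "lr": lr, "noise_sigma": sigma,
            "d_x": d_x_loss.item(), "d_y": d_y_loss.item(),
            "g_adv": g_adv.item(), "f_adv": f_adv.item(),
            "cycle_l1": cyc_l1.item(), "cycle_bce": cyc_bce.item(),
            "rec": rec.item(), "topo": topo.item(),
            "total_G": total_g.item(), "total_F": total_f.item(),
        }
        if not all(np.isfinite(v) for v in record.values()):
            raise TrainingDiverged(record)
        self.history.append(record)
        return record

    def _zero_all(self) -> None:
        for net in (self.G, self.F, self.D_X, self.D_Y):
            net.zero_grad()

    # -- batch assembly ------------------------------------------------
    def make_batch(self, imaging: Sequence[np.ndarray],
                   seg: Sequence[np.ndarray]
                   ) -> Tuple[np.ndarray, np.ndarray]:
        c = self.cfg
        xs, ys = [], []
        for _ in range(c.batch_size):
            vol = imaging[int(self.rng.integers(len(imaging)))]
            xs.append(augment(_random_patch(vol, c.patch_shape, self.rng),
                              self.rng).copy())
            pool = _SegPatchPool(seg, c.patch_shape, self.rng)
            pool_patch = sample_seg_volume(pool, self.rng,
                                           c.vessel_bias_prob)
            ys.append(augment(pool_patch, self.rng).copy())
        return np.stack(xs), np.stack(ys)

    # -- full loop ------------------------------------------------------
    def train(self, imaging: Sequence[np.ndarray], seg: Sequence[np.ndarray],
              out_dir: str | Path | None = None,
              val_imaging: Sequence[np.ndarray] | None = None
              ) -> List[Dict[str, float]]:
        """Run ``cfg.epochs`` x ``cfg.steps_per_epoch`` optimisation steps.

        ``imaging``/``seg`` are sequences of 3-D arrays (preprocessed
        volumes and binary masks).  Checkpoints and a JSONL loss log are
        written to ``out_dir`` when given; the checkpoint with the lowest
        validation generator total is kept as ``best.npz``.
        """
        if not len(imaging) or not len(seg):
            raise ValueError("both domains need at least one volume")
        out = Path(out_dir) if out_dir else None
        if out:
            out.mkdir(parents=True, exist_ok=True)
        best_val = np.inf
        for epoch in range(self.epoch, self.cfg.epochs):
            self.epoch = epoch
            for _ in range(self.cfg.steps_per_epoch):
                bx, by = self.make_batch(imaging, seg)
                self.train_step(bx, by, epoch)
            if out:
                self._append_log(out / "losses.jsonl",
                                 self.history[-self.cfg.steps_per_epoch:])
                self.save_checkpoint(out / "last.npz")
                if val_imaging:
                    val = self.validate(val_imaging, seg)
                    if val["total_G"] < best_val:
                        best_val = val["total_G"]
                        self.save_checkpoint(out / "best.npz")
        self.epoch = self.cfg.epochs
        return self.history

    def validate(self, imaging: Sequence[np.ndarray],
                 seg: Sequence[np.ndarray]) -> Dict[str, float]:
        """Loss components on centre crops, without noise or updates."""
        c = self.cfg
        self.G.eval(), self.F.eval(), self.D_X.eval(), self.D_Y.eval()
        recs = []
        rng = np.random.default_rng(c.seed + 1)
        pool = _SegPatchPool(seg, c.patch_shape, rng)
        for vol in imaging:
            x = _center_patch(vol, c.patch_shape)[None, ..., None]
            yv = sample_seg_volume(pool, rng, c.vessel_bias_prob)
            y01 = np.asarray(yv, np.float32)[None, ..., None]
            xt = Tensor(np.asarray(x, np.float32))
            fake_y = self.G(xt)
            x_rec = self.F(fake_y)
            fake_x = self.F(Tensor(y01 * 2 - 1))
            y_rec01 = L.signed_to_unit(self.G(fake_x))
            rec = {
                "cycle_l1": L.cycle_forward_l1(xt, x_rec).item(),
                "cycle_bce": L.cycle_backward_bce(
                    Tensor(y01), y_rec01).item(),
                "g_adv": L.lsgan_g_loss(self.D_Y(fake_y)).item(),
            }
            if c.use_topo_loss:
                rec["topo"] = L.topology_loss(
                    Tensor(y01), y_rec01, c.weights,
                    L.SoftSkeletonParams(c.skeleton_iters)).item()
            else:
                rec["topo"] = 0.0
            rec["total_G"] = rec["g_adv"] + c.lam * rec["cycle_bce"] \
                + c.eta * rec["topo"]
            recs.append(rec)
        self.G.train(), self.F.train(), self.D_X.train(), self.D_Y.train()
        return {k: float(np.mean([r[k] for r in recs])) for k in recs[0]}

    # -- persistence ----------------------------------------------------
    def save_checkpoint(self, path: str | Path) -> None:
        arrays = {}
        for name, net in (("G", self.G), ("F", self.F),
                          ("DX", self.D_X), ("DY", self.D_Y)):
            for k, v in net.state_dict().items():
                arrays[f"{name}/{k}"] = v
        for name, opt in (("G", self.opt_g), ("F", self.opt_f),
                          ("DX", self.opt_dx), ("DY", self.opt_dy)):
            st = opt.state_dict()
            arrays[f"opt_{name}/t"] = np.array(st["t"])
            for i, m in enumerate(st["m"]):
                arrays[f"opt_{name}/m{i}"] = m
            for i, v in enumerate(st["v"]):
                arrays[f"opt_{name}/v{i}"] = v
        arrays["epoch"] = np.array(self.epoch)
        arrays["format_version"] = np.array(1)
        np.savez_compressed(path, **arrays)
        meta = Path(path).with_suffix(".json")
        meta.write_text(json.dumps({"config": asdict(self.cfg),
                                    "epoch": self.epoch}, indent=2))

    def load_checkpoint(self, path: str | Path) -> None:
        data = np.load(path)
        for name, net in (("G", self.G), ("F", self.F),
                          ("DX", self.D_X), ("DY", self.D_Y)):
            prefix = f"{name}/"
            state = {k[len(prefix):]: data[k] for k in data.files
                     if k.startswith(prefix)}
            net.load_state_dict(state)
        for name, opt in (("G", self.opt_g), ("F", self.opt_f),
                          ("DX", self.opt_dx), ("DY", self.opt_dy)):
            n = len(opt.params)
            opt.load_state_dict({
                "t": int(data[f"opt_{name}/t"]),
                "m": [data[f"opt_{name}/m{i}"] for i in range(n)],
                "v": [data[f"opt_{name}/v{i}"] for i in range(n)],
                "lr": opt.lr})
        self.epoch = int(data["epoch"])

    @staticmethod
    def _append_log(path: Path, records: List[Dict[str, float]]) -> None:
        with open(path, "a") as fh:
            for r in records:
                fh.write(json.dumps(r) + "\n")


class _SegPatchPool:
    """Lazily crops random patches from segmentation volumes so the
    vessel-bias resampling rule operates on patches, not whole masks."""

    def __init__(self, volumes: Sequence[np.ndarray],
                 shape: Tuple[int, int, int], rng: np.random.Generator):
        self.volumes = volumes
        self.shape = shape
        self.rng = rng

    def __len__(self) -> int:
        return len(self.volumes)

    def __getitem__(self, idx: int) -> np.ndarray:
        vol = self.volumes[idx]
        vol = getattr(vol, "values", vol)
        return _random_patch(np.asarray(vol), self.shape, self.rng)


def _center_patch(volume: np.ndarray, shape: Tuple[int, int, int]
                  ) -> np.ndarray:
    volume = np.asarray(getattr(volume, "values", volume))
    starts = [(e - w) // 2 for e, w in zip(volume.shape, shape)]
    sx, sy, sz = starts
    return volume[sx:sx + shape[0], sy:sy + shape[1], sz:sz + shape[2]]
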