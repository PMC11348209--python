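"""Scikit-learn style estimators wrapping the training and inference stack.

``VanGanSegmenter`` is the user-facing model: ``fit`` takes *unpaired*
collections of imaging volumes and binary vessel masks and trains the
cycle-consistent adversarial translator; ``predict`` segments new volumes
by sliding-window inference and histogram thresholding.  Being a
``BaseEstimator``, it composes with sklearn model selection and pipelines
(``get_params``/``set_params``/``clone`` all work).

``PAIPreprocessor`` is a stateless transformer applying the imaging-domain
normalisation chain (slice z-score, percentile clip, Z-resample, [-1, 1]
rescale).
"""
from __future__ import annotations

from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .emulator import IntensityVolume3D, preprocess
from .inference import binarize, sliding_window_predict
from .metrics import confusion, seg_metrics
from .nn import Tensor
from .vessel_synth import BinaryMask3D

__all__ = ["VanGanSegmenter", "PAIPreprocessor"]


class PAIPreprocessor(TransformerMixin, BaseEstimator):
    """Imaging-domain normalisation as a transformer.

    Parameters
    ----------
    target_z : depth extent after cubic Z-resampling (network input depth).
    clip_percent : two-sided percentile clip applied after slice z-scoring.
    """

    def __init__(self, target_z: int = 128, clip_percent: float = 0.05):
        self.target_z = target_z
        self.clip_percent = clip_percent

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> List[IntensityVolume3D]:
        single = isinstance(X, (np.ndarray, IntensityVolume3D)) and \
            getattr(X, "ndim", np.asarray(getattr(X, "values", X)).ndim) == 3
        vols = [X] if single else list(X)
        out = [preprocess(v, target_z=self.target_z,
                          clip_percent=self.clip_percent) for v in vols]
        return out[0] if single else out


class VanGanSegmenter(BaseEstimator):
    """Unsupervised 3-D vessel segmenter trained on unpaired volumes/masks.

    Parameters mirror the published recipe (cube patches, residual U-Net
    generators, five-layer PatchGAN discriminators, LSGAN with annealed
    input noise, per-generator cycle losses with lambda=10, eta=5,
    alpha=0.5).  Reduce ``patch_size``, ``levels``, ``base_filters``,
    ``epochs`` and ``steps_per_epoch`` for desk-scale experiments.

    Fitted attributes: ``generator_`` (imaging -> segmentation network),
    ``inverse_generator_``, ``discriminator_x_``, ``discriminator_y_``,
    ``history_`` (per-step loss records) and ``trainer_``.
    """

    def __init__(self, patch_size: int = 128, levels: int = 4,
                 base_filters: int = 16, disc_base_filters: int = 64,
                 epochs: int = 200, steps_per_epoch: int = 100,
                 batch_size: int = 2, lr: float = 2e-4,
                 adam_moments=(0.5, 0.9), decay_start_epoch: int = 100,
                 clip_norm: float = 100.0, noise_variance0: float = 0.1,
                 vessel_bias_prob: float = 0.9, alpha: float = 0.5,
                 lam: float = 10.0, eta: float = 5.0,
                 skeleton_iters: int = 10, ssim_window: int = 11,
                 loss_split: str = "per_generator",
                 use_disc_noise: bool = True, use_rec_loss: bool = True,
                 use_topo_loss: bool = True, stride_xy: int = 25,
                 random_state: int = 0):
        self.patch_size = patch_size
        self.levels = levels
        self.base_filters = base_filters
        self.disc_base_filters = disc_base_filters
        self.epochs = epochs
        self.steps_per_epoch = steps_per_epoch
        self.batch_size = batch_size
        self.lr = lr
        self.adam_moments = adam_moments
        self.decay_start_epoch = decay_start_epoch
        self.clip_norm = clip_norm
        self.noise_variance0 = noise_variance0
        self.vessel_bias_prob = vessel_bias_prob
        self.alpha = alpha
        self.lam = lam
        self.eta = eta
        self.skeleton_iters = skeleton_iters
        self.ssim_window = ssim_window
        self.loss_split = loss_split
        self.use_disc_noise = use_disc_noise
        self.use_rec_loss = use_rec_loss
        self.use_topo_loss = use_topo_loss
        self.stride_xy = stride_xy
        self.random_state = random_state

    # -- config plumbing ----------------------------------------------
    def _train_config(self):
        from .training import TrainConfig

        return TrainConfig(
            epochs=self.epochs, steps_per_epoch=self.steps_per_epoch,
            batch_size=self.batch_size, lr0=self.lr,
            adam_moments=tuple(self.adam_moments),
            decay_start_epoch=min(self.decay_start_epoch, self.epochs - 1),
            clip_norm=self.clip_norm, noise_variance0=self.noise_variance0,
            vessel_bias_prob=self.vessel_bias_prob,
            patch_shape=(self.patch_size,) * 3, gen_levels=self.levels,
            gen_base_filters=self.base_filters,
            disc_base_filters=self.disc_base_filters, alpha=self.alpha,
            lam=self.lam, eta=self.eta, skeleton_iters=self.skeleton_iters,
            ssim_window=self.ssim_window, loss_split=self.loss_split,
            use_disc_noise=self.use_disc_noise,
            use_rec_loss=self.use_rec_loss,
            use_topo_loss=self.use_topo_loss, seed=self.random_state)

    # -- estimator API -------------------------------------------------
    def fit(self, X: Sequence, y: Sequence,
            out_dir: str | Path | None = None) -> "VanGanSegmenter":
        """Train on unpaired imaging volumes ``X`` and vessel masks ``y``.

        ``X``: preprocessed volumes in [-1, 1] (arrays or
        ``IntensityVolume3D``); ``y``: binary masks (arrays or
        ``BinaryMask3D``).  The two collections are never paired during
        training.
        """
        from .training import Trainer

        imaging = [np.asarray(getattr(v, "values", v), np.float32)
                   for v in X]
        seg = [np.asarray(getattr(m, "values", m)) for m in y]
        trainer = Trainer(self._train_config())
        trainer.train(imaging, seg, out_dir=out_dir)
        self.trainer_ = trainer
        self.generator_ = trainer.G
        self.inverse_generator_ = trainer.F
        self.discriminator_x_ = trainer.D_X
        self.discriminator_y_ = trainer.D_Y
        self.history_ = trainer.history
        return self

    def _check_fitted(self):
        if not hasattr(self, "generator_"):
            raise RuntimeError("this VanGanSegmenter instance is not fitted")

    def segment_batch(self, batch: np.ndarray) -> np.ndarray:
        """Raw generator forward: (N, X, Y, Z, 1) in [-1,1] -> same shape."""
        self._check_fitted()
        self.generator_.eval()
        out = self.generator_(Tensor(np.asarray(batch, np.float32))).data
        self.generator_.train()
        return out

    def predict_proba(self, X):
        """Per-voxel vessel probability maps (list, or single map)."""
        self._check_fitted()
        single = getattr(X, "ndim", None) == 3 or \
            isinstance(X, IntensityVolume3D)
        vols = [X] if single else list(X)
        maps = []
        for vol in vols:
            arr = np.asarray(getattr(vol, "values", vol), np.float32)
            normalized = getattr(vol, "normalized", None)
            if normalized is None:
                normalized = arr.shape[2] == self.patch_size \
                    and arr.min() >= -1.0 - 1e-6 and arr.max() <= 1.0 + 1e-6
            if not normalized or arr.shape[2] != self.patch_size:
                arr = preprocess(arr, target_z=self.patch_size).values
            pmap = sliding_window_predict(
                arr, self.segment_batch, window=self.patch_size,
                stride_xy=self.stride_xy)
            maps.append(pmap)
        return maps[0] if single else maps

    def predict(self, X, target_z: Optional[int] = None):
        """Binary segmentation masks via Otsu thresholding of the
        probability maps.  ``target_z`` defaults to each input's depth."""
        single = getattr(X, "ndim", None) == 3 or \
            isinstance(X, IntensityVolume3D)
        vols = [X] if single else list(X)
        masks = []
        for vol in vols:
            arr = np.asarray(getattr(vol, "values", vol))
            pmap = self.predict_proba(vol)
            tz = target_z or arr.shape[2]
            masks.append(binarize(pmap, target_z=tz))
        return masks[0] if single else masks

    def score(self, X, y) -> float:
        """Mean voxelwise F1 of predictions against paired truth masks."""
        masks = self.predict(X)
        if isinstance(masks, BinaryMask3D):
            masks, y = [masks], [y]
        f1 = [seg_metrics(confusion(m.values,
                                    np.asarray(getattr(t, "values", t))))["f1"]
              for m, t in zip(masks, y)]
        return float(np.mean(f1))

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        self._check_fitted()
        import json

        self.trainer_.save_checkpoint(path)
        meta_path = Path(path).with_suffix(".json")
        meta = json.loads(meta_path.read_text())
        meta["estimator"] = {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in self.get_params().items()}
        meta_path.write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "VanGanSegmenter":
        """Rebuild a fitted estimator from a training checkpoint."""
        import json

        from .training import TrainConfig, Trainer

        meta = json.loads(Path(path).with_suffix(".json").read_text())
        raw = meta["config"]
        cfg = TrainConfig(**{k: tuple(v) if isinstance(v, list) else v
                             for k, v in raw.items()})
        if "estimator" in meta:
            params = {k: tuple(v) if isinstance(v, list) else v
                      for k, v in meta["estimator"].items()}
            est = cls(**params)
            trainer = Trainer(cfg)
            trainer.load_checkpoint(path)
            est.trainer_ = trainer
            est.generator_ = trainer.G
            est.inverse_generator_ = trainer.F
            est.discriminator_x_ = trainer.D_X
            est.discriminator_y_ = trainer.D_Y
            est.history_ = trainer.history
            return est
        est = cls(patch_size=cfg.patch_shape[0], levels=cfg.gen_levels,
                  base_filters=cfg.gen_base_filters,
                  disc_base_filters=cfg.disc_base_filters,
                  epochs=cfg.epochs, steps_per_epoch=cfg.steps_per_epoch,
                  batch_size=cfg.batch_size, lr=cfg.lr0,
                  adam_moments=cfg.adam_moments,
                  decay_start_epoch=cfg.decay_start_epoch,
                  clip_norm=cfg.clip_norm,
                  noise_variance0=cfg.noise_variance0,
                  vessel_bias_prob=cfg.vessel_bias_prob, alpha=cfg.alpha,
                  lam=cfg.lam, eta=cfg.eta,
                  skeleton_iters=cfg.skeleton_iters,
                  ssim_window=cfg.ssim_window, loss_split=cfg.loss_split,
                  use_disc_noise=cfg.use_disc_noise,
                  use_rec_loss=cfg.use_rec_loss,
                  use_topo_loss=cfg.use_topo_loss, random_state=cfg.seed)
        trainer = Trainer(cfg)
        trainer.load_checkpoint(path)
        est.trainer_ = trainer
        est.generator_ = trainer.G
        est.inverse_generator_ = trainer.F
        est.discriminator_x_ = trainer.D_X
        est.discriminator_y_ = trainer.D_Y
        est.history_ = trainer.history
        return est
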