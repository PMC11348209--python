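import numpy as np
import pytest

from vangan.emulator import EmulatorParams, emulate_pai, preprocess
from vangan.vessel_synth import LSystemSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_masks():
    """Four reproducible 32-cube vessel masks."""
    spec = LSystemSpec(step_length_um=150, initial_radius_um=45,
                       tortuosity_angle_deg=(0, 4), shrink_prob=0.0,
                       aneurysm_prob=0.0)
    return generate_dataset(4, spec, seed=42, shape=(32, 32, 32),
                            iteration_range=(4, 5))


@pytest.fixture(scope="session")
def small_volumes(small_masks):
    """High-SNR emulated + preprocessed imaging volumes for the masks."""
    params = dict(attenuation_per_mm=0.2, illum_arc_weight=0.0,
                  psf_sigma_vox=0.5, noise_sigma=0.01)
    return [preprocess(emulate_pai(m, EmulatorParams(**params, seed=i)),
                       target_z=32).values
            for i, m in enumerate(small_masks)]


def tiny_train_config(**overrides):
    from vangan.training import TrainConfig

    defaults = dict(epochs=2, steps_per_epoch=1, decay_start_epoch=1,
                    batch_size=1, patch_shape=(16, 16, 16),
                    skeleton_iters=3, ssim_window=7, gen_levels=1,
                    gen_base_filters=4, disc_base_filters=4, seed=0)
    defaults.update(overrides)
    return TrainConfig(**defaults)
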