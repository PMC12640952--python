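import numpy as np
import pytest

from ccperf import AIFParams, PhantomConfig, SectorTruth, build_phantom, make_aif


@pytest.fixture(scope="session")
def times31():
    return np.arange(31.0)


@pytest.fixture(scope="session")
def aif(times31):
    return make_aif(AIFParams(), times31)


@pytest.fixture(scope="session")
def clean_study():
    """Default-geometry study without noise, motion or artifact."""
    return build_phantom(
        PhantomConfig(noise_sd_hu=0.0, motion_amplitude_vox=0), seed=1)


@pytest.fixture(scope="session")
def noisy_study():
    return build_phantom(
        PhantomConfig(noise_sd_hu=20.0, motion_amplitude_vox=0), seed=1)


def small_phantom_config(**overrides):
    """~250 myocardial voxels; fast enough for per-voxel fitting."""
    defaults = dict(grid_shape=(28, 28, 4), voxel_mm=(2.0, 2.0, 4.0),
                    heart_slices=(1, 3), lv_center_frac=(0.5, 0.5),
                    aorta_center_frac=(0.1, 0.1), aorta_radius_mm=5.0,
                    myo_outer_mm=16.0, apex_taper=0.0,
                    noise_sd_hu=0.0, motion_amplitude_vox=0)
    defaults.update(overrides)
    return PhantomConfig(**defaults)


def deficit_config(**overrides):
    """LAD-territory deficit (150) against remote myocardium (300); the
    anterior insertion sits at 300 deg so the deficit covers segments 2/8."""
    defaults = dict(noise_sd_hu=10.0, motion_amplitude_vox=0,
                    septal_angle_deg=300.0,
                    sectors=(SectorTruth(300, 360, 0, 10 ** 6, 150.0, 2.0, 0.15),
                             SectorTruth(0, 300, 0, 10 ** 6, 300.0, 2.0, 0.15)))
    defaults.update(overrides)
    return PhantomConfig(**defaults)
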