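import numpy as np
import pytest

from qsmme.phantom_sim import (attach_fields, build_phantom,
                               default_head_phantom, simulate_gre,
                               sphere_phantom)


@pytest.fixture(scope="session")
def small_head():
    """48-cube head phantom with fields attached (shared, read-only)."""
    spec = default_head_phantom((48, 48, 48), seed=7)
    lv, gt = build_phantom(spec)
    gt = attach_fields(gt, spec, lv)
    return spec, lv, gt


@pytest.fixture(scope="session")
def small_head_gre(small_head):
    spec, lv, gt = small_head
    return simulate_gre(gt, spec, n_repeats=2)


@pytest.fixture(scope="session")
def sphere64():
    """Noiseless 64-cube single-sphere phantom (1 ppm, 4-voxel radius)."""
    spec = sphere_phantom(grid_shape=(64, 64, 64), chi_ppm=1.0,
                          radius_frac=4.0 / 64)
    lv, gt = build_phantom(spec)
    gt = attach_fields(gt, spec, lv)
    return spec, lv, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
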