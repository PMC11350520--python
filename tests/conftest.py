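import numpy as np
import pytest

from nucleoscatter import forward_scattering as fs
from nucleoscatter import nucleus_models as nm


@pytest.fixture(scope="session")
def small_sphere_spec():
    """A small, fast sphere phantom spec (Nyquist-valid voxel)."""
    return nm.NucleusSpec(
        shape="sphere", radius_um=1.5, corr_length_um=0.5, fluct_std=0.02,
        voxel_um=0.14, padding_um=0.7, seed=7,
    )


@pytest.fixture(scope="session")
def small_homog_sphere_volume():
    spec = nm.NucleusSpec(
        shape="sphere", radius_um=2.0, corr_length_um=0.5, fluct_std=0.0,
        voxel_um=0.14, padding_um=0.7, seed=0,
    )
    return nm.build_ri_volume(spec)


@pytest.fixture(scope="session")
def small_born_signal(small_sphere_spec):
    volume = nm.build_ri_volume(small_sphere_spec)
    return fs.born_far_field(volume, 800.0)


def periodic_map(values_181x361: np.ndarray) -> np.ndarray:
    """Force exact phi-periodicity so arrays satisfy the signal contract."""
    out = np.array(values_181x361, dtype=np.float64)
    out[:, -1] = out[:, 0]
    return out
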