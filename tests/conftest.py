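import numpy as np
import pytest

import osteotex as ot


@pytest.fixture(scope="session")
def small_group_kwargs():
    """Reduced annulus geometry for fast cohort runs (~4.8k voxels/specimen)."""
    return dict(outer_radius=16.0, canal_radius=8.0, n_slices=8)


@pytest.fixture(scope="session")
def two_point_histogram():
    """Half the pixels at 0, half at 255."""
    return ot.build_histogram(np.array([0] * 50 + [255] * 50))


@pytest.fixture(scope="session")
def cohort_profiles(small_group_kwargs):
    """Texture profiles of a seeded small two-arm cohort, threshold 1."""
    spec = ot.RoiSpec(mask_threshold=1, length_mm=8 * 9.0 / 1000.0)
    control = ot.control_group_spec(seed=101, **small_group_kwargs)
    treated = ot.low_mg_group_spec(seed=202, **small_group_kwargs)
    vols_a, vols_b = ot.generate_cohort(control, treated)
    profiles_a = [ot.texture_profile(ot.extract_roi_pixels(v, spec)) for v in vols_a]
    profiles_b = [ot.texture_profile(ot.extract_roi_pixels(v, spec)) for v in vols_b]
    return profiles_a, profiles_b
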