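import numpy as np
import pytest

from pvcnet import PSFModel, build_parcellation, render_subject, simulate_acquisition


@pytest.fixture(scope="session")
def small_parcellation():
    """24^3 grid, 3 mm voxels, 5 regions — shared by PVC/quantify tests."""
    return build_parcellation((24, 24, 24), (3.0, 3.0, 3.0), n_regions=5, seed=1)


@pytest.fixture(scope="session")
def psf6():
    return PSFModel(fwhm_mm=6.0)


@pytest.fixture(scope="session")
def small_phantom(small_parcellation):
    """Ground-truth activities, piecewise-constant PET and MR volumes."""
    activities = np.array([1.0, 2.0, 0.5, 1.5, 3.0])
    true_pet, mr = render_subject(small_parcellation, activities)
    return activities, true_pet, mr


@pytest.fixture(scope="session")
def blurred_phantom(small_phantom, psf6):
    _, true_pet, _ = small_phantom
    return simulate_acquisition(true_pet, psf6, noise_sd=0.0)
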