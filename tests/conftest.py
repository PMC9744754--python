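import numpy as np
import pytest

from tractcluster.atlas import ToyAtlasSpec, build_reference_atlas
from tractcluster.signatures import default_signatures
from tractcluster.synthetic import sample_subject


@pytest.fixture(scope="session")
def signatures():
    return default_signatures()


@pytest.fixture(scope="session")
def spec64():
    return ToyAtlasSpec()


@pytest.fixture(scope="session")
def spec32():
    return ToyAtlasSpec(shape=(32, 32))


@pytest.fixture(scope="session")
def atlas_c4(spec64):
    atlas, wm = build_reference_atlas(spec64, "C4")
    return atlas, wm


@pytest.fixture(scope="session")
def merged_atlas_c4():
    spec = ToyAtlasSpec(merge_lf_vf=True)
    atlas, wm = build_reference_atlas(spec, "C4")
    return atlas, wm


@pytest.fixture(scope="session")
def clean_sample_c4(atlas_c4, signatures):
    """Noise-free, undeformed subject: each tract pixel carries its mean."""
    atlas, _ = atlas_c4
    return sample_subject(atlas, signatures, noise_scale=0.0, deform_amplitude=0.0, seed=0)


@pytest.fixture()
def blob_image():
    """Smooth two-blob test image for registration tests."""
    rows, cols = np.mgrid[0:64, 0:64].astype(float)
    return np.exp(-(((rows - 30) / 12) ** 2 + ((cols - 34) / 15) ** 2)) + 0.6 * np.exp(
        -(((rows - 44) / 8) ** 2 + ((cols - 20) / 7) ** 2)
    )
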