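import numpy as np
import pytest

from histocnn.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """Small deterministic cohort: 10 patients x 4 images, 64 px."""
    out = tmp_path_factory.mktemp("cohort")
    spec = CohortSpec(n_patients=10, images_per_patient=4, image_size=(64, 64),
                      separability=1.0, seed=0)
    generate_cohort(spec, out)
    return out


@pytest.fixture(scope="session")
def cohort_manifest(cohort_dir):
    from histocnn.data import load_manifest

    return load_manifest(cohort_dir / "manifest.csv")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
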