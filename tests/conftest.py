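import numpy as np
import pytest

from epifuse.synthetic_fixtures import PhantomSpec, generate_cohort, generate_records, make_atlas

DIMS = (48, 48, 48)


@pytest.fixture(scope="session")
def atlas():
    return make_atlas(DIMS, R=6, seed=0)


@pytest.fixture(scope="session")
def small_spec():
    return PhantomSpec(dims=DIMS, n_ep=4, n_hc=4, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec, atlas):
    """Eight in-memory phantom subjects (4 EP + 4 HC)."""
    records, truth = generate_records(small_spec, atlas)
    return records, truth


@pytest.fixture(scope="session")
def disk_cohort(tmp_path_factory, atlas):
    """A cohort written to disk: (out_dir, manifest, truth)."""
    out = tmp_path_factory.mktemp("cohort")
    spec = PhantomSpec(dims=DIMS, n_ep=3, n_hc=3, seed=5)
    manifest, truth = generate_cohort(spec, atlas, out)
    return out, manifest, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
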