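import numpy as np
import pytest

from cmapaug.phantoms import PhantomSpec, default_phantom_spec, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A miniature paired-modality dataset (8x32x32 volumes, 8+8 patients)
    for fast pipeline tests."""
    out = tmp_path_factory.mktemp("tiny_phantoms")
    spec = PhantomSpec(shape=(8, 32, 32), n_patients=8, seed=1)
    src, tgt = generate_dataset(spec, out)
    return {"spec": spec, "source": src, "target": tgt, "dir": out}


@pytest.fixture(scope="session")
def desk_dataset(tmp_path_factory):
    """The shipped desk-scale phantom cohort (32x64x64, 8+8 patients)."""
    out = tmp_path_factory.mktemp("desk_phantoms")
    spec = default_phantom_spec(seed=0)
    src, tgt = generate_dataset(spec, out)
    return {"spec": spec, "source": src, "target": tgt, "dir": out}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
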