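import numpy as np
import pytest

from hepadose import PhantomSpec, TumourSpec, generate_phantom


@pytest.fixture(scope="session")
def rim_core_spec() -> PhantomSpec:
    """One tumour with a hypervascular rim and a necrotic core, noise-free."""
    return PhantomSpec(
        tumours=(
            TumourSpec(
                centre=(141.0, 141.0, 141.0),
                radius=25.0,
                rim_width=6.0,
                rim_maa_intensity=0.3,
                necrotic_core_radius=10.0,
            ),
        ),
    )


@pytest.fixture(scope="session")
def rim_core_phantom(rim_core_spec):
    """(maa, sc, truth) triple for the rim+core phantom at 1.73 GBq."""
    return generate_phantom(rim_core_spec, administered_gbq=1.73)


@pytest.fixture
def rng():
    return np.random.default_rng(20150428)
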