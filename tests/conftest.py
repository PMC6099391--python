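import numpy as np
import pytest

from codonits import synthetic_data as sd
from codonits import genotyping as gt


@pytest.fixture(scope="session")
def reference() -> str:
    return sd.make_reference(seed=1)


@pytest.fixture(scope="session")
def type_sequences(reference) -> dict[str, str]:
    return {label: sd.render_type_sequence(label, reference)
            for label in gt.TYPE_DEFS}


@pytest.fixture()
def params() -> sd.SimParams:
    return sd.SimParams(seed=11)


@pytest.fixture(scope="session")
def panel():
    return sd.build_specimen_panel(warn_discrepancies=False)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
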