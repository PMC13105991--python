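import numpy as np
import pytest

from ricerisk import load_toxicology, shifted_lognormal, triangular

import reference_values as ref


@pytest.fixture(scope="session")
def toxicology():
    return load_toxicology()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def cd_distribution():
    """The published shifted-lognormal cadmium concentration model (mg/kg)."""
    p = ref.CD_LOGNORMAL
    return shifted_lognormal(p["m"], p["s"], p["tau"])


@pytest.fixture(scope="session")
def intake_distribution():
    """The published triangular rice-intake model (g/day)."""
    p = ref.INTAKE_TRIANGULAR
    return triangular(p["a"], p["c"], p["b"])
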