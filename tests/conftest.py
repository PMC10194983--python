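import numpy as np
import pytest

import mortrend as mt


@pytest.fixture(scope="session")
def eu5_fixture():
    """Noise-free pooled-European series at the reference estimates."""
    return mt.make_reference_fixture("EU5-Model1")


@pytest.fixture(scope="session")
def eu5_ref():
    return mt.reference_fit("EU5-Model1")


@pytest.fixture(scope="session")
def eu5_fit(eu5_fixture, eu5_ref):
    """One shared fit of the noise-free pooled-European fixture."""
    return mt.fit_model(eu5_fixture, eu5_ref.spec)


@pytest.fixture
def toy_series():
    """Tiny hand-checkable three-year series."""
    return mt.MortalitySeries(
        year=np.array([1950, 1951, 1952]),
        births=np.array([1000, 2000, 1500]),
        deaths=np.array([10, 30, 12]),
    )


def make_series(years, births, deaths):
    return mt.MortalitySeries(year=np.asarray(years), births=np.asarray(births),
                              deaths=np.asarray(deaths))
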