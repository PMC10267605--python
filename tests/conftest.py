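import numpy as np
import pytest

from indirect_ri import BoxCoxGaussian, MeasurementSeries
from indirect_ri.synthetic import SyntheticSpec, generate


def gaussian_spec(n=100_000, seed=7, mu=99.0, sigma=10.0):
    """Zero-contamination population, Gaussian on the original scale up
    to the +1 shift of the lam=1 transform (x = y + 1 ~ N(mu+1, sigma))."""
    return SyntheticSpec(
        healthy=BoxCoxGaussian(lam=1.0, mu=mu, sigma=sigma),
        frac_patho_low=0.0,
        frac_patho_high=0.0,
        patho_low=None,
        patho_high=None,
        n=n,
        decimals=1,
        seed=seed,
        analyte_name="SYN",
        unit="U",
    )


@pytest.fixture(scope="session")
def gaussian_series():
    """One large clean dataset shared by recovery tests."""
    series, truth = generate(gaussian_spec())
    return series, truth


def make_series(values, decimals=1, analyte="SYN", unit="U"):
    return MeasurementSeries(
        analyte_name=analyte, unit=unit,
        values=np.asarray(values, dtype=float), decimals=decimals,
    )
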