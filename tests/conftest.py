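import numpy as np
import pytest

from elebench import SimulationSpec, generate_stable_density_training
from elebench.growth import CountTimeSeries


@pytest.fixture(scope="session")
def training18():
    """One 18-row stable-density training set with NB scatter."""
    spec = SimulationSpec(seed=42)
    tr, surface = generate_stable_density_training(spec)
    return tr, surface


@pytest.fixture(scope="session")
def training60():
    """Larger, lower-noise training set for fits that need a clear signal."""
    spec = SimulationSpec(seed=43, nb_dispersion=50.0)
    tr, surface = generate_stable_density_training(spec, n_train=60)
    return tr, surface


def make_series(densities, area_km2=1000.0, start_year=1995, ses=None,
                reliability="A", area_id="X"):
    densities = np.asarray(densities, dtype=float)
    n = len(densities)
    est = densities * area_km2
    return CountTimeSeries(
        area_id=area_id,
        years=np.arange(start_year, start_year + n, dtype=float),
        estimates=est,
        ses=np.zeros(n) if ses is None else np.asarray(ses, dtype=float),
        reliabilities=np.array([reliability] * n, dtype=object),
        area_km2=area_km2,
    )


@pytest.fixture
def series_factory():
    return make_series
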