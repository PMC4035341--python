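import numpy as np
import pytest

from salmosurv.series import AgeComposition, AnnualSeries
from salmosurv.simulate import default_config, simulate_population


@pytest.fixture
def chinook_comp():
    """A fully observed age-3..5 composition over 1980-1995."""
    props = {y: {3: 0.2, 4: 0.5, 5: 0.3} for y in range(1980, 1996)}
    return AgeComposition(taxon="chinook", age_range=(3, 5),
                          proportions=props)


@pytest.fixture
def spawners_1980_1995():
    rng = np.random.default_rng(42)
    return AnnualSeries(
        name="spawners", unit="fish",
        values={y: float(v) for y, v in
                zip(range(1980, 1996), rng.uniform(100, 2000, 16))})


@pytest.fixture(scope="session")
def default_simulation():
    """One default-scenario simulation shared across read-only tests."""
    return simulate_population(default_config(seed=11))
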