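import numpy as np
import pandas as pd
import pytest

from seiszoo.synthetic import (
    ApproachScenario,
    LayerResponse,
    LayerScenario,
    gen_approach_track,
)


@pytest.fixture(scope="session")
def full_track() -> pd.DataFrame:
    """Track of a complete 10 km approach at 4.5 knots."""
    return gen_approach_track(ApproachScenario())


@pytest.fixture()
def short_approach() -> ApproachScenario:
    """A 30 s excerpt of the default approach (keeps audio synthesis cheap)."""
    return ApproachScenario(duration=30.0, seed=7)


@pytest.fixture()
def quiet_layer() -> LayerScenario:
    """Noise-free stationary Gaussian layer: mean 25 m, sd 5 m."""
    return LayerScenario(noise_sd_db=0.0)


def make_layer(seed=0, inertia_slope=0.0, cm_slope=0.0, noise_db=3.0):
    return LayerScenario(
        noise_sd_db=noise_db,
        response=LayerResponse(cm_slope_m_per_km=cm_slope,
                               inertia_slope_m2_per_km=inertia_slope),
        seed=seed,
    )
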