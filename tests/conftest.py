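import warnings

import numpy as np
import pytest

from chillgrid import (GridSpec, WeatherGenConfig, generate_baseline,
                       seasonal_totals)

# incomplete-season warnings are expected all over these fixtures
warnings.filterwarnings("ignore", message=".*not fully covered by data.*")


@pytest.fixture(scope="session")
def single_site_grid() -> GridSpec:
    return GridSpec([40.0], [-8.0])


@pytest.fixture(scope="session")
def small_grid() -> GridSpec:
    return GridSpec(np.linspace(37.0, 42.0, 3), np.linspace(-9.0, -7.0, 3))


@pytest.fixture(scope="session")
def baseline_site(single_site_grid):
    """Six years of noisy single-site weather (fixed seed)."""
    cfg = WeatherGenConfig(grid=single_site_grid, year_start=1989,
                           year_end=1994, noise_sd=2.0, seed=11)
    return generate_baseline(cfg)


@pytest.fixture(scope="session")
def site_totals(baseline_site):
    """CP and GDH seasonal totals for the single-site fixture."""
    return {"CP": seasonal_totals(baseline_site, "chill"),
            "GDH": seasonal_totals(baseline_site, "forcing")}
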