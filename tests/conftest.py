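import numpy as np
import pytest

from titrascreen import titration as ti
from titrascreen import synthetic_data as syn


@pytest.fixture(scope="session")
def config() -> ti.ScreenConfig:
    return ti.ScreenConfig()


@pytest.fixture(scope="session")
def reference_screen(config):
    """Noiseless reference-screen scenario run once for the whole session."""
    scenario = syn.reference_screen_scenario()
    peaklists, truth = syn.generate_titration(scenario, config)
    series = ti.build_series(peaklists, config)
    records = [
        ti.classify_group(s, ti.compute_csp(s, config), config) for s in series
    ]
    return {
        "scenario": scenario,
        "peaklists": peaklists,
        "truth": truth,
        "series": series,
        "records": records,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20150811)
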