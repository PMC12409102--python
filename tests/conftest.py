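import warnings

import pytest

from leafquanta import fluor_core
from leafquanta.synthetic_canopy import SyntheticConfig, simulate_campaign


@pytest.fixture(scope="session")
def small_config():
    """A reduced campaign (fast) keeping the full two-season structure."""
    return SyntheticConfig(seed=11, n_trees_per_stratum=10, leaves_per_branch=3)


@pytest.fixture(scope="session")
def small_campaign(small_config):
    return simulate_campaign(small_config, with_truth=True)


@pytest.fixture(scope="session")
def default_campaign_kept():
    """One full-size campaign with yields computed and QC applied."""
    df = fluor_core.add_yields(simulate_campaign(SyntheticConfig(seed=3)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept, _ = fluor_core.qc_filter(df)
    return kept
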