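import numpy as np
import pandas as pd
import pytest

from metasucc import data, simulate

#: master seed for the paper-like synthetic landscape used across the suite
MASTER_SEED = 1


@pytest.fixture(scope="session")
def paper_like():
    """One paper-like synthetic landscape shared by the whole session."""
    stems, sites, traits = simulate.generate_metacommunity(seed=MASTER_SEED)
    return stems, sites, traits


@pytest.fixture(scope="session")
def schemes(paper_like):
    _, sites, _ = paper_like
    return (data.assign_classes(sites, "sba"), data.assign_classes(sites, "age"))


@pytest.fixture()
def toy_stems():
    """Two sites x two plots with hand-countable composition."""
    rows = [
        # site A, upper: 3x SP1 saplings; lower: 2x SP1, 1x SP2
        *[dict(site_id="A", plot_id="upper", species_code="SP1",
               stratum="sapling", life_form="tree", diameter_cm=2.0)] * 3,
        *[dict(site_id="A", plot_id="lower", species_code="SP1",
               stratum="sapling", life_form="tree", diameter_cm=3.0)] * 2,
        dict(site_id="A", plot_id="lower", species_code="SP2",
             stratum="sapling", life_form="shrub", diameter_cm=1.5),
        # site B: one tree, one liana, one seedling
        dict(site_id="B", plot_id="upper", species_code="SP2",
             stratum="tree", life_form="tree", diameter_cm=7.1),
        dict(site_id="B", plot_id="lower", species_code="SP3",
             stratum="liana", life_form="liana", diameter_cm=1.3),
        dict(site_id="B", plot_id="upper", species_code="SP1",
             stratum="seedling", life_form="tree", diameter_cm=np.nan),
    ]
    return pd.DataFrame(rows)


@pytest.fixture()
def toy_sites():
    return pd.DataFrame({
        "site_id": ["A", "B"], "age_y": [5, 25], "sba_m2ha": [8.0, 24.0],
        "x_m": [0.0, 100.0], "y_m": [0.0, 0.0],
    }).set_index("site_id", drop=False)
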