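import pytest

from ptxmap.formats_io import MAP_COLUMNS
from ptxmap.simulate import SimConfig, simulate_cross


@pytest.fixture(scope="session")
def small_cross():
    """Three-LG cross at reduced size, with missingness and error."""
    cfg = SimConfig(n_progeny=150, lg_lengths=(100.0, 80.0, 60.0),
                    n_markers=450, missing_rate=0.05, error_rate=0.005,
                    seed=7)
    return simulate_cross(cfg)


@pytest.fixture(scope="session")
def clean_cross():
    """Two-LG cross with no missing data and no genotyping error."""
    cfg = SimConfig(n_progeny=200, lg_lengths=(90.0, 70.0), n_markers=300,
                    missing_rate=0.0, error_rate=0.0, seed=13)
    return simulate_cross(cfg)


def true_map_table(truth):
    """Map table built from simulation truth (positions in cM)."""
    mt = truth.markers.rename(columns={"cm": "position"}).copy()
    mt["bin_id"] = mt["pos_index"] + 1
    return mt[MAP_COLUMNS].reset_index(drop=True)


@pytest.fixture(scope="session")
def small_true_map(small_cross):
    return true_map_table(small_cross[1])
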