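"""Shared fixtures: published embedding-parameter tables and tiny datasets."""

import numpy as np
import pytest

from hydrorqa import SimConfig, Coupling, generate

STATIONS = ("ST1", "ST2", "ST3")
FACTORS = ("Do", "Chl", "Turb", "Bga", "Tds", "DoP", "Temp", "pH")

# Published per-series embedding fits from the motivating three-station
# coastal deployment: dimension and delay per (station, factor), and the
# published best-match parameters of each series paired with pH at ST1.
DIMENSIONS = {
    "ST1": (5, 8, 6, 5, 6, 5, 5, 6),
    "ST2": (4, 9, 8, 8, 7, 6, 5, 6),
    "ST3": (4, 7, 15, 17, 7, 5, 6, 5),
}
DELAYS = {
    "ST1": (18, 28, 42, 22, 19, 14, 14, 9),
    "ST2": (22, 18, 22, 22, 35, 15, 15, 18),
    "ST3": (13, 15, 24, 24, 20, 21, 26, 18),
}
BEST_MATCH_VS_PH_ST1 = {
    "ST1": ("6/9", "8/9", "6/9", "6/9", "6/9", "6/9", "6/9", "6/9"),
    "ST2": ("6/9", "9/9", "8/9", "8/9", "7/9", "6/9", "6/9", "6/9"),
    "ST3": ("6/9", "7/9", "15/9", "17/9", "7/9", "6/9", "6/9", "6/9"),
}


@pytest.fixture(scope="session")
def published_params():
    return {
        st: {
            f: (DIMENSIONS[st][k], DELAYS[st][k]) for k, f in enumerate(FACTORS)
        }
        for st in STATIONS
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20230419)


@pytest.fixture(scope="session")
def small_dataset():
    """2 stations x 3 factors x 600 samples with one cross-station coupling."""
    cfg = SimConfig(
        n_stations=2,
        factors=("Do", "Temp", "pH"),
        n_samples=600,
        couplings=(
            Coupling(("ST1", "pH"), ("ST2", "pH"), 0.8, 4),
            Coupling(("ST1", "Temp"), ("ST1", "pH"), 0.5, 0),
        ),
        seed=7,
    )
    return generate(cfg)
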