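import warnings

import numpy as np
import pandas as pd
import pytest

from imdkit import simulate as sim
from imdkit.geometry import DeviceLayout


@pytest.fixture(autouse=True)
def _silence_expected_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="no .* low region")
        warnings.filterwarnings("ignore", message="no .*-positive cells")
        yield


@pytest.fixture(scope="session")
def small_layout():
    """Two condition reservoirs + two empty controls, well separated."""
    return DeviceLayout.from_records(
        "dev0",
        [
            (1, 1300.0, 1300.0, "drugA", False),
            (2, 3800.0, 1300.0, "drugA", False),
            (3, 1300.0, 3800.0, "empty", True),
            (4, 3800.0, 3800.0, "empty", True),
        ],
    )


@pytest.fixture(scope="session")
def arg_cd8_experiment():
    sc = sim.perturbation_scenario("ARG_CD8", seed=42, n_tumors=3)
    return sim.gen_experiment(sc)


@pytest.fixture(scope="session")
def cd8_hotspot_section():
    sc = sim.metabolomics_scenario("CD8_HOTSPOT", seed=3)
    return sim.gen_ion_image(sc)


@pytest.fixture(scope="session")
def st_cohort():
    return sim.gen_st_rois(sim.st_scenario(seed=7))


def random_cells(rng, n, bounds, marker="CD8"):
    xmin, ymin, xmax, ymax = bounds
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x": rng.uniform(xmin, xmax, n),
            "y": rng.uniform(ymin, ymax, n),
            "tumor_id": "t0",
            "CD3": True,
            "CD8": marker == "CD8",
            "FOXP3": marker == "FOXP3",
            "nucleus": True,
        }
    )
    return df
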