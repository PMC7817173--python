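import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from clonedyn import io as cio
from clonedyn import simulator as sim

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rosette_cells() -> pd.DataFrame:
    """7-cell hexagonal clone with its untransduced neighbour ring."""
    return cio.make_fixtures("clone_cells")


@pytest.fixture(scope="session")
def cfi_events() -> pd.DataFrame:
    """Deterministic event table at the measured fate frequencies."""
    return cio.make_fixtures("cfi_events")


def hex_disc_cells(k: int, spacing: float = 10.0) -> pd.DataFrame:
    """Compact hexagonal disc clone of radius k (3k^2+3k+1 cells)."""
    rows = []
    i = 0
    for q in range(-k, k + 1):
        for r in range(-k, k + 1):
            if sim.hex_distance((q, r)) > k:
                continue
            x, y = sim.axial_to_xy((q, r), spacing)
            rows.append(
                {
                    "animal_id": "a1", "clone_id": "c1", "cell_id": f"d{i}",
                    "x_um": x, "y_um": y, "layer": "basal",
                    "genotype": "HrasG12V", "edu": 0, "brdu": 0, "k10": 0,
                }
            )
            i += 1
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def random_cell_table() -> pd.DataFrame:
    """A scattered field of basal cells with one blob-shaped clone inside."""
    rng = np.random.default_rng(7)
    n_bg = 150
    xy_bg = rng.uniform(0, 300, size=(n_bg, 2))
    rows = [
        {
            "animal_id": "a1", "clone_id": "", "cell_id": f"w{i}",
            "x_um": float(x), "y_um": float(y), "layer": "basal",
            "genotype": "WT", "edu": 0, "brdu": 0, "k10": 0,
        }
        for i, (x, y) in enumerate(xy_bg)
    ]
    xy_clone = rng.normal(loc=150, scale=18, size=(40, 2))
    rows += [
        {
            "animal_id": "a1", "clone_id": "c1", "cell_id": f"m{i}",
            "x_um": float(x), "y_um": float(y), "layer": "basal",
            "genotype": "HrasG12V", "edu": 0, "brdu": 0, "k10": 0,
        }
        for i, (x, y) in enumerate(xy_clone)
    ]
    return pd.DataFrame(rows)
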