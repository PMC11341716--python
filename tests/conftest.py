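import numpy as np
import pandas as pd
import pytest

from depthzone import SimulationConfig, generate_community
from depthzone.obsdata import AbundanceMatrix


@pytest.fixture
def tiny_obs() -> pd.DataFrame:
    """Hand-written observation table: 2 sites, a few dives and species."""
    rows = [
        # site, dive, depth, species, genus, family, count
        ("A", "d1", 41.0, "Sparus alpha", "Sparus", "Fam1", 2),
        ("A", "d1", 48.0, "Sparus alpha", "Sparus", "Fam1", 3),
        ("A", "d2", 55.0, "Sparus beta", "Sparus", "Fam1", 4),
        ("A", "d2", 62.0, "Gobius gamma", "Gobius", "Fam2", 1),
        ("A", "d3", 75.0, "Gobius gamma", "Gobius", "Fam2", 6),
        ("B", "d4", 43.0, "Sparus alpha", "Sparus", "Fam1", 1),
        ("B", "d4", 90.0, "Gobius delta", "Gobius", "Fam2", 2),
        ("B", "d5", 95.0, "Gobius delta", "Gobius", "Fam2", 5),
    ]
    return pd.DataFrame(
        rows, columns=["site", "dive_id", "depth_m", "species", "genus", "family", "count"]
    )


@pytest.fixture
def tiny_effort() -> pd.DataFrame:
    rows = []
    for b in range(40, 100, 10):
        rows.append({"site": "A", "depth_bin": b, "hours": 2.0})
        rows.append({"site": "B", "depth_bin": b, "hours": 1.0 + b / 100.0})
    return pd.DataFrame(rows)


def make_matrix(values, bins=None, site="A", species=None, transforms=()) -> AbundanceMatrix:
    """Build an AbundanceMatrix from a plain 2-D list."""
    arr = np.asarray(values, dtype=float)
    bins = list(bins) if bins is not None else [40 + 10 * i for i in range(len(arr))]
    species = list(species) if species is not None else [f"sp{j}" for j in range(arr.shape[1])]
    labels = [f"{site}:{b}" for b in bins]
    data = pd.DataFrame(arr, index=labels, columns=species)
    meta = pd.DataFrame({"site": site, "depth_bin": bins, "bins": [(b,) for b in bins]},
                        index=labels)
    return AbundanceMatrix(data=data, sample_meta=meta, transforms=list(transforms))


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic survey shared across read-only tests."""
    return generate_community(SimulationConfig(seed=11))
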