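import numpy as np
import pandas as pd
import pytest
from scipy.stats import special_ortho_group

from mutcycle.synthetic_data import build_synthetic_pentamer, default_pentamer_rings


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def pentamer():
    """Default C5-symmetric toy pentamer (pore-lining-bundle-like)."""
    return build_synthetic_pentamer(default_pentamer_rings())


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return special_ortho_group.rvs(3, random_state=rng)


def aligned_coords(structure) -> np.ndarray:
    """Coordinates sorted by atom identity, for order-independent comparison."""
    df = structure.atoms.sort_values(["chain", "resnum", "atom"]).reset_index(drop=True)
    return df[["x", "y", "z"]].to_numpy(float)
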