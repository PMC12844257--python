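import numpy as np
import pytest

from clickscreen import chem
from clickscreen.simulate import building_block_pool
from clickscreen.tsa import MeltCurve, boltzmann

TEMPS = np.arange(25.0, 95.01, 0.5)


@pytest.fixture(scope="session")
def pool():
    return building_block_pool()


@pytest.fixture(scope="session")
def small_design(pool):
    """A tiny validated 2x2x2 design with sulfonamide-carrying alkynes."""
    azides = [
        chem.validate_building_block(s, "azide", set_label="1", index=i + 1)
        for i, s in enumerate(pool["azide"][:2])
    ]
    alkynes = [
        chem.validate_building_block(s, "alkyne", set_label="2", index=j + 1)
        for j, s in enumerate(pool["alkyne_sulfonamide"][:2])
    ]
    acids = [
        chem.validate_building_block(s, "acid", set_label="3", index=k + 1)
        for k, s in enumerate(pool["acid"][:2])
    ]
    return chem.LibraryDesign("4", azides, alkynes, acids)


def make_melt_curve(tm=55.0, noise_sd=0.0, seed=0, amp=1.0, base=0.1, slope=1.2):
    rng = np.random.default_rng(seed)
    f = boltzmann(TEMPS, base, amp, tm, slope) + noise_sd * rng.standard_normal(TEMPS.size)
    return MeltCurve("P1", "W01", "c1", "sample", TEMPS, f)
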