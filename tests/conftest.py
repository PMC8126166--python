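import numpy as np
import pytest

from endocharge import (
    TitrationOptions,
    charge_curve,
    default_grid,
    get_builtin,
    repeats,
)
from endocharge.protonation import get_table


@pytest.fixture(scope="session")
def opts():
    """Default titration options pinned to the calibrated table."""
    return TitrationOptions(pka_table=get_table("protcalc_like"))


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def fixture_curves(opts, grid):
    """(E3 curve, E4 curve, [RP1..RP7 curves]) on the standard grid."""
    e3 = charge_curve(get_builtin("R112C_E3"), grid, opts)
    e4 = charge_curve(get_builtin("R112C_E4"), grid, opts)
    reps = [charge_curve(r, grid, opts) for r in repeats()]
    return e3, e4, reps


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210510)
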