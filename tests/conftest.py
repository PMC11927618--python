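import numpy as np
import pytest

from memfp.msd_models import (
    make_bidiffusive,
    make_brownian,
    make_powerlaw,
    make_rouse_monomer_msd,
    make_viscoelastic,
)


@pytest.fixture(scope="session")
def model_zoo():
    """One representative of each shipped MSD family."""
    return {
        "brownian": make_brownian(0.5),
        "fbm_sub": make_powerlaw(1.0, 0.4),
        "fbm_super": make_powerlaw(1.0, 0.6),
        "bidiffusive": make_bidiffusive(10.0),
        "viscoelastic": make_viscoelastic(1.0, 3.0, 0.5),
        "rouse": make_rouse_monomer_msd(80),
    }


@pytest.fixture(scope="session")
def brownian_solution():
    """Solver output for the Brownian reference problem (reused across tests)."""
    from memfp.theory1d import SplittingProblem1D, solve_splitting_1d

    prob = SplittingProblem1D(make_brownian(0.5), 0.3, 1.0)
    return prob, solve_splitting_1d(prob)


@pytest.fixture(scope="session")
def fbm_sub_solution():
    """Converged subdiffusive fBM solution at the reference geometry x0/L = 0.208."""
    from memfp.msd_models import make_powerlaw
    from memfp.theory1d import SplittingProblem1D, solve_splitting_1d

    prob = SplittingProblem1D(make_powerlaw(1.0, 0.4), 0.208, 1.0)
    return prob, solve_splitting_1d(prob)
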