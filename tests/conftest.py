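import numpy as np
import pytest

from morphoscar import ParameterSet, NumericsConfig, simulate


@pytest.fixture
def default_params():
    return ParameterSet()


@pytest.fixture
def coarse_cfg():
    """Cheap numerics for structural tests (not converged, but stable)."""
    return NumericsConfig(n_elements=60, dt=0.5, dt_early=0.25, t_early=2.0,
                          t_end=10.0, grading=2.0)


@pytest.fixture(scope="session")
def full_default_run():
    """The production-resolution healing-year run at the adult mean
    parameter set; shared across tests because it takes ~1 min."""
    return simulate(ParameterSet(), NumericsConfig())


@pytest.fixture(scope="session")
def coarse_year_run():
    """A coarse full-year default run for qualitative-shape tests."""
    cfg = NumericsConfig(n_elements=100, dt=0.5, dt_early=0.1)
    return simulate(ParameterSet(), cfg)


def unwounded_params():
    """Wound values equal to the healthy equilibrium: nothing happens."""
    p = ParameterSet()
    return p.replace(N_tilde=p.N_bar, c_tilde=0.0, rho_tilde=p.rho_bar)
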