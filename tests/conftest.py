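"""Shared fixtures: the packaged reference epithelium and its solved states.

Expensive steady states and protocol runs are session-scoped so the suite
solves each of them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import proxtubule as pt
from proxtubule.flux_laws import compute_fluxes
from proxtubule.solver import SolverSettings, solve_steady_state


@pytest.fixture(scope="session")
def constants():
    return pt.PhysicalConstants()


@pytest.fixture(scope="session")
def ref_params():
    return pt.reference_parameters()


@pytest.fixture(scope="session")
def settings():
    return SolverSettings()


@pytest.fixture(scope="session")
def steady_1mm(ref_params):
    """Reference steady state at 1 mM bilateral glucose (pre-step state of
    the glucose-step experiment)."""
    baths = ref_params.baths.with_glucose(1.0)
    state = solve_steady_state(ref_params, baths)
    return state, compute_fluxes(state, ref_params, baths), baths


@pytest.fixture(scope="session")
def steady_6mm(ref_params):
    """Reference steady state at 6 mM bilateral glucose."""
    baths = ref_params.baths
    state = solve_steady_state(ref_params, baths)
    return state, compute_fluxes(state, ref_params, baths), baths


@pytest.fixture(scope="session")
def isosmotic_tuning(ref_params):
    """Serosal-recirculation tuning result at the reference bath."""
    from proxtubule.protocols import tune_isosmotic_recirculation

    k, result = tune_isosmotic_recirculation(ref_params, tolerance_mosm=0.1)
    return k, result


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
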