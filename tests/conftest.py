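"""Shared fixtures: coarse desk-scale grid and reference runs.

Expensive session-scoped artefacts (the coarse reference trajectory and
the +/-10% screening campaign) are computed once and shared between the
behavioural and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import svzsim as sv


@pytest.fixture(scope="session")
def ref_params() -> sv.ModelParameters:
    return sv.reference_parameters()


@pytest.fixture(scope="session")
def coarse_spec_fx() -> sv.DomainSpec:
    return sv.coarse_spec(h=0.1)


@pytest.fixture(scope="session")
def coarse_grid(coarse_spec_fx) -> sv.Grid:
    return sv.build_grid(coarse_spec_fx)


@pytest.fixture(scope="session")
def coarse_system(coarse_grid) -> sv.System:
    return sv.System(coarse_grid)


@pytest.fixture(scope="session")
def coarse_config() -> sv.NumericsConfig:
    return sv.NumericsConfig(t_final=100.0, save_every=1.0)


@pytest.fixture(scope="session")
def ref_run_coarse(ref_params, coarse_spec_fx, coarse_config, coarse_grid,
                   coarse_system) -> sv.SimulationResult:
    """Reference parameter set on the coarse fixture grid, 100 days."""
    res = sv.run_simulation(ref_params, coarse_spec_fx, coarse_config,
                            grid=coarse_grid, system=coarse_system)
    assert not res.failure_flag
    return res


@pytest.fixture(scope="session")
def ref_run_long(ref_params, coarse_spec_fx, coarse_grid, coarse_system
                 ) -> sv.SimulationResult:
    """Reference set over the full 300-day horizon (coarse grid)."""
    config = sv.NumericsConfig(t_final=300.0, save_every=1.0)
    res = sv.run_simulation(ref_params, coarse_spec_fx, config,
                            grid=coarse_grid, system=coarse_system)
    assert not res.failure_flag
    return res


@pytest.fixture(scope="session")
def perturbation_campaign(ref_params, coarse_spec_fx, coarse_config,
                          ref_run_coarse):
    """200 seeded +/-10% perturbations of the reference set, screened on
    the coarse grid with zeta^2 recorded against the reference run."""
    samples = sv.perturb_parameters(ref_params, 0.1, 200, seed=20120193)
    summary = sv.screen(samples, coarse_spec_fx, coarse_config,
                        reference_result=ref_run_coarse)
    return samples, summary
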