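"""Shared fixtures: verification geometries, a converged circulation run and
the full four-scenario experiment (computed once per session)."""

import numpy as np
import pytest

from laaoflow.domain import DomainConfig, build_domain, channel_domain, steady_flux_program
from laaoflow.lpm import apply_scenario, default_baseline, simulate_lpm
from laaoflow.solver import FlowField, FluidProps, ResidualHistory, solve_flow

#: viscous test fluid: 10x blood viscosity so channel flows develop quickly
CHANNEL_FLUID = FluidProps(density=1060.0, dynamic_viscosity=0.035)


@pytest.fixture(scope="session")
def channel():
    return channel_domain(length=60.0, height=10.0, spacing=0.5, depth=10.0)


@pytest.fixture(scope="session")
def channel_field(channel):
    """Steady developed channel flow, mean velocity 5 mm/s."""
    # Q = 5 mm/s * 10 mm * 10 mm = 0.5 mL/s
    return solve_flow(channel, steady_flux_program(0.5), CHANNEL_FLUID,
                      n_cycles=3, dt=0.001, n_init_cycles=1, store_per_cycle=10)


@pytest.fixture(scope="session")
def sr_waves_session():
    return simulate_lpm(apply_scenario(default_baseline(), "SR-LAA"), n_cycles=120)


@pytest.fixture(scope="session")
def short_scenario_field(sr_waves_session):
    """A 4-cycle pulsatile run on the default domain (cheap solver checks)."""
    from laaoflow.domain import make_flux_program

    dom = build_domain(DomainConfig(mode="2d"))
    flux = make_flux_program(sr_waves_session, dom)
    field = solve_flow(dom, flux, FluidProps(), n_cycles=4, dt=0.001,
                       n_init_cycles=1)
    return dom, flux, field


@pytest.fixture(scope="session")
def four_runs():
    """The default four-scenario experiment (the expensive fixture)."""
    from laaoflow.pipeline import run_four_scenarios

    reports, table = run_four_scenarios()
    return reports, table


def make_field(domain, u_snaps, v_snaps, cycle_length=1.0, n_cycles=None,
               n_init_cycles=0, fluid=None) -> FlowField:
    """Fabricate a FlowField from explicit MAC snapshots (metrics tests)."""
    u = np.asarray(u_snaps, dtype=float)
    v = np.asarray(v_snaps, dtype=float)
    n = u.shape[0]
    if n_cycles is None:
        n_cycles = n
    spc = n // n_cycles
    times = (np.arange(n) + 1) * (cycle_length / spc)
    hist = ResidualHistory(time=times, continuity=np.zeros(n),
                           momentum_x=np.zeros(n), momentum_y=np.zeros(n))
    return FlowField(times=times, u=u, v=v, domain=domain,
                     fluid=fluid or FluidProps(), dt=cycle_length / spc,
                     cycle_length=cycle_length, n_cycles=n_cycles,
                     n_init_cycles=n_init_cycles, store_per_cycle=spc,
                     residuals=hist)


def uniform_u_field(domain, speeds, **kw):
    """Snapshots with uniform x-velocity per snapshot (v = 0 everywhere)."""
    nx, ny = domain.labels.shape
    u = np.stack([np.full((nx + 1, ny), s, dtype=float) for s in speeds])
    v = np.zeros((len(speeds), nx, ny + 1))
    return make_field(domain, u, v, **kw)
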