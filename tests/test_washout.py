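"""Tests for the virtual-ink washout and residence bookkeeping."""

import numpy as np
import pytest

from laaoflow.domain import DomainConfig, build_domain, channel_domain, steady_flux_program
from laaoflow.errors import ParameterError
from laaoflow.solver import solve_flow
from laaoflow.washout import laa_residence, old_blood_fraction, transport_ink

from conftest import CHANNEL_FLUID, make_field, uniform_u_field


@pytest.fixture(scope="module")
def washout_channel():
    return channel_domain(length=60.0, height=10.0, spacing=1.0, depth=10.0)


@pytest.fixture(scope="module")
def washout_channel_field(washout_channel):
    """Steady 2 mL/s channel flow: turnover time V/Q = 3 s = 3 cycles."""
    return solve_flow(washout_channel, steady_flux_program(2.0, duration=1.0),
                      CHANNEL_FLUID, n_cycles=8, dt=0.001, n_init_cycles=2,
                      store_per_cycle=20)


class TestTransport:
    def test_zero_flow_keeps_concentration_zero(self, washout_channel):
        field = uniform_u_field(washout_channel, [0.0] * 4, n_cycles=2)
        ink = transport_ink(field, washout_channel, n_cycles=2, start_cycle=0)
        assert np.all(ink.conc == 0.0)
        assert old_blood_fraction(ink, washout_channel, "LA")[-1] == 100.0

    def test_boundedness(self, washout_channel, washout_channel_field):
        ink = transport_ink(washout_channel_field, washout_channel, n_cycles=6)
        assert ink.conc.min() >= 0.0
        assert ink.conc.max() <= 1.0

    def test_plug_flow_matches_characteristics_oracle(self, washout_channel):
        # method of characteristics: with a plug profile the fresh-blood
        # front advances at Q/A, so the old-blood fraction decreases linearly
        # and hits zero at V/Q (= 3 cycles here)
        field = uniform_u_field(washout_channel, [20.0] * 12, n_cycles=6,
                                cycle_length=1.0)
        ink = transport_ink(field, washout_channel, n_cycles=6, start_cycle=0)
        old = old_blood_fraction(ink, washout_channel, "LA")
        V = washout_channel.region_volume("LA") / 1000.0        # mL
        Q = 20.0 * 10.0 * 10.0 / 1000.0                         # mL/s
        for cyc, got in enumerate(old):
            exact = 100.0 * max(0.0, 1.0 - cyc * Q / V)
            assert got == pytest.approx(exact, abs=5.0)

    def test_old_blood_monotone_non_increasing(self, washout_channel,
                                               washout_channel_field):
        ink = transport_ink(washout_channel_field, washout_channel, n_cycles=6)
        old = old_blood_fraction(ink, washout_channel, "LA")
        assert np.all(np.diff(old) <= 1e-12)

    def test_ink_budget_closes(self, washout_channel, washout_channel_field):
        # total marker change per cycle equals the net boundary ink flux
        ink = transport_ink(washout_channel_field, washout_channel, n_cycles=6)
        cv = washout_channel.cell_volume / 1000.0               # mL
        for cyc in range(6):
            before = ink.at_cycle(cyc).sum() * cv
            after = ink.at_cycle(cyc + 1).sum() * cv
            net = (ink.boundary_budget["in"][cyc] - ink.boundary_budget["out"][cyc]
                   + ink.boundary_budget["laa_wall"][cyc])
            throughput = max(ink.boundary_budget["in"][cyc], 1e-12)
            assert abs((after - before) - net) / throughput < 0.01

    def test_window_beyond_stored_cycles_rejected(self, washout_channel,
                                                  washout_channel_field):
        with pytest.raises(ParameterError):
            transport_ink(washout_channel_field, washout_channel, n_cycles=20)

    def test_enumeration_oracle_tiny_channel(self):
        # independent cell-by-cell Python re-implementation of the upwind
        # update must reproduce the vectorised transport exactly
        dom = channel_domain(length=8.0, height=3.0, spacing=1.0, depth=10.0)
        field = uniform_u_field(dom, [2.0] * 4, n_cycles=2, cycle_length=0.2)
        ink = transport_ink(field, dom, n_cycles=2, start_cycle=0, cfl=0.45)
        u_val, h = 2.0, 1.0
        dt_snap = 0.2 / 2
        nsub = int(np.ceil(dt_snap * u_val / (0.45 * h)))
        dts = dt_snap / nsub
        F = dom.mask("fluid")
        nx, ny = F.shape
        c = np.zeros((nx, ny))
        inlet_cols = {1}                      # first fluid column
        for _ in range(4 * nsub):             # 4 snapshots
            cn = c.copy()
            for i in range(nx):
                for j in range(ny):
                    if not F[i, j]:
                        continue
                    c_w = 1.0 if i in inlet_cols else c[i - 1, j]
                    flux_in = u_val * c_w
                    flux_out = u_val * c[i, j]
                    cn[i, j] = min(1.0, max(0.0, c[i, j]
                                            - dts / h * (flux_out - flux_in)))
            c = cn
        np.testing.assert_allclose(ink.conc[-1], c, atol=1e-12)


class TestResidence:
    def test_occluded_domain_yields_no_laa_result(self):
        dom = build_domain(DomainConfig(mode="2d", occluded=True, spacing=2.0))
        field = uniform_u_field(dom, [0.0] * 2, n_cycles=2)
        ink = transport_ink(field, dom, n_cycles=2, start_cycle=0)
        res = laa_residence(ink, dom)
        assert not res.has_laa
        assert res.laa_residence_ml is None

    def test_stagnant_pouch_retains_everything(self):
        dom = build_domain(DomainConfig(mode="2d", spacing=2.0))
        field = uniform_u_field(dom, [0.0] * 3, n_cycles=3)
        ink = transport_ink(field, dom, n_cycles=3, start_cycle=0)
        res = laa_residence(ink, dom)
        assert res.has_laa
        np.testing.assert_allclose(res.laa_residence_percent, 100.0)

class TestMidTransportEnumeration:
    def test_old_blood_fraction_equals_cell_summation(self, washout_channel,
                                                      washout_channel_field):
        ink = transport_ink(washout_channel_field, washout_channel, n_cycles=4)
        got = old_blood_fraction(ink, washout_channel, "LA")[2]
        m = washout_channel.mask("LA")
        conc = ink.at_cycle(2)
        total = 0.0
        for i in range(conc.shape[0]):
            for j in range(conc.shape[1]):
                if m[i, j]:
                    total += 1.0 - conc[i, j]
        assert got == pytest.approx(100.0 * total / m.sum())
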