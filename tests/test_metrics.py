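"""Tests for the thrombosis-related flow metrics."""

import numpy as np
import pytest

from laaoflow.domain import DomainConfig, build_domain
from laaoflow.errors import ParameterError
from laaoflow.metrics import (
    detect_laa_recirculation,
    diastasis_window,
    stagnation_volume,
    velocity_stats,
    wss_classify,
)

from conftest import CHANNEL_FLUID, make_field, uniform_u_field


@pytest.fixture(scope="module")
def domain2d():
    return build_domain(DomainConfig(mode="2d"))


class TestStagnation:
    def test_uniform_fast_field_has_none(self, channel):
        field = uniform_u_field(channel, [10.0, 10.0])
        stag = stagnation_volume(field, channel)
        assert stag["LA"] == 0.0

    def test_zero_field_is_fully_stagnant(self, channel):
        field = uniform_u_field(channel, [0.0, 0.0])
        stag = stagnation_volume(field, channel)
        assert stag["LA"] == pytest.approx(channel.region_volume("LA") / 1000.0)

    def test_half_slow_half_fast_matches_enumeration(self, channel):
        # left half columns at 0.5 mm/s, right half at 5 mm/s
        nx, ny = channel.labels.shape
        u = np.zeros((1, nx + 1, ny))
        u[0, : nx // 2 + 1, :] = 0.5
        u[0, nx // 2 + 1:, :] = 5.0
        v = np.zeros((1, nx, ny + 1))
        field = make_field(channel, u, v)
        stag = stagnation_volume(field, channel)
        # independent brute-force enumeration over cells
        expected = 0
        F = channel.mask("LA")
        for i in range(nx):
            for j in range(ny):
                if F[i, j] and 0.5 * (u[0, i, j] + u[0, i + 1, j]) < 1.0:
                    expected += 1
        assert stag["LA"] == pytest.approx(expected * channel.cell_volume / 1000.0)

    def test_oscillating_flow_not_stagnant_by_magnitude_average(self, channel):
        field = uniform_u_field(channel, [5.0, -5.0])
        by_mag = stagnation_volume(field, channel, average="magnitude")
        by_vec = stagnation_volume(field, channel, average="vector")
        assert by_mag["LA"] == 0.0
        assert by_vec["LA"] == pytest.approx(channel.region_volume("LA") / 1000.0)

    def test_empty_window_rejected(self, channel):
        field = uniform_u_field(channel, [1.0, 1.0], n_cycles=2)
        with pytest.raises(ValueError):
            stagnation_volume(field, channel, window=(2, 2))


class TestWSS:
    def test_zero_flow_all_area_in_low_bin(self, channel):
        field = uniform_u_field(channel, [0.0])
        areas = wss_classify(field, channel, CHANNEL_FLUID)
        total_walls = len(channel.boundary_faces["wall"])
        assert areas["low"]["LA"] == pytest.approx(total_walls * channel.face_area / 100.0)
        assert areas["physiological"]["LA"] == 0.0

    def test_poiseuille_wall_stress_within_2_percent(self, channel, channel_field):
        # analytic oracle: tau_wall = 6 mu U / H for plane Poiseuille flow
        from laaoflow.metrics import wall_shear_series
        tau, _ = wall_shear_series(channel_field, channel, CHANNEL_FLUID,
                                   window=(2, 3))
        walls = channel.boundary_faces["wall"]
        x = channel.origin[0] + (walls[:, 0] + 0.5) * channel.spacing
        straight = (walls[:, 2] == 1) & (np.abs(x - 30.0) < 15.0)
        exact = 6.0 * CHANNEL_FLUID.dynamic_viscosity * 5.0 / 10.0
        assert np.abs(tau[straight] - exact).max() / exact < 0.02

    def test_bins_partition_total_wall_area(self, short_scenario_field):
        dom, _, field = short_scenario_field
        areas = wss_classify(field, dom)
        by_region = dom.wall_faces_by_region()
        for region in ("LA", "LAA", "LV"):
            total = areas["low"][region] + areas["physiological"][region] \
                + areas["high"][region]
            assert total == pytest.approx(len(by_region[region]) * dom.face_area / 100.0)

    def test_default_bin_edges(self):
        import inspect
        from laaoflow.metrics import wss_classify as fn
        assert inspect.signature(fn).parameters["bins"].default == (0.0, 0.2, 9.0)


class TestVelocityStats:
    def test_steady_field_has_zero_sd(self, channel):
        field = uniform_u_field(channel, [7.0, 7.0])
        mean, sd = velocity_stats(field, channel, "LA")
        assert sd == 0.0
        assert mean == pytest.approx(0.7)   # 7 mm/s = 0.7 cm/s

    def test_two_instant_mean_and_population_sd(self, channel):
        # speeds 1 and 3 cm/s in every cell -> mean 2 cm/s, sd 1 cm/s
        field = uniform_u_field(channel, [10.0, 30.0])
        mean, sd = velocity_stats(field, channel, "LA")
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)

    def test_volume_weighting_matches_brute_force(self, channel):
        nx, ny = channel.labels.shape
        rng = np.random.default_rng(11)
        u = rng.uniform(0, 20, size=(3, nx + 1, ny))
        v = rng.uniform(0, 20, size=(3, nx, ny + 1))
        field = make_field(channel, u, v)
        mean, sd = velocity_stats(field, channel, "LA")
        speeds = np.stack([field.cell_speed(k) for k in range(3)])
        F = channel.mask("LA")
        acc_mean, acc_sd, n = 0.0, 0.0, 0
        for i in range(nx):
            for j in range(ny):
                if F[i, j]:
                    s = speeds[:, i, j]
                    acc_mean += s.mean()
                    acc_sd += s.std()
                    n += 1
        assert mean == pytest.approx(acc_mean / n / 10.0)
        assert sd == pytest.approx(acc_sd / n / 10.0)

    def test_unknown_region_rejected(self, channel):
        field = uniform_u_field(channel, [1.0])
        with pytest.raises(ParameterError):
            velocity_stats(field, channel, "aorta")


class TestDiastasis:
    def test_window_between_e_and_a_peaks(self):
        t = np.linspace(0, 0.75, 750)
        q = 300 * np.exp(-((t - 0.40) / 0.04) ** 2) \
            + 250 * np.exp(-((t - 0.65) / 0.03) ** 2)
        t0, t1 = diastasis_window(q, t)
        assert 0.40 < t0 < 0.65
        assert t0 < t1 < 0.68

    def test_window_after_single_wave(self):
        t = np.linspace(0, 0.75, 750)
        q = 300 * np.exp(-((t - 0.40) / 0.04) ** 2)
        t0, t1 = diastasis_window(q, t)
        assert t0 > 0.40
        assert t1 > t0


class TestRecirculation:
    def _rotation_field(self, domain, omega=0.5):
        # solid-body rotation about the pouch centre on the MAC grids
        nx, ny = domain.labels.shape
        cc = domain.cell_centers()[domain.mask("LAA")]
        cx, cy = cc.mean(axis=0)
        h = domain.spacing
        xf = domain.origin[0] + np.arange(nx + 1) * h
        yc = domain.origin[1] + (np.arange(ny) + 0.5) * h
        u = -omega * (yc[None, :] - cy) * np.ones((nx + 1, 1))
        xc = domain.origin[0] + (np.arange(nx) + 0.5) * h
        yf = domain.origin[1] + np.arange(ny + 1) * h
        v = omega * (xc[:, None] - cx) * np.ones((1, ny + 1))
        return u, v

    def test_slow_vortex_detected(self, domain2d):
        u, v = self._rotation_field(domain2d, omega=0.5)
        field = make_field(domain2d, u[None], v[None])
        res = detect_laa_recirculation(field, domain2d, (0.0, 1.0))
        assert res.present
        assert res.swirl_fraction > 0.9

    def test_uniform_translation_not_detected(self, domain2d):
        field = uniform_u_field(domain2d, [5.0])
        res = detect_laa_recirculation(field, domain2d, (0.0, 1.0))
        assert not res.present
        assert res.swirl_fraction < 0.3

    def test_fast_vortex_not_a_stagnation_pocket(self, domain2d):
        u, v = self._rotation_field(domain2d, omega=10.0)
        field = make_field(domain2d, u[None], v[None])
        res = detect_laa_recirculation(field, domain2d, (0.0, 1.0))
        assert not res.present          # rotating but too fast to be stasis

    def test_occluded_domain_reports_absent(self):
        dom = build_domain(DomainConfig(mode="2d", occluded=True))
        field = uniform_u_field(dom, [1.0])
        res = detect_laa_recirculation(field, dom, (0.0, 1.0))
        assert not res.present
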