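"""Unit and property tests for the closed-loop lumped-parameter circulation."""

import numpy as np
import pytest
from dataclasses import replace

from laaoflow.errors import ConvergenceError, ParameterError
from laaoflow.lpm import (
    ChamberParams,
    PumpParams,
    ScenarioParams,
    activation_waveform,
    apply_scenario,
    chamber_pressure,
    compute_ea_ratio,
    default_baseline,
    pump_flow,
    simulate_lpm,
    summarize_hemodynamics,
    _derivatives,
)


@pytest.fixture(scope="module")
def sr_waves():
    return simulate_lpm(apply_scenario(default_baseline(), "SR-LAA"), n_cycles=120)


@pytest.fixture(scope="module")
def af_waves():
    return simulate_lpm(apply_scenario(default_baseline(), "AF-LAA"), n_cycles=120)


# ---------------------------------------------------------------------------
# activation waveform
# ---------------------------------------------------------------------------

class TestActivation:
    def test_periodic_with_cycle_length(self):
        lv = default_baseline().chambers["lv"]
        t = np.linspace(0, 0.75, 101)
        a = activation_waveform(t, 80.0, lv)
        b = activation_waveform(t + 0.75, 80.0, lv)  # 80 bpm -> 0.75 s period
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_zero_at_onset_and_peak_one(self):
        lv = default_baseline().chambers["lv"]
        T = 60.0 / 80.0
        assert activation_waveform(lv.activation_onset * T, 80.0, lv) == pytest.approx(0.0)
        t_peak = (lv.activation_onset + lv.activation_duration / 2) * T
        assert activation_waveform(t_peak, 80.0, lv) == pytest.approx(1.0)

    def test_cycle_integral_matches_refined_quadrature(self):
        # refinement oracle: 750-point trapezoid vs 7500-point
        lv = default_baseline().chambers["lv"]
        T = 60.0 / 80.0
        coarse = np.trapezoid(activation_waveform(np.linspace(0, T, 751), 80.0, lv),
                              dx=T / 750)
        fine = np.trapezoid(activation_waveform(np.linspace(0, T, 7501), 80.0, lv),
                            dx=T / 7500)
        assert abs(coarse - fine) < 1e-4

    def test_nonpositive_heart_rate_rejected(self):
        with pytest.raises(ParameterError):
            activation_waveform(0.1, 0.0, default_baseline().chambers["lv"])


# ---------------------------------------------------------------------------
# chamber pressure
# ---------------------------------------------------------------------------

class TestChamberPressure:
    def test_active_term_is_peak_pressure_at_reference_volume(self):
        lv = apply_scenario(default_baseline(), "SR-LAA").chambers["lv"]
        T = 60.0 / 80.0
        t_full = (lv.activation_onset + lv.activation_duration / 2) * T
        p_total = chamber_pressure(lv.reference_volume, t_full, lv, 80.0)
        p_passive = chamber_pressure(lv.reference_volume, lv.activation_onset * T, lv, 80.0)
        assert p_total - p_passive == pytest.approx(80.0, abs=1e-9)  # 100 -> 80 mmHg

    def test_passive_pressure_vanishes_at_unstressed_volume(self):
        lv = default_baseline().chambers["lv"]
        T = 60.0 / 70.0
        t0 = lv.activation_onset * T  # activation zero there
        assert chamber_pressure(lv.unstressed_volume, t0, lv, 70.0) == pytest.approx(0.0)

    def test_passive_pressure_closed_form(self):
        lv = default_baseline().chambers["lv"]
        T = 60.0 / 70.0
        v = lv.unstressed_volume + 50.0
        expected = lv.edpvr_alpha * (np.exp(lv.edpvr_exponent * 50.0) - 1.0)
        assert chamber_pressure(v, lv.activation_onset * T, lv, 70.0) == pytest.approx(expected)

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ParameterError):
            chamber_pressure(0.0, 0.0, default_baseline().chambers["lv"], 70.0)


# ---------------------------------------------------------------------------
# pump characteristic
# ---------------------------------------------------------------------------

class TestPump:
    def test_shutoff_point(self):
        pump = default_baseline().pump
        c0 = pump.head_coeffs[0]
        assert pump_flow(0.0, c0, pump) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("dp", [20.0, 60.0, 90.0, 110.0])
    def test_root_matches_bisection_oracle(self, dp):
        pump = default_baseline().pump
        q = pump_flow(0.0, dp, pump)
        lo, hi = -50.0, 15.0
        for _ in range(200):  # brute-force bisection on head(q) - dp
            mid = 0.5 * (lo + hi)
            if pump.head(mid) - dp > 0:
                lo = mid
            else:
                hi = mid
        assert q == pytest.approx(0.5 * (lo + hi), abs=1e-9)

    def test_retrograde_flow_allowed(self):
        pump = default_baseline().pump
        assert pump_flow(0.0, pump.head_coeffs[0] + 10.0, pump) < 0.0

    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ParameterError):
            PumpParams(speed=2700.0, head_coeffs=(100.0, 1.0, 0.0))

    def test_calibrated_operating_point(self, sr_waves):
        s = summarize_hemodynamics(sr_waves)
        assert s.pump_flow == pytest.approx(5.2, abs=0.05)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

class TestScenarios:
    def test_baseline_identity(self):
        b = default_baseline()
        same = apply_scenario(b, "baseline")
        assert same.heart_rate == b.heart_rate
        assert same.chambers["lv"] == b.chambers["lv"]
        assert same.vessels["sa"] == b.vessels["sa"]

    def test_lvad_adjustments(self):
        b = default_baseline()
        p = apply_scenario(b, "SR-LAA")
        assert p.heart_rate == 80.0
        assert p.chambers["lv"].peak_isovolumic_pressure == 80.0
        assert p.chambers["rv"].peak_isovolumic_pressure == 50.0
        assert p.mean_circulatory_pressure == 10.0
        assert p.vessels["sa"].resistance == pytest.approx(b.vessels["sa"].resistance * 0.94)
        assert p.chambers["lv"].edpvr_alpha == pytest.approx(b.chambers["lv"].edpvr_alpha * 1.70)
        assert not p.af_flag and not p.laao_flag

    def test_af_deactivates_la_contraction(self):
        p = apply_scenario(default_baseline(), "AF-LAA")
        t = np.linspace(0, 2.0, 500)
        assert np.all(activation_waveform(t, p.heart_rate, p.chambers["la"]) == 0.0)
        assert p.af_flag

    def test_laao_flag_only_routing(self):
        a = apply_scenario(default_baseline(), "SR-LAA")
        b = apply_scenario(default_baseline(), "SR-LAAO")
        assert b.laao_flag and not a.laao_flag
        assert a.chambers == b.chambers and a.vessels == b.vessels

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ParameterError):
            apply_scenario(default_baseline(), "SR-WHAT")


# ---------------------------------------------------------------------------
# closed-loop simulation
# ---------------------------------------------------------------------------

class TestSimulation:
    def test_blood_volume_conserved(self, sr_waves):
        tv = sr_waves.total_volume()
        assert (tv.max() - tv.min()) / tv.mean() < 1e-3

    def test_waveforms_cyclic(self, sr_waves):
        for name, v in sr_waves.volumes.items():
            assert abs(v[0] - v[-1]) < 0.005 * max(abs(v[0]), 1.0), name

    def test_valve_flows_nonnegative(self, sr_waves):
        for name in ("mitral", "aortic", "tricuspid", "pulmonary"):
            assert np.all(sr_waves.flows[name] >= 0.0), name

    def test_mitral_flow_zero_during_systole(self, sr_waves):
        systole = sr_waves.pressures["lv"] > sr_waves.pressures["la"]
        assert np.all(sr_waves.flows["mitral"][systole] == 0.0)

    def test_af_reduces_stroke_volumes(self, sr_waves, af_waves):
        s_sr = summarize_hemodynamics(sr_waves)
        s_af = summarize_hemodynamics(af_waves)
        assert s_af.mitral_stroke_volume <= s_sr.mitral_stroke_volume
        assert s_af.la_stroke_volume < s_sr.la_stroke_volume

    def test_static_equilibrium_all_flows_zero(self):
        # all compartments at one pressure, zero-head pump: nothing moves
        p = default_baseline()
        p = apply_scenario(p, "baseline")
        p.pump = PumpParams(p.pump.speed, (0.0, -1.5, -0.8))
        pressure = 8.0
        vols = []
        for name in ("la", "lv", "ra", "rv"):
            ch = p.chambers[name]
            vols.append(ch.unstressed_volume +
                        np.log(pressure / ch.edpvr_alpha + 1.0) / ch.edpvr_exponent)
        for name in ("sa", "sv", "pa", "pv"):
            ves = p.vessels[name]
            vols.append(ves.unstressed_volume + ves.compliance * pressure)
        dv, flows, pressures = _derivatives(np.array(vols), np.zeros(4), p)
        np.testing.assert_allclose(pressures, pressure, atol=1e-9)
        np.testing.assert_allclose(flows, 0.0, atol=1e-9)
        np.testing.assert_allclose(dv, 0.0, atol=1e-9)

    def test_convergence_failure_raises_with_residual(self):
        with pytest.raises(ConvergenceError) as exc:
            simulate_lpm(apply_scenario(default_baseline(), "SR-LAA"), n_cycles=1)
        assert exc.value.residual is not None

    def test_too_coarse_dt_rejected(self):
        with pytest.raises(ParameterError):
            simulate_lpm(apply_scenario(default_baseline(), "SR-LAA"), dt=0.01)

    def test_dt_refinement_changes_pump_flow_below_0p2_percent(self, sr_waves):
        p = apply_scenario(default_baseline(), "SR-LAA")
        w2 = simulate_lpm(p, n_cycles=120, dt=(60.0 / 80.0) / 1500.0)
        q1 = summarize_hemodynamics(sr_waves).pump_flow
        q2 = summarize_hemodynamics(w2).pump_flow
        assert abs(q2 - q1) / q1 < 0.002


# ---------------------------------------------------------------------------
# E/A ratio and summaries
# ---------------------------------------------------------------------------

class TestEARatio:
    def test_two_equal_gaussians_give_unity(self):
        t = np.linspace(0, 1, 750)
        q = np.exp(-((t - 0.4) / 0.05) ** 2) + np.exp(-((t - 0.8) / 0.05) ** 2)
        r = compute_ea_ratio(q)
        assert r.has_a_wave
        assert r.ratio == pytest.approx(1.0, abs=1e-3)  # grid sampling offset

    def test_calibrated_sr_ratio(self, sr_waves):
        r = compute_ea_ratio(sr_waves)
        assert r.has_a_wave
        assert r.ratio == pytest.approx(1.2, abs=0.1)

    def test_af_has_no_a_wave(self, af_waves):
        r = compute_ea_ratio(af_waves)
        assert not r.has_a_wave
        assert np.isnan(r.ratio)

    def test_no_flow_raises(self):
        with pytest.raises(ValueError):
            compute_ea_ratio(np.zeros(750))

    def test_ea_monotone_in_lv_alpha(self):
        # supports using the EDPVR alpha as the E/A calibration knob
        ratios = []
        for scale in (0.5, 1.0, 1.5):
            b = default_baseline()
            b.chambers["lv"] = replace(
                b.chambers["lv"], edpvr_alpha=b.chambers["lv"].edpvr_alpha * scale)
            w = simulate_lpm(apply_scenario(b, "SR-LAA"), n_cycles=120)
            ratios.append(compute_ea_ratio(w).ratio)
        assert ratios[0] < ratios[1] < ratios[2]


class TestSummary:
    def test_constant_pressure_map(self, sr_waves):
        w = sr_waves
        w2 = replace(w, pressures={**w.pressures, "sa": np.full_like(w.time, 91.0)})
        assert summarize_hemodynamics(w2).mean_arterial_pressure == pytest.approx(91.0)

    def test_cardiac_output_equals_mitral_stroke_volume_rate(self, sr_waves):
        # conservation oracle: over a converged cycle all LV inflow leaves again
        s = summarize_hemodynamics(sr_waves)
        co_from_mitral = s.mitral_stroke_volume * s.heart_rate * 1e-3  # L/min
        assert co_from_mitral == pytest.approx(s.cardiac_output, rel=0.01)

    def test_non_cyclic_input_rejected(self, sr_waves):
        w = sr_waves
        bad = {k: v.copy() for k, v in w.volumes.items()}
        bad["lv"] = bad["lv"] + np.linspace(0, 30.0, bad["lv"].size)
        with pytest.raises(ValueError):
            summarize_hemodynamics(replace(w, volumes=bad))
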