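"""Deterministic calibration of the baseline lumped-parameter model.

The clinical operating point of a fully supported LVAD patient is given as
targets, not as parameter values: cycle-mean pump flow 5.2 L/min, mean
arterial pressure 83.8 mmHg and mitral E/A ratio 1.2 at 80 bpm.  Three
baseline knobs map almost one-to-one onto those targets:

* pump zero-flow head ``c0``        -> cycle-mean pump flow,
* systemic arterial resistance      -> mean arterial pressure,
* LV end-diastolic alpha            -> E/A ratio (stiffer LV damps the A wave
  relative to the E wave in this model family).

The calibration runs once, offline, by damped least squares on the converged
periodic solution after the LVAD-patient scenario adjustments are applied;
the resulting numbers are committed as the package defaults
(:func:`laaoflow.lpm.default_baseline`).  Nothing here is stochastic.
"""

from __future__ import annotations

from dataclasses import replace

from scipy.optimize import least_squares

from laaoflow.lpm import (
    PumpParams,
    ScenarioParams,
    apply_scenario,
    simulate_lpm,
    summarize_hemodynamics,
)

#: Target operating point of the supported patient (pump L/min, MAP mmHg, E/A).
DEFAULT_TARGETS = (5.2, 83.8, 1.2)


def evaluate_operating_point(baseline: ScenarioParams, scenario: str = "SR-LAA"):
    """(pump flow L/min, MAP mmHg, E/A) of the converged scenario run."""
    w = simulate_lpm(apply_scenario(baseline, scenario), n_cycles=120)
    s = summarize_hemodynamics(w)
    return s.pump_flow, s.mean_arterial_pressure, s.ea.ratio


def calibrate_baseline(baseline: ScenarioParams,
                       targets=DEFAULT_TARGETS,
                       verbose: bool = False) -> ScenarioParams:
    """Return a copy of ``baseline`` with the three knobs fitted to ``targets``."""

    def with_knobs(x) -> ScenarioParams:
        c0, r_sa, alpha = x
        p = apply_scenario(baseline, "baseline")  # deep copy
        p.pump = PumpParams(p.pump.speed, (c0,) + tuple(p.pump.head_coeffs[1:]))
        p.vessels["sa"] = replace(p.vessels["sa"], resistance=r_sa)
        p.chambers["lv"] = replace(p.chambers["lv"], edpvr_alpha=alpha)
        return p

    q0, map0, ea0 = targets

    def residuals(x):
        q, map_, ea = evaluate_operating_point(with_knobs(x))
        # scale so one unit of residual is comparable across targets
        return [(q - q0) / 0.05, (map_ - map0) / 0.5, (ea - ea0) / 0.02]

    x0 = [baseline.pump.head_coeffs[0],
          baseline.vessels["sa"].resistance,
          baseline.chambers["lv"].edpvr_alpha]
    sol = least_squares(residuals, x0, diff_step=[1e-2, 1e-2, 5e-2],
                        xtol=1e-10, ftol=1e-10, gtol=1e-12)
    if verbose:
        print("calibrated knobs:", sol.x, "residuals:", sol.fun)
    return with_knobs(sol.x)


if __name__ == "__main__":
    from laaoflow.lpm import default_baseline

    fitted = calibrate_baseline(default_baseline(), verbose=True)
    print("pump c0      =", repr(fitted.pump.head_coeffs[0]))
    print("R_sa         =", repr(fitted.vessels["sa"].resistance))
    print("alpha_lv     =", repr(fitted.chambers["lv"].edpvr_alpha))
    print("operating point:", evaluate_operating_point(fitted))
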