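"""Closed-loop lumped-parameter model (LPM) of the circulation with an LVAD.

The model is a standard 0-D closed loop: four time-varying-elastance chambers
(LA, LV, RA, RV), four diode valves with small series resistances, two-element
Windkessel arterial beds plus venous compliances for the systemic and pulmonary
circulations, and a continuous-flow assist-device pump connecting the LV apex
to the systemic arterial node through a quadratic head-flow characteristic.

Chamber pressure combines an activated linear end-systolic characteristic with
an exponential end-diastolic pressure-volume relation (EDPVR):

    P(V, t) = e(t) * P_iso * (V - V0) / (Vref - V0)  +  alpha * (exp(beta*(V - V0)) - 1)

where ``e(t)`` is a squared-sine activation pulse in [0, 1].  Atrial
fibrillation is modelled by switching the LA activation off entirely, leaving
only the passive EDPVR (the atrium then fills and empties like a compliant
conduit).

All internal units: pressure mmHg, volume mL, flow mL/s, time s.  The pump
characteristic uses the clinical convention L/min for flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Dict

import numpy as np

from laaoflow.errors import ConvergenceError, ParameterError

#: Recognised scenario names for :func:`apply_scenario`.
SCENARIO_NAMES = ("baseline", "SR-LAA", "SR-LAAO", "AF-LAA", "AF-LAAO")


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass
class ChamberParams:
    """Time-varying elastance chamber.

    Parameters
    ----------
    peak_isovolumic_pressure : float
        Active pressure (mmHg) generated at full activation and the reference
        volume; the chamber's contractility scale.
    unstressed_volume : float
        Volume V0 (mL) at which both active and passive pressures vanish.
    reference_volume : float
        Volume (mL) at which the fully-activated active term equals
        ``peak_isovolumic_pressure``; ``reference_volume - unstressed_volume``
        sets the inverse of the end-systolic elastance.
    edpvr_alpha : float
        Scale (mmHg) of the exponential EDPVR.
    edpvr_exponent : float
        Exponent beta (1/mL) of the EDPVR.
    activation_onset, activation_duration : float
        Start and length of the activation pulse as fractions of the cycle.
    active : bool
        When False the activation is identically zero (used for the fibrillating
        atrium); the chamber is purely passive.
    """

    peak_isovolumic_pressure: float
    unstressed_volume: float
    reference_volume: float
    edpvr_alpha: float
    edpvr_exponent: float
    activation_onset: float
    activation_duration: float
    active: bool = True

    def __post_init__(self):
        if self.peak_isovolumic_pressure < 0:
            raise ParameterError("peak_isovolumic_pressure must be >= 0")
        if self.edpvr_alpha <= 0:
            raise ParameterError("edpvr_alpha must be > 0")
        if not (0.0 <= self.activation_onset < 1.0):
            raise ParameterError("activation_onset must be in [0, 1)")
        if not (0.0 < self.activation_duration <= 1.0):
            raise ParameterError("activation_duration must be in (0, 1]")
        if self.reference_volume <= self.unstressed_volume:
            raise ParameterError("reference_volume must exceed unstressed_volume")


@dataclass
class VesselParams:
    """Lumped compliant vessel with a series outflow resistance."""

    resistance: float   # mmHg*s/mL, resistance of the downstream path
    compliance: float   # mL/mmHg
    unstressed_volume: float  # mL

    def __post_init__(self):
        if self.resistance <= 0:
            raise ParameterError("resistance must be > 0")
        if self.compliance <= 0:
            raise ParameterError("compliance must be > 0")


@dataclass
class PumpParams:
    """Continuous-flow pump: static quadratic head-flow law at fixed speed.

    ``head(Q) = c0 + c1*Q + c2*Q**2`` for forward flow, with Q in L/min and
    head in mmHg.  The curve must be monotonically decreasing over the
    0-10 L/min operating range (checked at construction), which is the shape
    of a centrifugal assist device characteristic at constant speed.  For
    retrograde flow (Q < 0) the characteristic is continued linearly with the
    zero-flow slope ``c1`` so the head keeps rising monotonically and an
    operating point exists for any pressure rise above the shut-off head.
    """

    speed: float                       # rpm, informational
    head_coeffs: tuple                 # (c0 mmHg, c1 mmHg*min/L, c2 mmHg*min^2/L^2)

    def __post_init__(self):
        c0, c1, c2 = self.head_coeffs
        q = np.linspace(0.0, 10.0, 101)
        slope = c1 + 2.0 * c2 * q
        if np.any(slope >= 0.0):
            raise ParameterError(
                "pump head must decrease monotonically with flow on 0-10 L/min")

    def head(self, q_lmin):
        c0, c1, c2 = self.head_coeffs
        q = np.asarray(q_lmin, dtype=float)
        h = np.where(q >= 0.0, c0 + c1 * q + c2 * q ** 2, c0 + c1 * q)
        return h if h.ndim else float(h)


@dataclass
class ScenarioParams:
    """Complete parameter set for one simulated scenario."""

    heart_rate: float                       # bpm
    chambers: Dict[str, ChamberParams]      # keys: la, lv, ra, rv
    vessels: Dict[str, VesselParams]        # keys: sa, sv, pa, pv
    valves: Dict[str, float]                # series resistance mmHg*s/mL:
                                            # mitral, aortic, tricuspid, pulmonary
    pump: PumpParams
    mean_circulatory_pressure: float        # mmHg
    af_flag: bool = False
    laao_flag: bool = False

    def __post_init__(self):
        if self.heart_rate <= 0:
            raise ParameterError("heart_rate must be > 0")

    @property
    def cycle_length(self) -> float:
        return 60.0 / self.heart_rate

    def total_volume(self) -> float:
        """Total blood volume implied by the mean circulatory pressure.

        The stressed volume is ``MCP * sum(vessel compliances)``; chambers are
        initialised at their unstressed volumes, so the mean circulatory
        pressure fully determines the loop's blood content.
        """
        v0 = sum(c.unstressed_volume for c in self.chambers.values())
        v0 += sum(v.unstressed_volume for v in self.vessels.values())
        ctot = sum(v.compliance for v in self.vessels.values())
        return v0 + self.mean_circulatory_pressure * ctot


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def activation_waveform(t, heart_rate: float, chamber: ChamberParams):
    """Normalised activation e(t) in [0, 1] of a chamber.

    A squared-sine pulse of length ``activation_duration`` (cycle fraction)
    starting at ``activation_onset``; zero elsewhere, hence zero at the
    chamber's end-diastole.  Periodic with period 60/heart_rate.  Returns 0
    identically for a deactivated chamber (AF atrium).
    """
    if heart_rate <= 0:
        raise ParameterError("heart_rate must be > 0")
    t = np.asarray(t, dtype=float)
    if not chamber.active:
        return np.zeros_like(t) if t.ndim else 0.0
    period = 60.0 / heart_rate
    tau = np.mod(t / period - chamber.activation_onset, 1.0)
    e = np.where(tau < chamber.activation_duration,
                 np.sin(np.pi * tau / chamber.activation_duration) ** 2, 0.0)
    return e if e.ndim else float(e)


def _passive_pressure(volume, chamber: ChamberParams):
    return chamber.edpvr_alpha * (
        np.exp(chamber.edpvr_exponent * (volume - chamber.unstressed_volume)) - 1.0)


def _active_iso_pressure(volume, chamber: ChamberParams):
    return chamber.peak_isovolumic_pressure * (volume - chamber.unstressed_volume) / (
        chamber.reference_volume - chamber.unstressed_volume)


def chamber_pressure(volume, t, chamber: ChamberParams, heart_rate: float):
    """Chamber pressure (mmHg): activated isovolumic line plus passive EDPVR."""
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise ParameterError("chamber volume must be > 0")
    e = activation_waveform(t, heart_rate, chamber)
    p = e * _active_iso_pressure(volume, chamber) + _passive_pressure(volume, chamber)
    return p if p.ndim else float(p)


def pump_flow(inlet_pressure: float, outlet_pressure: float, pump: PumpParams) -> float:
    """Pump flow (L/min) at which the head-flow curve balances the pressure rise.

    Solves ``head(Q) = outlet_pressure - inlet_pressure`` on the decreasing
    branch of the quadratic characteristic.  No clipping at zero: a pressure
    difference above the shut-off head yields retrograde flow, as in a real
    continuous-flow pump.
    """
    c0, c1, c2 = pump.head_coeffs
    dp = outlet_pressure - inlet_pressure
    if dp > c0:  # above shut-off head: retrograde branch (linear continuation)
        return (dp - c0) / c1
    if c2 == 0.0:
        return (dp - c0) / c1
    disc = c1 * c1 - 4.0 * c2 * (c0 - dp)
    if disc < 0.0:
        raise ConvergenceError(
            f"no real pump operating point for head {dp:.1f} mmHg "
            f"(coeffs {pump.head_coeffs})", residual=disc)
    # With c2 < 0 this root sits on the decreasing branch and passes through
    # Q = 0 at the shut-off head.
    return (-c1 - math.sqrt(disc)) / (2.0 * c2)


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

def apply_scenario(baseline: ScenarioParams, scenario_name: str) -> ScenarioParams:
    """Apply the LVAD-patient adjustments (and optionally AF) to a baseline.

    For the four LVAD scenarios: heart rate 80 bpm, LV peak isovolumic
    pressure 80 mmHg (from 100), RV 50 mmHg (from 80), mean circulatory
    pressure 10 mmHg (from 12.5), systemic arterial resistance reduced by 6 %,
    and the LV EDPVR alpha increased by 70 % (sets the E/A ratio).  AF
    scenarios additionally deactivate the LA active contraction.  The
    occlusion flag only routes to the downstream flow domain; it changes no
    circulation parameter.
    """
    name = scenario_name.strip().upper().replace("_", "-")
    if name == "BASELINE":
        return _copy_scenario(baseline)
    if name not in ("SR-LAA", "SR-LAAO", "AF-LAA", "AF-LAAO"):
        raise ParameterError(
            f"unknown scenario {scenario_name!r}; expected one of {SCENARIO_NAMES}")

    p = _copy_scenario(baseline)
    p.heart_rate = 80.0
    p.chambers["lv"] = replace(p.chambers["lv"], peak_isovolumic_pressure=80.0,
                               edpvr_alpha=p.chambers["lv"].edpvr_alpha * 1.70)
    p.chambers["rv"] = replace(p.chambers["rv"], peak_isovolumic_pressure=50.0)
    p.mean_circulatory_pressure = 10.0
    p.vessels["sa"] = replace(p.vessels["sa"], resistance=p.vessels["sa"].resistance * 0.94)
    p.af_flag = name.startswith("AF")
    p.laao_flag = name.endswith("LAAO")
    if p.af_flag:
        p.chambers["la"] = replace(p.chambers["la"], active=False)
    return p


def _copy_scenario(p: ScenarioParams) -> ScenarioParams:
    return ScenarioParams(
        heart_rate=p.heart_rate,
        chambers={k: replace(v) for k, v in p.chambers.items()},
        vessels={k: replace(v) for k, v in p.vessels.items()},
        valves=dict(p.valves),
        pump=PumpParams(p.pump.speed, tuple(p.pump.head_coeffs)),
        mean_circulatory_pressure=p.mean_circulatory_pressure,
        af_flag=p.af_flag,
        laao_flag=p.laao_flag,
    )


def default_baseline() -> ScenarioParams:
    """Committed baseline parameter set.

    The three starred values (pump zero-flow head, systemic arterial
    resistance, LV EDPVR alpha) were fixed once by deterministic least squares
    (see :mod:`laaoflow.calibrate`) so that after :func:`apply_scenario` the
    SR LVAD scenario reproduces the target operating point of a fully
    supported patient: cycle-mean pump flow 5.2 L/min, mean arterial pressure
    83.8 mmHg and mitral E/A ratio 1.2 at 80 bpm.
    """
    chambers = {
        # Ventricular activation starts the cycle; atrial kick sits at its end.
        "lv": ChamberParams(peak_isovolumic_pressure=100.0, unstressed_volume=20.0,
                            reference_volume=100.0,
                            edpvr_alpha=0.24398061863183726,      # * calibrated
                            edpvr_exponent=0.035,
                            activation_onset=0.0, activation_duration=0.40),
        "la": ChamberParams(peak_isovolumic_pressure=2.0, unstressed_volume=15.0,
                            reference_volume=65.0, edpvr_alpha=0.30,
                            edpvr_exponent=0.025,
                            activation_onset=0.85, activation_duration=0.17),
        "rv": ChamberParams(peak_isovolumic_pressure=80.0, unstressed_volume=20.0,
                            reference_volume=120.0, edpvr_alpha=0.25,
                            edpvr_exponent=0.02,
                            activation_onset=0.0, activation_duration=0.40),
        "ra": ChamberParams(peak_isovolumic_pressure=5.0, unstressed_volume=15.0,
                            reference_volume=65.0, edpvr_alpha=0.25,
                            edpvr_exponent=0.025,
                            activation_onset=0.85, activation_duration=0.17),
    }
    vessels = {
        "sa": VesselParams(resistance=0.9799274127521045,        # * calibrated
                           compliance=1.6, unstressed_volume=600.0),
        "sv": VesselParams(resistance=0.030, compliance=60.0, unstressed_volume=2400.0),
        "pa": VesselParams(resistance=0.070, compliance=5.0, unstressed_volume=120.0),
        "pv": VesselParams(resistance=0.015, compliance=12.0, unstressed_volume=350.0),
    }
    valves = {"mitral": 0.010, "aortic": 0.012, "tricuspid": 0.008, "pulmonary": 0.010}
    pump = PumpParams(speed=2700.0,
                      head_coeffs=(101.82730119533129,           # * calibrated
                                   -1.5, -0.8))
    return ScenarioParams(heart_rate=70.0, chambers=chambers, vessels=vessels,
                          valves=valves, pump=pump, mean_circulatory_pressure=12.5)


# ---------------------------------------------------------------------------
# Waveforms and simulation
# ---------------------------------------------------------------------------

@dataclass
class WaveformSet:
    """One converged cardiac cycle of the LPM state.

    ``time`` spans [0, T] inclusive (cycle start at ventricular activation
    onset), so a converged cycle satisfies first-sample == last-sample for
    every series up to the integrator tolerance.  Volumes in mL, flows in
    mL/s, pressures in mmHg.
    """

    time: np.ndarray
    volumes: Dict[str, np.ndarray]
    flows: Dict[str, np.ndarray]
    pressures: Dict[str, np.ndarray]
    heart_rate: float
    dt: float
    cycles_run: int
    converged: bool
    residual: float

    @property
    def cycle_length(self) -> float:
        return 60.0 / self.heart_rate

    def total_volume(self) -> np.ndarray:
        return sum(self.volumes.values())


_CHAMBER_ORDER = ("la", "lv", "ra", "rv")
_VESSEL_ORDER = ("sa", "sv", "pa", "pv")


def _derivatives(vols, acts, p: ScenarioParams):
    """Right-hand side of the volume ODEs plus the instantaneous flows."""
    v_la, v_lv, v_ra, v_rv, v_sa, v_sv, v_pa, v_pv = vols
    a_la, a_lv, a_ra, a_rv = acts
    ch = p.chambers
    p_la = a_la * _active_iso_pressure(v_la, ch["la"]) + _passive_pressure(v_la, ch["la"])
    p_lv = a_lv * _active_iso_pressure(v_lv, ch["lv"]) + _passive_pressure(v_lv, ch["lv"])
    p_ra = a_ra * _active_iso_pressure(v_ra, ch["ra"]) + _passive_pressure(v_ra, ch["ra"])
    p_rv = a_rv * _active_iso_pressure(v_rv, ch["rv"]) + _passive_pressure(v_rv, ch["rv"])
    ves = p.vessels
    p_sa = (v_sa - ves["sa"].unstressed_volume) / ves["sa"].compliance
    p_sv = (v_sv - ves["sv"].unstressed_volume) / ves["sv"].compliance
    p_pa = (v_pa - ves["pa"].unstressed_volume) / ves["pa"].compliance
    p_pv = (v_pv - ves["pv"].unstressed_volume) / ves["pv"].compliance

    q_mv = max(0.0, (p_la - p_lv) / p.valves["mitral"])
    q_av = max(0.0, (p_lv - p_sa) / p.valves["aortic"])
    q_tv = max(0.0, (p_ra - p_rv) / p.valves["tricuspid"])
    q_pu = max(0.0, (p_rv - p_pa) / p.valves["pulmonary"])
    q_pump = pump_flow(p_lv, p_sa, p.pump) * (1000.0 / 60.0)  # L/min -> mL/s
    q_sys = (p_sa - p_sv) / ves["sa"].resistance
    q_svr = (p_sv - p_ra) / ves["sv"].resistance
    q_pul = (p_pa - p_pv) / ves["pa"].resistance
    q_pvr = (p_pv - p_la) / ves["pv"].resistance

    dv = (
        q_pvr - q_mv,            # LA
        q_mv - q_av - q_pump,    # LV
        q_svr - q_tv,            # RA
        q_tv - q_pu,             # RV
        q_av + q_pump - q_sys,   # systemic arteries
        q_sys - q_svr,           # systemic veins
        q_pu - q_pul,            # pulmonary arteries
        q_pul - q_pvr,           # pulmonary veins
    )
    flows = (q_mv, q_av, q_tv, q_pu, q_pump, q_sys, q_svr, q_pul, q_pvr)
    pressures = (p_la, p_lv, p_ra, p_rv, p_sa, p_sv, p_pa, p_pv)
    return dv, flows, pressures


def simulate_lpm(params: ScenarioParams, n_cycles: int = 40, dt: float | None = None,
                 convergence_tol: float = 0.005) -> WaveformSet:
    """Integrate the closed loop to periodic steady state; return the last cycle.

    Fixed-step classical Runge-Kutta at ``dt`` (default: cycle/750, mirroring
    the 750-step waveform discretisation used downstream).  The run stops once
    the cycle-to-cycle change of every compartment volume is below
    ``convergence_tol`` (relative, default 0.5 %), then records one full cycle
    at every step.

    Raises
    ------
    ConvergenceError
        If the periodic steady state is not reached within ``n_cycles``.
    """
    period = params.cycle_length
    if dt is None:
        dt = period / 750.0
    steps = int(round(period / dt))
    if steps < 750:
        raise ParameterError("dt must divide the cycle into at least 750 steps")
    if n_cycles < 1:
        raise ParameterError("n_cycles must be >= 1")
    dt = period / steps  # exact cycle fit

    # Activation lookup at half-step resolution for the RK4 stages.
    t_half = np.arange(2 * steps + 1) * (dt / 2.0)
    acts = np.stack([activation_waveform(t_half, params.heart_rate, params.chambers[c])
                     for c in _CHAMBER_ORDER])  # (4, 2*steps+1)

    v = np.empty(8)
    mcp = params.mean_circulatory_pressure
    for i, c in enumerate(_CHAMBER_ORDER):
        v[i] = params.chambers[c].unstressed_volume + 5.0
    extra = 20.0  # the 4 x 5 mL chamber priming, removed from the veins
    for i, name in enumerate(_VESSEL_ORDER):
        ves = params.vessels[name]
        v[4 + i] = ves.unstressed_volume + mcp * ves.compliance
    v[5] -= extra

    def rk4_cycle(v, record=False):
        if record:
            vol_rec = np.empty((steps + 1, 8))
            flow_rec = np.empty((steps + 1, 9))
            pres_rec = np.empty((steps + 1, 8))
        for i in range(steps):
            a0 = acts[:, 2 * i]
            a1 = acts[:, 2 * i + 1]
            a2 = acts[:, 2 * i + 2]
            k1, f1, pr1 = _derivatives(v, a0, params)
            if record:
                vol_rec[i] = v
                flow_rec[i] = f1
                pres_rec[i] = pr1
            k1 = np.array(k1)
            k2 = np.array(_derivatives(v + 0.5 * dt * k1, a1, params)[0])
            k3 = np.array(_derivatives(v + 0.5 * dt * k2, a1, params)[0])
            k4 = np.array(_derivatives(v + dt * k3, a2, params)[0])
            v = v + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if record:
            _, fN, prN = _derivatives(v, acts[:, -1], params)
            vol_rec[steps] = v
            flow_rec[steps] = fN
            pres_rec[steps] = prN
            return v, vol_rec, flow_rec, pres_rec
        return v

    residual = np.inf
    converged = False
    cycles_run = 0
    for cyc in range(n_cycles):
        v_prev = v.copy()
        v = rk4_cycle(v)
        cycles_run = cyc + 1
        residual = float(np.max(np.abs(v - v_prev) / np.maximum(np.abs(v), 1.0)))
        if residual < convergence_tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"LPM did not reach periodic steady state in {n_cycles} cycles "
            f"(last cycle-to-cycle residual {residual:.3e}, tol {convergence_tol:g})",
            residual=residual)

    v, vol_rec, flow_rec, pres_rec = rk4_cycle(v, record=True)
    time = np.arange(steps + 1) * dt
    flow_names = ("mitral", "aortic", "tricuspid", "pulmonary", "pump",
                  "systemic", "venous_return", "pulmonary_bed", "pulmonary_vein_return")
    return WaveformSet(
        time=time,
        volumes={name: vol_rec[:, i] for i, name in enumerate(_CHAMBER_ORDER + _VESSEL_ORDER)},
        flows={name: flow_rec[:, i] for i, name in enumerate(flow_names)},
        pressures={name: pres_rec[:, i] for i, name in enumerate(_CHAMBER_ORDER + _VESSEL_ORDER)},
        heart_rate=params.heart_rate,
        dt=dt,
        cycles_run=cycles_run,
        converged=True,
        residual=residual,
    )


# ---------------------------------------------------------------------------
# Waveform analysis
# ---------------------------------------------------------------------------

@dataclass
class EAResult:
    """Mitral filling-pattern peaks.  ``ratio`` is NaN when no A wave exists."""

    e_peak: float
    a_peak: float | None
    has_a_wave: bool

    @property
    def ratio(self) -> float:
        if not self.has_a_wave:
            return float("nan")
        return self.e_peak / self.a_peak


def compute_ea_ratio(mitral_flow, time=None) -> EAResult:
    """E/A ratio of a one-cycle mitral-flow series.

    Accepts a :class:`WaveformSet` or a plain array over one cycle.  The
    series is rolled so the zero-flow (systolic) stretch leads, then peaks are
    found with a 5 % prominence floor.  Two or more peaks: E is the first
    (early-diastolic), A the last (atrial kick).  One peak: the "no A wave"
    sentinel is returned -- the fibrillating atrium produces a single
    diastolic wave.
    """
    from scipy.signal import find_peaks

    if isinstance(mitral_flow, WaveformSet):
        q = np.asarray(mitral_flow.flows["mitral"], dtype=float)
    else:
        q = np.asarray(mitral_flow, dtype=float)
    qmax = float(np.max(q)) if q.size else 0.0
    if qmax <= 0.0:
        raise ValueError("no diastolic mitral flow in the series")
    # drop the duplicated cycle endpoint if present, then rotate the minimum
    # (systolic zero-flow) to the front so diastole is contiguous
    if q.size > 2 and abs(q[0] - q[-1]) < 1e-6 * max(qmax, 1.0):
        q = q[:-1]
    q = np.roll(q, -int(np.argmin(q)))
    peaks, _ = find_peaks(q, prominence=0.05 * qmax)
    if peaks.size == 0:  # monotone-edge degenerate series
        peaks = np.array([int(np.argmax(q))])
    if peaks.size == 1:
        return EAResult(e_peak=float(q[peaks[0]]), a_peak=None, has_a_wave=False)
    return EAResult(e_peak=float(q[peaks[0]]), a_peak=float(q[peaks[-1]]), has_a_wave=True)


@dataclass
class HemoSummary:
    mean_arterial_pressure: float   # mmHg
    cardiac_output: float           # L/min, aortic + pump
    pump_flow: float                # L/min, cycle mean
    mitral_stroke_volume: float     # mL
    lv_stroke_volume: float         # mL (max - min LV volume)
    la_stroke_volume: float         # mL
    ea: EAResult
    heart_rate: float


def summarize_hemodynamics(w: WaveformSet, cyclic_tol: float = 0.02) -> HemoSummary:
    """Cycle summaries of a converged waveform set.

    Raises ``ValueError`` if the input is not cyclic (first vs last sample of
    any chamber volume differing by more than ``cyclic_tol`` relative).
    """
    for name, vol in w.volumes.items():
        scale = max(abs(float(vol[0])), 1.0)
        if abs(float(vol[0]) - float(vol[-1])) > cyclic_tol * scale:
            raise ValueError(f"waveform set is not cyclic (compartment {name!r})")
    T = w.time[-1] - w.time[0]
    map_ = float(np.trapezoid(w.pressures["sa"], w.time) / T)
    q_out = w.flows["aortic"] + w.flows["pump"]
    co = float(np.trapezoid(q_out, w.time) / T) * 60.0 / 1000.0
    pump = float(np.trapezoid(w.flows["pump"], w.time) / T) * 60.0 / 1000.0
    sv_mv = float(np.trapezoid(w.flows["mitral"], w.time))
    return HemoSummary(
        mean_arterial_pressure=map_,
        cardiac_output=co,
        pump_flow=pump,
        mitral_stroke_volume=sv_mv,
        lv_stroke_volume=float(np.max(w.volumes["lv"]) - np.min(w.volumes["lv"])),
        la_stroke_volume=float(np.max(w.volumes["la"]) - np.min(w.volumes["la"])),
        ea=compute_ea_ratio(w),
        heart_rate=w.heart_rate,
    )
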