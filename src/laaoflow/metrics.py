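"""Thrombosis-related flow metrics.

Evaluated on the stored velocity snapshots of a :class:`~laaoflow.solver.FlowField`
(or any field read back from the VTK series), over the post-initialisation
cycle window by default:

* **stagnation volume** - volume of fluid whose time-averaged velocity stays
  below 1 mm/s, the classical stasis surrogate;
* **wall-shear-stress classification** - wall area in the low
  non-physiological band 0-0.2 Pa, the physiological band 0.2-9 Pa and above;
* **velocity statistics** - volume-weighted mean speed and the
  volume-averaged temporal standard deviation of speed per region.

"Time-averaged velocity" is interpreted as the time average of the speed
(magnitude), so fluid that oscillates but keeps moving does not count as
stagnant; the vector-average reading is available via ``average="vector"``.

Wall shear stress uses the one-sided gradient consistent with the solver's
reflected-ghost no-slip walls: with tangential speed ``u1`` at the first cell
centre (h/2 from the wall), ``tau = mu * 2 * u1 / h``, which is second-order
accurate against the discrete channel solution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from laaoflow.domain import REGION_IDS, FlowDomain
from laaoflow.errors import ParameterError
from laaoflow.solver import FlowField, FluidProps

REGIONS = ("LA", "LAA", "LV")


@dataclass
class MetricsResult:
    """Per-region thrombosis-related flow metrics (clinical units: cm^3, cm^2, cm/s)."""

    stagnation_volume_cm3: Dict[str, float]
    wss_area_low_cm2: Dict[str, float]          # 0 - 0.2 Pa
    wss_area_physiological_cm2: Dict[str, float]  # 0.2 - 9 Pa
    wss_area_high_cm2: Dict[str, float]         # > 9 Pa
    mean_velocity_cm_s: Dict[str, float]
    velocity_sd_cm_s: Dict[str, float]
    window_cycles: Tuple[int, int]

    def atrial(self, field: str) -> float:
        """Atrium = chamber + appendage, the clinically reported unit."""
        d = getattr(self, field)
        return d["LA"] + d.get("LAA", 0.0)


def _window_speeds(field: FlowField, window):
    idx = field.snapshot_indices(window)
    if len(idx) == 0:
        raise ValueError("empty evaluation window")
    return idx, np.stack([field.cell_speed(k) for k in idx])


def stagnation_volume(field: FlowField, domain: FlowDomain,
                      threshold_mm_s: float = 1.0, window=None,
                      average: str = "magnitude") -> Dict[str, float]:
    """Stagnant volume (cm^3) per region: cells whose time-averaged velocity
    over the window falls below ``threshold_mm_s`` (default 1 mm/s)."""
    idx = field.snapshot_indices(window)
    if len(idx) == 0:
        raise ValueError("empty evaluation window")
    if average == "magnitude":
        avg = np.mean([field.cell_speed(k) for k in idx], axis=0)
    elif average == "vector":
        avg_vec = np.mean([field.cell_velocity(k) for k in idx], axis=0)
        avg = np.hypot(avg_vec[..., 0], avg_vec[..., 1])
    else:
        raise ParameterError("average must be 'magnitude' or 'vector'")
    out = {}
    for region in REGIONS:
        m = domain.mask(region)
        out[region] = float(np.count_nonzero(avg[m] < threshold_mm_s)
                            * domain.cell_volume / 1000.0)
    return out


def _wall_tangential_speeds(field: FlowField, domain: FlowDomain, k: int):
    """|tangential velocity| at the first cell centre inward of every wall
    face, with the region label of that cell."""
    walls = domain.boundary_faces["wall"]
    vel = field.cell_velocity(k)
    i, j, ax = walls[:, 0], walls[:, 1], walls[:, 2]
    tang_axis = 1 - ax  # the tangential component in 2-D
    u1 = np.abs(vel[i, j, tang_axis])
    return u1, domain.labels[i, j]


def wall_shear_series(field: FlowField, domain: FlowDomain, fluid: FluidProps,
                      window=None):
    """Time-averaged WSS magnitude (Pa) per wall face over the window."""
    idx = field.snapshot_indices(window)
    h = domain.spacing
    mu = fluid.dynamic_viscosity
    acc = None
    for k in idx:
        u1, region = _wall_tangential_speeds(field, domain, k)
        tau = mu * 2.0 * u1 / h
        acc = tau if acc is None else acc + tau
    return acc / len(idx), region


def wss_classify(field: FlowField, domain: FlowDomain, fluid: FluidProps = None,
                 bins=(0.0, 0.2, 9.0), window=None) -> Dict[str, Dict[str, float]]:
    """Wall area (cm^2) per WSS band and region.

    Faces are binned by their *time-averaged* WSS magnitude into
    [bins[0], bins[1]), [bins[1], bins[2]) and [bins[2], inf); the three
    areas partition the total wall area exactly.
    """
    if fluid is None:
        fluid = field.fluid
    tau_avg, region = wall_shear_series(field, domain, fluid, window)
    area_cm2 = domain.face_area / 100.0
    out = {"low": {}, "physiological": {}, "high": {}}
    for name, rid in REGION_IDS.items():
        sel = region == rid
        t = tau_avg[sel]
        out["low"][name] = float(np.count_nonzero((t >= bins[0]) & (t < bins[1])) * area_cm2)
        out["physiological"][name] = float(
            np.count_nonzero((t >= bins[1]) & (t < bins[2])) * area_cm2)
        out["high"][name] = float(np.count_nonzero(t >= bins[2]) * area_cm2)
    return out


def velocity_stats(field: FlowField, domain: FlowDomain, region: str,
                   window=None) -> Tuple[float, float]:
    """(mean, sd) of speed in cm/s for a region over the window.

    Mean: volume-weighted, time-averaged speed.  SD: volume-weighted average
    of the per-cell temporal (population) standard deviation of speed.
    """
    if region not in REGION_IDS and region != "atrium":
        raise ParameterError(f"unknown region {region!r}")
    _, speeds = _window_speeds(field, window)
    m = domain.mask(region)
    if not m.any():
        return 0.0, 0.0
    per_cell_mean = speeds[:, m].mean(axis=0)
    per_cell_sd = speeds[:, m].std(axis=0)
    return float(per_cell_mean.mean() / 10.0), float(per_cell_sd.mean() / 10.0)


def compute_metrics(field: FlowField, domain: FlowDomain,
                    fluid: FluidProps = None, window=None,
                    stagnation_threshold_mm_s: float = 1.0) -> MetricsResult:
    """All thrombosis-related metrics in one pass (stagnation, WSS bands, velocity)."""
    if window is None:
        window = (field.n_init_cycles, field.n_cycles)
    if fluid is None:
        fluid = field.fluid
    stag = stagnation_volume(field, domain, stagnation_threshold_mm_s, window)
    wss = wss_classify(field, domain, fluid, window=window)
    mean_v, sd_v = {}, {}
    for region in REGIONS:
        mean_v[region], sd_v[region] = velocity_stats(field, domain, region, window)
    return MetricsResult(
        stagnation_volume_cm3=stag,
        wss_area_low_cm2=wss["low"],
        wss_area_physiological_cm2=wss["physiological"],
        wss_area_high_cm2=wss["high"],
        mean_velocity_cm_s=mean_v,
        velocity_sd_cm_s=sd_v,
        window_cycles=tuple(window),
    )


# ---------------------------------------------------------------------------
# recirculation detection
# ---------------------------------------------------------------------------

def diastasis_window(mitral_flow: np.ndarray, time: np.ndarray) -> Tuple[float, float]:
    """In-cycle time window of diastasis (low transmitral flow after the E wave).

    Between the E and A peaks when an A wave exists, otherwise from the decay
    of the single diastolic wave to late diastole.  Bounds are the times where
    flow drops below 25 % of the E peak.
    """
    from laaoflow.lpm import compute_ea_ratio

    q = np.asarray(mitral_flow, dtype=float)
    t = np.asarray(time, dtype=float)
    ea = compute_ea_ratio(q)
    thresh = 0.25 * ea.e_peak
    peak_idx = int(np.argmax(q))
    after = np.nonzero((np.arange(len(q)) > peak_idx) & (q < thresh))[0]
    if len(after) == 0:
        raise ValueError("no diastasis interval found")
    t0 = t[after[0]]
    if ea.has_a_wave:
        rest = np.nonzero((t > t0) & (q > thresh))[0]
        t1 = t[rest[0]] if len(rest) else t[-1]
    else:
        t1 = t0 + 0.6 * (t[-1] - t0)
    return float(t0), float(t1)


@dataclass
class RecirculationResult:
    present: bool
    mean_speed_mm_s: float
    swirl_fraction: float       # |sum of tangential velocity| / sum of speed
    window: Tuple[float, float]


def detect_laa_recirculation(field: FlowField, domain: FlowDomain,
                             time_window: Tuple[float, float],
                             speed_threshold_mm_s: float = 20.0,
                             swirl_threshold: float = 0.3,
                             cycles=None) -> RecirculationResult:
    """Detect a low-velocity recirculation pocket in the appendage.

    The phasic-average velocity field over ``time_window`` (in-cycle times,
    e.g. diastasis) is evaluated on appendage cells.  A pocket is reported
    when the mean speed is below ``speed_threshold_mm_s`` while the flow has
    coherent rotation about the vortex core (swirl fraction above
    ``swirl_threshold``): slow but persistently circulating blood.  The core
    is located as the vorticity-magnitude-weighted centre of the pouch, which
    tracks the vortex even when it sits off the geometric centroid.
    """
    m = domain.mask("LAA")
    if not m.any():
        return RecirculationResult(False, 0.0, 0.0, tuple(time_window))
    idx = field.snapshot_indices(cycles)
    tau = np.mod(field.times[idx], field.cycle_length)
    t0, t1 = time_window
    sel = idx[(tau >= t0) & (tau <= t1)]
    if len(sel) == 0:
        raise ValueError("no stored snapshots inside the requested window")
    vel = np.mean([field.cell_velocity(k) for k in sel], axis=0)

    h = domain.spacing
    u, v = vel[..., 0], vel[..., 1]
    omega = np.zeros_like(u)
    omega[1:-1, 1:-1] = (v[2:, 1:-1] - v[:-2, 1:-1]) / (2 * h) \
        - (u[1:-1, 2:] - u[1:-1, :-2]) / (2 * h)
    interior = m.copy()
    for ax, s in ((0, 1), (0, -1), (1, 1), (1, -1)):
        interior &= np.roll(m, s, axis=ax)
    w_abs = np.where(interior, np.abs(omega), 0.0)
    all_centers = domain.cell_centers()
    if w_abs.sum() > 0:
        core = np.array([(all_centers[..., 0] * w_abs).sum(),
                         (all_centers[..., 1] * w_abs).sum()]) / w_abs.sum()
    else:
        core = all_centers[m].mean(axis=0)

    centers = all_centers[m]
    r = centers - core
    rn = np.linalg.norm(r, axis=1)
    ok = rn > 1e-9
    t_hat = np.column_stack([-r[:, 1], r[:, 0]])
    t_hat[ok] /= rn[ok, None]
    vm = vel[m]
    speed = np.hypot(vm[:, 0], vm[:, 1])
    tang = vm[:, 0] * t_hat[:, 0] + vm[:, 1] * t_hat[:, 1]
    mean_speed = float(speed.mean())
    swirl = float(abs(tang[ok].sum()) / max(speed[ok].sum(), 1e-12))
    present = (mean_speed < speed_threshold_mm_s) and (swirl > swirl_threshold) \
        and (mean_speed > 0.0)
    return RecirculationResult(present, mean_speed, swirl, (t0, t1))
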