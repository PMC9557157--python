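"""Four-scenario experiment orchestration.

``run_scenario`` chains the stages - circulation model, synthetic domain,
flux program, flow solve, metrics, washout - for one of the four study arms
(SR-LAA, SR-LAAO, AF-LAA, AF-LAAO) under a single configuration dictionary,
and ``compare_scenarios`` assembles the comparison table with the relative
changes between paired arms.

Reporting convention for percentage changes: increases are rounded to the
nearest integer percent, reductions are truncated toward zero (a 66.7 %
reduction is reported as 66 %), i.e. reductions are never overstated.  Raw
values are retained alongside.

Everything is deterministic: identical configurations produce byte-identical
CSV/JSON outputs, and stage outputs cached in a working directory are keyed
by a hash of the configuration slice they depend on.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass
from typing import Dict, Optional

import numpy as np

from laaoflow._version import __version__ as _version
from laaoflow.domain import DomainConfig, build_domain, make_flux_program
from laaoflow.errors import ParameterError
from laaoflow.lpm import (
    HemoSummary,
    apply_scenario,
    default_baseline,
    simulate_lpm,
    summarize_hemodynamics,
)
from laaoflow.metrics import (
    MetricsResult,
    RecirculationResult,
    compute_metrics,
    detect_laa_recirculation,
    diastasis_window,
)
from laaoflow.solver import FluidProps, solve_flow
from laaoflow.washout import WashoutResult, laa_residence, transport_ink

FOUR_SCENARIOS = ("SR-LAA", "SR-LAAO", "AF-LAA", "AF-LAAO")


def default_config() -> dict:
    """The committed configuration of the default desk-scale experiment."""
    return {
        "lpm": {"n_cycles": 120},
        "domain": {"mode": "2d", "spacing": 1.0},
        "fluid": {"density": 1060.0, "dynamic_viscosity": 0.0035},
        "solver": {"n_cycles": 12, "dt": 0.001, "n_init_cycles": 4,
                   "store_per_cycle": 50},
        "washout": {"n_cycles": 8},
        "metrics": {"stagnation_threshold_mm_s": 1.0},
    }


def config_digest(config: dict, *sections: str) -> str:
    """Deterministic SHA-256 digest of selected config sections."""
    payload = {s: config.get(s) for s in (sections or sorted(config))}
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class ScenarioReport:
    """Everything one study arm produces, with provenance."""

    scenario: str
    hemodynamics: HemoSummary
    metrics: MetricsResult
    washout: WashoutResult
    recirculation: Optional[RecirculationResult]
    provenance: Dict[str, str]

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [conv(v) for v in x]
            return x

        d = {
            "scenario": self.scenario,
            "hemodynamics": conv(asdict(self.hemodynamics)),
            "metrics": conv(asdict(self.metrics)),
            "washout": conv(asdict(self.washout)),
            "recirculation": conv(asdict(self.recirculation))
            if self.recirculation is not None else None,
            "provenance": dict(self.provenance),
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)


def run_scenario(config: dict, scenario_name: str,
                 workdir: Optional[str] = None) -> ScenarioReport:
    """Execute all stages for one scenario.

    With a ``workdir``, stage outputs are written there and the expensive
    stages (circulation waveforms, velocity snapshots) are reused when a
    matching configuration digest is found.
    """
    name = scenario_name.strip().upper().replace("_", "-")
    if name not in FOUR_SCENARIOS:
        raise ParameterError(f"scenario must be one of {FOUR_SCENARIOS}")
    cfg = default_config()
    for k, v in (config or {}).items():
        cfg.setdefault(k, {})
        cfg[k] = {**cfg[k], **v} if isinstance(v, dict) else v

    params = apply_scenario(default_baseline(), name)
    waves = simulate_lpm(params, n_cycles=cfg["lpm"]["n_cycles"])
    hemo = summarize_hemodynamics(waves)

    dom_cfg = DomainConfig(occluded=params.laao_flag, **cfg["domain"])
    domain = build_domain(dom_cfg)
    flux = make_flux_program(waves, domain)
    fluid = FluidProps(**cfg["fluid"])

    cache_key = config_digest(cfg, "lpm", "domain", "fluid", "solver") + "-" + name
    field_npz = os.path.join(workdir, f"field_{cache_key}.npz") if workdir else None
    if field_npz and os.path.exists(field_npz):
        dat = np.load(field_npz)
        from laaoflow.solver import FlowField, ResidualHistory
        sc = cfg["solver"]
        ff = FlowField(times=dat["times"], u=dat["u"], v=dat["v"], domain=domain,
                       fluid=fluid, dt=sc["dt"], cycle_length=flux.cycle_length,
                       n_cycles=sc["n_cycles"], n_init_cycles=sc["n_init_cycles"],
                       store_per_cycle=int(dat["store_per_cycle"]),
                       residuals=ResidualHistory(dat["res_t"], dat["res_c"],
                                                 dat["res_u"], dat["res_v"]))
    else:
        ff = solve_flow(domain, flux, fluid, **cfg["solver"])
        if field_npz:
            os.makedirs(workdir, exist_ok=True)
            np.savez_compressed(
                field_npz, times=ff.times, u=ff.u, v=ff.v,
                store_per_cycle=ff.store_per_cycle, res_t=ff.residuals.time,
                res_c=ff.residuals.continuity, res_u=ff.residuals.momentum_x,
                res_v=ff.residuals.momentum_y)

    met = compute_metrics(ff, domain, fluid,
                          stagnation_threshold_mm_s=cfg["metrics"]
                          ["stagnation_threshold_mm_s"])
    ink = transport_ink(ff, domain, n_cycles=cfg["washout"]["n_cycles"])
    wash = laa_residence(ink, domain)

    recirc = None
    if not params.laao_flag:
        tw = diastasis_window(flux.mitral_plane, flux.time)
        recirc = detect_laa_recirculation(ff, domain, tw)

    report = ScenarioReport(
        scenario=name, hemodynamics=hemo, metrics=met, washout=wash,
        recirculation=recirc,
        provenance={
            "config_sha256": config_digest(cfg),
            "laaoflow_version": _version,
            "scenario": name,
        },
    )
    if workdir:
        os.makedirs(workdir, exist_ok=True)
        with open(os.path.join(workdir, f"report_{name}.json"), "w") as fh:
            fh.write(report.to_json())
        waves_csv = os.path.join(workdir, f"waveforms_{name}.csv")
        _write_waveforms_csv(waves, waves_csv)
    return report


def _write_waveforms_csv(waves, path):
    import pandas as pd
    data = {"time_s": waves.time}
    for group, unit in (("volumes", "ml"), ("flows", "ml_per_s"),
                        ("pressures", "mmhg")):
        for k, v in getattr(waves, group).items():
            data[f"{group[:-1]}_{k}_{unit}"] = v
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def percent_change(a: float, b: float) -> int:
    """Integer percent change from ``a`` to ``b``.

    Increases round to the nearest percent; reductions truncate toward zero
    so they are never overstated (a 66.7 % drop reports as -66 %).
    """
    if a == 0:
        raise ZeroDivisionError("relative change from zero is undefined")
    x = (b - a) / abs(a) * 100.0
    if x >= 0:
        return int(np.floor(x + 0.5))
    return int(x)  # Python truncation toward zero


_COMPARED_PAIRS = (("SR-LAA", "AF-LAA"), ("SR-LAA", "SR-LAAO"),
                   ("AF-LAA", "AF-LAAO"))


def scenario_summary_row(report: ScenarioReport) -> Dict[str, float]:
    m = report.metrics
    w = report.washout
    row = {
        "atrial_stagnation_cm3": m.atrial("stagnation_volume_cm3"),
        "atrial_low_wss_cm2": m.atrial("wss_area_low_cm2"),
        "ventricular_stagnation_cm3": m.stagnation_volume_cm3["LV"],
        "ventricular_low_wss_cm2": m.wss_area_low_cm2["LV"],
        "mean_atrial_velocity_cm_s": m.mean_velocity_cm_s["LA"],
        "atrial_old_blood_final_pct": float(w.old_blood_percent["atrium"][-1]),
        "ventricular_old_blood_final_pct": float(w.old_blood_percent["LV"][-1]),
        "pump_flow_l_min": report.hemodynamics.pump_flow,
        "map_mmhg": report.hemodynamics.mean_arterial_pressure,
    }
    if w.has_laa:
        row["laa_residence_final_pct"] = float(w.laa_residence_percent[-1])
    return row


def compare_scenarios(reports) -> "pandas.DataFrame":
    """Comparison table of the four arms with paired percent changes.

    ``reports`` is a mapping or iterable of the four :class:`ScenarioReport`
    objects.  All four must come from the same configuration digest.
    """
    import pandas as pd

    if not isinstance(reports, dict):
        reports = {r.scenario: r for r in reports}
    missing = [s for s in FOUR_SCENARIOS if s not in reports]
    if missing:
        raise ValueError(f"missing scenarios: {missing}")
    digests = {r.provenance["config_sha256"] for r in reports.values()}
    if len(digests) != 1:
        raise ValueError("scenario reports come from different configurations")

    rows = {s: scenario_summary_row(reports[s]) for s in FOUR_SCENARIOS}
    df = pd.DataFrame(rows)
    for a, b in _COMPARED_PAIRS:
        col = f"change_{a}_to_{b}_pct"
        vals = []
        for metric in df.index:
            va, vb = df.at[metric, a], df.at[metric, b]
            if isinstance(va, float) and va != 0 and not np.isnan(va) \
                    and vb == vb:
                vals.append(percent_change(va, vb))
            else:
                vals.append(np.nan)
        df[col] = vals
    return df


def compare_to_markdown(df) -> str:
    out = ["| metric | " + " | ".join(df.columns) + " |",
           "|" + "---|" * (len(df.columns) + 1)]
    for metric, row in df.iterrows():
        cells = []
        for c in df.columns:
            v = row[c]
            if v != v:
                cells.append("-")
            elif c.startswith("change_"):
                cells.append(f"{int(v):+d}%")
            else:
                cells.append(f"{v:.2f}")
        out.append("| " + metric + " | " + " | ".join(cells) + " |")
    return "\n".join(out)


def run_four_scenarios(config: dict = None, workdir: Optional[str] = None):
    """Run all four arms and return ``(reports, comparison table)``."""
    reports = {s: run_scenario(config, s, workdir=workdir) for s in FOUR_SCENARIOS}
    table = compare_scenarios(reports)
    if workdir:
        table.to_csv(os.path.join(workdir, "comparison.csv"))
        with open(os.path.join(workdir, "comparison.md"), "w") as fh:
            fh.write(compare_to_markdown(table))
    return reports, table
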