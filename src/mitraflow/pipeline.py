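"""End-to-end case and cohort orchestration.

A *case* runs one anatomy through the full chain — voxelization of both
cardiac phases, systolic and diastolic steady solves, baseline endpoints,
then virtual device implantation and post-implant endpoints — and emits a
report with the clinical decision flags (iatrogenic-stenosis risk when the
diastolic mean gradient reaches 5 mmHg, residual regurgitation when the
regurgitant volume stays above threshold).

A *cohort* samples n synthetic patients, runs each case at baseline and
after one virtually implanted device, and compares the CFD endpoints with
their echo-emulated counterparts (PISA regurgitant volume and EROA,
simplified-Bernoulli gradient) by Pearson correlation and Bland–Altman
agreement, pooled and per stage.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .agreement_stats import bland_altman, pearson_r
from .domain_builder import label_boundaries, orifice_area, voxelize_anatomy, write_vtk
from .echo_emulation import (
    DEFAULT_ALIASING_VELOCITY,
    bernoulli_gradient,
    pisa_quantification,
    pisa_radius,
)
from .flow_solver import (
    BoundaryConditions,
    FluidProperties,
    NumericsConfig,
    derive_flow_rates,
    solve_steady,
)
from .hemodynamics import (
    eroa_cfd,
    mean_diastolic_gradient,
    peak_velocity,
    regurgitant_flow,
    regurgitant_volume,
)
from .synthetic_anatomy import (
    PopulationModel,
    ValveAnatomy,
    anatomy_to_dict,
    make_valve_anatomy,
    sample_population,
)
from .virtual_teer import DeviceSpec, implant_device

__all__ = ["CaseReport", "CohortTable", "run_case", "run_cohort", "DEFAULT_CONFIG", "load_config"]

log = logging.getLogger("mitraflow")

DEFAULT_CONFIG: dict = {
    "anatomy": {},
    "devices": [],  # [{label, position_s, width?}] implanted cumulatively
    "resolution": 1.5,  # mm voxel size (0.5 for high-fidelity runs)
    "numerics": {"rtol": 2e-4, "max_iter": 4000},
    "physiology": {"p_la": 10.0, "p_lvot": 80.0, "p_lv": 120.0},
    "echo": {"aliasing_velocity": DEFAULT_ALIASING_VELOCITY},
    "flags": {"stenosis_mpg_mmhg": 5.0, "residual_rv_ml": 15.0},
    "output": {"vtk": False},
}


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


def load_config(path_or_dict) -> dict:
    """Merge a YAML config file (or dict) over the documented defaults."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


@dataclass
class CaseReport:
    anatomy: dict
    stages: dict  # stage name -> endpoint record
    notices: list
    complete: bool  # True iff every attempted solve converged

    def as_dict(self) -> dict:
        return {
            "anatomy": self.anatomy,
            "stages": self.stages,
            "notices": self.notices,
            "complete": self.complete,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), sort_keys=True, indent=1, default=_jsonify)

    def stage_table(self) -> pd.DataFrame:
        rows = []
        for name, rec in self.stages.items():
            rows.append({"stage": name, **rec})
        return pd.DataFrame(rows)


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.bool_):
        return bool(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")


def _solve_phase(anatomy: ValveAnatomy, phase: str, cfg: dict, stage: str):
    """Voxelize, label, and solve one phase; returns (domain, field)."""
    try:
        dom = voxelize_anatomy(anatomy, phase, cfg["resolution"])
        label_boundaries(dom, phase)
    except Exception as exc:  # noqa: BLE001 - structured re-raise
        raise PipelineStageError(stage, f"domain construction failed: {exc}") from exc
    rates = derive_flow_rates(anatomy.stroke_volume, anatomy.t_sys, anatomy.t_dia)
    phys = cfg["physiology"]
    if phase == "systole":
        bc = BoundaryConditions.systole(
            rates.Q_sys, p_la=phys["p_la"], p_lvot=phys["p_lvot"], p_lv_reference=phys["p_lv"]
        )
    else:
        bc = BoundaryConditions.diastole(rates.Q_dia)
    num = NumericsConfig(**cfg["numerics"])
    try:
        t0 = time.perf_counter()
        fld = solve_steady(dom, FluidProperties(), bc, num)
        log.info(
            "%s/%s: %d cells, %d iters, converged=%s (%.1f s)",
            stage,
            phase,
            dom.n_fluid,
            fld.meta["iterations"],
            fld.converged,
            time.perf_counter() - t0,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError(stage, f"{phase} solve failed: {exc}") from exc
    return dom, fld


def _run_stage(anatomy: ValveAnatomy, cfg: dict, stage: str, out_dir=None) -> dict:
    """All endpoints for one anatomy state (one systole + one diastole)."""
    rec: dict = {"anatomic_orifice_mm2": anatomy.anatomic_orifice_area_sys}
    rates = derive_flow_rates(anatomy.stroke_volume, anatomy.t_sys, anatomy.t_dia)

    # --- systole / regurgitation ---
    if anatomy.anatomic_orifice_area_sys > 0:
        dom_s, fld_s = _solve_phase(anatomy, "systole", cfg, stage)
        q_reg = regurgitant_flow(fld_s, dom_s)
        v_max = peak_velocity(fld_s, dom_s, region="jet")
        rec.update(
            Q_reg_ml_s=q_reg,
            RV_ml=regurgitant_volume(q_reg, anatomy.t_sys),
            V_max_m_s=v_max,
            EROA_mm2=eroa_cfd(q_reg, v_max) if q_reg > 0 else 0.0,
            converged_sys=bool(fld_s.converged),
            reynolds_sys=fld_s.meta["reynolds"],
        )
        va = cfg["echo"]["aliasing_velocity"]
        if q_reg > 0 and v_max > va:
            r = pisa_radius(fld_s, dom_s, Va=va)
            pisa = pisa_quantification(r, va, v_max, anatomy.t_sys)
        else:
            pisa = pisa_quantification(0.0, va, max(v_max, 1e-9), anatomy.t_sys)
        rec.update(
            r_pisa_mm=pisa.r,
            Q_pisa_ml_s=pisa.Q_pisa,
            EROA_pisa_mm2=pisa.EROA_pisa,
            RV_pisa_ml=pisa.RV_pisa,
        )
        if out_dir is not None and cfg["output"]["vtk"]:
            write_vtk(Path(out_dir) / f"{stage}_systole.vtk", dom_s, fld_s)
    else:
        rec.update(
            Q_reg_ml_s=0.0,
            RV_ml=0.0,
            V_max_m_s=0.0,
            EROA_mm2=0.0,
            converged_sys=True,
            reynolds_sys=0.0,
            r_pisa_mm=0.0,
            Q_pisa_ml_s=0.0,
            EROA_pisa_mm2=0.0,
            RV_pisa_ml=0.0,
        )

    # --- diastole / gradient ---
    dom_d, fld_d = _solve_phase(anatomy, "diastole", cfg, stage)
    mpg = mean_diastolic_gradient(fld_d, dom_d)
    area_dia = orifice_area(dom_d)
    # mean transmitral velocity by continuity: (ml/s) / mm² == m/s
    v_mean = rates.Q_dia / max(area_dia, 1e-9)
    rec.update(
        MPG_dia_mmHg=mpg,
        diastolic_orifice_mm2=area_dia,
        v_mean_dia_m_s=v_mean,
        MPG_bernoulli_mmHg=bernoulli_gradient(v_mean),
        converged_dia=bool(fld_d.converged),
    )
    if out_dir is not None and cfg["output"]["vtk"]:
        write_vtk(Path(out_dir) / f"{stage}_diastole.vtk", dom_d, fld_d)

    flags = cfg["flags"]
    rec["stenosis_risk"] = bool(mpg >= flags["stenosis_mpg_mmhg"])
    rec["residual_MR"] = bool(rec["RV_ml"] >= flags["residual_rv_ml"])
    return rec


def run_case(config, out_dir: Optional[str] = None) -> CaseReport:
    """Run one anatomy through baseline and post-implant stages.

    Deterministic for a fixed config: rerunning writes a bit-identical
    report.  Device stages are skipped (with a notice) when the baseline
    valve is already sealed or the baseline solve did not converge.
    """
    cfg = load_config(config)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
    anatomy = make_valve_anatomy(**cfg["anatomy"])
    notices: list[str] = []
    stages: dict = {}

    stages["baseline"] = _run_stage(anatomy, cfg, "baseline", out_dir)
    baseline_ok = stages["baseline"]["converged_sys"] and stages["baseline"]["converged_dia"]

    if anatomy.anatomic_orifice_area_sys == 0 and cfg["devices"]:
        notices.append("baseline valve is sealed; device stages skipped")
    elif not baseline_ok and cfg["devices"]:
        notices.append("baseline solve did not converge; device stages skipped")
    else:
        current = anatomy
        for i, dev in enumerate(cfg["devices"], start=1):
            spec = DeviceSpec(
                label=dev["label"],
                position_s=dev["position_s"],
                grasping_width=dev.get("width"),
            )
            current = implant_device(current, spec)
            stage = f"post_{i}_{spec.label}"
            stages[stage] = _run_stage(current, cfg, stage, out_dir)

    complete = all(
        rec["converged_sys"] and rec["converged_dia"] for rec in stages.values()
    )
    report = CaseReport(
        anatomy=anatomy_to_dict(anatomy),
        stages=stages,
        notices=notices,
        complete=complete,
    )
    if out_dir is not None:
        (Path(out_dir) / "case_report.json").write_text(report.to_json())
        report.stage_table().to_csv(Path(out_dir) / "case_stages.csv", index=False)
    return report


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Device-family frequencies observed in the clinical cohort the synthetic
#: population emulates (21 implanted devices).
DEVICE_FREQUENCIES = {
    "Pascal": 3,
    "PascalAce": 6,
    "XTw": 6,
    "XTr": 2,
    "XT": 1,
    "NT": 1,
    "NTr": 2,
}

#: Endpoint pairs compared between CFD and echo emulation.
ENDPOINT_PAIRS = {
    "RV": ("RV_ml", "RV_pisa_ml"),
    "EROA": ("EROA_mm2", "EROA_pisa_mm2"),
    "MPG": ("MPG_dia_mmHg", "MPG_bernoulli_mmHg"),
}


@dataclass
class CohortTable:
    table: pd.DataFrame  # one row per patient × stage
    stats: dict  # endpoint -> {mode -> AgreementStats/correlation or reason}
    n_patients: int
    failures: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "n_rows": int(len(self.table)),
            "failures": self.failures,
            "stats": self.stats,
        }


def _agreement_block(x: np.ndarray, y: np.ndarray) -> dict:
    """Pearson + Bland–Altman, or the reason they are undefined."""
    if len(x) < 3:
        return {"undefined": f"only {len(x)} pairs"}
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"undefined": "zero variance"}
    ba = bland_altman(x, y)
    return {
        "R": pearson_r(x, y),
        "mean_diff": ba.mean_diff,
        "SDD": ba.sdd,
        "LoA": [ba.loa_low, ba.loa_high],
        "n": ba.n,
    }


def run_cohort(config, n: int, seed: Optional[int] = None, out_dir: Optional[str] = None) -> CohortTable:
    """Sample n synthetic patients, run baseline + one-device cases, and
    assemble the CFD-vs-echo agreement table.

    Each patient receives one device drawn from the observed device-family
    frequencies, centred on the (largest) coaptation defect.  Individual
    case failures are recorded and excluded from the statistics.
    """
    if n < 3:
        raise ValueError("a cohort needs n >= 3 patients")
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0) if seed is None else seed)
    model = PopulationModel(**cfg.get("population", {}), seed=seed)
    anatomies = sample_population(model, n)
    rng = np.random.default_rng(seed + 1)
    labels = list(DEVICE_FREQUENCIES)
    probs = np.array(list(DEVICE_FREQUENCIES.values()), dtype=float)
    probs /= probs.sum()

    rows = []
    failures = []
    for i, anatomy in enumerate(anatomies):
        label = labels[int(rng.choice(len(labels), p=probs))]
        target = max(anatomy.open_defects, key=lambda d: d.area, default=None)
        pos = target.center_s if target else 0.5 * anatomy.coaptation_line_length
        try:
            rec0 = _run_stage(anatomy, cfg, f"p{i}_baseline")
            rows.append({"patient": i, "stage": "baseline", "device": "", **rec0})
            post = implant_device(anatomy, DeviceSpec(label=label, position_s=pos))
            rec1 = _run_stage(post, cfg, f"p{i}_post")
            rows.append({"patient": i, "stage": "post", "device": label, **rec1})
        except Exception as exc:  # noqa: BLE001 - per-case isolation
            failures.append({"patient": i, "error": str(exc)})
            log.warning("patient %d failed: %s", i, exc)

    table = pd.DataFrame(rows)
    stats: dict = {}
    for name, (cfd_col, echo_col) in ENDPOINT_PAIRS.items():
        block = {}
        for mode, sub in (
            ("pooled", table),
            ("baseline", table[table["stage"] == "baseline"] if len(table) else table),
            ("post", table[table["stage"] == "post"] if len(table) else table),
        ):
            if len(sub) == 0:
                block[mode] = {"undefined": "no rows"}
                continue
            block[mode] = _agreement_block(
                sub[cfd_col].to_numpy(float), sub[echo_col].to_numpy(float)
            )
        stats[name] = block

    result = CohortTable(table=table, stats=stats, n_patients=n, failures=failures)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort_table.csv", index=False)
        (out / "cohort_stats.json").write_text(
            json.dumps(result.as_dict(), sort_keys=True, indent=1, default=_jsonify)
        )
    return result
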