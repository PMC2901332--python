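"""Delivered-dose indices: TAC, EKR, EKRc, MPC and weekly std Kt/V.

EKR (equivalent renal clearance) is the continuous clearance that would remove
solute at the observed time-averaged rate at the observed time-averaged
concentration (TAC); at periodic steady state removal balances generation, so
EKR = G/TAC.  EKRc rescales EKR to the reference 40-L body-water volume.  The
weekly standardised Kt/V instead references the mean pre-treatment
concentration (MPC): std Kt/V = (G/MPC) * 10080 / V.  For an anuric patient
with 40 L of body water the adequacy lines are EKRc >= 11 mL/min and
std Kt/V >= 2 per week.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clearance import DialyserSpec, TherapyMode
from .errors import DialsimUserError
from .patient import PatientParams, PatientState
from .pump import PumpCurve, PumpType
from .schedule import CourseResult, TreatmentCourse, run_course
from .units import V_REF_L, WEEK_MIN

logger = logging.getLogger(__name__)

EKRC_ADEQUACY_ML_MIN = 11.0
STD_KTV_ADEQUACY = 2.0

#: EKR estimator disagreement above which the course is flagged non-steady
EKR_STEADY_RTOL = 0.02


def tac(times: np.ndarray, conc: np.ndarray) -> float:
    """Time-averaged concentration over the window (trapezoid rule)."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.size < 2 or times[-1] <= times[0]:
        raise DialsimUserError("TAC needs a window of positive length")
    return float(np.trapezoid(conc, times) / (times[-1] - times[0]))


def ekr(
    g: float,
    tac_value: float,
    removed_mass: float | None = None,
    window_min: float | None = None,
) -> tuple[float, float | None]:
    """Equivalent renal clearance, mL/min; ``tac_value`` in mg/mL.

    Returns ``(ekr_from_generation, ekr_from_removal)``.  The generation
    estimator G/TAC assumes periodic steady state; when a removal log is given
    (total mass removed over the window, mg), the removal-rate estimator is
    also computed and a disagreement beyond 2% is logged as a non-steady-state
    warning.
    """
    if tac_value <= 0:
        raise DialsimUserError("TAC must be positive")
    ekr_gen = g / tac_value
    ekr_rem = None
    if removed_mass is not None:
        if window_min is None or window_min <= 0:
            raise DialsimUserError("removal estimator needs the window length")
        ekr_rem = (removed_mass / window_min) / tac_value
        if ekr_gen > 0 and abs(ekr_rem - ekr_gen) / ekr_gen > EKR_STEADY_RTOL:
            logger.warning(
                "EKR estimators disagree by %.1f%% - course may not be at "
                "periodic steady state",
                100.0 * abs(ekr_rem - ekr_gen) / ekr_gen,
            )
    return ekr_gen, ekr_rem


def ekrc(ekr_value: float, v_total: float) -> float:
    """EKR corrected to the 40-L reference body-water volume."""
    if v_total <= 0:
        raise DialsimUserError("total body water must be positive")
    return ekr_value * V_REF_L / v_total


def std_ktv(g: float, mpc: float, v_total: float, t_week: float = WEEK_MIN) -> float:
    """Weekly standardised Kt/V = (G/MPC) * t_week / V.

    ``g`` mg/min, ``mpc`` mg/mL, ``v_total`` L, ``t_week`` min.
    """
    if mpc <= 0:
        raise DialsimUserError("MPC must be positive")
    return (g / mpc) * t_week / (v_total * 1000.0)


@dataclass(frozen=True)
class SoluteDose:
    tac: float                    # mg/mL
    mpc: float                    # mg/mL
    ekr: float                    # mL/min (removal-rate estimator)
    ekr_from_generation: float    # mL/min (G/TAC)
    ekrc: float                   # mL/min, 40-L normalised
    std_ktv: float                # per week
    meets_ekrc_line: bool
    meets_std_ktv_line: bool


@dataclass(frozen=True)
class DoseReport:
    """Adequacy indices per solute, computed on the steady-state week."""

    solutes: dict[str, SoluteDose]
    week: int
    v_total: float                # mean total body water over the week, L

    def to_json(self) -> str:
        return json.dumps(
            {
                "week": self.week,
                "V_total_L": self.v_total,
                "solutes": {
                    s: {
                        "TAC_mg_mL": d.tac,
                        "MPC_mg_mL": d.mpc,
                        "EKR_mL_min": d.ekr,
                        "EKR_from_G_mL_min": d.ekr_from_generation,
                        "EKRc_mL_min": d.ekrc,
                        "std_KtV_per_week": d.std_ktv,
                        "meets_EKRc_line": d.meets_ekrc_line,
                        "meets_stdKtV_line": d.meets_std_ktv_line,
                    }
                    for s, d in self.solutes.items()
                },
            },
            indent=2,
        )


def compute_dose_report(
    result: CourseResult, params: PatientParams, week: int | None = None
) -> DoseReport:
    """Dose indices on one simulated week (default: the final week).

    MPC averages the pre-session extracellular concentrations of all sessions
    in that week.  Both EKR estimators are computed; the removal-rate one is
    reported as EKR, with G/TAC kept alongside as the steady-state check.
    """
    w = result.analysis_week if week is None else week
    if not 0 <= w < result.course.weeks:
        raise DialsimUserError(f"week {w} outside the simulated course")
    t0, t1 = result.week_window(w)
    traj = result.trajectory
    sel = (traj.times >= t0 - 1e-9) & (traj.times <= t1 + 1e-9)
    if sel.sum() < 2:
        raise DialsimUserError("trajectory window is empty; lower the output stride")
    times = traj.times[sel]
    v_total = float(np.mean(traj.v_total()[sel]))

    pre = {
        s: [
            rec.pre_concentrations[s]
            for rec in result.sessions
            if rec.week == w
        ]
        for s in traj.m_ic
    }
    if not any(pre.values()) or any(len(v) == 0 for v in pre.values()):
        raise DialsimUserError("no sessions in the analysis week")

    solutes: dict[str, SoluteDose] = {}
    for s in traj.m_ic:
        conc_mg_ml = traj.c_ex(s)[sel] / 1000.0
        tac_s = tac(times, conc_mg_ml)
        removed = float(traj.removed[s][sel][-1] - traj.removed[s][sel][0])
        g = params.solutes[s].g
        ekr_gen, ekr_rem = ekr(g, tac_s, removed_mass=removed, window_min=t1 - t0)
        mpc_s = float(np.mean(pre[s])) / 1000.0
        ekrc_s = ekrc(ekr_rem, v_total)
        ktv = std_ktv(g, mpc_s, v_total)
        solutes[s] = SoluteDose(
            tac=tac_s,
            mpc=mpc_s,
            ekr=ekr_rem,
            ekr_from_generation=ekr_gen,
            ekrc=ekrc_s,
            std_ktv=ktv,
            meets_ekrc_line=ekrc_s >= EKRC_ADEQUACY_ML_MIN,
            meets_std_ktv_line=ktv >= STD_KTV_ADEQUACY,
        )
    return DoseReport(solutes=solutes, week=w, v_total=v_total)


def adequacy_sweep(
    course_template: TreatmentCourse,
    qb_grid: list[float],
    modes: list[TherapyMode],
    pump_curves: dict[PumpType, PumpCurve],
    dialyser: DialyserSpec,
    params: PatientParams,
    state0: PatientState,
    pump_types: list[PumpType] | None = None,
    dt: float = 0.2,
    solute: str = "urea",
) -> pd.DataFrame:
    """One simulated course per (mode, pump, Qb) cell; Fig-style dose table.

    Returns a DataFrame with columns mode, pump_type, Qb, EKRc, std_KtV,
    meets_EKRc_line, meets_stdKtV_line for ``solute`` (urea by default, the
    solute the adequacy lines are defined for).
    """
    pump_types = pump_types or list(pump_curves)
    rows = []
    from dataclasses import replace

    for mode in modes:
        for pt in pump_types:
            for qb in qb_grid:
                presc = replace(
                    course_template.prescription,
                    mode=mode,
                    pump_type=pt,
                    qb=qb,
                    net_fluid_removal=(
                        0.0
                        if mode is TherapyMode.HFX
                        else course_template.prescription.net_fluid_removal
                    ),
                )
                course = replace(course_template, prescription=presc)
                res = run_course(state0, params, course, pump_curves, dialyser, dt=dt)
                report = compute_dose_report(res, params)
                d = report.solutes[solute]
                rows.append(
                    {
                        "mode": mode.value,
                        "pump_type": pt.value,
                        "Qb": qb,
                        "EKRc": d.ekrc,
                        "std_KtV": d.std_ktv,
                        "meets_EKRc_line": d.meets_ekrc_line,
                        "meets_stdKtV_line": d.meets_std_ktv_line,
                    }
                )
    return pd.DataFrame(rows)


def minimal_adequate_qb(sweep: pd.DataFrame) -> pd.DataFrame:
    """Smallest Qb meeting each adequacy line per (mode, pump), NaN if none."""
    out = []
    for (mode, pt), grp in sweep.groupby(["mode", "pump_type"]):
        grp = grp.sort_values("Qb")
        ok_ekrc = grp.loc[grp["meets_EKRc_line"], "Qb"]
        ok_ktv = grp.loc[grp["meets_stdKtV_line"], "Qb"]
        out.append(
            {
                "mode": mode,
                "pump_type": pt,
                "min_Qb_EKRc": float(ok_ekrc.iloc[0]) if len(ok_ekrc) else float("nan"),
                "min_Qb_stdKtV": float(ok_ktv.iloc[0]) if len(ok_ktv) else float("nan"),
            }
        )
    return pd.DataFrame(out)
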