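"""Treatment courses: compose sessions into weeks and drive the patient model.

A course is a weekly pattern of identical sessions (default three per week,
4 h each, Mon/Wed/Fri-style spacing) repeated for several weeks.  During a
session the dialyser clearances apply and net ultrafiltration removes fluid;
between sessions the patient generates solute and drinks back the removed
fluid, so the weekly fluid balance closes and the concentration cycle settles
into a periodic steady state.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .clearance import (
    ClearanceResult,
    DialyserSpec,
    OperatingPoint,
    TherapyMode,
    hfx_operating_point,
    session_clearances,
)
from .errors import DialsimUserError
from .patient import PatientParams, PatientState, PhaseContext, Trajectory, integrate
from .pump import PumpCurve, PumpType, interpolate_pump_state
from .units import WEEK_MIN

logger = logging.getLogger(__name__)

#: default session start offsets within the week for n sessions (minutes);
#: three sessions follow the clinical 2-2-3-day pattern
_DEFAULT_3 = (0.0, 2.0 * 1440.0, 4.0 * 1440.0)


@dataclass(frozen=True)
class SessionPrescription:
    """One session's therapy settings."""

    mode: TherapyMode
    pump_type: PumpType = PumpType.NON_PULSATILE
    qb: float = 300.0                  # mL/min
    qd: float = 300.0                  # mL/min (ignored for HF)
    duration: float = 240.0            # min
    net_fluid_removal: float = 2000.0  # mL per session (must be 0 for HFx)
    p_d_in: float = 30.0               # HDF dialysate-side pressures, mmHg
    p_d_out: float = 10.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise DialsimUserError("session duration must be positive")
        if self.mode is TherapyMode.HFX and self.net_fluid_removal != 0:
            raise DialsimUserError("HFx sessions have zero net fluid removal")
        if self.net_fluid_removal < 0:
            raise DialsimUserError("net fluid removal must be >= 0")


@dataclass(frozen=True)
class TreatmentCourse:
    """Weekly schedule of identical sessions over a number of weeks."""

    prescription: SessionPrescription
    sessions_per_week: int = 3
    weeks: int = 5
    interdialytic_intake: float | None = None   # mL/min; None = close fluid balance
    start_offsets: tuple[float, ...] | None = None  # min within the week

    def __post_init__(self) -> None:
        if self.sessions_per_week < 1 or self.weeks < 1:
            raise DialsimUserError("sessions_per_week and weeks must be >= 1")


def build_week_timeline(course: TreatmentCourse) -> list[tuple[float, float]]:
    """Ordered, disjoint (start, end) session windows within a 10080-min week."""
    n = course.sessions_per_week
    dur = course.prescription.duration
    if course.start_offsets is not None:
        if len(course.start_offsets) != n:
            raise DialsimUserError("need one start offset per session")
        starts = sorted(float(s) for s in course.start_offsets)
    elif n == 3:
        starts = list(_DEFAULT_3)
    else:
        starts = [i * WEEK_MIN / n for i in range(n)]
    windows = [(s, s + dur) for s in starts]
    for (s0, e0), (s1, _) in zip(windows, windows[1:]):
        if s1 < e0:
            raise DialsimUserError(f"session windows overlap: {e0} > {s1}")
    if windows[-1][1] > WEEK_MIN:
        raise DialsimUserError("sessions do not fit within the week")
    return windows


def operating_point_for(
    prescription: SessionPrescription, pump_state: tuple[float, float, float]
) -> OperatingPoint:
    """Build the session operating point from the interpolated pump state."""
    p_b_in, p_b_out, _ = pump_state
    mode = prescription.mode
    if mode is TherapyMode.HF:
        # dialysate side open to atmosphere
        return OperatingPoint(mode=mode, qb=prescription.qb, qd=0.0,
                              p_b_in=p_b_in, p_b_out=p_b_out, p_d_in=0.0, p_d_out=0.0)
    if mode is TherapyMode.HDF:
        return OperatingPoint(
            mode=mode, qb=prescription.qb, qd=prescription.qd,
            p_b_in=p_b_in, p_b_out=p_b_out,
            p_d_in=prescription.p_d_in, p_d_out=prescription.p_d_out,
        )
    return hfx_operating_point(pump_state, prescription.qb, prescription.qd)


@dataclass
class SessionRecord:
    week: int
    index_in_week: int
    start_min: float
    clearances: ClearanceResult
    pre_concentrations: dict[str, float]   # extracellular, mg/L, at session start


@dataclass
class CourseResult:
    """Full-course trajectory plus the per-session clearance log."""

    trajectory: Trajectory
    sessions: list[SessionRecord]
    course: TreatmentCourse
    steady_week: int                      # first week meeting the steadiness test
    mpc_by_week: dict[str, list[float]]   # per-solute weekly mean pre-session conc., mg/L

    @property
    def analysis_week(self) -> int:
        """Final simulated week, used for dose indices."""
        return self.course.weeks - 1

    def week_window(self, week: int) -> tuple[float, float]:
        return week * WEEK_MIN, (week + 1) * WEEK_MIN


def session_clearances_for(
    prescription: SessionPrescription,
    pump_curves: dict[PumpType, PumpCurve],
    dialyser: DialyserSpec,
) -> ClearanceResult:
    """Pump-state interpolation + per-mode clearance assembly for one session."""
    curve = pump_curves[prescription.pump_type]
    pump_state = interpolate_pump_state(curve, prescription.qb)
    op = operating_point_for(prescription, pump_state)
    net_uf = (
        0.0
        if prescription.mode is TherapyMode.HFX
        else prescription.net_fluid_removal / prescription.duration
    )
    return session_clearances(dialyser, op, kuf_override=pump_state[2], net_uf=net_uf)


def run_course(
    state0: PatientState,
    params: PatientParams,
    course: TreatmentCourse,
    pump_curves: dict[PumpType, PumpCurve],
    dialyser: DialyserSpec,
    dt: float = 0.2,
    output_stride: int = 25,
    steady_rtol: float = 0.005,
) -> CourseResult:
    """Simulate a multi-week course.

    Each week is the timeline from :func:`build_week_timeline`; sessions use
    the pump state interpolated at the prescribed Qb, inter-dialytic phases
    apply fluid intake (defaulting to the rate that returns the week's net UF,
    closing the weekly fluid balance).  The per-solute mean pre-session
    concentration (MPC) is tracked per week; ``steady_week`` is the first week
    whose MPC changed by less than ``steady_rtol`` relative to the previous
    one (or the final week if never reached).
    """
    presc = course.prescription
    windows = build_week_timeline(course)
    clearances = session_clearances_for(presc, pump_curves, dialyser)

    weekly_removal = presc.net_fluid_removal * course.sessions_per_week  # mL
    inter_time = WEEK_MIN - presc.duration * course.sessions_per_week
    if course.interdialytic_intake is not None:
        intake = course.interdialytic_intake
    else:
        intake = weekly_removal / inter_time if inter_time > 0 else 0.0

    ctx_session = PhaseContext(
        clearances={s: clearances.k(s) for s in dialyser.solutes},
        fluid_removal=clearances.net_uf,
        intake=0.0,
    )
    ctx_rest = PhaseContext.rest(intake)

    # one week's segment pattern
    week_segments: list[tuple[float, PhaseContext]] = []
    session_starts: list[float] = []
    cursor = 0.0
    for s, e in windows:
        if s > cursor:
            week_segments.append((s - cursor, ctx_rest))
        session_starts.append(s)
        week_segments.append((e - s, ctx_session))
        cursor = e
    if cursor < WEEK_MIN:
        week_segments.append((WEEK_MIN - cursor, ctx_rest))

    segments = week_segments * course.weeks
    traj = integrate(state0, params, segments, dt=dt, output_stride=output_stride)

    solutes = list(dialyser.solutes)
    sessions: list[SessionRecord] = []
    mpc_by_week: dict[str, list[float]] = {s: [] for s in solutes}
    for w in range(course.weeks):
        pre_per_solute: dict[str, list[float]] = {s: [] for s in solutes}
        for i, s0 in enumerate(session_starts):
            t_start = w * WEEK_MIN + s0
            idx = int(np.searchsorted(traj.times, t_start - 1e-6))
            pre = {s: float(traj.c_ex(s)[idx]) for s in solutes}
            sessions.append(
                SessionRecord(
                    week=w,
                    index_in_week=i,
                    start_min=t_start,
                    clearances=clearances,
                    pre_concentrations=pre,
                )
            )
            for s in solutes:
                pre_per_solute[s].append(pre[s])
        for s in solutes:
            mpc_by_week[s].append(float(np.mean(pre_per_solute[s])))

    steady_week = course.weeks - 1
    for w in range(1, course.weeks):
        rel = max(
            abs(mpc_by_week[s][w] - mpc_by_week[s][w - 1]) / max(mpc_by_week[s][w], 1e-12)
            for s in solutes
        )
        if rel < steady_rtol:
            steady_week = w
            break
    else:
        logger.info("periodic steady state not reached within %d weeks", course.weeks)

    return CourseResult(
        trajectory=traj,
        sessions=sessions,
        course=course,
        steady_week=steady_week,
        mpc_by_week=mpc_by_week,
    )
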