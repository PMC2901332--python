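"""Whole-body lumped model: three fluid compartments, two solute compartments.

Fluid moves between the intracellular and interstitial compartments down the
osmotic gradient, between interstitium and plasma by Starling (hydrostatic
minus oncotic) gradients at the arterial and venous capillaries, and between
plasma and dialysate as net ultrafiltration.  Each uraemic solute (urea, B2M)
lives in an intracellular and an extracellular pool exchanging diffusively
across the cell membrane; the dialyser removes solute from the extracellular
pool in proportion to total clearance, the Gibbs-Donnan ratio and the plasma
water fraction.

State vector (internal, floats): [V_ic, V_is, V_pl, M_ic(s), M_ex(s)..., plus
augmented bookkeeping states: cumulative dialyser removal per solute and
cumulative net fluid loss].  The bookkeeping states make the mass and volume
balances linear invariants of the RK4 map, so conservation holds to rounding.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AccuracyError, DialsimUserError, NumericalError
from .units import MW_B2M, MW_UREA, mg_dl_to_mg_l

SOLUTES = ("urea", "b2m")

#: baseline total osmolarity the default calibration targets, mmol/L
BASELINE_OSMOLARITY = 285.0

#: intracellular : interstitial : plasma partition of total body water
VOLUME_PARTITION = (25.0, 12.0, 3.0)


@dataclass(frozen=True)
class SolutePatientParams:
    """Cell-membrane kinetics and generation of one solute."""

    eta: float            # cellular mass-transfer coefficient, L/min
    beta: float = 1.0     # equilibrium ratio across the cell membrane
    g: float = 0.0        # generation rate, mg/min (into the extracellular pool)
    alpha: float = 1.0    # Gibbs-Donnan ratio at the dialyser
    mw: float = MW_UREA   # molar mass, mg/mmol (osmotic bookkeeping)

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.beta <= 0 or self.mw <= 0:
            raise DialsimUserError("eta, beta and molar mass must be positive")
        if self.g < 0 or self.alpha <= 0:
            raise DialsimUserError("generation must be >= 0 and alpha > 0")


@dataclass(frozen=True)
class CapillaryParams:
    """Two-conductance Starling exchange between interstitium and plasma.

    Arterial filtration F_a and venous reabsorption R_v are each a conductance
    times a non-negative net (hydrostatic minus oncotic) gradient.  Capillary
    pressure stiffens with plasma volume; plasma oncotic pressure varies
    inversely with plasma volume (fixed protein mass).  ``conductance_v`` is
    calibrated at construction so F_a = R_v at the reference state.
    """

    conductance_a: float = 6.0e-4   # L/min/mmHg
    p_cap_a0: float = 25.0          # arterial capillary pressure at reference, mmHg
    p_cap_v0: float = 10.0          # venous capillary pressure at reference, mmHg
    elastance: float = 10.0         # dP_cap/dV_pl, mmHg/L
    p_is: float = -3.0              # interstitial hydrostatic pressure, mmHg
    pi_pl0: float = 25.0            # plasma oncotic pressure at reference, mmHg
    pi_is: float = 5.0              # interstitial oncotic pressure, mmHg

    @property
    def grad_a0(self) -> float:
        return self.p_cap_a0 - self.p_is - (self.pi_pl0 - self.pi_is)

    @property
    def grad_v0(self) -> float:
        return (self.pi_pl0 - self.pi_is) - (self.p_cap_v0 - self.p_is)

    @property
    def conductance_v(self) -> float:
        """Venous conductance making F_a = R_v at the reference state."""
        return self.conductance_a * self.grad_a0 / self.grad_v0

    def __post_init__(self) -> None:
        if self.conductance_a < 0:
            raise DialsimUserError("capillary conductance must be >= 0")
        if self.conductance_a > 0 and (self.grad_a0 <= 0 or self.grad_v0 <= 0):
            raise DialsimUserError(
                "reference Starling gradients must be positive for calibration"
            )


@dataclass(frozen=True)
class PatientParams:
    """Whole-body parameters.

    ``background_osmoles_ic`` / ``background_osmoles_ex`` are the fixed
    non-urea osmole pools (mmol) that set the isotonic baseline; they do not
    cross membranes on the dialysis time scale.
    """

    k_f: float                       # osmotic filtration coefficient, L^2/min/mmol
    r: float                         # plasma water fraction
    solutes: dict[str, SolutePatientParams]
    capillary: CapillaryParams
    background_osmoles_ic: float     # mmol
    background_osmoles_ex: float     # mmol
    v_pl_ref: float                  # reference plasma volume for Starling terms, L
    v_total_ref: float               # total body water at reference, L

    def __post_init__(self) -> None:
        if self.k_f <= 0:
            raise DialsimUserError("k_f must be positive")
        if not 0.0 < self.r <= 1.0:
            raise DialsimUserError("plasma water fraction must lie in (0, 1]")
        if min(self.background_osmoles_ic, self.background_osmoles_ex) < 0:
            raise DialsimUserError("background osmole pools must be >= 0")


@dataclass(frozen=True)
class PatientState:
    """Compartment volumes (L) and solute masses (mg)."""

    v_ic: float
    v_is: float
    v_pl: float
    m_ic: dict[str, float]
    m_ex: dict[str, float]

    def __post_init__(self) -> None:
        if min(self.v_ic, self.v_is, self.v_pl) <= 0:
            raise DialsimUserError("compartment volumes must be positive")
        if any(v < 0 for v in self.m_ic.values()) or any(
            v < 0 for v in self.m_ex.values()
        ):
            raise DialsimUserError("solute masses must be non-negative")

    @property
    def v_ex(self) -> float:
        """Extracellular fluid volume, L."""
        return self.v_is + self.v_pl

    @property
    def v_total(self) -> float:
        return self.v_ic + self.v_is + self.v_pl

    def c_ic(self, solute: str) -> float:
        """Intracellular concentration, mg/L."""
        return self.m_ic[solute] / self.v_ic

    def c_ex(self, solute: str) -> float:
        """Extracellular concentration, mg/L."""
        return self.m_ex[solute] / self.v_ex


def default_patient(
    weight_kg: float = 73.0,
    predialysis_urea_mg_dl: float = 105.0,
    predialysis_b2m_mg_l: float = 30.0,
    g_b2m: float = 0.12,
    water_fraction: float = 0.58,
) -> tuple[PatientParams, PatientState]:
    """Default anuric patient: parameters plus a calibrated baseline state.

    Total body water is ``weight * water_fraction``, partitioned 25:12:3
    (ic:is:pl).  Solute pools start at cell-membrane equilibrium (beta = 1) at
    the given predialysis concentrations; background osmole pools are chosen so
    both compartments sit at the isotonic baseline (285 mmol/L) initially.
    """
    v_total = weight_kg * water_fraction
    frac = sum(VOLUME_PARTITION)
    v_ic, v_is, v_pl = (v_total * p / frac for p in VOLUME_PARTITION)

    c_urea = mg_dl_to_mg_l(predialysis_urea_mg_dl)   # mg/L
    c_b2m = predialysis_b2m_mg_l

    sol = {
        "urea": SolutePatientParams(eta=0.77, beta=1.0, g=6.24, alpha=1.0, mw=MW_UREA),
        "b2m": SolutePatientParams(eta=0.077, beta=1.0, g=g_b2m, alpha=1.0, mw=MW_B2M),
    }
    m_ic = {"urea": c_urea * v_ic, "b2m": c_b2m * v_ic}
    m_ex = {"urea": c_urea * (v_is + v_pl), "b2m": c_b2m * (v_is + v_pl)}

    urea_osm = c_urea / MW_UREA + c_b2m / MW_B2M     # mmol/L, both compartments
    bg_conc = BASELINE_OSMOLARITY - urea_osm
    params = PatientParams(
        k_f=0.24,
        r=0.94,
        solutes=sol,
        capillary=CapillaryParams(),
        background_osmoles_ic=bg_conc * v_ic,
        background_osmoles_ex=bg_conc * (v_is + v_pl),
        v_pl_ref=v_pl,
        v_total_ref=v_total,
    )
    state = PatientState(v_ic=v_ic, v_is=v_is, v_pl=v_pl, m_ic=m_ic, m_ex=m_ex)
    return params, state


# ---------------------------------------------------------------------------
# elementary fluxes


def osmotic_water_flux(o_ic: float, o_is: float, k_f: float) -> float:
    """Water flux INTO the intracellular compartment, L/min.

    Water moves toward the higher osmolarity: flux = k_f * (O_ic - O_is) is
    positive when the cell interior is the more concentrated side.
    """
    return k_f * (o_ic - o_is)


def osmolarities(state: PatientState, params: PatientParams) -> tuple[float, float]:
    """(O_ic, O_is) in mmol/L, including the fixed background pools."""
    osm_ic = params.background_osmoles_ic
    osm_ex = params.background_osmoles_ex
    for name, sp in params.solutes.items():
        osm_ic += state.m_ic[name] / sp.mw
        osm_ex += state.m_ex[name] / sp.mw
    return osm_ic / state.v_ic, osm_ex / state.v_ex


def capillary_exchange(state: PatientState, params: PatientParams) -> tuple[float, float]:
    """(F_a, R_v): arterial filtration and venous reabsorption, L/min."""
    cap = params.capillary
    if cap.conductance_a == 0:
        return 0.0, 0.0
    dv = state.v_pl - params.v_pl_ref
    pi_pl = cap.pi_pl0 * params.v_pl_ref / state.v_pl   # fixed protein mass
    net_oncotic = pi_pl - cap.pi_is
    f_a = cap.conductance_a * max(0.0, cap.p_cap_a0 + cap.elastance * dv - cap.p_is - net_oncotic)
    r_v = cap.conductance_v * max(0.0, net_oncotic - (cap.p_cap_v0 + cap.elastance * dv - cap.p_is))
    return f_a, r_v


def cellular_solute_flux(c_ic: float, c_ex: float, eta: float, beta: float) -> float:
    """Diffusive solute flux OUT of the cells, mg/min: eta*(C_ic - beta*C_ex)."""
    return eta * (c_ic - beta * c_ex)


def dialyser_removal_rate(k: float, alpha: float, r: float, c_ex: float) -> float:
    """Dialyser solute removal J = K*alpha*r*C_ex, mg/min (toxin-free dialysate).

    ``k`` in mL/min, ``c_ex`` in mg/L.
    """
    if k < 0:
        raise DialsimUserError("clearance must be non-negative")
    return (k / 1000.0) * alpha * r * c_ex


# ---------------------------------------------------------------------------
# context and derivatives


@dataclass(frozen=True)
class PhaseContext:
    """Exchange terms active during one integration phase.

    During a session ``clearances`` holds total clearance per solute (mL/min)
    and ``fluid_removal`` the net plasma water loss Qf - Q_inf (mL/min);
    between sessions both are zero and ``intake`` (mL/min) feeds the plasma
    compartment.
    """

    clearances: dict[str, float] = field(default_factory=dict)
    fluid_removal: float = 0.0   # mL/min, net of replacement fluid
    intake: float = 0.0          # mL/min

    @staticmethod
    def rest(intake: float = 0.0) -> "PhaseContext":
        return PhaseContext(intake=intake)


def state_derivatives(
    state: PatientState, params: PatientParams, ctx: PhaseContext
) -> dict[str, float]:
    """Time derivatives of all state variables (volumes L/min, masses mg/min).

    Returns a dict with keys v_ic, v_is, v_pl, d(M_ic)/dt and d(M_ex)/dt per
    solute (keys ``m_ic:<s>``, ``m_ex:<s>``) and the dialyser removal rate per
    solute (``j:<s>``).  Total solute change equals generation minus removal;
    total volume change equals intake minus net fluid removal.
    """
    y = _pack(state)
    dy = _rhs(y, params, ctx)
    n = len(SOLUTES)
    out = {"v_ic": dy[0], "v_is": dy[1], "v_pl": dy[2]}
    for i, s in enumerate(SOLUTES):
        out[f"m_ic:{s}"] = dy[3 + i]
        out[f"m_ex:{s}"] = dy[3 + n + i]
        out[f"j:{s}"] = dy[3 + 2 * n + i]
    return out


def _pack(state: PatientState) -> list[float]:
    n = len(SOLUTES)
    y = [state.v_ic, state.v_is, state.v_pl]
    y += [state.m_ic[s] for s in SOLUTES]
    y += [state.m_ex[s] for s in SOLUTES]
    y += [0.0] * (n + 1)          # cumulative removal per solute, cumulative fluid loss
    return y


def _unpack(y: list[float]) -> PatientState:
    n = len(SOLUTES)
    return PatientState(
        v_ic=y[0],
        v_is=y[1],
        v_pl=y[2],
        m_ic={s: y[3 + i] for i, s in enumerate(SOLUTES)},
        m_ex={s: y[3 + n + i] for i, s in enumerate(SOLUTES)},
    )


def _rhs(y: list[float], params: PatientParams, ctx: PhaseContext) -> list[float]:
    """Right-hand side over the augmented state vector (plain floats for speed)."""
    n = len(SOLUTES)
    v_ic, v_is, v_pl = y[0], y[1], y[2]
    if v_ic <= 0 or v_is <= 0 or v_pl <= 0:
        raise NumericalError(f"non-positive compartment volume in state {y[:3]}")
    v_ex = v_is + v_pl

    # osmolarities
    osm_ic = params.background_osmoles_ic
    osm_ex = params.background_osmoles_ex
    for i, s in enumerate(SOLUTES):
        sp = params.solutes[s]
        osm_ic += y[3 + i] / sp.mw
        osm_ex += y[3 + n + i] / sp.mw
    q_osm = params.k_f * (osm_ic / v_ic - osm_ex / v_ex)   # L/min into cells

    # capillary Starling exchange
    cap = params.capillary
    if cap.conductance_a > 0:
        dv = v_pl - params.v_pl_ref
        pi_pl = cap.pi_pl0 * params.v_pl_ref / v_pl
        net_onc = pi_pl - cap.pi_is
        f_a = cap.conductance_a * max(0.0, cap.p_cap_a0 + cap.elastance * dv - cap.p_is - net_onc)
        r_v = cap.conductance_v * max(0.0, net_onc - (cap.p_cap_v0 + cap.elastance * dv - cap.p_is))
    else:
        f_a = r_v = 0.0

    removal_l_min = ctx.fluid_removal / 1000.0
    intake_l_min = ctx.intake / 1000.0

    dy = [0.0] * len(y)
    dy[0] = q_osm
    dy[1] = f_a - r_v - q_osm
    dy[2] = r_v - f_a - removal_l_min + intake_l_min

    for i, s in enumerate(SOLUTES):
        sp = params.solutes[s]
        c_ic = y[3 + i] / v_ic
        c_ex = y[3 + n + i] / v_ex
        phi = sp.eta * (c_ic - sp.beta * c_ex)     # mg/min out of cells
        k = ctx.clearances.get(s, 0.0)
        j = (k / 1000.0) * sp.alpha * params.r * c_ex if k else 0.0
        dy[3 + i] = -phi
        dy[3 + n + i] = phi + sp.g - j
        dy[3 + 2 * n + i] = j                       # cumulative removal
    dy[3 + 3 * n] = removal_l_min - intake_l_min    # cumulative net fluid loss, L
    return dy


# ---------------------------------------------------------------------------
# integration


@dataclass
class Trajectory:
    """Recorded time series of the patient state and bookkeeping integrals."""

    times: np.ndarray                       # min
    volumes: np.ndarray                     # (n, 3): V_ic, V_is, V_pl in L
    m_ic: dict[str, np.ndarray]             # mg
    m_ex: dict[str, np.ndarray]             # mg
    removed: dict[str, np.ndarray]          # cumulative dialyser removal, mg
    fluid_loss: np.ndarray                  # cumulative net fluid loss, L
    r: float                                # plasma water fraction used

    def c_ic(self, solute: str) -> np.ndarray:
        """Intracellular concentration, mg/L."""
        return self.m_ic[solute] / self.volumes[:, 0]

    def c_ex(self, solute: str) -> np.ndarray:
        """Extracellular (plasma-water) concentration, mg/L."""
        return self.m_ex[solute] / (self.volumes[:, 1] + self.volumes[:, 2])

    def v_total(self) -> np.ndarray:
        return self.volumes.sum(axis=1)

    def final_state(self) -> PatientState:
        return PatientState(
            v_ic=float(self.volumes[-1, 0]),
            v_is=float(self.volumes[-1, 1]),
            v_pl=float(self.volumes[-1, 2]),
            m_ic={s: float(self.m_ic[s][-1]) for s in self.m_ic},
            m_ex={s: float(self.m_ex[s][-1]) for s in self.m_ex},
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular export; concentrations in mg/mL, whole-plasma = r * plasma water."""
        df = pd.DataFrame(
            {
                "time_min": self.times,
                "V_ic_L": self.volumes[:, 0],
                "V_is_L": self.volumes[:, 1],
                "V_pl_L": self.volumes[:, 2],
            }
        )
        for s in self.m_ic:
            label = "B2M" if s == "b2m" else s
            df[f"C_{label}_ic_mg_mL"] = self.c_ic(s) / 1000.0
            df[f"C_{label}_ex_mg_mL"] = self.c_ex(s) / 1000.0
            df[f"C_{label}_plasma_mg_mL"] = self.r * self.c_ex(s) / 1000.0
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _rk4_run(
    y: list[float],
    params: PatientParams,
    segments: list[tuple[float, PhaseContext]],
    dt: float,
    record_times: set[float] | None,
    stride: int,
) -> tuple[list[float], list[list[float]]]:
    """Advance through the segments with fixed-step RK4, recording samples."""
    t = 0.0
    nstep_total = 0
    samples: list[list[float]] = [[t, *y]]
    for dur, ctx in segments:
        nsteps = round(dur / dt)
        if abs(nsteps * dt - dur) > 1e-9 * max(1.0, dur) or nsteps < 1:
            raise DialsimUserError(
                f"segment duration {dur} min is not a multiple of dt={dt} min"
            )
        for i in range(nsteps):
            h = dt
            k1 = _rhs(y, params, ctx)
            y2 = [yi + 0.5 * h * ki for yi, ki in zip(y, k1)]
            k2 = _rhs(y2, params, ctx)
            y3 = [yi + 0.5 * h * ki for yi, ki in zip(y, k2)]
            k3 = _rhs(y3, params, ctx)
            y4 = [yi + h * ki for yi, ki in zip(y, k3)]
            k4 = _rhs(y4, params, ctx)
            y = [
                yi + (h / 6.0) * (a + 2.0 * b + 2.0 * c + d)
                for yi, a, b, c, d in zip(y, k1, k2, k3, k4)
            ]
            nstep_total += 1
            t = nstep_total * dt   # avoid accumulating round-off in t
            if not all(math.isfinite(v) for v in y):
                raise NumericalError(f"non-finite state at t={t} min")
            last_of_segment = i == nsteps - 1
            if last_of_segment or (i + 1) % stride == 0:
                samples.append([t, *y])
    return y, samples


def integrate(
    state0: PatientState,
    params: PatientParams,
    segments: list[tuple[float, PhaseContext]],
    dt: float = 0.2,
    output_stride: int = 1,
    check: bool = False,
    check_rtol: float = 1e-6,
) -> Trajectory:
    """Fixed-step classical Runge-Kutta integration through phase segments.

    ``segments`` is an ordered list of (duration_min, PhaseContext); each
    boundary falls exactly on the step grid (durations must be multiples of
    ``dt``).  The trajectory is recorded every ``output_stride`` steps plus at
    every segment boundary.  With ``check=True`` the run is repeated at dt/2
    and an :class:`AccuracyError` is raised if the final states disagree beyond
    ``check_rtol`` (relative), advising a smaller dt.
    """
    if dt <= 0:
        raise DialsimUserError("dt must be positive")
    if output_stride < 1:
        raise DialsimUserError("output stride must be >= 1")
    y0 = _pack(state0)
    y, samples = _rk4_run(list(y0), params, segments, dt, None, output_stride)
    if check:
        y_half, _ = _rk4_run(list(y0), params, segments, dt / 2.0, None, 10**9)
        for a, b in zip(y, y_half):
            scale = max(abs(a), abs(b), 1e-9)
            if abs(a - b) / scale > check_rtol:
                raise AccuracyError(
                    f"step-halving check failed ({abs(a - b) / scale:.2e} relative "
                    f"at dt={dt}); use a smaller dt"
                )
    arr = np.asarray(samples)
    n = len(SOLUTES)
    return Trajectory(
        times=arr[:, 0],
        volumes=arr[:, 1:4],
        m_ic={s: arr[:, 4 + i] for i, s in enumerate(SOLUTES)},
        m_ex={s: arr[:, 4 + n + i] for i, s in enumerate(SOLUTES)},
        removed={s: arr[:, 4 + 2 * n + i] for i, s in enumerate(SOLUTES)},
        fluid_loss=arr[:, 4 + 3 * n],
        r=params.r,
    )
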