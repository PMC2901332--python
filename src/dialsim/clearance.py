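"""Per-session dialyser clearances for HF, HDF and high-flux (HFx) therapy.

The dialyser is a counter-current hollow-fibre device.  Diffusive clearance
follows the classical counter-current (Michaels) expression in KoA, Qb and Qd;
convective clearance is the sieved ultrafiltration flow, discounted in the
presence of diffusion by the transmittance T = 1 - Kd/Qb (solute already
removed by diffusion cannot be removed again by filtration downstream).  HFx
runs at zero *net* ultrafiltration: forward filtration near the blood inlet is
balanced by backfiltration near the outlet, and only the internal filtration
branch contributes convective transport.
"""
from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass, field

from .errors import DialsimUserError
from .units import kuf_to_ml_min_mmhg

logger = logging.getLogger(__name__)


class TherapyMode(str, enum.Enum):
    HF = "HF"
    HDF = "HDF"
    HFX = "HFx"


@dataclass(frozen=True)
class SoluteSpec:
    """Membrane transport constants of one solute."""

    koa: float  # diffusive mass-transfer coefficient, mL/min
    si: float   # sieving coefficient, dimensionless in [0, 1]

    def __post_init__(self) -> None:
        if self.koa < 0:
            raise DialsimUserError("KoA must be non-negative")
        if not 0.0 <= self.si <= 1.0:
            raise DialsimUserError("sieving coefficient must lie in [0, 1]")


@dataclass(frozen=True)
class DialyserSpec:
    """Membrane transport constants of the dialyser.

    ``kuf`` is in mL/(h*mmHg) and may be overridden by a pump curve; ``length``
    is the fibre length in an arbitrary unit (it cancels from the internal-UF
    closed form under linear pressure profiles).
    """

    solutes: dict[str, SoluteSpec]
    kuf: float = 35.0
    length: float = 1.0

    def __post_init__(self) -> None:
        if self.kuf <= 0:
            raise DialsimUserError("K_uf must be positive")
        if self.length <= 0:
            raise DialsimUserError("fibre length must be positive")

    @staticmethod
    def default() -> "DialyserSpec":
        """High-flux polysulphone dialyser constants (urea and B2M)."""
        return DialyserSpec(
            solutes={
                "urea": SoluteSpec(koa=967.0, si=1.0),
                "b2m": SoluteSpec(koa=290.0, si=0.8),
            }
        )


@dataclass(frozen=True)
class OperatingPoint:
    """Flows and side pressures of one session's extracorporeal circuit."""

    mode: TherapyMode
    qb: float                  # mL/min
    qd: float = 0.0            # mL/min, 0 for HF
    p_b_in: float = 0.0        # mmHg
    p_b_out: float = 0.0
    p_d_in: float = 0.0
    p_d_out: float = 0.0
    q_inf: float = 0.0         # replacement-fluid rate, mL/min, 0 for HFx

    def __post_init__(self) -> None:
        if self.qb <= 0:
            raise DialsimUserError("Qb must be positive")
        if self.qd < 0:
            raise DialsimUserError("Qd must be non-negative")
        if self.mode is TherapyMode.HF and self.qd != 0:
            raise DialsimUserError("HF uses no dialysate: Qd must be 0")
        if self.mode is not TherapyMode.HF and self.qd == 0:
            raise DialsimUserError(f"{self.mode.value} requires Qd > 0")
        if self.mode is TherapyMode.HFX and self.q_inf != 0:
            raise DialsimUserError("HFx uses no replacement fluid: Q_inf must be 0")
        for p in (self.p_b_in, self.p_b_out, self.p_d_in, self.p_d_out):
            if not math.isfinite(p):
                raise DialsimUserError("pressures must be finite")


@dataclass(frozen=True)
class SoluteClearance:
    kd: float  # diffusive clearance, mL/min
    kc: float  # convective clearance, mL/min

    @property
    def k(self) -> float:
        """Total clearance, mL/min."""
        return self.kd + self.kc


@dataclass(frozen=True)
class ClearanceResult:
    """Per-session clearances and the filtration state behind them.

    ``qf`` is the filtration flow driving convection (the *internal* UF in
    HFx); ``net_uf`` is the net fluid removed from the patient per minute.
    """

    mode: TherapyMode
    solutes: dict[str, SoluteClearance]
    qf: float                      # mL/min
    tmpm: float                    # mmHg
    net_uf: float = 0.0            # mL/min
    hfx_crossover: float | None = None   # position M in [0, L], HFx only
    hfx_degenerate: str | None = None    # 'all_filtration' / 'all_backfiltration'

    def k(self, solute: str) -> float:
        return self.solutes[solute].k

    def to_json(self) -> str:
        return json.dumps(
            {
                "mode": self.mode.value,
                "qf_mL_min": self.qf,
                "net_uf_mL_min": self.net_uf,
                "tmpm_mmHg": self.tmpm,
                "hfx_crossover": self.hfx_crossover,
                "hfx_degenerate": self.hfx_degenerate,
                "solutes": {
                    s: {"Kd": c.kd, "Kc": c.kc, "K": c.k}
                    for s, c in self.solutes.items()
                },
            }
        )


def tmp_mean(p_b_in: float, p_b_out: float, p_d_in: float, p_d_out: float) -> float:
    """Mean transmembrane pressure: blood-side mean minus dialysate-side mean."""
    return 0.5 * (p_b_in + p_b_out) - 0.5 * (p_d_in + p_d_out)


def uf_rate(kuf_ml_h_mmhg: float, tmpm: float) -> float:
    """Ultrafiltration rate Qf = K_uf * TMPm, returned in mL/min.

    A negative TMPm yields a negative Qf (net backfiltration) and a warning.
    """
    if kuf_ml_h_mmhg <= 0:
        raise DialsimUserError("K_uf must be positive")
    qf = kuf_to_ml_min_mmhg(kuf_ml_h_mmhg) * tmpm
    if qf < 0:
        logger.warning("negative TMPm (%.3g mmHg): net backfiltration Qf=%.3g mL/min", tmpm, qf)
    return qf


def diffusive_clearance(koa: float, qb: float, qd: float) -> float:
    """Counter-current diffusive clearance Kd(KoA, Qb, Qd), mL/min.

    Kd = Qb*(e^Z - 1)/(e^Z - Qb/Qd) with Z = (KoA/Qb)*(1 - Qb/Qd); the
    removable singularity at Qb = Qd is evaluated by its analytic limit
    Kd = Qb*KoA/(KoA + Qb).
    """
    if koa < 0:
        raise DialsimUserError("KoA must be non-negative")
    if qb <= 0:
        raise DialsimUserError("Qb must be positive")
    if qd <= 0:
        raise DialsimUserError("diffusive clearance requires Qd > 0 (HF bypasses it)")
    if koa == 0:
        return 0.0
    ratio = qb / qd
    z = (koa / qb) * (1.0 - ratio)
    if abs(z) < 1e-10:
        return qb * koa / (koa + qb)
    ez = math.exp(z)
    kd = qb * (ez - 1.0) / (ez - ratio)
    return min(kd, qb, qd)  # clamp rounding noise at the transport bound


def transmittance(kd: float, qb: float) -> float:
    """Transmittance T = 1 - Kd/Qb: clearance gained per mL/min of filtration."""
    if not 0.0 <= kd <= qb:
        raise DialsimUserError("require 0 <= Kd <= Qb for transmittance")
    return 1.0 - kd / qb


def convective_clearance(
    mode: TherapyMode, si: float, qf: float, t: float | None = None
) -> float:
    """Convective clearance: Si*Qf in HF; Si*Qf*T when diffusion is active."""
    if qf < 0:
        raise DialsimUserError("negative Qf: handle net backfiltration upstream")
    if mode is TherapyMode.HF:
        return si * qf
    if t is None or not 0.0 <= t <= 1.0:
        raise DialsimUserError("HDF/HFx convective clearance needs T in [0, 1]")
    return si * qf * t


def hfx_internal_uf(
    kuf_ml_h_mmhg: float,
    length: float,
    p_b_in: float,
    p_b_out: float,
    p_d_in: float,
    p_d_out: float,
) -> tuple[float, float, str | None]:
    """Internal (forward) filtration flow in an HFx dialyser, mL/min.

    Both side pressures are taken linear along the fibre; blood enters at
    x = 0, dialysate at x = L (counter-current), so P_d runs from P_d_out at
    x = 0 to P_d_in at x = L.  M is the crossover where P_b(x) = P_d(x):
    filtration occurs on [0, M], backfiltration on [M, L].  The forward flow is
    K_ufl * integral_0^M (P_b - P_d) dx in closed (trapezoid) form.

    Returns ``(qf_internal, M, degenerate)`` where ``degenerate`` is None for a
    proper crossover, 'all_filtration' (M = L) or 'all_backfiltration' (M = 0).
    """
    if kuf_ml_h_mmhg <= 0 or length <= 0:
        raise DialsimUserError("K_uf and length must be positive")
    kufl = kuf_to_ml_min_mmhg(kuf_ml_h_mmhg) / length
    d0 = p_b_in - p_d_out            # pressure difference at x = 0
    d1 = p_b_out - p_d_in            # at x = L
    if d0 == d1:
        # uniform difference: no crossover anywhere
        if d0 > 0:
            return kufl * d0 * length, length, "all_filtration"
        return 0.0, 0.0, ("all_backfiltration" if d0 < 0 else None)
    m = length * d0 / (d0 - d1)      # root of the affine difference
    if m <= 0.0:
        return 0.0, 0.0, "all_backfiltration"
    if m >= length:
        qf = kufl * 0.5 * (d0 + d1) * length
        return qf, length, "all_filtration"
    # triangle area between 0 and the crossover
    qf = kufl * 0.5 * d0 * m
    return qf, m, None


def hfx_operating_point(
    pump_state: tuple[float, float, float], qb: float, qd: float
) -> OperatingPoint:
    """HFx operating point with zero net UF by construction.

    The mean dialysate pressures at the dialyser inlet and outlet are set equal
    to the blood-side ones; with linear profiles and counter-current geometry
    the filtration and backfiltration areas then balance exactly.
    """
    p_b_in, p_b_out, _ = pump_state
    return OperatingPoint(
        mode=TherapyMode.HFX,
        qb=qb,
        qd=qd,
        p_b_in=p_b_in,
        p_b_out=p_b_out,
        p_d_in=p_b_in,
        p_d_out=p_b_out,
        q_inf=0.0,
    )


def session_clearances(
    spec: DialyserSpec,
    op: OperatingPoint,
    kuf_override: float | None = None,
    net_uf: float = 0.0,
) -> ClearanceResult:
    """Assemble the per-solute clearances for one session.

    HF: Kd = 0 and Kc = Si*Qf with the dialysate side at atmospheric pressure.
    HDF: Kd from the counter-current formula, Qf from K_uf*TMPm, Kc = Si*Qf*T.
    HFx: Kd as HDF, Qf is the internal filtration branch, Kc = Si*Qf*T;
    net UF is zero by the equal-mean pressure assignment.

    ``kuf_override`` (mL/(h*mmHg)) replaces the dialyser's nominal K_uf, e.g.
    with the pump-curve value; ``net_uf`` (mL/min) is the prescribed net fluid
    removal recorded in the result (0 for HFx).
    """
    kuf = kuf_override if kuf_override is not None else spec.kuf
    mode = op.mode
    crossover: float | None = None
    degenerate: str | None = None

    if mode is TherapyMode.HFX:
        if net_uf != 0.0:
            raise DialsimUserError("HFx runs at zero net UF")
        tmpm = tmp_mean(op.p_b_in, op.p_b_out, op.p_d_in, op.p_d_out)
        qf, crossover, degenerate = hfx_internal_uf(
            kuf, spec.length, op.p_b_in, op.p_b_out, op.p_d_in, op.p_d_out
        )
    else:
        tmpm = tmp_mean(op.p_b_in, op.p_b_out, op.p_d_in, op.p_d_out)
        qf = uf_rate(kuf, tmpm)
        if qf < 0:
            raise DialsimUserError(
                "net backfiltration (Qf < 0) is not a valid HF/HDF operating point"
            )

    solutes: dict[str, SoluteClearance] = {}
    for name, sol in spec.solutes.items():
        if mode is TherapyMode.HF:
            kd = 0.0
            kc = convective_clearance(mode, sol.si, qf)
        else:
            kd = diffusive_clearance(sol.koa, op.qb, op.qd)
            t = transmittance(kd, op.qb)
            kc = convective_clearance(mode, sol.si, qf, t)
        solutes[name] = SoluteClearance(kd=kd, kc=kc)

    return ClearanceResult(
        mode=mode,
        solutes=solutes,
        qf=qf,
        tmpm=tmpm,
        net_uf=net_uf,
        hfx_crossover=crossover,
        hfx_degenerate=degenerate,
    )


def clearances_for_prescribed_uf(
    spec: DialyserSpec,
    mode: TherapyMode,
    qb: float,
    qd: float,
    qf: float,
    net_uf: float | None = None,
) -> ClearanceResult:
    """Clearances for a machine-controlled (volumetric) UF prescription.

    Conventional dialysis machines set Qf directly rather than exposing the
    membrane pressures; this helper computes Kd/T/Kc at a prescribed Qf.  Used
    for the clinical-fixture session (Qb 300, Qd 500, UF 0.5 L/h, 4 h).
    """
    if qf < 0:
        raise DialsimUserError("prescribed Qf must be non-negative")
    if mode is TherapyMode.HF:
        solutes = {
            n: SoluteClearance(kd=0.0, kc=convective_clearance(mode, s.si, qf))
            for n, s in spec.solutes.items()
        }
    else:
        solutes = {}
        for n, s in spec.solutes.items():
            kd = diffusive_clearance(s.koa, qb, qd)
            t = transmittance(kd, qb)
            solutes[n] = SoluteClearance(kd=kd, kc=convective_clearance(mode, s.si, qf, t))
    return ClearanceResult(
        mode=mode,
        solutes=solutes,
        qf=qf,
        tmpm=float("nan"),
        net_uf=qf if net_uf is None else net_uf,
    )
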