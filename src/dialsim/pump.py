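"""Pump characteristic curves: dialyser blood-side pressures and UF coefficient
as functions of the mean blood flow rate, per pump type.

A pulsatile blood pump develops a higher dialyser-inlet pressure than a
non-pulsatile (roller) pump at the same mean flow, while the outlet pressure is
essentially identical; the instantaneous pressure peaks also mitigate protein
layering on the membrane, raising the UF coefficient, with the advantage
shrinking as the pumping rate increases.  This module represents such curves as
tabulated data, interpolates them, reads/writes them as delimited text, and
synthesises curve pairs that reproduce those qualitative trends when no
measured table is available.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DialsimUserError, RangeError

TABLE_COLUMNS = ["pump_type", "Qb_mL_min", "Pb_in_mmHg", "Pb_out_mmHg", "Kuf_mL_h_mmHg"]


class PumpType(str, enum.Enum):
    PULSATILE = "pulsatile"
    NON_PULSATILE = "non_pulsatile"


@dataclass(frozen=True)
class PumpCurve:
    """Tabulated (Qb, P_b_in, P_b_out, K_uf) samples for one pump type.

    Qb in mL/min, pressures in mmHg, K_uf in mL/(h*mmHg).  Qb must be strictly
    increasing, K_uf positive and P_b_in >= P_b_out at every sample.
    """

    pump_type: PumpType
    qb: np.ndarray
    pb_in: np.ndarray
    pb_out: np.ndarray
    kuf: np.ndarray

    def __post_init__(self) -> None:
        for name in ("qb", "pb_in", "pb_out", "kuf"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.qb.size
        if n < 2:
            raise DialsimUserError("pump curve needs at least two samples")
        if any(arr.size != n for arr in (self.pb_in, self.pb_out, self.kuf)):
            raise DialsimUserError("pump curve columns have unequal lengths")
        if not np.all(np.diff(self.qb) > 0):
            raise DialsimUserError("Qb samples must be strictly increasing")
        if not np.all(self.kuf > 0):
            raise DialsimUserError("K_uf must be positive at every sample")
        if not np.all(self.pb_in >= self.pb_out):
            raise DialsimUserError("P_b_in must be >= P_b_out at every sample")

    @property
    def qb_range(self) -> tuple[float, float]:
        return float(self.qb[0]), float(self.qb[-1])


def interpolate_pump_state(curve: PumpCurve, qb: float) -> tuple[float, float, float]:
    """Piecewise-linear interpolation of (P_b_in, P_b_out, K_uf) at ``qb``.

    Each of the three quantities is interpolated independently between the
    neighbouring samples.  Queries outside the tabulated Qb range raise
    :class:`RangeError`; pressure behaviour outside the measured range is
    unknown, so no extrapolation is attempted.
    """
    lo, hi = curve.qb_range
    if not (lo <= qb <= hi):
        raise RangeError(
            f"Qb={qb:g} mL/min outside the tabulated range [{lo:g}, {hi:g}] mL/min"
        )
    return (
        float(np.interp(qb, curve.qb, curve.pb_in)),
        float(np.interp(qb, curve.qb, curve.pb_out)),
        float(np.interp(qb, curve.qb, curve.kuf)),
    )


@dataclass(frozen=True)
class PumpTrendParams:
    """Parametric baselines for synthetic pump-curve pairs.

    Pressures are affine in Qb; the pulsatile inlet-pressure advantage is a
    constant gap; the pulsatile K_uf advantage decays exponentially with Qb
    (the membrane-layering relief is most effective at low pumping rates).
    Noise, when enabled, is drawn once per grid point and added to *both*
    curves, so the pulsatile/non-pulsatile orderings hold for any seed.
    """

    pb_out_intercept: float = 20.0     # mmHg
    pb_out_slope: float = 0.10         # mmHg per (mL/min)
    drop_intercept: float = 20.0       # axial pressure drop at Qb=0, mmHg
    drop_slope: float = 0.10           # mmHg per (mL/min)
    inlet_gap: float = 30.0            # pulsatile extra inlet pressure, mmHg
    kuf_base: float = 35.0             # non-pulsatile K_uf, mL/(h*mmHg)
    kuf_gap0: float = 25.0             # pulsatile K_uf advantage at Qb_ref
    kuf_gap_tau: float = 300.0         # decay length of the advantage, mL/min
    qb_ref: float = 100.0              # flow at which kuf_gap0 applies
    noise_pressure: float = 0.0        # SD of shared pressure noise, mmHg
    noise_kuf: float = 0.0             # SD of shared K_uf noise, mL/(h*mmHg)

    def __post_init__(self) -> None:
        if self.kuf_base <= 0 or self.kuf_gap_tau <= 0:
            raise DialsimUserError("kuf_base and kuf_gap_tau must be positive")
        if self.inlet_gap < 0 or self.kuf_gap0 < 0:
            raise DialsimUserError("gap magnitudes must be non-negative")
        if min(self.noise_pressure, self.noise_kuf) < 0:
            raise DialsimUserError("noise amplitudes must be non-negative")


DEFAULT_QB_GRID = tuple(float(q) for q in range(100, 401, 50))


def synthesize_pump_curves(
    qb_grid: Sequence[float] = DEFAULT_QB_GRID,
    trend_params: PumpTrendParams | None = None,
    seed: int = 0,
) -> tuple[PumpCurve, PumpCurve]:
    """Generate a (pulsatile, non_pulsatile) pump-curve pair.

    The pair satisfies, at every grid point: pulsatile P_b_in > non-pulsatile
    P_b_in (when ``inlet_gap > 0``), identical P_b_out, pulsatile K_uf >=
    non-pulsatile K_uf, with the K_uf gap strictly decreasing in Qb.
    Deterministic for a fixed seed.
    """
    p = trend_params or PumpTrendParams()
    qb = np.asarray(qb_grid, dtype=float)
    if qb.ndim != 1 or qb.size < 2 or not np.all(np.diff(qb) > 0):
        raise DialsimUserError("Qb grid must be a strictly increasing 1-D sequence")
    if qb[0] < 100.0 or qb[-1] > 400.0:
        raise DialsimUserError("Qb grid must lie within 100-400 mL/min")

    rng = np.random.default_rng(seed)
    eps_p_out = rng.normal(0.0, p.noise_pressure, qb.size) if p.noise_pressure else 0.0
    eps_p_in = rng.normal(0.0, p.noise_pressure, qb.size) if p.noise_pressure else 0.0
    eps_k = rng.normal(0.0, p.noise_kuf, qb.size) if p.noise_kuf else 0.0

    pb_out = p.pb_out_intercept + p.pb_out_slope * qb + eps_p_out
    pb_in_np = pb_out + p.drop_intercept + p.drop_slope * qb + eps_p_in
    pb_in_p = pb_in_np + p.inlet_gap

    kuf_np = np.maximum(np.full(qb.size, p.kuf_base) + eps_k, 1e-6)
    gap = p.kuf_gap0 * np.exp(-(qb - p.qb_ref) / p.kuf_gap_tau)
    kuf_p = kuf_np + gap

    pulsatile = PumpCurve(PumpType.PULSATILE, qb, pb_in_p, pb_out, kuf_p)
    non_pulsatile = PumpCurve(PumpType.NON_PULSATILE, qb, pb_in_np, pb_out, kuf_np)
    return pulsatile, non_pulsatile


def curves_to_frame(curves: Sequence[PumpCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for i in range(c.qb.size):
            rows.append(
                {
                    "pump_type": c.pump_type.value,
                    "Qb_mL_min": c.qb[i],
                    "Pb_in_mmHg": c.pb_in[i],
                    "Pb_out_mmHg": c.pb_out[i],
                    "Kuf_mL_h_mmHg": c.kuf[i],
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_pump_table(curves: Sequence[PumpCurve], path) -> None:
    """Write pump curves as a tab-delimited text table."""
    curves_to_frame(curves).to_csv(path, sep="\t", index=False)


def read_pump_table(path) -> dict[PumpType, PumpCurve]:
    """Read pump curves from a delimited text table (tab or comma)."""
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except FileNotFoundError as exc:
        raise DialsimUserError(f"pump curve file not found: {path}") from exc
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise DialsimUserError(
            f"pump table {path} is missing columns {sorted(missing)}; "
            f"expected header {TABLE_COLUMNS}"
        )
    out: dict[PumpType, PumpCurve] = {}
    for name, grp in df.groupby("pump_type"):
        grp = grp.sort_values("Qb_mL_min")
        out[PumpType(name)] = PumpCurve(
            PumpType(name),
            grp["Qb_mL_min"].to_numpy(),
            grp["Pb_in_mmHg"].to_numpy(),
            grp["Pb_out_mmHg"].to_numpy(),
            grp["Kuf_mL_h_mmHg"].to_numpy(),
        )
    return out
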