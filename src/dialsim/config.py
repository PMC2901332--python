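"""Run configuration: schema-validated YAML binding all modules together.

The default configuration reproduces the reference parameter set: high-flux
dialyser constants (KoA 967/290 mL/min, Si 1/0.8), cellular transfer
coefficients 0.77/0.077 L/min, k_f 0.24 L^2/min/mmol, plasma water fraction
0.94, urea generation 6.24 mg/min, a 73-kg anuric patient at 105 mg/dL
predialysis urea, and a 3-per-week, 4-h, 5-week HDF course at Qb 300.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .clearance import DialyserSpec, SoluteSpec, TherapyMode
from .errors import DialsimUserError
from .patient import PatientParams, PatientState, default_patient
from .pump import (
    PumpCurve,
    PumpTrendParams,
    PumpType,
    read_pump_table,
    synthesize_pump_curves,
)
from .schedule import SessionPrescription, TreatmentCourse


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SoluteConfig(_Strict):
    koa: float = Field(gt=0, description="dialyser KoA, mL/min")
    si: float = Field(ge=0, le=1, description="sieving coefficient")
    eta: float = Field(gt=0, description="cellular transfer coefficient, L/min")
    beta: float = Field(gt=0, description="cell-membrane equilibrium ratio")
    g: float = Field(ge=0, description="generation rate, mg/min")
    alpha: float = Field(gt=0, description="Gibbs-Donnan ratio")


class PatientConfig(_Strict):
    weight_kg: float = Field(default=73.0, gt=0)
    water_fraction: float = Field(default=0.58, gt=0, le=1)
    predialysis_urea_mg_dl: float = Field(default=105.0, gt=0)
    predialysis_b2m_mg_l: float = Field(default=30.0, gt=0)
    plasma_water_fraction: float = Field(default=0.94, gt=0, le=1)
    k_f: float = Field(default=0.24, gt=0, description="L^2/min/mmol")


class DialyserConfig(_Strict):
    kuf_ml_h_mmhg: float = Field(default=35.0, gt=0)
    solutes: dict[str, SoluteConfig] = Field(
        default_factory=lambda: {
            "urea": SoluteConfig(koa=967.0, si=1.0, eta=0.77, beta=1.0, g=6.24, alpha=1.0),
            "b2m": SoluteConfig(koa=290.0, si=0.8, eta=0.077, beta=1.0, g=0.12, alpha=1.0),
        }
    )


class PumpSynthesisConfig(_Strict):
    qb_min: float = 100.0
    qb_max: float = 400.0
    qb_step: float = 50.0
    seed: int = 0
    pb_out_intercept: float = 20.0
    pb_out_slope: float = 0.10
    drop_intercept: float = 20.0
    drop_slope: float = 0.10
    inlet_gap: float = 30.0
    kuf_base: float = 35.0
    kuf_gap0: float = 25.0
    kuf_gap_tau: float = 300.0
    noise_pressure: float = 0.0
    noise_kuf: float = 0.0

    def trend_params(self) -> PumpTrendParams:
        return PumpTrendParams(
            pb_out_intercept=self.pb_out_intercept,
            pb_out_slope=self.pb_out_slope,
            drop_intercept=self.drop_intercept,
            drop_slope=self.drop_slope,
            inlet_gap=self.inlet_gap,
            kuf_base=self.kuf_base,
            kuf_gap0=self.kuf_gap0,
            kuf_gap_tau=self.kuf_gap_tau,
            noise_pressure=self.noise_pressure,
            noise_kuf=self.noise_kuf,
        )

    def grid(self) -> list[float]:
        out, q = [], self.qb_min
        while q <= self.qb_max + 1e-9:
            out.append(round(q, 6))
            q += self.qb_step
        return out


class PumpConfig(_Strict):
    curve_file: Optional[str] = None
    synthesis: PumpSynthesisConfig = Field(default_factory=PumpSynthesisConfig)


class TherapyConfig(_Strict):
    mode: Literal["HF", "HDF", "HFx"] = "HDF"
    pump_type: Literal["pulsatile", "non_pulsatile"] = "non_pulsatile"
    qb: float = Field(default=300.0, gt=0)
    qd: float = Field(default=300.0, ge=0)
    duration_min: float = Field(default=240.0, gt=0)
    net_fluid_removal_ml: float = Field(default=2000.0, ge=0)
    p_d_in: float = 30.0
    p_d_out: float = 10.0
    sessions_per_week: int = Field(default=3, ge=1)
    weeks: int = Field(default=5, ge=1)
    interdialytic_intake_ml_min: Optional[float] = None

    @model_validator(mode="after")
    def _hfx_no_net_uf(self) -> "TherapyConfig":
        if self.mode == "HFx" and self.net_fluid_removal_ml != 0:
            raise ValueError("HFx requires net_fluid_removal_ml = 0")
        return self


class NumericsConfig(_Strict):
    dt_min: float = Field(default=0.2, gt=0)
    output_stride: int = Field(default=10, ge=1)
    steady_rtol: float = Field(default=0.005, gt=0)


class OutputConfig(_Strict):
    directory: str = "dialsim_out"
    trajectory_csv: str = "trajectory.csv"
    dose_json: str = "dose.json"
    sessions_jsonl: str = "sessions.jsonl"


class RunConfig(_Strict):
    patient: PatientConfig = Field(default_factory=PatientConfig)
    dialyser: DialyserConfig = Field(default_factory=DialyserConfig)
    pump: PumpConfig = Field(default_factory=PumpConfig)
    therapy: TherapyConfig = Field(default_factory=TherapyConfig)
    numerics: NumericsConfig = Field(default_factory=NumericsConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: str | Path) -> RunConfig:
    p = Path(path)
    if not p.exists():
        raise DialsimUserError(f"config file not found: {p}")
    try:
        data = yaml.safe_load(p.read_text()) or {}
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(x) for x in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise DialsimUserError("invalid configuration:\n" + "\n".join(lines)) from exc
    except yaml.YAMLError as exc:
        raise DialsimUserError(f"cannot parse YAML in {p}: {exc}") from exc


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False)


# ---------------------------------------------------------------------------
# materialisation into domain objects


def build_dialyser(cfg: RunConfig) -> DialyserSpec:
    return DialyserSpec(
        solutes={n: SoluteSpec(koa=s.koa, si=s.si) for n, s in cfg.dialyser.solutes.items()},
        kuf=cfg.dialyser.kuf_ml_h_mmhg,
    )


def build_patient(cfg: RunConfig) -> tuple[PatientParams, PatientState]:
    from dataclasses import replace

    pc = cfg.patient
    params, state = default_patient(
        weight_kg=pc.weight_kg,
        predialysis_urea_mg_dl=pc.predialysis_urea_mg_dl,
        predialysis_b2m_mg_l=pc.predialysis_b2m_mg_l,
        g_b2m=cfg.dialyser.solutes["b2m"].g,
        water_fraction=pc.water_fraction,
    )
    sol = {}
    for n, sc in cfg.dialyser.solutes.items():
        sol[n] = replace(
            params.solutes[n], eta=sc.eta, beta=sc.beta, g=sc.g, alpha=sc.alpha
        )
    params = replace(
        params, k_f=pc.k_f, r=pc.plasma_water_fraction, solutes=sol
    )
    return params, state


def build_pump_curves(cfg: RunConfig) -> dict[PumpType, PumpCurve]:
    if cfg.pump.curve_file:
        return read_pump_table(cfg.pump.curve_file)
    syn = cfg.pump.synthesis
    pulsatile, non_pulsatile = synthesize_pump_curves(
        syn.grid(), syn.trend_params(), seed=syn.seed
    )
    return {PumpType.PULSATILE: pulsatile, PumpType.NON_PULSATILE: non_pulsatile}


def build_course(cfg: RunConfig) -> TreatmentCourse:
    t = cfg.therapy
    presc = SessionPrescription(
        mode=TherapyMode(t.mode),
        pump_type=PumpType(t.pump_type),
        qb=t.qb,
        qd=t.qd,
        duration=t.duration_min,
        net_fluid_removal=t.net_fluid_removal_ml,
        p_d_in=t.p_d_in,
        p_d_out=t.p_d_out,
    )
    return TreatmentCourse(
        prescription=presc,
        sessions_per_week=t.sessions_per_week,
        weeks=t.weeks,
        interdialytic_intake=t.interdialytic_intake_ml_min,
    )
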