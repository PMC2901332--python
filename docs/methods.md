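# Methods

This note records the model equations as implemented, the defaults and why
they were chosen, what the synthetic pump-curve generator does and does not
emulate, and the numerical choices.

## Dialyser clearances

Working units: flows mL/min, pressures mmHg, clearances mL/min. The UF
coefficient is configured in the clinical unit mL/(h·mmHg) and converted once
(`dialsim.units.kuf_to_ml_min_mmhg`).

- **Mean TMP.** `TMPm = mean(P_b,in, P_b,out) − mean(P_d,in, P_d,out)` — the
  standard clinical definition from the four measured port pressures. Oncotic
  pressure is ignored: the UF rate is taken as a purely hydraulic product
  `Qf = K_uf·TMPm`, consistent with deriving K_uf itself from measured
  pressure/flux data (any oncotic offset is absorbed into the measured
  coefficient). Negative TMPm yields a negative Qf and a logged warning.
- **Diffusive clearance** is the counter-current two-stream closed form in
  `KoA`, `Qb`, `Qd`. The removable singularity at `Qb = Qd` is evaluated by
  its limit `Qb·KoA/(KoA+Qb)`; the switch is taken at `|Z| < 1e-10`, where the
  general expression loses precision. The result is clamped to
  `min(Qb, Qd)` to absorb rounding at the transport bound. Blood-side flow is
  whole-blood `Qb`; the plasma-water correction enters once, in the patient
  model's removal term.
- **Transmittance.** `T = 1 − Kd/Qb`: solute already cleared by diffusion is
  unavailable to convection downstream, so each mL/min of filtration adds
  only `Si·T` mL/min of clearance. In HF (no diffusion) `Kc = Si·Qf`.
- **HFx internal filtration.** Axial pressure profiles are taken linear on
  both sides (a simplified approximation; the fibre length L cancels from the
  closed form under linearity). With the counter-current geometry — blood in
  at x = 0, dialysate in at x = L — and the zero-net-UF assignment
  `P_d,in := P_b,in`, `P_d,out := P_b,out`, the pressure difference crosses
  zero exactly at mid-fibre and the forward-filtration branch integrates to
  `K_uf·(P_b,in − P_b,out)/4`. Degenerate profiles (no crossover) are flagged
  `all_filtration` / `all_backfiltration`; in the former case the closed form
  reduces exactly to `K_uf·TMPm`.
- **Replacement fluid.** HF/HDF are post-dilution: `Q_inf = Qf − net removal
  rate`, so the patient loses only the prescribed net fluid. HFx uses no
  replacement fluid and no net UF.
- **Prescribed-UF helper.** Modern machines control Qf volumetrically;
  `clearances_for_prescribed_uf` computes Kd/T/Kc at a given Qf and is used
  for the conventional-dialysis reference session (Qb 300, Qd 500,
  UF 0.5 L/h, 4 h). The pressure route (pump curves) is used for the
  pulsatile-vs-non-pulsatile comparisons, which is where pump identity
  matters.

## Patient model

Three fluid compartments (V_ic, V_is, V_pl) and per-solute two mass pools
(M_ic, M_ex with C_ex referred to V_is + V_pl):

- `dV_ic/dt = k_f·(O_ic − O_is)` — water moves toward the higher osmolarity
  (into cells when the interior is more concentrated).
- `dV_is/dt = F_a − R_v − dV_ic/dt`
- `dV_pl/dt = R_v − F_a − (Qf − Q_inf) + intake`
- `dM_ic/dt = −η·(C_ic − β·C_ex)`
- `dM_ex/dt = +η·(C_ic − β·C_ex) + G − J`,  `J = K·α·r·C_ex`

Osmolarities include a fixed background (non-urea) osmole pool per
compartment plus the toxins' molar contributions (urea at 60.06 mg/mmol
dominates; B2M at 11.8 g/mmol is negligible but included). The background
pools are calibrated at construction so both compartments sit at 285 mmol/L
at baseline. Urea generation enters the extracellular pool (hepatic
production into blood). A consequence worth knowing: at the pre-dialytic
quasi-steady state the extracellular concentration slightly *exceeds* the
intracellular one (the cells fill from the plasma side), so the familiar
rebound ordering C_ic > C_ex holds during the ~30 min of post-session
re-equilibration — the gradient's decay time constant is
`1/(η(1/V_ic + 1/V_ex)) ≈ 12 min for urea` — and then reverses sign. Tests
and the acceptance script evaluate the rebound ordering on that 30-min
window and the plasma rise over a full hour.

**Capillary exchange** is a deliberately minimal two-conductance Starling
description (the full microvascular model behind the compartment structure is
not reproduced here): arterial filtration
`F_a = L_a·max(0, P_cap,a(V_pl) − P_is − (π_pl(V_pl) − π_is))` and venous
reabsorption analogously, with capillary pressures stiffening at
10 mmHg/L of plasma volume and π_pl ∝ 1/V_pl (fixed protein mass). Defaults
(P_cap,a 25, P_cap,v 10, P_is −3, π_pl 25, π_is 5 mmHg,
L_a = 6e-4 L/min/mmHg) give physiological baseline gradients; the venous
conductance is computed at construction so that `F_a = R_v` exactly at the
reference state. During a 0.5 L/h UF session the resulting refilling buffers
the plasma volume drop to ≈ 0.35 L (≈ 11%), a clinically plausible figure.

**Defaults** (all exposed in the YAML config): `KoA` 967/290 mL/min and
`Si` 1/0.8 for urea/B2M; `η` 0.77/0.077 L/min; `β` 1; `k_f`
0.24 L²/min/mmol; plasma water fraction `r` 0.94; `G_urea` 6.24 mg/min;
`α` 1 for both solutes (urea is uncharged; no measured value exists for B2M).
B2M generation (0.12 mg/min) and initial level (30 mg/L) are set to typical
figures for dialysis-dependent patients — production around 170 mg/day and a
predialysis plasma level of ~30 mg/L — since neither is part of the
reference parameter set. Initial volumes: total body water = weight × 0.58,
partitioned 25:12:3 (ic:is:pl); predialysis urea 105 mg/dL at cell-membrane
equilibrium.

## Treatment schedule

Three sessions/week, 4 h each, in the clinical Mon/Wed/Fri pattern
(2-2-3-day gaps) by default; other counts space evenly, and explicit offsets
override. Between sessions a constant fluid intake returns the week's net UF
over the inter-dialytic time, closing the weekly fluid balance (body weight
maintained), and solute generation continues. The horizon defaults to
5 weeks; periodic steady state is declared when the per-solute mean
pre-session concentration changes by <0.5% week-over-week. Dose indices are
computed on the final week; MPC averages all pre-session samples of that
week (the literal reading of "mean pre-treatment concentration").

## Synthetic pump curves

No tabulated pump data exist, so the generator produces the measured *trends*
with smooth parametric baselines on a 100–400 mL/min grid:

- outlet pressure affine in Qb, identical for both pumps
  (`20 + 0.10·Qb` mmHg);
- axial pressure drop affine (`20 + 0.10·Qb`), giving the non-pulsatile inlet
  pressure; the pulsatile inlet sits a constant 30 mmHg higher;
- K_uf baseline 35 mL/(h·mmHg) (a protein-layered high-flux membrane) with a
  pulsatile advantage `25·exp(−(Qb−100)/300)` that decays with flow —
  mirroring the observation that pressure peaks mitigate membrane layering
  best at low pumping rates.

Optional Gaussian noise (disabled by default) is drawn once per grid point
and added to **both** curves, so the orderings (pulsatile inlet pressure and
K_uf above non-pulsatile, K_uf gap strictly decreasing) hold for every seed
by construction. These defaults make the HF clearance gain largest at low Qb
(≈ +129% at 100 mL/min, falling to ≈ +47% at 400) while keeping all dose
indices increasing in Qb; the HDF/HFx gains land at a few percent, larger
for B2M than urea. What the generator does **not** emulate: instantaneous
pressure waveforms or pumping frequency (the clearance model consumes only
session means), measurement noise correlated across Qb, and any absolute
calibration of pressures or K_uf to a specific pump/dialyser pair — so
passing tests establish the *directional* pump effects and the internal
consistency of the model, not device-specific magnitudes.

## Numerics

- Fixed-step classical RK4 over an augmented state that carries cumulative
  dialyser removal per solute and cumulative net fluid loss. Because these
  book-keeping integrals are propagated by the same linear RK4 map as the
  states, mass balance `Δ(M_ic+M_ex) = ∫G − ∫J` and volume balance
  `ΔV_total = ∫(intake − net UF)` hold to round-off by construction, and the
  removal log used by the EKR estimator is exactly consistent with the
  trajectory.
- **Step size.** The osmotic water exchange is the stiff mode: with
  `k_f = 0.24 L²/min/mmol` and ≈285 mmol/L on ≈26/16 L compartments its
  relaxation time is ≈0.15 min, putting explicit RK4 with dt = 0.5 min
  outside its stability region. The default is **dt = 0.2 min** (λh ≈ 1.6),
  used for all courses and sweeps; session boundaries must fall on the step
  grid (durations are validated as multiples of dt). An optional
  step-halving check (`integrate(..., check=True)`) re-runs at dt/2 and
  raises an accuracy error advising a smaller dt if the final states
  disagree beyond 1e-6 relative.
- Trajectories are recorded every `output_stride` steps (default 25 ⇒ 5-min
  sampling) plus at every segment boundary; TAC uses trapezoid quadrature on
  that grid (verified against 10× finer recording to 0.1%).
- Problem sizes: the dose-index sweep runs 4 Qb × 3 modes × 2 pumps with
  2-week courses (the weekly cycle is within ~1% of its fixed point after
  two weeks for these clearances); steady-state and adequacy analyses use
  the full 5-week horizon.
- Pump-curve interpolation is piecewise linear and refuses to extrapolate
  outside the tabulated 100–400 mL/min range (behaviour there is unmeasured).
- Degenerate inputs: zero pressure gradient in HFx gives zero internal UF
  with crossover reported at 0; `KoA = 0` gives `Kd = 0`; `T = 0` (diffusion
  saturated) disables convective gain; negative prescribed Qf is rejected at
  the clearance level.

## Design choices where the design was open

- **HFx convective clearance uses the transmittance form** (`Kc = Si·Qf·T`),
  since diffusion is active in HFx; the pure-convection form applies to HF
  only.
- **HDF dialysate-side pressures** are prescription fields (defaults
  P_d,in = 30, P_d,out = 10 mmHg, typical counter-current circuit values)
  rather than pump-curve columns, because the pump characterisation covers
  the blood side only.
- **Whole-plasma vs plasma-water concentration:** the trajectory export
  provides the extracellular (plasma-water) concentration and the
  whole-plasma equivalent `r·C_ex`; dose indices use the extracellular
  profile.
- **Adequacy flags** are computed per solute but the adequacy lines
  (EKRc ≥ 11 mL/min, std Kt/V ≥ 2/week) are defined for urea in an anuric
  40-L patient; residual renal clearance is not modelled (anuric default).

## Known limitations

- No electrolyte (Na/K/Cl) or acid–base kinetics; no dialysate sodium
  profiling; no cardiovascular/baroreflex response.
- No filtration-fraction ceiling: at low Qb with a strong pulsatile pump the
  HF operating point can imply UF rates approaching plasma water flow, which
  a real machine would not sustain; interpret absolute HF clearances at low
  Qb accordingly (the pulsatile/non-pulsatile *ratios* are the meaningful
  output there).
- Membrane fouling enters only through the measured/synthetic K_uf; no
  intra-session K_uf dynamics.
- Pressure profiles along the HFx fibre are linear by assumption; curvature
  from viscosity changes along the fibre is ignored.
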