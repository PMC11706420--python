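# Methods

This note documents the models implemented in `aopbpk`, the defaults and
units that matter, the numerical choices, and what the synthetic-data
machinery does and does not demonstrate.

## Scope and units

The package predicts systemic clearance, fraction metabolized (fm),
plasma concentration–time profiles and CYP3A4/AO DDI risk for aldehyde
oxidase (AO) and dual AO–CYP3A4 substrates, from in vitro intrinsic
clearance plus standard physicochemical/ADME inputs. All whole-body
quantities are litres, hours, milligrams and mg/L; assay-scale inputs
keep their bench units (µL/min/mg protein, µL/min/10⁶ cells, ng/mL for
blood-to-plasma query concentrations) and are converted exactly once, in
the organ-scaling step (`×60·10⁻⁶` from µL/min to L/h).

## System physiology

Liver and kidney scalars carry stated means and inter-individual CVs:
hepatocellularity 120·10⁶ cells/g liver (42%), cytosolic protein
80.7 mg/g liver (30%), microsomal protein 40 mg/g liver (27%), and for
kidney cortex 53.3 mg cytosolic and 26.2 mg microsomal protein/g (30%
each). AO is modelled as a cytosolic enzyme of liver (37% abundance CV)
and kidney (52% CV), with kidney abundance 10% of hepatic per mg
cytosolic protein and no other extrahepatic expression; the enzyme
turnover constant used for time-dependent inhibition is kdeg =
0.00026 min⁻¹ (a P450 average — no AO-specific value has been
measured, and predictions of time-dependent AO inhibition inherit this
uncertainty).

Quantities the protein-scalar literature does not fix are set to
conventional healthy-adult reference values and are plainly stand-ins,
all overridable on `SystemPhysiology`: body weight 70 kg, liver 1650 g,
hepatic blood flow 97 L/h, kidneys 310 g with cortex fraction 0.70,
renal blood flow 66 L/h, villous blood flow 18 L/h, and an intestinal
CYP3A4 pool set to 1% of the hepatic one. Changing them moves absolute
clearances by a few percent but none of the qualitative conclusions.

Virtual subjects draw every CV-bearing scalar independently from a
lognormal parameterized by arithmetic mean m and CV
(σ² = ln(1+CV²), µ = ln m − σ²/2 — so the arithmetic mean of the draws
equals m). No covariance structure is imposed: none is reported for
these scalars, and correlated sampling would be guesswork. The
arithmetic mean of a sampled population ("mean-subject physiology") is
what the retrograde calculations consume.

## IVIVE

Apparent CLint is corrected for incubational binding (`value/fu_inc`),
multiplied by a system/pathway-specific empirical scaling factor, and
scaled with the matching protein scalar and organ mass. The ESFs —
cytosol-AO 5.6, microsomes 2.8, hepatocytes-AO 10.4,
hepatocytes-non-AO 4.2 — compensate the systematic loss of (especially
AO) activity in vitro; a disabled policy reduces to pure physiological
scaling. Cytosolic activity is attributed to AO and microsomal activity
to CYP3A4, the conservative reading for dual substrates without further
phenotyping; hepatocyte assays provide the AO/non-AO split directly
(chemical AO inhibition).

Kidney AO scales the *per-mg-cytosolic-protein* value by the 10%
relative abundance, kidney-cortex cytosolic protein content and cortex
mass (kidney mass × cortex fraction). Hepatocyte entries are first
converted to per-mg-cytosol via HPGL/CPPGL using mean physiology. Under
the defaults the kidney:liver AO CLint ratio is ≈0.0087 for any
cytosol-sourced compound.

Unbound fraction in cytosolic incubations prefers a measured value
(in practice from dog liver cytosol, which lacks functional AO);
otherwise `transpose_binding` maps fu_mic across protein concentrations
through a single nonspecific binding class (Ka = (1/fu−1)/c).

## Clearance network

Organ models run on blood (fu_B = fu_p/(B/P)) with the well-stirred
approximation; reported clearances are plasma (CL_p = CL_b·B/P). Within
an organ, the well-stirred clearance of the summed CLint is split across
pathways in proportion to CLint — so fm is a share of systemic
clearance, not of raw CLint, and high-extraction compounds are handled
consistently. Renal and biliary excretory clearances enter as observed
plasma values. Gut availability uses the Qgut model with gut CYP3A4
CLint tied to the scaled hepatic CYP3A4 pathway by the 1% abundance
ratio and fu_gut defaulting to fu_p; when no Qgut value is supplied it
is predicted from permeability (Peff from Papp by the
log-linear regression logPeff = 0.6431·logPapp − 0.34; absorptive
area 0.66 m²).

Concentration-dependent blood-to-plasma tables are resolved by the
tabulated point nearest the query concentration on the log scale (no
interpolation), queried by default at the predicted Cmax of the
compound's standard regimen. CL/F for oral drugs is nearly independent
of this choice (for hepatic elimination B/P cancels exactly), so the
convention is benign.

**Retrograde (middle-out / top-down).** Observed excretory clearance is
subtracted from observed plasma clearance and the joint liver+kidney
well-stirred system inverted for total liver CLint,u; kidney AO is tied
to liver AO by the fixed abundance ratio, and for oral observations fa,
Fg (itself a function of the solved CLint) and F_H are folded in. The
inversion is a bracketed 1-D root find (`brentq`, relative tolerance
10⁻⁹; the bracket grows geometrically from the linear regime). An
observed metabolic blood clearance at or above the available organ flow
raises an explicit infeasibility error reporting the flow that would be
required. A supplied fm table splits the recovered CLint,u
proportionally (top-down); without one, all metabolism is attributed to
AO — the conservative choice for AO-cleared drugs. `middle_out_fm`
instead redistributes a bottom-up model's total CLint,u to an observed
fm split, leaving total clearance essentially unchanged.

## PK engine

The minimal model has an absorption depot, a central compartment
V_c = (Vss − Vsac)·BW and a single adjusting compartment exchanging with
clearance Q. Hepatic and gut first pass act as the scalar Fg·F_H on the
absorption flux rather than through an explicit portal/liver chain: AUC,
CL and Cmax are invariant to that choice; transient liver concentrations
(not an output of this package) are not. Absorption lag is a pure delay
on depot initialization. The full model is perfusion-limited over a
reduced tissue set (adipose, muscle, liver, kidney, rest) with
venous/arterial pools; the liver (plus kidney AO) clears on its outflow
blood concentration, which makes dose/AUC agree with the well-stirred
algebra by construction. Kp sets are user-supplied (tissue-composition
prediction is out of scope); a uniform Vss-matched set is available as a
stand-in, and a >15% mismatch between Kp-implied and recorded Vss warns.

Integration is piecewise over dose events with LSODA (rtol 10⁻⁸, atol
10⁻¹², dense output resampled to the requested grid). Non-compartmental
metrics use linear-up/log-down trapezoids; λz comes from log-linear
regression over the last ≥3 positive concentrations (a wider window is
advisable for noisy data), requiring only a negative slope; AUC_inf =
AUC_t + C_last/λz. An instantaneous venous bolus in the full model
produces a sub-grid mixing spike (time constant V_venous/Q_co ≈ 0.01 h);
AUC comparisons there should dose by short infusion or use a fine early
grid.

## DDI

The static model multiplies each affected pathway's clearance by
x = [1/(1+I/Ki)]·[kdeg/(kdeg+kinact·I/(KI+I))]·[1+d·Indmax·I/(IndC50+I)],
terms present only when parameterized, and AUCR = 1/(Σfm·x + 1−Σfm).
Two exposure bases are provided: unbound hepatic-inlet Cmax (default for
CYP3A4 predictions, conservative) and unbound systemic Cmax (the basis
of the AO exposure-margin screen Cmax,u/Ki,u). Intestinal interaction is
omitted because predicted Fg for the dual substrates is ≥0.98. A Ki,u
range (e.g. discordant literature values) propagates to an AUCR band;
min/max fm assumptions should bracket any point prediction. AO is
treated as non-inducible.

The dynamic variant co-simulates the victim with one enzyme-amount state
per affected enzyme (dE/dt = synthesis − degradation, inhibitor-modified
on both sides) and pathway CLint scaled by (E/E₀)/(1+I_u/Ki); at
constant inhibitor exposure the enzyme pool starts at steady state and
the result converges to the static model (regression-tested at 2%, using
a low-extraction victim — at high hepatic extraction the static fm
formulation and explicit CLint scaling legitimately diverge).

Perpetrator kinetic constants are deliberately **not** packaged:
published Ki/kinact/KI values for the usual CYP3A4 and AO perpetrators
vary several-fold between laboratories, so users must supply values they
have verified.

## Evaluation

GMFE = 10^mean|log₁₀(pred/obs)| (spread), AFE = 10^mean log₁₀(pred/obs)
(bias), RMSE untransformed, and the fraction within k-fold (default 2).
Guest limits for AUC ratios use L = (δ+2(R−1))/R after mirroring ratios
below 1, with δ = 1 by default (the strict variant; δ = 1.25 available).
All metrics operate on plasma-scale quantities as reported clinically.

## Synthetic data and what it shows

`synth_profiles` draws between-subject lognormal variability on
clearance (through the well-stirred nonlinearity, so realized
dose/AUC_inf matches the drawn multiplier exactly) and on Vss, then
applies proportional lognormal residual error — the minimal error model
for concentration assays. `synth_mass_balance` perturbs true pathway
fractions lognormally on the simplex and reports the replicate mean and
min/max envelope. `recovery_experiment` chains the whole middle-out
machinery: simulate a study from a random plausible compound, estimate
CL non-compartmentally, back-calculate CLint,u, and compare with truth
(noiseless recovery is exact to <0.1%; with 20% residual CV and 24
subjects it is within 15% for the tested seeds).

These generators validate the *machinery* — identities, inverses,
estimator behaviour under known noise. They do not emulate covariates,
BLQ censoring, dropout, nonlinear kinetics or enterohepatic
recirculation, so passing recovery tests says nothing about those
features of real clinical data.

## Problem sizes and defaults used in the shipped analyses

The packaged acceptance analysis uses the six shipped drug records, the
default physiology for bottom-up predictions, a 1000-subject virtual
population (seeded) whose arithmetic mean drives the retrograde step,
and simulation grids of a few hundred points over 8–16 terminal
half-lives. Everything runs in seconds on one core.

## Known limitations

- Linear CLint only: no Km/Vmax saturation, so high-dose nonlinearity
  (e.g. idelalisib at 400 mg) is outside the model.
- The non-AO pathway is treated wholesale as CYP3A4; minor CYP/UGT
  contributions fold into it.
- Liver/kidney masses and flows are literature stand-ins, not fitted.
- First-order absorption only; no segmented-gut model, no transporters.
- The full-PBPK tissue set is reduced and perfusion-limited; it is meant
  for Vss-consistent distribution, not organ-level exposure prediction.
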