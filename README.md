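# aopbpk

Physiologically based pharmacokinetic (PBPK) modelling for **aldehyde
oxidase (AO)** substrates and **dual AO–CYP3A4** substrates.

AO is a cytosolic enzyme of liver and kidney that oxidizes
azaheterocycles (many kinase inhibitors among them). Its in vivo
clearance is systematically underpredicted from in vitro systems, there
are no clinical index AO inhibitors, and most AO substrates are also
CYP3A4 substrates — so the fraction metabolized by AO (fm_AO) is hard to
pin down and drug–drug interaction (DDI) risk assessment for these
compounds is unusually uncertain. This package implements a reusable,
tested pipeline for that problem, aimed at DMPK / clinical pharmacology
scientists:

- **IVIVE** of intrinsic clearance from human liver cytosol (HLC),
  microsomes (HLM) or hepatocytes (HH), with incubational-binding
  correction, empirical scaling factors (ESFs: 5.6 cytosol-AO, 2.8
  microsomes, 10.4 hepatocytes-AO, 4.2 hepatocytes-non-AO) and
  physiological scalars, including renal AO at 10% of hepatic abundance
  per mg cytosolic protein.
- **Clearance networks**: well-stirred liver and kidney on the blood
  scale, Qgut-model gut availability, forward prediction of CL and CL/F,
  and retrograde back-calculation of in vivo CLint,u for middle-out and
  top-down model refinement.
- **PK simulation**: minimal PBPK (central + single adjusting
  compartment, first-order absorption with lag) and a perfusion-limited
  full model with user-supplied Kp sets; non-compartmental metrics.
- **DDI prediction**: mechanistic static model (reversible, time-dependent
  and induction terms; enzyme turnover kdeg = 0.00026 min⁻¹) and a
  dynamic enzyme-turnover co-simulation; Guest acceptance limits, GMFE /
  AFE / RMSE / twofold metrics.
- **Synthetic data**: noisy concentration–time studies, mass-balance fm
  tables with uncertainty envelopes, and end-to-end parameter-recovery
  experiments.

The core organ model is the well-stirred relation on the blood scale

    CL_b = Q · fu_B · CLint,u / (Q + fu_B · CLint,u),   fu_B = fu_p / (B/P)

with whole-organ unbound intrinsic clearance obtained as

    CLint,u = (CLint,app / fu_inc) · ESF · PS · M_organ · 60·10⁻⁶  [L/h]

where PS is the protein/cellularity scalar matching the assay (CPPGL
80.7 mg cytosolic protein/g liver, MPPGL 40 mg/g, HPGL 120·10⁶
hepatocytes/g) and M the organ mass. Gut availability uses
Fg = Qgut/(Qgut + fu_gut·CLint,gut,u), and the static DDI model is
AUCR = 1/(Σᵢ fmᵢ·xᵢ + 1 − Σᵢ fmᵢ).

Input records for six drugs spanning the in vivo AO clearance range —
capmatinib, idelalisib, lenvatinib, zaleplon, ziprasidone, zoniporide —
ship with the package.

## Worked example

Bottom-up model of ziprasidone from microsomal + cytosolic data with
ESFs:

```python
import aopbpk as a

phys = a.default_physiology()
zipr = a.fixture("ziprasidone")
pc = a.assemble_pathways(zipr, phys, source="HLM+HLC", esf=a.ESFPolicy())
print(f"CL_iv  = {pc.cl_total_plasma:.2f} L/h (observed {zipr.cl_obs.summary:.2f})")
print(f"fm_AO  = {pc.fm['AO']:.3f}   Fg = {pc.fg:.3f}   F_H = {pc.fh:.3f}")

no_esf = a.assemble_pathways(zipr, phys, esf=a.ESFPolicy.disabled())
print(f"fm_AO without ESFs = {no_esf.fm['AO']:.3f}")
```

prints

```
CL_iv  = 13.06 L/h (observed 23.04)
fm_AO  = 0.362   Fg = 0.983   F_H = 0.756
fm_AO without ESFs = 0.221
```

i.e. the ESF-supported model predicts ziprasidone systemic clearance
within twofold of the 23.04 L/h observation, and applying the
system-specific ESFs raises the predicted AO share of clearance from
0.22 to 0.36 (the cytosol factor 5.6 outweighs the microsome factor
2.8). The same objects feed the simulator and the DDI layer; the
equivalent shell command is
`aox ivive --compound ziprasidone --source hlm-hlc --esf`.

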