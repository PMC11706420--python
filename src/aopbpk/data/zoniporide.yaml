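name: zoniporide
mw: 320.35
ionization: diprotic base
logp: 1.15
pka1: 3.4
pka2: 7.2
fu_p: 0.288
bp:
  points:
  - [null, 0.86]
papp: 1.72
distribution:
  model: full
  vss: 1.70
  kp_scalar: 0.64
clint_entries:
- {system: HLM, pathway: nonAO, value: 5.19, fu_inc: 0.642, protein_conc: 0.5}
- {system: HLC, pathway: AO, value: 16.5, fu_inc: 0.664, protein_conc: 1.0}
- {system: HH, pathway: nonAO, value: 1.6, fu_inc: 0.890}
- {system: HH, pathway: AO, value: 5.3, fu_inc: 0.890}
cl_obs: {route: iv, value: 95.35, cv_percent: 5.7}
cl_renal_obs: 16.2
regimen: {route: iv-infusion, dose: 80, infusion_duration: 1.0}
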