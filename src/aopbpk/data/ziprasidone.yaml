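name: ziprasidone
mw: 412.94
ionization: diprotic base
logp: 4.53
pka1: 8.24
pka2: 6.31
fu_p: 0.0029
bp:
  points:
  - [null, 0.55]
papp: 3.15
fa: 0.744
ka: 0.417
t_lag: 4.0
qgut: 6.21
distribution:
  model: full
  vss: 1.01
  kp_scalar: 0.56
clint_entries:
- {system: HLM, pathway: nonAO, value: 71.9, fu_inc: 0.210, protein_conc: 0.5}
- {system: HLC, pathway: AO, value: 4.67, fu_inc: 0.098, protein_conc: 1.0}
- {system: HH, pathway: total, value: 21.8, fu_inc: 0.261}
cl_obs: {route: iv, value: 23.04, cv_percent: 14}
cl_renal_obs: 0.0
fm_obs:
  mean: {AO: 0.67}
regimen: {route: iv-infusion, dose: 5, infusion_duration: 1.0}
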