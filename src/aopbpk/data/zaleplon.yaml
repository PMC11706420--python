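name: zaleplon
mw: 305.34
ionization: neutral
logp: 1.3
fu_p: 0.569
bp:
  points:
  - [null, 0.91]
papp: 38.9
fa: 0.994
ka: 2.10
t_lag: 0.25
qgut: 15.0
distribution:
  model: minimal
  vss: 1.16
  vsac: 0.00001
  q_intercompartment: 0.0
  kp_scalar: 1.7
clint_entries:
- {system: HLM, pathway: nonAO, value: 5.95, fu_inc: 0.964, protein_conc: 0.5}
- {system: HLC, pathway: AO, value: 4.12, fu_inc: 1.000, protein_conc: 1.0}
- {system: HH, pathway: nonAO, value: 0.8, fu_inc: 0.830}
- {system: HH, pathway: AO, value: 1.9, fu_inc: 0.830}
cl_obs:
  route: iv
  strata: {female: 52.51, male: 71.58}
cl_renal_obs: 0.0
fm_obs:
  minimum: {AO: 0.57}
  maximum: {AO: 0.74}
regimen: {route: iv-infusion, dose: 5, infusion_duration: 1.0}
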