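name: idelalisib
mw: 415.42
ionization: diprotic base
logp: 2.0
pka1: 1.6
pka2: 3.4
fu_p: 0.0536
bp:
  points:
  - [null, 0.7]
papp: 16.2
fa: 0.965
ka: 1.20
qgut: 11.9
distribution:
  model: minimal
  vss: 0.811
  vsac: 0.108
  q_intercompartment: 0.347
  kp_scalar: 1.0
clint_entries:
- {system: HLM, pathway: nonAO, value: 9.73, fu_inc: 0.828, protein_conc: 0.5}
- {system: HLC, pathway: AO, value: 3.82, fu_inc: 0.523, protein_conc: 1.0}
- {system: HH, pathway: nonAO, value: 3.9, fu_inc: 0.836}
- {system: HH, pathway: AO, value: 1.6, fu_inc: 0.836}
cl_obs: {route: oral, value: 15.3, cv_percent: 28.2}
cl_renal_obs: 0.459
fm_obs:
  minimum: {CYP3A4: 0.12}
  maximum: {CYP3A4: 0.68}
regimen: {route: oral, dose: 150}
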