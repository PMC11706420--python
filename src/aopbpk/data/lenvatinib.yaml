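name: lenvatinib
mw: 426.85
ionization: ampholyte
logp: 3.3
pka1: 12.37
pka2: 5.05
fu_p: 0.0247
bp:
  points:
  - [null, 0.645]
papp: 29.8
fa: 0.989
ka: 1.77
qgut: 14.1
distribution:
  model: minimal
  vss: 1.33
  vsac: 0.492
  q_intercompartment: 1.53
  kp_scalar: 1.0
clint_entries:
- {system: HLM, pathway: nonAO, value: 7.43, fu_inc: 0.627, protein_conc: 0.5}
- {system: HLC, pathway: AO, value: 0.982, fu_inc: 0.331, protein_conc: 1.0}
- {system: HH, pathway: nonAO, value: 0.5, fu_inc: 0.137}
- {system: HH, pathway: AO, value: 0.3, fu_inc: 0.137}
cl_obs: {route: oral, value: 9.9, cv_percent: 34.3}
cl_renal_obs: 0.040
fm_obs:
  minimum: {CYP3A4: 0.28}
regimen: {route: oral, dose: 10}
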