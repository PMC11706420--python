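name: capmatinib
mw: 412.43
ionization: ampholyte
logp: 3.04
pka1: 12.8
pka2: 4.55
fu_p: 0.0516
bp:
  points:
  - [5000, 1.37]
  - [1000, 2.56]
  - [50, 3.58]
  - [10, 3.95]
papp: 32
fa: 0.67
ka: 0.623
qgut: 14.4
distribution:
  model: minimal
  vss: 0.620
  vsac: 0.218
  q_intercompartment: 1.81
  kp_scalar: 1.0
clint_entries:
- {system: HLM, pathway: nonAO, value: 30.4, fu_inc: 0.826, protein_conc: 0.5}
- {system: HLC, pathway: AO, value: 4.04, fu_inc: 0.461, protein_conc: 1.0}
- {system: HH, pathway: nonAO, value: 7.8, fu_inc: 0.671}
- {system: HH, pathway: AO, value: 0.7, fu_inc: 0.671}
cl_obs: {route: oral, value: 42.3, cv_percent: 60}
cl_renal_obs: 0.0
fm_obs:
  mean: {AO: 0.40}
regimen: {route: oral, dose: 600}
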