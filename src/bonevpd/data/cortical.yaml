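# Calibrated cortical bone parameters (bovine femoral cortical bone,
# transversely isotropic about material axis 1).  Moduli in MPa, eta in s.
name: cortical
elastic:
  E1: 19900.0
  E2: 11200.0
  E3: 11200.0
  nu12: 0.3
  nu23: 0.4
  nu31: 0.3
  G12: 5700.0
  G23: 4300.0
  G31: 5700.0
damage:
  k0: 1.0e-4
  kp: 5.0
hardening:
  yr: 5.0
  sh: 10.5
  ks: 0.01
  ss: 1.5
  mode: softening
viscosity:
  m: 5.0
  eta: 0.01
yield:
  eps0p: 0.0018
  eps0m: 0.015
  xi0: 0.25
  m1: [1.0, 0.0, 0.0]
  m2: [0.0, 1.0, 0.0]
  m3: [0.0, 0.0, 1.0]
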