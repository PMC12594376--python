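# Calibrated trabecular bone parameters (human lumbar spine trabecular bone,
# transversely isotropic about material axis 1).  Moduli in MPa, eta in s.
name: trabecular
elastic:
  E1: 280.0
  E2: 160.0
  E3: 160.0
  nu12: 0.22
  nu23: 0.48
  nu31: 0.22
  G12: 80.0
  G23: 60.0
  G31: 80.0
damage:
  k0: 1.0e-4
  kp: 5.0
hardening:
  yr: 5.5
  sh: 20.0
  ks: 0.005
  ss: 4.5
  mode: softening
viscosity:
  m: 5.0
  eta: 0.01
yield:
  eps0p: 0.005
  eps0m: 0.0075
  xi0: 0.25
  m1: [1.0, 0.0, 0.0]
  m2: [0.0, 1.0, 0.0]
  m3: [0.0, 0.0, 1.0]
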