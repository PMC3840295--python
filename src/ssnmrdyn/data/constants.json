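{
  "hbar": 1.054571817e-34,
  "mu0_over_4pi": 1e-07,
  "gamma": {
    "1H": 267519000.0,
    "15N": -27116000.0
  },
  "rNH_angstrom": 1.02,
  "delta_sigma_ppm": 170.0,
  "rigid_NH_anisotropy_hz": 20400.0
}
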