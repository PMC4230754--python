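{
  "_comment": "Contractile-element curve shapes for slow (type-I) and fast (type-II) fibres, in the virtual-muscle formulation: FL(L) = exp(-|(L^beta - 1)/omega|^rho); FV piecewise in normalised fibre velocity V (L0/s, positive = stretch): shortening (V<=0): (vmax - V)/(vmax + V*(cv0 + cv1*L)); lengthening (V>0): (bv - V*(av0 + av1*L + av2*L^2))/(bv + V). vmax is negative by the shortening sign convention.",
  "version": 1,
  "slow": {
    "fl": {"beta": 2.30, "omega": 1.12, "rho": 1.62},
    "fv": {"vmax": -7.88, "cv0": 5.88, "cv1": 0.0,
           "av0": -4.70, "av1": 8.41, "av2": -5.34, "bv": 0.35}
  },
  "fast": {
    "fl": {"beta": 1.55, "omega": 0.75, "rho": 2.12},
    "fv": {"vmax": -9.15, "cv0": -5.70, "cv1": 9.18,
           "av0": -1.53, "av1": 0.0, "av2": 0.0, "bv": 0.69}
  }
}
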