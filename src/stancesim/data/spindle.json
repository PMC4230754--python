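{
  "_comment": "Muscle spindle intrafusal-fibre parameters (bag1, bag2, chain) in the tension-based formulation. Tension units are arbitrary ('FU') and lengths are in optimal-fibre-length units; the afferent gains (gain_primary, gain_secondary, Hz per FU-derived stretch unit) were adjusted so that the Ia and II operating rates in quiet stance fall in the 5-40 Hz band of human microneurography, as the cited receptor literature does not fix them.",
  "version": 1,
  "bag1": {
    "k_sr": 10.4649,
    "k_pr": 0.15,
    "mass": 0.0002,
    "beta0": 0.0605,
    "beta_fus": 0.2592,
    "gamma_fus": 0.0289,
    "tau": 0.149,
    "freq": 60.0,
    "p": 2.0
  },
  "bag2": {
    "k_sr": 10.27,
    "k_pr": 0.0356,
    "mass": 0.0002,
    "beta0": 0.0822,
    "beta_fus": -0.046,
    "gamma_fus": 0.0636,
    "tau": 0.205,
    "freq": 60.0,
    "p": 2.0
  },
  "chain": {
    "k_sr": 10.27,
    "k_pr": 0.0356,
    "mass": 0.0002,
    "beta0": 0.0822,
    "beta_fus": -0.069,
    "gamma_fus": 0.0954,
    "tau": 0.0,
    "freq": 90.0,
    "p": 2.0
  },
  "shared": {
    "c_lengthening": 1.0,
    "c_shortening": 0.42,
    "a": 0.3,
    "r": 0.46,
    "l0_sr": 0.04,
    "l0_pr": 0.76,
    "ln_sr": 0.0423,
    "ln_pr": 0.89,
    "x": 0.7,
    "l_secondary": 0.04,
    "occlusion": 0.156
  },
  "gain_primary": 9000.0,
  "gain_secondary": 5000.0
}
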