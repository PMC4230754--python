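{
  "_comment": "Motor-unit pool composition (counts of S/FR/FF motor neurons per motor nucleus) and the distributions that map each motor unit's spike train to muscle activation: second-order critically damped filter time constant tau_act (ms, linear across each type segment), tetanic rate (Hz, the firing rate at which the saturated activation reaches its tetanic plateau), and tetanic amplitude (dimensionless, exponential across the whole pool with the given range factor, so small low-threshold units contribute little force). EMG motor-unit action potentials are first-order Hermite-Rodriguez shapes with amplitude ~ tetanic_amplitude^amp_exponent and duration lambda (ms).",
  "version": 1,
  "composition": {
    "SO": {
      "S": 800,
      "FR": 50,
      "FF": 50
    },
    "MG": {
      "S": 300,
      "FR": 150,
      "FF": 150
    },
    "LG": {
      "S": 130,
      "FR": 65,
      "FF": 65
    },
    "TA": {
      "S": 250,
      "FR": 50,
      "FF": 50
    }
  },
  "activation": {
    "tau_act_ms": {
      "S": [
        130.0,
        95.0
      ],
      "FR": [
        60.0,
        42.0
      ],
      "FF": [
        40.0,
        26.0
      ]
    },
    "tetanic_rate_hz": {
      "S": [
        12.0,
        20.0
      ],
      "FR": [
        20.0,
        35.0
      ],
      "FF": [
        35.0,
        50.0
      ]
    },
    "amplitude_range_factor": 10.0,
    "saturation_at_tetanic": 0.964
  },
  "emg": {
    "amp_exponent": 0.6,
    "lambda_ms": {
      "S": [
        6.0,
        4.5
      ],
      "FR": [
        4.5,
        3.5
      ],
      "FF": [
        3.5,
        2.5
      ]
    },
    "noise_rms_frac": 0.0
  }
}
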