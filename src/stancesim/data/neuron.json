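{
  "_comment": "Electrophysiological parameter set for the spinal neuron models (two-compartment motor neurons, point interneurons) in the pulse-conductance simplification of the cat lumbar motoneuron literature. Values not printed in any table were chosen to reproduce type-graded input resistance, rheobase ordering (S < FR < FF), afterhyperpolarisation durations and f-I behaviour of cat MNs, and are versioned here. Bands are [first_unit, last_unit] and interpolate linearly across each type segment of a pool. Units: conductances uS, capacitance-time-constants ms, potentials mV relative to rest, rates 1/ms.",
  "version": 1,
  "motoneuron": {
    "S": {
      "g_leak_soma": [
        0.35,
        0.55
      ],
      "tau_soma": [
        10.0,
        8.0
      ],
      "v_threshold": [
        11.37,
        16.37
      ],
      "tau_ahp": [
        90.0,
        70.0
      ],
      "axon_velocity": [
        44.0,
        51.0
      ]
    },
    "FR": {
      "g_leak_soma": [
        0.55,
        0.7
      ],
      "tau_soma": [
        8.0,
        7.0
      ],
      "v_threshold": [
        16.37,
        18.87
      ],
      "tau_ahp": [
        55.0,
        40.0
      ],
      "axon_velocity": [
        51.0,
        52.0
      ]
    },
    "FF": {
      "g_leak_soma": [
        0.7,
        0.9
      ],
      "tau_soma": [
        7.0,
        6.0
      ],
      "v_threshold": [
        18.87,
        21.87
      ],
      "tau_ahp": [
        35.0,
        25.0
      ],
      "axon_velocity": [
        52.0,
        53.0
      ]
    },
    "dend_leak_ratio": 1.3,
    "g_coupling": 1.2,
    "g_na_ratio": 100.0,
    "g_kf_ratio": 20.0,
    "g_ks_ratio": 7.0,
    "delta_q": 0.5,
    "axon_length_m": 0.8
  },
  "interneuron": {
    "g_leak": [
      0.08,
      0.1
    ],
    "tau": [
      6.0,
      5.0
    ],
    "v_threshold": [
      10.0,
      20.0
    ],
    "tau_ahp": [
      35.0,
      25.0
    ],
    "g_na_ratio": 70.0,
    "g_kf_ratio": 20.0,
    "g_ks_ratio": 5.0,
    "delta_q": 0.4,
    "conduction_delay_ms": 1.0
  },
  "spike": {
    "e_na": 120.0,
    "e_k": -10.0,
    "na_pulse_ms": 0.6,
    "alpha_m": 22.0,
    "beta_m": 13.0,
    "h_pulse_ms": 0.6,
    "alpha_h": 8.0,
    "beta_h": 0.12,
    "kf_pulse_ms": 0.8,
    "alpha_n": 4.0,
    "beta_n": 0.45,
    "refractory_ms": 3.0
  },
  "synapse": {
    "exc": {
      "alpha": 6.0,
      "beta": 0.5,
      "pulse_ms": 1.0,
      "e_rev": 70.0
    },
    "inh": {
      "alpha": 2.0,
      "beta": 0.33,
      "pulse_ms": 1.0,
      "e_rev": -16.0
    },
    "transmission_delay_ms": 0.5
  },
  "threshold_jitter_frac": 0.025
}
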