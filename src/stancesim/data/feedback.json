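{
  "_comment": "Sensory feedback parameters: afferent counts per muscle, conduction-velocity bands (linear along each bundle), recruitment law (thresholds linear 0-50 Hz, initial rates Gaussian mean 5 Hz sd 2.5 Hz), connectivity fractions and projection saturation conductances (nS), and the descending-drive projection. no_mg_ia_to_so: Ia afferents from MG make no connection onto SO motor neurons.",
  "version": 1,
  "afferent_counts": {
    "SO": {
      "Ia": 400,
      "II": 500,
      "Ib": 300
    },
    "MG": {
      "Ia": 160,
      "II": 200,
      "Ib": 120
    },
    "LG": {
      "Ia": 160,
      "II": 200,
      "Ib": 120
    },
    "TA": {
      "Ia": 280,
      "II": 350,
      "Ib": 140
    }
  },
  "conduction_velocity": {
    "Ia": [
      62.0,
      67.0
    ],
    "Ib": [
      56.0,
      62.0
    ],
    "II": [
      30.0,
      35.0
    ]
  },
  "recruitment": {
    "threshold_range_hz": [
      0.0,
      50.0
    ],
    "initial_rate_mean_hz": 5.0,
    "initial_rate_sd_hz": 2.5,
    "gamma_order": 6
  },
  "path_length_m": 0.8,
  "interneurons_per_group": 350,
  "connectivity": {
    "ia_to_mn_homonymous": 0.8,
    "ia_to_mn_synergist": 0.15,
    "ia_to_in": 0.7,
    "ib_to_in": 0.3,
    "ii_to_in": 0.3,
    "ia_in_to_mn": 0.15,
    "ib_in_to_mn": 0.1,
    "ii_in_to_mn": 0.2,
    "no_mg_ia_to_so": true
  },
  "g_max_ns": {
    "ia_to_mn": 600.0,
    "ia_to_in": 600.0,
    "ii_to_in": 450.0,
    "ib_to_in": 300.0,
    "in_to_mn": 300.0
  },
  "descending": {
    "n_axons": 400,
    "rate_hz": 50.0,
    "shape": 25,
    "connectivity": 0.3,
    "g_max_ns": 656.0,
    "targets": [
      "SO",
      "MG",
      "LG"
    ]
  },
  "gto": {
    "rate_max_hz": 60.0,
    "force_half_n": 4.0,
    "tf_zeros": [
      0.15,
      1.5,
      16.0
    ],
    "tf_poles": [
      0.2,
      2.0,
      37.0
    ]
  }
}
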