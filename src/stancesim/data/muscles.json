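{
  "_comment": "Musculotendon parameters for the ankle muscles. Passive parameters per muscle; polynomial kinematics (MTU length and moment arm vs ankle angle in degrees, dorsiflexion/forward lean positive). length_poly coefficients in cm/deg^k, moment_arm_poly in cm/deg^k; plantar-flexor moment arms are negative.",
  "version": 1,
  "shared": {
    "k_pe": 5.0,
    "b_pe": 0.005,
    "strain_pe": 0.50,
    "tendon_ct": 27.80,
    "tendon_kt": 0.0047,
    "tendon_lr": 0.964
  },
  "muscles": {
    "SO": {
      "group": "TS",
      "f0_n": 3586.0,
      "l0_cm": 4.90,
      "mass_kg": 0.53,
      "alpha0_deg": 28.30,
      "lt0_cm": 28.90,
      "length_poly": [32.30, 7.22e-2, -2.24e-4, -3.15e-6, 9.27e-8],
      "moment_arm_poly": [-4.10, 2.57e-2, 5.45e-4, -2.22e-5, -5.50e-7]
    },
    "MG": {
      "group": "TS",
      "f0_n": 1306.0,
      "l0_cm": 5.70,
      "mass_kg": 0.22,
      "alpha0_deg": 9.90,
      "lt0_cm": 42.40,
      "length_poly": [46.40, 7.48e-2, -1.13e-4, -3.50e-6, 7.35e-8],
      "moment_arm_poly": [-4.30, 1.30e-2, 6.08e-4, -1.87e-5, -1.02e-7]
    },
    "LG": {
      "group": "TS",
      "f0_n": 606.0,
      "l0_cm": 6.40,
      "mass_kg": 0.12,
      "alpha0_deg": 12.0,
      "lt0_cm": 41.30,
      "length_poly": [45.50, 7.62e-2, -1.25e-4, -3.55e-6, 7.65e-8],
      "moment_arm_poly": [-4.40, 1.44e-2, 6.18e-4, -1.94e-5, -1.02e-7]
    },
    "TA": {
      "group": "TA",
      "f0_n": 674.0,
      "l0_cm": 6.80,
      "mass_kg": 0.15,
      "alpha0_deg": 9.60,
      "lt0_cm": 24.90,
      "length_poly": [30.60, -7.44e-2, -1.41e-4, 2.42e-6, 1.50e-8],
      "moment_arm_poly": [4.30, 1.66e-2, -3.89e-4, -4.45e-5, -4.34e-7]
    }
  }
}
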