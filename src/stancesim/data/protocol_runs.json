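{
 "_comment": "Tuned study conditions for the six reference standing runs: per-run fusimotor means found by grid search (first pair whose 30-s run completes, mirroring the per-run adjustment of the protocol) and, for model 1, release at that variant's own quasi-static equilibrium lean. Scale 0.1.",
 "version": 1,
 "scale": 0.1,
 "duration": 30.0,
 "runs": [
  {
   "variant": "model2",
   "seed": 1,
   "fusimotor_static": 30.5,
   "fusimotor_dynamic": 32.0,
   "theta0_deg": 6.4
  },
  {
   "variant": "model2",
   "seed": 2,
   "fusimotor_static": 30.5,
   "fusimotor_dynamic": 32.0,
   "theta0_deg": 6.4
  },
  {
   "variant": "model2",
   "seed": 3,
   "fusimotor_static": 30.0,
   "fusimotor_dynamic": 31.5,
   "theta0_deg": 6.4
  },
  {
   "variant": "model1",
   "seed": 1,
   "fusimotor_static": 30.5,
   "fusimotor_dynamic": 32.0,
   "theta0_deg": 7.4
  },
  {
   "variant": "model1",
   "seed": 2,
   "fusimotor_static": 30.5,
   "fusimotor_dynamic": 32.0,
   "theta0_deg": 7.4
  },
  {
   "variant": "model1",
   "seed": 3,
   "fusimotor_static": 30.5,
   "fusimotor_dynamic": 32.0,
   "theta0_deg": 7.4
  }
 ]
}
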