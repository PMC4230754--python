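# Methods

`stancesim` simulates human upright quiet standing with a spiking spinal
circuit closed around Hill-type ankle muscles and a single-link inverted
pendulum, and quantifies the simulated sway with the standard
posturography/motor-unit battery.  This note records the model, the
numerical choices, the free parameters and how they were set, and what the
reduced-scale study conditions do and do not show.

## Model overview

Four motor nuclei (soleus SO, medial and lateral gastrocnemius MG/LG,
tibialis anterior TA) and ten interneuron pools (Ia-inhibitory pools for
the triceps-surae and TA sides; Ib-inhibitory and group-II-excitatory
pools per muscle) are simulated as conductance-based neurons.  Sensory
feedback comes from a muscle-spindle model (bag1/bag2/chain intrafusal
fibres; Ia and II outputs) in parallel with each muscle's fibres and a
Golgi tendon organ in series with each tendon (Ib output).  Continuous
receptor rates are converted to afferent spike trains by a recruitment law
(thresholds linear from 0 to 50 Hz along each bundle, initial rates
Gaussian 5 ± 2.5 Hz) and non-homogeneous gamma point processes (default
order 6, ISI CV ≈ 0.41).  The circuit implements monosynaptic Ia
excitation (homonymous 80%, synergist 15%, no MG-Ia→SO connection),
di-synaptic Ib inhibition, di-synaptic group-II excitation, and reciprocal
inhibition from antagonist Ia afferents; *model 1* removes the TA→TS
reciprocal pathway, *model 2* is the full circuit.  The TS nuclei receive
400 descending gamma-process axons (50 Hz, shape 25).

Muscles are Hill-type: per-motor-unit activation (second-order critically
damped filter + smooth saturation), slow/fast contractile elements with
virtual-muscle force-length/velocity curves, exponential parallel elastic
and linear viscous fibre elements, a softplus series tendon, pinnation by
the constant-thickness rule, and a fibre mass integrated explicitly.  MTU
length and moment arm are quartic polynomials of the ankle angle.  The
body is a point-mass inverted pendulum (60 kg, COM at 0.85 m) with passive
ankle stiffness 0.65 of the critical stiffness m·g·h and viscosity
5.81 Nm·s/rad; COP follows from the ankle-torque/ground-reaction balance
so that COP = COM in statics.

All continuous states advance on one fixed-step RK4 clock (50 µs).
Synaptic conductances use a two-state kinetic scheme whose transmitter
drive is the normalised count of open terminals of a projection class, and
the printed class maxima (600/450/300 nS) bound the aggregate conductance;
single-terminal EPSPs come out near 0.1 mV and the mean drive is invariant
under pool down-scaling.  Spikes are detected by upward threshold crossing
and timed at the end of the step; gating variables use exact
piecewise-exponential pulse kinetics.

## The standing protocol

A run locks the pendulum at the initial lean for 1 s so the neuromuscular
system reaches steady state, then frees it for the remaining 29 s.  The
release angle is part of the tuned study conditions: each variant starts
at its own quasi-static equilibrium lean (6.4° for model 2, 7.4° for
model 1 in the reference runs; the tonic drive of model 1 is a few Nm
stronger because the reciprocal inhibition is absent).  The passive ankle spring is neutral at the stance
posture: the printed stance facts (≈5° lean, basal plantar-flexion torque
≈10% of maximum, COP around 80 mm) are mutually consistent only with that
reference, not with a spring centred at the vertical.  Falls (|lean| >
25°) end the run with status `fell`; the threshold is plumbing, not
physiology.

Fusimotor drive is a clipped Ornstein-Uhlenbeck process (variance 3% of
the mean, 100-ms correlation time — a band-limited realisation of the
specified Gaussian process).  As in the original protocol, the *mean*
static/dynamic fusimotor rates are tuned per run by grid search
(`engine.tune_fusimotor`) until the pendulum oscillates for the whole
duration; the tuned means for the six reference runs (static 30.0–30.5 Hz,
dynamic 31.5–32.0 Hz) ship in `data/protocol_runs.json` together with the
per-variant release angles.  Closed-loop standing in this model is
genuinely marginal — the passive + reflex stiffness barely exceeds the
gravitational load stiffness — so whether a particular 30-s noise
realisation survives depends on these means at the 0.1-Hz level, exactly
as the per-run values of the source protocol suggest.

## Free parameters and how they were set

The tables pin pool sizes, afferent counts, conduction-velocity bands,
connectivity fractions, synaptic class maxima, muscle constants and
anthropometrics.  Everything else is versioned in `stancesim/data/` and
was set as follows, using two calibration anchors stated by the protocol
itself — the basal torque under descending drive alone (≈2% of maximum)
and a stance torque consistent with equilibrium at the initial lean —
plus physiological bands for receptor rates (5–40 Hz):

* **Neuron electrophysiology** (`neuron.json`): type-graded leak, time
  constants and AHP parameters reproduce cat-like input resistance,
  rheobase ordering S < FR < FF (≈4–33 nA), minimum steady rates of
  ~4–6 Hz and shallow primary-range f–I slopes.  Spike thresholds within
  a pool rise linearly across the type bands with 2.5% seeded jitter; the
  absolute placement of the bands is the calibration dial that balances
  the stance torque without touching printed conductances.
* **Synapse kinetics**: opening rate 6 /ms, closing 0.5 /ms (inhibitory
  0.33 /ms), 1-ms transmitter pulses, 0.5-ms transmission delay.
* **Motor-unit distributions** (`motorunits.json`): activation filter
  time constants follow measured twitch times (soleus S units
  130–95 ms); tetanic rates 12–50 Hz across the types; tetanic amplitudes
  exponential with a 10-fold range.  The saturation shape of each unit is
  tuned so the unit reaches 96.4% of its plateau at its tetanic rate; the
  muscle activation is normalised by the summed plateau amplitudes, so
  a_slow + a_fast ≤ 1 always and ≈0.96 with every unit at its tetanic
  rate.
* **Spindle** (`spindle.json`): intrafusal mechanics in the standard
  tension-based parameterisation; the primary/secondary output gains are
  the documented free receptor gains.  A second-order 100-ms "mechanical
  embedding" low-pass sits between the extrafusal fibre length and the
  receptor.  This represents the compliant attachment of the receptor in
  the muscle tissue and is essential at reduced scale: with ~10× fewer
  motor units the 2–8 Hz force ripple is several-fold larger than at full
  scale and, fed raw into the intrafusal tension dynamics, drives a
  non-physiological vibration-ratchet response (thousands of Hz of
  "primary afferent" rate) and a ~3-Hz reflex clonus.  The filter passes
  the sway band (< 1.5 Hz) essentially unchanged.
* **Golgi tendon organ**: saturating static law (60 Hz, 4 N) applied to
  the per-afferent force share at the full-scale afferent count, then the
  classical third-order rate-sensitive transfer function (bilinear
  discretisation).

## Reduced-scale study conditions

The reference experiments run at pool scale 0.1 (e.g. SO 80/5/5 motor
neurons, 40 Ia afferents), which preserves type proportions and mean
synaptic drive.  Population noise is ~√10 larger than at full scale, so
sway amplitudes and intermittency statistics are compared with the
printed values under wide (scaled-down) tolerances, and the closed loop
sits closer to its stability boundary than the full-scale system would.
Passive-plant quantities (passive stiffness) and rate/ISI statistics are
scale-free.  Simulated durations follow the protocol (30 s per run, 60 s
for the passive-stiffness record, 5 s for the basal check) as the
package's standard problem sizes.

## Implementation of the inner loop

The reference integrator is a pure-Python per-step loop
(`engine.run_simulation` with `compiled=False`).  For production runs the
same dynamics are executed by a numba kernel (`stancesim/_fastloop.py`)
that advances the whole coupled system in batches of ten 50-µs steps —
valid because the shortest synaptic delay is ten steps, so nothing
emitted inside a batch can act within it.  The two paths are equivalent
(a conformance test asserts identical spike rasters on a short
feedback-off run); in closed loop their trajectories separate after a few
simulated seconds through floating-point ordering, exactly as two runs
with perturbed initial conditions would, leaving all statistics
unchanged.  Each path is deterministic given the configuration and seed.

## Numerical notes

* Tendon constants use the unrounded cited values (curvature 0.0047,
  linear onset 0.964), which satisfy the normalisation F_T(1) = 1 to 0.1%;
  the rounded printed pair would give 1.11.
* Degenerate pinnation (sin α ≥ 1) raises `GeometryError`; it indicates a
  mis-parameterised run rather than a state to clamp.
* Fibre states are initialised at the passive static equilibrium for the
  initial posture; the spindle starts at its intrafusal spring
  equilibrium; the GTO filter starts at the DC value of its first input.
* The Welch spectrum uses a Hann window, segment length a quarter of the
  record, 50% overlap; F50 is interpolated linearly on the cumulative
  spectrum.  The 21-window sign comparison uses the plain Pearson
  chi-square without continuity correction.  Inter-recruitment-interval
  modes use 50-ms bins.
* Cross-correlation lags are positive when the first series leads the
  second; COP–EMG lags are reported with the EMG envelope as the leading
  series.

## Known limitations

* No persistent inward currents, Renshaw cells, vestibular/visual/
  cutaneous input, multi-link or medio-lateral mechanics (by design).
* Hill muscles lack short-range stiffness; the passive joint impedance
  absorbs that role at the joint level.
* The reduced-scale loop is marginally stable by construction; individual
  untuned (seed, fusimotor) combinations can fall within 30 s.  This is a
  property of the protocol, not a numerical failure, and the per-run
  tuned means are part of the documented study conditions.
* Absolute EMG amplitude is arbitrary (phenomenological action-potential
  shapes); only correlation/lag structure is meaningful.
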