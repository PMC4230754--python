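# stancesim

A biologically based neuromusculoskeletal simulator of human upright quiet
standing, for computational motor-control research.  Instead of an abstract
feedback controller, posture is stabilised by a spinal-like circuit built
from its physiological parts: pools of type-specified spiking motor
neurons and interneurons, muscle-spindle and Golgi-tendon-organ receptor
models feeding stochastic Ia/II/Ib afferent fibres, Hill-type models of
the ankle plantar flexors (soleus, medial/lateral gastrocnemius) and
dorsiflexor (tibialis anterior), and a single-link inverted pendulum for
the body.  The package also provides the full posturography and motor-unit
analysis battery used to characterise the simulated sway (COP metrics,
cross-correlations, activation ratios, recruitment phase plots, windowed
COM/fibre-length correlations, COM-histogram Gaussianity tests).

## The model in brief

Body dynamics: an inverted pendulum about the ankle,

    I θ̈ = m g h sin θ − T_a,    T_a = K(θ − θ₀) + B θ̇ − T_m,

with m = 60 kg, h = 0.85 m, I = m h², passive ankle stiffness K = 0.65 ×
m g h (about the stance posture θ₀), viscosity B = 5.81 Nm·s/rad, and T_m
the muscular torque of both legs (dorsiflexion positive), T_m = 2 Σ r(θ)
F_T.  Since K < m g h the passive system is unstable: the reflex loops
must supply the missing stiffness and damping.

Each musculotendon unit follows a Hill-type force balance along the fibre,

    M L̈_f = F_T/cos α − F_CE(a, L_f, L̇_f) − F_PE(L_f, L̇_f),

with a softplus series tendon, exponential parallel elasticity, slow/fast
contractile elements driven by per-motor-unit activation filters, and
constant-thickness pinnation.  Motor neurons are two-compartment
conductance-based models with pulse-kinetic spike conductances; synapses
follow a two-state kinetic scheme bounded by the class conductance.
Spindle Ia/II rates come from bag1/bag2/chain intrafusal tension dynamics
(dynamic/static fusimotor sensitised), Ib rates from a saturating static
law plus the classical rate-sensitive transfer function; afferent fibres
are recruited linearly over 0–50 Hz of receptor output and spike as
order-6 gamma point processes.

Two circuit variants are built from one seed: *model 1* lacks the
reciprocal-inhibition pathway from the antagonist's (TA) Ia afferents onto
the triceps-surae motor nuclei; *model 2* is the complete circuit.

See `docs/methods.md` for assumptions, free parameters and limitations.

## Worked example

```python
from stancesim import engine, analysis

cfg = engine.SimulationConfig(variant="model2", duration=30.0, scale=0.1,
                              seed=1, fusimotor_static=30.5,
                              fusimotor_dynamic=32.0, theta0_deg=6.4)
res = engine.run_simulation(cfg)
print(res.status)
m = analysis.sway_metrics(res)
print(f"COP RMS {m.cop_rms_mm:.2f} mm, MV {m.cop_mv_mm_s:.2f} mm/s, "
      f"F50 {m.f50_hz:.2f} Hz")
print(f"COM-COP rho {m.rho_com_cop:.2f} at lag {m.lag_com_cop_s*1000:.0f} ms")
```

prints (exact numbers are deterministic for a given seed):

```
completed
COP RMS 26.82 mm, MV 160.02 mm/s, F50 0.50 Hz
COM-COP rho 0.85 at lag -0 ms
```

i.e. a completed 30-s standing run whose centre of pressure wanders around
the forward-lean equilibrium, with centre of mass and centre of pressure
correlated and peaking at zero lag — the signature pattern of quiet-stance
sway.  At the reduced population scale the sway amplitude and the
fast COP fluctuations run well above the full-scale figures because
population noise and reflex-loop fluctuation power are roughly √10
larger; see `docs/methods.md` for what does and does not carry over.

The same protocol is available from the shell:

```
stancesim simulate --variant model2 --duration 30 --seed 1 --scale 0.1 --out run1
stancesim analyze run1
stancesim passive-stiffness --seed 1
stancesim basal-check --seed 1 --scale 0.1
```

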