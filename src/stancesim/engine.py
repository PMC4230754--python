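"""Closed-loop simulation engine and protocol experiments.

One global fixed-step clock (RK4, 50 us by default) advances every
subsystem: the spinal network, the Hill-type musculotendon units, the
muscle receptors and their stochastic afferent encoders, and the inverted
pendulum.  The standard protocol locks the pendulum at the initial lean for
the first second so the neuromuscular system reaches steady state before
the loop is closed.  Model variant ``model1`` removes the reciprocal
inhibition from the antagonist's Ia afferents; ``model2`` is the complete
circuit.

Seeding: one master seed spawns named sub-streams (network build,
descending drive, fusimotor noise, afferent encoding) so a single noise
source can be varied at a time while the rest stays frozen.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import biomechanics as bm
from . import musculotendon as mt
from . import proprioception as pr
from . import spinal_network as sn
from . import emg as emg_mod
from . import _fastloop
from . import params as _params
from .events import SpikeEventList

MUSCLES = ("SO", "MG", "LG", "TA")
TS = ("SO", "MG", "LG")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    variant: str = "model2"
    duration: float = 30.0
    lock_pendulum_s: float = 1.0
    dt: float = 5e-5
    scale: float = 1.0
    seed: int = 0
    theta0_deg: float = 5.0
    fusimotor_static: float = 32.0
    fusimotor_dynamic: float = 33.8
    fusimotor_variance_frac: float = 0.03
    descending_on: bool = True
    feedback_on: bool = True
    controller_on: bool = True      # False: no neural drive at all
    lock_pendulum: bool = False     # True: pendulum clamped for the whole run
    fs_out: float = 2000.0
    synthesize_emg: bool = True
    body: bm.BodyParams = field(default_factory=bm.BodyParams)
    imposed_theta: object = None    # t -> rad; overrides the pendulum (for
    #                                 system-identification experiments)
    compiled: bool = True           # use the batched compiled inner loop
    #                                 when numba is available

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.lock_pendulum and self.lock_pendulum_s >= self.duration:
            raise ValueError("warm-up must be shorter than the run")
        if not (0 < self.scale <= 1):
            raise ValueError("scale must be in (0, 1]")


def reduced_scale_config(scale: float, **overrides) -> SimulationConfig:
    """A configuration with every pool and afferent count scaled down,
    proportions preserved; synaptic drive per neuron is invariant because
    transmitter weights are normalised by the scaled source counts."""
    return SimulationConfig(scale=scale, **overrides)


@dataclass
class SimulationResult:
    config: SimulationConfig
    status: str                      # "completed" / "fell"
    fall_time: float | None
    t: np.ndarray                    # output clock (fs_out)
    series: dict[str, np.ndarray]    # pendulum + per-muscle series
    mn_spikes: dict[str, SpikeEventList]         # soma spike times
    mn_arrivals: dict[str, SpikeEventList]       # at the muscle, conducted
    afferent_spikes: dict[tuple[str, str], SpikeEventList]
    in_spikes: dict[str, SpikeEventList]
    descending: SpikeEventList
    emg: dict[str, np.ndarray]
    emg_envelope: dict[str, np.ndarray]
    info: dict

    def muscle_series(self, muscle: str, name: str) -> np.ndarray:
        return self.series[f"{name}_{muscle}"]


# ---------------------------------------------------------------------------
# static torque helpers
# ---------------------------------------------------------------------------

def _static_fibre_equilibrium(l_mtu, p, a_slow, a_fast):
    accel = mt.make_fibre_accel(p)
    lo = math.sin(p.alpha0) + 1e-3
    hi = 1.25
    if accel(hi, 0.0, l_mtu, a_slow, a_fast)[0] > 0:
        return hi
    while accel(lo, 0.0, l_mtu, a_slow, a_fast)[0] < 0 and lo < hi:
        lo += 0.02
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if accel(mid, 0.0, l_mtu, a_slow, a_fast)[0] > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def static_muscle_torque(theta_deg: float, activations: dict[str, tuple],
                         mtus=None) -> float:
    """Quasi-static muscular torque (Nm) with fibre states settled at the
    given activations (used for the passive baseline and the tetanic
    maximum)."""
    if mtus is None:
        mtus = mt.load_mtu_params()
    torque = 0.0
    for name, p in mtus.items():
        a_s, a_f = activations.get(name, (0.0, 0.0))
        l_mtu = mt.mtu_length(theta_deg, p)
        lf = _static_fibre_equilibrium(l_mtu, p, a_s, a_f)
        lt_norm, _ = mt.fibre_geometry(l_mtu, lf, p)
        f = float(mt.tendon_force(lt_norm, p)) * p.f0
        torque += 2.0 * mt.moment_arm(theta_deg, p) * f
    return torque


def max_plantarflexion_torque(theta_deg: float, scale: float = 1.0) -> float:
    """Magnitude of the triceps-surae torque with every motor unit at its
    tetanic activation (a_slow + a_fast = 1 per muscle)."""
    comp = sn.scaled_composition(scale)
    acts = {}
    for m in TS:
        pool = mt.build_activation_pool(m, comp[m])
        frac_s = float(np.sum(pool.amplitude[pool.is_slow])) \
            / pool.total_amplitude
        acts[m] = (frac_s, 1.0 - frac_s)
    t_full = static_muscle_torque(theta_deg, acts)
    t_passive = static_muscle_torque(theta_deg, {})
    return abs(t_full - t_passive)


# ---------------------------------------------------------------------------
# merged per-motor-unit activation channels
# ---------------------------------------------------------------------------

class _MuscleActivations:
    """All muscles' motor-unit activation filters in flat arrays."""

    def __init__(self, comp, dt):
        pools = {m: mt.build_activation_pool(m, comp[m]) for m in MUSCLES}
        self.offsets = {}
        off = 0
        tau, c, amp, group = [], [], [], []
        for gi, m in enumerate(MUSCLES):
            p = pools[m]
            self.offsets[m] = off
            off += p.n_units
            tau.append(p.tau)
            c.append(p.c)
            amp.append(p.amplitude)
            group.append(np.where(p.is_slow, 2 * gi, 2 * gi + 1))
        self.tau = np.concatenate(tau)
        self.c = np.concatenate(c)
        self.amp = np.concatenate(amp)
        self.group = np.concatenate(group)
        self.totals = np.bincount(self.group // 2 * 2, weights=self.amp,
                                  minlength=8)
        tot = np.bincount(self.group // 2, weights=self.amp, minlength=4)
        self.tot_per_muscle = tot                  # normalising constants
        self.n = len(self.tau)
        self.x1 = np.zeros(self.n)
        self.x2 = np.zeros(self.n)
        e = np.exp(-dt / self.tau)
        self.a11 = e * (1.0 + dt / self.tau)
        self.a12 = e * dt
        self.a21 = -e * dt / self.tau ** 2
        self.a22 = e * (1.0 - dt / self.tau)
        self.imp = 1.0 / self.tau ** 2

    def add_spikes(self, idx):
        np.add.at(self.x2, idx, self.imp[idx])

    def step(self):
        x1 = self.a11 * self.x1 + self.a12 * self.x2
        self.x2 = self.a21 * self.x1 + self.a22 * self.x2
        self.x1 = x1

    def activations(self):
        """dict muscle -> (a_slow, a_fast)."""
        sums = self._sums()
        return {m: (sums[2 * gi] / self.tot_per_muscle[gi],
                    sums[2 * gi + 1] / self.tot_per_muscle[gi])
                for gi, m in enumerate(MUSCLES)}

    def _sums(self):
        a = self.amp * np.tanh(self.c * np.maximum(self.x1, 0.0))
        return np.bincount(self.group, weights=a, minlength=8)

    def activation_pairs(self):
        """[(a_slow, a_fast)] in MUSCLES order (fast path)."""
        sums = self._sums()
        tot = self.tot_per_muscle
        return [(sums[0] / tot[0], sums[1] / tot[0]),
                (sums[2] / tot[1], sums[3] / tot[1]),
                (sums[4] / tot[2], sums[5] / tot[2]),
                (sums[6] / tot[3], sums[7] / tot[3])]


# ---------------------------------------------------------------------------
# merged afferent encoder
# ---------------------------------------------------------------------------

class _Afferents:
    """All afferent bundles in flat arrays, with per-fibre projection maps."""

    def __init__(self, seed_seq, scale, variant):
        seeds = seed_seq.spawn(len(MUSCLES) * 3 + 1)
        self.bundles = {}
        k = 0
        thr, r0, seg_len = [], [], []
        self.segments = []       # (muscle, type, projections)
        for m in MUSCLES:
            for a_type in ("Ia", "II", "Ib"):
                b = pr.build_bundle(m, a_type, seeds[k], scale)
                k += 1
                self.bundles[(m, a_type)] = b
                thr.append(b.thresholds)
                r0.append(b.initial_rates)
                seg_len.append(b.n)
                self.segments.append((m, a_type))
        self.thr = np.concatenate(thr)
        self.r0 = np.concatenate(r0)
        self.seg_len = np.array(seg_len)
        self.seg_start = np.concatenate([[0], np.cumsum(self.seg_len)[:-1]])
        self.n = len(self.thr)
        self.rng = np.random.default_rng(seeds[k])
        rec = _params.load("feedback")["recruitment"]
        self.order = rec["gamma_order"]
        self.integral = np.zeros(self.n)
        self.target = self.rng.gamma(self.order, 1.0 / self.order,
                                     size=self.n)
        # per-fibre local index and segment id
        self.local_idx = np.concatenate(
            [np.arange(n) for n in self.seg_len])
        self.seg_id = np.repeat(np.arange(len(self.seg_len)), self.seg_len)
        # projection names per segment
        self.proj_names = []
        synergy_targets = {"SO": ["SO", "MG", "LG"], "MG": ["MG", "LG"],
                           "LG": ["SO", "MG", "LG"], "TA": ["TA"]}
        for (m, a_type) in self.segments:
            names = []
            if a_type == "Ia":
                names += [f"Ia_{m}->{t}" for t in synergy_targets[m]]
                if m in TS:
                    names.append(f"Ia_{m}->IaIN_TS")
                elif variant == "model2":
                    names.append("Ia_TA->IaIN_TA")
            elif a_type == "Ib":
                names.append(f"Ib_{m}->IbIN_{m}")
            else:
                names.append(f"II_{m}->IIIN_{m}")
            self.proj_names.append(names)

    def step(self, receptor_rates: np.ndarray, dt: float):
        """receptor_rates: one value per segment; returns fired global ids."""
        excess = receptor_rates[self.seg_id] - self.thr
        rates = np.where(excess >= 0.0, self.r0 + excess, 0.0)
        self.integral += rates * dt
        fired = np.nonzero(self.integral >= self.target)[0]
        if len(fired):
            self.integral[fired] -= self.target[fired]
            self.target[fired] = self.rng.gamma(self.order, 1.0 / self.order,
                                                size=len(fired))
        return fired


# ---------------------------------------------------------------------------
# the simulation proper
# ---------------------------------------------------------------------------

def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Run the closed-loop protocol and collect every output series."""
    cfg = config
    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    dec = max(1, int(round(1.0 / (cfg.fs_out * dt))))
    n_out = n_steps // dec
    mtus = mt.load_mtu_params()
    body = cfg.body
    if body.theta_ref is None:
        # the passive ankle spring is neutral at the stance posture
        body = replace(body, theta_ref=math.radians(cfg.theta0_deg))

    ss = np.random.SeedSequence(cfg.seed)
    s_net, s_desc, s_fus, s_aff = ss.spawn(4)

    net = sn.build_network(cfg.variant, s_net, cfg.scale)
    net.begin_run(dt)
    comp = net.composition
    acts = _MuscleActivations(comp, dt)
    aff = _Afferents(s_aff, cfg.scale, cfg.variant)

    fb = _params.load("feedback")
    desc_cfg = fb["descending"]
    if cfg.controller_on and cfg.descending_on:
        d_times, d_ids = sn.generate_descending_drive(
            desc_cfg["n_axons"], desc_cfg["rate_hz"], desc_cfg["shape"],
            cfg.duration, s_desc)
        d_steps = np.minimum((d_times / dt).astype(np.int64), n_steps - 1)
    else:
        d_times = np.array([])
        d_ids = np.array([], dtype=int)
        d_steps = np.array([], dtype=np.int64)
    desc_projs = [f"desc->{m}" for m in desc_cfg["targets"]]

    fus_seeds = s_fus.spawn(2)
    fus_s = pr.FusimotorDrive(cfg.fusimotor_static, fus_seeds[0],
                              cfg.fusimotor_variance_frac)
    fus_d = pr.FusimotorDrive(cfg.fusimotor_dynamic, fus_seeds[1],
                              cfg.fusimotor_variance_frac)

    # per-muscle plant state
    theta0 = math.radians(cfg.theta0_deg)
    accel_fns = {m: mt.make_fibre_accel(mtus[m]) for m in MUSCLES}
    lf = {}
    vf = {m: 0.0 for m in MUSCLES}
    facc = {m: 0.0 for m in MUSCLES}
    f_tendon = {}
    for m in MUSCLES:
        l0 = mt.mtu_length(cfg.theta0_deg, mtus[m])
        lf[m] = mt.passive_equilibrium_fibre_length(l0, mtus[m])
        lt, _ = mt.fibre_geometry(l0, lf[m], mtus[m])
        f_tendon[m] = float(mt.tendon_force(lt, mtus[m])) * mtus[m].f0
    spindles = {m: pr.MuscleSpindle(lf0=lf[m]) for m in MUSCLES}
    spindle_in = {m: pr.SpindleInputFilter(lf[m]) for m in MUSCLES}
    gtos = {m: pr.GTO(fb["afferent_counts"][m]["Ib"], dt) for m in MUSCLES}

    pend = bm.PendulumState(theta=theta0, omega=0.0)
    pend.torque_ankle = bm.ankle_torque(theta0, 0.0, 0.0, body)

    # motor-spike conduction to the muscles
    mn_pools = {m: net.pools[m] for m in MUSCLES}
    motor_delay_steps = {
        m: np.maximum(1, np.rint(mn_pools[m].axon_delay_s / dt)
                      .astype(np.int64))
        for m in MUSCLES}
    mhorizon = max(int(d.max()) for d in motor_delay_steps.values()) + 2
    motor_ring = [[] for _ in range(mhorizon)]

    # IN projections per pool
    in_projs = {}
    for name, pool in net.pools.items():
        if pool.kind == "IN":
            in_projs[name] = [p.name for p in net.projections.values()
                              if p.source == name]

    # recorders
    series = {k: np.zeros(n_out) for k in
              ("theta", "omega", "torque_muscle", "torque_ankle",
               "x_com", "x_cop")}
    for m in MUSCLES:
        for k in ("lf", "vf", "f_tendon", "a_slow", "a_fast"):
            series[f"{k}_{m}"] = np.zeros(n_out)
    for (m, a_type) in aff.segments:
        series[f"rate_{a_type}_{m}"] = np.zeros(n_out)
    mn_spk = {m: ([], []) for m in MUSCLES}
    mn_arr = {m: ([], []) for m in MUSCLES}
    in_spk = {p: ([], []) for p in in_projs}
    aff_spk = {seg: ([], []) for seg in aff.segments}

    pool_list = sorted(net.pools.values(), key=lambda p: p.start)
    pool_starts = np.array([p.start for p in pool_list])

    status = "completed"
    fall_time = None
    d_ptr = 0
    n_desc = len(d_steps)
    lock_steps = n_steps if cfg.lock_pendulum \
        else int(round(cfg.lock_pendulum_s / dt))
    receptor = np.zeros(len(aff.segments))
    seg_index = {seg: i for i, seg in enumerate(aff.segments)}
    controller = cfg.controller_on
    feedback = cfg.feedback_on and controller

    # fast-path packs: per-muscle constants and callables bound once
    muscle_pack = []
    for mi, m in enumerate(MUSCLES):
        p = mtus[m]
        muscle_pack.append((
            m, mi, accel_fns[m],
            tuple(reversed(p.length_poly)),
            tuple(reversed(p.moment_arm_poly)),
            p.f0,
            spindle_in[m], spindles[m], gtos[m],
            seg_index[(m, "Ia")], seg_index[(m, "II")],
            seg_index[(m, "Ib")],
        ))
    lf_l = [lf[m] for m in MUSCLES]
    vf_l = [vf[m] for m in MUSCLES]
    facc_l = [0.0] * 4
    ften_l = [f_tendon[m] for m in MUSCLES]
    desc_proj_objs = [net.projections[n] for n in desc_projs]
    in_proj_objs = {name: [net.projections[n] for n in lst]
                    for name, lst in in_projs.items()}
    aff_proj_objs = [[net.projections[n] for n in lst]
                     for lst in aff.proj_names]
    deliver = net.deliver
    half_dt = 0.5 * dt
    # pendulum state in locals (bit-identical inline of pendulum_step)
    p_th = pend.theta
    p_om = pend.omega
    p_ta = pend.torque_ankle
    p_fell = False
    mgh_ = bm.critical_stiffness(body)
    inertia_ = body.inertia
    k_pas_ = body.k_passive
    b_pas_ = body.b_passive
    ref_ = body.theta_ref if body.theta_ref is not None else 0.0
    fall_thr_ = body.fall_threshold
    sin = math.sin
    degrees = math.degrees

    use_fast = (cfg.compiled and _fastloop.HAVE_NUMBA
                and cfg.imposed_theta is None)
    if use_fast:
        return _run_batched(
            cfg, net, aff, acts, mtus, comp, spindles, spindle_in, gtos,
            fus_s, fus_d, body, d_times, d_ids, d_steps, desc_proj_objs,
            in_proj_objs, aff_proj_objs, motor_delay_steps, motor_ring,
            mhorizon, lf_l, vf_l, ften_l, series, mn_spk, mn_arr, in_spk,
            aff_spk, pool_list, pool_starts, lock_steps, n_steps, dec,
            n_out, mgh_, inertia_, k_pas_, b_pas_, ref_, fall_thr_,
            p_th, p_om, p_ta)

    for step in range(n_steps):
        t_next = (step + 1) * dt
        # 1. descending events due at this step
        while d_ptr < n_desc and d_steps[d_ptr] <= step:
            axon = int(d_ids[d_ptr])
            for proj in desc_proj_objs:
                deliver(proj, axon)
            d_ptr += 1
        # 2. motor spike arrivals -> activation filters
        slot = motor_ring[step % mhorizon]
        if slot:
            acts.add_spikes(np.asarray(slot, dtype=np.intp))
            slot.clear()
        acts.step()
        pairs = acts.activation_pairs()
        # 3. muscle fibre dynamics (RK4, MTU length frozen over the step)
        theta_deg = degrees(p_th)
        torque = 0.0
        for (m, mi, accel, lpoly, apoly, f0, sfilt, spin, gto,
             i_ia, i_ii, i_ib) in muscle_pack:
            acc_p = 0.0
            for c in lpoly:
                acc_p = acc_p * theta_deg + c
            l_mtu = acc_p / 100.0
            a_s, a_f = pairs[mi]
            l = lf_l[mi]
            v = vf_l[mi]
            k1v, f_t = accel(l, v, l_mtu, a_s, a_f)
            v2 = v + half_dt * k1v
            k2v, _ = accel(l + half_dt * v, v2, l_mtu, a_s, a_f)
            v3 = v + half_dt * k2v
            k3v, _ = accel(l + half_dt * v2, v3, l_mtu, a_s, a_f)
            v4 = v + dt * k3v
            k4v, _ = accel(l + dt * v3, v4, l_mtu, a_s, a_f)
            lf_l[mi] = l + dt * (v + 2 * v2 + 2 * v3 + v4) / 6.0
            vf_l[mi] = v + dt * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0
            facc_l[mi] = k1v
            f_n = f_t * f0
            ften_l[mi] = f_n
            acc_p = 0.0
            for c in apoly:
                acc_p = acc_p * theta_deg + c
            torque += 2.0 * (acc_p / 100.0) * f_n
        # 4. pendulum
        if cfg.imposed_theta is not None:
            th_new = float(cfg.imposed_theta(t_next))
            p_om = (th_new - p_th) / dt
            p_th = th_new
            p_ta = k_pas_ * (p_th - ref_) + b_pas_ * p_om - torque
        elif step >= lock_steps:
            th = p_th
            om = p_om
            k1t = om
            k1o = (mgh_ * sin(th)
                   - (k_pas_ * (th - ref_) + b_pas_ * om - torque)) / inertia_
            k2t = om + 0.5 * dt * k1o
            th2 = th + 0.5 * dt * k1t
            k2o = (mgh_ * sin(th2)
                   - (k_pas_ * (th2 - ref_) + b_pas_ * k2t - torque)) \
                / inertia_
            k3t = om + 0.5 * dt * k2o
            th3 = th + 0.5 * dt * k2t
            k3o = (mgh_ * sin(th3)
                   - (k_pas_ * (th3 - ref_) + b_pas_ * k3t - torque)) \
                / inertia_
            k4t = om + dt * k3o
            th4 = th + dt * k3t
            k4o = (mgh_ * sin(th4)
                   - (k_pas_ * (th4 - ref_) + b_pas_ * k4t - torque)) \
                / inertia_
            th += dt * (k1t + 2 * k2t + 2 * k3t + k4t) / 6.0
            om += dt * (k1o + 2 * k2o + 2 * k3o + k4o) / 6.0
            if not (math.isfinite(th) and math.isfinite(om)):
                raise FloatingPointError("non-finite pendulum state")
            p_th = th
            p_om = om
            p_ta = k_pas_ * (th - ref_) + b_pas_ * om - torque
            if p_fell or abs(th) > fall_thr_:
                p_fell = True
                status = "fell"
                fall_time = t_next
        else:
            p_ta = k_pas_ * (p_th - ref_) + b_pas_ * 0.0 - torque
        # 5. receptors
        g_s = fus_s.step(dt)
        g_d = fus_d.step(dt)
        for (m, mi, accel, lpoly, apoly, f0, sfilt, spin, gto,
             i_ia, i_ii, i_ib) in muscle_pack:
            lf_s, vf_s, acc_s = sfilt.step(lf_l[mi], dt)
            ia, ii = spin.step(lf_s, vf_s, acc_s, g_s, g_d, dt)
            receptor[i_ia] = ia
            receptor[i_ii] = ii
            receptor[i_ib] = gto.step(ften_l[mi])
        # 6. afferent encoding and delivery
        if feedback:
            fired = aff.step(receptor, dt)
            for g in fired:
                si = aff.seg_id[g]
                li = int(aff.local_idx[g])
                ts_l, ids_l = aff_spk[aff.segments[si]]
                ts_l.append(t_next)
                ids_l.append(li)
                for proj in aff_proj_objs[si]:
                    deliver(proj, li)
        # 7. spinal network
        if controller:
            fired = net.step()
            if len(fired):
                pis = np.searchsorted(pool_starts, fired, side="right") - 1
                for g, pi in zip(fired, pis):
                    pool = pool_list[pi]
                    li = g - pool.start
                    if pool.kind == "MN":
                        m = pool.name
                        ts_l, ids_l = mn_spk[m]
                        ts_l.append(t_next)
                        ids_l.append(li)
                        d_arr = int(motor_delay_steps[m][li])
                        motor_ring[(step + d_arr) % mhorizon].append(
                            acts.offsets[m] + li)
                        ts_a, ids_a = mn_arr[m]
                        ts_a.append(t_next + d_arr * dt)
                        ids_a.append(li)
                    else:
                        ts_l, ids_l = in_spk[pool.name]
                        ts_l.append(t_next)
                        ids_l.append(li)
                        for proj in in_proj_objs[pool.name]:
                            deliver(proj, li)
        # 8. recording
        if step % dec == 0:
            i = step // dec
            if i < n_out:
                series["theta"][i] = p_th
                series["omega"][i] = p_om
                series["torque_muscle"][i] = torque
                series["torque_ankle"][i] = p_ta
                series["x_com"][i] = body.height * sin(p_th)
                series["x_cop"][i] = p_ta / (body.mass * body.gravity)
                for (m, mi, *_rest) in muscle_pack:
                    series[f"lf_{m}"][i] = lf_l[mi]
                    series[f"vf_{m}"][i] = vf_l[mi]
                    series[f"f_tendon_{m}"][i] = ften_l[mi]
                    a_s, a_f = pairs[mi]
                    series[f"a_slow_{m}"][i] = a_s
                    series[f"a_fast_{m}"][i] = a_f
                for si, seg in enumerate(aff.segments):
                    series[f"rate_{seg[1]}_{seg[0]}"][i] = receptor[si]
        if status == "fell":
            break

    return _finalize(cfg, status, fall_time, series, n_out, dec, dt,
                     mn_spk, mn_arr, aff_spk, in_spk, aff, d_times, d_ids,
                     comp, net, fus_s, fus_d)


def _finalize(cfg, status, fall_time, series, n_out, dec, dt, mn_spk,
              mn_arr, aff_spk, in_spk, aff, d_times, d_ids, comp, net,
              fus_s, fus_d) -> SimulationResult:
    # truncate recordings on a fall
    if status == "fell":
        n_kept = min(n_out, int(fall_time / (dec * dt)) + 1)
        for k in series:
            series[k] = series[k][:n_kept]
        n_out = n_kept
    t_out = np.arange(n_out) * dec * dt

    def _mk(pairs):
        return SpikeEventList(np.asarray(pairs[0]),
                              np.asarray(pairs[1], dtype=int))

    emg_raw, emg_env = {}, {}
    if cfg.synthesize_emg and status == "completed":
        for m in MUSCLES:
            tpl = emg_mod.build_templates(m, comp[m])
            ts_a, ids_a = mn_arr[m]
            emg_raw[m] = emg_mod.synthesize_emg(
                np.asarray(ts_a), np.asarray(ids_a, dtype=int), tpl,
                cfg.fs_out, cfg.duration)
            emg_env[m] = emg_mod.emg_envelope(emg_raw[m], cfg.fs_out)

    return SimulationResult(
        config=cfg, status=status, fall_time=fall_time, t=t_out,
        series=series,
        mn_spikes={m: _mk(v) for m, v in mn_spk.items()},
        mn_arrivals={m: _mk(v) for m, v in mn_arr.items()},
        afferent_spikes={seg: _mk(v) for seg, v in aff_spk.items()},
        in_spikes={p: _mk(v) for p, v in in_spk.items()},
        descending=SpikeEventList(d_times, d_ids),
        emg=emg_raw, emg_envelope=emg_env,
        info={
            "composition": comp,
            "n_neurons": net.n_neurons,
            "fusimotor_clipped": (fus_s.n_clipped, fus_d.n_clipped),
            "variant": cfg.variant,
        },
    )


# ---------------------------------------------------------------------------
# batched (compiled) runner
# ---------------------------------------------------------------------------

def _run_batched(cfg, net, aff, acts, mtus, comp, spindles, spindle_in,
                 gtos, fus_s, fus_d, body, d_times, d_ids, d_steps,
                 desc_proj_objs, in_proj_objs, aff_proj_objs,
                 motor_delay_steps, motor_ring, mhorizon, lf_l, vf_l,
                 ften_l, series, mn_spk, mn_arr, in_spk, aff_spk,
                 pool_list, pool_starts, lock_steps, n_steps, dec, n_out,
                 mgh_, inertia_, k_pas_, b_pas_, ref_, fall_thr_,
                 p_th, p_om, p_ta) -> SimulationResult:
    """Drive the compiled batch kernel; semantics match the reference loop
    (a conformance test compares the two on short runs)."""
    dt = cfg.dt
    K = _fastloop.BATCH
    curves = _params.load("curves")

    def _fl_fv(kind):
        c = curves[kind]
        return [c["fl"]["beta"], c["fl"]["omega"], c["fl"]["rho"],
                c["fv"]["vmax"], c["fv"]["cv0"], c["fv"]["cv1"],
                c["fv"]["av0"], c["fv"]["av1"], c["fv"]["av2"],
                c["fv"]["bv"]]

    mconst = np.zeros((4, 42))
    for mi, m in enumerate(MUSCLES):
        p = mtus[m]
        mconst[mi, 0] = math.sin(p.alpha0)
        mconst[mi, 1] = p.l0
        mconst[mi, 2] = p.lt0
        mconst[mi, 3] = p.ct
        mconst[mi, 4] = p.kt
        mconst[mi, 5] = p.lr
        mconst[mi, 6] = p.k_pe
        mconst[mi, 7] = p.strain_pe
        mconst[mi, 8] = math.expm1(p.k_pe)
        mconst[mi, 9] = p.b_pe
        mconst[mi, 10] = p.mass_norm
        mconst[mi, 11] = p.f0
        mconst[mi, 12:17] = list(reversed(p.length_poly))
        mconst[mi, 17:22] = list(reversed(p.moment_arm_poly))
        mconst[mi, 22:32] = _fl_fv("slow")
        mconst[mi, 32:42] = _fl_fv("fast")

    # activation filters
    act_group = acts.group.astype(np.int64)
    act_tot = np.zeros(16)
    for mi in range(4):
        act_tot[8 + 2 * mi] = acts.tot_per_muscle[mi]

    # spindle packs
    sp_const = np.zeros((4, 3, 9))
    sp_T = np.zeros((4, 3))
    sp_Td = np.zeros((4, 3))
    sp_f = np.zeros((4, 3))
    sp_decay = np.zeros((4, 3))
    for mi, m in enumerate(MUSCLES):
        sp = spindles[m]
        for fi in range(3):
            sp_const[mi, fi, :] = sp._const[fi]
            tau_f = sp._const[fi][6]
            sp_decay[mi, fi] = math.exp(-dt / tau_f) if tau_f > 0 else 0.0
        sp_T[mi] = sp.tension
        sp_Td[mi] = sp.tension_dot
        sp_f[mi] = sp.f_fus
    sh = spindles["SO"]._s
    sp_shared = np.array([
        sh["a"], sh["c_lengthening"], sh["c_shortening"],
        sh["l0_sr"] + sh["r"], sh["l0_sr"] + sh["l0_pr"],
        sh["ln_sr"] - sh["l0_sr"], sh["occlusion"],
        sh["x"] * sh["l_secondary"] / sh["l0_sr"],
        (1.0 - sh["x"]) * sh["l_secondary"] / sh["l0_pr"],
        sh["l0_sr"] + sh["ln_pr"]])
    g_pri = spindles["SO"].g_primary
    g_sec = spindles["SO"].g_secondary

    # spindle input filters
    sf_y = np.array([spindle_in[m].y for m in MUSCLES])
    sf_yd = np.array([spindle_in[m].yd for m in MUSCLES])
    taus = np.array([spindle_in[m].tau for m in MUSCLES])
    e_f = np.exp(-dt / taus)
    sf_a11 = e_f * (1.0 + dt / taus)
    sf_a12 = e_f * dt
    sf_a21 = -e_f * dt / taus ** 2
    sf_a22 = e_f * (1.0 - dt / taus)

    # GTOs (same transfer function for every muscle)
    g0 = gtos["SO"]
    gto_b = np.asarray(g0._b)
    gto_a = np.asarray(g0._a)
    gto_w = np.zeros((4, 3))
    for mi, m in enumerate(MUSCLES):
        u = float(g0.static_rate(ften_l[mi]))
        gto_w[mi, :] = u / (1.0 + gto_a[1] + gto_a[2] + gto_a[3])

    # afferent encoder
    aff_seg = aff.seg_id.astype(np.int64)
    receptor = np.zeros(12)
    feedback = cfg.feedback_on and cfg.controller_on
    if not feedback:
        # silence every afferent by unreachable thresholds
        aff_thr = np.full(aff.n, 1e12)
    else:
        aff_thr = aff.thr
    controller = cfg.controller_on

    pend = np.array([p_th, p_om, p_ta])
    out_series = np.zeros((36, K))
    fn_sub = np.zeros(net.n_neurons * K, dtype=np.int64)
    fn_id = np.zeros(net.n_neurons * K, dtype=np.int64)
    fa_sub = np.zeros(aff.n * K + 1, dtype=np.int64)
    fa_id = np.zeros(aff.n * K + 1, dtype=np.int64)
    gs_arr = np.zeros(K)
    gd_arr = np.zeros(K)

    series_keys = (["theta", "omega", "torque_muscle", "torque_ankle"]
                   + [f"lf_{m}" for m in MUSCLES]
                   + [f"vf_{m}" for m in MUSCLES]
                   + [f"f_tendon_{m}" for m in MUSCLES]
                   + [f"a_slow_{m}" for m in MUSCLES]
                   + [f"a_fast_{m}" for m in MUSCLES]
                   + [f"rate_{t}_{m}" for m in MUSCLES
                      for t in ("Ia", "II", "Ib")])
    series_arrs = [series[k1] for k1 in series_keys]

    status = "completed"
    fall_time = None
    d_ptr = 0
    n_desc = len(d_steps)
    queue = net._queue
    horizon = net._horizon
    pool_of = np.zeros(net.n_neurons, dtype=np.int64)
    for pi, pl in enumerate(pool_list):
        pool_of[pl.start:pl.stop] = pi
    lf_a = np.asarray(lf_l, dtype=float)
    vf_a = np.asarray(vf_l, dtype=float)
    ften_a = np.asarray(ften_l, dtype=float)
    rng_targets = aff.rng
    order = aff.order
    finite_check = 0

    step0 = 0
    while step0 < n_steps:
        k = min(K, n_steps - step0)
        # descending events due inside this batch
        while d_ptr < n_desc and d_steps[d_ptr] < step0 + k:
            s_ev = int(d_steps[d_ptr])
            if s_ev < step0:
                s_ev = step0
            axon = int(d_ids[d_ptr])
            if controller and cfg.descending_on:
                for proj in desc_proj_objs:
                    net.deliver_at(proj, axon, s_ev)
            d_ptr += 1
        # gather transmitter events and motor arrivals for the batch
        ev_sub, ev_start, ev_ch_parts, ev_w = [], [0], [], []
        arr_sub, arr_mu = [], []
        for j in range(k):
            slot = queue[(step0 + j) % horizon]
            for ch, w in slot:
                ev_sub.append(j)
                ev_ch_parts.append(ch)
                ev_start.append(ev_start[-1] + len(ch))
                ev_w.append(w)
            slot.clear()
            mslot = motor_ring[(step0 + j) % mhorizon]
            for mu in mslot:
                arr_sub.append(j)
                arr_mu.append(mu)
            mslot.clear()
        ev_sub_a = np.asarray(ev_sub, dtype=np.int64)
        ev_start_a = np.asarray(ev_start, dtype=np.int64)
        ev_ch_a = (np.concatenate(ev_ch_parts).astype(np.int64)
                   if ev_ch_parts else np.zeros(0, dtype=np.int64))
        ev_w_a = np.asarray(ev_w, dtype=np.float64)
        arr_sub_a = np.asarray(arr_sub, dtype=np.int64)
        arr_mu_a = np.asarray(arr_mu, dtype=np.int64)
        for j in range(k):
            gs_arr[j] = fus_s.step(dt)
            gd_arr[j] = fus_d.step(dt)

        n_fn, n_fa, fall_sub = _fastloop.run_batch(
            step0, k, dt, lock_steps, fall_thr_, True,
            ev_sub_a, ev_start_a, ev_ch_a, ev_w_a,
            arr_sub_a, arr_mu_a, gs_arr, gd_arr,
            pend, mgh_, inertia_, k_pas_, b_pas_, ref_,
            body.height, body.mass * body.gravity,
            mconst, lf_a, vf_a, ften_a,
            acts.x1, acts.x2, acts.a11, acts.a12, acts.a21, acts.a22,
            acts.imp, acts.amp, acts.c, act_group, act_tot,
            sf_y, sf_yd, sf_a11, sf_a12, sf_a21, sf_a22, taus,
            sp_const, sp_shared, sp_T, sp_Td, sp_f, sp_decay, g_pri, g_sec,
            gto_b, gto_a, gto_w, g0.rate_max, g0.force_half,
            float(g0.n_afferents_full),
            aff_thr, aff.r0, aff.integral, aff.target, aff_seg, receptor,
            net._n_exc, net.ch_won, net.ch_r, net.ch_gmax,
            net._ch_neuron64, net._ch_comp,
            net._alpha_e, net._beta_e, net._alpha_i, net._beta_i,
            net._dtms, net._g_exc_d, net._g_exc_s, net._g_inh_s,
            net.na_off, net.h_off, net.kf_off, net.refrac_until,
            net.m, net.h, net.ng, net.q,
            net._e_am, net._e_bm, net._e_ah, net._e_bh, net._e_an,
            net._e_bn, net._e_q,
            net.g_ls, net.g_ld, net.g_c, net.c_s_inv, net.c_d_inv,
            net.g_na, net.g_kf, net.g_ks, net.delta_q, net.v_th,
            net.v_s, net.v_d, net._spk_e_na, net._spk_e_k,
            net._e_exc, net._e_inh,
            net._na_steps, net._h_steps, net._kf_steps,
            net._refrac_steps, out_series, fn_sub, fn_id, fa_sub, fa_id)

        # -- afferent spikes: record, schedule deliveries, new gamma targets
        for e in range(n_fa):
            a = int(fa_id[e])
            s_abs = step0 + int(fa_sub[e])
            si = int(aff_seg[a])
            li = int(aff.local_idx[a])
            ts_l, ids_l = aff_spk[aff.segments[si]]
            ts_l.append((s_abs + 1) * dt)
            ids_l.append(li)
            for proj in aff_proj_objs[si]:
                net.deliver_at(proj, li, s_abs)
            aff.target[a] = rng_targets.gamma(order, 1.0 / order)
        # -- neuron spikes
        for e in range(n_fn):
            g = int(fn_id[e])
            s_abs = step0 + int(fn_sub[e])
            t_next = (s_abs + 1) * dt
            pool = pool_list[pool_of[g]]
            li = g - pool.start
            if pool.kind == "MN":
                m = pool.name
                ts_l, ids_l = mn_spk[m]
                ts_l.append(t_next)
                ids_l.append(li)
                d_arr = int(motor_delay_steps[m][li])
                motor_ring[(s_abs + d_arr) % mhorizon].append(
                    acts.offsets[m] + li)
                ts_a, ids_a = mn_arr[m]
                ts_a.append(t_next + d_arr * dt)
                ids_a.append(li)
            else:
                ts_l, ids_l = in_spk[pool.name]
                ts_l.append(t_next)
                ids_l.append(li)
                for proj in in_proj_objs[pool.name]:
                    net.deliver_at(proj, li, s_abs)
        # -- recording (decimated)
        first = (-step0) % dec
        for j in range(first, k, dec):
            i = (step0 + j) // dec
            if i < n_out:
                for row, arr in enumerate(series_arrs):
                    arr[i] = out_series[row, j]
                series["x_com"][i] = body.height \
                    * math.sin(out_series[0, j])
                series["x_cop"][i] = out_series[3, j] \
                    / (body.mass * body.gravity)
        # -- fall / blow-up handling
        if fall_sub >= 0:
            status = "fell"
            fall_time = (step0 + fall_sub + 1) * dt
            break
        finite_check += k
        if finite_check >= 4000:
            finite_check = 0
            if not (np.all(np.isfinite(net.v_s))
                    and np.all(np.isfinite(sp_T))):
                raise sn.SimulationBlowupError(
                    f"non-finite state near step {step0}")
        step0 += k
    net.step_index = step0

    return _finalize(cfg, status, fall_time, series, n_out, dec, dt,
                     mn_spk, mn_arr, aff_spk, in_spk, aff, d_times, d_ids,
                     comp, net, fus_s, fus_d)

def basal_drive_check(scale: float = 0.1, duration: float = 5.0,
                      seed: int = 0, warmup: float = 1.0,
                      theta0_deg: float = 5.0) -> dict:
    """Locked-pendulum, feedback-off check of the basal muscle torque under
    the stochastic descending drive, as a fraction of the maximum
    (all-units-tetanic) triceps-surae torque."""
    cfg = SimulationConfig(
        duration=duration, scale=scale, seed=seed, theta0_deg=theta0_deg,
        lock_pendulum=True, feedback_on=False, synthesize_emg=False)
    res = run_simulation(cfg)
    sel = res.t >= warmup
    t_mean = float(np.mean(res.series["torque_muscle"][sel]))
    t_passive = static_muscle_torque(theta0_deg, {})
    t_max = max_plantarflexion_torque(theta0_deg, scale)
    frac = abs(t_mean - t_passive) / t_max
    return {"fraction": frac, "torque_mean": t_mean,
            "torque_passive": t_passive, "torque_max_active": t_max,
            "result": res}


def protocol_run_configs(**overrides) -> list[SimulationConfig]:
    """The six reference standing runs (three per model variant) with their
    tuned per-run fusimotor means, as shipped in ``data/protocol_runs.json``."""
    table = _params.load("protocol_runs")
    configs = []
    for run in table["runs"]:
        kw = dict(variant=run["variant"], seed=run["seed"],
                  fusimotor_static=run["fusimotor_static"],
                  fusimotor_dynamic=run["fusimotor_dynamic"],
                  theta0_deg=run.get("theta0_deg", 5.0),
                  scale=table["scale"], duration=table["duration"])
        kw.update(overrides)
        configs.append(SimulationConfig(**kw))
    return configs


def tune_fusimotor(config: SimulationConfig, static_grid, dynamic_grid,
                   trial_duration: float = 10.0):
    """Grid-search the fusimotor means: returns the first (static, dynamic)
    pair whose trial run completes without falling; logs all trials."""
    log = []
    for g_s in static_grid:
        for g_d in dynamic_grid:
            trial = replace(config, duration=trial_duration,
                            fusimotor_static=g_s, fusimotor_dynamic=g_d,
                            synthesize_emg=False)
            res = run_simulation(trial)
            log.append((g_s, g_d, res.status))
            if res.status == "completed":
                return (g_s, g_d), log
    raise RuntimeError(f"no stabilising fusimotor pair in the grid: {log}")
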