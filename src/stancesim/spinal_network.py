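"""Spinal neuron pools, synaptic dynamics and network construction.

Motor neurons (MNs) are two-compartment conductance-based models: a somatic
compartment carrying the spike-generating (Na, fast K) and
afterhyperpolarisation (slow K) conductances, coupled to a passive dendritic
compartment that receives the excitatory synaptic input; inhibitory synapses
contact the soma.  The conductance time courses are simplified to
threshold-triggered pulse kinetics (piecewise-exponential gating), which
preserves the spike/AHP phenomenology of the full model at a fraction of the
cost.  Interneurons (INs) are single-compartment versions of the same
template with spike thresholds spread linearly from 10 to 20 mV along each
pool.

Synaptic conductances follow a two-state kinetic scheme: each presynaptic
terminal opens a fixed-duration transmitter pulse after its conduction +
transmission delay; all terminals of one projection class onto one target
share a kinetic state ``r`` driven by the normalised count of open pulses
and bounded by the class's maximum conductance.  This yields
single-terminal postsynaptic potentials at the ~0.1 mV scale of animal data,
saturation of the aggregate conductance under heavy drive, and a mean drive
that is invariant under pool down-scaling.

Potentials are in mV relative to rest, conductances in uS, capacitances in
nF, currents in nA, internal rate constants in 1/ms.
"""
from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np

try:
    import numba as _numba
    _NJIT = _numba.njit(cache=True, fastmath=False)
except Exception:                                   # pragma: no cover
    _numba = None

    def _NJIT(f):
        return f

from . import params as _params

MU_TYPES = ("S", "FR", "FF")


class SimulationBlowupError(FloatingPointError):
    """Numerical blow-up (non-finite neuron state) with diagnostics."""


@_NJIT
def _step_core(idx, n_exc, ch_won, ch_r, ch_gmax, ch_neuron, ch_comp,
               alpha_e, beta_e, alpha_i, beta_i, dtms,
               g_exc_d, g_exc_s, g_inh_s,
               na_off, h_off, kf_off, refrac_until,
               m, h, ng, q, e_am, e_bm, e_ah, e_bh, e_an, e_bn, e_q,
               g_ls, g_ld, g_c, c_s_inv, c_d_inv, g_na, g_kf, g_ks,
               delta_q, v_th, v_s, v_d, e_na, e_k, e_exc, e_inh,
               i_inj, na_steps, h_steps, kf_steps, refrac_steps,
               fired_buf):
    """One RK4 step for every neuron (compiled inner loop).

    Kinetic synaptic channels (piecewise-exact), pulse gating, two-
    compartment membrane RK4, and threshold-crossing spike detection.
    Returns the number of spikes written into ``fired_buf``.
    """
    n_ch = ch_won.shape[0]
    n = v_s.shape[0]
    for i in range(n):
        g_exc_d[i] = 0.0
        g_exc_s[i] = 0.0
        g_inh_s[i] = 0.0
    for c in range(n_ch):
        if c < n_exc:
            alpha = alpha_e
            beta = beta_e
        else:
            alpha = alpha_i
            beta = beta_i
        w = ch_won[c]
        if w < 0.0:
            w = 0.0
        aw = alpha * w
        rate = aw + beta
        r_inf = aw / rate
        r = r_inf + (ch_r[c] - r_inf) * math.exp(-rate * dtms)
        ch_r[c] = r
        g = ch_gmax[c] * r
        tgt = ch_neuron[c]
        comp = ch_comp[c]
        if comp == 0:
            g_exc_d[tgt] += g
        elif comp == 1:
            g_exc_s[tgt] += g
        else:
            g_inh_s[tgt] += g
    n_fired = 0
    for i in range(n):
        # gating: exact piecewise exponentials
        mi = m[i]
        if na_off[i] > idx:
            mi = 1.0 + (mi - 1.0) * e_am
        else:
            mi = mi * e_bm
        m[i] = mi
        hi = h[i]
        if h_off[i] > idx:
            hi = hi * e_ah
        else:
            hi = 1.0 + (hi - 1.0) * e_bh
        h[i] = hi
        ni = ng[i]
        if kf_off[i] > idx:
            ni = 1.0 + (ni - 1.0) * e_an
        else:
            ni = ni * e_bn
        ng[i] = ni
        qi = q[i] * e_q[i]
        q[i] = qi
        # effective spike conductances
        g_na_eff = g_na[i] * (mi * mi * mi) * hi
        n2 = ni * ni
        g_kf_eff = g_kf[i] * n2 * n2
        g_ks_eff = g_ks[i] * qi
        ged = g_exc_d[i]
        ges = g_exc_s[i]
        gis = g_inh_s[i]
        gsum_s = (g_ls[i] + g_c[i] + g_na_eff + g_kf_eff + g_ks_eff
                  + gis + ges)
        b_s = (g_na_eff * e_na + (g_kf_eff + g_ks_eff) * e_k
               + gis * e_inh + ges * e_exc + i_inj[i])
        gsum_d = g_ld[i] + g_c[i] + ged
        b_d = ged * e_exc
        cis = c_s_inv[i]
        cid = c_d_inv[i]
        gc = g_c[i]
        vs = v_s[i]
        vd = v_d[i]
        k1s = (b_s - gsum_s * vs + gc * vd) * cis
        k1d = (b_d - gsum_d * vd + gc * vs) * cid
        a2 = vs + 0.5 * dtms * k1s
        b2 = vd + 0.5 * dtms * k1d
        k2s = (b_s - gsum_s * a2 + gc * b2) * cis
        k2d = (b_d - gsum_d * b2 + gc * a2) * cid
        a3 = vs + 0.5 * dtms * k2s
        b3 = vd + 0.5 * dtms * k2d
        k3s = (b_s - gsum_s * a3 + gc * b3) * cis
        k3d = (b_d - gsum_d * b3 + gc * a3) * cid
        a4 = vs + dtms * k3s
        b4 = vd + dtms * k3d
        k4s = (b_s - gsum_s * a4 + gc * b4) * cis
        k4d = (b_d - gsum_d * b4 + gc * a4) * cid
        vs = vs + dtms * (k1s + 2.0 * k2s + 2.0 * k3s + k4s) / 6.0
        vd = vd + dtms * (k1d + 2.0 * k2d + 2.0 * k3d + k4d) / 6.0
        v_s[i] = vs
        v_d[i] = vd
        if vs >= v_th[i] and refrac_until[i] <= idx:
            na_off[i] = idx + na_steps
            h_off[i] = idx + h_steps
            kf_off[i] = idx + kf_steps
            refrac_until[i] = idx + refrac_steps
            q[i] = qi + delta_q[i] * (1.0 - qi)
            fired_buf[n_fired] = i
            n_fired += 1
    return n_fired


# ---------------------------------------------------------------------------
# descending drive
# ---------------------------------------------------------------------------

def generate_descending_drive(n_axons: int, rate_hz: float, shape: int,
                              duration: float, seed):
    """Independent gamma renewal processes, one per axon.

    Returns (times, axon_ids), time-sorted.  ISI mean is 1/rate and CV is
    1/sqrt(shape); shape = 1 recovers a Poisson process.
    """
    if rate_hz <= 0:
        raise ValueError("rate must be positive")
    if shape < 1:
        raise ValueError("gamma shape must be >= 1")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    times, ids = [], []
    scale = 1.0 / (rate_hz * shape)
    for axon in range(n_axons):
        n_est = int(duration * rate_hz * 1.5) + 20
        t = np.cumsum(rng.gamma(shape, scale, size=n_est))
        while t[-1] < duration:
            t = np.concatenate(
                [t, t[-1] + np.cumsum(rng.gamma(shape, scale, size=n_est))])
        t = t[t < duration]
        times.append(t)
        ids.append(np.full(len(t), axon, dtype=np.int32))
    times = np.concatenate(times)
    ids = np.concatenate(ids)
    order = np.argsort(times, kind="stable")
    return times[order], ids[order]


# ---------------------------------------------------------------------------
# standalone kinetic conductance (unit surface of the synapse model)
# ---------------------------------------------------------------------------

class KineticConductance:
    """Two-state kinetic synaptic conductance for one projection class onto
    one target neuron.

    ``r`` relaxes toward ``alpha*W/(alpha*W + beta)`` while transmitter
    pulses are open (W = normalised open-terminal count) and decays with
    ``beta`` otherwise; the conductance is ``g_max * r``; time in ms.
    """

    def __init__(self, g_max_us: float, n_terminals: int, kind: str = "exc"):
        syn = _params.load("neuron")["synapse"][kind]
        self.alpha = syn["alpha"]
        self.beta = syn["beta"]
        self.pulse_ms = syn["pulse_ms"]
        self.e_rev = syn["e_rev"]
        self.g_max = g_max_us
        self.n_terminals = n_terminals
        self.r = 0.0
        self.w_on = 0.0
        self._events: list[tuple[float, float]] = []
        self._t = 0.0

    def add_spike(self, t_ms: float, weight: float | None = None):
        if t_ms < self._t:
            raise ValueError("presynaptic event earlier than current time")
        w = (1.0 / self.n_terminals) if weight is None else weight
        self._events.append((t_ms, +w))
        self._events.append((t_ms + self.pulse_ms, -w))
        self._events.sort()

    def advance(self, t_ms: float) -> float:
        """Advance the kinetic state to ``t_ms`` (piecewise-exact); returns
        the conductance g_max * r."""
        while self._events and self._events[0][0] <= t_ms:
            t_ev, dw = self._events.pop(0)
            self._advance_const(t_ev)
            self.w_on += dw
        self._advance_const(t_ms)
        return self.g_max * self.r

    def _advance_const(self, t_ms):
        dt = t_ms - self._t
        if dt <= 0:
            return
        rate = self.alpha * self.w_on + self.beta
        r_inf = self.alpha * self.w_on / rate
        self.r = r_inf + (self.r - r_inf) * math.exp(-rate * dt)
        self._t = t_ms

    @property
    def saturation_bound(self) -> float:
        """Fixed point of the kinetic scheme with every terminal open."""
        return self.g_max * self.alpha / (self.alpha + self.beta)


# ---------------------------------------------------------------------------
# network data structures
# ---------------------------------------------------------------------------

@dataclass
class PoolInfo:
    name: str
    kind: str                   # "MN" or "IN"
    muscle: str | None
    start: int
    stop: int
    mu_types: np.ndarray | None = None      # per-unit type codes (MN only)
    axon_delay_s: np.ndarray | None = None  # per-unit conduction delay (MN)

    @property
    def n(self) -> int:
        return self.stop - self.start

    @property
    def sl(self) -> slice:
        return slice(self.start, self.stop)


@dataclass
class Projection:
    """One projection class: per-source-unit channel target lists."""
    name: str
    source: str                 # pool name or external source name
    target_pool: str
    sign: str                   # "exc" / "inh"
    weight: float               # normalised transmitter weight per terminal
    channel_ids: list[np.ndarray]           # per source unit
    delay_s: np.ndarray                     # per source unit
    delay_steps: np.ndarray | None = None   # set by begin_run


def _band(values, n):
    lo, hi = values
    if n == 1:
        return np.array([0.5 * (lo + hi)])
    return np.linspace(lo, hi, n)


def scaled_composition(scale: float, composition=None):
    """Motor-neuron counts per nucleus at a reduced scale, preserving the
    type proportions (rounded; at least one S unit per nucleus)."""
    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    comp = composition or _params.load("motorunits")["composition"]
    out = {}
    for muscle, counts in comp.items():
        sc = {t: int(round(n * scale)) for t, n in counts.items()}
        if sum(sc.values()) == 0:
            raise ValueError("scale produces an empty pool")
        if sc["S"] == 0:
            sc["S"] = 1
        out[muscle] = sc
    return out


class SpinalNetwork:
    """All neuron pools of one model variant, stored as contiguous slices of
    global state/parameter arrays, plus the projection tables."""

    def __init__(self, pools, arrays, channels, projections, variant,
                 seed, scale, composition):
        self.pools: dict[str, PoolInfo] = pools
        self.variant = variant
        self.seed = seed
        self.scale = scale
        self.composition = composition
        self.projections: dict[str, Projection] = projections
        for k, v in arrays.items():
            setattr(self, k, v)
        self.n_neurons = len(self.g_ls)
        self.ch_neuron = channels["neuron"]
        self.ch_gmax = channels["gmax"]
        self.ch_exc = channels["exc"]
        self.ch_dend = channels["dend"]
        self.n_channels = len(self.ch_neuron)
        self._lookup = channels["lookup"]
        self._spk = _params.load("neuron")["spike"]
        self._syn = _params.load("neuron")["synapse"]
        self.reset_state()

    # -- state ---------------------------------------------------------------
    def reset_state(self):
        n = self.n_neurons
        self.v_s = np.zeros(n)
        self.v_d = np.zeros(n)
        self.m = np.zeros(n)
        self.h = np.ones(n)
        self.ng = np.zeros(n)
        self.q = np.zeros(n)
        self.na_off = np.full(n, -1, dtype=np.int64)
        self.h_off = np.full(n, -1, dtype=np.int64)
        self.kf_off = np.full(n, -1, dtype=np.int64)
        self.refrac_until = np.zeros(n, dtype=np.int64)
        self.ch_r = np.zeros(self.n_channels)
        self.ch_won = np.zeros(self.n_channels)
        self.step_index = 0
        self._queue = None

    def channel_ids(self, pool: str, class_name: str) -> np.ndarray:
        return self._lookup[(pool, class_name)]

    # -- per-dt constants ----------------------------------------------------
    def begin_run(self, dt: float, horizon_s: float = 0.05):
        """Freeze per-step constants for step size ``dt`` and allocate the
        synaptic event ring buffer (capacity >= the longest delay)."""
        self.dt = dt
        dtms = dt * 1000.0
        spk = self._spk
        self._e_am = math.exp(-spk["alpha_m"] * dtms)
        self._e_bm = math.exp(-spk["beta_m"] * dtms)
        self._e_ah = math.exp(-spk["alpha_h"] * dtms)
        self._e_bh = math.exp(-spk["beta_h"] * dtms)
        self._e_an = math.exp(-spk["alpha_n"] * dtms)
        self._e_bn = math.exp(-spk["beta_n"] * dtms)
        self._e_q = np.exp(-dtms / self.tau_q)
        self._na_steps = max(1, round(spk["na_pulse_ms"] / dtms))
        self._h_steps = max(1, round(spk["h_pulse_ms"] / dtms))
        self._kf_steps = max(1, round(spk["kf_pulse_ms"] / dtms))
        self._refrac_steps = max(1, round(spk["refractory_ms"] / dtms))
        self._pulse_steps = max(1, round(self._syn["exc"]["pulse_ms"] / dtms))
        self._alpha_e = self._syn["exc"]["alpha"]
        self._beta_e = self._syn["exc"]["beta"]
        self._alpha_i = self._syn["inh"]["alpha"]
        self._beta_i = self._syn["inh"]["beta"]
        self._e_exc = self._syn["exc"]["e_rev"]
        self._e_inh = self._syn["inh"]["e_rev"]
        self._dtms = dtms
        horizon = int(horizon_s / dt) + self._pulse_steps + 2
        for proj in self.projections.values():
            proj.delay_steps = np.maximum(
                1, np.rint(proj.delay_s / dt).astype(np.int64))
            upper = int(proj.delay_steps.max(initial=0)) \
                + self._pulse_steps + 2
            horizon = max(horizon, upper)
        self._horizon = horizon
        self._queue = [[] for _ in range(horizon)]

        def block(mask):
            idx = np.nonzero(mask)[0]
            if len(idx) == 0:
                return slice(0, 0)
            if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise AssertionError("channel blocks must be contiguous")
            return slice(int(idx[0]), int(idx[-1]) + 1)

        self._exc_sl = block(self.ch_exc)
        self._inh_sl = block(~self.ch_exc)
        self._exc_d_sl = block(self.ch_exc & self.ch_dend)
        self._exc_s_sl = block(self.ch_exc & ~self.ch_dend)
        self._inh_s_sl = block(~self.ch_exc & ~self.ch_dend)
        self._nrn_exc_d = self.ch_neuron[self._exc_d_sl]
        self._nrn_exc_s = self.ch_neuron[self._exc_s_sl]
        self._nrn_inh_s = self.ch_neuron[self._inh_s_sl]
        # compiled-core scratch: compartment code per channel and buffers
        self._n_exc = self._exc_sl.stop
        comp = np.full(self.n_channels, 2, dtype=np.int8)
        comp[self.ch_exc & self.ch_dend] = 0
        comp[self.ch_exc & ~self.ch_dend] = 1
        self._ch_comp = comp
        self._ch_neuron64 = self.ch_neuron.astype(np.int64)
        n = self.n_neurons
        self._g_exc_d = np.zeros(n)
        self._g_exc_s = np.zeros(n)
        self._g_inh_s = np.zeros(n)
        self._zero_inj = np.zeros(n)
        self._fired_buf = np.zeros(n, dtype=np.int64)
        self._spk_e_na = float(self._spk["e_na"])
        self._spk_e_k = float(self._spk["e_k"])
        self.step_index = 0

    # -- event scheduling ----------------------------------------------------
    def deliver_spike(self, projection: str, source_unit: int):
        """Schedule the synaptic effect of one presynaptic spike (descending
        axon, afferent fibre, or spiking neuron)."""
        self.deliver(self.projections[projection], source_unit)

    def deliver(self, proj: Projection, source_unit: int):
        ch = proj.channel_ids[source_unit]
        if len(ch) == 0:
            return
        d = int(proj.delay_steps[source_unit])
        w = proj.weight
        q = self._queue
        h = self._horizon
        q[(self.step_index + d) % h].append((ch, w))
        q[(self.step_index + d + self._pulse_steps) % h].append((ch, -w))

    def deliver_at(self, proj: Projection, source_unit: int,
                   from_step: int):
        """Like :meth:`deliver`, measuring the delay from ``from_step``
        (used by the batched runner, which processes spikes after the
        fact)."""
        ch = proj.channel_ids[source_unit]
        if len(ch) == 0:
            return
        d = int(proj.delay_steps[source_unit])
        w = proj.weight
        q = self._queue
        h = self._horizon
        q[(from_step + d) % h].append((ch, w))
        q[(from_step + d + self._pulse_steps) % h].append((ch, -w))

    # -- main step -----------------------------------------------------------
    def step(self, i_inj: np.ndarray | None = None) -> np.ndarray:
        """Advance every neuron one RK4 step; returns the global indices of
        units that spiked (spike time = end of the step)."""
        idx = self.step_index
        # 1. scheduled transmitter on/off events
        slot = self._queue[idx % self._horizon]
        if slot:
            won = self.ch_won
            for ch, w in slot:
                # channel ids are unique within one event, so fancy-index
                # accumulation is safe (and much faster than ufunc.at)
                won[ch] += w
            slot.clear()
        # 2.-5. compiled inner loop: channels, gating, membrane RK4, spikes
        n_fired = _step_core(
            idx, self._n_exc, self.ch_won, self.ch_r, self.ch_gmax,
            self._ch_neuron64, self._ch_comp,
            self._alpha_e, self._beta_e, self._alpha_i, self._beta_i,
            self._dtms, self._g_exc_d, self._g_exc_s, self._g_inh_s,
            self.na_off, self.h_off, self.kf_off, self.refrac_until,
            self.m, self.h, self.ng, self.q,
            self._e_am, self._e_bm, self._e_ah, self._e_bh, self._e_an,
            self._e_bn, self._e_q,
            self.g_ls, self.g_ld, self.g_c, self.c_s_inv, self.c_d_inv,
            self.g_na, self.g_kf, self.g_ks, self.delta_q, self.v_th,
            self.v_s, self.v_d, self._spk_e_na, self._spk_e_k,
            self._e_exc, self._e_inh,
            self._zero_inj if i_inj is None else i_inj,
            self._na_steps, self._h_steps, self._kf_steps,
            self._refrac_steps, self._fired_buf)
        if idx % 4000 == 0 and not np.all(np.isfinite(self.v_s)):
            bad = np.nonzero(~np.isfinite(self.v_s))[0][:5]
            raise SimulationBlowupError(
                f"non-finite somatic potential at step {idx}, units {bad}")
        self.step_index = idx + 1
        return self._fired_buf[:n_fired].copy()

    def _step_reference(self, i_inj: np.ndarray | None = None) -> np.ndarray:
        """Pure-numpy reference step (kept as the conformance oracle for the
        compiled core)."""
        idx = self.step_index
        slot = self._queue[idx % self._horizon]
        if slot:
            won = self.ch_won
            for ch, w in slot:
                won[ch] += w
            slot.clear()
        # 2. kinetic conductances (piecewise-exact update)
        r = self.ch_r
        for sl, alpha, beta in ((self._exc_sl, self._alpha_e, self._beta_e),
                                (self._inh_sl, self._alpha_i, self._beta_i)):
            aw = alpha * np.maximum(self.ch_won[sl], 0.0)
            rate = aw + beta
            r_inf = aw / rate
            r[sl] = r_inf + (r[sl] - r_inf) * np.exp(-rate * self._dtms)
        gr = self.ch_gmax * r
        n = self.n_neurons
        g_exc_d = np.bincount(self._nrn_exc_d, weights=gr[self._exc_d_sl],
                              minlength=n)
        g_exc_s = np.bincount(self._nrn_exc_s, weights=gr[self._exc_s_sl],
                              minlength=n)
        g_inh_s = np.bincount(self._nrn_inh_s, weights=gr[self._inh_s_sl],
                              minlength=n)
        # 3. gating (exact exponentials, pulse-scheduled alpha phases)
        in_na = self.na_off > idx
        in_h = self.h_off > idx
        in_kf = self.kf_off > idx
        m, h_, ng = self.m, self.h, self.ng
        self.m = np.where(in_na, 1.0 + (m - 1.0) * self._e_am, m * self._e_bm)
        self.h = np.where(in_h, h_ * self._e_ah,
                          1.0 + (h_ - 1.0) * self._e_bh)
        self.ng = np.where(in_kf, 1.0 + (ng - 1.0) * self._e_an,
                           ng * self._e_bn)
        self.q *= self._e_q
        # 4. membrane RK4 with conductances frozen over the step
        spk = self._spk
        g_na_eff = self.g_na * (self.m * self.m * self.m) * self.h
        n2 = self.ng * self.ng
        g_kf_eff = self.g_kf * n2 * n2
        g_ks_eff = self.g_ks * self.q
        gsum_s = (self.g_ls + self.g_c + g_na_eff + g_kf_eff + g_ks_eff
                  + g_inh_s + g_exc_s)
        b_s = (g_na_eff * spk["e_na"] + (g_kf_eff + g_ks_eff) * spk["e_k"]
               + g_inh_s * self._e_inh + g_exc_s * self._e_exc)
        if i_inj is not None:
            b_s = b_s + i_inj
        gsum_d = self.g_ld + self.g_c + g_exc_d
        b_d = g_exc_d * self._e_exc
        ci_s, ci_d = self.c_s_inv, self.c_d_inv
        g_c = self.g_c
        dtms = self._dtms
        vs, vd = self.v_s, self.v_d

        k1s = (b_s - gsum_s * vs + g_c * vd) * ci_s
        k1d = (b_d - gsum_d * vd + g_c * vs) * ci_d
        a2 = vs + 0.5 * dtms * k1s
        b2 = vd + 0.5 * dtms * k1d
        k2s = (b_s - gsum_s * a2 + g_c * b2) * ci_s
        k2d = (b_d - gsum_d * b2 + g_c * a2) * ci_d
        a3 = vs + 0.5 * dtms * k2s
        b3 = vd + 0.5 * dtms * k2d
        k3s = (b_s - gsum_s * a3 + g_c * b3) * ci_s
        k3d = (b_d - gsum_d * b3 + g_c * a3) * ci_d
        a4 = vs + dtms * k3s
        b4 = vd + dtms * k3d
        k4s = (b_s - gsum_s * a4 + g_c * b4) * ci_s
        k4d = (b_d - gsum_d * b4 + g_c * a4) * ci_d
        vs = vs + dtms * (k1s + 2 * k2s + 2 * k3s + k4s) / 6.0
        vd = vd + dtms * (k1d + 2 * k2d + 2 * k3d + k4d) / 6.0
        self.v_s, self.v_d = vs, vd
        # 5. spike detection: upward crossing outside refractoriness
        fired = np.nonzero((vs >= self.v_th) & (self.refrac_until <= idx))[0]
        if len(fired):
            self.na_off[fired] = idx + self._na_steps
            self.h_off[fired] = idx + self._h_steps
            self.kf_off[fired] = idx + self._kf_steps
            self.refrac_until[fired] = idx + self._refrac_steps
            self.q[fired] += self.delta_q[fired] * (1.0 - self.q[fired])
        if idx % 4000 == 0 and not np.all(np.isfinite(vs)):
            bad = np.nonzero(~np.isfinite(vs))[0][:5]
            raise SimulationBlowupError(
                f"non-finite somatic potential at step {idx}, units {bad}")
        self.step_index = idx + 1
        return fired

    # -- exports -------------------------------------------------------------
    def manifest(self):
        """Rows (unit_id, population, kind, mu_type) for every neuron."""
        rows = []
        for p in self.pools.values():
            for i in range(p.n):
                mu = MU_TYPES[p.mu_types[i]] if p.mu_types is not None else ""
                rows.append((p.start + i, p.name, p.kind, mu))
        return rows

    def edge_list(self):
        """(source, target, g_max_nS, delay_s, sign) for every connection;
        g_max here is the per-terminal share of the class conductance."""
        edges = []
        for proj in self.projections.values():
            tgt = self.pools[proj.target_pool]
            for src, ch in enumerate(proj.channel_ids):
                for c in ch:
                    edges.append((
                        f"{proj.source}:{src}",
                        f"{proj.target_pool}:{self.ch_neuron[c] - tgt.start}",
                        self.ch_gmax[c] * proj.weight * 1e3,
                        float(proj.delay_s[src]),
                        proj.sign,
                    ))
        return edges


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def build_network(variant: str = "model2", seed=0, scale: float = 1.0,
                  composition=None,
                  afferent_counts: dict[str, dict[str, int]] | None = None
                  ) -> SpinalNetwork:
    """Instantiate every pool and projection of one model variant.

    ``model1`` omits the reciprocal-inhibition pathway from the antagonist's
    (TA) Ia afferents through the TA-side Ia-inhibitory interneurons onto
    the triceps-surae motor nuclei; everything else is identical to
    ``model2``.  All randomised per-unit properties (threshold jitter,
    Bernoulli connectivity draws) derive from ``seed``.
    """
    if variant not in ("model1", "model2"):
        raise ValueError(f"unknown variant {variant!r}")
    np_cfg = _params.load("neuron")
    fb = _params.load("feedback")
    comp = scaled_composition(scale, composition)
    if afferent_counts is None:
        afferent_counts = {
            m: {t: max(1, int(round(n * scale)))
                for t, n in fb["afferent_counts"][m].items()}
            for m in fb["afferent_counts"]}
    n_in = max(2, int(round(fb["interneurons_per_group"] * scale)))

    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    ss_thresh, ss_conn = ss.spawn(2)
    rng_thresh = np.random.default_rng(ss_thresh)
    # connectivity draws are keyed by projection name so that shared
    # projections are identical across model variants built from one seed
    _conn_state = ss_conn.generate_state(4)

    def rng_for_projection(name: str):
        key = zlib.crc32(name.encode())
        return np.random.default_rng(
            np.random.SeedSequence(entropy=[int(x) for x in _conn_state],
                                   spawn_key=(key,)))

    # ---- pools -------------------------------------------------------------
    pools: dict[str, PoolInfo] = {}
    par = {k: [] for k in ("g_ls", "g_ld", "g_c", "c_s_inv", "c_d_inv",
                           "g_na", "g_kf", "g_ks", "v_th", "tau_q",
                           "delta_q")}
    offset = 0
    jit = np_cfg["threshold_jitter_frac"]
    mn = np_cfg["motoneuron"]
    for muscle in ("SO", "MG", "LG", "TA"):
        counts = comp[muscle]
        types, g_ls, tau_s, v_th, tau_q, vel = [], [], [], [], [], []
        for code, t in enumerate(MU_TYPES):
            ncnt = counts[t]
            if ncnt == 0:
                continue
            types.append(np.full(ncnt, code, dtype=np.int8))
            g_ls.append(_band(mn[t]["g_leak_soma"], ncnt))
            tau_s.append(_band(mn[t]["tau_soma"], ncnt))
            v_th.append(_band(mn[t]["v_threshold"], ncnt))
            tau_q.append(_band(mn[t]["tau_ahp"], ncnt))
            vel.append(_band(mn[t]["axon_velocity"], ncnt))
        types = np.concatenate(types)
        g_ls = np.concatenate(g_ls)
        tau_s = np.concatenate(tau_s)
        v_th = np.concatenate(v_th) \
            * (1.0 + rng_thresh.uniform(-jit, jit, size=len(types)))
        tau_q = np.concatenate(tau_q)
        vel = np.concatenate(vel)
        g_ld = mn["dend_leak_ratio"] * g_ls
        par["g_ls"].append(g_ls)
        par["g_ld"].append(g_ld)
        par["g_c"].append(np.full(len(types), mn["g_coupling"]))
        par["c_s_inv"].append(1.0 / (tau_s * g_ls))
        par["c_d_inv"].append(1.0 / (tau_s * g_ld))
        par["g_na"].append(mn["g_na_ratio"] * g_ls)
        par["g_kf"].append(mn["g_kf_ratio"] * g_ls)
        par["g_ks"].append(mn["g_ks_ratio"] * g_ls)
        par["v_th"].append(v_th)
        par["tau_q"].append(tau_q)
        par["delta_q"].append(np.full(len(types), mn["delta_q"]))
        pools[muscle] = PoolInfo(
            name=muscle, kind="MN", muscle=muscle, start=offset,
            stop=offset + len(types), mu_types=types,
            axon_delay_s=mn["axon_length_m"] / vel)
        offset += len(types)

    inp = np_cfg["interneuron"]
    in_pools = (["IaIN_TS", "IaIN_TA"]
                + [f"IbIN_{m}" for m in ("SO", "MG", "LG", "TA")]
                + [f"IIIN_{m}" for m in ("SO", "MG", "LG", "TA")])
    for name in in_pools:
        g_l = _band(inp["g_leak"], n_in)
        tau = _band(inp["tau"], n_in)
        v_th = _band(inp["v_threshold"], n_in) \
            * (1.0 + rng_thresh.uniform(-jit, jit, size=n_in))
        par["g_ls"].append(g_l)
        par["g_ld"].append(np.zeros(n_in))
        par["g_c"].append(np.zeros(n_in))
        par["c_s_inv"].append(1.0 / (tau * g_l))
        par["c_d_inv"].append(np.ones(n_in))    # inert dendrite
        par["g_na"].append(inp["g_na_ratio"] * g_l)
        par["g_kf"].append(inp["g_kf_ratio"] * g_l)
        par["g_ks"].append(inp["g_ks_ratio"] * g_l)
        par["v_th"].append(v_th)
        par["tau_q"].append(_band(inp["tau_ahp"], n_in))
        par["delta_q"].append(np.full(n_in, inp["delta_q"]))
        muscle = name.split("_")[1] if "_" in name else None
        pools[name] = PoolInfo(name=name, kind="IN", muscle=muscle,
                               start=offset, stop=offset + n_in)
        offset += n_in
    arrays = {k: np.concatenate(v) for k, v in par.items()}

    # ---- channels ----------------------------------------------------------
    ch_neuron, ch_gmax, ch_exc, ch_dend = [], [], [], []
    lookup: dict[tuple[str, str], np.ndarray] = {}

    def add_channels(pool: str, class_name: str, g_max_ns: float,
                     exc: bool, dend: bool) -> np.ndarray:
        p = pools[pool]
        ids = np.arange(len(ch_neuron), len(ch_neuron) + p.n)
        ch_neuron.extend(range(p.start, p.stop))
        ch_gmax.extend([g_max_ns * 1e-3] * p.n)
        ch_exc.extend([exc] * p.n)
        ch_dend.extend([dend] * p.n)
        lookup[(pool, class_name)] = ids
        return ids

    g = fb["g_max_ns"]
    conn = fb["connectivity"]
    desc = fb["descending"]
    # channels are laid out in contiguous kinetic blocks (exc-dend, exc-soma,
    # inh-soma) so the per-step updates can run on slices
    for m in desc["targets"]:
        add_channels(m, "desc", desc["g_max_ns"], True, True)
    for m in ("SO", "MG", "LG", "TA"):
        add_channels(m, "ia", g["ia_to_mn"], True, True)
        add_channels(m, "ii_in", g["in_to_mn"], True, True)
    add_channels("IaIN_TS", "aff", g["ia_to_in"], True, False)
    add_channels("IaIN_TA", "aff", g["ia_to_in"], True, False)
    for m in ("SO", "MG", "LG", "TA"):
        add_channels(f"IbIN_{m}", "aff", g["ib_to_in"], True, False)
        add_channels(f"IIIN_{m}", "aff", g["ii_to_in"], True, False)
    for m in ("SO", "MG", "LG", "TA"):
        add_channels(m, "ib_in", g["in_to_mn"], False, False)
        add_channels(m, "ia_in", g["in_to_mn"], False, False)
    channels = {
        "neuron": np.asarray(ch_neuron, dtype=np.intp),
        "gmax": np.asarray(ch_gmax),
        "exc": np.asarray(ch_exc, dtype=bool),
        "dend": np.asarray(ch_dend, dtype=bool),
        "lookup": lookup,
    }

    # ---- projections -------------------------------------------------------
    projections: dict[str, Projection] = {}
    syn_delay = np_cfg["synapse"]["transmission_delay_ms"] * 1e-3
    path = fb["path_length_m"]

    def add_projection(name, source, target_pool, class_name, n_src, p_conn,
                       delay_s, sign, n_norm):
        ids = lookup[(target_pool, class_name)]
        rng = rng_for_projection(name)
        targets = [ids[rng.random(len(ids)) < p_conn] for _ in range(n_src)]
        projections[name] = Projection(
            name=name, source=source, target_pool=target_pool, sign=sign,
            weight=1.0 / n_norm,
            channel_ids=targets,
            delay_s=np.broadcast_to(np.asarray(delay_s, dtype=float),
                                    (n_src,)).copy(),
        )

    def aff_velocities(muscle, a_type):
        lo, hi = fb["conduction_velocity"][a_type]
        return _band((lo, hi), afferent_counts[muscle][a_type])

    # descending drive onto the TS motor nuclei
    for m in desc["targets"]:
        add_projection(f"desc->{m}", "descending", m, "desc",
                       desc["n_axons"], desc["connectivity"], syn_delay,
                       "exc", desc["n_axons"] * desc["connectivity"])

    # Ia -> MN (homonymous + synergist; no MG Ia onto SO MNs)
    synergists = {"SO": ["LG"], "MG": ["SO", "LG"], "LG": ["SO", "MG"],
                  "TA": []}
    for m in ("SO", "MG", "LG", "TA"):
        contributions = [(m, conn["ia_to_mn_homonymous"])] \
            + [(s, conn["ia_to_mn_synergist"]) for s in synergists[m]]
        n_norm = sum(afferent_counts[src]["Ia"] * p
                     for src, p in contributions)
        for src, p_conn in contributions:
            add_projection(f"Ia_{src}->{m}", f"Ia_{src}", m, "ia",
                           afferent_counts[src]["Ia"], p_conn,
                           path / aff_velocities(src, "Ia") + syn_delay,
                           "exc", n_norm)

    # Ia -> Ia-inhibitory interneurons (side pools)
    ts_sources = ("SO", "MG", "LG")
    n_norm = sum(afferent_counts[s]["Ia"] for s in ts_sources) \
        * conn["ia_to_in"]
    for s in ts_sources:
        add_projection(f"Ia_{s}->IaIN_TS", f"Ia_{s}", "IaIN_TS", "aff",
                       afferent_counts[s]["Ia"], conn["ia_to_in"],
                       path / aff_velocities(s, "Ia") + syn_delay,
                       "exc", n_norm)
    if variant == "model2":
        add_projection("Ia_TA->IaIN_TA", "Ia_TA", "IaIN_TA", "aff",
                       afferent_counts["TA"]["Ia"], conn["ia_to_in"],
                       path / aff_velocities("TA", "Ia") + syn_delay,
                       "exc", afferent_counts["TA"]["Ia"] * conn["ia_to_in"])

    # Ib and II afferents onto their interneuron pools
    for m in ("SO", "MG", "LG", "TA"):
        for a_type, prefix, key in (("Ib", "IbIN", "ib_to_in"),
                                    ("II", "IIIN", "ii_to_in")):
            n_src = afferent_counts[m][a_type]
            add_projection(f"{a_type}_{m}->{prefix}_{m}",
                           f"{a_type}_{m}", f"{prefix}_{m}", "aff",
                           n_src, conn[key],
                           path / aff_velocities(m, a_type) + syn_delay,
                           "exc", n_src * conn[key])

    # interneurons onto motor nuclei
    in_delay = np_cfg["interneuron"]["conduction_delay_ms"] * 1e-3
    for m in ("SO", "MG", "LG", "TA"):
        add_projection(f"IbIN_{m}->{m}", f"IbIN_{m}", m, "ib_in",
                       n_in, conn["ib_in_to_mn"], in_delay, "inh",
                       n_in * conn["ib_in_to_mn"])
        add_projection(f"IIIN_{m}->{m}", f"IIIN_{m}", m, "ii_in",
                       n_in, conn["ii_in_to_mn"], in_delay, "exc",
                       n_in * conn["ii_in_to_mn"])
    # reciprocal inhibition: the TS-side Ia-INs silence the TA motor nucleus
    # in both variants; the studied TA->TS pathway exists only in model2
    add_projection("IaIN_TS->TA", "IaIN_TS", "TA", "ia_in",
                   n_in, conn["ia_in_to_mn"], in_delay, "inh",
                   n_in * conn["ia_in_to_mn"])
    if variant == "model2":
        for m in ("SO", "MG", "LG"):
            add_projection(f"IaIN_TA->{m}", "IaIN_TA", m, "ia_in",
                           n_in, conn["ia_in_to_mn"], in_delay, "inh",
                           n_in * conn["ia_in_to_mn"])

    return SpinalNetwork(pools, arrays, channels, projections, variant,
                         seed, scale, comp)
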