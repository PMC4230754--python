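"""Muscle proprioceptors and afferent fibre encoding.

Three receptor models feed the spinal circuitry:

* a muscle spindle with bag1, bag2 and chain intrafusal fibres in the
  tension-based formulation: the primary (Ia) discharge combines all three
  intrafusal outputs (dynamic + static stretch information, with partial
  occlusion between the bag1 and the static branch), the secondary (II)
  discharge only the static bag2/chain branch; bag1 is sensitised by dynamic
  fusimotor drive, bag2/chain by static fusimotor drive;
* a Golgi tendon organ: a saturating static nonlinearity of tendon force in
  series with the classical third-order rate-sensitive transfer function,
  discretised by the bilinear transform;
* afferent bundles (Ia, II, Ib per muscle) that convert the continuous
  receptor rate into independent stochastic spike trains: each fibre is
  recruited when the receptor output crosses its threshold (thresholds linear
  0-50 Hz along the bundle), fires at its own initial rate plus the
  suprathreshold receptor modulation, and emits spikes as a non-homogeneous
  gamma point process (time-rescaling construction).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from . import params as _params

AFFERENT_TYPES = ("Ia", "II", "Ib")


# ---------------------------------------------------------------------------
# muscle spindle
# ---------------------------------------------------------------------------

class MuscleSpindle:
    """Tension-based intrafusal spindle (bag1, bag2, chain).

    Input is the normalised extrafusal fibre length (the spindle lies in
    parallel with the muscle fibres), its velocity and acceleration, plus the
    static and dynamic fusimotor rates.  Outputs are the Ia and II mean
    firing rates in Hz.  Each intrafusal fibre carries a second-order tension
    state whose acceleration balances the non-linear polar-region friction,
    the polar-region spring, the fusimotor bias and the sensory-region
    spring; the afferent potentials read out the sensory-region stretch
    ``T/K_SR``.
    """

    _FIBRES = ("bag1", "bag2", "chain")

    def __init__(self, lf0: float = 1.05):
        raw = _params.load("spindle")
        self._p = [raw[f] for f in self._FIBRES]
        self._s = raw["shared"]
        self.g_primary = raw["gain_primary"]
        self.g_secondary = raw["gain_secondary"]
        s = self._s
        self._lf = lf0
        # start each fibre at its passive polar/sensory spring equilibrium
        self.tension = np.array([
            p["k_sr"] * p["k_pr"] / (p["k_sr"] + p["k_pr"])
            * (lf0 - s["l0_sr"] - s["l0_pr"]) for p in self._p])
        self.tension_dot = np.zeros(3)
        self.f_fus = np.zeros(3)          # fusimotor activations, 0-1
        # flat per-fibre constants for the fast scalar path
        self._const = [
            (p["k_sr"], p["k_pr"], p["mass"], p["beta0"], p["beta_fus"],
             p["gamma_fus"], p["tau"], p["freq"] ** p["p"], p["p"])
            for p in self._p]
        self._fus_decay = {}
        self._check_countdown = 0
        self._a_pow = s["a"]
        self._c_len = s["c_lengthening"]
        self._c_sho = s["c_shortening"]
        self._off_r = s["l0_sr"] + s["r"]
        self._off_pr = s["l0_sr"] + s["l0_pr"]

    # -- fusimotor activation -------------------------------------------------
    def _fus_inf(self, i, gamma):
        p = self._p[i]
        g = max(gamma, 0.0) ** p["p"]
        return g / (g + p["freq"] ** p["p"])

    def _advance_fusimotor(self, gamma_s, gamma_d, dt):
        drives = (gamma_d, gamma_s, gamma_s)   # bag1 dynamic; bag2/chain static
        for i in range(3):
            inf = self._fus_inf(i, drives[i])
            tau = self._p[i]["tau"]
            if tau <= 0.0:
                self.f_fus[i] = inf
            else:
                self.f_fus[i] = inf + (self.f_fus[i] - inf) * math.exp(-dt / tau)

    # -- intrafusal tension dynamics ------------------------------------------
    def _tension_accel(self, i, t, t_dot, lf, vf, acc):
        p, s = self._p[i], self._s
        beta = p["beta0"] + p["beta_fus"] * self.f_fus[i]
        gamma = p["gamma_fus"] * self.f_fus[i]
        k_sr = p["k_sr"]
        v_pr = vf - t_dot / k_sr            # polar-region velocity
        c = s["c_lengthening"] if v_pr > 0 else s["c_shortening"]
        term = (c * beta * math.copysign(abs(v_pr) ** s["a"], v_pr)
                * (lf - s["l0_sr"] - t / k_sr - s["r"])
                + p["k_pr"] * (lf - s["l0_sr"] - t / k_sr - s["l0_pr"])
                + p["mass"] * acc + gamma - t)
        return k_sr / p["mass"] * term

    def step(self, lf: float, vf: float, acc: float, gamma_s: float,
             gamma_d: float, dt: float):
        """Advance one RK4 step; returns (Ia_rate, II_rate) in Hz."""
        if not (lf > 0.0):
            raise ValueError("fibre length must be positive")
        self._check_countdown -= 1
        if self._check_countdown <= 0:
            self._check_countdown = 2000
            if not np.all(np.isfinite(self.tension)):
                raise FloatingPointError("non-finite spindle state")
        self._lf = lf
        a_pow = self._a_pow
        c_len = self._c_len
        c_sho = self._c_sho
        off_r = self._off_r
        off_pr = self._off_pr
        drives = (gamma_d, gamma_s, gamma_s)
        key = round(dt, 12)
        decays = self._fus_decay.get(key)
        if decays is None:
            decays = tuple(math.exp(-dt / c[6]) if c[6] > 0 else 0.0
                           for c in self._const)
            self._fus_decay[key] = decays
        tension = self.tension
        tension_dot = self.tension_dot
        f_fus = self.f_fus
        half = 0.5 * dt
        for i in range(3):
            (k_sr, k_pr, mass, beta0, beta_fus, gamma_fus, tau, freq_p,
             p_pow) = self._const[i]
            # fusimotor activation
            gme = drives[i]
            g = (gme if gme > 0.0 else 0.0) ** p_pow
            inf = g / (g + freq_p)
            e = decays[i]
            f = inf + (f_fus[i] - inf) * e if tau > 0.0 else inf
            f_fus[i] = f
            beta = beta0 + beta_fus * f
            gam = gamma_fus * f
            ksr_m = k_sr / mass
            spring_base = lf - off_pr
            # RK4 on the tension state, friction/spring balance inlined
            cb = beta
            macc = mass * acc
            t0, td0 = tension[i], tension_dot[i]

            v_pr = vf - td0 / k_sr
            c = c_len if v_pr > 0 else c_sho
            av = abs(v_pr) ** a_pow
            fr = av if v_pr > 0 else -av
            x = lf - t0 / k_sr
            k1d = ksr_m * (c * cb * fr * (x - off_r)
                           + k_pr * (spring_base - t0 / k_sr) + macc + gam - t0)
            d2 = td0 + half * k1d
            t_ = t0 + half * td0
            v_pr = vf - d2 / k_sr
            c = c_len if v_pr > 0 else c_sho
            av = abs(v_pr) ** a_pow
            fr = av if v_pr > 0 else -av
            x = lf - t_ / k_sr
            k2d = ksr_m * (c * cb * fr * (x - off_r)
                           + k_pr * (spring_base - t_ / k_sr) + macc + gam - t_)
            d3 = td0 + half * k2d
            t_ = t0 + half * d2
            v_pr = vf - d3 / k_sr
            c = c_len if v_pr > 0 else c_sho
            av = abs(v_pr) ** a_pow
            fr = av if v_pr > 0 else -av
            x = lf - t_ / k_sr
            k3d = ksr_m * (c * cb * fr * (x - off_r)
                           + k_pr * (spring_base - t_ / k_sr) + macc + gam - t_)
            d4 = td0 + dt * k3d
            t_ = t0 + dt * d3
            v_pr = vf - d4 / k_sr
            c = c_len if v_pr > 0 else c_sho
            av = abs(v_pr) ** a_pow
            fr = av if v_pr > 0 else -av
            x = lf - t_ / k_sr
            k4d = ksr_m * (c * cb * fr * (x - off_r)
                           + k_pr * (spring_base - t_ / k_sr) + macc + gam - t_)
            tension[i] = t0 + dt * (td0 + 2 * d2 + 2 * d3 + d4) / 6.0
            tension_dot[i] = td0 + dt * (k1d + 2 * k2d + 2 * k3d + k4d) / 6.0
        return self.rates()

    def _sensory_stretch(self, i):
        s = self._s
        return self.tension[i] / self._const[i][0] - (s["ln_sr"] - s["l0_sr"])

    def rates(self):
        """(Ia_rate, II_rate) in Hz for the current intrafusal state."""
        s = self._s
        off = s["ln_sr"] - s["l0_sr"]
        x1 = self.tension[0] / self._const[0][0] - off
        x2 = self.tension[1] / self._const[1][0] - off
        x3 = self.tension[2] / self._const[2][0] - off
        b1 = self.g_primary * x1
        static = self.g_primary * (x2 + x3)
        if b1 >= static:
            ia = b1 + s["occlusion"] * static
        else:
            ia = static + s["occlusion"] * b1
        w_sr = s["x"] * s["l_secondary"] / s["l0_sr"]
        w_pr = (1.0 - s["x"]) * s["l_secondary"] / s["l0_pr"]
        base = self._lf - s["l0_sr"] - s["ln_pr"]
        ii = self.g_secondary * (
            w_sr * (x2 + x3)
            + w_pr * (2.0 * base - (self.tension[1] + self.tension[2])
                      / self._const[1][0]))
        return (ia if ia > 0.0 else 0.0), (ii if ii > 0.0 else 0.0)

    def settle(self, lf: float, gamma_s: float, gamma_d: float,
               dt: float = 5e-4, duration: float = 3.0):
        """Run to steady state at constant length and fusimotor drive."""
        for _ in range(int(duration / dt)):
            self.step(lf, 0.0, 0.0, gamma_s, gamma_d, dt)
        return self.rates()


class SpindleInputFilter:
    """Mechanical embedding of the spindle in the muscle mass.

    A second-order critically damped low-pass (default time constant 100 ms)
    applied to the extrafusal fibre length before it reaches the intrafusal
    dynamics, supplying a consistent (length, velocity, acceleration)
    triplet.  It represents the compliant attachment of the receptor within
    the muscle tissue: sway-band movements (< 2 Hz) pass unchanged while the
    spurious high-frequency ripple of a down-scaled motor-unit population is
    attenuated, keeping the intrafusal tension dynamics in their
    physiological regime.
    """

    def __init__(self, lf0: float, tau: float = 0.1):
        self.tau = tau
        self.y = lf0
        self.yd = 0.0
        self._prop = {}

    def step(self, lf: float, dt: float):
        key = round(dt, 12)
        pr_ = self._prop.get(key)
        if pr_ is None:
            e = math.exp(-dt / self.tau)
            pr_ = (e * (1.0 + dt / self.tau), e * dt,
                   -e * dt / self.tau ** 2, e * (1.0 - dt / self.tau))
            self._prop[key] = pr_
        a11, a12, a21, a22 = pr_
        dy = self.y - lf
        y = lf + a11 * dy + a12 * self.yd
        self.yd = a21 * dy + a22 * self.yd
        self.y = y
        acc = (lf - y) / self.tau ** 2 - 2.0 * self.yd / self.tau
        return self.y, self.yd, acc


# ---------------------------------------------------------------------------
# Golgi tendon organ
# ---------------------------------------------------------------------------

class GTO:
    """Golgi tendon organ: saturating static nonlinearity of the per-afferent
    tendon-force share followed by the classical rate-sensitive transfer
    function H(s) = K (s+z1)(s+z2)(s+z3) / ((s+p1)(s+p2)(s+p3)) with DC gain
    1, discretised with the bilinear transform at the engine rate."""

    def __init__(self, n_afferents_full: int, dt: float):
        g = _params.load("feedback")["gto"]
        self.rate_max = g["rate_max_hz"]
        self.force_half = g["force_half_n"]
        self.n_afferents_full = n_afferents_full
        zeros = np.array(g["tf_zeros"])
        poles = np.array(g["tf_poles"])
        k = np.prod(poles) / np.prod(zeros)      # DC gain 1
        num = k * np.poly(-zeros)
        den = np.poly(-poles)
        self.b, self.a = scipy.signal.bilinear(num, den, fs=1.0 / dt)
        self._b = tuple(self.b / self.a[0])
        self._a = tuple(self.a / self.a[0])
        self._df2 = None               # direct-form II state (w1, w2, w3)

    def static_rate(self, force_n):
        """Saturating static nonlinearity applied to the per-afferent force
        share (Hz); monotone in force, 0 at 0, bounded by ``rate_max``."""
        f = np.asarray(force_n, dtype=float)
        if np.any(f < 0):
            raise ValueError("tendon force must be non-negative")
        x = f / self.n_afferents_full
        return self.rate_max * x / (x + self.force_half)

    def step(self, force_n: float) -> float:
        """One sample of the per-afferent Ib rate (Hz, clamped at 0);
        direct-form II difference equation, started at DC equilibrium."""
        if force_n < 0:
            raise ValueError("tendon force must be non-negative")
        x = force_n / self.n_afferents_full
        u = self.rate_max * x / (x + self.force_half)
        b0, b1, b2, b3 = self._b
        a0, a1, a2, a3 = self._a
        if self._df2 is None:
            w = u / (1.0 + a1 + a2 + a3)      # DC equilibrium of the lattice
            self._df2 = [w, w, w]
        w1, w2, w3 = self._df2
        w0 = u - a1 * w1 - a2 * w2 - a3 * w3
        y = b0 * w0 + b1 * w1 + b2 * w2 + b3 * w3
        self._df2 = [w0, w1, w2]
        return y if y > 0.0 else 0.0

    def response(self, force_series_n) -> np.ndarray:
        """Per-afferent Ib rate for a whole force record: identical to
        repeated :meth:`step` calls on a fresh filter (offline helper)."""
        u = self.static_rate(np.asarray(force_series_n, dtype=float))
        b0, b1, b2, b3 = self._b
        a0, a1, a2, a3 = self._a
        w1 = w2 = w3 = u[0] / (1.0 + a1 + a2 + a3)
        out = np.empty(len(u))
        for i, ui in enumerate(u):
            w0 = ui - a1 * w1 - a2 * w2 - a3 * w3
            out[i] = b0 * w0 + b1 * w1 + b2 * w2 + b3 * w3
            w1, w2, w3 = w0, w1, w2
        return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# afferent bundles
# ---------------------------------------------------------------------------

@dataclass
class AfferentBundle:
    """A bundle of afferent fibres of one type from one muscle.

    Recruitment thresholds rise linearly 0-50 Hz along the bundle; initial
    rates are Gaussian (5 +- 2.5 Hz, clipped positive); conduction velocities
    vary linearly within the type band.  Spike generation is a per-fibre
    non-homogeneous gamma process of the configured order.
    """
    muscle: str
    afferent_type: str
    n: int
    n_full: int
    thresholds: np.ndarray
    initial_rates: np.ndarray
    velocities: np.ndarray
    gamma_order: int
    path_length: float
    _rng: np.random.Generator = field(repr=False, default=None)
    _integral: np.ndarray = field(repr=False, default=None)
    _target: np.ndarray = field(repr=False, default=None)

    @property
    def delays(self) -> np.ndarray:
        """Conduction delays (s) = path length / conduction velocity."""
        return self.path_length / self.velocities

    def rates(self, receptor_rate: float) -> np.ndarray:
        """Per-fibre mean rates (Hz) for a receptor output: fibre i is active
        iff receptor_rate >= threshold_i, discharging at its initial rate
        plus the suprathreshold receptor modulation."""
        if receptor_rate < 0:
            raise ValueError("receptor rate must be non-negative")
        excess = receptor_rate - self.thresholds
        return np.where(excess >= 0.0, self.initial_rates + excess, 0.0)

    def start_encoding(self, seed):
        self._rng = np.random.default_rng(seed)
        self._integral = np.zeros(self.n)
        k = self.gamma_order
        self._target = self._rng.gamma(k, 1.0 / k, size=self.n)

    def encode_step(self, receptor_rate: float, dt: float) -> np.ndarray:
        """Advance the per-fibre gamma renewal clocks by one step; returns
        the indices of fibres that spiked."""
        self._integral += self.rates(receptor_rate) * dt
        fired = np.nonzero(self._integral >= self._target)[0]
        if len(fired):
            k = self.gamma_order
            self._integral[fired] -= self._target[fired]
            self._target[fired] = self._rng.gamma(k, 1.0 / k, size=len(fired))
        return fired


def build_bundle(muscle: str, afferent_type: str, seed,
                 scale: float = 1.0) -> AfferentBundle:
    """Construct one afferent bundle from the versioned feedback tables,
    optionally at reduced scale (counts rounded, proportions preserved)."""
    fb = _params.load("feedback")
    n_full = fb["afferent_counts"][muscle][afferent_type]
    n = max(1, int(round(n_full * scale)))
    rec = fb["recruitment"]
    rng = np.random.default_rng(seed)
    lo, hi = rec["threshold_range_hz"]
    thresholds = np.linspace(lo, hi, n, endpoint=False) if n > 1 \
        else np.array([lo])
    r0 = rng.normal(rec["initial_rate_mean_hz"], rec["initial_rate_sd_hz"],
                    size=n)
    v_lo, v_hi = fb["conduction_velocity"][afferent_type]
    return AfferentBundle(
        muscle=muscle, afferent_type=afferent_type, n=n, n_full=n_full,
        thresholds=thresholds,
        initial_rates=np.clip(r0, 0.5, None),
        velocities=np.linspace(v_lo, v_hi, n) if n > 1
        else np.array([0.5 * (v_lo + v_hi)]),
        gamma_order=rec["gamma_order"],
        path_length=fb["path_length_m"],
    )


def encode_spikes(rate_fn, duration: float, dt: float, gamma_order: int,
                  seed):
    """Offline gamma-process encoder for a single fibre.

    ``rate_fn`` maps time (s) to intensity (Hz); returns (spike_times, isis).
    Implements the time-rescaling construction: successive rescaled waiting
    times are gamma(order, 1/order), so the intensity is recovered in the
    mean and the ISI CV tends to 1/sqrt(order) at constant rate.
    """
    rng = np.random.default_rng(seed)
    k = gamma_order
    times = []
    integral = 0.0
    target = rng.gamma(k, 1.0 / k)
    n_steps = int(round(duration / dt))
    t = 0.0
    for _ in range(n_steps):
        r = rate_fn(t)
        if r < 0:
            raise ValueError("negative intensity")
        integral += r * dt
        if integral >= target:
            times.append(t + dt)
            integral -= target
            target = rng.gamma(k, 1.0 / k)
        t += dt
    times = np.asarray(times)
    return times, np.diff(times)


# ---------------------------------------------------------------------------
# fusimotor drive
# ---------------------------------------------------------------------------

class FusimotorDrive:
    """Gaussian stochastic fusimotor rate with variance 3% of the mean.

    Realised as an Ornstein-Uhlenbeck process (correlation time ``tau``) so
    the fluctuations are band-limited; clipped at zero with clipping events
    counted.  ``variance_frac = 0`` gives a constant drive.
    """

    def __init__(self, mean: float, seed, variance_frac: float = 0.03,
                 tau: float = 0.1):
        if mean <= 0:
            raise ValueError("fusimotor mean must be positive")
        self.mean = mean
        self.sd = math.sqrt(variance_frac * mean)
        self.tau = tau
        self._rng = np.random.default_rng(seed)
        self.value = mean if self.sd == 0 else \
            float(self._rng.normal(mean, self.sd))
        self.n_clipped = 0

    def step(self, dt: float) -> float:
        if self.sd == 0.0:
            return self.mean
        e = math.exp(-dt / self.tau)
        self.value = (self.mean + (self.value - self.mean) * e
                      + self.sd * math.sqrt(1.0 - e * e)
                      * self._rng.standard_normal())
        if self.value < 0.0:
            self.n_clipped += 1
            return 0.0
        return self.value

    def series(self, duration: float, dt: float) -> np.ndarray:
        n = int(round(duration / dt))
        return np.array([self.step(dt) for _ in range(n)])


def fusimotor_drive(mean_static: float, mean_dynamic: float, duration: float,
                    seed, dt: float = 5e-5, variance_frac: float = 0.03):
    """Sample paths (gamma_static(t), gamma_dynamic(t)) of the fusimotor
    drives over ``duration`` at the engine step."""
    ss = np.random.SeedSequence(seed).spawn(2)
    gs = FusimotorDrive(mean_static, ss[0], variance_frac).series(duration, dt)
    gd = FusimotorDrive(mean_dynamic, ss[1], variance_frac).series(duration, dt)
    return gs, gd
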