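"""Hill-type musculotendon mechanics for the ankle muscles (SO, MG, LG, TA).

Each musculotendon unit (MTU) consists of a non-linear series-elastic tendon,
parallel visco-elastic fibre elements, two contractile elements (slow and fast
fibre populations driven by the motor-unit activation signals), a pinnation
angle that preserves muscle thickness, and a small fibre mass that makes the
fibre state an explicit second-order system.  All fibre quantities are
normalised: lengths by the optimal fibre length ``L0``, forces by the maximum
isometric force ``F0``, velocities in ``L0/s`` with positive velocity meaning
fibre stretch.  Tendon length is normalised by the reference length ``LT0`` at
which the tendon transmits ``F0``.

MTU length and moment arm about the ankle are fourth-order polynomials in the
ankle angle (degrees, dorsiflexion/forward lean positive); plantar-flexor
moment arms are negative so plantar-flexion torque is negative.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import params as _params

MUSCLES = ("SO", "MG", "LG", "TA")
TS_MUSCLES = ("SO", "MG", "LG")

DEG = math.pi / 180.0


class GeometryError(ValueError):
    """Raised when the constant-thickness pinnation rule becomes impossible."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MTUParams:
    name: str
    group: str                  # "TS" (plantar flexor) or "TA" (dorsiflexor)
    f0: float                   # maximum isometric force, N
    l0: float                   # optimal fibre length, m
    mass: float                 # muscle mass, kg
    alpha0: float               # pinnation at optimal fibre length, rad
    lt0: float                  # tendon length at which F_T = F0, m
    k_pe: float                 # parallel elastic exponential shape
    b_pe: float                 # parallel viscosity, F0 per (L0/s)
    strain_pe: float            # fibre strain at which F_PE = F0
    ct: float                   # tendon linear-region stiffness (F0 per LT0)
    kt: float                   # tendon toe-region curvature constant
    lr: float                   # normalised tendon length at toe/linear onset
    length_poly: tuple[float, ...]      # cm, cm/deg, ...
    moment_arm_poly: tuple[float, ...]  # cm, cm/deg, ...

    @property
    def mass_norm(self) -> float:
        """Fibre mass in normalised units (F0, L0): M * L0 / F0, s^2."""
        return self.mass * self.l0 / self.f0


def load_mtu_params() -> dict[str, MTUParams]:
    raw = _params.load("muscles")
    shared = raw["shared"]
    out = {}
    for name, m in raw["muscles"].items():
        out[name] = MTUParams(
            name=name,
            group=m["group"],
            f0=m["f0_n"],
            l0=m["l0_cm"] / 100.0,
            mass=m["mass_kg"],
            alpha0=m["alpha0_deg"] * DEG,
            lt0=m["lt0_cm"] / 100.0,
            k_pe=shared["k_pe"],
            b_pe=shared["b_pe"],
            strain_pe=shared["strain_pe"],
            ct=shared["tendon_ct"],
            kt=shared["tendon_kt"],
            lr=shared["tendon_lr"],
            length_poly=tuple(m["length_poly"]),
            moment_arm_poly=tuple(m["moment_arm_poly"]),
        )
    return out


# ---------------------------------------------------------------------------
# musculoskeletal geometry
# ---------------------------------------------------------------------------

def _polyval(coeffs, x):
    acc = 0.0
    for c in reversed(coeffs):
        acc = acc * x + c
    return acc


def mtu_length(theta_deg: float, p: MTUParams) -> float:
    """MTU length (m) at ankle angle ``theta_deg``."""
    return _polyval(p.length_poly, theta_deg) / 100.0


def moment_arm(theta_deg: float, p: MTUParams) -> float:
    """Signed moment arm (m) about the ankle at ``theta_deg``."""
    return _polyval(p.moment_arm_poly, theta_deg) / 100.0


def kinematics(theta_deg: float, mtus: dict[str, MTUParams]):
    """MTU lengths and moment arms (m) for every muscle at one ankle angle."""
    lengths = {n: mtu_length(theta_deg, p) for n, p in mtus.items()}
    arms = {n: moment_arm(theta_deg, p) for n, p in mtus.items()}
    return lengths, arms


def muscle_torque(theta_deg: float, tendon_forces_n: dict[str, float],
                  mtus: dict[str, MTUParams]) -> float:
    """Net muscular ankle torque (Nm) for both legs.

    Torque = 2 * sum(moment_arm * tendon force); the factor two lumps the two
    legs, assumed identical.  Dorsiflexion (TA) torque is positive,
    plantar flexion negative.
    """
    t = 0.0
    for name, f in tendon_forces_n.items():
        if f < 0:
            raise ValueError(f"negative tendon force for {name}")
        t += moment_arm(theta_deg, mtus[name]) * f
    return 2.0 * t


# ---------------------------------------------------------------------------
# passive elements
# ---------------------------------------------------------------------------

def tendon_force(lt_norm, p: MTUParams):
    """Normalised tendon force: exponential toe region blending into a linear
    region of stiffness ``ct`` above ``lr`` (softplus form); ~0 when slack."""
    x = (np.asarray(lt_norm, dtype=float) - p.lr) / p.kt
    return p.ct * p.kt * np.logaddexp(0.0, x)


def parallel_passive_force(lf_norm, vf_norm, p: MTUParams):
    """Normalised parallel passive force: exponential-strain elastic part plus
    linear viscosity ``b_pe * V``."""
    lf = np.asarray(lf_norm, dtype=float)
    if np.any(lf <= 0):
        raise ValueError("non-positive fibre length")
    elastic = np.expm1(p.k_pe * (lf - 1.0) / p.strain_pe) / math.expm1(p.k_pe)
    return elastic + p.b_pe * np.asarray(vf_norm, dtype=float)


def pinnation(lf_norm: float, p: MTUParams) -> float:
    """Pinnation angle (rad) from the constant muscle-thickness rule
    ``sin(alpha) * L_f = sin(alpha0) * L0``."""
    s = math.sin(p.alpha0) / lf_norm
    if s >= 1.0:
        raise GeometryError(
            f"{p.name}: fibre length {lf_norm:.3f} L0 requires sin(alpha) = "
            f"{s:.3f} >= 1")
    return math.asin(s)


def fibre_geometry(l_mtu: float, lf_norm: float, p: MTUParams):
    """Tendon length (normalised by LT0) and pinnation for a given MTU length
    and fibre length."""
    alpha = pinnation(lf_norm, p)
    lt_norm = (l_mtu - lf_norm * p.l0 * math.cos(alpha)) / p.lt0
    return lt_norm, alpha


# ---------------------------------------------------------------------------
# contractile elements
# ---------------------------------------------------------------------------

_CURVES = None


def _curves():
    global _CURVES
    if _CURVES is None:
        _CURVES = _params.load("curves")
    return _CURVES


def force_length(lf_norm, kind: str):
    c = _curves()[kind]["fl"]
    lf = np.asarray(lf_norm, dtype=float)
    return np.exp(-np.abs((lf ** c["beta"] - 1.0) / c["omega"]) ** c["rho"])


def force_velocity(lf_norm, vf_norm, kind: str):
    """Force-velocity factor; continuous and equal to 1 at V = 0, above 1 for
    lengthening (eccentric) and decreasing toward 0 for shortening."""
    c = _curves()[kind]["fv"]
    lf = np.asarray(lf_norm, dtype=float)
    v = np.asarray(vf_norm, dtype=float)
    shortening = (c["vmax"] - v) / (c["vmax"] + v * (c["cv0"] + c["cv1"] * lf))
    lengthening = (c["bv"] - v * (c["av0"] + c["av1"] * lf + c["av2"] * lf ** 2)) \
        / (c["bv"] + v)
    out = np.where(v <= 0.0, shortening, lengthening)
    return np.clip(out, 0.0, None)


def contractile_force(a_slow, a_fast, lf_norm, vf_norm):
    """Normalised contractile force: sum of slow and fast contributions, each
    activation x FL(L) x FV(L, V)."""
    a_slow = np.asarray(a_slow, dtype=float)
    a_fast = np.asarray(a_fast, dtype=float)
    if np.any(a_slow < 0) or np.any(a_slow > 1) or np.any(a_fast < 0) \
            or np.any(a_fast > 1):
        raise ValueError("activations must lie in [0, 1]")
    return (a_slow * force_length(lf_norm, "slow")
            * force_velocity(lf_norm, vf_norm, "slow")
            + a_fast * force_length(lf_norm, "fast")
            * force_velocity(lf_norm, vf_norm, "fast"))


# ---------------------------------------------------------------------------
# fibre dynamics
# ---------------------------------------------------------------------------

def fibre_acceleration(lf_norm: float, vf_norm: float, l_mtu: float,
                       a_slow: float, a_fast: float, p: MTUParams) -> float:
    """Fibre acceleration (L0/s^2) from the force balance along the fibre:
    tendon load resolved through the pinnation angle versus contractile plus
    parallel passive forces, acting on the fibre mass."""
    lt_norm, alpha = fibre_geometry(l_mtu, lf_norm, p)
    f_t = float(tendon_force(lt_norm, p))
    f_ce = float(contractile_force(a_slow, a_fast, lf_norm, vf_norm))
    f_pe = float(parallel_passive_force(lf_norm, vf_norm, p))
    return (f_t / math.cos(alpha) - f_ce - f_pe) / p.mass_norm


def make_fibre_accel(p: MTUParams):
    """Return a fast scalar closure ``accel(lf, vf, l_mtu, a_slow, a_fast) ->
    (fibre acceleration, normalised tendon force)``.

    Same physics as :func:`fibre_acceleration`, with the per-muscle constants
    bound to local floats; used by the simulation engine's inner loop (a
    conformance test pins the two paths together).
    """
    sin_a0 = math.sin(p.alpha0)
    l0, lt0 = p.l0, p.lt0
    ct, kt, lr = p.ct, p.kt, p.lr
    k_pe, eps, b_pe = p.k_pe, p.strain_pe, p.b_pe
    pe_denom = math.expm1(p.k_pe)
    mass_norm = p.mass_norm
    cs = _curves()
    s_beta = cs["slow"]["fl"]["beta"]
    s_omega = cs["slow"]["fl"]["omega"]
    s_rho = cs["slow"]["fl"]["rho"]
    s_vmax = cs["slow"]["fv"]["vmax"]
    s_cv0 = cs["slow"]["fv"]["cv0"]
    s_cv1 = cs["slow"]["fv"]["cv1"]
    s_av0 = cs["slow"]["fv"]["av0"]
    s_av1 = cs["slow"]["fv"]["av1"]
    s_av2 = cs["slow"]["fv"]["av2"]
    s_bv = cs["slow"]["fv"]["bv"]
    f_beta = cs["fast"]["fl"]["beta"]
    f_omega = cs["fast"]["fl"]["omega"]
    f_rho = cs["fast"]["fl"]["rho"]
    f_vmax = cs["fast"]["fv"]["vmax"]
    f_cv0 = cs["fast"]["fv"]["cv0"]
    f_cv1 = cs["fast"]["fv"]["cv1"]
    f_av0 = cs["fast"]["fv"]["av0"]
    f_av1 = cs["fast"]["fv"]["av1"]
    f_av2 = cs["fast"]["fv"]["av2"]
    f_bv = cs["fast"]["fv"]["bv"]
    name = p.name
    exp, log1p, sqrt = math.exp, math.log1p, math.sqrt

    def accel(lf, vf, l_mtu, a_slow, a_fast):
        s = sin_a0 / lf
        if s >= 1.0:
            raise GeometryError(f"{name}: sin(alpha) >= 1 at L_f = {lf:.3f}")
        cos_a = sqrt(1.0 - s * s)
        x = ((l_mtu - lf * l0 * cos_a) / lt0 - lr) / kt
        if x > 0.0:
            f_t = ct * kt * (x + log1p(exp(-x)))
        else:
            f_t = ct * kt * log1p(exp(x))
        f_pe = (exp(k_pe * (lf - 1.0) / eps) - 1.0) / pe_denom + b_pe * vf
        f_ce = 0.0
        if a_slow > 0.0:
            flv = exp(-abs((lf ** s_beta - 1.0) / s_omega) ** s_rho)
            if vf <= 0.0:
                fvv = (s_vmax - vf) / (s_vmax + vf * (s_cv0 + s_cv1 * lf))
            else:
                fvv = (s_bv - vf * (s_av0 + s_av1 * lf
                                    + s_av2 * lf * lf)) / (s_bv + vf)
            f_ce += a_slow * flv * (fvv if fvv > 0.0 else 0.0)
        if a_fast > 0.0:
            flv = exp(-abs((lf ** f_beta - 1.0) / f_omega) ** f_rho)
            if vf <= 0.0:
                fvv = (f_vmax - vf) / (f_vmax + vf * (f_cv0 + f_cv1 * lf))
            else:
                fvv = (f_bv - vf * (f_av0 + f_av1 * lf
                                    + f_av2 * lf * lf)) / (f_bv + vf)
            f_ce += a_fast * flv * (fvv if fvv > 0.0 else 0.0)
        return (f_t / cos_a - f_ce - f_pe) / mass_norm, f_t

    return accel


@dataclass
class MTUState:
    lf_norm: float
    vf_norm: float = 0.0
    lt_norm: float = 0.0
    alpha: float = 0.0
    f_tendon_norm: float = 0.0
    acc: float = 0.0            # fibre acceleration, L0/s^2


def fibre_dynamics_step(state: MTUState, l_mtu: float, a_slow: float,
                        a_fast: float, p: MTUParams, dt: float) -> MTUState:
    """Advance (L_f, V_f) one RK4 step with MTU length and activations held
    constant over the step; refresh the derived geometry/forces."""
    def deriv(lf, vf):
        return vf, fibre_acceleration(lf, vf, l_mtu, a_slow, a_fast, p)

    lf, vf = state.lf_norm, state.vf_norm
    k1l, k1v = deriv(lf, vf)
    k2l, k2v = deriv(lf + 0.5 * dt * k1l, vf + 0.5 * dt * k1v)
    k3l, k3v = deriv(lf + 0.5 * dt * k2l, vf + 0.5 * dt * k2v)
    k4l, k4v = deriv(lf + dt * k3l, vf + dt * k3v)
    lf += dt * (k1l + 2 * k2l + 2 * k3l + k4l) / 6.0
    vf += dt * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0
    if not (math.isfinite(lf) and math.isfinite(vf)):
        raise FloatingPointError(f"{p.name}: non-finite fibre state")
    lt_norm, alpha = fibre_geometry(l_mtu, lf, p)
    return MTUState(
        lf_norm=lf, vf_norm=vf, lt_norm=lt_norm, alpha=alpha,
        f_tendon_norm=float(tendon_force(lt_norm, p)),
        acc=fibre_acceleration(lf, vf, l_mtu, a_slow, a_fast, p),
    )


def passive_equilibrium_fibre_length(l_mtu: float, p: MTUParams,
                                     tol: float = 1e-10) -> float:
    """Fibre length at which the passive elastic force balances the tendon
    force for a fixed MTU length (bisection; used to initialise runs)."""
    def residual(lf):
        return fibre_acceleration(lf, 0.0, l_mtu, 0.0, 0.0, p)

    lo, hi = math.sin(p.alpha0) + 1e-3, 2.0
    # residual > 0 means the tendon wins and the fibre would stretch
    if residual(hi) > 0:
        return hi
    while residual(lo) < 0:
        lo += 0.02
        if lo >= hi:
            raise GeometryError(f"{p.name}: no passive equilibrium")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if residual(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# motor-unit activation dynamics
# ---------------------------------------------------------------------------

def saturate(u, c):
    """Smooth saturation of the filtered activation signal: monotone,
    zero at zero, asymptoting to 1."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ValueError("filtered activation must be non-negative")
    return np.tanh(np.asarray(c, dtype=float) * u)


@dataclass
class ActivationPool:
    """Per-motor-unit activation channels of one muscle.

    Each motor unit owns a second-order critically damped filter (time
    constant ``tau``) driven by its (conducted) spike train, followed by the
    smooth saturation whose shape ``c`` is tuned so that the unit reaches its
    tetanic plateau at its tetanic firing rate.  The slow contractile element
    receives the sum over S-type units, the fast one the sum over FR+FF,
    both normalised by the total tetanic amplitude of the muscle.
    """
    tau: np.ndarray              # s, per MU
    c: np.ndarray                # saturation shape, per MU
    amplitude: np.ndarray        # tetanic amplitude, per MU
    is_slow: np.ndarray          # bool, per MU
    x1: np.ndarray = field(default=None)  # filter states
    x2: np.ndarray = field(default=None)
    _prop: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        n = len(self.tau)
        if self.x1 is None:
            self.x1 = np.zeros(n)
        if self.x2 is None:
            self.x2 = np.zeros(n)
        self.total_amplitude = float(np.sum(self.amplitude))

    @property
    def n_units(self) -> int:
        return len(self.tau)

    def _propagator(self, dt):
        key = round(dt, 12)
        if key not in self._prop:
            e = np.exp(-dt / self.tau)
            self._prop[key] = (
                e * (1.0 + dt / self.tau),          # a11
                e * dt,                             # a12
                -e * dt / self.tau ** 2,            # a21
                e * (1.0 - dt / self.tau),          # a22
            )
        return self._prop[key]

    def add_spikes(self, unit_indices):
        """Register spike arrivals (unit-area impulses) at the current step."""
        if len(unit_indices):
            idx = np.asarray(unit_indices, dtype=np.intp)
            if idx.max() >= self.n_units:
                raise KeyError("unknown motor-unit id")
            np.add.at(self.x2, idx, 1.0 / self.tau[idx] ** 2)

    def step(self, dt: float):
        a11, a12, a21, a22 = self._propagator(dt)
        x1 = a11 * self.x1 + a12 * self.x2
        self.x2 = a21 * self.x1 + a22 * self.x2
        self.x1 = x1

    def activations(self):
        """(a_slow, a_fast) of the muscle for the current filter state."""
        a = self.amplitude * saturate(np.maximum(self.x1, 0.0), self.c)
        a_slow = float(np.sum(a[self.is_slow])) / self.total_amplitude
        a_fast = float(np.sum(a[~self.is_slow])) / self.total_amplitude
        return a_slow, a_fast


def _band(values, n):
    """Linear interpolation of a [first, last] band across n units."""
    lo, hi = values
    if n == 1:
        return np.array([0.5 * (lo + hi)])
    return np.linspace(lo, hi, n)


def build_activation_pool(muscle: str, counts: dict[str, int] | None = None) \
        -> ActivationPool:
    """Construct the activation channels of one muscle from the versioned
    motor-unit distributions (optionally with reduced-scale counts)."""
    mu = _params.load("motorunits")
    if counts is None:
        counts = mu["composition"][muscle]
    act = mu["activation"]
    taus, rates, slow = [], [], []
    for t in ("S", "FR", "FF"):
        n = counts[t]
        taus.append(_band(act["tau_act_ms"][t], n) / 1000.0)
        rates.append(_band(act["tetanic_rate_hz"][t], n))
        slow.append(np.full(n, t == "S"))
    tau = np.concatenate(taus)
    f_tet = np.concatenate(rates)
    is_slow = np.concatenate(slow)
    n_total = len(tau)
    rng_factor = act["amplitude_range_factor"]
    amplitude = np.exp(np.linspace(0.0, math.log(rng_factor), n_total))
    c = np.arctanh(act["saturation_at_tetanic"]) / f_tet
    return ActivationPool(tau=tau, c=c, amplitude=amplitude, is_slow=is_slow)


def activation_from_spikes(spike_times: np.ndarray, unit_ids: np.ndarray,
                           pool: ActivationPool, duration: float, dt: float):
    """Offline helper: run the activation channels over a finished spike list
    and return (t, a_slow, a_fast) sampled every ``dt``."""
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps) * dt
    a_slow = np.empty(n_steps)
    a_fast = np.empty(n_steps)
    order = np.argsort(spike_times, kind="stable")
    times = np.asarray(spike_times)[order]
    ids = np.asarray(unit_ids)[order]
    k = 0
    for i in range(n_steps):
        j = k
        while j < len(times) and times[j] < t[i] + dt:
            j += 1
        pool.add_spikes(ids[k:j])
        k = j
        pool.step(dt)
        a_slow[i], a_fast[i] = pool.activations()
    return t, a_slow, a_fast
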