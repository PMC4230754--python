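"""Single-link inverted-pendulum biomechanics of quiet standing.

The body (minus the feet) is a point mass ``m`` at height ``h`` above the
ankle, rotating about a fixed ankle pivot; forward lean is positive.  The
restoring ankle torque combines the muscular torque (dorsiflexion positive)
with a passive visco-elastic joint impedance.  Centre-of-mass (COM) and
centre-of-pressure (COP) anteroposterior displacements are the standard
posturographic observables; in static equilibrium they coincide.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .musculotendon import (MTUParams, load_mtu_params,
                            passive_equilibrium_fibre_length, make_fibre_accel)

GRAVITY = 9.81


@dataclass(frozen=True)
class BodyParams:
    mass: float = 60.0          # kg, body minus feet
    height: float = 0.85        # m, COM above the ankle
    gravity: float = GRAVITY
    k_passive_frac: float = 0.65   # added passive stiffness, fraction of m*g*h
    b_passive: float = 5.81        # Nm*s/rad
    theta_ref: float | None = None  # rad; passive-spring neutral posture
    #   (None -> 0; the standing protocol re-centres it at the initial lean)
    fall_threshold: float = math.radians(25.0)

    @property
    def inertia(self) -> float:
        """Point-mass body inertia about the ankle, kg*m^2."""
        return self.mass * self.height ** 2

    @property
    def k_passive(self) -> float:
        return self.k_passive_frac * critical_stiffness(self)


def critical_stiffness(p: BodyParams) -> float:
    """Gravitational load stiffness m*g*h (Nm/rad): the ankle stiffness that
    must be exceeded for passive stability of the inverted pendulum."""
    return p.mass * p.gravity * p.height


@dataclass
class PendulumState:
    theta: float = 0.0          # rad, forward lean positive
    omega: float = 0.0          # rad/s
    torque_ankle: float = 0.0   # restoring ankle torque, Nm
    fell: bool = False


def ankle_torque(theta: float, omega: float, t_muscles: float,
                 p: BodyParams) -> float:
    """Total restoring ankle torque: passive visco-elastic torque minus the
    muscular torque (muscular plantar flexion, negative, restores a forward
    lean)."""
    ref = p.theta_ref if p.theta_ref is not None else 0.0
    return p.k_passive * (theta - ref) + p.b_passive * omega - t_muscles


def pendulum_step(state: PendulumState, t_muscles: float, p: BodyParams,
                  dt: float) -> PendulumState:
    """Advance the pendulum one RK4 step with the muscular torque held
    constant; flags (does not raise) a fall beyond the configured lean."""
    inertia = p.inertia
    mgh = critical_stiffness(p)

    def acc(theta, omega):
        return (mgh * math.sin(theta)
                - ankle_torque(theta, omega, t_muscles, p)) / inertia

    th, om = state.theta, state.omega
    k1t, k1o = om, acc(th, om)
    k2t, k2o = om + 0.5 * dt * k1o, acc(th + 0.5 * dt * k1t, om + 0.5 * dt * k1o)
    k3t, k3o = om + 0.5 * dt * k2o, acc(th + 0.5 * dt * k2t, om + 0.5 * dt * k2o)
    k4t, k4o = om + dt * k3o, acc(th + dt * k3t, om + dt * k3o)
    th += dt * (k1t + 2 * k2t + 2 * k3t + k4t) / 6.0
    om += dt * (k1o + 2 * k2o + 2 * k3o + k4o) / 6.0
    if not (math.isfinite(th) and math.isfinite(om)):
        raise FloatingPointError("non-finite pendulum state")
    return PendulumState(
        theta=th, omega=om,
        torque_ankle=ankle_torque(th, om, t_muscles, p),
        fell=state.fell or abs(th) > p.fall_threshold,
    )


def observables(state: PendulumState, p: BodyParams):
    """(x_COM, x_COP) in metres.  COM follows the pendulum geometry; COP from
    the ankle-torque/ground-reaction balance, so the two coincide in
    statics."""
    x_com = p.height * math.sin(state.theta)
    x_cop = state.torque_ankle / (p.mass * p.gravity)
    return x_com, x_cop


# ---------------------------------------------------------------------------
# passive ankle stiffness of the Hill-type MTUs
# ---------------------------------------------------------------------------

def band_limited_angle_noise(n_steps: int, dt: float, sigma_rad: float,
                             cutoff_hz: float, rng: np.random.Generator,
                             mean_rad: float = 0.0) -> np.ndarray:
    """Gaussian stochastic ankle-angle trajectory: lowpass-filtered white
    noise rescaled to the requested standard deviation."""
    if sigma_rad <= 0:
        raise ValueError("angle excitation requires positive variance")
    white = rng.standard_normal(n_steps)
    sos = scipy.signal.butter(4, cutoff_hz, fs=1.0 / dt, output="sos")
    x = scipy.signal.sosfilt(sos, white)
    x *= sigma_rad / np.std(x)
    return mean_rad + x


def passive_muscle_torque_series(theta_rad: np.ndarray, dt: float,
                                 mtus: dict[str, MTUParams] | None = None
                                 ) -> np.ndarray:
    """Simulate the passive (zero-activation) Hill MTUs under an imposed
    ankle-angle trajectory and return the muscular torque series (Nm).

    Fibre states start from the passive equilibrium at the initial angle and
    are integrated by RK4 on the common clock.
    """
    if mtus is None:
        mtus = load_mtu_params()
    theta_deg = np.degrees(theta_rad)
    n = len(theta_deg)
    torque = np.zeros(n)
    for p in mtus.values():
        l_series = np.polynomial.polynomial.polyval(
            theta_deg, np.array(p.length_poly)) / 100.0
        arm_series = np.polynomial.polynomial.polyval(
            theta_deg, np.array(p.moment_arm_poly)) / 100.0
        lf = passive_equilibrium_fibre_length(l_series[0], p)
        vf = 0.0
        f_t_series = np.empty(n)
        accel = make_fibre_accel(p)
        half = 0.5 * dt
        for i in range(n):
            l_mtu = l_series[i]
            k1v, f_t = accel(lf, vf, l_mtu, 0.0, 0.0)
            v2 = vf + half * k1v
            k2v, _ = accel(lf + half * vf, v2, l_mtu, 0.0, 0.0)
            v3 = vf + half * k2v
            k3v, _ = accel(lf + half * v2, v3, l_mtu, 0.0, 0.0)
            v4 = vf + dt * k3v
            k4v, _ = accel(lf + dt * v3, v4, l_mtu, 0.0, 0.0)
            lf += dt * (vf + 2 * v2 + 2 * v3 + v4) / 6.0
            vf += dt * (k1v + 2 * k2v + 2 * k3v + k4v) / 6.0
            f_t_series[i] = f_t
        torque += 2.0 * arm_series * f_t_series * p.f0
    return torque


def passive_impedance(theta_rad: np.ndarray, torque: np.ndarray, fs: float,
                      f_lo: float = 0.0, f_hi: float = 1.0,
                      nperseg_s: float = 20.0):
    """Cross-spectral ankle impedance estimate |S_xy/S_xx| between an imposed
    angle and the resulting restoring torque, averaged over [f_lo, f_hi] Hz."""
    nperseg = int(nperseg_s * fs)
    if nperseg > len(theta_rad):
        raise ValueError("record too short for the requested spectral "
                         "resolution")
    if np.std(theta_rad) == 0:
        raise ValueError("angle excitation has zero variance")
    f, pxx = scipy.signal.welch(theta_rad, fs=fs, nperseg=nperseg)
    _, pxy = scipy.signal.csd(theta_rad, torque, fs=fs, nperseg=nperseg)
    band = (f > f_lo) & (f <= f_hi)
    z = np.abs(pxy[band] / pxx[band])
    return float(np.mean(z))


def estimate_passive_mtu_stiffness(seed: int, duration: float = 60.0,
                                   dt: float = 5e-5, sigma_deg: float = 1.0,
                                   cutoff_hz: float = 5.0,
                                   mean_deg: float = 0.0,
                                   body: BodyParams | None = None,
                                   plant=None) -> float:
    """Controller-off estimate of the ankle stiffness contributed by the
    passive Hill-type MTUs, as a fraction of the critical stiffness.

    The ankle angle is driven by a Gaussian stochastic trajectory, the
    restoring muscle torque is recorded, and the mean cross-spectral impedance
    magnitude over 0-1 Hz is divided by m*g*h.  ``plant`` may substitute a
    different angle->torque map (e.g. a linear spring) to validate the
    estimator.
    """
    if body is None:
        body = BodyParams()
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    theta = band_limited_angle_noise(n, dt, math.radians(sigma_deg), cutoff_hz,
                                     rng, mean_rad=math.radians(mean_deg))
    if plant is None:
        torque = passive_muscle_torque_series(theta, dt)
    else:
        torque = plant(theta, dt)
    # restoring torque: muscular plantar flexion opposes a forward lean
    fs_target = 200.0
    dec = max(1, int(round(1.0 / (fs_target * dt))))
    z = passive_impedance(theta[::dec], -torque[::dec], fs=1.0 / (dt * dec))
    return z / critical_stiffness(body)
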