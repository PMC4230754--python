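"""Muscle spindle, Golgi tendon organ, afferent recruitment and encoding."""
import math

import numpy as np
import pytest
import scipy.signal
import scipy.stats

from stancesim import proprioception as pr


# ---------------------------------------------------------------------------
# muscle spindle
# ---------------------------------------------------------------------------

def test_spindle_settles_at_constant_input():
    sp = pr.MuscleSpindle(lf0=1.05)
    ia1, ii1 = sp.settle(1.05, 32.0, 33.8, duration=3.0)
    ia2, ii2 = sp.settle(1.05, 32.0, 33.8, duration=0.5)
    assert ia2 == pytest.approx(ia1, abs=0.5)
    assert ii2 == pytest.approx(ii1, abs=0.5)
    assert ia1 >= 0 and ii1 >= 0


def _ramp_response(gamma_s, gamma_d, v_ramp=0.05):
    sp = pr.MuscleSpindle(lf0=1.0)
    sp.settle(1.0, gamma_s, gamma_d)
    dt = 5e-4
    lf = 1.0
    ia, ii = [], []
    for i in range(int(3.0 / dt)):
        vf = v_ramp if i * dt < 1.0 else 0.0
        lf = min(1.0 + v_ramp, lf + vf * dt)
        a, b = sp.step(lf, vf, 0.0, gamma_s, gamma_d, dt)
        ia.append(a)
        ii.append(b)
    ia, ii = np.array(ia), np.array(ii)
    n_ramp = int(1.0 / dt)
    return (ia[:n_ramp].max(), ia[-200:].mean(),
            ii[:n_ramp].max(), ii[-200:].mean())


def test_primary_dynamic_overshoot_exceeds_secondary():
    ia_pk, ia_ss, ii_pk, ii_ss = _ramp_response(32.0, 33.8)
    assert ia_pk > ia_ss * 1.2              # clear dynamic overshoot
    assert (ia_pk / max(ia_ss, 1e-9)) > (ii_pk / max(ii_ss, 1e-9))


def test_dynamic_fusimotor_raises_ramp_response_only():
    lo = _ramp_response(32.0, 5.0)
    hi = _ramp_response(32.0, 60.0)
    assert hi[0] - hi[1] > lo[0] - lo[1]    # bigger dynamic response
    assert hi[3] == pytest.approx(lo[3], rel=0.25)   # II plateau unchanged


def test_spindle_input_validation():
    sp = pr.MuscleSpindle()
    with pytest.raises(ValueError):
        sp.step(-0.1, 0.0, 0.0, 32.0, 33.8, 5e-4)


def test_spindle_input_filter_band():
    filt = pr.SpindleInputFilter(1.0, tau=0.045)
    dt = 5e-4
    # slow sinusoid passes, fast ripple is attenuated
    for f_hz, min_gain, max_gain in ((0.3, 0.9, 1.05), (20.0, 0.0, 0.15)):
        filt = pr.SpindleInputFilter(1.0, tau=0.045)
        ys = []
        for i in range(int(8.0 / f_hz / dt)):
            y, yd, acc = filt.step(
                1.0 + 0.01 * math.sin(2 * math.pi * f_hz * i * dt), dt)
            ys.append(y)
        amp = (max(ys[len(ys) // 2:]) - min(ys[len(ys) // 2:])) / 0.02
        assert min_gain <= amp <= max_gain


# ---------------------------------------------------------------------------
# Golgi tendon organ
# ---------------------------------------------------------------------------

def test_gto_static_properties():
    g = pr.GTO(300, 5e-5)
    assert float(g.static_rate(0.0)) == 0.0
    forces = np.linspace(0, 2000, 50)
    rates = g.static_rate(forces)
    assert np.all(np.diff(rates) > 0)
    assert rates[-1] < g.rate_max
    with pytest.raises(ValueError):
        g.static_rate(-1.0)


def test_gto_rate_sensitivity_and_settling():
    dt = 1e-3                                # coarse clock: long settle
    g = pr.GTO(300, dt)
    force = np.concatenate([np.full(2000, 100.0), np.full(40000, 300.0)])
    resp = g.response(force)
    before = resp[1999]
    settle = resp[-1]
    assert resp.max() > settle > before      # transient overshoot then settle
    assert settle == pytest.approx(float(g.static_rate(300.0)), rel=0.02)


def test_gto_digital_filter_matches_continuous():
    """The bilinear discretisation reproduces the continuous transfer
    function to better than 1% up to 10 Hz."""
    dt = 5e-5
    g = pr.GTO(300, dt)
    fb = __import__("stancesim.params", fromlist=["load"]).load("feedback")
    zeros = np.array(fb["gto"]["tf_zeros"])
    poles = np.array(fb["gto"]["tf_poles"])
    k = np.prod(poles) / np.prod(zeros)
    num = k * np.poly(-zeros)
    den = np.poly(-poles)
    w = 2 * np.pi * np.array([0.1, 0.5, 1.0, 5.0, 10.0])
    _, h_c = scipy.signal.freqs(num, den, worN=w)
    _, h_d = scipy.signal.freqz(g.b, g.a, worN=w * dt)
    assert np.allclose(np.abs(h_d), np.abs(h_c), rtol=0.01)


def test_gto_step_matches_response():
    dt = 5e-5
    g1 = pr.GTO(300, dt)
    force = 50.0 + 20.0 * np.sin(np.linspace(0, 10, 2000))
    stepped = np.array([g1.step(f) for f in force])
    g2 = pr.GTO(300, dt)
    batch = g2.response(force)
    assert np.allclose(stepped, batch, atol=1e-9)


# ---------------------------------------------------------------------------
# afferent recruitment
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def bundle():
    return pr.build_bundle("SO", "Ia", seed=11, scale=0.25)


def test_bundle_construction(bundle):
    assert bundle.n == 100 and bundle.n_full == 400
    assert np.all(np.diff(bundle.thresholds) > 0)
    assert bundle.thresholds[0] == 0.0 and bundle.thresholds[-1] < 50.0
    assert np.all(bundle.velocities >= 62.0) \
        and np.all(bundle.velocities <= 67.0)
    assert np.all(bundle.initial_rates > 0)
    assert np.allclose(bundle.delays, 0.80 / bundle.velocities)


def test_recruitment_law(bundle):
    assert np.count_nonzero(bundle.rates(50.0)) == bundle.n   # all recruited
    assert np.count_nonzero(bundle.rates(0.0)) == 1           # threshold 0
    half = np.count_nonzero(bundle.rates(25.0))
    assert abs(half - bundle.n // 2) <= 1
    with pytest.raises(ValueError):
        bundle.rates(-1.0)


def test_recruitment_monotone(bundle):
    prev = set()
    for r in np.linspace(0, 60, 40):
        cur = set(np.nonzero(bundle.rates(r))[0])
        assert prev <= cur
        prev = cur


# ---------------------------------------------------------------------------
# gamma-process spike encoding
# ---------------------------------------------------------------------------

def test_constant_rate_isi_moments():
    rate, order = 100.0, 6
    times, isis = pr.encode_spikes(lambda t: rate, duration=120.0, dt=5e-4,
                                   gamma_order=order, seed=3)
    assert np.mean(isis) == pytest.approx(1.0 / rate, rel=0.03)
    cv = np.std(isis) / np.mean(isis)
    assert cv == pytest.approx(1.0 / math.sqrt(order), rel=0.08)


def test_poisson_limit():
    times, isis = pr.encode_spikes(lambda t: 50.0, duration=120.0, dt=2e-4,
                                   gamma_order=1, seed=4)
    cv = np.std(isis) / np.mean(isis)
    assert cv == pytest.approx(1.0, rel=0.08)


def test_time_rescaled_isis_are_gamma():
    """Rescaling ISIs by the (constant) intensity yields gamma(k, 1/k)
    waiting times (KS test at alpha = 0.01 on ~1e4 intervals)."""
    rate, order = 40.0, 6
    _, isis = pr.encode_spikes(lambda t: rate, duration=260.0, dt=1e-4,
                               gamma_order=order, seed=5)
    assert len(isis) > 9000
    rescaled = isis * rate
    stat, p = scipy.stats.kstest(rescaled, "gamma", args=(order, 0, 1 / order))
    assert p > 0.01


def test_intensity_recovery_on_slow_modulation():
    """The kernel-smoothed pooled rate of a bundle tracks a slowly varying
    intensity with small relative bias."""
    b = pr.build_bundle("SO", "Ia", seed=6, scale=1.0)
    b.thresholds = np.zeros(b.n)            # isolate encoding from recruitment
    b.initial_rates = np.zeros(b.n)
    b.start_encoding(7)
    dt = 1e-3
    dur = 20.0
    counts = np.zeros(int(dur / dt))
    target = np.zeros(int(dur / dt))
    for i in range(len(counts)):
        r = 20.0 + 10.0 * math.sin(2 * math.pi * 0.2 * i * dt)
        target[i] = r
        counts[i] = len(b.encode_step(r, dt))
    kernel = scipy.signal.windows.gaussian(501, 100)
    kernel /= kernel.sum()
    est = np.convolve(counts / (b.n * dt), kernel, mode="same")
    sel = slice(2000, -2000)
    bias = np.mean(np.abs(est[sel] - target[sel])) / np.mean(target)
    assert bias < 0.05


def test_encode_rejects_negative_intensity():
    with pytest.raises(ValueError):
        pr.encode_spikes(lambda t: -1.0, duration=0.1, dt=1e-3,
                         gamma_order=6, seed=0)


# ---------------------------------------------------------------------------
# fusimotor drive
# ---------------------------------------------------------------------------

def test_fusimotor_moments():
    gs, gd = pr.fusimotor_drive(32.0, 33.8, duration=120.0, seed=9, dt=1e-3)
    assert np.mean(gs) == pytest.approx(32.0, abs=0.5)
    assert np.var(gs) == pytest.approx(0.03 * 32.0, rel=0.30)
    assert np.mean(gd) == pytest.approx(33.8, abs=0.5)


def test_fusimotor_zero_variance_and_seeds():
    d = pr.FusimotorDrive(32.0, seed=1, variance_frac=0.0)
    s = d.series(0.1, 1e-3)
    assert np.all(s == 32.0)
    a = pr.FusimotorDrive(32.0, seed=1).series(1.0, 1e-3)
    b = pr.FusimotorDrive(32.0, seed=2).series(1.0, 1e-3)
    assert not np.allclose(a, b)
    assert np.mean(a) == pytest.approx(np.mean(b), abs=1.0)
    with pytest.raises(ValueError):
        pr.FusimotorDrive(-1.0, seed=0)
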