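"""Spinal neuron pools, synapses, descending drive, network construction."""
import math

import numpy as np
import pytest

from stancesim import spinal_network as sn

TINY = dict(
    composition={"SO": {"S": 4, "FR": 1, "FF": 1},
                 "MG": {"S": 2, "FR": 1, "FF": 1},
                 "LG": {"S": 1, "FR": 1, "FF": 1},
                 "TA": {"S": 2, "FR": 1, "FF": 1}},
    afferent_counts={m: {"Ia": 4, "II": 4, "Ib": 2}
                     for m in ("SO", "MG", "LG", "TA")},
)


# ---------------------------------------------------------------------------
# descending drive
# ---------------------------------------------------------------------------

def test_descending_drive_isi_statistics():
    times, ids = sn.generate_descending_drive(400, 50.0, 25, 20.0, seed=1)
    isis = []
    for axon in range(400):
        t = times[ids == axon]
        isis.append(np.diff(t))
    isis = np.concatenate(isis)
    cv = np.std(isis) / np.mean(isis)
    assert cv == pytest.approx(0.20, abs=0.01)
    # pooled mean ISI within 2 s.e. of 20 ms
    se = np.std(isis) / math.sqrt(len(isis))
    assert abs(np.mean(isis) - 0.020) < 2 * se


def test_descending_drive_poisson_limit():
    times, ids = sn.generate_descending_drive(50, 50.0, 1, 40.0, seed=2)
    isis = np.concatenate([np.diff(times[ids == a]) for a in range(50)])
    assert np.std(isis) / np.mean(isis) == pytest.approx(1.0, abs=0.05)


def test_descending_drive_validation():
    with pytest.raises(ValueError):
        sn.generate_descending_drive(10, 0.0, 25, 1.0, 0)
    with pytest.raises(ValueError):
        sn.generate_descending_drive(10, 50.0, 0, 1.0, 0)
    with pytest.raises(ValueError):
        sn.generate_descending_drive(10, 50.0, 25, -1.0, 0)


# ---------------------------------------------------------------------------
# kinetic synapse
# ---------------------------------------------------------------------------

def test_kinetic_conductance_decay_and_linearity():
    k = sn.KineticConductance(0.6, 300)
    assert k.advance(5.0) == 0.0                       # no input -> zero
    k.add_spike(5.0)
    peak1 = max(k.advance(5.0 + 0.1 * i) for i in range(1, 40))
    k2 = sn.KineticConductance(0.6, 300)
    k2.add_spike(5.0, weight=2.0 / 300)
    peak2 = max(k2.advance(5.0 + 0.1 * i) for i in range(1, 40))
    assert peak2 == pytest.approx(2 * peak1, rel=0.02)  # linear at low drive
    assert k.advance(200.0) < 1e-12                     # decays back to zero


def test_kinetic_conductance_saturates():
    k = sn.KineticConductance(0.6, 10)
    for i in range(400):                                # 100 Hz on all 10
        for term in range(10):
            k.add_spike(i * 10.0, weight=1.0 / 10)
    g = [k.advance(t) for t in np.arange(0.0, 4000.0, 0.5)]
    assert max(g) <= k.saturation_bound + 1e-12
    assert max(g) > 0.3 * k.saturation_bound


def test_kinetic_conductance_rejects_past_events():
    k = sn.KineticConductance(0.6, 10)
    k.advance(10.0)
    with pytest.raises(ValueError):
        k.add_spike(5.0)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def test_full_scale_composition():
    comp = sn.scaled_composition(1.0)
    assert comp["SO"] == {"S": 800, "FR": 50, "FF": 50}
    assert comp["MG"] == {"S": 300, "FR": 150, "FF": 150}
    assert comp["LG"] == {"S": 130, "FR": 65, "FF": 65}
    assert comp["TA"] == {"S": 250, "FR": 50, "FF": 50}
    small = sn.scaled_composition(0.1)
    assert small["SO"] == {"S": 80, "FR": 5, "FF": 5}
    assert sum(sn.scaled_composition(0.1)["MG"].values()) == 60
    with pytest.raises(ValueError):
        sn.scaled_composition(0.0)


def test_mg_pool_size_model2():
    net = sn.build_network("model2", seed=0, scale=1.0,
                           afferent_counts=TINY["afferent_counts"])
    assert net.pools["MG"].n == 600
    counts = np.bincount(net.pools["MG"].mu_types, minlength=3)
    assert list(counts) == [300, 150, 150]


def test_build_determinism():
    a = sn.build_network("model2", seed=5, **TINY)
    b = sn.build_network("model2", seed=5, **TINY)
    for name in a.projections:
        for ca, cb in zip(a.projections[name].channel_ids,
                          b.projections[name].channel_ids):
            assert np.array_equal(ca, cb)
    assert np.array_equal(a.v_th, b.v_th)


def test_variant_difference_is_reciprocal_only():
    m1 = sn.build_network("model1", seed=5, **TINY)
    m2 = sn.build_network("model2", seed=5, **TINY)
    only2 = set(m2.projections) - set(m1.projections)
    assert only2 == {"Ia_TA->IaIN_TA", "IaIN_TA->SO", "IaIN_TA->MG",
                     "IaIN_TA->LG"}
    assert set(m1.projections) <= set(m2.projections)
    for name in m1.projections:
        for ca, cb in zip(m1.projections[name].channel_ids,
                          m2.projections[name].channel_ids):
            assert np.array_equal(ca, cb)


def test_unknown_variant_and_empty_pool():
    with pytest.raises(ValueError):
        sn.build_network("model3", seed=0, **TINY)
    with pytest.raises(ValueError):
        sn.build_network("model2", seed=0, composition={
            m: {"S": 0, "FR": 0, "FF": 0} for m in ("SO", "MG", "LG", "TA")})


def test_axonal_delays_match_velocity_bands():
    net = sn.build_network("model2", seed=0, **TINY)
    for m, pool in ((k, v) for k, v in net.pools.items() if v.kind == "MN"):
        v = 0.80 / pool.axon_delay_s
        assert np.all(v >= 43.9) and np.all(v <= 53.1)
        # within a pool, S-type axons are slower than FF-type
        s_v = v[pool.mu_types == 0]
        ff_v = v[pool.mu_types == 2]
        assert s_v.max() <= ff_v.min() + 1e-9


def test_interneuron_thresholds_linear_10_20():
    net = sn.build_network("model2", seed=3, scale=1.0,
                           composition=TINY["composition"],
                           afferent_counts=TINY["afferent_counts"])
    p = net.pools["IbIN_SO"]
    th = net.v_th[p.sl]
    assert p.n == 350
    assert th.min() > 10.0 * 0.97 and th.max() < 20.0 * 1.03
    # linear within jitter: correlation with index ~ 1
    r = np.corrcoef(np.arange(p.n), th)[0, 1]
    assert r > 0.99


def test_connectivity_fraction_within_binomial_bounds():
    net = sn.build_network("model2", seed=0, scale=1.0,
                           composition=TINY["composition"])
    proj = net.projections["Ia_SO->SO"]        # 400 afferents, p = 0.8
    n_targets = net.pools["SO"].n
    fractions = [len(ch) / n_targets for ch in proj.channel_ids]
    assert np.mean(fractions) == pytest.approx(0.8, abs=0.02)


def test_no_mg_ia_to_so_projection():
    net = sn.build_network("model2", seed=0, **TINY)
    assert "Ia_MG->SO" not in net.projections
    assert "Ia_LG->SO" in net.projections
    assert "Ia_SO->MG" in net.projections


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

@pytest.fixture()
def tiny_net():
    net = sn.build_network("model2", seed=7, **TINY)
    net.begin_run(5e-5)
    return net


def test_resting_stability(tiny_net):
    for _ in range(8000):                      # 0.4 s, no input
        assert len(tiny_net.step()) == 0
    assert np.all(np.abs(tiny_net.v_s) < 1e-9)


def _spike_times(net, unit, current, duration, dt):
    net.reset_state()
    net.begin_run(dt)
    inj = np.zeros(net.n_neurons)
    inj[unit] = current
    out = []
    for i in range(int(round(duration / dt))):
        if unit in net.step(inj):
            out.append((i + 1) * dt)
    return np.array(out)


def test_fi_curve_monotone(tiny_net):
    rates = [len(_spike_times(tiny_net, 0, i, 0.8, 5e-5))
             for i in (8.0, 14.0, 26.0)]
    assert rates[0] > 0
    assert all(b >= a for a, b in zip(rates, rates[1:]))
    assert rates[-1] > rates[0]


def test_afterhyperpolarisation_follows_spike(tiny_net):
    net = tiny_net
    net.reset_state()
    net.begin_run(5e-5)
    inj = np.zeros(net.n_neurons)
    inj[0] = 20.0
    fired_at = None
    for i in range(8000):
        if len(net.step(inj)):
            fired_at = i
            break
    assert fired_at is not None
    for _ in range(900):                       # release the stimulus; let
        net.step()                             # the spike itself pass
    assert net.q[0] > 0.1                      # AHP conductance engaged
    assert net.v_s[0] < 0.0                    # hyperpolarised below rest
    for _ in range(40000):
        net.step()
    assert abs(net.v_s[0]) < 0.5               # recovers toward rest


def test_step_matches_refined_integration(tiny_net):
    coarse = _spike_times(tiny_net, 0, 14.0, 0.4, 5e-5)
    fine = _spike_times(tiny_net, 0, 14.0, 0.4, 5e-6)
    assert len(coarse) == len(fine)
    assert np.all(np.abs(coarse - fine) < 1e-3)


def test_recruitment_order_under_ramp():
    """A slow common ramp recruits S before FR before FF."""
    net = sn.build_network(
        "model2", seed=1, scale=1.0,
        composition={"SO": {"S": 14, "FR": 4, "FF": 4},
                     "MG": {"S": 1, "FR": 1, "FF": 1},
                     "LG": {"S": 1, "FR": 1, "FF": 1},
                     "TA": {"S": 1, "FR": 1, "FF": 1}},
        afferent_counts=TINY["afferent_counts"])
    dt = 1e-4
    net.begin_run(dt)
    pool = net.pools["SO"]
    first = np.full(pool.n, np.inf)
    inj = np.zeros(net.n_neurons)
    for i in range(int(1.8 / dt)):
        inj[pool.sl] = 55.0 * (i * dt) / 1.8
        for g in net.step(inj):
            if pool.start <= g < pool.stop and first[g - pool.start] == np.inf:
                first[g - pool.start] = (i + 1) * dt
    types = pool.mu_types
    assert np.isfinite(first).all()
    assert first[types == 0].mean() < first[types == 1].mean() \
        < first[types == 2].mean()
    # pairwise inversions across increasing nominal threshold order
    inv = sum(1 for i in range(pool.n) for j in range(i + 1, pool.n)
              if first[i] > first[j])
    assert inv / (pool.n * (pool.n - 1) / 2) <= 0.02


def test_spike_times_on_clock_grid(tiny_net):
    t = _spike_times(tiny_net, 0, 16.0, 0.3, 5e-5)
    assert len(t) > 0
    steps = t / 5e-5
    assert np.allclose(steps, np.round(steps), atol=1e-6)


def test_manifest_and_edge_list(tiny_net):
    rows = tiny_net.manifest()
    assert len(rows) == tiny_net.n_neurons
    assert rows[0][1] == "SO" and rows[0][2] == "MN" and rows[0][3] == "S"
    edges = tiny_net.edge_list()
    assert len(edges) > 0
    src, tgt, g, d, sign = edges[0]
    assert g > 0 and d > 0 and sign in ("exc", "inh")
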