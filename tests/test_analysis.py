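"""Posturography and motor-unit analysis battery."""
import numpy as np
import pytest
import scipy.stats

from stancesim import analysis as an

FS = 2000.0


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def test_preprocess_trims_to_analysis_window():
    x = np.random.default_rng(0).normal(size=int(30.0 * FS))
    y = an.preprocess(x, FS)
    assert len(y) == int(22.5 * FS)


def test_preprocess_removes_linear_trend():
    x = np.linspace(0, 5, int(30 * FS))
    y = an.preprocess(x, FS)
    assert np.max(np.abs(y)) < 1e-8


def test_preprocess_resampling_preserves_sinusoid():
    fs_in = 4000.0
    t = np.arange(int(30 * fs_in)) / fs_in
    x = np.sin(2 * np.pi * 1.0 * t)
    y = an.preprocess(x, fs_in)
    assert len(y) == int(22.5 * FS)
    amp = 0.5 * (y.max() - y.min())
    assert amp == pytest.approx(1.0, rel=0.01)


def test_preprocess_rejects_short_records():
    with pytest.raises(ValueError):
        an.preprocess(np.zeros(100), FS)


# ---------------------------------------------------------------------------
# COP metrics
# ---------------------------------------------------------------------------

def test_cop_metrics_sine():
    t = np.arange(int(22.5 * FS)) / FS
    x = np.sin(2 * np.pi * 0.4 * t)
    rms, mv, f50 = an.cop_metrics(x, FS)
    assert rms == pytest.approx(1 / np.sqrt(2), rel=0.01)
    # F50 matches the tone frequency within the Welch resolution
    # (segment length is a quarter of the 22.5-s record)
    df = 4.0 / 22.5
    assert abs(f50 - 0.4) <= df


def test_cop_metrics_triangle_mean_velocity():
    f0, amp = 0.8, 2.0
    t = np.arange(int(22.5 * FS)) / FS
    from scipy.signal import sawtooth
    x = amp * sawtooth(2 * np.pi * f0 * t, width=0.5)
    _, mv, _ = an.cop_metrics(x, FS)
    assert mv == pytest.approx(4 * amp * f0, rel=0.01)


# ---------------------------------------------------------------------------
# cross-correlation
# ---------------------------------------------------------------------------

def test_xcorr_identity_and_shift():
    rng = np.random.default_rng(2)
    from scipy.signal import sosfilt, butter
    sos = butter(2, 5.0, fs=FS, output="sos")
    x = sosfilt(sos, rng.normal(size=int(20 * FS)))
    rho, lag = an.xcorr_peak(x, x, FS)
    assert rho == pytest.approx(1.0) and lag == 0.0
    shift = int(0.2 * FS)
    y = np.roll(x, shift)                     # y delayed: x leads y
    rho, lag = an.xcorr_peak(x[shift:-shift], y[shift:-shift], FS,
                             max_lag_s=1.0)
    assert rho > 0.95
    assert lag == pytest.approx(0.2, abs=0.005)


def test_xcorr_swap_negates_lag():
    rng = np.random.default_rng(3)
    from scipy.signal import sosfilt, butter
    sos = butter(2, 5.0, fs=FS, output="sos")
    x = sosfilt(sos, rng.normal(size=int(10 * FS)))
    y = np.roll(x, 100)
    r1, l1 = an.xcorr_peak(x, y, FS, max_lag_s=0.5)
    r2, l2 = an.xcorr_peak(y, x, FS, max_lag_s=0.5)
    assert r1 == pytest.approx(r2, abs=1e-6)
    assert l1 == pytest.approx(-l2, abs=1e-6)


def test_xcorr_independent_noise_below_null_band():
    rng = np.random.default_rng(4)
    x = rng.normal(size=4000)
    y = rng.normal(size=4000)
    rho, _ = an.xcorr_peak(x, y, FS, max_lag_s=0.05)
    null = []
    for _ in range(50):
        perm = rng.permutation(len(x))
        r, _ = an.xcorr_peak(x[perm], y, FS, max_lag_s=0.05)
        null.append(abs(r))
    assert abs(rho) < np.quantile(null, 0.95) * 2.0


def test_xcorr_zero_variance_rejected():
    with pytest.raises(ValueError):
        an.xcorr_peak(np.zeros(100), np.ones(100), FS)


# ---------------------------------------------------------------------------
# motor-unit intermittency
# ---------------------------------------------------------------------------

def test_activation_ratio_boundaries():
    assert an.activation_ratio([], 0.0, 10.0) == 0.0
    spikes = np.arange(0.0, 10.0001, 0.1)          # continuous 10 Hz
    assert an.activation_ratio(spikes, 0.0, 10.0) == pytest.approx(1.0,
                                                                   abs=0.01)
    half = np.arange(0.0, 5.0001, 0.1)             # active half the record
    assert an.activation_ratio(half, 0.0, 10.0) == pytest.approx(0.5,
                                                                 abs=0.01)
    with pytest.raises(ValueError):
        an.activation_ratio([], 5.0, 5.0)


def test_inter_recruitment_intervals():
    tonic = np.arange(0, 10, 0.1)
    iri, mean, mode = an.inter_recruitment_intervals(tonic)
    assert len(iri) == 0 and mean is None
    # bursts of 3 spikes every 500 ms
    bursts = np.concatenate([[k * 0.5, k * 0.5 + 0.02, k * 0.5 + 0.04]
                             for k in range(20)])
    iri, mean, mode = an.inter_recruitment_intervals(bursts)
    assert mean == pytest.approx(0.46, abs=0.02)
    assert np.all(iri > 0.25)
    mixed = np.array([0.0, 0.1, 0.2, 1.0, 1.1, 2.0])
    iri, _, _ = an.inter_recruitment_intervals(mixed)
    assert np.allclose(sorted(iri), [0.8, 0.9])


def test_coverage_partition():
    """Activation ratio + long-ISI fraction + boundary terms cover the whole
    record exactly."""
    rng = np.random.default_rng(5)
    spikes = np.cumsum(rng.exponential(0.15, size=200))
    t0, t1 = 0.0, spikes[-1] + 0.3
    isi = np.diff(spikes)
    ar = an.activation_ratio(spikes, t0, t1)
    long_frac = np.sum(isi[isi >= an.ISI_RECRUIT_S]) / (t1 - t0)
    boundary = (spikes[0] - t0 + t1 - spikes[-1]) / (t1 - t0)
    assert ar + long_frac + boundary == pytest.approx(1.0, abs=1e-9)


def test_recruitment_events():
    spikes = np.array([0.0, 0.1, 0.2, 1.0, 1.05, 3.0])
    ev = an.recruitment_events(spikes)
    assert np.allclose(ev, [0.0, 1.0, 3.0])


def test_recruitment_phase_plot():
    fs = 100.0
    t = np.arange(0, 30, 1 / fs)
    theta = np.sin(2 * np.pi * 0.2 * t)
    omega = np.gradient(theta, t)
    torque = -theta
    # recruitments only while leaning forward
    forward = t[theta > 0.5]
    trains = {0: forward[::40], 1: forward[5::40]}
    out = an.recruitment_phase_plot(trains, t, theta, omega, torque)
    q = out["quadrants_angle_velocity"]
    assert q[0] + q[3] > 0.9                    # forward-lean quadrants
    assert out["counts"].sum() == out["n_events"]
    empty = an.recruitment_phase_plot({}, t, theta, omega, torque)
    assert empty["n_events"] == 0


# ---------------------------------------------------------------------------
# windowed COM / fibre-length correlation
# ---------------------------------------------------------------------------

def test_windowed_length_correlation_signs():
    rng = np.random.default_rng(6)
    com = np.cumsum(rng.normal(size=int(22.5 * FS)))
    rhos, n_pos, n_neg = an.windowed_length_correlation(com, com, FS)
    assert len(rhos) == 7                        # 22.5 s -> 7 full windows
    assert n_pos == 7 and n_neg == 0 and np.allclose(rhos, 1.0)
    rhos, n_pos, n_neg = an.windowed_length_correlation(com, -com, FS)
    assert n_neg == 7 and n_pos == 0


def test_compare_window_signs_chi2():
    chi2, p = an.compare_window_signs(17, 4, 10, 11)
    assert p < 0.05
    _, p_same = an.compare_window_signs(10, 11, 11, 10)
    assert p_same > 0.5


# ---------------------------------------------------------------------------
# COM histogram / bimodality
# ---------------------------------------------------------------------------

def test_com_bimodality_type_one_error_rate():
    rng = np.random.default_rng(7)
    rejections = 0
    reps = 60
    for _ in range(reps):
        runs = [rng.normal(size=4000) * 0.005 for _ in range(3)]
        *_, p = an.com_bimodality(runs)
        rejections += p < 0.05
    assert rejections / reps < 0.15              # near-nominal type-I rate


def test_com_bimodality_detects_mixture():
    rng = np.random.default_rng(8)
    power = 0
    reps = 20
    for _ in range(reps):
        runs = [np.concatenate([rng.normal(-1, 1, 8000),
                                rng.normal(1, 1, 8000)]) * 0.001
                for _ in range(3)]
        *_, p = an.com_bimodality(runs)
        power += p < 0.05
    assert power / reps > 0.9
    with pytest.raises(ValueError):
        an.com_bimodality([np.zeros(10)])


def test_com_histogram_mean_subtraction():
    rng = np.random.default_rng(9)
    runs = [rng.normal(loc=0.08, scale=0.005, size=5000) for _ in range(3)]
    edges, counts, *_ = an.com_bimodality(runs)
    centres = edges[:-1] + 0.5
    mean_mm = np.sum(centres * counts) / counts.sum()
    assert abs(mean_mm) < 0.5                    # pooled mean removed


def test_metrics_invariant_to_storage_decimation():
    rng = np.random.default_rng(10)
    from scipy.signal import sosfilt, butter
    sos = butter(4, 3.0, fs=8000.0, output="sos")
    x8k = sosfilt(sos, rng.normal(size=int(30 * 8000)))
    m_direct = an.cop_metrics(an.preprocess(x8k, 8000.0), FS)
    m_dec = an.cop_metrics(an.preprocess(x8k[::2], 4000.0), FS)
    assert m_direct[0] == pytest.approx(m_dec[0], rel=0.01)
    assert m_direct[2] == pytest.approx(m_dec[2], rel=0.05)
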