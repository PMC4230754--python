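"""Posturography and motor-unit analysis battery.

Operates on simulation results or externally supplied recordings: centre-of-
pressure (COP) summary metrics, cross-correlations (COM-COP, COP-EMG),
motor-unit activation ratios and inter-recruitment intervals, recruitment
phase plots, windowed COM/fibre-length correlations ("paradoxical" sway
behaviour), and the pooled COM histogram with its Gaussianity test.

All analyses run on 2 kHz series with the first 5 s and last 2.5 s of the
30-s protocol removed, after linear detrending.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.signal
import scipy.stats


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(x, fs: float, fs_out: float = 2000.0, trim_head: float = 5.0,
               trim_tail: float = 2.5, detrend: bool = True) -> np.ndarray:
    """Trim transients (5 s head, 2.5 s tail), linearly detrend, and
    resample to 2 kHz."""
    x = np.asarray(x, dtype=float)
    n_head = int(round(trim_head * fs))
    n_tail = int(round(trim_tail * fs))
    if len(x) <= n_head + n_tail:
        raise ValueError("record too short for the analysis window")
    x = x[n_head:len(x) - n_tail]
    if detrend:
        x = scipy.signal.detrend(x)
    if fs != fs_out:
        up = int(round(fs_out))
        down = int(round(fs))
        g = math.gcd(up, down)
        x = scipy.signal.resample_poly(x, up // g, down // g)
    return x


# ---------------------------------------------------------------------------
# COP metrics
# ---------------------------------------------------------------------------

def cop_metrics(cop, fs: float = 2000.0, nperseg_frac: float = 0.25):
    """(RMS, mean velocity, F50) of a preprocessed COP series.

    RMS in the series' units; MV = mean |dCOP/dt|; F50 is the frequency
    below which half of the Welch power lies (Hann window, segment length a
    quarter of the record, 50% overlap, linear interpolation on the
    cumulative spectrum).
    """
    cop = np.asarray(cop, dtype=float)
    rms = float(np.sqrt(np.mean(cop ** 2)))
    mv = float(np.mean(np.abs(np.diff(cop)))) * fs
    nperseg = max(256, int(len(cop) * nperseg_frac))
    f, pxx = scipy.signal.welch(cop, fs=fs, window="hann", nperseg=nperseg)
    cum = np.cumsum(pxx)
    cum /= cum[-1]
    f50 = float(np.interp(0.5, cum, f))
    return rms, mv, f50


def xcorr_peak(x, y, fs: float = 2000.0, max_lag_s: float | None = None):
    """Peak of the normalised cross-correlation and its signed lag (s).

    Positive lag means ``x`` leads ``y`` (the peak occurs with x shifted
    earlier in time).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    sx, sy = np.std(x), np.std(y)
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    x = (x - np.mean(x)) / sx
    y = (y - np.mean(y)) / sy
    n = len(x)
    c = scipy.signal.correlate(y, x, mode="full", method="fft") / n
    lags = np.arange(-n + 1, n)
    if max_lag_s is not None:
        keep = np.abs(lags) <= max_lag_s * fs
        c, lags = c[keep], lags[keep]
    i = int(np.argmax(np.abs(c)))
    return float(c[i]), float(lags[i] / fs)


# ---------------------------------------------------------------------------
# motor-unit intermittency
# ---------------------------------------------------------------------------

ISI_RECRUIT_S = 0.250       # ISIs above this mark a de-recruited stretch


def activation_ratio(spike_times, t_start: float, t_stop: float,
                     isi_max: float = ISI_RECRUIT_S) -> float:
    """Fraction of the record covered by interspike intervals shorter than
    ``isi_max``: 0 for an inactive unit, 1 for continuous activity."""
    span = t_stop - t_start
    if span <= 0:
        raise ValueError("empty record span")
    t = np.sort(np.asarray(spike_times, dtype=float))
    t = t[(t >= t_start) & (t <= t_stop)]
    if len(t) < 2:
        return 0.0
    isi = np.diff(t)
    return float(np.sum(isi[isi < isi_max]) / span)


def inter_recruitment_intervals(spike_times, isi_min: float = ISI_RECRUIT_S,
                                mode_bin_s: float = 0.050):
    """Intervals between successive recruitments of one unit: the ISIs
    longer than 250 ms; returns (intervals, mean, mode) with the mode from
    50-ms binning (None when no such interval exists)."""
    t = np.sort(np.asarray(spike_times, dtype=float))
    if len(t) < 2:
        return np.array([]), None, None
    isi = np.diff(t)
    iri = isi[isi > isi_min]
    if len(iri) == 0:
        return iri, None, None
    edges = np.arange(isi_min, iri.max() + 2 * mode_bin_s, mode_bin_s)
    counts, _ = np.histogram(iri, bins=edges)
    mode = float(edges[np.argmax(counts)] + 0.5 * mode_bin_s)
    return iri, float(np.mean(iri)), mode


def recruitment_events(spike_times, isi_min: float = ISI_RECRUIT_S):
    """Times at which a unit is (re)recruited: its first spike and every
    spike that follows a silent stretch longer than 250 ms."""
    t = np.sort(np.asarray(spike_times, dtype=float))
    if len(t) == 0:
        return t
    gaps = np.diff(t) > isi_min
    return t[np.concatenate([[True], gaps])]


def recruitment_phase_plot(spike_trains: dict[int, np.ndarray],
                           t: np.ndarray, theta: np.ndarray,
                           omega: np.ndarray, torque: np.ndarray,
                           window_s: float = 0.100):
    """Recruitment counts in 100-ms windows against mean-subtracted phase
    coordinates.

    Returns a dict with per-window (angle, velocity, torque) coordinates,
    recruited-unit counts, and quadrant occupancy fractions for the
    angle-velocity and angle-torque planes (quadrants numbered 1-4
    anticlockwise from +x/+y).
    """
    t = np.asarray(t)
    t0, t1 = t[0], t[-1]
    n_win = int((t1 - t0) / window_s)
    if n_win < 1:
        raise ValueError("record shorter than one window")
    edges = t0 + np.arange(n_win + 1) * window_s
    counts = np.zeros(n_win, dtype=int)
    for times in spike_trains.values():
        ev = recruitment_events(times)
        ev = ev[(ev >= t0) & (ev < edges[-1])]
        idx = np.unique(((ev - t0) / window_s).astype(int))
        counts[idx[idx < n_win]] += 1
    centres = edges[:-1] + window_s / 2

    def win_mean(x):
        return np.interp(centres, t, np.asarray(x, dtype=float))
    ang = win_mean(theta)
    vel = win_mean(omega)
    trq = win_mean(torque)
    ang = ang - ang.mean()
    vel = vel - vel.mean()
    trq = trq - trq.mean()

    def quadrant_fractions(xx, yy):
        total = counts.sum()
        if total == 0:
            return np.zeros(4)
        q = np.zeros(4)
        q[0] = counts[(xx > 0) & (yy > 0)].sum()
        q[1] = counts[(xx <= 0) & (yy > 0)].sum()
        q[2] = counts[(xx <= 0) & (yy <= 0)].sum()
        q[3] = counts[(xx > 0) & (yy <= 0)].sum()
        return q / total

    return {
        "angle": ang, "velocity": vel, "torque": trq, "counts": counts,
        "quadrants_angle_velocity": quadrant_fractions(ang, vel),
        "quadrants_angle_torque": quadrant_fractions(ang, trq),
        "n_events": int(counts.sum()),
    }


# ---------------------------------------------------------------------------
# fibre-length / COM correlation windows
# ---------------------------------------------------------------------------

def windowed_length_correlation(com, fibre_length, fs: float = 2000.0,
                                window_s: float = 3.0):
    """Pearson correlation between COM and fibre length in non-overlapping
    3-s windows; returns (rhos, n_positive, n_negative).  Zero-variance
    windows are skipped."""
    com = np.asarray(com, dtype=float)
    fl = np.asarray(fibre_length, dtype=float)
    if len(com) != len(fl):
        raise ValueError("series must have equal length")
    w = int(round(window_s * fs))
    rhos = []
    for i in range(len(com) // w):
        a = com[i * w:(i + 1) * w]
        b = fl[i * w:(i + 1) * w]
        if np.std(a) == 0 or np.std(b) == 0:
            continue
        rhos.append(float(np.corrcoef(a, b)[0, 1]))
    rhos = np.asarray(rhos)
    return rhos, int(np.sum(rhos > 0)), int(np.sum(rhos < 0))


def compare_window_signs(n_pos_1, n_neg_1, n_pos_2, n_neg_2):
    """Chi-square comparison of positive/negative window counts between two
    designs; returns (chi2, p)."""
    table = np.array([[n_pos_1, n_neg_1], [n_pos_2, n_neg_2]])
    # plain Pearson chi-square (no continuity correction), as customary for
    # the 21-window two-sample design
    chi2, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# COM histogram and bimodality
# ---------------------------------------------------------------------------

def com_bimodality(com_runs, bin_mm: float = 1.0):
    """Pool mean-subtracted COM samples (m) from several runs, histogram
    them in 1-mm bins, and test Gaussianity with the Jarque-Bera statistic.

    Returns (bin_edges_mm, counts, jb_statistic, p_value).
    """
    runs = [np.asarray(r, dtype=float) for r in com_runs]
    if len(runs) < 2:
        raise ValueError("pooling requires at least two runs")
    pooled = np.concatenate([r - r.mean() for r in runs]) * 1000.0
    lo = math.floor(pooled.min())
    hi = math.ceil(pooled.max())
    edges = np.arange(lo, hi + bin_mm, bin_mm)
    counts, _ = np.histogram(pooled, bins=edges)
    jb, p = scipy.stats.jarque_bera(pooled)
    return edges, counts, float(jb), float(p)


# ---------------------------------------------------------------------------
# summary over a set of runs
# ---------------------------------------------------------------------------

@dataclass
class SwayMetrics:
    cop_rms_mm: float
    cop_mv_mm_s: float
    f50_hz: float
    rho_com_cop: float
    lag_com_cop_s: float
    rho_cop_emg: dict
    lag_cop_emg_s: dict


def sway_metrics(result, fs: float = 2000.0) -> SwayMetrics:
    """Standard posturographic summary of one completed simulation run.

    COP-EMG correlations use the (positively rectified) EMG envelopes; the
    reported lag is positive when the EMG envelope leads the COP.
    """
    if result.status != "completed":
        raise ValueError("metrics require a completed run")
    cop = preprocess(result.series["x_cop"] * 1000.0, result.config.fs_out,
                     fs)
    com = preprocess(result.series["x_com"] * 1000.0, result.config.fs_out,
                     fs)
    rms, mv, f50 = cop_metrics(cop, fs)
    rho0, lag0 = xcorr_peak(com, cop, fs, max_lag_s=2.0)
    rho_emg, lag_emg = {}, {}
    for m, env in result.emg_envelope.items():
        if m == "TA":
            continue
        e = preprocess(env, result.config.fs_out, fs)
        if np.std(e) == 0:
            continue
        rho, lag = xcorr_peak(e, cop, fs, max_lag_s=2.0)
        rho_emg[m] = rho
        lag_emg[m] = lag
    return SwayMetrics(cop_rms_mm=rms, cop_mv_mm_s=mv, f50_hz=f50,
                       rho_com_cop=rho0, lag_com_cop_s=lag0,
                       rho_cop_emg=rho_emg, lag_cop_emg_s=lag_emg)
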