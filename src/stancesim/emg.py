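"""Phenomenological surface EMG synthesis and envelope processing.

Each motor unit contributes a stereotyped action potential (first-order
Hermite-Rodriguez shape) at every conducted spike time; the surface signal
is the linear superposition over units, optionally with additive Gaussian
measurement noise.  The envelope follows the standard posturography
processing: downsample to 2 kHz, full-wave rectify, zero-phase low-pass at
2 Hz (fourth-order Butterworth applied forward-backward).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.signal

from . import params as _params
from .spinal_network import MU_TYPES


@dataclass(frozen=True)
class MUAPTemplate:
    """Hermite-Rodriguez (first-order) motor-unit action potential."""
    amplitude: float
    lambda_s: float            # time scale, s
    polarity: int = 1

    def waveform(self, fs: float) -> np.ndarray:
        """Sampled template on [-3 lambda, +3 lambda]."""
        half = int(math.ceil(3.0 * self.lambda_s * fs))
        t = np.arange(-half, half + 1) / fs
        x = t / self.lambda_s
        return self.polarity * self.amplitude * x * np.exp(-x * x)


def build_templates(muscle: str, counts: dict[str, int] | None = None
                    ) -> list[MUAPTemplate]:
    """Templates for a motor-unit pool: amplitudes grow with motor-unit size
    (tetanic amplitude ** amp_exponent), durations shrink from S to FF."""
    mu = _params.load("motorunits")
    if counts is None:
        counts = mu["composition"][muscle]
    cfg = mu["emg"]
    n_total = sum(counts.values())
    rng_factor = mu["activation"]["amplitude_range_factor"]
    sizes = np.exp(np.linspace(0.0, math.log(rng_factor), n_total))
    templates, i = [], 0
    for t in MU_TYPES:
        n = counts[t]
        lam_lo, lam_hi = cfg["lambda_ms"][t]
        lams = np.linspace(lam_lo, lam_hi, max(n, 1)) * 1e-3
        for j in range(n):
            templates.append(MUAPTemplate(
                amplitude=sizes[i] ** cfg["amp_exponent"],
                lambda_s=float(lams[j])))
            i += 1
    return templates


def synthesize_emg(spike_times, unit_ids, templates, fs: float,
                   duration: float, noise_rms: float = 0.0,
                   seed=None) -> np.ndarray:
    """Superpose per-unit templates at the conducted spike times."""
    if fs < 2000.0:
        raise ValueError("EMG sampling rate must be >= 2 kHz")
    unit_ids = np.asarray(unit_ids, dtype=int)
    if len(unit_ids) and unit_ids.max() >= len(templates):
        raise ValueError("spike references a unit without a template")
    n = int(round(duration * fs))
    out = np.zeros(n)
    waves = [tpl.waveform(fs) for tpl in templates]
    for t, u in zip(np.asarray(spike_times, dtype=float), unit_ids):
        w = waves[u]
        half = (len(w) - 1) // 2
        c = int(round(t * fs))
        lo, hi = c - half, c + half + 1
        wlo = max(0, -lo)
        whi = len(w) - max(0, hi - n)
        if whi > wlo:
            out[max(lo, 0):min(hi, n)] += w[wlo:whi]
    if noise_rms > 0.0:
        out += np.random.default_rng(seed).normal(0.0, noise_rms, size=n)
    return out


def emg_envelope(emg, fs: float, fs_out: float = 2000.0,
                 cutoff_hz: float = 2.0) -> np.ndarray:
    """Envelope: downsample to 2 kHz, full-wave rectify, zero-phase
    fourth-order Butterworth low-pass at 2 Hz."""
    x = np.asarray(emg, dtype=float)
    if fs != fs_out:
        up = int(round(fs_out))
        down = int(round(fs))
        g = math.gcd(up, down)
        x = scipy.signal.resample_poly(x, up // g, down // g)
    sos = scipy.signal.butter(4, cutoff_hz, fs=fs_out, output="sos")
    if len(x) <= 50:
        raise ValueError("record shorter than the filter transient")
    return scipy.signal.sosfiltfilt(sos, np.abs(x))
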