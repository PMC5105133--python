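"""Slow, direct-convolution wavelet-coherence reference for tests.

Independent route to the same estimator definition: the Morlet transform
uses the closed-form time-domain kernel (a Gaussian-windowed complex
exponential) with explicit ``np.convolve`` per scale; smoothing convolves
the explicit composite triple-boxcar kernel and the explicit scale boxcar
with edge-mass renormalisation, all in float64.  No FFT filter banks, no
running sums -- the fast engine must reproduce these numbers.
"""

import numpy as np

from lfcnet.coherence import (
    WCEngine,
    composite_time_kernel,
    scale_boxcar_kernel,
    triple_box_width,
)

_SQRT2 = np.sqrt(2.0)


def slow_cwt(x: np.ndarray, scales: np.ndarray, fs: float, omega0: float) -> np.ndarray:
    """Morlet CWT via explicit time-domain convolution per scale."""
    x = np.asarray(x, dtype=np.float64)
    n = len(x)
    out = np.empty((len(scales), n), dtype=np.complex128)
    for j, s in enumerate(scales):
        half = int(np.ceil(6.5 * s * fs))
        t = np.arange(-half, half + 1) / fs
        kernel = (
            np.pi**-0.25
            * np.sqrt(fs / s)
            * np.exp(-0.5 * (t / s) ** 2)
            * np.exp(1j * omega0 * t / s)
        )
        out[j] = np.convolve(x, kernel, mode="full")[half : half + n]
    return out


def slow_smooth(field: np.ndarray, engine: WCEngine) -> np.ndarray:
    """Normalised time-then-scale smoothing with explicit kernels."""
    cfg = engine.config
    J, n = field.shape
    s_cap = (engine.n / (2.0 * engine.fs)) / _SQRT2 if cfg.trim_to_coi else np.inf
    tsm = np.empty_like(field, dtype=np.float64)
    ones = np.ones(n)
    for j, s in enumerate(engine.scales):
        w = triple_box_width(cfg.time_sd_scales * min(s, s_cap) * engine.fs)
        if w <= 1:
            tsm[j] = field[j]
            continue
        k3 = composite_time_kernel(w)
        start = (len(k3) - 1) // 2  # centered crop; kernel may exceed n
        num = np.convolve(field[j], k3)[start : start + n]
        den = np.convolve(ones, k3)[start : start + n]
        tsm[j] = num / den
    sk = scale_boxcar_kernel(cfg.scale_boxcar_octaves, cfg.dj)
    half = (len(sk) - 1) // 2
    out = np.empty_like(tsm)
    for j in range(J):
        acc = np.zeros(n)
        mass = 0.0
        for k, wk in enumerate(sk):
            jj = j + k - half
            if 0 <= jj < J:
                acc += wk * tsm[jj]
                mass += wk
        out[j] = acc / mass
    return out


def slow_wc(x: np.ndarray, y: np.ndarray, engine: WCEngine) -> np.ndarray:
    """Squared wavelet coherence along the engine's scale ladder."""
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    Wx = slow_cwt(x, engine.scales, engine.fs, engine.config.omega0)
    Wy = slow_cwt(y, engine.scales, engine.fs, engine.config.omega0)
    inv_s = 1.0 / engine.scales[:, None]
    Sxx = slow_smooth(np.abs(Wx) ** 2 * inv_s, engine)
    Syy = slow_smooth(np.abs(Wy) ** 2 * inv_s, engine)
    cross = Wx * np.conj(Wy) * inv_s
    Sxy = slow_smooth(cross.real, engine) + 1j * slow_smooth(cross.imag, engine)
    r2 = np.abs(Sxy) ** 2 / (Sxx * Syy)
    return np.clip(r2, 0.0, 1.0)
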