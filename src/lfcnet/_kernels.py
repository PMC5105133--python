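"""Numba kernels for the per-trial coherence hot path.

The time smoother is a cascade of three equal boxcars (quasi-Gaussian,
see :mod:`lfcnet.coherence`) realised as running sums, O(n) per scale
regardless of kernel width.  Accumulators are float64 so the running
sums do not drift over wide windows; outputs stay float32.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _box_pass_rows(x: np.ndarray, y: np.ndarray, m: int, w: int, R: int) -> None:
    """Centered moving average along axis 0 of an (m, R) slab.

    Zero-extension outside [0, m); float64 running sums per column keep
    the sliding accumulation exact to float32 output precision.  Laying
    the rows along the fast axis lets the accumulator update vectorise.
    """
    hw = (w - 1) // 2
    inv = 1.0 / w
    acc = np.zeros(R, dtype=np.float64)
    lim = hw if hw < m - 1 else m - 1
    for k in range(lim + 1):
        for r in range(R):
            acc[r] += x[k, r]
    for r in range(R):
        y[0, r] = acc[r] * inv
    for i in range(1, m):
        ip = i + hw
        im = i - hw - 1
        if ip < m and im >= 0:
            for r in range(R):
                acc[r] += x[ip, r] - x[im, r]
                y[i, r] = acc[r] * inv
        elif ip < m:
            for r in range(R):
                acc[r] += x[ip, r]
                y[i, r] = acc[r] * inv
        elif im >= 0:
            for r in range(R):
                acc[r] -= x[im, r]
                y[i, r] = acc[r] * inv
        else:
            for r in range(R):
                y[i, r] = acc[r] * inv


@njit(cache=True)
def smooth_time_cascade(
    F: np.ndarray, widths: np.ndarray, masses: np.ndarray, out: np.ndarray
) -> None:
    """Triple-boxcar time smoothing with edge-mass renormalisation.

    F, out: (rows, scales, n) float32; widths: per-scale odd boxcar width;
    masses: (scales, n) float32 response of the cascade to all-ones.
    Each scale's slab is processed transposed (time-major) so all rows
    advance together.
    """
    R, J, n = F.shape
    wmax = 1
    for j in range(J):
        if widths[j] > wmax:
            wmax = widths[j]
    mmax = n + 3 * (wmax - 1)
    P = np.zeros((mmax, R), dtype=np.float32)
    Q = np.empty((mmax, R), dtype=np.float32)
    for j in range(J):
        w = widths[j]
        if w <= 1:
            for r in range(R):
                for i in range(n):
                    out[r, j, i] = F[r, j, i]
            continue
        h = 3 * (w - 1) // 2  # composite kernel half-width
        m = n + 2 * h
        for i in range(h):
            for r in range(R):
                P[i, r] = 0.0
        for i in range(n):
            for r in range(R):
                P[h + i, r] = F[r, j, i]
        for i in range(h + n, m):
            for r in range(R):
                P[i, r] = 0.0
        _box_pass_rows(P, Q, m, w, R)
        _box_pass_rows(Q, P, m, w, R)
        _box_pass_rows(P, Q, m, w, R)
        for i in range(n):
            mv = masses[j, i]
            for r in range(R):
                out[r, j, i] = Q[h + i, r] / mv


@njit(cache=True)
def smooth_scale_boxcar(
    F: np.ndarray, h: int, frac: float, wsum: float, smass: np.ndarray, out: np.ndarray
) -> None:
    """Boxcar across the scale axis with ladder-edge renormalisation.

    The kernel is unit weights at offsets |k| <= h plus fractional weight
    ``frac`` at offsets +-(h+1), normalised by ``wsum``; implemented as a
    running sum, O(J n) per row regardless of width.  ``smass`` is the
    per-scale in-range kernel mass (edge renormalisation).

    F, out: (rows, scales, n) float32.
    """
    R, J, n = F.shape
    acc = np.zeros(n, dtype=np.float64)
    for r in range(R):
        for i in range(n):
            acc[i] = 0.0
        top = h if h < J - 1 else J - 1
        for j in range(top + 1):
            for i in range(n):
                acc[i] += F[r, j, i]
        for j in range(J):
            jl = j - h - 1
            jr = j + h + 1
            ms = wsum * smass[j]
            if 0 <= jl and jr < J:
                for i in range(n):
                    out[r, j, i] = (
                        acc[i] + frac * (F[r, jl, i] + F[r, jr, i])
                    ) / ms
            elif jl >= 0:
                for i in range(n):
                    out[r, j, i] = (acc[i] + frac * F[r, jl, i]) / ms
            elif jr < J:
                for i in range(n):
                    out[r, j, i] = (acc[i] + frac * F[r, jr, i]) / ms
            else:
                for i in range(n):
                    out[r, j, i] = acc[i] / ms
            # slide the window: drop j-h, add j+h+1
            jd = j - h
            if jd >= 0:
                for i in range(n):
                    acc[i] -= F[r, jd, i]
            if jr < J:
                for i in range(n):
                    acc[i] += F[r, jr, i]


@njit(cache=True)
def build_cross_stack(
    Wre: np.ndarray,
    Wim: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
    stack: np.ndarray,
) -> None:
    """Fill [auto powers | cross real | cross imag] from CWT components.

    Wre/Wim: (channels, scales, n) float32, already scaled by 1/sqrt(s);
    stack: (channels + 2 * n_pairs, scales, n) float32, written in place.
    """
    C, J, n = Wre.shape
    P = ii.shape[0]
    for c in range(C):
        for j in range(J):
            for i in range(n):
                stack[c, j, i] = Wre[c, j, i] ** 2 + Wim[c, j, i] ** 2
    for p in range(P):
        a = ii[p]
        b = jj[p]
        for j in range(J):
            for i in range(n):
                stack[C + p, j, i] = (
                    Wre[a, j, i] * Wre[b, j, i] + Wim[a, j, i] * Wim[b, j, i]
                )
                stack[C + P + p, j, i] = (
                    Wim[a, j, i] * Wre[b, j, i] - Wre[a, j, i] * Wim[b, j, i]
                )
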