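"""Squared wavelet coherence between electrode pairs, per single trial.

The estimator follows the standard continuous-wavelet-coherence recipe:
analytic Morlet CWT of both signals, cross- and auto-spectra normalised by
scale, smoothing in time (kernel width proportional to scale) and across
scales (fixed-octave boxcar), and the coherence ratio

    R^2(s, t) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

which lies in [0, 1] inside the cone of influence (COI).  Without the
smoothing operator S the ratio is identically 1, so S is part of the
estimator's definition, not a cosmetic step.

Numerical choices
-----------------
* CWT by FFT convolution with the analytic Morlet (central frequency
  ``omega0``, default 6); scales are a dyadic ladder ``s_j = s_min 2^{j dj}``
  with ``dj = 1/12`` octave steps; the equivalent Fourier frequency of a
  scale is ``1 / (lambda s)`` with the Morlet Fourier factor
  ``lambda = 4 pi / (omega0 + sqrt(2 + omega0^2))``.
* The FFT buffer is padded far enough that the result equals exact linear
  convolution to < 1e-8, so a direct-convolution reference reproduces it.
* Time smoothing uses a quasi-Gaussian kernel (three equal boxcars in
  cascade) whose SD is ``s * fs / sqrt(2)`` samples -- the e-folding time
  of the Morlet autocorrelation -- applied as a normalised convolution
  (zero-padded, mass-renormalised), so constant fields are preserved.
  The cascade runs in O(n) per scale regardless of kernel width, which is
  what makes 66 pairs x hundreds of trials tractable.
* Scale smoothing is a 0.6-octave boxcar with fractional end weights,
  also mass-renormalised at the ladder edges.
* COI: a cell (s, t) is valid when ``sqrt(2) s`` does not exceed the
  distance from t to the nearer epoch edge.  Scales that can never be
  valid for the given epoch length are trimmed from the ladder (after a
  margin that keeps full scale-smoothing windows for all retained valid
  scales); this is exact for every in-cone quantity and can be disabled
  with ``trim_to_coi=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy.ndimage import correlate1d, uniform_filter1d

from .epochs import EpochSet
from .grids import BAND_ORDER, PERIOD_ORDER, TFGrid
from .montage import all_pairs

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class WCConfig:
    """Wavelet and smoothing parameters for the coherence estimator."""

    omega0: float = 6.0
    dj: float = 1.0 / 12.0
    fmin: float = 0.1  # Hz, lower edge of the analysed spectrum
    fmax: float = 30.0  # Hz, upper edge
    time_sd_scales: float = 1.0 / _SQRT2  # time-smoothing SD in units of s
    #: Width of the boxcar across scales.  1.8 octaves gives short
    #: single-trial epochs enough smoothing degrees of freedom for stable
    #: per-trial coherence (see docs/methods.md); 0.6 octaves is the
    #: common long-record choice and remains selectable.
    scale_boxcar_octaves: float = 1.8
    trim_to_coi: bool = True
    #: 'fallback': a divisional cell whose band x period area contains no
    #: in-cone point (geometrically unavoidable for the delta band in the
    #: short pre-stimulus period) is averaged without the COI mask and
    #: flagged; 'strict': such a cell raises.
    coi_policy: str = "fallback"

    def __post_init__(self) -> None:
        if self.omega0 < 5:
            raise ValueError("omega0 must be >= 5 for practical admissibility")
        if not 0 < self.dj <= 0.5:
            raise ValueError("dj must be a small positive octave fraction")
        if not 0 < self.fmin < self.fmax:
            raise ValueError("need 0 < fmin < fmax")
        if self.coi_policy not in ("fallback", "strict"):
            raise ValueError("coi_policy must be 'fallback' or 'strict'")

    @property
    def fourier_factor(self) -> float:
        w0 = self.omega0
        return 4.0 * np.pi / (w0 + np.sqrt(2.0 + w0 * w0))


@dataclass
class WCMap:
    """Squared wavelet coherence for one signal pair of one trial."""

    r2: np.ndarray  # scales x samples, in [0, 1]
    scales: np.ndarray  # seconds, ascending
    freq_axis: np.ndarray  # Hz per scale, descending
    time_axis: np.ndarray  # seconds relative to stimulus onset
    coi: np.ndarray  # per-sample maximum valid Fourier period, seconds
    pair: tuple[str, str] | None = None

    @property
    def valid(self) -> np.ndarray:
        """Boolean scales x samples mask of in-cone cells."""
        period = (1.0 / self.freq_axis)[:, None]
        return period <= self.coi[None, :] + 1e-12


@dataclass
class DivisionalWCMap:
    """4 bands x 4 periods matrix of in-cone mean coherence.

    ``in_cone`` is False for cells averaged without the COI mask because
    their area holds no in-cone point (see ``WCConfig.coi_policy``).
    """

    cells: np.ndarray  # (4 bands, 4 periods)
    n_valid: np.ndarray  # (4, 4) count of averaged cells
    in_cone: np.ndarray | None = None  # (4, 4) bool
    pair: tuple[str, str] | None = None
    bands: tuple[str, ...] = BAND_ORDER
    periods: tuple[str, ...] = PERIOD_ORDER

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cells, index=list(self.bands), columns=list(self.periods))


# ----------------------------------------------------------------------
# smoothing kernels

def triple_box_width(sigma: float) -> int:
    """Odd boxcar width whose three-fold cascade has SD ~ ``sigma`` samples."""
    if sigma <= 0.5:
        return 1
    w = np.sqrt(4.0 * sigma * sigma + 1.0)
    return max(1, int(round((w - 1) / 2)) * 2 + 1)


def composite_time_kernel(width: int) -> np.ndarray:
    """Explicit quasi-Gaussian kernel: boxcar of ``width`` convolved 3x."""
    box = np.ones(width) / width
    return np.convolve(np.convolve(box, box), box)


def scale_boxcar_kernel(octaves: float, dj: float) -> np.ndarray:
    """Boxcar over ``octaves`` of scale with fractional end weights."""
    half = octaves / (2.0 * dj)  # half-width in ladder steps
    k = int(np.ceil(half - 0.5))
    offsets = np.arange(-k, k + 1)
    weights = np.clip(half - np.abs(offsets) + 0.5, 0.0, 1.0)
    return weights / weights.sum()


# ----------------------------------------------------------------------
# engine: precomputed plan for a fixed (fs, n_samples, config, grid)

class WCEngine:
    """Precomputed wavelet filters, smoothing plan and divisional masks.

    Building the plan once and reusing it across trials is what the
    cohort-level loops rely on; all public functions below are thin
    wrappers over an engine instance.
    """

    def __init__(
        self,
        fs: float,
        n_samples: int,
        t0: float = -0.3,
        config: WCConfig | None = None,
        grid: TFGrid | None = None,
        bands: tuple[str, ...] | None = None,
    ) -> None:
        self.config = config or WCConfig()
        self.grid = grid or TFGrid()
        self.fs = float(fs)
        self.n = int(n_samples)
        self.t0 = float(t0)
        cfg = self.config
        all_bands = tuple(self.grid.bands)
        if bands is None:
            self.bands = all_bands
        else:
            unknown = set(bands) - set(all_bands)
            if unknown:
                raise ValueError(f"unknown bands {sorted(unknown)}")
            self.bands = tuple(b for b in all_bands if b in bands)

        lam = cfg.fourier_factor
        # The estimator is per-band separable (the scale ladder only has
        # to cover the analysed bands plus smoothing margins), so a
        # band-restricted engine analyses just that slice of the spectrum.
        span_lo = min(self.grid.bands[b][0] for b in self.bands)
        span_hi = max(self.grid.bands[b][1] for b in self.bands)
        fmin_eff = max(cfg.fmin, span_lo)
        fmax_eff = min(cfg.fmax, span_hi)
        # margin keeping full scale-smoothing windows for retained scales
        margin_oct = cfg.scale_boxcar_octaves / 2.0 + 2.0 * cfg.dj
        f_hi = fmax_eff * 2.0**margin_oct
        if cfg.trim_to_coi:
            # largest scale that is ever inside the cone for this epoch
            s_coi = (self.n / (2.0 * self.fs)) / _SQRT2
            f_lo_core = max(fmin_eff, 1.0 / (lam * s_coi))
        else:
            f_lo_core = fmin_eff
        f_lo = f_lo_core / 2.0**margin_oct
        s_min = max(1.0 / (lam * f_hi), 2.0 / self.fs)
        s_max = 1.0 / (lam * f_lo)
        J = int(np.ceil(np.log2(s_max / s_min) / cfg.dj))
        self.scales = s_min * 2.0 ** (cfg.dj * np.arange(J + 1))
        self.freqs = 1.0 / (lam * self.scales)

        self.time_axis = self.t0 + np.arange(self.n) / self.fs
        # distance to the nearer epoch edge, seconds
        i = np.arange(self.n)
        d_edge = np.minimum(i, self.n - 1 - i) / self.fs
        self.coi_periods = lam * d_edge / _SQRT2  # max valid Fourier period
        self.valid = (1.0 / self.freqs)[:, None] <= self.coi_periods[None, :] + 1e-12

        # Morlet filters on wrap-safe FFT buffers: padding of 6.5 x the
        # scale keeps circular wrap-around below ~1e-9 of the kernel peak,
        # so the result equals exact linear convolution.  Scales are split
        # into groups so small scales use a smaller buffer.
        def _mk_filters(scale_idx: np.ndarray, nfft: int) -> np.ndarray:
            omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0 / self.fs)
            arg = self.scales[scale_idx, None] * omega[None, :]
            filt = (
                np.pi**-0.25
                * np.sqrt(2.0 * np.pi * self.scales[scale_idx, None] * self.fs)
                * np.exp(-0.5 * (arg - cfg.omega0) ** 2)
            )
            filt[:, omega <= 0] = 0.0
            return filt.astype(np.complex64)

        def _nfft_for(s: float) -> int:
            return sp_fft.next_fast_len(
                self.n + int(np.ceil(6.5 * s * self.fs)), real=False
            )

        J1 = len(self.scales)
        s_coi_max = (self.n / (2.0 * self.fs)) / _SQRT2
        split = int(np.searchsorted(self.scales, s_coi_max, side="right"))
        self._cwt_groups: list[tuple[np.ndarray, int, np.ndarray]] = []
        if 0 < split < J1:
            lo = np.arange(split)
            hi = np.arange(split, J1)
            for idx in (lo, hi):
                nf = _nfft_for(self.scales[idx[-1]])
                self._cwt_groups.append((idx, nf, _mk_filters(idx, nf)))
        else:
            idx = np.arange(J1)
            nf = _nfft_for(self.scales[-1])
            self._cwt_groups.append((idx, nf, _mk_filters(idx, nf)))
        self.nfft = max(nf for _, nf, _ in self._cwt_groups)

        # time-smoothing plan: per-scale cascade widths and edge masses;
        # the width is capped at the largest in-cone scale -- wider scales
        # (retained only as scale-smoothing context) keep that boundary
        # kernel instead of growing without bound
        s_cap = (self.n / (2.0 * self.fs)) / _SQRT2 if cfg.trim_to_coi else np.inf
        sigmas = cfg.time_sd_scales * np.minimum(self.scales, s_cap) * self.fs
        self._widths = np.array([triple_box_width(s) for s in sigmas])
        self._masses = np.stack([
            _cascade_mass(int(w), self.n) for w in self._widths
        ]).astype(np.float32)

        # scale-smoothing boxcar: unit weights at offsets |k| <= h plus a
        # fractional end weight, matching scale_boxcar_kernel()
        half_steps = cfg.scale_boxcar_octaves / (2.0 * cfg.dj)
        self._sk_h = max(0, int(np.floor(half_steps - 0.5)))
        self._sk_frac = float(np.clip(half_steps - self._sk_h - 0.5, 0.0, 1.0))
        self._sk_wsum = 2 * self._sk_h + 1 + 2 * self._sk_frac
        skernel = scale_boxcar_kernel(cfg.scale_boxcar_octaves, cfg.dj).astype(
            np.float32
        )
        ones = np.ones(len(self.scales), dtype=np.float32)
        self._smass = correlate1d(ones, skernel, mode="constant", cval=0.0)

        # divisional cell masks: (band, period) -> flattened float mask;
        # cells whose area has no in-cone point fall back to the unmasked
        # area (coi_policy='fallback') and are flagged via in_cone=False
        self._cell_masks = {}
        self.cell_in_cone = {}
        for b in self.bands:
            bmask = self.grid.band_mask(b, self.freqs)
            for p in self.grid.periods:
                pmask = self.grid.period_mask(p, self.time_axis)
                area = bmask[:, None] & pmask[None, :]
                m = self.valid & area
                if not m.any():
                    if cfg.coi_policy == "strict":
                        raise ValueError(
                            f"divisional cell ({b}, {p}) has no in-cone samples"
                        )
                    m = area
                    self.cell_in_cone[(b, p)] = False
                else:
                    self.cell_in_cone[(b, p)] = True
                self._cell_masks[(b, p)] = m
        self._mask_matrix = np.stack(
            [m.reshape(-1) for m in self._cell_masks.values()]
        ).astype(np.float32)
        self._mask_counts = self._mask_matrix.sum(axis=1)

    # -- transforms ----------------------------------------------------
    def cwt(self, x: np.ndarray) -> np.ndarray:
        """Morlet CWT of one or many signals: (..., n) -> (..., J, n)."""
        x = np.asarray(x, dtype=np.float64)
        if not np.all(np.isfinite(x)):
            raise ValueError("signal contains NaN or Inf")
        if x.shape[-1] != self.n:
            raise ValueError(f"expected {self.n} samples, got {x.shape[-1]}")
        out = np.empty(x.shape[:-1] + (len(self.scales), self.n), dtype=np.complex64)
        for idx, nfft, filters in self._cwt_groups:
            X = sp_fft.fft(x, n=nfft, axis=-1).astype(np.complex64)
            prod = X[..., None, :] * filters
            W = sp_fft.ifft(prod, axis=-1, overwrite_x=True)
            out[..., idx, :] = W[..., : self.n]
        return out

    def smooth(self, F: np.ndarray) -> np.ndarray:
        """Time-then-scale smoothing of fields shaped (..., J, n)."""
        if np.iscomplexobj(F):
            return self._smooth_real(F.real) + 1j * self._smooth_real(F.imag)
        return self._smooth_real(F)

    def _smooth_real(self, F: np.ndarray) -> np.ndarray:
        from ._kernels import smooth_scale_boxcar, smooth_time_cascade

        F = np.ascontiguousarray(F, dtype=np.float32)
        squeeze = F.ndim == 2
        if squeeze:
            F = F[None]
        tmp = np.empty_like(F)
        smooth_time_cascade(F, self._widths, self._masses, tmp)
        out = np.empty_like(tmp)
        smooth_scale_boxcar(
            tmp, self._sk_h, self._sk_frac, self._sk_wsum, self._smass, out
        )
        return out[0] if squeeze else out

    # -- coherence -----------------------------------------------------
    def wc_from_cwt(self, Wx: np.ndarray, Wy: np.ndarray) -> np.ndarray:
        inv_s = (1.0 / self.scales[:, None]).astype(np.float32)
        xr = np.ascontiguousarray(Wx.real, dtype=np.float32)
        xi = np.ascontiguousarray(Wx.imag, dtype=np.float32)
        yr = np.ascontiguousarray(Wy.real, dtype=np.float32)
        yi = np.ascontiguousarray(Wy.imag, dtype=np.float32)
        Sxx = self.smooth((xr * xr + xi * xi) * inv_s)
        Syy = self.smooth((yr * yr + yi * yi) * inv_s)
        # cross spectrum from explicit components: the real part is a
        # symmetric expression and the imaginary part exactly negates
        # under argument swap, so WC(x, y) == WC(y, x) bit for bit
        Sre = self.smooth((xr * yr + xi * yi) * inv_s)
        Sim = self.smooth((xi * yr - xr * yi) * inv_s)
        denom = Sxx * Syy
        num = Sre * Sre + Sim * Sim
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(denom > 0, num / denom, 0.0)
        return np.clip(r2, 0.0, 1.0)

    def compute_wc(self, x: np.ndarray, y: np.ndarray, pair=None) -> WCMap:
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        if x.shape != y.shape:
            raise ValueError("signals must have equal length")
        Wx = self.cwt(x - x.mean())
        Wy = self.cwt(y - y.mean())
        r2 = self.wc_from_cwt(Wx, Wy)
        return WCMap(
            r2=r2,
            scales=self.scales.copy(),
            freq_axis=self.freqs.copy(),
            time_axis=self.time_axis.copy(),
            coi=self.coi_periods.copy(),
            pair=pair,
        )

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    def divisional_from_r2(self, r2: np.ndarray, pair=None) -> DivisionalWCMap:
        """Reduce one r2 map to the bands x periods cell means."""
        flat = r2.reshape(-1).astype(np.float32)
        sums = self._mask_matrix @ flat
        shape = (self.n_bands, 4)
        cells = (sums / self._mask_counts).reshape(shape)
        in_cone = np.array(list(self.cell_in_cone.values())).reshape(shape)
        return DivisionalWCMap(
            cells=cells,
            n_valid=self._mask_counts.reshape(shape).astype(int),
            in_cone=in_cone,
            pair=pair,
            bands=self.bands,
        )

    def trial_divisional(self, epoch: np.ndarray) -> np.ndarray:
        """All-pairs divisional cells for one trial: (n_pairs, bands, 4).

        Computes each channel's CWT once and shares a single smoothing
        pass between the auto-spectra and the real/imaginary parts of all
        cross-spectra; the per-pair coherence ratio and the divisional
        reduction then run as batched float32 array operations.
        """
        C = epoch.shape[0]
        J, n = len(self.scales), self.n
        W = self.cwt(epoch - epoch.mean(axis=-1, keepdims=True))
        # fold the 1/s normalisation into the coefficients once
        W *= (1.0 / np.sqrt(self.scales[:, None])).astype(np.float32)
        Wre = np.ascontiguousarray(W.real)
        Wim = np.ascontiguousarray(W.imag)
        del W
        ii, jj = np.triu_indices(C, k=1)
        P = len(ii)
        stack = np.empty((C + 2 * P, J, n), dtype=np.float32)
        from ._kernels import build_cross_stack

        build_cross_stack(Wre, Wim, ii, jj, stack)
        sm = self._smooth_real(stack)
        num = sm[C : C + P]
        np.multiply(num, num, out=num)
        im2 = sm[C + P :]
        np.multiply(im2, im2, out=im2)
        num += im2
        denom = sm[ii] * sm[jj]
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.divide(num, denom, out=num, where=denom > 0)
            r2[denom <= 0] = 0.0
        np.clip(r2, 0.0, 1.0, out=r2)
        sums = r2.reshape(P, -1) @ self._mask_matrix.T
        return (sums / self._mask_counts).reshape(P, self.n_bands, 4)


# ----------------------------------------------------------------------
# functional wrappers (spec-level operations)

@lru_cache(maxsize=8)
def _cached_engine(fs, n, t0, config: WCConfig, grid_key) -> WCEngine:
    return WCEngine(fs, n, t0, config)


def get_engine(fs: float, n: int, t0: float = -0.3, config: WCConfig | None = None) -> WCEngine:
    return _cached_engine(float(fs), int(n), float(t0), config or WCConfig(), None)


def morlet_cwt(
    x: np.ndarray, config: WCConfig | None = None, fs: float = 500.0, t0: float = -0.3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic Morlet CWT: returns (coefficients, scales, frequencies)."""
    x = np.asarray(x, float)
    eng = get_engine(fs, x.shape[-1], t0, config)
    return eng.cwt(x), eng.scales, eng.freqs


def smooth_tf(
    field: np.ndarray,
    config: WCConfig | None = None,
    fs: float = 500.0,
    t0: float = -0.3,
) -> np.ndarray:
    """Time x scale smoothing of a (J, n) field on the engine's ladder."""
    field = np.asarray(field)
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains NaN or Inf")
    eng = get_engine(fs, field.shape[-1], t0, config)
    if field.shape[-2] != len(eng.scales):
        raise ValueError(
            f"field has {field.shape[-2]} scales; ladder has {len(eng.scales)}"
        )
    return eng.smooth(field)


def compute_wc(
    x: np.ndarray,
    y: np.ndarray,
    config: WCConfig | None = None,
    fs: float = 500.0,
    t0: float = -0.3,
    pair=None,
) -> WCMap:
    """Squared wavelet coherence of two equal-length signals."""
    x = np.asarray(x, float)
    eng = get_engine(fs, x.shape[-1], t0, config)
    return eng.compute_wc(x, y, pair=pair)


def divisional_map(
    wcmap: WCMap, grid: TFGrid | None = None, coi_policy: str = "fallback"
) -> DivisionalWCMap:
    """Average a WCMap's in-cone cells over the 4x4 band x period grid.

    Under ``coi_policy='strict'`` a cell whose area contains no in-cone
    point raises, naming the cell; the default falls back to the unmasked
    area mean and flags the cell through ``in_cone``.
    """
    grid = grid or TFGrid()
    cells = np.empty((4, 4))
    n_valid = np.empty((4, 4), dtype=int)
    in_cone = np.ones((4, 4), dtype=bool)
    for bi, b in enumerate(grid.bands):
        bmask = grid.band_mask(b, wcmap.freq_axis)
        for pi, p in enumerate(grid.periods):
            pmask = grid.period_mask(p, wcmap.time_axis)
            area = bmask[:, None] & pmask[None, :]
            m = wcmap.valid & area
            if not m.any():
                if coi_policy == "strict":
                    raise ValueError(
                        f"divisional cell ({b}, {p}) has no in-cone samples"
                    )
                m = area
                in_cone[bi, pi] = False
            cells[bi, pi] = float(wcmap.r2[m].mean())
            n_valid[bi, pi] = int(m.sum())
    return DivisionalWCMap(cells=cells, n_valid=n_valid, in_cone=in_cone, pair=wcmap.pair)


def pairwise_wc(
    epoch: np.ndarray,
    channel_names: tuple[str, ...],
    config: WCConfig | None = None,
    fs: float = 500.0,
    t0: float = -0.3,
) -> list[DivisionalWCMap]:
    """Divisional WC maps for every unordered channel pair of one epoch.

    For the 12-channel montage this yields the 66 canonical pairs in
    index-sorted order.
    """
    epoch = np.asarray(epoch, float)
    eng = get_engine(fs, epoch.shape[-1], t0, config)
    cells = eng.trial_divisional(epoch)
    pairs = all_pairs(tuple(channel_names))
    shape = (eng.n_bands, 4)
    in_cone = np.array(list(eng.cell_in_cone.values())).reshape(shape)
    return [
        DivisionalWCMap(
            cells=cells[k],
            n_valid=eng._mask_counts.reshape(shape).astype(int),
            in_cone=in_cone,
            pair=pairs[k],
            bands=eng.bands,
        )
        for k in range(len(pairs))
    ]


def cohort_divisional_table(
    epochs: EpochSet,
    config: WCConfig | None = None,
    grid: TFGrid | None = None,
    bands: tuple[str, ...] | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """Long-format divisional WC table for every trial and pair.

    Columns: trial, subject, group, stim, pair, band, period, wc, n_valid.
    This is the pipeline's central intermediate product; group statistics
    and classifier features are both views of it.  ``bands`` restricts the
    analysis to a subset of frequency bands (the estimator is per-band
    separable, so a restricted run is simply a narrower scale ladder).
    """
    eng = WCEngine(epochs.fs, epochs.n_samples, epochs.t0, config, grid, bands)
    pairs = all_pairs(epochs.channel_names)
    labels = [f"{a}-{b}" for a, b in pairs]
    n_pairs, n_cells = len(pairs), eng.n_bands * 4
    band_col = np.repeat(list(eng.bands), 4)
    periods = np.tile(list(eng.grid.periods), eng.n_bands)
    nv = eng._mask_counts.astype(int)

    frames = []
    iterator = range(epochs.n_trials)
    if progress:
        from tqdm import tqdm

        iterator = tqdm(iterator, desc="wc")
    for k in iterator:
        cells = eng.trial_divisional(epochs.data[k].astype(np.float64))
        row = epochs.meta.iloc[k]
        frames.append(
            pd.DataFrame(
                {
                    "trial": k,
                    "subject": row["subject"],
                    "group": row["group"],
                    "stim": row["stim"],
                    "pair": np.repeat(labels, n_cells),
                    "band": np.tile(band_col, n_pairs),
                    "period": np.tile(periods, n_pairs),
                    "wc": cells.reshape(-1),
                    "n_valid": np.tile(nv, n_pairs),
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["wc"] = table["wc"].astype(np.float32)
    return table


def plot_wc_map(wcmap: WCMap, ax=None, show_grid: bool = True):
    """Render one pair's coherence map with the cone of influence.

    Time on the x axis, log-frequency on the y axis; the region outside
    the cone is hatched.  Optionally overlays the band/period grid lines.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    mesh = ax.pcolormesh(
        wcmap.time_axis, wcmap.freq_axis, wcmap.r2,
        vmin=0, vmax=1, cmap="jet", shading="nearest",
    )
    coi_freq = 1.0 / np.maximum(wcmap.coi, 1e-6)
    ax.plot(wcmap.time_axis, coi_freq, "w--", lw=1)
    ax.fill_between(
        wcmap.time_axis, coi_freq, wcmap.freq_axis.min(),
        color="none", edgecolor="w", hatch="xx", linewidth=0,
    )
    if show_grid:
        grid = TFGrid()
        for _, hi in list(grid.periods.values())[:-1]:
            ax.axvline(hi, color="k", lw=0.5)
        for lo, _ in list(grid.bands.values())[1:]:
            ax.axhline(lo, color="k", lw=0.5)
    ax.set_yscale("log")
    ax.set_ylim(wcmap.freq_axis.min(), wcmap.freq_axis.max())
    ax.set_xlabel("time re stimulus (s)")
    ax.set_ylabel("frequency (Hz)")
    if wcmap.pair:
        ax.set_title(f"{wcmap.pair[0]}-{wcmap.pair[1]}")
    plt.colorbar(mesh, ax=ax, label="squared wavelet coherence")
    return ax


def _cascade_mass(width: int, n: int) -> np.ndarray:
    """Edge mass of the triple-boxcar cascade on an n-sample window."""
    if width <= 1:
        return np.ones(n)
    halo = 3 * (width - 1) // 2
    ones = np.zeros(n + 2 * halo)
    ones[halo : halo + n] = 1.0
    for _ in range(3):
        ones = uniform_filter1d(ones, size=width, mode="constant")
    return ones[halo : halo + n]
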