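"""Synthetic two-group GKT-EEG generator.

Emulates the statistical structure the downstream analysis assumes for a
guilty-knowledge-test (GKT) experiment: 12-channel 10-20 EEG sampled at
500 Hz, epochs of -0.3 s to +1.3 s around stimulus onset, 1/f-type
background activity, a P300-like centro-parietal deflection for target
responses (both groups) and probe responses of the guilty group only, and
band-limited zero-lag coupling injected on designated electrode pairs
inside a restricted time window -- the deceptive-response signature that
wavelet coherence is meant to detect.

The coupled-source model is variance-preserving mixing into synchronized
assemblies.  Plan entries that carry the same ``source`` tag (and band and
window) share one driver: an independent realisation of band-limited
noise with the same 1/f spectral shape as the background, band edges
widened by the analyser's scale-smoothing half-width.  Inside the window
(50 ms raised-cosine ramps, taper ``g(t)``) every member channel replaces
part of its own in-band background content with the driver,

    x_band <- sqrt(1 - g^2 kappa) * bg_band + g * sqrt(kappa) * sigma_band * s,

so each pair of member channels attains in-band coherence ``kappa`` while
total power is untouched.  The only statistical difference between groups
is therefore the shared component: coherence rises exactly within the
driven assemblies, in the designated band and window, and nowhere else.
(A purely additive burst would also modulate local power, which biases
smoothed coherence on every pair whose channels carry bursts; and
pairwise-independent sources cannot give many edges over 12 channels a
detectable shared fraction, because the channel covariance must remain
positive semi-definite.)  A channel driven by several same-band sources
has its total mixed fraction capped at 0.95, rescaling entry weights
proportionally.

Reproducibility: the master seed is split with ``numpy.random.SeedSequence``
into per-subject streams and those into per-trial streams, so any subject's
data can be regenerated independently of cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .epochs import EpochSet, GROUPS, STIMS
from .grids import DEFAULT_BANDS
from .montage import CHANNELS, CENTRO_PARIETAL, canonical_pair


@dataclass(frozen=True)
class CouplingSpec:
    """One injected coupling: a shared band-limited source on a pair.

    ``kappa`` in [0, 1] is the in-band coherence the pair attains inside
    the window: each channel mixes the shared source in with amplitude
    ``sqrt(kappa)`` of its in-band SD, suppressing its own in-band content
    so variance is preserved.  Entries with the same ``source`` tag, band
    and window share one driver, turning a clique of pairs into one
    synchronized assembly.
    """

    pair: tuple[str, str]
    band: str  # one of delta/theta/alpha/beta
    window: tuple[float, float] = (0.250, 0.600)  # seconds re stimulus
    kappa: float = 0.8
    group: str = "guilty"  # condition the entry applies to
    stim: str = "P"
    source: str | None = None  # shared-driver tag; None = private driver

    def applies(self, group: str, stim: str) -> bool:
        return group == self.group and stim == self.stim


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort-level generator settings.

    Defaults mirror the acquisition and session structure of the emulated
    experiment: 15 subjects per group, 4 sessions with 26 retained probe
    trials each, 500 Hz, 12 channels, epochs -0.3 s to +1.3 s.
    """

    n_subjects_per_group: int = 15
    n_sessions: int = 4
    trials_per_session: dict[str, int] = field(
        default_factory=lambda: {"P": 26, "T": 0, "I": 0}
    )
    fs: float = 500.0
    epoch_window: tuple[float, float] = (-0.3, 1.3)
    channels: tuple[str, ...] = CHANNELS
    background_exponent: float = 1.0  # 1/f^gamma spectral slope
    background_sd: float = 10.0  # microvolts
    erp_amplitude: float = 8.0  # microvolts, P300-like bump peak
    erp_latency_ms: float = 400.0
    erp_width_ms: float = 60.0  # Gaussian SD
    coupling_plan: tuple[CouplingSpec, ...] = ()
    rt_mean_ms: float = 450.0
    rt_sd_ms: float = 80.0
    rt_tail_frac: float = 0.0  # fraction of trials with RT > 700 ms
    click_error_rate: float = 0.0
    #: Amplitude fraction of each driver that is phase-locked across a
    #: subject's trials (evoked); the rest is induced (fresh per trial).
    #: Default 0: fully induced.  Locking adds subject-level dependence
    #: between trials, which weakens trial-pooled group tests.
    driver_locking: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.channels) != CHANNELS:
            raise ValueError("channel list must be the canonical 12-electrode montage")
        if self.n_trials_per_subject < 1:
            raise ValueError("need at least one trial per subject")
        if not 0 <= self.rt_tail_frac <= 1:
            raise ValueError("rt_tail_frac must be in [0, 1]")
        t0, t1 = self.epoch_window
        if not t1 > t0:
            raise ValueError("empty epoch window")
        for spec in self.coupling_plan:
            canonical_pair(*spec.pair)  # validates electrodes
            if spec.band not in DEFAULT_BANDS:
                raise ValueError(f"unknown band {spec.band!r}")
            if not (t0 <= spec.window[0] < spec.window[1] <= t1):
                raise ValueError(
                    f"coupling window {spec.window} outside epoch {self.epoch_window}"
                )
            if not 0 <= spec.kappa <= 1:
                raise ValueError("kappa must be in [0, 1]")
            if spec.group not in GROUPS or spec.stim not in STIMS:
                raise ValueError("coupling condition must name a valid group/stim")

    @property
    def n_samples(self) -> int:
        t0, t1 = self.epoch_window
        return int(round(self.fs * (t1 - t0)))

    @property
    def n_trials_per_subject(self) -> int:
        return self.n_sessions * sum(self.trials_per_session.values())

    @property
    def time_axis(self) -> np.ndarray:
        return self.epoch_window[0] + np.arange(self.n_samples) / self.fs


# ----------------------------------------------------------------------
# building blocks

def one_over_f_noise(
    n: int, fs: float, exponent: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """1/f^gamma noise synthesised in the frequency domain, unit-free SD.

    Amplitudes follow f^(-gamma/2) with a 0.5 Hz low-frequency knee to keep
    the variance finite; phases are random; output is rescaled to ``sd``.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.maximum(freqs, 0.5) ** (-exponent / 2.0)
    amp[0] = 0.0  # no DC
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    s = x.std()
    if s > 0:
        x *= sd / s
    return x


def raised_cosine_window(
    time_axis: np.ndarray, window: tuple[float, float], ramp_s: float = 0.050
) -> np.ndarray:
    """Taper: 1 inside ``window`` with raised-cosine ramps, 0 outside.

    Ramps lie inside the window and are shortened if the window is shorter
    than two ramps.
    """
    w0, w1 = window
    ramp = min(ramp_s, (w1 - w0) / 2.0)
    w = np.zeros_like(time_axis)
    inside = (time_axis >= w0) & (time_axis <= w1)
    w[inside] = 1.0
    if ramp > 0:
        up = inside & (time_axis < w0 + ramp)
        w[up] = 0.5 * (1 - np.cos(np.pi * (time_axis[up] - w0) / ramp))
        down = inside & (time_axis > w1 - ramp)
        w[down] = 0.5 * (1 - np.cos(np.pi * (w1 - time_axis[down]) / ramp))
    return w


#: Source band edges are widened by this many octaves beyond the nominal
#: band so the analyser's across-scale smoothing sees uniformly coherent
#: content throughout the band rather than a mixed band edge.
SOURCE_WIDEN_OCTAVES = 0.45


def _band_sos(band: str, fs: float, widen_octaves: float = 0.0) -> np.ndarray:
    lo, hi = DEFAULT_BANDS[band]
    lo = max(lo / 2.0**widen_octaves, 0.2)  # numerically sane low edge
    hi = min(hi * 2.0**widen_octaves, 0.45 * fs)
    return signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")


def band_limited_source(
    band: str,
    n: int,
    fs: float,
    rng: np.random.Generator,
    widen_octaves: float = SOURCE_WIDEN_OCTAVES,
    exponent: float = 1.0,
) -> np.ndarray:
    """Band-limited noise with the background's 1/f spectral shape, SD 1.

    Matching the background spectrum matters: substituting content with a
    different in-band shape shifts the coherence estimator's smoothing
    bias even without any shared signal.
    """
    pink = one_over_f_noise(n, fs, exponent, 1.0, rng)
    x = signal.sosfiltfilt(_band_sos(band, fs, widen_octaves), pink)
    s = x.std()
    return x / s if s > 0 else x


#: Cap on the total in-band variance fraction a channel may devote to
#: shared drivers; weights of overloaded channels rescale proportionally.
MAX_MIXED_FRACTION = 0.95


def _driver_groups(entries: list[CouplingSpec]) -> list[dict]:
    """Group plan entries into shared-driver assemblies.

    Entries with the same (band, source tag, window) share one driver;
    untagged entries each get a private driver.  Order follows first
    appearance in the plan, keeping the generator bit-reproducible.
    """
    groups: dict[tuple, dict] = {}
    for k, e in enumerate(entries):
        tag = e.source if e.source is not None else f"_private{k}"
        key = (e.band, tag, e.window)
        grp = groups.setdefault(
            key,
            {
                "band": e.band,
                "window": e.window,
                "kappa": e.kappa,
                "tag": tag,
                "channels": [],
            },
        )
        if abs(grp["kappa"] - e.kappa) > 1e-12:
            raise ValueError(f"entries sharing driver {tag!r} must agree on kappa")
        for ch in e.pair:
            if ch not in grp["channels"]:
                grp["channels"].append(ch)
    return list(groups.values())


def subject_evoked_components(
    config: "SyntheticConfig", rng: np.random.Generator
) -> dict:
    """Per-subject phase-locked driver components for every plan entry.

    For each shared-driver assembly one waveform (keyed by band and
    source tag) and, for the matched control, one private waveform per
    member channel.  Drawn once per subject so the evoked part repeats
    across that subject's trials.
    """
    evoked: dict = {}
    if config.driver_locking <= 0:
        return evoked
    for grp in _driver_groups(list(config.coupling_plan)):
        band, window = grp["band"], grp["window"]
        tag = grp["tag"]
        evoked[("shared", band, tag, window)] = band_limited_source(
            band, config.n_samples, config.fs, rng,
            exponent=config.background_exponent,
        )
        for ch in grp["channels"]:
            evoked[("private", band, tag, window, ch)] = band_limited_source(
                band, config.n_samples, config.fs, rng,
                exponent=config.background_exponent,
            )
    return evoked


def _mix_driver(
    stochastic: np.ndarray, locked: np.ndarray | None, phi: float
) -> np.ndarray:
    """Blend a per-trial stochastic driver with a phase-locked component."""
    if locked is None or phi <= 0:
        return stochastic
    return phi * locked + np.sqrt(max(0.0, 1.0 - phi * phi)) * stochastic


def _apply_couplings(
    data: np.ndarray,
    config: "SyntheticConfig",
    entries: list[CouplingSpec],
    rng: np.random.Generator,
    shared: bool = True,
    evoked: dict | None = None,
) -> None:
    """Mix drivers into the assemblies' member channels, in place.

    Per channel and band: the windowed in-band background is suppressed to
    ``sqrt(1 - g^2 sum(kappa))`` of itself and the drivers enter with
    amplitudes ``g sqrt(kappa) sigma_band``, preserving variance.  With
    ``shared=True`` all members of an assembly receive the same driver, so
    every within-assembly pair attains in-band coherence kappa; with
    ``shared=False`` (the matched control applied to conditions the plan
    does not target) each channel receives its own private driver -- the
    marginal process of every channel is identical in distribution to the
    coupled case, so group contrasts isolate pure synchrony.
    """
    t = config.time_axis
    n = config.n_samples
    phi = config.driver_locking
    evoked = evoked or {}
    groups = _driver_groups(entries)
    for grp in groups:
        grp["taper"] = raised_cosine_window(t, grp["window"])
        band, tag, window = grp["band"], grp["tag"], grp["window"]
        if shared:
            stoch = band_limited_source(
                band, n, config.fs, rng, exponent=config.background_exponent
            )
            grp["driver"] = _mix_driver(
                stoch, evoked.get(("shared", band, tag, window)), phi
            )
        else:
            grp["driver"] = {
                ch: _mix_driver(
                    band_limited_source(
                        band, n, config.fs, rng,
                        exponent=config.background_exponent,
                    ),
                    evoked.get(("private", band, tag, window, ch)),
                    phi,
                )
                for ch in grp["channels"]
            }
    bands = sorted({g["band"] for g in groups})
    for band in bands:
        sos = _band_sos(band, config.fs, SOURCE_WIDEN_OCTAVES)
        for c, ch in enumerate(config.channels):
            member = [g for g in groups if g["band"] == band and ch in g["channels"]]
            if not member:
                continue
            total = sum(g["kappa"] for g in member)
            norm = min(1.0, MAX_MIXED_FRACTION / total) if total > 0 else 1.0
            bg_band = signal.sosfiltfilt(sos, data[c])
            sigma = bg_band.std()
            mixed_sq = np.zeros(n)
            mixed = np.zeros(n)
            for g in member:
                kap = g["kappa"] * norm
                driver = g["driver"] if shared else g["driver"][ch]
                mixed_sq += kap * g["taper"] ** 2
                mixed += np.sqrt(kap) * g["taper"] * driver
            suppress = np.sqrt(np.clip(1.0 - mixed_sq, 0.0, None))
            data[c] += (suppress - 1.0) * bg_band + sigma * mixed


def draw_rt_ms(config: SyntheticConfig, rng: np.random.Generator) -> float:
    """Response time in ms: truncated normal body plus a >700 ms tail."""
    if rng.uniform() < config.rt_tail_frac:
        return float(700.0 + rng.uniform(10.0, 250.0))
    rt = rng.normal(config.rt_mean_ms, config.rt_sd_ms)
    return float(np.clip(rt, 80.0, 700.0))


def generate_behavior(
    config: SyntheticConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Draw ``n`` response times and click-correctness flags.

    The configured ``rt_tail_frac`` of draws exceeds 700 ms and
    ``click_error_rate`` of clicks are wrong, so the downstream rejection
    filter has something to reject.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    rts = np.array([draw_rt_ms(config, rng) for _ in range(n)])
    click_ok = rng.uniform(size=n) >= config.click_error_rate
    return pd.DataFrame({"rt_ms": rts, "click_ok": click_ok})


# ----------------------------------------------------------------------
# trial and cohort simulation

def simulate_trial(
    config: SyntheticConfig,
    group: str,
    stim: str,
    rng: np.random.Generator,
    evoked: dict | None = None,
) -> tuple[np.ndarray, dict]:
    """Simulate one epoch: channels x samples array plus trial metadata.

    Background is independent 1/f^gamma noise per channel; a Gaussian
    P300-like bump is added on centro-parietal channels for T trials of
    both groups and for P trials of the guilty group; every coupling-plan
    entry whose condition matches adds its shared tapered source to both
    electrodes of its pair.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    if stim not in STIMS:
        raise ValueError(f"unknown stimulus {stim!r}; expected one of {STIMS}")

    n = config.n_samples
    t = config.time_axis
    data = np.empty((len(config.channels), n), dtype=np.float64)
    for c in range(len(config.channels)):
        data[c] = one_over_f_noise(
            n, config.fs, config.background_exponent, config.background_sd, rng
        )

    entries = [e for e in config.coupling_plan if e.applies(group, stim)]
    control = [e for e in config.coupling_plan if not e.applies(group, stim)]
    if entries:
        _apply_couplings(data, config, entries, rng, shared=True, evoked=evoked)
    if control:
        # matched control: same windowed in-band activation, private
        # drivers, so groups differ only in cross-channel synchrony
        _apply_couplings(data, config, control, rng, shared=False, evoked=evoked)

    erp_present = stim == "T" or (stim == "P" and group == "guilty")
    if erp_present and config.erp_amplitude != 0:
        mu = config.erp_latency_ms / 1000.0
        sd = config.erp_width_ms / 1000.0
        bump = config.erp_amplitude * np.exp(-0.5 * ((t - mu) / sd) ** 2)
        for name in CENTRO_PARIETAL:
            c = config.channels.index(name)
            # amplitude-matched injection: the ongoing activity yields to
            # the evoked deflection so total power stays flat and the
            # deflection does not read as a power burst downstream
            sigma = data[c].std()
            if sigma > 0:
                suppress = np.sqrt(np.clip(1.0 - (bump / sigma) ** 2, 0.0, None))
                data[c] = suppress * data[c] + bump
            else:
                data[c] = data[c] + bump

    rt = draw_rt_ms(config, rng)
    click_ok = bool(rng.uniform() >= config.click_error_rate)
    meta = {"group": group, "stim": stim, "rt_ms": rt, "click_ok": click_ok}
    return data.astype(np.float32), meta


def simulate_cohort(config: SyntheticConfig) -> EpochSet:
    """Simulate both groups, all subjects, all sessions and trials.

    Determinism contract: the same (config, seed) reproduces the cohort
    bit-for-bit; per-subject streams are spawned from the master seed so
    subjects are independent and individually reproducible.
    """
    master = np.random.SeedSequence(config.seed)
    n_subj = config.n_subjects_per_group
    subject_seeds = master.spawn(2 * n_subj)

    arrays: list[np.ndarray] = []
    rows: list[dict] = []
    k = 0
    for gi, group in enumerate(GROUPS):
        for s in range(n_subj):
            subject = f"{'g' if group == 'guilty' else 'i'}{s + 1:02d}"
            subj_ss = subject_seeds[gi * n_subj + s]
            streams = subj_ss.spawn(config.n_trials_per_subject + 1)
            evoked = subject_evoked_components(
                config, np.random.default_rng(streams[-1])
            )
            ti = 0
            for session in range(config.n_sessions):
                for stim, count in config.trials_per_session.items():
                    for _ in range(count):
                        rng = np.random.default_rng(streams[ti])
                        ti += 1
                        arr, meta = simulate_trial(config, group, stim, rng, evoked)
                        arrays.append(arr)
                        meta.update(subject=subject, session=session + 1, trial=k)
                        rows.append(meta)
                        k += 1
    data = np.stack(arrays) if arrays else np.empty((0, 12, config.n_samples))
    meta = pd.DataFrame(rows)
    return EpochSet(
        data=data,
        fs=config.fs,
        t0=config.epoch_window[0],
        channel_names=config.channels,
        meta=meta,
    )


# ----------------------------------------------------------------------
# designated pair sets and presets
#
# The designated connection sets are synchronized assemblies (cliques of
# electrodes sharing one driver) whose within-clique pair counts echo the
# published network sizes: theta 10+6+1 = 17 connections dominated by
# central/frontal/parietal links, beta 6+1 = 7 anchored on posterior
# sites, delta 3 weak occipital/frontal links.  Assemblies within a band
# are disjoint, so no electrode splits its in-band budget across drivers.

THETA_CLIQUES: tuple[tuple[str, ...], ...] = (
    ("C3", "Cz", "C4", "P3", "Pz"),  # centro-parietal assembly (P300 sites)
    ("Fp1", "Fp2", "F3", "F4"),
    ("Fz", "Oz"),
)

BETA_CLIQUES: tuple[tuple[str, ...], ...] = (
    ("Oz", "C3", "P3", "P4"),
    ("Cz", "Pz"),
)

DELTA_CLIQUES: tuple[tuple[str, ...], ...] = (("Oz", "C3", "Fp2"),)


def clique_pairs(
    cliques: tuple[tuple[str, ...], ...]
) -> tuple[tuple[str, str], ...]:
    """All within-clique electrode pairs, canonically ordered."""
    pairs = []
    for clique in cliques:
        for i in range(len(clique)):
            for j in range(i + 1, len(clique)):
                pairs.append(canonical_pair(clique[i], clique[j]))
    return tuple(sorted(pairs, key=lambda p: (CHANNELS.index(p[0]), CHANNELS.index(p[1]))))


THETA_PAIRS_17 = clique_pairs(THETA_CLIQUES)  # 10 + 6 + 1
BETA_PAIRS_7 = clique_pairs(BETA_CLIQUES)  # 6 + 1
DELTA_PAIRS_3 = clique_pairs(DELTA_CLIQUES)

RECOVERY_WINDOW = (0.250, 0.600)


def _plan(
    cliques, band, kappa, window=RECOVERY_WINDOW
) -> tuple[CouplingSpec, ...]:
    entries = []
    for k, clique in enumerate(cliques):
        tag = f"{band}-assembly{k}"
        for i in range(len(clique)):
            for j in range(i + 1, len(clique)):
                entries.append(
                    CouplingSpec(
                        pair=canonical_pair(clique[i], clique[j]),
                        band=band,
                        window=window,
                        kappa=kappa,
                        source=tag,
                    )
                )
    return tuple(entries)


def null_preset(seed: int = 0, trials_per_subject: int = 20) -> SyntheticConfig:
    """No coupling anywhere and no evoked response: the pure null generator.

    The P300-like bump is disabled because a group-specific deterministic
    deflection is itself a coherence source on centro-parietal pairs --
    with it, guilty and innocent trials would not be exchangeable.
    Behavioural rejections are off, so the analysed trial counts equal
    the generated ones.
    """
    return SyntheticConfig(
        n_sessions=1,
        trials_per_session={"P": trials_per_subject},
        coupling_plan=(),
        erp_amplitude=0.0,
        seed=seed,
    )


def theta_recovery_preset(seed: int = 0, kappa: float = 0.8) -> SyntheticConfig:
    """Strong theta-band coupling on the 17 designated connections.

    Guilty-P trials additionally carry the P300-like evoked deflection on
    the centro-parietal sites; those five electrodes form the largest
    designated assembly, so the evoked synchrony reinforces designated
    pairs without touching any non-designated pair.
    """
    return replace(
        null_preset(seed),
        erp_amplitude=8.0,
        coupling_plan=_plan(THETA_CLIQUES, "theta", kappa),
    )


def beta_recovery_preset(seed: int = 0, kappa: float = 0.8) -> SyntheticConfig:
    """Strong beta-band coupling on the 7 designated connections."""
    return replace(
        null_preset(seed),
        erp_amplitude=8.0,
        coupling_plan=_plan(BETA_CLIQUES, "beta", kappa),
    )


def strong_preset(seed: int = 0) -> SyntheticConfig:
    """Graded multi-band effect mirroring the published network ordering.

    Theta coupling is strongest (17 connections), beta intermediate (7),
    delta weakest (3); the alpha band carries nothing.  The delta
    coupling spans 250-1300 ms: slow-wave synchrony persists through the
    response -- a 350 ms window holds barely one delta cycle, far below
    the estimator's resolution.  Classifiers trained on the resulting
    band networks order theta > beta > delta in accuracy.
    """
    return replace(
        null_preset(seed),
        coupling_plan=(
            _plan(THETA_CLIQUES, "theta", 0.8)
            + _plan(BETA_CLIQUES, "beta", 0.35)
            + _plan(DELTA_CLIQUES, "delta", 0.55, window=(0.25, 1.3))
        ),
    )
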