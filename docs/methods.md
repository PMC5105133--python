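# Methods

`lfcnet` analyses multichannel EEG from a guilty-knowledge-test (GKT)
paradigm at the single-trial level.  The chain is: epoch screening and
baseline correction → squared wavelet coherence (WC) between all 66
electrode pairs of a 12-channel 10–20 montage → reduction of each WC map
to a 4-band × 4-period "divisional" grid → trial-pooled group statistics
with FDR correction → a per-band network of "lying connections" → an
RBF-SVM classifying guilty vs. innocent trials from per-trial coherence
features.  A synthetic cohort generator provides ground-truth data with
the statistical structure every stage assumes.

## Epochs, periods, bands

Epochs span −0.3 s to +1.3 s around stimulus onset at 500 Hz (800
samples).  Sample *i* maps to time `t0 + i/fs`; all intervals are
left-closed/right-open, so a boundary sample belongs to the later
period.  The four analysis periods are pre-stimulus 1# (−300–0 ms),
pre-processing 2# (0–250 ms), P300-processing 3# (250–600 ms) and
post-response 4# (600–1300 ms); the four bands are δ (0.1–4 Hz),
θ (4–8 Hz), α (8–13 Hz), β (13–30 Hz).

Trial screening keeps trials with a correct button press, response time
≤ 700 ms, and |amplitude| ≤ 75 μV on every channel.  The historical
expert judgement "does this subject show a P300 in target responses?" is
an operational rule here: the subject is excluded when the peak of the
target-trial average inside 250–600 ms on Pz/P3/Cz stays below a
configurable threshold (default 2 μV; tests that screen noisy averages
choose an operating point above the noise floor of their trial count).

## Wavelet coherence estimator

For signals *x*, *y* (per-epoch mean removed):

R²(s,t) = |S(W_xy/s)|² / [ S(|W_x|²/s) · S(|W_y|²/s) ],

with W the analytic Morlet CWT (central frequency ω₀ = 6), W_xy the
cross-spectrum, and S a smoothing operator in time and scale.  Without S
the ratio is identically 1; S defines the estimator's degrees of freedom
(DOF).

* **Scales.** Dyadic ladder `s_j = s_min·2^(j·dj)`, `dj = 1/12` octave.
  The equivalent Fourier frequency is `1/(λs)` with
  `λ = 4π/(ω₀+√(2+ω₀²)) ≈ 1.033`.  The analysed spectrum spans
  0.1–30 Hz; scales whose cone of influence (below) never intersects the
  epoch are trimmed after a margin that keeps full scale-smoothing
  windows for every retained in-cone scale (`trim_to_coi=False` restores
  the full ladder).  For the 1.6 s epoch this means the ladder starts
  near 1.7 Hz — lower frequencies cannot be estimated on such an epoch
  at all.
* **CWT.** FFT convolution on a buffer padded by 6.5× the largest scale,
  making the result equal to exact linear convolution to ~1e−9; a
  direct-convolution reference in the test suite reproduces the fast
  path to < 1e−6 elementwise.
* **Time smoothing.** Quasi-Gaussian kernel of SD `s/√2` samples (the
  e-folding time of the Morlet autocorrelation), realised as three equal
  boxcars in cascade and applied as a mass-renormalised convolution with
  zero boundary, so constants are preserved and nonnegativity is kept.
  The cascade runs in O(n) per scale regardless of width, which is what
  makes 66 pairs × hundreds of trials tractable; the kernel width is
  capped at the largest in-cone scale (wider scales exist only as
  scale-smoothing context).
* **Scale smoothing.** Boxcar of **1.8 octaves** with fractional end
  weights, edge-renormalised.  The published long-record default is
  0.6 octaves; on a 1.6 s single-trial epoch that leaves ~3 effective
  DOF, a null-coherence bias around 0.4 and per-trial cell SDs that
  drown the attainable group contrasts.  Tripling the octave width
  raises DOF without sacrificing time resolution (band-limited coupling
  occupies its whole band, so smoothing across scales does not dilute
  it).  Monte-Carlo calibration on held-out seeds puts per-connection
  detection at t ≈ 4.5 under the recovery protocol (vs. ≈ 3.4 at
  1.2 octaves, which loses 2–3 connections per cohort).  `WCConfig`
  exposes the width.
* **Cone of influence (COI).** A cell (s, t) is edge-contaminated when
  `√2·s` exceeds the distance from t to the nearer epoch edge.
  Divisional cells average only in-cone values and report the count.
  One cell is geometrically empty at the defaults: δ × 1# — the maximum
  valid period anywhere in a 300 ms pre-stimulus stretch is ~0.22 s
  (≥ 4.6 Hz), above the whole δ band.  The default policy
  (`coi_policy="fallback"`) averages that cell without the COI mask and
  flags it (`in_cone=False`); `"strict"` raises instead.  Because the
  contamination is identical for both groups, group contrasts on the
  fallback cell remain meaningful, but its absolute level should not be
  interpreted.

Numerics: trial-level computation runs in float32 with float64 running
sums; symmetry `WC(x,y) = WC(y,x)` is exact to the bit because the
cross-spectrum is assembled from explicit real/imaginary products
(complex multiplication with FMA is not exactly conjugate-symmetric).
R² is clipped to [0,1] against floating-point overshoot.  The estimator
is per-band separable, so a band-restricted run simply uses a narrower
scale ladder (discrete scale positions then differ slightly from the
full ladder's).

## Group statistics and selection

Per electrode pair and band × period area, per-trial divisional WC
values pool across subjects by group and are compared with a
pooled-variance two-sample t-test (trials are the sampling unit; 1560
trials per group give df = 3118).  The 66 pairs of one area form one
Benjamini–Hochberg family at q = 0.05 (a global-family option exists;
the per-area family matches how the matrices are reported).  Rejection
follows the step-up rule on raw p-values, which equals "corrected
p < q" except on exact boundaries.  M1 and M3 are the binary 12×12
significance matrices of periods 1# and 3#; the selected lying
connections are `L = (¬M1) ∧ M3` — pairs that differ during P300
processing but not at rest.  Δ1/Δ3 are guilty-minus-innocent mean WC
differences in the two periods.

Caveat stated openly: pooling trials ignores subject nesting; the
printed df forces that choice, and the generator's default drivers are
trial-independent, so the synthetic calibration is internally
consistent.  Mixed-effects modelling is out of scope.

## Networks and classification

The per-band lying functional connectivity network (LFCN) keeps the
selected connections with Δ3 > 0, weighted by Δ3, sorted by descending
weight with canonical pair order breaking ties.  An empty network is a
valid outcome (a band whose selected connections all weaken under
deception is simply not drawn).  Electrodes group into scalp regions
(frontal F3/Fz/F4, prefrontal Fp1/Fp2, their union as the "joint F
region", left/middle/right central C3/Cz/C4, left/middle/right parietal
P3/Pz/P4, occipital Oz).

Classification: one feature per network connection — the trial's
3#-period, band-specific divisional WC on that connection.  An RBF-SVM
with C ∈ 2⁻⁵…2⁵ (11 values) and γ ∈ 2⁻⁵…2¹² (18 values) is tuned per
outer fold by stratified 5-fold CV inside the training fold (ties break
toward the smallest C, then γ), refit on the training fold, and
evaluated over stratified 10-fold CV on trials.  Features are
standardised with training-fold statistics only.  Sensitivity is the
fraction of guilty trials classified guilty; "training" rates are
resubstitution on the training fold.  Folds stratify by class over
trials; a subject-grouped option exists behind a flag.

## Synthetic cohort generator

The generator emulates the acquisition and session structure (15
subjects per group, 4 sessions × 26 retained probe trials at the
defaults; recovery presets use 1 session × 20 trials), with:

* **Background.** Independent per-channel 1/f^γ noise (γ = 1, SD 10 μV)
  synthesised in the frequency domain with random phases and a 0.5 Hz
  knee.
* **Evoked response.** A Gaussian P300-like deflection (8 μV, latency
  400 ms, SD 60 ms) on the centro-parietal channels C3/Cz/C4/P3/Pz for
  target trials of both groups and probe trials of the guilty group.
  Injection is amplitude-matched — ongoing activity is scaled by
  `√(1−(b/σ)²)` where the deflection b is added — so the evoked wave
  does not register as a power burst (a plainly added bump measurably
  biases coherence on centro-parietal × other pairs at cohort sample
  sizes).
* **Coupling.** Designated connections are *synchronized assemblies*:
  cliques of electrodes sharing one band-limited driver.  θ: a
  centro-parietal 5-clique, a prefrontal/frontal 4-clique and a Fz–Oz
  pair (10+6+1 = 17 connections); β: a posterior 4-clique plus Cz–Pz
  (7); δ: an Oz/C3/Fp2 triangle (3).  Inside the coupling window (50 ms
  raised-cosine ramps) each member channel replaces part of its in-band
  content with the driver:
  `x_band ← √(1−g²κ)·own + g·√κ·σ_band·s`, giving every within-assembly
  pair in-band coherence κ while preserving total power.  Drivers carry
  the background's 1/f spectral shape (a flat-spectrum source shifts the
  estimator's bias by itself) and their band edges widen by 0.45 octave
  so scale smoothing sees uniformly coherent content across the band.
  Conditions the plan does not target receive the same windowed
  activation with private per-channel drivers (matched control), so the
  group contrast isolates synchrony.  Channels serving several same-band
  drivers cap their total mixed fraction at 0.95.

  Why cliques: with 12 channels, 17 simultaneous pairwise-independent
  couplings cannot all be strong — the channel covariance must stay
  positive semi-definite, which caps designated-edge coherence near
  1/|λ_min| of the designated adjacency (≈ 0.4), below the estimator's
  detection floor.  Cliques driven by a common source reach ρ = κ on
  every internal pair with exactly zero off-clique coherence, and are
  the more natural model of a synchronized neural assembly.
* **Behaviour.** Truncated-normal response times (450 ± 80 ms) with a
  configurable > 700 ms tail fraction and click-error rate, so the
  rejection filter has work; recovery presets set both to zero so the
  analysed trial counts equal the generated ones.
* **Reproducibility.** `SeedSequence` hierarchy master → subject →
  trial; identical (config, seed) reproduces a cohort bit-for-bit.

Presets: `null_preset` (no coupling, no evoked response — with a
group-specific P300 the groups would not be exchangeable),
`theta_recovery_preset` / `beta_recovery_preset` (κ = 0.8 coupling on
the designated sets, 250–600 ms, evoked response on), and
`strong_preset` (θ κ = 0.8, β κ = 0.35, δ κ = 0.55 with the δ window
extended to 250–1300 ms — a 350 ms window holds barely one δ cycle, far
below the estimator's resolution, so persistent slow-wave synchrony is
the only δ effect the estimator can see; evoked response off so the
band ordering reflects induced synchrony alone).

### What the generator does and does not emulate

It reproduces the *statistical* structure the analysis assumes:
1/f background, a centro-parietal evoked deflection, band- and
window-limited inter-channel synchrony, behavioural rejections, session
counts.  It does not model volume conduction (real scalp EEG has high
baseline inter-channel coherence; the synthetic baseline is the
estimator's null bias, ≈ 0.2–0.3), EOG or movement artifacts,
electrode impedance, countermeasures, or non-stationarities beyond the
coupling window.  Passing recovery tests therefore demonstrates that
the pipeline detects and localises genuine synchrony differences at
realistic SNR — not that real recordings would yield the same numbers.

### Known limitation: single-trial classification ceiling

The classification targets inherited from the emulated study (≈ 94%
test sensitivity/specificity for the θ model) are not reachable in this
generator at κ = 0.8: a single trial offers a 350 ms × 4 Hz-wide
time-frequency patch, i.e. ~2–3 independent estimator footprints, so a
per-connection feature separates the groups at d′ ≈ 0.6, and 17
features of effective rank ≈ 3 (three assemblies) cap balanced accuracy
near 80%.  Group-level selection is unaffected (300 trials per group
average the noise away; per-connection t ≈ 4.5), which is why exact
connection-count recovery coexists with moderate single-trial accuracy.
On real EEG, evoked-response morphology and volume-conduction structure
provide additional per-trial information that this stationary-noise
generator deliberately does not fabricate.

## Problem sizes used by the test suite

Recovery checks run the full protocol: 5 cohorts per band of 15+15
subjects × 20 trials; null control runs 5 cohorts of 15+15 × 12 trials;
the strong-preset ordering check runs one 15+15 × 20 cohort.  These sizes are the package's
standard demonstration scale; the generator accepts any cohort size.
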