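# Methods

This note documents the models behind each stage, the parameters that
matter, the design choices made where the design was genuinely open, and
what the synthetic data can and cannot show.

## Signal model and synthetic data

An AE recording is modelled as the convolution chain
`V(t) = S(t) * G(t) * R(t)`: a source event train, the propagation medium
and the acquisition electronics, the latter two lumped into one linear
impulse response. The generator renders this chain per class:

* **Event train** — Poisson or jittered-periodic onsets at `burst_rate`
  events/s. Periodic trains (jitter as a fraction of the period) model
  the reciprocating contact of sliding-wear rigs; Poisson models the
  irregular dense activity of advanced scratching.
* **Burst** — asymmetric-exponential envelope
  `(1 − e^(−t/τ_rise)) · e^(−t/τ_decay)` (short rise, peak, longer decay)
  multiplying a unit-RMS carrier: band-passed white noise (4th-order
  Butterworth) for the rough signatures, a fixed tone with random phase
  for the smoother adhesive signature. Broadband carriers additionally
  carry a narrow spectral-peak component (the same white-noise draw
  filtered through a ±5 % band around a class-specific frequency),
  emulating the dominant structural modes each wear mechanism excites —
  the feature-ranking results only make sense if per-class spectra have
  stable distinctive peaks, which is also what the frequency-led ranking
  on the real data implies.
* **Per-event amplitude** — log-normal with median `amplitude_scale` and
  sigma `amplitude_dispersion` (mean-corrected so the scale is the
  median), keeping the noise-free render exactly linear in
  `amplitude_scale`.
* **Instrument** — a unit-peak-gain second-order resonator at 300 kHz.
  Damping 0.3: a broad resonance that colours every burst without
  erasing the carrier-band differences between classes (a high-Q
  resonance would make all classes spectrally identical at the output,
  which contradicts both the class phenomenology and the observed
  dominance of frequency features).
* **Nuisances** — white Gaussian noise of `noise_sigma` volts plus
  class-independent interference clicks (sparse broadband transients fed
  through the same sensor; Poisson at 150/s, log-normal amplitudes with
  median 25·`noise_sigma`). Both scale with the documented `difficulty`
  scalar; at difficulty 0 the render is nuisance-free. Tying the click
  amplitude to `noise_sigma` keeps the contract "noise_sigma = 0 implies
  a clean render" intact.

Concrete class profiles (one registry, all overridable): burst rates
100/100/400/400/700 per second, amplitude scales 1.0/0.45/0.5/0.85/1.6,
carrier bands inside the 100–600 kHz acquisition band with spectral peaks
at 380/260(tonal)/160/220/300 kHz, for abrasive / adhesive / burnishing /
transition / scratching respectively. These numbers are the package's own
calibration: only the orderings between classes (adhesive quieter and
smoother than abrasive; burnishing far denser in events; the transition
slightly louder than burnishing; scratching loudest and densest) are
externally constrained.

Two presets: **paper** (2 MHz, 0.5 s records → 1,000,000 samples) and
**desk** (all frequencies ÷10, time constants ×10, 200 kHz, 0.1 s). The
desk preset is used throughout the test suite and the acceptance script so
simulations complete in seconds; the problem sizes reported there
(20 recordings of 20,000 samples, 10 windows of 2,000 samples each) are
the package's default study size at that preset.

What the generator does **not** emulate: session-to-session drift
(temperature, coupling, load), multi-path propagation and attenuation,
nonstationary interference, hit-based triggering, and any genuine
tribological contact mechanics. Passing tests therefore demonstrate the
correctness and the qualitative behaviour of the pipeline, not clinical or
tribological validity on real joints.

## Windowing

Disjoint equal slices: `n_windows` contiguous windows of
`floor(L/n_windows)` samples, trailing remainder dropped (the nominal
1,000,000/10 divides evenly, so the truncation rule only matters for
irregular lengths). No overlap, no threshold-triggered segmentation.

## Handcrafted features

Computed on raw (unnormalised) windows so the 1 µV threshold retains its
physical meaning. Conventions worth stating:

* **WL** is the plain cumulative absolute difference; the tabulated
  threshold applies to the event-counting features ZC, SSC and NP only
  (a gated waveform length is nonstandard and no gating rule exists).
* **ZC** counts sign changes whose step exceeds the threshold; **SSC**
  counts slope-polarity changes whose larger adjacent step exceeds it;
  **NP** counts strict local maxima at or above it.
* **AR(4)** by the Burg lattice recursion on the demeaned window,
  prediction convention `x_t ≈ Σ a_k x_{t−k}`; all four coefficients are
  emitted (`ar_emit="last"` reduces to the fourth). Constant input yields
  zeros.
* **SampEn**: m = 2, tolerance 0.2·SD of the window, Chebyshev distance,
  self-matches excluded, the same N−m templates for both lengths;
  degenerate input (zero variance, or no matches) returns 0. The
  template-distance computation is blocked over rows so memory stays
  bounded on long windows.
* **Ceps** is the maximum of the real cepstrum over quefrencies 1..N/2
  (quefrency 0 is overall log-energy); spectra are floored at the
  smallest positive double before the log.
* **MF/PF** from a Welch PSD (Hann, 50 % overlap). The default segment
  length is adaptive — about a quarter of the window, capped at 4096 —
  giving the ~8-segment averaging practitioners get from default Welch
  settings at full scale; a fixed segment length and a bare periodogram
  remain available. MF is the smallest frequency where the cumulative
  PSD reaches half the total power. All-zero windows map to
  MF = PF = Ceps = 0.
* **DFA**: integrate the mean-removed window, first-order detrend per
  non-overlapping box, slope of log F(n) vs log n over boxes 30:10:300.
  An error is raised when the largest box exceeds half the window (the
  stricter quarter-window guideline is advisory; the operation contract
  governs).
* **MFL** floor: a flat window would give log10(0); it is floored at
  log10 of the smallest positive normal double so vectors stay finite.

Every feature is verified against an independently written brute-force
oracle (explicit loops, cdist-based counting, a written-out single-segment
Welch estimator) at 1e-12 relative tolerance, and the fractal/AR features
against known exponents (DFA α of 0.5/1.5 for white/integrated noise,
Higuchi dimension 1/2 for line/white noise, AR(1) coefficient recovery).

## Wavelet scattering

Analytic Gabor (Gaussian-in-frequency) wavelets built directly on the FFT
grid of the reflection-padded window; non-positive frequencies are zeroed,
so the filters have no DC response. Centre frequencies descend
geometrically at `2^(1/Q)` from just below Nyquist down to `2·fs/N` (about
two oscillations per window) — reaching low enough that the second-order
bank covers the burst-rhythm band, which carries most of the
class-discriminative modulation. Bandwidths put adjacent crossings near
−3 dB; each bank is then made tight by the pointwise normalisation
`ψ̂ /= sqrt(max(L, 1/4))` with `L` the raw Littlewood–Paley sum, so energy
preservation holds exactly over the covered band while the filters stay
smooth. The averaging low-pass is a Gaussian whose time support is the
nominal 1 s invariance scale capped at the window duration (a longer
support is ill-posed; a warning is emitted and pooling then amounts to one
value per path). Second-order paths follow the frequency-decreasing rule
(centre of the second wavelet below the −3 dB full width of the first).
Convolutions are frequency-domain products on the padded grid, cropped
back; no subsampling is applied (full time resolution until pooling), so
the `oversampling` knob is accepted for interface compatibility but has no
effect.

The transform itself emits raw pooled coefficients, and the metric
properties (non-expansiveness, translation stability, order-wise energy
decay, equivalence with an explicit per-path oracle) are asserted on that
raw output. The classification pipeline applies the customary log stage
by default: pooled path amplitudes span orders of magnitude, and the
compressed scale measurably improves most classifiers — the standard
practice in scattering-based classification.

## Benchmark

Twelve fixed configurations mapped from the common interactive-tool
presets: CART/Gini tree capped at 100 splits; pooled-covariance LDA;
kernel naive Bayes (per-feature Gaussian KDE, Silverman bandwidth —
implemented in-package, scikit-learn has no such estimator); SVMs with
box constraint 1, one-vs-one, linear / quadratic / cubic polynomial
(coef0 = 1) and Gaussian kernels at scales √P/4, √P, 4√P (P = feature
count); Euclidean KNN at k = 1, 10, 100. Features are z-scored inside a
pipeline so scaling is fit on training folds only (a leakage-guard test
perturbs held-out rows and asserts the CV statistics are untouched).

The protocol performs a stratified 80:20 outer split; the held-out
accuracy on the 20 % is the headline number, and a stratified 10-fold CV
accuracy inside the 80 % is reported alongside (the source tables do not
say which of the two they print, so both are labelled). Aggregation is
mean ± **population** standard deviation (divide by N) — the convention
verified to reproduce the published "mean across all models" cells
exactly at printed precision.

Two small-sample caveats, deliberate and documented: the coarse KNN
(k = 100) needs more than ~50 training windows per class before its
neighbourhood vote can avoid cross-class ties, and the fine-Gaussian SVM
kernel (scale √P/4) is close to degenerate on high-dimensional feature
sets — its dip on scattering features mirrors the same model's dip in the
published table.

## ReliefF

Multiclass ReliefF: all instances, k = 10 nearest hits and per-class
misses by Manhattan distance on range-normalised features, miss
contributions weighted by the class prior renormalised over the other
classes. Deterministic (no sampling); ties in neighbour distance break by
instance order. Binary Relief does not extend to five classes, hence the
multiclass variant. Weights are invariant to positive rescaling of any
feature column (range normalisation), verified property-wise, and the
whole computation is checked against an explicit double-loop oracle at
1e-12.

## Experiment driver

`run_experiment(config)` chains simulate → window → both feature banks →
benchmark → ReliefF → 2-component PCA of the scattering features, writing
CSV outputs plus a `run.json` with the config hash. Everything downstream
of the master seed is deterministic; reruns produce byte-identical CSVs.
PCA projects all five classes by default (subsetting is the caller's
choice).

## Numerical and degenerate-input conventions

Fixed class order (enum order) everywhere; per-record seeds drawn from one
master generator; welch detrending is constant (scipy default) and the
test oracles reproduce it explicitly; scattering pooled values are clipped
at 0 against −1e−16-scale float residue; the log feature stage uses
log(1e−12 + v). Errors are raised (not silently corrected) for invalid
bands, non-finite samples, class-starved stratification and oversized DFA
boxes.

## Known limitations

* The synthetic conditions put both feature pipelines within a few points
  of each other; the scattering advantage appears as a majority across
  seeds (and grows with difficulty), not as the wide margin seen on the
  real recordings — real-data complexity (drift, heterogeneity) is what
  the generator does not reproduce.
* SampEn on full-rate 100,000-sample windows is an O(N²) computation
  (minutes per window); the desk preset exists precisely so the default
  study completes in seconds.
* The scattering implementation keeps full time resolution through the
  cascade; memory scales with (paths × padded window length), which is
  fine at desk scale and acceptable at full rate, but a subsampled
  implementation would be needed for much longer windows.
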