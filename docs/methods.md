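# Methods

## The measurement model

The toolkit treats figure-tracking behavior as a quasilinear two-input
system. A figure (a textured window on a panoramic binary background) is
displaced in ±1-pixel steps; the texture inside the window is displaced
independently. The steering output y (ΔWBA, arbitrary units, positive =
rightward effort) is modelled as the superposition of an elementary-motion
(EM) stream driven by texture steps Δ_EM and a figure-motion (FM) stream
driven by window steps Δ_FM:

    y(t) = Σ_τ G_FM(t−τ, γ(τ))·Δ_FM(τ) + Σ_τ G_EM(t−τ, γ(τ))·Δ_EM(τ)
         + Σ_{θ} G_FM(t, θ)·Δ_F(θ),          θ on the pixel arc 0 → γ(0)

G_EM is an impulse response (decays to zero); G_FM is an *incremental step
response* that may hold a nonzero value indefinitely, which is how a
position-holding ("fixation") component appears in a velocity-step
formalism. The initial-position sum makes the response of a figure held
away from front center equal the azimuthal cumulative sum of the FM
asymptote — front center is by definition the azimuth of zero figure-evoked
effort.

Conventions that matter and are fixed package-wide:

* Azimuth γ: 0° at front center, positive clockwise, wrapped to
  (−180°, 180°]. Display: 96 pixels × 3.75° = 360° (the physical arena's
  rear access gap is metadata only).
* Frame τ = 0 is the pre-motion state; the step stored at frame t acts
  between frames t−1 and t.
* **Step attribution**: every step is attributed to the azimuth the figure
  occupied *before* the step. This is not cosmetic: because position is the
  running integral of the FM drive, attributing steps to the landing pixel
  couples the kernel's spatial gradient to products of sequence lags
  (m-sequence "shift-and-multiply" third-order structure) and biases
  recovered kernels on spatial flanks by roughly (excursion scale) ×
  (local spatial slope); measured on a linear spatial ramp the pre-step
  convention reduces this bias about threefold.
* Beyond the sampled kernel span, EM kernels are zero and FM kernels hold
  their final value (step responses persist).
* Bits map to steps as 1 → +1 px, 0 → −1 px.

## m-sequences

Order-n m-sequences are generated by a Fibonacci LFSR whose characteristic
polynomial is primitive over GF(2); taps are the polynomial's nonzero
exponents, output from the last stage, bit recurrence
a_t = a_{t−n} ⊕ (⊕_{e∈taps, e<n} a_{t−(n−e)}). Primitivity is validated
empirically: the register must first revisit its seed after exactly
2^n − 1 shifts (at these orders a maximal period is equivalent to
primitivity). A built-in table carries two polynomials per degree 3–10 so
distinct-sequence pairs need no search; `all_primitive_taps(7)` enumerates
all 18 degree-7 polynomials exhaustively.

The properties the estimators rely on, each covered by tests: balance
(net sum ±1, so one period displaces the figure exactly one pixel),
circular autocorrelation p at lag 0 and −1 elsewhere, and small
cross-correlation between distinct sequences (max |c| = 17 for the built-in
order-7 pair, vs the 127 peak). Sequences of length 127–255 keep the
within-period excursion small — median SD 3.13 px (≈ 12°) across all
degree-7 polynomials from the all-ones seed — so kernels sample an
approximately linear neighborhood of their centroid azimuth.

## Estimators

Protocol: paired runs with (m_FM, +m_EM) and (m_FM, −m_EM), identical m_FM.
Each run spans `n_periods` periods (default 4); the first period is
discarded as transient and the rest are averaged, so analysis operates on
one periodic steady-state cycle and circular correlation algebra is exact.
Cross-correlations are normalized by p + 1 (the autocorrelation is
(p+1)δ − 1, so a pure-delay system recovers a unit peak up to O(1/p)); the
divisor is configurable ("p") for comparison with other conventions.

**EM kernel.** u_EM = ½[m_EM ⋆ ȳ1 − m_EM ⋆ ȳ2]/(p+1). The difference
cancels, exactly in the linear noiseless limit, both the dc figure-position
response (identical in the two runs) and the m_FM/m_EM cross-talk. What
remains is g_EM minus the uniform m-sequence dc offset Σg_EM/(p+1). The
conventional estimate keeps that offset (it is the raw cross-correlation);
`EstimationConfig(em_dc_correction=True)` removes it using the closed
identity Σ_k u(k) = Σg/(p+1) ⇒ g = u + Σu — an algebraic inversion with no
free parameters, useful when the forward-prediction residual must be pushed
below the dc floor.

**FM kernel.** Because g_FM is step-like, y is differentiated first
(first difference × frame rate; the derivative of a persistent step dies
out within a period even when the step itself never does, which is what
makes the steady-state record analyzable). Then
u_FM = ½[m_FM ⋆ ẏ1 + m_FM ⋆ ẏ2]/(p+1) estimates dg_FM/dt with a uniform dc
error −A/(p+1), A the kernel asymptote. Its cumulative sum is therefore
c(k) = g(k) − (k+1)·A/(p+1): the accumulating error nearly cancels the true
step at k = p−1 (c(p−1) = A/(p+1)). The default correction inverts this in
closed form: over a window W where the true slope is negligible
(default 2–5 s), mean_W c = A·(1 − mean_W ramp), so
Â = mean_W c / (1 − mean_W (k+1)/(p+1)) and g(k) = c(k) + (k+1)·Â/(p+1).
On noiseless data this recovers a unit asymptote to 0.5%. A "literal"
variant that takes the window mean itself as the asymptote (the other
reading of a verbal recipe whose arithmetic is ambiguous) is provided for
comparison; it under-corrects by exactly the shrink factor and the suite
asserts that behavior. The dc window must lie within one period; at 25 Hz
and p = 127 the 2–5 s default spans lags 50–125.

**Assembly.** Kernels are estimated per run and averaged per start azimuth
(equivalent to averaging traces for fixed sequences, but enabling per-run
quality control), placed at their centroid azimuths (circular mean of γ
over the analyzed span), and each time slice is smoothed with a circular
boxcar specified in display pixels (default 4 px = 15°). On axes sampled
coarser than the boxcar (e.g. the default 30° block grid) the boxcar
degenerates to a no-op; on pixel-dense axes (sliding-window mode) it spans
4 samples. Smoothing is unit-sum and circular, so azimuthal means of every
time slice are preserved. Block mode (independent runs on an even azimuth
grid, default every 8 px) and sliding-window mode (one kernel per
steady-state period of a long record, each window assigned its own
centroid) agree on spatially uniform ground truth to < 5% and share all
downstream code.

## The synthetic plant

The plant exists so that every stage has a ground truth. It evaluates the
same superposition used for prediction (one code path — "predict with the
true STAFs" and "simulate noiselessly" are the same computation), then adds
seeded Gaussian noise, optional slow sinusoidal drift, and an optional
static tanh saturation (both off by default).

Ground-truth shapes emulate the published phenomenology, with all
amplitudes being fixture choices in arbitrary ΔWBA units per pixel step:

| parameter | default | meaning |
|---|---|---|
| em_delay, em_rise | 40 ms, 100 ms | alpha-function EM impulse response, unit peak |
| em_sigma | 51° | frontal Gaussian (60° half-width at half max) |
| fm_delay, fm_saturation | 200 ms, 400 ms | delayed exponential FM step, saturated by ~2 s |
| fm_sigma_center / surround | 80° / 300° | difference of Gaussians; surround weight solved for exactly zero azimuthal sum, sign inversion ≈ ±86° |
| duration_frames | 127 | one order-7 period at 25 Hz |
| noise_sigma | 2.5 | = noiseless response SD of a frontal protocol run (SNR ≈ 1 per sample) |

The noise default makes single-period kernel estimates visibly noisy while
the default 20-repeat × 3-period averages are clean (noise on an averaged
kernel lag ≈ σ·√p/(p+1)/√(2·60) ≈ 0.02 units). A `uniform_azimuth` variant
(spatial profiles constant) isolates the temporal algebra for exactness
tests, since with spatially varying profiles the recovered kernel is an
excursion-weighted local average — worst-column deviations on steep flanks
are ≤ 12% of the global peak under the default conditions, a genuine
quasilinearity limit of the method, not an implementation artifact.

What the plant does *not* emulate: behavioral nonstationarity (fatigue,
state changes), saccadic structure in the steering output, closed-loop
dynamics, EMD-level nonlinearities (contrast/velocity dependence of the EM
stream, reverse-phi), and inter-individual variability unless populations
are constructed explicitly. Passing tests therefore demonstrate correctness
of the estimation machinery under the model's own assumptions, not that a
fly obeys the model.

## Prediction and scoring

`predict_response` evaluates the superposition for arbitrary step
trajectories, with linear interpolation (circular in azimuth) off the STAF
grid, the initial-position term included, and FM persistence beyond the
sampled span. Step magnitudes above the 1-px calibration step warn rather
than fail: the STAF is only validated where mean speed ≈ step size ×
update rate. R² is the squared Pearson correlation (undefined, hence an
error, for constant reference traces). Per-azimuth Fourier transforms of
the kernels are exposed as descriptive transfer functions only.

Under the default study conditions (order 7, 12 azimuths, 20 repeats,
SNR ≈ 1, seed 1) the full simulate → estimate → predict loop scores
R² ≈ 0.98 against the noiseless plant on a 90° trisweep; the noiseless
pipeline reproduces the simulation up to the documented dc floor
(exactly dc_EM × the 24-px position swing per kernel span), and < 2% of
response scale with the algebraic EM dc correction enabled.

## Statistics

Group comparisons are pixelwise paired t-tests (df = n−1, two-tailed; no
variance pooling across pixels) with Benjamini–Hochberg step-up control of
the false discovery rate over all pixels — appropriate because neighboring
STAF pixels are positively correlated (the fields are smooth), a regime
where BH remains valid. Effective dimensionality is reported separately via
SVD of the flattened member grids; members are *not* mean-centered by
default (the leading component then captures the shared mean STAF shape,
which is the population-homogeneity question), with `center=True` available
for variance about the mean — the two decompositions differ and the choice
is explicit in the API.

## Problem sizes and determinism

Defaults everywhere are the study conditions themselves: p = 127 (order 7),
25 Hz update (one period = 5.08 s, consistent with a 2–5 s dc window),
4 periods per run, 12 start azimuths, 20 repeats per sign. One full
protocol simulation plus estimation runs in well under a second on one
core. Every stochastic stage (plant noise, background/texture rendering,
protocol orchestration) descends from a single integer seed through
`numpy.random.SeedSequence` spawning; identical config + seed reproduce
STAF grids bit-for-bit.

## Known limitations

* The quasilinear spatial approximation biases kernels where the spatial
  profile has strong gradient or curvature over the figure's excursion
  (see above); shorter sequences reduce the excursion but lengthen the
  relative dc error and coarsen the frequency resolution.
* The FM dc correction assumes the true kernel slope is negligible inside
  the dc window; kernels still rising after 2 s violate this and bias the
  asymptote.
* The EM estimate retains the m-sequence dc offset by default (convention);
  enable `em_dc_correction` when absolute offsets matter.
* Eq-level path independence of the initial-position term is assumed, as in
  the source formalism; a path-dependent position response would make the
  decomposition of γ(0) convention-dependent.
* Sliding-window mode assigns each period the circular mean of a drifting
  trajectory; with net drift ±1 px per period, azimuthal sampling is dense
  but not exactly uniform.
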