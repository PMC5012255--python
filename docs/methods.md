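# Methods

## Resonance fitting

One conductance sweep is modelled as a four-parameter Lorentzian
G(x) = baseline + amplitude·Γ²/((x−f)² + Γ²). The fit is bounded
nonlinear least squares (trust-region reflective, relative tolerances
10⁻¹⁴, ≤ 200 function evaluations) with f constrained inside the sweep
and Γ > 0. Frequencies are shifted to the sweep origin before
optimisation so that the ~5·10⁶ Hz carrier does not dominate the
conditioning of the Jacobian. The starting point is parameter-free:
f₀ at the argmax of a lightly smoothed (edge-padded 3–7-point moving
average) sweep, Γ₀ as half the distance between the half-maximum
crossings, amplitude₀ = peak − median, baseline₀ = median. A sweep whose
smoothed maximum lies on an edge, or with zero range, is rejected as
having no interior peak rather than fitted. On noiseless model data the
fit recovers the generator parameters to better than 10⁻⁶ relative
error from any reasonable start; on 1 % amplitude noise it agrees with
an exhaustive (f, Γ) grid search to within the grid resolution.

Only the conductance (real part of admittance) is fitted; susceptance
and equivalent-circuit extraction are out of scope.

### Shift conventions

Δf(t) = f_air − f(t), so mass loading yields positive Δf and the
model's M_t is positive for a forming clot; ΔΓ(t) = Γ(t) − Γ_air is
positive under dissipative loading. The starred channels subtract the
z-snapshot (default: the first sample of the series), the measurement
taken immediately after sample deposition and before clot onset:
Δf*(t) = Δf(t) − Δf_z, ΔΓ*(t) = ΔΓ(t) − ΔΓ_z, so both are exactly zero
at the snapshot.

## Kinetic parameters

* **max response**: maximum of the starred channel over t ≥ t_z.
* **R-QCM** (clotting time): first time the starred channel reaches
  10 % of its maximum, located by linear interpolation between the
  bracketing samples.
* **MRCF / TMRCF**: maximum of the smoothed first derivative and its
  time; ties break to the earliest sample.

The derivative is a Savitzky–Golay local-cubic filter (default window
11 samples at 1 s sampling, configurable; central differences below 5
samples). A cubic rather than quadratic local fit matters: the
derivative of an even-order symmetric fit picks up a bias from the
curve's own cubic term that grows as (k·window)²/20 for a logistic of
rate k — about −5 % on MRCF at window 101 for k = 0.02 s⁻¹ — while the
odd-order fit cancels it.

For noisy traces the extraction can pre-smooth the curve with the same
filter before the maximum/threshold steps (`presmooth=True`). The
pre-smoothing is applied to the raw channel and then re-referenced at
the z-index: subtracting a single noisy z-sample first would imprint
that sample's noise on the entire starred series as a constant offset
that no subsequent filtering can remove (at 20 Hz noise this alone
contributes a ≈5 s standard deviation to R-QCM; re-referencing reduces
it to ≈1 s). The window should be scaled to the trace: roughly 2/k
samples (samples per transition width) balances noise suppression
against peak-flattening bias; 151 samples is appropriate for the
reference curve (k = 0.02 s⁻¹, 1 s sampling) at 1 % noise.

Both channels are processed; the frequency channel is the default for
single-channel reporting.

## Viscoelastic model

Per time point, with constants a (Hz⁻², default 2.5·10⁻⁷) and b (Hz⁻¹,
default 10⁻³):

* c(t) = ΔΓ_z/ΔΓ(t) — evaluated per time point. This reading makes
  c = 1 at the z-snapshot, which is required for the definitional zeros
  below; a frozen-c variant would not satisfy them.
* μ_t = a·(ΔΓ² − c²·ΔΓ_z²), M_t = b·(Δf − c·Δf_z) — both exactly zero
  at the z-snapshot for any input, by construction.
* RF = μ_t/M_t, computed only where |M_t| > b·rf_floor
  (rf_floor = 1 Hz of net frequency shift by default) and flagged
  undefined (NaN) elsewhere. The guard exists because clot onset is a
  0/0: both numerator and denominator vanish at the snapshot and ratios
  of noise would otherwise dominate the early trace.

A scalar per-sample summary takes the mean of μ_t and M_t, and the mean
of the defined RF(t), over a plateau window — by default the last 20 %
of the trace, where clot formation is complete. The reduction window is
a modelling choice; any (t_start, t_stop) range with at least three
defined RF points is accepted.

The algebra has a useful internal check: for any increasing ΔΓ(t) and
any constant ρ > 0, setting Δf(t) = c·Δf_z + (a/(b·ρ))·(ΔΓ² − c²ΔΓ_z²)
produces RF(t) ≡ ρ at every defined point. The test suite and the
acceptance script verify this constancy to 10⁻⁶.

## Fibre-network image analysis

Chain: structure filter → mean-threshold binarization → porosity;
binary image → 2-D FFT → radially averaged power spectrum → density;
then F.Diam = (1 − √F.Por)/F.Dens (nm).

* **Structure filter**: sharp Fourier low-pass removing components with
  wavelength < 2 px (radial frequency > 0.5 cycles/px); the DC term and
  hence the mean are preserved. A real-space median alternative is
  available behind a switch for images where the sharp cutoff rings.
* **Binarization**: threshold at the mean intensity; pixels exactly at
  the mean count as bright (+1) for determinism. Porosity is the
  fraction of −1 pixels, so porosity + bright fraction = 1 exactly, and
  the whole chain is invariant to affine intensity rescaling.
* **Radial spectrum**: power |FFT|² binned by radial frequency
  r = √(u²+v²) with bin width Δ = 1/max(dimensions); each non-DC
  coefficient joins the single bin round(r/Δ), so bin centres sit at
  i·Δ and a grating fundamental k/N lands exactly on a centre. The
  per-bin mean power is reported together with per-bin counts (the
  partition reproduces total non-DC power exactly).
* **Windowing**: a Hann window is applied by default before the FFT.
  On ground-truth gratings whose period does not divide the image size,
  the rectangular window splits the fundamental across two bins and the
  second harmonic can overtake the per-bin mean — on a 256-px image this
  loses 10 of 125 (w, P) grid points; with the Hann window all 125 are
  recovered, at every image size tried. `window="none"` gives the raw
  periodogram.
* **Peak search** excludes the DC bin and the first bin (large-scale
  illumination gradients). A maximum in the highest bin raises an
  `unresolved_structure` flag; a peak below 3× the median searched
  power raises `weak_peak` (no dominant periodicity — e.g. white
  noise). F.Dens converts the peak from cycles/px to cycles/μm with the
  user-supplied pixel size (scale bars are not parsed); one fibre per
  period is assumed.

## Synthetic generators

* **Clot curves**: Δf(t) = Δf_z + A_f·σ(t), ΔΓ(t) = ΔΓ_z + A_g·σ(t)
  with σ a logistic (default) or Gompertz sigmoid, plus additive white
  Gaussian noise. The logistic is the canonical choice because every
  extracted parameter has a closed form: max = A,
  R = t₀ − ln 9/k, MRCF = A·k/4, TMRCF = t₀ (Gompertz:
  R = t₀ − ln ln 10/k, MRCF = A·k/e). Defaults (Δf_z = 700 Hz,
  ΔΓ_z = 1000 Hz, A = 2000 Hz, k = 0.02 s⁻¹, t₀ = 400 s, 1 s sampling
  over 1200 s) sit in the range of slow tissue-factor activation:
  sub-kHz liquid-loading shifts, minutes-scale clotting, ~10 Hz/s peak
  rate. The closed forms assume the sigmoid starts near zero, i.e.
  k·t₀ ≳ 6; parameter choices below that leave no pre-clot plateau and
  the closed-form targets drift.
* **Spectrum series**: one Lorentzian sweep per time point with
  f = f_air − Δf(t), Γ = Γ_air + ΔΓ(t); the sweep must span every peak
  with at least one linewidth of margin. Round-trips through the fitter
  to 10⁻⁴ relative.
* **Network images**: two orthogonal sets of bright bars (width w,
  period P) on a dark background, optionally rotated, blurred and
  noised. Ground truth is exact: F.Por = (1 − w/P)², F.Dens = 1/P per
  pixel, F.Diam = w pixels.

What the generators do **not** emulate: baseline drift and temperature
effects in the QCM signal (additive white noise only), non-sigmoidal or
multi-phase clot curves, curved/branching fibres, fibre-width
dispersion, SEM charging artefacts and depth-of-field blur. Passing the
recovery tests therefore demonstrates correctness of the extraction
algebra and robustness to stationary noise, not performance on real
micrographs or drifting instruments.

## Determinism and problem sizes

Every stochastic step takes an explicit seed (numpy `default_rng`);
pipelines with identical configuration and inputs produce byte-identical
reports. The validation workloads use a 1201-sample clot trace, 125
grating images at 256² px, 100 noisy kinetics replicates and 20 noisy
spectra against a 0.1 Hz × 1 Hz brute-force grid — sizes chosen so the
full suite runs in seconds while keeping discretisation effects (bin
width, sampling) well below the tolerances being checked.

## Known limitations

* The Lorentzian model assumes a single well-separated resonance;
  overlapping modes or strongly asymmetric (Fano-like) peaks are not
  handled and will either fail or bias Γ.
* R-QCM's 10 % threshold uses each channel's own maximum; for
  non-monotone starred series the first crossing is reported, which may
  precede the global rise.
* The fibre metrics assume one dominant spatial period; multi-scale
  networks yield the strongest periodicity only, and F.Diam inherits the
  ideal-grating assumption.
* μ_t, M_t and RF are normalised, unitless descriptors under the fixed
  scaling constants a and b; they are comparable across runs but are
  not absolute material moduli.
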