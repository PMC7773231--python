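# Methods

## Data model and time conventions

A TCSPC measurement is a histogram of photon arrival times: `n_bins`
contiguous bins of width `bin_width_ns` (ns).  All estimators share one time
convention: **models are evaluated at bin centers, with t restarting at 0 at
the leading edge of the fit range** (half-open `[start_bin, end_bin)`).
This single choice makes the closed-form RLD estimate, the LM fitters and
the phasor transform mutually consistent, and makes recovery from noiseless
bin-center-sampled data exact — which is what the oracle tests assert.
Whether real TCSPC hardware timestamps correspond better to bin centers or
edges is a sub-bin-width question; with 256 bins over 10 ns the distinction
is ~20 ps and absorbed into the calibration of the time axis.

Decay laws:

* multi-exponential: `y(t) = Z + Σᵢ Aᵢ exp(−t/τᵢ)` — `Z` a constant
  background (counts/bin), `Aᵢ` amplitudes (counts), `τᵢ` lifetimes (ns);
* stretched exponential: `y(t) = Z + A exp(−(t/τ)^(1/h))`, `h > 0` the
  stretch (heterogeneity) parameter, `h = 1` reducing to mono-exponential.

With an instrument response function (IRF), the model curve minus `Z` is
convolved with the unit-sum-normalized IRF (causal discrete convolution,
truncated to the window) and `Z` added back — a constant background is not
smeared by the instrument.  Convolution is direct (`O(n²)`, `n ≤ 512` bins
in practice); an FFT path exists for spatial binning where the kernel is
large (see below).

## Noise models and objectives

Per-bin variances weight the least-squares objective `χ² = Σ (yᵢ−fᵢ)²/σᵢ²`:

| kind | variance | notes |
|---|---|---|
| `constant` | σ² supplied | classic unweighted LS up to scale |
| `given` | per-bin array | e.g. from a variance map |
| `gaussian` | max(yᵢ, 1) | floor avoids division by empty bins |
| `poisson` | max(yᵢ, 15) | Gaussian approximation to Poisson noise; below ~15 counts that approximation breaks down, so the variance is floored at 15 |
| `mle` | — | minimizes the Poisson deviance `2Σ[fᵢ − yᵢ + yᵢ ln(yᵢ/fᵢ)]` (the `yᵢ=0` term is `2fᵢ`, its continuous limit); requires `fᵢ > 0` |

The `gaussian`/`poisson` kinds weight by the *observed* counts (Neyman
weighting).  This is fast and standard in FLIM packages but carries a known
small-sample bias: bins that fluctuate low get over-weighted, biasing
lifetimes a few percent low at tens of counts per bin (about −1% for a
4 ns/10⁴-photon transient with the offset fixed, −4% with the offset free,
where the Z–tail degeneracy amplifies it).  The `mle` deviance objective is
free of this bias and is the right choice at low counts; the validation
protocols that fit photon-limited data with weighted LS therefore fix the
offset at its known value, mirroring standard practice of fitting
(amplitude, lifetime) with the background held at a measured constant.

## Levenberg–Marquardt fitter

Free parameters are optimized by the classic damped normal-equations
schedule: λ starts at 10⁻³, ×10 on a rejected step, ÷10 on an accepted one;
convergence when an accepted step improves the objective by less than a
relative `tolerance` (default 10⁻⁶) or λ exceeds 10¹⁰ (stalled at a
minimum); hitting `max_iterations` (default 100) returns
`converged = False` rather than raising.  Derivatives are analytic for
multi-exponential models (each basis column IRF-convolved when
reconvolving) and central finite differences (10⁻⁶ relative step) for the
stretched exponential.  The `mle` objective uses Fisher scoring — the same
LM machinery with weights 1/fᵢ — whose curvature matrix is the Fisher
information.

Parameter fixing comes in two forms: `fixed` (hold at the initial
estimate) and `fixed_values` (hold at a stated value, e.g. a measured
background).  Restraints are enforced by projection — the trial point is
clamped into its box after each step — which preserves the LM descent
property at the cost of first-order optimality exactly on a bound, an
acceptable trade for the way restraints are used here (keeping parameters
physical).

Standard errors come from the curvature ("alpha") matrix at the optimum:
`SE_k = √((α⁻¹)ₖₖ)`, scaled by √(reduced χ²) for the weighted-LS kinds
(both scaled and raw values are reported, since conventions differ between
packages); Fisher errors are reported unscaled for `mle`.  A Monte-Carlo
test confirms ≈68% one-sigma coverage for the MLE fitter.

Initial estimates: RLD for one component; for k components the RLD lifetime
is split geometrically over (τ/2, 2τ) with the amplitude divided equally.
If RLD fails (flat or rising transient) the fallback is Z = min(y),
A = max(y) − min(y) (at least 1), τ = a quarter of the window.

## Rapid lifetime determination

The fit range (truncated to a multiple of 3 bins, leftovers dropped from
the tail) is split into thirds with sums S₁, S₂, S₃.  For bin-center
sampling the decay part of each third is a geometric sum, so
`x = (S₃−S₂)/(S₂−S₁) = exp(−mΔt/τ)` exactly, giving τ; the decay sum of the
first third `C = (S₂−S₁)/(x−1)` then back-solves `Z = (S₁−C)/m` and
`A = C(1−r)/(√r(1−r^m))` with `r = exp(−Δt/τ)`.  Using the discrete
geometric-sum identity (rather than the continuous-integral approximation)
makes noiseless recovery exact to machine precision — a deliberate
discretization choice, verified by property tests over the (Z, A, τ) space.
Non-decaying integrals (S differences not both negative, or ratio outside
(0,1)) raise a fit error.

## Global analysis

Lifetimes are shared across pixels; offset and amplitudes stay local.  For
fixed lifetimes the per-pixel problem is weighted linear least squares on
the basis {1, exp(−t/τᵢ)}, solved exactly by normal equations (batched over
all pixels).  The outer problem — the k shared lifetimes — is LM on the
stacked weighted residuals (variable projection), parametrized in log τ so
lifetimes stay positive without constraints, with a central-difference
Jacobian (the inner solve is exact, so the outer problem is k-dimensional
and cheap).  Initialization: a k-component LM fit of the image-summed
transient.  Offset is local per pixel (it varies spatially in practice);
the `mle` noise kind is not available for global fits, which are
weighted-LS by construction.  Degrees of freedom for the per-pixel reduced
χ² are counted as n − (k+1), ignoring each pixel's infinitesimal share of
the k shared parameters.

## Phasor

`ω` defaults to the fundamental of the fit range, `2π/T` (e.g. 100 MHz for
a 10 ns range), because the universal-circle geometry is exact at the
window's own harmonic: for a truncated exponential the window-fundamental
Fourier ratio equals `1/(1 − iωτ)` with no truncation error, so noiseless
mono-exponentials land on the circle up to O((ωΔt)²) discretization.  An
explicit `--frequency` override supports referencing to a laser repetition
rate instead; the frequency used is always reported in the output.  An
optional scalar background is subtracted before the transform.

## Bayesian estimation

Mono-exponential plus uniform background, conditioned on the total in-range
count N (multinomial likelihood): bin probabilities
`pᵢ = b/n + (1−b)(e^(−tᵢˡᵒ/τ) − e^(−tᵢʰⁱ/τ))/(1 − e^(−T/τ))`, which sum to
1 over the window.  Priors are uniform on τ ∈ (0.05 ns, 2T) and b ∈ (0, 1);
the posterior is integrated on a 200×200 grid, log-spaced in τ with the
linear cell widths as quadrature weights (so the prior stays uniform in τ,
not in log τ).  The reported estimate is the posterior mean ± posterior
standard deviation (the grid MAP is reported alongside); amplitude and
offset are back-computed so the implied curve carries exactly N photons.  A
`boundary_warning` is raised when more than 20% of the mass sits in the
grid's edge rows/columns.  This binned-likelihood estimator uses the same
evidence as arrival-time Bayesian methods at the granularity of the
histogram; a 10× finer grid changes the posterior mean by well under 0.5%
(tested against an independently coded quadrature).

For whole images the per-grid-point log bin probabilities are precomputed
once (`BayesGrid`), reducing each pixel to one matrix product — this is
what makes Bayesian fitting of thousands of pixels practical.

## Image-level operations

Spatial binning **sums** counts over the k×k neighborhood (zero-padded
edges): sums, not means, preserve the Poisson interpretation the noise
models rely on.  The default path convolves by FFT over the spatial axes;
a direct path exists and the two agree to 1e-6 (tested).  Thresholding
masks pixels by total in-range photons; masked or failed pixels are NaN in
every parameter map and 0 in the validity mask.  Per-pixel fitting is
dispatched over pixel chunks (optionally threaded); each fit is
deterministic and independent, so results are invariant to chunk size and
worker count (tested bitwise for RLD/phasor, to 1e-9 for LMA).

Mean lifetime: amplitude-weighted `τ_m = ΣAᵢτᵢ/ΣAᵢ` (default — the fraction
of excited molecules) or intensity-weighted `τ_m = ΣAᵢτᵢ²/ΣAᵢτᵢ` (the
fraction of detected photons); both are provided since conventions differ.
FRET efficiency is `E = 1 − τ_DA/τ_D` for scalar ROI means or maps.

## Synthetic data and what the tests show

The generators reproduce the package's validation conditions:

* `simulate_transient` — expected curve scaled to a photon budget, counts
  drawn independently Poisson per bin; pure function of (parameters, seed).
* `simulate_onecomp_image` — 32 evenly spaced lifetimes, 0.2–6.0 ns, inside
  a 10 ns / 256-bin window, arranged in equal rectangular blocks (row-major;
  the layout is immaterial because the truth map is returned), Z = 0,
  default 5,000 photons/pixel (the budget is a package default, chosen as a
  typical good-quality TCSPC pixel; it is overridable).
* `simulate_twocomp_image` — two species at 0.4 and 2.1 ns (the canonical
  free-NAD(P)H / FAD contrast), 128×128 pixels, amplitude fraction of the
  short species falling linearly in (x+y) from 1 at the top-left corner to
  0 at the bottom-right, each pixel scaled to the photon budget.
* `thin_photons` — binomial thinning per bin (each photon kept with
  probability f), turning a Poisson(μ) dataset into Poisson(fμ): the
  standard model for reduced acquisition time; a nine-step 10%…90% ladder
  is provided.

These simulations draw ideal Poisson counts from the exact model on the
exact grid.  They do **not** include IRF distortion (unless one is passed),
detector afterpulsing, dark counts beyond the constant Z, pile-up, or
incomplete-decay wrap-around from the previous excitation period.  Passing
tests therefore demonstrate estimator correctness and statistical behavior
under ideal photon statistics — not robustness to instrument artifacts.

### Validation studies (rerun by `scripts/acceptance.py`)

* **Two-component global recovery** — full 128×128 mixture at 5,000
  photons/pixel; the two shared lifetimes are recovered to well within 5%.
* **Fluorescence-standard ensemble** — 200 transients at 4.0 ns, 10⁴
  photons each, fit by 1-component LMA (Poisson noise model, offset fixed
  at its true value per the fixed-offset protocol above); the ensemble mean
  is within 2% of truth (the residual ≈ −1% is the Neyman-weighting bias
  discussed above).
* **Sweep regression** — LMA, RLD and phasor estimates regressed on truth
  over the 32-level sweep (16 pixels per level); all three slopes are
  within 1.00 ± 0.05, and the script reports the slope farthest from 1.
* **Low-photon comparison** — at 10% of the photons, the across-pixel
  spread of (noisy − clean) lifetime differences is smaller for Bayes than
  for LMA at every one of the 32 sweep lifetimes (200 pixels per level);
  for this comparison LMA lifetimes are box-restrained to the same
  0.05–20 ns range the Bayes prior spans, since otherwise a handful of
  divergent least-squares fits dominate the spread with arbitrarily large
  values.

Problem sizes (pixels per level, ensemble counts) are the package's test
conditions; they were chosen to make the Monte-Carlo comparisons sharp at
interactive runtimes and are stated in each test.

## Known limitations

* No time-shift (IRF alignment) as a free fit parameter, no scatter
  fraction, no pile-up correction, no incomplete-decay (wrap-around) model.
* RLD is mono-exponential only and has no IRF-aware variant.
* Bayesian estimation is 1-component with a uniform background; no model
  selection between component counts, and the IRF is not estimated.
* Neyman-weighted noise models carry the small-count bias described above;
  use `mle` when counts are low and the offset cannot be fixed.
* Vendor TCSPC file formats are not parsed; convert to TIFF+JSON or CSV
  upstream.
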