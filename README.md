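# flimkit

Time-domain fluorescence lifetime (FLIM) decay analysis in Python.

Fluorescence lifetime imaging microscopy records, for every pixel, a
time-correlated single-photon counting (TCSPC) histogram of photon arrival
times — a *transient*.  The excited-state lifetime extracted from that
transient reports on the fluorophore's microenvironment (FRET, pH, binding
state, metabolic redox ratio) independently of intensity.  `flimkit` is a
library + CLI for estimating decay parameters from such data:

* **RLD** — rapid lifetime determination: a closed-form mono-exponential
  estimate from three contiguous integrals; also the default initializer for
  the iterative fitters.
* **LMA** — Levenberg–Marquardt fitting of multi-exponential
  *y(t) = Z + Σᵢ Aᵢ e^(−t/τᵢ)* and stretched-exponential
  *y(t) = Z + A e^(−(t/τ)^(1/h))* models, with five selectable noise models
  (constant / given / Gaussian / Poisson-floored / Poisson-deviance MLE),
  parameter fixing and box restraints, iterative reconvolution with a
  measured instrument response function (IRF), and alpha-matrix standard
  errors.
* **Global analysis** — lifetimes shared across all pixels of an image while
  amplitudes and offset stay local, solved by variable projection.
* **Phasor** — the fit-free transform g = Σy cos(ωt)/Σy, s = Σy sin(ωt)/Σy;
  mono-exponentials fall on the universal semicircle g² + s² = g, and
  τ_phase = s/(ωg), τ_mod = ω⁻¹√(1/(g²+s²) − 1).
* **Bayes** — grid-based Bayesian mono-exponential estimation from the
  binned multinomial likelihood, markedly more stable than least squares at
  low photon counts.
* **Image operations** — FFT spatial binning, intensity thresholding,
  chunked per-pixel fitting into parameter maps, mean-lifetime maps, ROI
  cropping, and FRET efficiency E = 1 − τ_DA/τ_D.
* **Formats** — multi-page TIFF stacks (time as pages) with a JSON sidecar,
  two-column CSV transients/IRFs, float-TIFF parameter maps with a JSON
  manifest.
* **Simulation** — seeded Poisson-statistics generators for the validation
  studies: a 32-level lifetime sweep (0.2–6.0 ns in a 10 ns window), a
  128×128 two-component mixture (0.4/2.1 ns with a linear species-fraction
  gradient), and binomial photon thinning (10%…90%).

## Worked example

Simulate a 4.0 ns fluorescence-standard transient (≈20,000 photons on a
10 ns / 256-bin window) and fit it three ways:

```sh
flimkit simulate transient --out fluorescein.csv --tau 4.0 --photons 20000 --seed 7
flimkit fit-lma fluorescein.csv --noise mle --fix Z=0
```

```
Z = 0
A1 = 212.28
tau1 = 4.03988
stderr(A1) = 2.39
stderr(tau1) = 0.04589
reduced_chisq = 1.04885
converged = True (iterations=3)
```

The fitted lifetime 4.04 ± 0.05 ns brackets the simulated truth; a reduced
χ² near 1 says the Poisson-deviance residuals are consistent with counting
noise.  The fit-free phasor agrees:

```sh
flimkit fit-phasor fluorescein.csv
```

```
g = 0.137643
s = 0.339698
frequency_mhz = 100
tau_phase = 3.9279
tau_mod = 4.04008
```

`frequency_mhz` is the fundamental of the 10 ns fit range (100 MHz); phase
and modulation lifetimes agree because a mono-exponential lies on the
universal circle.  Finally, the FRET efficiency for donor / donor+acceptor
lifetimes of 2.23 ns and 2.16 ns:

```sh
flimkit fret --tau-donor 2.23 --tau-donor-acceptor 2.16
```

```
fret_efficiency = 0.0313901
fret_efficiency_percent = 3.1
```

i.e. a 3.1% lifetime reduction of the donor in the presence of the acceptor.

Image-scale workflows use the same commands on TIFF stacks
(`flimkit simulate twocomp --out stack.tif`, then
`flimkit fit-global stack.tif --components 2 --out-dir maps/`), or the
library API (`flimkit.fit_image`, `flimkit.fit_global`, ...).

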