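# Methods

## Signal model

Pump–probe signals are modeled as sums of first-order population kinetics
convolved with a Gaussian instrument response function (IRF). For a decay
time τ, IRF width σ and time zero t₀,

    c(t; τ, t₀, σ) = ½ exp(σ²/2τ² − (t−t₀)/τ) · erfc[(σ/τ − (t−t₀)/σ)/√2],

the exact convolution of a unit-area Gaussian with a step-exponential. For
σ/τ large the leading exponential overflows while erfc underflows; the
implementation switches to the scaled complementary error function
(`erfcx`), for which the exponents combine exactly to −(t−t₀)²/2σ², and is
finite for any σ/τ. Values below 1e−290 are flushed to zero so that scaling
amplitudes remains exactly linear at double precision. A quadrature oracle
(adaptive integration of the smooth form ∫₀^∞ G(t−t₀−s) e^(−s/τ) ds) agrees
with the closed form to better than 1e−6 across τ from 50 fs to 500 ps and
σ from 10 to 50 fs; the test suite and the acceptance script both recompute
this comparison.

Long-lived plateaus (e.g. triplet photoproducts formed within the
observation window but decaying far outside it) are represented by the
IRF-convolved step, the τ → ∞ limit of c. The coherent cross-phase
modulation (CPM) artifact near time zero is a₀G + a₁G′ + a₂G″ with G the
unit-peak Gaussian sharing the IRF's center and width; the derivative basis
reproduces the dispersive line shapes seen in stimulated-Raman transients.
The derivative terms scale as 1/σ and 1/σ², so artifact coefficients are
small numbers even when the rendered artifact is comparable to the signal.

## Fitting

All fits are separable nonlinear least squares (variable projection):
amplitudes, offsets and CPM coefficients enter linearly and are solved
exactly per trace at every trial of the nonlinear time constants, which are
optimized in log space (enforcing positivity) with `scipy.optimize.
least_squares`. Multiexponential objectives are multimodal, so the
nonlinear stage is multi-started (default 8 starts) from log-spaced time
constants spanning the resolvable range — from half the smallest delay step
to twice the delay span — with seeded log-uniform jitter; the best-residual
start wins, ties broken toward the smaller fastest time constant. Time
constants are reported sorted ascending; adjacent constants within 5% are
flagged degenerate. Fixing every time constant reduces the fit to a single
exact linear solve.

Uncertainties are linearized 1σ estimates: the covariance s²(JᵀJ)⁻¹ of the
*full* parameter vector (time constants plus all per-trace linear
coefficients), with J evaluated numerically at the optimum and s² the
reduced residual variance. Including the linear parameters in J matters:
amplitude–lifetime correlations would otherwise understate the lifetime
errors. On 50 synthetic transient-absorption replicates at signal-to-noise
100, the generating time constants fall inside the reported 3σ intervals in
≈98% of replicates (recomputed by the test suite). Traces carrying
per-point uncertainties are fit with inverse-sigma weights; otherwise fits
are unweighted.

The peak-shift fit uses the same machinery on a band-center track,
ν̃(t) = ν̃∞ + Σ Δν̃ᵢ·c(t; τᵢ), with a true constant ν̃∞ as the asymptote.
The sub-band reversal fit couples two traces: a shared reversal component
+A·c(t; τ_fast) in one trace and −A·c(t; τ_fast) in the other, plus
fixed-τ components (default 0.72, 4.4, 163 ps — the solvent-band decays)
with free per-trace amplitudes. τ_fast is located by a 60-point log scan
over [5, 500] fs followed by local refinement; a solution pinned within 2%
of either bound is flagged. With τ_fast ≈ 30 fs under a 21 fs IRF the
problem is resolution-limited: recovery to ~20% is the realistic
expectation, and that is what the tests assert.

## Preprocessing

**Chirp.** Group-velocity dispersion makes time zero depend on probe
wavelength. Per channel, t₀ is estimated as the center of a Gaussian fitted
to |dS/dt| inside a user-chosen artifact window — the derivative magnitude
peaks at t₀ for both step-like and dispersive artifact shapes, which is why
it is preferred over the raw artifact extremum. A polynomial (default
degree 2, max 3) of t₀ versus spectral position is then fitted; channels
without a usable artifact are skipped, and fewer than degree+2 usable
channels is an error. Correction resamples each channel by linear
interpolation onto delays shifted by −(t₀(ν) − t₀(ν_ref)), repeating edge
values outside the recorded range; linear interpolation is monotone and
artifact-free and adequate at the 10–25 fs grid scale used here. A
time-zero spread above 10 ps across the axis is rejected as unphysical.
Chirp is only estimable where the per-channel time zero falls inside the
recorded artifact window, and reduction ratios are only meaningful when the
injected spread exceeds the delay sampling step.

**Reference subtraction.** The column nearest the reference delay (default
−5 ps; ties resolve to the earlier column) is subtracted from every column,
removing static ground-state spectra exactly. No averaging over pre-zero
columns is done by default, matching the single-reference-spectrum
convention.

**Baselines.** Fluorescence backgrounds under stimulated-Raman spectra are
removed by ordinary least-squares polynomials (default order 4 — "low
order" in the trade's sense; orders 0–6 supported) fitted outside exclusion
windows, which default to every configured band ± 1.5×FWHM. For narrow
windows around single solvent bands, a straight line through the 3-pixel
means at the two window ends is used instead. The corrected spectrum is
defined bitwise as input minus baseline.

**Band integration.** Band kinetics are the mean of the spectral rows in a
closed interval center ± bandwidth/2 (default bandwidth 25 cm⁻¹, narrow
enough to exclude inter-band spectral changes). Closed-interval membership
on axis values, rather than pixel counts, keeps the operation reproducible
across grids.

## Band analysis

Peak tracking fits a Gaussian plus straight line inside the band window at
every delay, initialized at the extremum of the line-detrended spectrum.
Gaussian (not Voigt) line shapes are used: at sub-10 cm⁻¹ spectral
resolution solute bands are near-Gaussian and a Voigt mixing parameter is
not identifiable at realistic noise. Delays where the fitted amplitude is
below 3× the local residual RMS, the center leaves the window, or the
width is unphysical are flagged unsuccessful and excluded downstream. When
a tracked band is a depletion (negative-going), restricting downstream
shift fits to negative-amplitude track points guards against the fitter
latching onto unrelated positive features once the band has decayed away.

Sub-band decomposition solves, per delay, a linear least-squares problem
against fixed-center fixed-width Gaussian profiles plus a straight-line
baseline; only amplitudes are free. Freeing sub-band positions or widths
makes the ultrafast reversal ill-posed at stimulated-Raman noise levels, so
they are held at their configured values (default FWHM 14 cm⁻¹, below the
25 cm⁻¹ integration bandwidth so the two species remain separable). A
design-matrix condition number above 1e8 raises an "unresolvable" error.
The free/aggregated/hydrogen-bonded trichotomy of DMSO is folded into a
two-sub-band (free vs hydrogen-bonded) decomposition by default; any number
of sub-bands ≥ 2 is accepted for users who want the three-species variant.

## Synthetic data

The generator renders surfaces as Σ_bands lineshape(ν̃; t) × [static +
step·A_step + Σ_c A_c·c(t − chirp(ν̃); τ_c)] + CPM(t − chirp(ν̃)) + noise.
Parallel (decay-associated) schemes are the default — published global fits
report multiexponential components, not a resolved compartmental scheme —
and sequential chains are available through the Bateman closed form, each
term built from the convolved exponential. Band centers may drift
bi-exponentially (vibrational Stokes shift); the configured center is the
relaxed (late-time) position and the drift amplitudes add on top. Static
amplitudes model ground-state Raman intensity present before excitation
(so the −5 ps reference-subtraction workflow is exercised); step
amplitudes model long-lived photoproducts. Noise is additive white
Gaussian from a seeded generator — no shot-noise or 1/f structure — and
identical seeds reproduce surfaces bitwise.

Three presets encode the published curcumin photophysics:

* `curcumin_chloroform_ta` — τ = 0.79, 6.3, 210 ps; SE band at 485 nm,
  ESA at 580 nm, triplet ESA at 765 nm rising with the 210 ps component
  toward a plateau.
* `curcumin_dmso_ta` — τ = 0.11, 1.2, 5.8, 178 ps; LE-state SE/ESA at
  460/595 nm, CT-state ESA/SE at 495/660 nm.
* `curcumin_dmso_fsrs` — a parallel scheme holding the union of the
  published FSRS time constants (0.03, 0.72, 1.3, 4.4, 7.1, 8.4, 163 ps);
  ground-state bands at 1160/1186/1596/1631 cm⁻¹, excited-state bands at
  767/815/1254/1330/1485/1564 cm⁻¹, the ν_C=C,C=O depletion drifting
  1633→1626 cm⁻¹ with (0.23, 9.0) ps, DMSO ν_CSC sub-bands at 657 (free)
  and 678 cm⁻¹ (H-bonded) with a 30 fs amplitude reversal, ν_S=O sub-bands
  at 1058/1027 cm⁻¹ reversing oppositely, a broad fluorescence background
  following the 163 ps population, and a CPM artifact.

Defaults chosen where the published record is silent: IRF σ = 21 fs (FWHM
50 fs, the stated instrument class); band FWHM 40 nm (TA), 15 cm⁻¹ (solute
Raman), 20 cm⁻¹ (solvent Raman), 14 cm⁻¹ (solvent sub-bands); band
amplitudes are unit-order values recorded in the presets themselves and
are the ground truth for recovery tests. Delay grids combine dense linear
sampling through time zero (10–40 fs steps) with geometric spacing out to
800 ps (TA) / 100 ps (FSRS) — enough to determine both the fastest and
slowest printed constants while keeping test runtimes in seconds.

## What the synthetic tests do and do not show

Passing recovery tests demonstrate that the pipeline is internally
consistent: when data truly follow the IRF-convolved multiexponential
model with Gaussian bands and additive white noise, the implementation
recovers the generating parameters at the stated tolerances (time
constants to 10% at signal-to-noise 100; the resolution-limited 30 fs
reversal to the published 20–50 fs window in ≥80% of replicates). They do
not validate the model itself against instrument realities absent from the
generator: correlated (pink) noise, pump scatter, solvent Raman
backgrounds beyond a smooth fluorescence term, anisotropy, coherent
oscillations, non-Gaussian IRFs, or detector nonlinearity. Experimental
time constants from the original study are therefore reproduced here only
in the sense that the printed values, used as generating truth, are
recovered by the analysis.

## Numerical choices and edge cases

* Time constants are optimized as logarithms; bounds default to
  [1 fs, 10 ns] and are clipped per problem to the resolvable range for
  initialization only.
* Identical seeds give identical fits; trace order changes nothing beyond
  1e−9 relative.
* Sequential schemes with duplicate time constants (a degenerate Bateman
  denominator) raise immediately rather than returning near-singular
  output.
* Non-finite cells are rejected at load; masking is deliberately not an
  I/O concern.
* Surfaces are written with 17 significant digits; write→read round trips
  are bitwise lossless.
* All-zero traces fit with zero amplitudes, zero residual, and
  `converged=True`.
* Non-convergence after all multi-starts returns a flagged result with
  diagnostics rather than raising.

## Known limitations

* Only all-shared time constants are supported in a single global fit;
  per-band independent fits are expressed by fitting each trace separately.
* Chirp correction interpolates linearly; sub-grid ringing suppression
  (e.g. spline or sinc resampling) is out of scope.
* Uncertainties are linearized; the covariance can understate errors near
  degenerate time-constant pairs (which are at least flagged). No bootstrap
  or posterior sampling is provided.
* The generator's noise is white and additive; heteroscedastic weighting is
  supported in fits but not emulated in synthesis.
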