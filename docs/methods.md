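# Methods

## The statistical model

`lookelsewhere` tests a noise-only null hypothesis H0 against a family of
alternatives H1(z) indexed by continuous parameters z — an amplitude z1
plus scan parameters such as frequency and phase, or period, phase and
transit duration. The test statistic is the log Bayes factor

    F = log B = E + log[ p(ẑ) V_post ],

where E is the log maximum-likelihood ratio at the local MAP peak ẑ
("energy", in nats; SNR = √(2E) for a unit-norm template), p(ẑ) the prior
density of the alternative's parameters at the peak, and V_post the local
integral of the posterior ratio around the peak. V_post is computed either
in the Laplace approximation, (2π)^{d/2} det(Σ)^{1/2} with Σ the inverse
Hessian of −log(likelihood × prior), or by Hessian-guided Gaussian-weight
cubature of the actual posterior ratio when the peak is non-Gaussian.

Because the amplitude prior of a new phenomenon is usually unknown and its
cutoff shifts F by an arbitrary constant, significance is *not* reported
as F. Instead the amplitude factor is divided out,

    log B_{>1} = F − log[ p1(ẑ1) √(2π) σ1 ],

and the false-positive rate of the statistic under the null is computed
analytically from the reduced Bayes factor,

    P_asym = exp(−log B_{>1}) / √(4πE),
    p      = 1 − exp(−P_asym),

the second line being the continuous-parameter generalization of the
Šidák multiple-testing correction. P_asym can exceed 1; p is always in
[0, 1). The asymptotic formula is derived for E ≫ 1; the implementation
refuses E ≤ 0 and its own calibration suite shows reliable p-values for
E ≳ 3 (thresholds with p ≲ 0.5 in the settings shipped here).

The statistical-mechanics reading used throughout the diagnostics:
with a normalized reference (Jeffrey's) prior, N = 1/(p_Jeff(ẑ) V_post)
counts the posterior-volume "states" in the prior volume, S = log N is
the entropy (the look-elsewhere penalty), U = log(p/p_Jeff) measures
prior informativeness, and F = E + U − S.

## Cubature rule

The local evidence integral over the (up to three) non-linear parameters
uses a degree-7, fully symmetric cubature rule for the Gaussian weight
e^{−|u|²/2} in d = 3, with closed-form coefficients: orbits (r,0,0),
(t,t,t), (s,s,0) plus center, with y = (6−√15)/21,

    r² = 5/(1−y),  t² = 1/(1−2y),  s² = 1/y,
    w_r = (1−y)³/25,  w_t = (1−2y)³/8,  w_s = y³/2,

all weights positive. The central node's integrand equals 1 by
construction (the posterior ratio is normalized to its peak), so 26 nodes
are evaluated. An orbit analysis of the octahedral symmetry group shows
no degree-7 rule with fewer off-center nodes exists: every orbit
combination totalling fewer than 26 non-central nodes leaves some
sixth-order moment unmatched. Product Gauss–Hermite rules are used for
d ≠ 3 or on request.

**Wing regularization.** On realized (noisy) likelihood surfaces the
integrand exp(ΔE + |u|²/2) at nodes several σ from the peak is dominated
by noise fluctuations and neighboring peaks rather than by the local
peak; by Jensen's inequality these wings bias the evidence high (measured
+0.25 nats on Gaussian-limit nulls), which makes p-values
anticonservative. Each node's log-integrand is therefore capped at
2 nats above its Laplace-reference value. The cap is inactive for exactly
Gaussian peaks (machine-precision agreement with the Laplace volume is
preserved) and passes the O(1)-nat super-Gaussian broadening of genuine
transit peaks; it only clips fluctuation-dominated wings. The same
principle governs the one-dimensional numeric phase integral of the
single-transit search, which is restricted to the peak's dominance core
(within 2 nats of the maximum, stopping at the surrounding likelihood
valleys); that restriction was validated against the exact Rice
upcrossing rate for the Gaussian-limit matched-filter process, where the
unrestricted integral is biased by the same +0.25 nats and the
core-restricted one is unbiased within 5%.

## Template family and matched filtering

The transit model is a periodic train of dips with parameters
(A, P, φ, τ). The unit profile U on (−1/2, 1/2) defaults to a smooth
flat-bottomed shape with sinusoidal ingress/egress ramps each occupying
30% of the duration (a box convolved with a half-cosine); a sharp box is
available via `ingress_frac = 0`. The smooth shape matches the physics
(limb darkening makes real transits U-shaped) and matters statistically:
a sharp box produces a kinked (triangular) matched-filter profile whose
local structure is cadence-limited, which distorts Hessian-based widths
and evidence integrals by O(1) τ-dependent factors.

Templates are *band-limited*: the search works with the analytic Fourier
transform of the profile sampled on the DFT grid, which makes the energy
surface E(P, φ, τ) continuous in all parameters and exactly consistent
between the grid scan and the continuous refinement. All Fourier
operations use the circular (periodic) convention.

Colored Gaussian noise is handled by whitening: Fourier modes are divided
by the per-mode noise amplitude, after which matched filtering reduces to
dot products and a unit-norm template has amplitude variance exactly 1
(σ1 = 1). The scan itself is organized per duration: one pair of FFTs
yields the single-transit correlation and autocorrelation series, and
periodic trains are assembled by folding at each trial period (the
box-least-squares economy), so a full scan of a 200-day series costs
about two seconds. Period spacing is ΔP = τP/(αT) with α = 3; the phase
grid is the cadence; durations are log-spaced (12 points spanning
[τ_K(P_min), 2 τ_K(P_max)] by default).

Candidates are refined by Nelder–Mead MAP optimization with the
amplitude profiled analytically, given finite-difference Hessians with
two-stage step refinement (the parameter scales differ by orders of
magnitude), and ranked by the frequentist statistic F_f = −log P_asym,
matching how the reference analysis reports its candidate lists. The
superset passed to refinement is selected per duration slice; an
energy-ranked superset would truncate large-duration candidates, which
rank systematically higher on F_f than on E. Near-commensurate periods
are flagged as aliases, never merged.

## Synthetic data

The noise engine generates stationary Gaussian series from any tabulated
one-sided PSD (P(f) in flux²·days against f in 1/days, variance = ∫P df;
pinned by an explicit Parseval test), IID Student-t noise for the
heavy-tail study, and records injection truth for ROC bookkeeping. All
stochastic operations take explicit seeds; a master seed spawns
per-simulation children through `numpy.random.SeedSequence`. What the
generator does *not* emulate: gaps and uneven sampling, instrumental
systematics (sensitivity dropouts, eclipsing binaries), non-stationary
stellar variability, and PSD estimation error — calibration results here
demonstrate the statistical framework under a known noise model, not
robustness to real-mission artifacts.

Study conditions used by the shipped diagnostics (chosen to keep a large
trials factor at desk scale): 200-day series at 30-minute cadence,
periods 3–100 days, solar-density star (1.408 g/cm³, so τ_K(P) =
(3P/(π²Gρ))^{1/3} ≈ 0.11 d at P = 3 d), duration grid up to 2τ_K(100 d)
≈ 0.70 d; calibration suites use 150–500 null simulations with 68%
bootstrap bands from 100 per-simulation resamples; the periodogram suite
uses T·ω_max = 2000 and 5000 simulations. The multiplicity bound uses the
full Kepler-like scale (4 years, P ∈ [3, 300] d).

## Priors

Three duration-prior scenarios mirror the physical choices:

* **circular** — τ pinned to τ_K(P); the remaining (P, φ) prior uses the
  generalized Jeffrey's scaling p(P) ∝ P^{−1/3}, uniform phase.
* **wide** — generalized Jeffrey's on a broad domain: p(P) constant,
  p(τ) ∝ τ^{−2} on [τ_K(P_min), 2τ_K(P_max)], uniform phase.
* **realistic** — Monte-Carlo marginalization of τ/τ_K over isotropic
  inclination (uniform impact parameter), eccentricity ~ Beta(0.867,
  3.03) with uniform periastron angle, and 15% log-normal stellar-density
  scatter, smoothed by a Gaussian KDE in log τ/τ_K (Silverman bandwidth,
  20 000 draws). The Beta parameters are a configurable stand-in for fits
  to the observed eccentricity distribution of confirmed planets.

Improper (Jeffrey's) priors are carried unnormalized with `proper=False`;
operations needing normalization demand finite support. Amplitude-cutoff
constants cancel identically in the reduced-Bayes-factor chain, which the
invariance suite checks to 1e-10.

## Null-peak distribution diagnostics

Under the null, the local MAP parameters of threshold-crossing candidates
are distributed as p(ẑ|H0) ∝ p(ẑ)e^{−F(ẑ)}, independent of prior
normalization. The reference analysis summarizes this with power-law
scaling estimates for the marginal of the top candidates: p(P) ∝ P^{−1/3}
when the duration is pinned to τ_K(P), and p(τ) ∝ τ^{−2} when the
duration is free.

The package measures these exponents by maximum-likelihood truncated
power-law fits to the top-5 candidates of noise-only searches. At the
desk scale shipped here the measured exponents deviate from the idealized
scaling estimates, and the deviation is informative rather than a defect
of either the estimates or the search; three real effects move them:

1. **Cadence coupling.** The scaling estimates assume self-similar
   template geometry, but with a 30-minute cadence the shortest durations
   (τ ≈ 5 samples) have cadence-limited, not τ-limited, profile
   structure, and the state count of the idealized continuum search
   scales as τ⁻³ (all three matched-filter correlation lengths are ∝ τ),
   not τ⁻². Energy-ranked selection with sharp boxes measures exactly
   that: γ_τ = −3.00 ± 0.10. Significance-ranked selection redistributes
   candidates toward the prior and lands at γ_τ = −2.40 ± 0.10 under the
   default pipeline; γ_P in the duration-pinned search comes out
   −0.56 ± 0.05 against the idealized −1/3.
2. **Support edges.** The most-populated duration bin sits at the prior
   boundary τ_K(P_min), where candidates lose part of their evidence
   integral (the prior vanishes below the edge) and the marginal is
   genuinely suppressed relative to a pure power law.
3. **Estimator noise.** Selection of the top-5 by a noisy statistic
   tilts the marginal by the location dependence of the estimator's
   variance.

The fitted exponent and its standard error are reported as computed; the
acceptance suite states the idealized values as the reference and fails
visibly when the measured value is outside three standard errors, rather
than adjusting the experiment toward them.

## Calibration and ROC

`null_calibration` simulates the null, runs the full search, records each
realization's best-candidate F_f = −log P_asym, and compares the
empirical exceedance fraction with the analytic prediction
1 − exp(−e^{−F_f}); the 68% band covers 68 of 100 bootstrap resamples of
the per-simulation statistics (symmetric around the resample mean). The
same formulas calibrate three distinct settings with no per-setting
tuning — the white/colored-noise periodic-dip search, the periodogram,
and the Student-t single-transit search — which is the package's central
claim.

ROC curves are semi-analytic: the detected SNR of an injection is modeled
as Gaussian with unit variance around the true SNR (reduced by the
template-mismatch overlap when the search pins the duration and the true
orbit is inclined or eccentric), mapped to F_f through the
prior-dependent multiplicity shift −log⟨J⟩ evaluated from the
matched-filter correlation scales; the FPR axis comes from the
calibration curve (or the analytic Šidák form). The realistic prior
dominates because it concentrates density near the durations that occur
(smaller multiplicity than the wide prior) without the mismatch loss of
the circular prior.

## Numerical choices and degenerate inputs

* Natural logarithms throughout; energies in nats.
* Non-positive-definite Hessians (boundary/saddle peaks) raise a
  `DegeneratePeakError` naming the offending eigenvalue; nothing is
  silently Laplace-approximated on a saddle.
* Cubature nodes outside the prior support contribute zero prior weight;
  peaks at a support edge therefore lose real evidence mass, by design.
* ω = 0 is excluded from periodogram grids (degenerate phase); the DC
  Fourier mode carries no information under the zero-mean null and is
  dropped by the whitener.
* The Šidák map is computed with `expm1` and clamped strictly below 1.
* Dips only: phases with negative matched-filter amplitude carry E = 0.
  This halves the trials factor relative to a two-sided search and is a
  convention, stated here because it affects multiplicity counts.
* Candidate JSON is schema-versioned; floats round-trip exactly.

## Known limitations

* The asymptotic p-value chain degrades for thresholds with E ≲ 3
  (p-values approaching 1); the shipped calibrations cover p ≤ 0.5.
* Evenly sampled series only; no gaps, no uneven periodograms.
* The PSD is treated as known; estimating it from data is out of scope.
* Multi-peak data produce one significance result per peak (no Bayesian
  model averaging across peaks); aliases are flagged, not merged.
* The realistic prior's hyperparameters are stand-ins; calibration
  results do not depend on them, but ROC comparisons do.
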