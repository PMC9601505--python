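# lookelsewhere

Significance testing for searches over continuous parameter spaces, using
the Bayes factor as a frequentist test statistic with analytic
look-elsewhere p-values.

## The problem

A search for a new signal — a planet transit in a stellar light curve, a
periodicity in a time series — scans a continuum of alternatives: every
trial period, phase and duration is a separate hypothesis. The maximum
likelihood ratio over the scan is badly miscalibrated as a significance
measure (pure noise routinely produces SNR > 5 "detections"), and the
Bayes factor alone is hostage to the unknown amplitude prior. This
package combines the two methodologies: the Bayes factor is the test
statistic (it encodes the prior information that exists and the
Occam-razor multiplicity penalty), while the reported significance is its
frequentist false-positive rate, obtained *analytically* instead of from
thousands of null simulations.

For a local MAP peak with energy `E = log max-likelihood-ratio`
(SNR = √2E), prior density `p(ẑ)` and local posterior volume `V_post`,

    F        = E + log[ p(ẑ) · V_post ]               (log Bayes factor)
    log B>1  = F − log[ p1(ẑ1) · √(2π) σ1 ]           (amplitude divided out)
    P_asym   = exp(−log B>1) / √(4πE)                 (asymptotic false-positive rate)
    p        = 1 − exp(−P_asym)                       (continuous Šidák correction)

The arbitrary amplitude cutoff cancels exactly in `p`. The posterior
volume is computed by Laplace approximation or, for the non-Gaussian
peaks of realistic searches, by a degree-7 Gaussian cubature guided by
the peak Hessian.

## What's in the box

- `lookelsewhere.core` — Bayes factors, Laplace/cubature evidence,
  the asymptotic p-value and its Šidák extension, Jeffrey's priors,
  the free-energy decomposition `F = E + U − S` (energy vs entropy vs
  prior-informativeness).
- `lookelsewhere.analytic` — closed-form instantiations: the linear model
  (χ²_d null) and the periodogram (cylinder-volume false-alarm rate).
- `lookelsewhere.noise` — synthetic-data engine: stationary Gaussian
  noise from any one-sided PSD, Student-t noise, Fourier whitening,
  signal injection.
- `lookelsewhere.transit` — the flagship application: a periodic-dip
  template bank with matched filtering in the whitened domain (BLS-style
  fast folding, band-limited smooth U-shaped templates), MAP refinement,
  per-candidate evidence and p-values; plus a single-transit search in
  heavy-tailed Student-t noise.
- `lookelsewhere.calibration` / `lookelsewhere.ensemble` — null-simulation
  calibration curves with bootstrap bands, null-peak distribution fits,
  multiplicity (trials-factor) counts, semi-analytic ROC curves for
  circular / wide / realistic duration priors.
- `lookelsewhere` CLI — `simulate`, `search`, `periodogram`, `calibrate`,
  `roc`, `significance` subcommands over CSV/JSON/YAML files.

## Worked example

Inject an SNR-8 transit train (period 21.3 d, phase 0.37, duration 0.30 d,
depth 0.904 in unit-variance noise) into a 200-day, 30-minute-cadence
white-noise light curve and search periods 3–100 d with the wide
(generalized Jeffrey's) duration prior:

```python
import math
import numpy as np
from lookelsewhere.noise import (TimeSeries, inject_signal, make_psd,
                                 simulate_stationary_gaussian)
from lookelsewhere.transit import (ScanContext, SearchGrid, TransitParams,
                                   search_candidates, tau_prior,
                                   transit_template)

dt, n = 1 / 48, 9600
psd = make_psd("white", np.geomspace(0.5 / (n * dt), 24.0, 300),
               sigma=1.0, cadence=dt)
noise = simulate_stationary_gaussian(psd, n, dt, seed=10)

shape = transit_template(TransitParams(1.0, 21.3, 0.37, 0.30), noise.times)
unit = ScanContext(TimeSeries(noise.times, shape), psd)
depth = 8.0 / math.sqrt(2 * unit.energy(21.3, 0.37, 0.30))  # SNR 8
series = inject_signal(noise, depth * shape)

grid = SearchGrid(period_range=(3.0, 100.0), tau_mode="free")
prior = tau_prior("wide", grid)
for c in search_candidates(series, psd, grid, prior, k=3):
    s = c.significance
    print(f"P={c.params.period:7.3f} phase={c.params.phase:.3f} "
          f"tau={c.params.duration:.3f} SNR={math.sqrt(2 * s.energy):.2f} "
          f"logB>1={s.log_bf_reduced:+.2f} p={s.p_value:.2e}")
```

prints

    P= 21.297 phase=0.369 tau=0.389 SNR=8.35 logB>1=+16.86 p=2.28e-09
    P= 42.576 phase=0.685 tau=0.304 SNR=8.11 logB>1=+15.39 p=1.02e-08
    P= 63.888 phase=0.456 tau=0.426 SNR=6.71 logB>1=+4.98 p=4.09e-04

The injected planet is recovered at the right period and phase with a
false-positive probability of 2 × 10⁻⁹ — computed analytically, with no
null simulations. Candidates 1 and 2 are the 2:1 and 3:1 period aliases
of the same signal (reported separately, flagged, never silently merged).
For contrast, pure noise in this search routinely reaches SNR ≈ 5.5: the
look-elsewhere effect of the ~10⁶-state template bank is what the
`log B>1` → `p` chain accounts for.

The same chain calibrates three very different settings with no
per-setting tuning — the colored-noise periodic-dip search, the
periodogram, and a single-transit search in Student-t noise — which the
test suite verifies against null simulations (`tests/test_acceptance.py`).

See `docs/methods.md` for the model, the cubature rule, prior choices,
and known limitations.

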