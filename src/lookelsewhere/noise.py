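"""Synthetic noise engine: colored Gaussian series, Student-t noise, whitening.

Conventions (pinned by the Parseval test in the suite):

* Times are in days, fluxes dimensionless.
* Power spectra are one-sided, ``P(f)`` in flux^2 * days against frequency
  ``f`` in 1/days, with the total variance ``sigma^2 = int_0^f_Ny P(f) df``.
* Fourier operations treat the series as circular (periodic); all series
  are evenly sampled.
* Every stochastic operation takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

__all__ = [
    "TimeSeries",
    "PowerSpectrum",
    "make_psd",
    "simulate_stationary_gaussian",
    "simulate_student_t",
    "whiten",
    "inject_signal",
]


@dataclass
class TimeSeries:
    """Evenly sampled observations (times in days, values in relative flux)."""

    times: np.ndarray
    values: np.ndarray
    per_point_sigma: Union[float, np.ndarray] = 1.0
    injection: Optional[dict] = None  # truth metadata for ROC bookkeeping

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.any(np.abs(steps - steps[0]) > 1e-9 * steps[0]):
                raise ValueError("times must be evenly spaced")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def cadence(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Total observation span n * cadence (circular convention)."""
        return self.n * self.cadence


@dataclass
class PowerSpectrum:
    """One-sided noise PSD: ``power`` in flux^2 * days on ``frequencies`` 1/days."""

    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape or self.frequencies.ndim != 1:
            raise ValueError("frequencies and power must be 1-D arrays of equal length")
        if self.frequencies[0] <= 0 or np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequencies must be strictly increasing and positive")
        if np.any(self.power <= 0):
            raise ValueError("power must be strictly positive")

    def interp(self, f: np.ndarray) -> np.ndarray:
        """Power interpolated (log-log) onto frequencies ``f``."""
        f = np.asarray(f, dtype=float)
        if np.any(f < self.frequencies[0] - 1e-12) or np.any(
            f > self.frequencies[-1] + 1e-6 * self.frequencies[-1]
        ):
            raise ValueError(
                "PSD grid mismatch: requested frequencies outside the tabulated range"
            )
        logp = np.interp(np.log(np.maximum(f, self.frequencies[0])),
                         np.log(self.frequencies), np.log(self.power))
        return np.exp(logp)

    def variance(self) -> float:
        """Total variance int P(f) df (trapezoid on the tabulated grid)."""
        return float(np.trapezoid(self.power, self.frequencies))


def fourier_mode_variance(psd: PowerSpectrum, n: int, cadence: float) -> np.ndarray:
    """Expected ``|DFT(noise)_k|^2`` for the rfft bins of an n-point series.

    With the one-sided convention, ``E|X_k|^2 = n P(f_k) / (2 dt)`` for
    every bin (Nyquist included), which makes the time-domain variance
    equal ``int P df``.  The DC bin is returned as inf (zero-mean
    convention: no information at f=0).
    """
    freqs = np.fft.rfftfreq(n, d=cadence)
    s = np.empty_like(freqs)
    s[0] = np.inf
    s[1:] = n * psd.interp(freqs[1:]) / (2.0 * cadence)
    return s


def make_psd(
    model: str,
    grid: np.ndarray,
    *,
    sigma: float = 1.0,
    cadence: Optional[float] = None,
    index: float = -2.0,
    knee: float = 1.0,
    components: Optional[list] = None,
) -> PowerSpectrum:
    """Analytic PSD families standing in for measured stellar spectra.

    ``model`` is one of

    * ``"white"``: flat, ``P = sigma^2 * 2 * cadence`` so that an n-point
      series has per-point variance ``sigma^2``;
    * ``"powerlaw"``: ``P(f) = A (f / knee)^index`` with the amplitude set
      so that the variance integrated over ``grid`` equals ``sigma^2``;
    * ``"mixture"``: pointwise sum of component spectra (pass
      ``components=[PowerSpectrum, ...]``).
    """
    grid = np.asarray(grid, dtype=float)
    if model == "white":
        if cadence is None or cadence <= 0:
            raise ValueError("white PSD needs a positive cadence")
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        power = np.full_like(grid, sigma**2 * 2.0 * cadence)
        return PowerSpectrum(grid, power)
    if model == "powerlaw":
        if sigma <= 0 or knee <= 0:
            raise ValueError("sigma and knee must be positive")
        shape = (grid / knee) ** index
        norm = np.trapezoid(shape, grid)
        return PowerSpectrum(grid, sigma**2 * shape / norm)
    if model == "mixture":
        if not components:
            raise ValueError("mixture needs a list of component spectra")
        power = np.zeros_like(grid)
        for comp in components:
            power = power + comp.interp(grid)
        return PowerSpectrum(grid, power)
    raise ValueError(f"unknown PSD model {model!r}")


def simulate_stationary_gaussian(
    psd: PowerSpectrum, n: int, cadence: float, seed: int
) -> TimeSeries:
    """Stationary Gaussian noise with the given one-sided PSD.

    Independent complex Fourier coefficients with uniformly distributed
    phases and normally distributed amplitudes of variance set by the PSD
    are inverse-transformed to the time domain.  Deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    s = fourier_mode_variance(psd, n, cadence)
    n_bins = s.size
    coeff = np.zeros(n_bins, dtype=complex)
    # interior bins: complex Gaussian, half the variance per quadrature
    re = rng.standard_normal(n_bins - 1)
    im = rng.standard_normal(n_bins - 1)
    coeff[1:] = (re + 1j * im) * np.sqrt(s[1:] / 2.0)
    if n % 2 == 0:
        coeff[-1] = re[-1] * math.sqrt(s[-1])  # Nyquist bin is real
    values = np.fft.irfft(coeff, n=n)
    times = cadence * np.arange(n)
    sigma = math.sqrt(psd.variance())
    return TimeSeries(times, values, per_point_sigma=sigma)


def simulate_student_t(nu: float, n: int, seed: int, cadence: float = 1.0) -> TimeSeries:
    """IID Student-t noise with ``nu`` degrees of freedom (unit scale)."""
    if nu <= 0:
        raise ValueError("nu must be positive")
    rng = np.random.default_rng(seed)
    values = rng.standard_t(df=nu, size=n)
    return TimeSeries(cadence * np.arange(n), values, per_point_sigma=1.0)


def whiten(series: TimeSeries, psd: PowerSpectrum) -> TimeSeries:
    """Divide Fourier modes by the noise amplitude, making them unit-variance.

    The whitened series ``xt`` satisfies ``sum_j xt_j yt_j = <x, y>`` where
    ``<.,.>`` is the noise-covariance-weighted inner product, so matched
    filtering on whitened data reduces to ordinary dot products.  The DC
    mode carries no information under the zero-mean null and is set to 0.
    """
    s = fourier_mode_variance(psd, series.n, series.cadence)
    if not np.all(s[1:] > 0):
        raise ValueError("zero-power mode: PSD must be strictly positive")
    coeff = np.fft.rfft(series.values)
    coeff[0] = 0.0
    coeff[1:] = coeff[1:] * math.sqrt(series.n) / np.sqrt(s[1:])
    values = np.fft.irfft(coeff, n=series.n)
    return TimeSeries(series.times.copy(), values, per_point_sigma=1.0,
                      injection=series.injection)


def inject_signal(series: TimeSeries, model_values: np.ndarray, truth: Optional[dict] = None) -> TimeSeries:
    """Pointwise sum of a series and a signal model, recording the truth."""
    model_values = np.asarray(model_values, dtype=float)
    if model_values.shape != series.values.shape:
        raise ValueError("model must have the same length as the series")
    meta = dict(series.injection or {})
    if truth:
        meta.update(truth)
    meta.setdefault("injected", True)
    return TimeSeries(
        series.times.copy(),
        series.values + model_values,
        per_point_sigma=series.per_point_sigma,
        injection=meta,
    )


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Child seeds for n independent simulations by a fixed counter scheme."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)])
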