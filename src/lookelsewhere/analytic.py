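"""Closed-form instantiations of the framework: linear model and periodogram.

Both models admit fully analytic Bayes factors and look-elsewhere
p-values, which makes them useful end-to-end checks of the general
machinery as well as practical tools in their own right.

Linear model
    Data ``x in R^n`` with standard Gaussian noise; the signal is a linear
    superposition of ``d`` orthonormal features.  The MAP weights are the
    projections ``w_i = x . m_i``, the energy is ``E = sum w_i^2 / 2`` and
    ``2E`` is chi^2-distributed with ``d`` degrees of freedom under the
    null.

Periodogram
    A sinusoid of unknown amplitude, frequency and phase in white noise.
    With the template normalized so that ``E = z1^2 / 2``, the
    look-elsewhere p-value over a frequency scan up to ``omega_max`` is
    ``P_asym = (T omega_max / sqrt(12 pi)) int_E^inf u^{1/2} e^-u du``,
    independent of the amplitude prior cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import special, stats

from lookelsewhere.core import extend_pvalue_sidak
from lookelsewhere.noise import TimeSeries

__all__ = [
    "LinearModelSpec",
    "PeriodogramSpec",
    "orthonormalize_features",
    "linear_map_fit",
    "linear_model_pvalue",
    "linear_model_log_bayes",
    "periodogram_scan",
    "periodogram_pvalue",
    "periodogram_log_bayes",
    "unit_ball_volume",
]


@dataclass
class LinearModelSpec:
    """``n x d`` feature matrix with an amplitude-ball prior cutoff."""

    features: np.ndarray
    orthonormal: bool = False
    amplitude_cutoff: float = 1.0

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        if self.amplitude_cutoff <= 0:
            raise ValueError("amplitude_cutoff must be positive")
        if self.orthonormal:
            gram = self.features.T @ self.features
            if np.max(np.abs(gram - np.eye(self.d))) > 1e-10:
                raise ValueError("features flagged orthonormal are not")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def d(self) -> int:
        return self.features.shape[1]


@dataclass
class PeriodogramSpec:
    """Scan definition for a sinusoid search.

    ``duration`` T in time units, ``omega_max`` in rad/time; the frequency
    grid is oversampled relative to the natural spacing ``2 pi / T`` so
    that the grid maximum stands in for the continuous maximum.  omega = 0
    is excluded (the phase is degenerate and the Fisher matrix singular
    there).
    """

    duration: float
    omega_max: float
    amplitude_cutoff: float = 1.0
    oversampling: float = 5.0
    frequency_grid: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.omega_max <= 0:
            raise ValueError("duration and omega_max must be positive")
        if self.oversampling < 5:
            raise ValueError("oversampling must be >= 5")
        if self.frequency_grid is None:
            step = 2.0 * math.pi / (self.duration * self.oversampling)
            self.frequency_grid = np.arange(step, self.omega_max * (1.0 + 1e-12), step)
        else:
            self.frequency_grid = np.asarray(self.frequency_grid, dtype=float)
        if self.frequency_grid[0] <= 0 or self.frequency_grid[-1] > self.omega_max * (1 + 1e-12):
            raise ValueError("frequency grid must lie in (0, omega_max]")


def orthonormalize_features(features: np.ndarray) -> LinearModelSpec:
    """Gram-Schmidt orthonormalization of a feature matrix.

    Raises a ``ValueError`` naming the first linearly dependent column if
    the features are rank-deficient.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n, d = features.shape
    basis = np.empty_like(features)
    for j in range(d):
        v = features[:, j].copy()
        for k in range(j):
            v -= (v @ basis[:, k]) * basis[:, k]
        norm = float(np.linalg.norm(v))
        if norm <= 1e-10 * max(1.0, float(np.linalg.norm(features[:, j]))):
            raise ValueError(
                f"feature column {j} is linearly dependent on previous columns"
            )
        basis[:, j] = v / norm
    return LinearModelSpec(features=basis, orthonormal=True)


def linear_map_fit(data: np.ndarray, model: LinearModelSpec) -> tuple[np.ndarray, float]:
    """MAP weights and energy of the linear model.

    The MAP model is the projection of the data on the model plane:
    ``w_i = x . m_i`` and ``E = sum w_i^2 / 2``.
    """
    data = np.asarray(data, dtype=float)
    if data.shape != (model.n,):
        raise ValueError(f"data must have length {model.n}")
    if not model.orthonormal:
        model = orthonormalize_features(model.features)
    w = model.features.T @ data
    energy = 0.5 * float(w @ w)
    return w, energy


def linear_model_pvalue(energy: float, d: int) -> float:
    """Upper chi^2_d tail of ``2E``: the exact null p-value of the MLR."""
    if energy < 0 or d < 1:
        raise ValueError("need energy >= 0 and d >= 1")
    return float(stats.chi2.sf(2.0 * energy, df=d))


def unit_ball_volume(d: int) -> float:
    """Volume of the d-dimensional unit ball."""
    return math.pi ** (d / 2.0) / math.gamma(d / 2.0 + 1.0)


def linear_model_log_bayes(energy: float, d: int, w_max: float) -> float:
    """Log Bayes factor with a uniform amplitude-ball prior of radius w_max.

    ``F = E + log[(2 pi)^{d/2} / (V(B_d) w_max^d)]``.  F and E differ only
    by a constant, so both are equally good frequentist test statistics;
    the p-value is independent of the (often unknown) cutoff.
    """
    if w_max <= 0:
        raise ValueError("w_max must be positive")
    return float(
        energy
        + 0.5 * d * math.log(2.0 * math.pi)
        - math.log(unit_ball_volume(d))
        - d * math.log(w_max)
    )


def periodogram_scan(series: TimeSeries, spec: PeriodogramSpec) -> pd.DataFrame:
    """Project the series onto an orthonormalized sin/cos pair per frequency.

    Returns a table with columns ``omega, z1_hat, phi_hat, E, is_max``.
    With the SNR normalization, ``E(omega) = z1_hat^2 / 2`` and under
    white noise ``2E`` at a fixed frequency is chi^2_2 distributed.
    """
    if series.n < 4:
        raise ValueError("periodogram needs at least 4 points")
    sigma = float(np.atleast_1d(series.per_point_sigma)[0])
    x = series.values / sigma
    t = series.times
    omegas = spec.frequency_grid
    z1 = np.empty_like(omegas)
    phi = np.empty_like(omegas)
    for i, om in enumerate(omegas):
        s, c = np.sin(om * t), np.cos(om * t)
        # exact per-frequency Gram-Schmidt of the (sin, cos) pair
        s_n = s / np.linalg.norm(s)
        c = c - (c @ s_n) * s_n
        c_n = c / np.linalg.norm(c)
        a, b = x @ s_n, x @ c_n
        z1[i] = math.hypot(a, b)
        phi[i] = math.atan2(b, a)
    energy = 0.5 * z1**2
    table = pd.DataFrame(
        {"omega": omegas, "z1_hat": z1, "phi_hat": phi, "E": energy}
    )
    table["is_max"] = False
    table.loc[table["E"].idxmax(), "is_max"] = True
    return table


def periodogram_pvalue_asym(energy: float, spec: PeriodogramSpec) -> float:
    """Asymptotic false-positive rate of the periodogram maximum.

    ``P_asym = (T omega_max / sqrt(12 pi)) Gamma(3/2) Q(3/2, E)`` where
    ``Q`` is the regularized upper incomplete gamma: the constant-
    likelihood surface in (amplitude, phase, omega) is a cylinder whose
    volume the parameter-space integral picks up.  Independent of the
    amplitude cutoff z_max.
    """
    if energy <= 0:
        raise ValueError("energy must be positive")
    tail = special.gammaincc(1.5, energy) * special.gamma(1.5)
    return float(spec.duration * spec.omega_max / math.sqrt(12.0 * math.pi) * tail)


def periodogram_pvalue(energy: float, spec: PeriodogramSpec) -> float:
    """Sidak-extended look-elsewhere p-value of a periodogram peak."""
    return extend_pvalue_sidak(periodogram_pvalue_asym(energy, spec))


def periodogram_log_bayes(energy: float, spec: PeriodogramSpec) -> float:
    """Log Bayes factor of a periodogram peak with uniform priors.

    ``F = E + log[sqrt(6 pi) / (z_max omega_max T E)]``; the cutoff
    z_max enters F but cancels in the p-value, and
    ``dF/dE = 1 - 1/E``.
    """
    if energy <= 0:
        raise ValueError("energy must be positive")
    return float(
        energy
        + 0.5 * math.log(6.0 * math.pi)
        - math.log(spec.amplitude_cutoff * spec.omega_max * spec.duration * energy)
    )
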