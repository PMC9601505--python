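"""Ensemble-level quantities: multiplicity counts and ROC ingredients.

These are the search-wide (rather than per-candidate) numbers: the total
number of distinguishable template states ``N`` in a scan domain (the
trials factor of the look-elsewhere effect), the corresponding entropy
shift per prior choice used by the semi-analytic ROC curves, and the
distribution of SNR reduction factors suffered by a duration-pinned
search template when the true orbit is inclined or eccentric.

State counting uses the white-noise matched-filter correlation scales of
the box train: at reference energy E the posterior widths are

* phase:     ``tau / (P sqrt(2 E / dt / tau))``-type, cadence-limited,
* period:    the phase width shrunk by the number of transits,
* duration:  proportional to ``tau``,

assembled from the finite-difference Hessian of the actual energy
surface on a coarse grid, so the count reflects the template family as
implemented rather than an idealized scaling.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from lookelsewhere import core
from lookelsewhere.noise import PowerSpectrum, TimeSeries
from lookelsewhere.transit import (
    ScanContext,
    SearchGrid,
    kepler_duration,
    snr_reduction,
    tau_prior,
)

__all__ = [
    "state_count",
    "prior_entropy_shifts",
    "circular_reduction_factors",
    "orbit_duration_factors",
]


def _local_widths(
    ctx: ScanContext, period: float, tau: float, snr_ref: float
) -> np.ndarray:
    """Posterior widths (P, phi, tau) of a template at reference SNR.

    Uses the curvature of the normalized template autocorrelation
    ``rho(z)`` around a self-match: for a peak of height ``z1 = snr_ref``
    the profiled energy falls as ``E rho^2``, so the width in direction i
    is ``1 / sqrt(E * |d^2 rho^2 / dz_i^2|)``.
    """
    m0 = ctx.template_fft(period, 0.5, tau)
    inv = np.where(np.isfinite(ctx.mode_var), 1.0 / ctx.mode_var, 0.0)
    w = ctx._weights
    n0 = float(np.sum(w * np.abs(m0) ** 2 * inv))

    def rho(dp: float, dphi: float, dtau: float) -> float:
        m = ctx.template_fft(period + dp, 0.5 + dphi, tau + dtau)
        cross = float(np.sum(w * np.real(np.conj(m0) * m) * inv))
        nn = float(np.sum(w * np.abs(m) ** 2 * inv))
        return cross / math.sqrt(n0 * nn)

    e_ref = 0.5 * snr_ref**2
    widths = np.empty(3)
    steps = [tau * period / (4.0 * ctx.duration), tau / (4.0 * period), 0.05 * tau]
    for i, step in enumerate(steps):
        d = [0.0, 0.0, 0.0]
        d[i] = step
        r = 0.5 * (rho(*d) + rho(*[-v for v in d]))
        curv = max(2.0 * (1.0 - r) / step**2, 1e-300)  # of 1 - rho
        # energy profile E rho(z)^2: curvature of -E rho^2 = 2 E curv(1-rho)
        widths[i] = 1.0 / math.sqrt(2.0 * e_ref * curv)
    return widths  # (P, phi, tau) widths


def state_count(
    grid: SearchGrid,
    n: int,
    cadence: float,
    snr_ref: float = 8.0,
    psd: Optional[PowerSpectrum] = None,
    n_period: int = 12,
    n_tau: int = 8,
) -> float:
    """Total number of distinguishable template states in the scan domain.

    ``N = int dz / V_post(z)`` with the Laplace posterior volume
    ``(2 pi)^{d/2} prod(width_i)`` at the reference SNR, evaluated on a
    coarse (P, tau) grid and integrated over the domain (phase volume is
    one period's worth of distinct phases).  This is the multiplicity
    whose logarithm is the entropy in the free-energy decomposition.
    """
    dummy = TimeSeries(cadence * np.arange(n), np.zeros(n))
    ctx = ScanContext(dummy, psd)
    pmin, pmax = grid.period_range
    periods = np.geomspace(pmin, pmax, n_period)
    free = grid.tau_mode == "free"
    if free:
        tmin, tmax = grid.tau_range
        taus = np.geomspace(tmin, tmax, n_tau)
    total = 0.0
    d = 3 if free else 2
    norm = (2.0 * math.pi) ** (d / 2.0)
    for i, p in enumerate(periods):
        dp = (
            periods[min(i + 1, n_period - 1)] - periods[max(i - 1, 0)]
        ) / (2.0 if 0 < i < n_period - 1 else 1.0)
        tau_list = taus if free else [kepler_duration(p, grid.stellar_density)]
        for j, tau in enumerate(tau_list):
            if tau >= p / 2:
                continue
            w = _local_widths(ctx, p, tau, snr_ref)
            if free:
                dtau = (
                    taus[min(j + 1, n_tau - 1)] - taus[max(j - 1, 0)]
                ) / (2.0 if 0 < j < n_tau - 1 else 1.0)
                cell = dp * 1.0 * dtau  # phase in [0,1)
                vpost = norm * w[0] * w[1] * w[2]
            else:
                cell = dp * 1.0
                vpost = norm * w[0] * w[1]
            total += cell / vpost
    return total


def prior_entropy_shifts(
    grid: SearchGrid,
    n: int,
    cadence: float,
    snr_ref: float = 8.0,
    seed: int = 0,
) -> dict[str, float]:
    """Multiplicity penalty ``-log <J>`` per prior choice for ROC curves.

    ``J = p(zhat) V_nl`` is the prior-weighted local volume entering the
    reduced Bayes factor; its typical value under a detection at the
    Kepler duration sets how the significance of a recovered signal is
    shifted relative to the bare energy.  Evaluated at a representative
    mid-domain period.
    """
    dummy = TimeSeries(cadence * np.arange(n), np.zeros(n))
    ctx = ScanContext(dummy, None)
    pmin, pmax = grid.period_range
    p_ref = math.sqrt(pmin * pmax)
    tau_ref = kepler_duration(p_ref, grid.stellar_density)
    w = _local_widths(ctx, p_ref, tau_ref, snr_ref)
    shifts: dict[str, float] = {}
    for choice in ("circular", "wide", "realistic"):
        prior = tau_prior(choice, grid, seed=seed)
        if choice == "circular":
            prior_n = prior if prior.proper else prior.normalized()
            dens = prior_n(np.array([p_ref, 0.5]))
            v_nl = (2.0 * math.pi) * w[0] * w[1]
        else:
            prior_n = prior if prior.proper else prior.normalized(n_per_dim=41)
            dens = prior_n(np.array([p_ref, 0.5, tau_ref]))
            v_nl = (2.0 * math.pi) ** 1.5 * w[0] * w[1] * w[2]
        shifts[choice] = -math.log(max(dens * v_nl, 1e-300))
    return shifts


def orbit_duration_factors(
    n_draws: int = 2000,
    ecc_beta_a: float = 0.867,
    ecc_beta_b: float = 3.03,
    density_sigma_frac: float = 0.15,
    seed: int = 0,
) -> np.ndarray:
    """Draws of ``tau_true / tau_K`` for inclined, eccentric orbits."""
    rng = np.random.default_rng(seed)
    ecc = rng.beta(ecc_beta_a, ecc_beta_b, n_draws)
    omega = rng.uniform(0.0, 2.0 * math.pi, n_draws)
    impact = rng.uniform(0.0, 1.0, n_draws)
    rho_fac = np.exp(rng.normal(0.0, density_sigma_frac, n_draws)) ** (-1.0 / 3.0)
    return (
        np.sqrt(1.0 - impact**2)
        * np.sqrt(1.0 - ecc**2)
        / (1.0 + ecc * np.sin(omega))
        * rho_fac
    )


def circular_reduction_factors(
    grid: SearchGrid,
    n_draws: int = 200,
    seed: int = 0,
    period: Optional[float] = None,
) -> np.ndarray:
    """SNR reduction factors for a tau-pinned search template.

    The search uses ``tau_K(P)`` while the true orbit has
    ``tau = u * tau_K`` with ``u`` from :func:`orbit_duration_factors`;
    for aligned boxes in white noise the reduction is
    ``sqrt(min(u, 1/u))``.
    """
    pmin, pmax = grid.period_range
    p = period if period is not None else math.sqrt(pmin * pmax)
    tau_k = kepler_duration(p, grid.stellar_density)
    u = orbit_duration_factors(n_draws, seed=seed,
                               density_sigma_frac=grid.density_sigma_frac)
    out = np.empty(n_draws)
    for i, ui in enumerate(u):
        out[i] = snr_reduction(ui * tau_k, tau_k, p, 0.5, None)
    return out
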