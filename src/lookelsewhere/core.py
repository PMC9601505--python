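"""Local Bayes factors and analytic look-elsewhere p-values.

The central objects are a local MAP peak (location, log maximum-likelihood
ratio ``E``, Hessian, posterior volume) and a prior over the alternative's
parameters.  From these the module computes

* the log Bayes factor ``F = E + log(p(zhat) * V_post)``,
* the reduced log Bayes factor ``log B_{>1}`` with the amplitude's
  prior/posterior factor divided out,
* the asymptotic false-positive rate
  ``P_asym = exp(-log B_{>1}) / sqrt(4 pi E)``,
* its continuous-parameter Sidak extension ``p = 1 - exp(-P_asym)``,
* and a statistical-mechanics decomposition ``F = E + U - S`` in which the
  entropy ``S = log N`` counts posterior-volume "states" in the prior
  volume and the potential ``U`` measures how informative the prior is.

All logarithms are natural; energies are in nats and SNR = sqrt(2 E).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from lookelsewhere.cubature import gauss_weight_rule

__all__ = [
    "PeakEstimate",
    "PriorSpec",
    "SignificanceResult",
    "laplace_volume",
    "local_evidence_cubature",
    "log_bayes_factor",
    "reduced_log_bayes_factor",
    "asymptotic_pvalue",
    "asymptotic_pvalue_integral",
    "extend_pvalue_sidak",
    "jeffreys_density",
    "null_peak_density",
    "free_energy_decomposition",
]


class DegeneratePeakError(ValueError):
    """Raised when a peak's Hessian is not positive definite.

    A non-positive-definite Hessian signals a boundary or saddle peak for
    which the Laplace posterior volume is undefined.
    """


@dataclass
class PeakEstimate:
    """A local MAP solution of the alternative hypothesis.

    Parameters
    ----------
    location
        Parameter values ``zhat`` at the peak (mixed units).  The
        coordinate at ``amplitude_index`` is the linear amplitude ``z1``.
    energy
        Log maximum-likelihood ratio ``E`` at the peak, in nats.
    hessian
        ``d x d`` matrix of second derivatives of
        ``-log(likelihood * prior)`` at ``zhat``.
    amplitude_sigma
        Posterior standard deviation ``sigma_1`` of the amplitude.
    posterior_volume
        Local integral of the posterior ratio around the peak (product of
        parameter units); filled in by Laplace or cubature.
    amplitude_index
        Which coordinate of ``location`` is the amplitude.
    """

    location: np.ndarray
    energy: float
    hessian: np.ndarray
    amplitude_sigma: float = 1.0
    posterior_volume: Optional[float] = None
    amplitude_index: int = 0

    def __post_init__(self) -> None:
        self.location = np.atleast_1d(np.asarray(self.location, dtype=float))
        self.hessian = np.atleast_2d(np.asarray(self.hessian, dtype=float))
        if self.energy < 0:
            raise ValueError(f"energy must be >= 0, got {self.energy}")
        if self.amplitude_sigma <= 0:
            raise ValueError("amplitude_sigma must be positive")
        asym = np.max(np.abs(self.hessian - self.hessian.T))
        scale = max(1.0, np.max(np.abs(self.hessian)))
        if asym > 1e-8 * scale:
            raise ValueError(f"hessian not symmetric (max asymmetry {asym:.3g})")
        if self.posterior_volume is not None and self.posterior_volume <= 0:
            raise ValueError("posterior_volume must be positive when set")

    @property
    def dim(self) -> int:
        return self.location.size


@dataclass
class PriorSpec:
    """Prior density for the alternative hypothesis parameters.

    ``density`` maps a parameter vector to probability per unit parameter
    volume; it must vanish outside ``support`` (a sequence of
    ``(low, high)`` bounds, one per parameter).  ``kind`` is one of
    ``"informative"``, ``"jeffreys"`` or ``"generalized_jeffreys"``.
    Improper priors (``proper=False``) are carried unnormalized; any
    operation that needs a normalization demands explicit finite support.
    """

    density: Callable[[np.ndarray], float]
    support: Sequence[tuple[float, float]]
    kind: str = "informative"
    proper: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("informative", "jeffreys", "generalized_jeffreys"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        self.support = [(float(a), float(b)) for a, b in self.support]
        for a, b in self.support:
            if not a < b:
                raise ValueError(f"empty support interval ({a}, {b})")

    @property
    def dim(self) -> int:
        return len(self.support)

    def contains(self, z: np.ndarray) -> bool:
        z = np.atleast_1d(z)
        return all(a <= zi <= b for zi, (a, b) in zip(z, self.support))

    def __call__(self, z: np.ndarray) -> float:
        z = np.atleast_1d(np.asarray(z, dtype=float))
        if not self.contains(z):
            return 0.0
        val = float(self.density(z))
        if val < 0:
            raise ValueError(f"prior density negative at {z}")
        return val

    def grid(self, n_per_dim: int) -> tuple[np.ndarray, float]:
        """Tensor grid over the support with midpoint spacing.

        Returns the ``(n_points, d)`` array of grid points and the cell
        volume; used for low-dimensional numeric normalization and
        integration.
        """
        axes, vol = [], 1.0
        for a, b in self.support:
            step = (b - a) / n_per_dim
            axes.append(a + step * (np.arange(n_per_dim) + 0.5))
            vol *= step
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
        return pts, vol

    def normalization(self, n_per_dim: int = 201) -> float:
        """Numeric integral of the density over the support."""
        if self.dim > 3:
            raise ValueError("numeric normalization supported for d <= 3 only")
        pts, vol = self.grid(n_per_dim)
        vals = np.array([self.density(p) for p in pts])
        return float(np.sum(vals) * vol)

    def normalized(self, n_per_dim: int = 201) -> "PriorSpec":
        """Return a proper prior rescaled to integrate to 1 on the support."""
        const = self.normalization(n_per_dim)
        if not const > 0:
            raise ValueError("prior has zero mass on its support")
        dens = self.density
        return PriorSpec(
            density=lambda z, _c=const, _d=dens: _d(z) / _c,
            support=self.support,
            kind=self.kind,
            proper=True,
        )


@dataclass
class SignificanceResult:
    """The statistic stack for one candidate peak.

    ``log_bf`` is F in nats, ``log_bf_reduced`` is log B_{>1},
    ``p_asym`` the asymptotic false-positive rate (may exceed 1) and
    ``p_value`` its Sidak extension into [0, 1].  ``entropy``/``potential``
    /``multiplicity`` hold the free-energy decomposition when computed.
    """

    log_bf: float
    energy: float
    log_bf_reduced: Optional[float] = None
    p_asym: Optional[float] = None
    p_value: Optional[float] = None
    entropy: Optional[float] = None
    potential: Optional[float] = None
    multiplicity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.p_asym is not None and self.p_value is None:
            self.p_value = extend_pvalue_sidak(self.p_asym)


def laplace_volume(hessian: np.ndarray) -> float:
    """Posterior volume in the Laplace approximation.

    For a peak with covariance ``Sigma = hessian^{-1}`` the local integral
    of the posterior ratio is ``(2 pi)^{d/2} sqrt(det Sigma)``.

    Raises
    ------
    DegeneratePeakError
        If the Hessian has a non-positive eigenvalue (boundary or saddle
        peak); the message names the offending eigenvalue.
    """
    hessian = np.atleast_2d(np.asarray(hessian, dtype=float))
    d = hessian.shape[0]
    if hessian.shape != (d, d):
        raise ValueError("hessian must be square")
    eigvals = np.linalg.eigvalsh(0.5 * (hessian + hessian.T))
    if eigvals[0] <= 0:
        raise DegeneratePeakError(
            "boundary/degenerate peak: hessian has non-positive eigenvalue "
            f"{eigvals[0]:.6g}; Laplace volume undefined"
        )
    return float((2.0 * math.pi) ** (d / 2.0) / math.sqrt(np.prod(eigvals)))


def local_evidence_cubature(
    log_posterior_ratio: Callable[[np.ndarray], float],
    peak: PeakEstimate,
    degree: int = 7,
    max_excess: float = 2.0,
) -> float:
    """Local evidence integral by Gaussian-weight cubature.

    Integrates ``exp(log_posterior_ratio(z))`` over the neighborhood of
    the peak.  The peak Hessian defines an affine map ``z = zhat + L u``
    with ``L L^T = hessian^{-1}``; in ``u`` the integrand is evaluated on
    the nodes of a Gaussian-weight cubature rule of the requested degree
    (degree 7 in d=3 evaluates exactly 24 off-center nodes, the value at
    the central node being fixed to 1 by the normalization
    ``log_posterior_ratio(zhat) = 0``).

    For an exactly Gaussian log-posterior ratio with the same Hessian the
    result equals :func:`laplace_volume` to rule precision.

    ``max_excess`` regularizes the integrand: each node's log-integrand
    is capped at ``max_excess`` nats above its Laplace-reference value
    (for which the cap is inactive, preserving Gaussian exactness).
    Genuine non-Gaussian peak cores are wider than Gaussian by O(1) nats
    and pass the cap; larger excesses occur where the evaluated surface
    is dominated by noise fluctuations or neighboring peaks rather than
    the local peak, and integrating them would inflate the evidence
    (on noise-only data the uncapped integral is biased high by the
    Jensen effect of the fluctuations, which makes the downstream
    p-values anticonservative).
    """
    d = peak.dim
    hessian = 0.5 * (peak.hessian + peak.hessian.T)
    eigvals, eigvecs = np.linalg.eigh(hessian)
    if eigvals[0] <= 0:
        raise DegeneratePeakError(
            "boundary/degenerate peak: hessian has non-positive eigenvalue "
            f"{eigvals[0]:.6g}; cubature map undefined"
        )
    # L = Sigma^{1/2} via eigendecomposition, Sigma = hessian^{-1}
    L = eigvecs @ np.diag(eigvals**-0.5) @ eigvecs.T
    det_L = float(np.prod(eigvals**-0.5))

    center_value = float(log_posterior_ratio(peak.location))
    if abs(center_value) > 1e-6:
        raise ValueError(
            "log_posterior_ratio must vanish at the peak "
            f"(got {center_value:.3g}); pass the ratio to the peak value"
        )

    nodes, weights, w_center = gauss_weight_rule(d, degree)
    total = w_center  # central node contributes exp(0) analytically
    for i, (u, w) in enumerate(zip(nodes, weights)):
        z = peak.location + L @ u
        lpr = float(log_posterior_ratio(z))
        if math.isnan(lpr) or lpr == math.inf:
            raise ValueError(
                f"integrand non-finite at cubature node {i} (z = {z})"
            )
        g = math.exp(min(lpr + 0.5 * float(u @ u), max_excess))
        total += w * g
    return det_L * total


def log_bayes_factor(
    energy: float, prior_density_at_peak: float, posterior_volume: float
) -> float:
    """Log Bayes factor ``F = E + log(p(zhat) * V_post)``.

    Returns ``-inf`` when the prior density at the peak is zero.
    """
    if posterior_volume <= 0:
        raise ValueError("posterior_volume must be positive")
    if prior_density_at_peak < 0:
        raise ValueError("prior density must be >= 0")
    if prior_density_at_peak == 0.0:
        return -math.inf
    return float(energy + math.log(prior_density_at_peak * posterior_volume))


def reduced_log_bayes_factor(
    log_bf: float, amplitude_prior_density: float, amplitude_sigma: float
) -> float:
    """Reduced log Bayes factor with the amplitude factor divided out.

    ``log B_{>1} = F - log(p1(z1hat) * sqrt(2 pi) * sigma_1)``.  The
    reduced Bayes factor is the quantity that maps directly onto the
    asymptotic p-value; the (often arbitrary) amplitude prior cutoff
    cancels between ``F`` and the subtracted term.
    """
    if amplitude_sigma <= 0:
        raise ValueError("amplitude_sigma must be positive")
    if amplitude_prior_density <= 0:
        raise ValueError(
            "amplitude prior density is zero at the peak: amplitude outside "
            "the prior support"
        )
    return float(
        log_bf - math.log(amplitude_prior_density * math.sqrt(2.0 * math.pi) * amplitude_sigma)
    )


def asymptotic_pvalue(log_bf_reduced: float, energy: float) -> float:
    """Asymptotic false-positive rate of the Bayes-factor statistic.

    ``P_asym = exp(-log B_{>1}) / sqrt(4 pi E)``.  Valid in the
    asymptotic regime ``E >> 1`` (practically E of a few or more); values
    above 1 are returned as computed and should be passed through
    :func:`extend_pvalue_sidak`.
    """
    if energy <= 0:
        raise ValueError(
            "asymptotic p-value requires E > 0: the formula is derived in "
            "the E >> 1 asymptotic regime where the amplitude integral is "
            "dominated by the peak"
        )
    return float(math.exp(-log_bf_reduced) / math.sqrt(4.0 * math.pi * energy))


def extend_pvalue_sidak(p_asym: float) -> float:
    """Continuous-parameter Sidak correction ``p = 1 - exp(-P_asym)``.

    Maps the asymptotic rate from [0, inf) into [0, 1); monotone with
    fixed point at 0.  For small arguments ``p ~= P_asym``.
    """
    if p_asym < 0:
        raise ValueError("p_asym must be >= 0")
    # keep the codomain strictly below 1 even when exp(-p) underflows
    return min(float(-math.expm1(-p_asym)), math.nextafter(1.0, 0.0))


def asymptotic_pvalue_integral(
    prior: PriorSpec,
    energy_of_z: Callable[[np.ndarray], float],
    vpost_of_z: Callable[[np.ndarray], float],
    threshold_F: float,
    n_per_dim: int = 201,
) -> float:
    """Asymptotic p-value by direct integration over the parameter space.

    Evaluates ``P_asym = int_{F(z) > F_threshold} exp(-E(z)) / V_post(z) dz``
    on a tensor grid over the prior support.  The integration region
    depends on the prior (through ``F = E + log(p V_post)``) but the
    integrand does not, so amplitude-cutoff changes that rescale the prior
    leave the result unchanged.

    The prior support must be finite (it is, by construction of
    :class:`PriorSpec`); an unbounded search region must be given an
    explicit cutoff before calling this.
    """
    if prior.dim > 3:
        raise ValueError("grid integration supported for d <= 3 only")
    for a, b in prior.support:
        if not (math.isfinite(a) and math.isfinite(b)):
            raise ValueError(
                "unbounded integration region: give the prior a finite cutoff"
            )
    pts, vol = prior.grid(n_per_dim)
    total = 0.0
    for z in pts:
        p = prior(z)
        if p == 0.0:
            continue
        e = float(energy_of_z(z))
        v = float(vpost_of_z(z))
        if not (math.isfinite(e) and v > 0):
            raise ValueError(f"integrand not finite at z = {z}")
        f = e + math.log(p * v)
        if f > threshold_F:
            total += math.exp(-e) / v
    return total * vol


def jeffreys_density(
    fisher_of_z: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    mean_vpost_of_z: Optional[Callable[[np.ndarray], float]] = None,
    support: Optional[Sequence[tuple[float, float]]] = None,
    normalize: bool = False,
) -> PriorSpec:
    """Jeffrey's prior from a Fisher matrix or a mean posterior volume.

    With ``fisher_of_z`` the density is ``sqrt(det I(z))`` (the classic
    Jeffrey's prior); with ``mean_vpost_of_z`` it is
    ``1 / <V_post(z)>`` (the generalized form appropriate beyond the
    Laplace regime).  Exactly one of the two must be supplied.  The
    returned prior is improper (unnormalized) unless ``normalize=True``,
    which requires a finite ``support``.
    """
    if (fisher_of_z is None) == (mean_vpost_of_z is None):
        raise ValueError("supply exactly one of fisher_of_z, mean_vpost_of_z")
    if support is None:
        raise ValueError("a support must be stated, even for an improper prior")

    if fisher_of_z is not None:

        def density(z: np.ndarray) -> float:
            I = np.atleast_2d(np.asarray(fisher_of_z(z), dtype=float))
            det = float(np.linalg.det(I))
            if det <= 0:
                raise ValueError(f"singular Fisher matrix at z = {z}")
            return math.sqrt(det)

        kind = "jeffreys"
    else:

        def density(z: np.ndarray) -> float:
            v = float(mean_vpost_of_z(z))
            if v <= 0:
                raise ValueError(f"non-positive mean posterior volume at z = {z}")
            return 1.0 / v

        kind = "generalized_jeffreys"

    prior = PriorSpec(density=density, support=support, kind=kind, proper=False)
    if normalize:
        prior = prior.normalized()
        prior.kind = kind
    return prior


def null_peak_density(
    prior: PriorSpec, log_bf_of_z: Callable[[np.ndarray], float]
) -> Callable[[np.ndarray], float]:
    """Unnormalized density of local MAP parameters under the null.

    ``p(zhat | H0) propto p(zhat) exp(-F(zhat))``.  Because multiplying
    the prior by a constant multiplies the Bayes factor by the same
    constant, the product is invariant under prior rescaling: the null
    peak distribution does not depend on how the prior is normalized.
    """

    def density(z: np.ndarray) -> float:
        p = prior(z)
        if p == 0.0:
            return 0.0
        f = float(log_bf_of_z(z))
        if not math.isfinite(f):
            raise ValueError(f"log Bayes factor not finite at z = {z}")
        return p * math.exp(-f)

    return density


def free_energy_decomposition(
    peak: PeakEstimate,
    prior: PriorSpec,
    jeffreys: PriorSpec,
    n_per_dim: int = 201,
) -> SignificanceResult:
    """Energy/entropy/potential decomposition of the log Bayes factor.

    With both priors normalized over the same support,

    * ``N = 1 / (p_Jeff(zhat) * V_post)`` is the number of
      posterior-volume states in the prior volume,
    * ``S = log N`` is the entropy,
    * ``U = log(p(zhat) / p_Jeff(zhat))`` is the potential measuring how
      informative the prior is (``U = 0`` for the Jeffrey's prior itself),
    * ``F = E + U - S`` equals :func:`log_bayes_factor`.
    """
    if list(map(tuple, prior.support)) != list(map(tuple, jeffreys.support)):
        raise ValueError("prior and Jeffrey's prior must share the same support")
    if peak.posterior_volume is None:
        raise ValueError("peak.posterior_volume must be set")
    prior_n = prior if prior.proper else prior.normalized(n_per_dim)
    jeff_n = jeffreys if jeffreys.proper else jeffreys.normalized(n_per_dim)
    p = prior_n(peak.location)
    pj = jeff_n(peak.location)
    if pj <= 0 or p <= 0:
        raise ValueError("peak lies outside the prior support")
    multiplicity = 1.0 / (pj * peak.posterior_volume)
    entropy = math.log(multiplicity)
    potential = math.log(p / pj)
    log_bf = peak.energy + potential - entropy
    return SignificanceResult(
        log_bf=log_bf,
        energy=peak.energy,
        entropy=entropy,
        potential=potential,
        multiplicity=multiplicity,
    )
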