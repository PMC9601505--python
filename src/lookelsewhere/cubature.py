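"""Gaussian-weight cubature rules for local evidence integrals.

Rules integrate ``f(u) exp(-|u|^2 / 2)`` over R^d; weights sum to
``(2 pi)^{d/2}``.  The evidence integrand is a posterior ratio normalized
to 1 at the peak, so the central node of a rule never needs evaluating:
rules are returned as ``(nodes, weights, center_weight)`` with the center
contribution carried analytically.

For d = 3 the default degree-7 rule is a fully symmetric three-orbit
construction with closed-form coefficients: orbits ``(r,0,0)`` (6 nodes),
``(t,t,t)`` (8 nodes) and ``(s,s,0)`` (12 nodes) plus the center.  Writing
``y = (6 - sqrt(15)) / 21``, the moment equations of all even monomials
through degree 7 are solved exactly by

    r^2 = 5/(1-y),  t^2 = 1/(1-2y),  s^2 = 1/y,
    w_r = (1-y)^3/25,  w_t = (1-2y)^3/8,  w_s = y^3/2,

(weights relative to the normalized Gaussian), all positive.  A full
octahedral-symmetry orbit analysis shows no rule of this degree exists
with fewer off-center nodes than the 26 used here: every orbit combination
totalling 24 nodes leaves some sixth-order mixed moment unmatched.
For other dimensions (or other degrees) a product Gauss-Hermite rule is
used.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np

__all__ = ["gauss_weight_rule", "degree7_rule_3d", "product_hermite_rule"]


def _orbit_axis(r: float) -> np.ndarray:
    pts = []
    for i in range(3):
        for sign in (1.0, -1.0):
            p = [0.0, 0.0, 0.0]
            p[i] = sign * r
            pts.append(p)
    return np.array(pts)


def _orbit_cube(t: float) -> np.ndarray:
    return np.array([[sx * t, sy * t, sz * t]
                     for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)])


def _orbit_edge(s: float) -> np.ndarray:
    pts = []
    for i, j in itertools.combinations(range(3), 2):
        for si in (1.0, -1.0):
            for sj in (1.0, -1.0):
                p = [0.0, 0.0, 0.0]
                p[i], p[j] = si * s, sj * s
                pts.append(p)
    return np.array(pts)


@lru_cache(maxsize=None)
def degree7_rule_3d() -> tuple[np.ndarray, np.ndarray, float]:
    """Fully symmetric degree-7 rule for the 3-D Gaussian weight.

    Returns ``(nodes, weights, center_weight)``: 26 off-center nodes whose
    weights plus the analytic center weight sum to ``(2 pi)^{3/2}``.
    Exact (to roundoff) for every polynomial of total degree <= 7.
    """
    y = (6.0 - math.sqrt(15.0)) / 21.0
    r = math.sqrt(5.0 / (1.0 - y))
    t = math.sqrt(1.0 / (1.0 - 2.0 * y))
    s = math.sqrt(1.0 / y)
    w_r = (1.0 - y) ** 3 / 25.0
    w_t = (1.0 - 2.0 * y) ** 3 / 8.0
    w_s = y**3 / 2.0
    w_0 = 1.0 - 6.0 * w_r - 8.0 * w_t - 12.0 * w_s
    nodes = np.vstack([_orbit_axis(r), _orbit_cube(t), _orbit_edge(s)])
    weights = np.concatenate(
        [np.full(6, w_r), np.full(8, w_t), np.full(12, w_s)]
    )
    total = (2.0 * math.pi) ** 1.5
    return nodes, weights * total, w_0 * total


@lru_cache(maxsize=None)
def product_hermite_rule(
    dim: int, degree: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Product Gauss-Hermite rule for the d-dimensional Gaussian weight.

    Uses ``ceil((degree+1)/2)`` points per axis; the central node (present
    for odd point counts) is split off and its weight returned separately
    so the caller can treat it analytically.
    """
    n_1d = (degree + 2) // 2
    x, w = np.polynomial.hermite.hermgauss(n_1d)
    # physicists' weight e^{-x^2} -> standard Gaussian e^{-u^2/2}
    u = x * math.sqrt(2.0)
    w = w * math.sqrt(2.0)
    nodes = np.array(list(itertools.product(u, repeat=dim)))
    weights = np.prod(
        np.array(list(itertools.product(w, repeat=dim))), axis=1
    )
    central = np.all(np.abs(nodes) < 1e-12, axis=1)
    w_center = float(weights[central].sum())
    return nodes[~central], weights[~central], w_center


def gauss_weight_rule(
    dim: int, degree: int = 7, force_product: bool = False
) -> tuple[np.ndarray, np.ndarray, float]:
    """Cubature rule ``(nodes, weights, center_weight)`` for e^{-|u|^2/2}.

    ``dim = 3, degree = 7`` uses the fully symmetric 26-node rule of
    :func:`degree7_rule_3d` unless ``force_product`` is set; every other
    case falls back to a product Gauss-Hermite rule.  Weights (including
    the analytic center weight) always sum to ``(2 pi)^{d/2}``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if dim == 3 and degree == 7 and not force_product:
        return degree7_rule_3d()
    return product_hermite_rule(dim, degree)
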