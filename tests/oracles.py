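"""Independent oracles used by the tests.

Deliberately coded apart from the package: spherical quadrature on a
Gauss-Legendre x uniform-azimuth grid, a term-by-term real SH basis built
on the associated-Legendre routine `scipy.special.lpmv` with explicit
normalisation, and closed-form ray-quadric intersections for the analytic
phantoms.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import lpmv


def quadrature_grid(n_theta: int = 100, n_phi: int = 128):
    """Deterministic spherical quadrature nodes/weights (>= 10^4 nodes)."""
    x, w = np.polynomial.legendre.leggauss(n_theta)
    theta = np.arccos(x)
    phi = np.arange(n_phi) * 2.0 * np.pi / n_phi
    T, P = np.meshgrid(theta, phi, indexing="ij")
    W = np.repeat(w[:, None], n_phi, axis=1) * (2.0 * np.pi / n_phi)
    return T, P, W


def sphere_integral(values: np.ndarray, weights: np.ndarray) -> float:
    return float(np.sum(values * weights))


def real_sh(l: int, m: int, theta, phi):
    """Real symmetric SH basis function via explicit Legendre normalisation."""
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    am = abs(m)
    norm = math.sqrt((2 * l + 1) / (4.0 * math.pi) * math.factorial(l - am) / math.factorial(l + am))
    P = lpmv(am, l, np.cos(theta))
    if m == 0:
        return norm * P
    if m > 0:
        return math.sqrt(2.0) * norm * P * np.cos(m * phi)
    return math.sqrt(2.0) * norm * P * np.sin(am * phi)


def eval_sh_series(coeffs, theta, phi):
    """Term-by-term evaluation of an even-order coefficient vector."""
    coeffs = np.asarray(coeffs, dtype=float)
    lmax = 0
    while (lmax + 1) * (lmax + 2) // 2 < len(coeffs):
        lmax += 2
    out = np.zeros(np.broadcast(np.asarray(theta), np.asarray(phi)).shape)
    j = 0
    for l in range(0, lmax + 1, 2):
        for m in range(-l, l + 1):
            out = out + coeffs[j] * real_sh(l, m, theta, phi)
            j += 1
    return out


def ray_quadric_exit(S, dirs, centre, semiaxes) -> np.ndarray:
    """Distance from interior point S to an axis-aligned ellipsoid along rays."""
    S = np.asarray(S, dtype=float)
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    centre = np.asarray(centre, dtype=float)
    semiaxes = np.asarray(semiaxes, dtype=float)
    o = (S - centre) / semiaxes
    d = dirs / semiaxes
    A = np.sum(d * d, axis=1)
    B = 2.0 * d @ o
    C = float(o @ o) - 1.0
    disc = B * B - 4.0 * A * C
    return (-B + np.sqrt(disc)) / (2.0 * A)


def random_rotation(rng) -> np.ndarray:
    """Haar-ish random rotation matrix from a QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
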