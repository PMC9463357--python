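"""Real symmetric spherical-harmonic (SH) basis machinery.

Antipodally symmetric spherical functions -- fibre orientation
distributions (FODs) and tract orientation distributions (TODs) -- are
represented by coefficient vectors in a real, even-order-only, orthonormal
SH basis.  The basis used throughout the package is:

* ``m == 0``: the standard complex harmonic ``Y_l^0`` (already real),
* ``m > 0``: ``sqrt(2) * Re(Y_l^m)``,
* ``m < 0``: ``sqrt(2) * Im(Y_l^|m|)``,

with only even degrees ``l`` retained.  Coefficients are stored l-major
with m ascending from -l to +l, i.e. the flat index of ``(l, m)`` is
``l*(l+1)/2 + m``; a band limit ``lmax`` therefore needs
``(lmax+1)*(lmax+2)/2`` coefficients (45 for ``lmax = 8``).  Because the
basis is orthonormal, the spherical integral of the product of two
band-limited functions reduces to the dot product of their coefficient
vectors, which is the per-voxel operation the tract maps are built on.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np
from scipy.special import sph_harm_y

DEFAULT_LMAX = 8

__all__ = [
    "DEFAULT_LMAX",
    "n_coefficients",
    "lmax_for_coefficients",
    "sh_index",
    "lm_pairs",
    "sh_basis",
    "sh_eval",
    "spherical_integral",
    "inner_product",
    "pad_coefficients",
    "delta_coefficients",
    "cartesian_to_spherical",
    "fit_coefficients",
    "rotation_matrix_between",
]


def n_coefficients(lmax: int) -> int:
    """Number of even-degree real SH coefficients up to ``lmax``."""
    if lmax < 0 or lmax % 2 != 0:
        raise ValueError(f"lmax must be an even non-negative integer, got {lmax}")
    return (lmax + 1) * (lmax + 2) // 2


def lmax_for_coefficients(n: int) -> int:
    """Invert :func:`n_coefficients`; raise if ``n`` is not a valid length."""
    lmax = 0
    while n_coefficients(lmax) < n:
        lmax += 2
    if n_coefficients(lmax) != n:
        raise ValueError(f"{n} is not a valid even-order SH coefficient count")
    return lmax


def sh_index(l: int, m: int) -> int:
    """Flat index of the (l, m) basis function (l even, -l <= m <= l)."""
    if l % 2 != 0 or abs(m) > l:
        raise ValueError(f"invalid (l, m) = ({l}, {m})")
    return l * (l + 1) // 2 + m


def lm_pairs(lmax: int) -> list[tuple[int, int]]:
    """(l, m) pairs in storage order."""
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def _check_coefficients(coeffs: np.ndarray) -> int:
    coeffs = np.asarray(coeffs)
    lmax = lmax_for_coefficients(coeffs.shape[-1])
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("SH coefficients must be finite")
    return lmax


def sh_basis(theta: np.ndarray, phi: np.ndarray, lmax: int = DEFAULT_LMAX) -> np.ndarray:
    """Evaluate every basis function at the given angles.

    Parameters
    ----------
    theta, phi:
        Polar angle in [0, pi] and azimuth in [0, 2*pi); broadcastable.
    lmax:
        Even band limit.

    Returns
    -------
    Array of shape ``broadcast(theta, phi).shape + (n_coefficients(lmax),)``.
    """
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    theta, phi = np.broadcast_arrays(theta, phi)
    out = np.empty(theta.shape + (n_coefficients(lmax),))
    sqrt2 = np.sqrt(2.0)
    for j, (l, m) in enumerate(lm_pairs(lmax)):
        y = sph_harm_y(l, abs(m), theta, phi)
        if m == 0:
            out[..., j] = y.real
        elif m > 0:
            out[..., j] = sqrt2 * y.real
        else:
            out[..., j] = sqrt2 * y.imag
    return out


def sh_eval(coeffs: np.ndarray, theta, phi) -> np.ndarray:
    """Evaluate the function with the given coefficients at (theta, phi)."""
    coeffs = np.asarray(coeffs, dtype=float)
    lmax = _check_coefficients(coeffs)
    basis = sh_basis(theta, phi, lmax)
    return basis @ coeffs


def spherical_integral(coeffs: np.ndarray) -> np.ndarray:
    """Integral of the represented function over the unit sphere.

    Only the l = 0 term survives: the integral is ``c_0 * 2*sqrt(pi)``.
    Accepts arrays of coefficient vectors (coefficients on the last axis).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    _check_coefficients(coeffs)
    return coeffs[..., 0] * (2.0 * np.sqrt(np.pi))


def pad_coefficients(coeffs: np.ndarray, lmax: int) -> np.ndarray:
    """Zero-pad coefficient vectors up to band limit ``lmax``.

    Truncation of a band-limited function is an orthogonal projection, so
    zero-padding is exact (it changes nothing about the represented
    function).
    """
    coeffs = np.asarray(coeffs, dtype=float)
    have = coeffs.shape[-1]
    want = n_coefficients(lmax)
    if have > want:
        raise ValueError(f"cannot pad {have} coefficients down to {want}")
    if have == want:
        return coeffs
    pad = [(0, 0)] * (coeffs.ndim - 1) + [(0, want - have)]
    return np.pad(coeffs, pad)


def inner_product(f: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Spherical integral of the product of two band-limited functions.

    By orthonormality this is just the dot product of the coefficient
    vectors; mixed band limits are handled by zero-padding the shorter
    vector.  Broadcasts over leading axes.
    """
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    _check_coefficients(f)
    _check_coefficients(g)
    lmax = max(lmax_for_coefficients(f.shape[-1]), lmax_for_coefficients(g.shape[-1]))
    f = pad_coefficients(f, lmax)
    g = pad_coefficients(g, lmax)
    return np.einsum("...j,...j->...", f, g)


def cartesian_to_spherical(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-sphere angles (theta, phi) of Cartesian vectors (need not be unit)."""
    v = np.asarray(v, dtype=float)
    r = np.linalg.norm(v, axis=-1)
    if np.any(r == 0):
        raise ValueError("zero vector has no direction")
    theta = np.arccos(np.clip(v[..., 2] / r, -1.0, 1.0))
    phi = np.mod(np.arctan2(v[..., 1], v[..., 0]), 2.0 * np.pi)
    return theta, phi


def delta_coefficients(
    direction: np.ndarray,
    lmax: int = DEFAULT_LMAX,
    apodization: Optional[Callable[[int], float]] = None,
) -> np.ndarray:
    """Band-limited expansion of a symmetric delta on the given axis.

    The unit-mass antipodally symmetric delta concentrated on axis ``v``
    projects onto the even-order basis as ``c_j = Y_j(v)`` (odd orders
    vanish by symmetry), so the coefficients are simply the basis row at
    ``v``.  The expansion is rotationally covariant and integrates to 1 on
    the sphere for every axis.  Supports an array of directions on the
    leading axes.

    ``apodization``, if given, maps degree ``l`` to a per-degree weight
    (e.g. to taper Gibbs ringing); no apodization is applied by default.
    """
    theta, phi = cartesian_to_spherical(direction)
    coeffs = sh_basis(theta, phi, lmax)
    if apodization is not None:
        weights = np.array([apodization(l) for l, _ in lm_pairs(lmax)])
        coeffs = coeffs * weights
    return coeffs


def fit_coefficients(values: np.ndarray, theta, phi, lmax: int = DEFAULT_LMAX) -> np.ndarray:
    """Least-squares fit of SH coefficients to point samples on the sphere."""
    basis = sh_basis(theta, phi, lmax)
    sol, *_ = np.linalg.lstsq(basis, np.asarray(values, dtype=float), rcond=None)
    return sol


def rotation_matrix_between(coeffs_dirs: np.ndarray, rotation: np.ndarray, lmax: int) -> np.ndarray:
    """Coefficient-space matrix applying a spatial rotation to SH functions.

    Built by re-fitting rotated point samples: for a rotation ``R`` the
    rotated function is ``F'(d) = F(R^T d)``, so evaluating the basis at
    ``R^T d`` over a well-spread direction set and projecting back gives
    the (exact, band-limited) rotation operator on coefficients.

    ``coeffs_dirs`` is the (N, 3) direction set used for the fit; it must
    over-determine the basis (N >= n_coefficients(lmax)).
    """
    dirs = np.asarray(coeffs_dirs, dtype=float)
    if dirs.shape[0] < n_coefficients(lmax):
        raise ValueError("direction set does not over-determine the basis")
    rotation = np.asarray(rotation, dtype=float)
    theta, phi = cartesian_to_spherical(dirs)
    basis = sh_basis(theta, phi, lmax)
    theta_r, phi_r = cartesian_to_spherical(dirs @ rotation)  # rows: R^T @ d
    basis_r = sh_basis(theta_r, phi_r, lmax)
    sol, *_ = np.linalg.lstsq(basis, basis_r, rcond=None)
    return sol
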