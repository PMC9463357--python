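"""Tract orientation atlas construction.

A tract atlas is built from streamline reconstructions of the same tract in
several training subjects (already brought into a common space): each
bundle is converted to a per-voxel tract orientation distribution (TOD) by
accumulating band-limited delta lobes along streamline segment directions,
each voxel's TOD is normalised to unit integral on the sphere (removing
streamline-density information), and the normalised maps are averaged
across subjects.  The resulting SH image is a joint spatial/orientational
prior for the tract.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import map_coordinates

from . import sh
from .image import GeometryError, SHImage, require_same_grid, world_to_voxel
from .io import validate_bundle

logger = logging.getLogger(__name__)

__all__ = [
    "map_streamlines_to_tod",
    "normalise_tod",
    "average_atlases",
    "apply_affine",
    "build_atlas",
]


def map_streamlines_to_tod(
    bundle,
    template: SHImage | tuple,
    lmax: int = sh.DEFAULT_LMAX,
) -> SHImage:
    """Map a streamline bundle to a per-voxel TOD image.

    Each streamline segment contributes a symmetric band-limited delta
    along its direction, weighted by its length, to the voxel containing
    its midpoint.  Zero-length segments are skipped (counted in the log).

    ``template`` supplies the output geometry: an :class:`SHImage`/volume
    or a ``(shape, affine)`` pair.
    """
    bundle = validate_bundle(bundle)
    if isinstance(template, tuple):
        shape, affine = template
        shape = tuple(shape)[:3]
    else:
        shape, affine = tuple(template.shape[:3]), template.affine
    affine = np.asarray(affine, dtype=float)

    starts = np.concatenate([s[:-1] for s in bundle])
    ends = np.concatenate([s[1:] for s in bundle])
    seg = ends - starts
    lengths = np.linalg.norm(seg, axis=1)
    keep = lengths > 0
    n_degenerate = int(np.sum(~keep))
    if n_degenerate:
        logger.info("skipping %d zero-length streamline segments", n_degenerate)
    seg, lengths = seg[keep], lengths[keep]
    mids = 0.5 * (starts + ends)[keep]

    ncoef = sh.n_coefficients(lmax)
    data = np.zeros(shape + (ncoef,))
    if len(seg) == 0:
        return SHImage(data, affine, lmax)

    vox = np.rint(world_to_voxel(affine, mids)).astype(int)
    in_grid = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    vox, seg, lengths = vox[in_grid], seg[in_grid], lengths[in_grid]

    deltas = sh.delta_coefficients(seg, lmax) * lengths[:, None]
    flat = np.zeros((int(np.prod(shape)), ncoef))
    flat_idx = np.ravel_multi_index((vox[:, 0], vox[:, 1], vox[:, 2]), shape)
    np.add.at(flat, flat_idx, deltas)
    return SHImage(flat.reshape(shape + (ncoef,)), affine, lmax)


def normalise_tod(tod: SHImage, eps_rel: float = 1e-8) -> SHImage:
    """Rescale each occupied voxel to unit integral on the sphere.

    Voxels whose integral is at or below ``eps_rel`` times the maximum
    voxel integral are treated as empty and zeroed, so numerically empty
    voxels are never amplified.  Idempotent.
    """
    integrals = sh.spherical_integral(tod.data)
    peak = float(np.max(integrals)) if integrals.size else 0.0
    eps = eps_rel * peak
    occupied = integrals > eps
    out = np.zeros_like(tod.data)
    out[occupied] = tod.data[occupied] / integrals[occupied, None]
    return SHImage(out, tod.affine.copy(), tod.lmax)


def average_atlases(maps: list[SHImage]) -> SHImage:
    """Voxel-wise arithmetic mean of coefficient vectors across subjects."""
    if not maps:
        raise ValueError("no maps to average")
    first = maps[0]
    for m in maps[1:]:
        require_same_grid(first, m, hint="all training maps must share grid and affine")
        if m.lmax != first.lmax:
            raise GeometryError("all training maps must share lmax")
    mean = np.mean([m.data for m in maps], axis=0)
    return SHImage(mean, first.affine.copy(), first.lmax)


def apply_affine(
    img: SHImage,
    A: np.ndarray,
    template: SHImage | tuple | None = None,
    reorient: bool = False,
) -> SHImage:
    """Resample an SH image through an affine registration ``A``.

    ``A`` maps source world coordinates into target world coordinates; the
    output grid (``template`` or, by default, the source grid) is filled by
    pull-back: each output voxel samples the source at ``A^{-1} w`` with
    per-coefficient trilinear interpolation.

    By default the transform is applied *spatially only*: coefficient
    vectors are moved, not reoriented.  The atlas-and-inner-product
    pipeline is deliberately tolerant of small orientation mismatch, and
    registration affines are near-rigid with small rotations, so this is
    the documented default.  ``reorient=True`` additionally rotates each
    voxel's distribution by the rotational (polar) factor of ``A``.
    """
    A = np.asarray(A, dtype=float)
    if A.shape != (4, 4) or abs(np.linalg.det(A[:3, :3])) < 1e-12:
        raise GeometryError("registration affine must be an invertible 4x4 matrix")
    if template is None:
        shape, out_affine = img.grid_shape, img.affine
    elif isinstance(template, tuple):
        shape, out_affine = tuple(template[0])[:3], np.asarray(template[1], dtype=float)
    else:
        shape, out_affine = tuple(template.shape[:3]), template.affine

    # output voxel -> output world -> source world -> source voxel
    M = np.linalg.inv(img.affine) @ np.linalg.inv(A) @ out_affine
    idx = np.indices(shape, dtype=float).reshape(3, -1)
    src = M[:3, :3] @ idx + M[:3, 3:4]

    ncoef = img.n_coefficients
    out = np.empty(tuple(shape) + (ncoef,))
    for j in range(ncoef):
        out[..., j] = map_coordinates(
            img.data[..., j], src, order=1, mode="constant", cval=0.0
        ).reshape(shape)

    if reorient:
        # Polar decomposition of the linear part; rotate distributions by R.
        u, _, vt = np.linalg.svd(A[:3, :3])
        R = u @ vt
        if np.linalg.det(R) < 0:
            R = u @ np.diag([1.0, 1.0, -1.0]) @ vt
        dirs = _fibonacci_directions(4 * sh.n_coefficients(img.lmax))
        rot = sh.rotation_matrix_between(dirs, R, img.lmax)
        out = out @ rot.T
    return SHImage(out, np.asarray(out_affine, dtype=float).copy(), img.lmax)


def _fibonacci_directions(n: int) -> np.ndarray:
    """Well-spread unit directions (Fibonacci sphere)."""
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def build_atlas(
    bundles: list,
    template: SHImage | tuple,
    lmax: int = sh.DEFAULT_LMAX,
) -> SHImage:
    """Full atlas construction: per-subject TOD, normalise, then average."""
    per_subject = [
        normalise_tod(map_streamlines_to_tod(b, template, lmax)) for b in bundles
    ]
    return average_atlases(per_subject)
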