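"""Synthetic phantoms: brain/tumour masks, fibre bundles, FOD fields.

Everything the pipeline consumes can be generated here deterministically
from a spec and a seed: an ellipsoidal brain mask with a spherical tumour
(both defined by analytic quadrics, so oracle distances exist in closed
form), arc/straight streamline bundles standing in for healthy training
tractograms, band-limited FOD fields built from bundle tangents (optionally
with crossing fibres and coefficient noise), and structured grid images on
which the deformation field is visually and numerically checkable.

The default desk-scale geometry is a 64x64x64 grid at 2 mm: an
80x60x60 mm brain with a 10 mm-radius tumour, large enough for realistic
ray geometry yet small enough that every generator runs in seconds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.ndimage import binary_dilation

from . import sh
from .atlas import map_streamlines_to_tod, normalise_tod
from .deformation import DeformationParams, RadialGeometry, forward_warp
from .image import SHImage, Volume, grid_world_coords, world_to_voxel

__all__ = [
    "PhantomSpec",
    "make_phantom_masks",
    "make_bundle",
    "make_fod_field",
    "make_grid_image",
    "warp_bundle",
    "bundle_mask",
    "make_scene",
]


def _seed_list(seed) -> list[int]:
    return [int(seed)] if np.isscalar(seed) else [int(s) for s in seed]


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n, dtype=float) + 0.5
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


@dataclasses.dataclass
class PhantomSpec:
    """Analytic brain-ellipsoid / tumour-sphere phantom description.

    All lengths in mm; the grid is centred on the world origin.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 2.0
    brain_centre: tuple[float, float, float] = (0.0, 0.0, 0.0)
    brain_semiaxes: tuple[float, float, float] = (40.0, 30.0, 30.0)
    tumour_centre: tuple[float, float, float] = (12.0, 4.0, 0.0)
    tumour_radius: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0 or self.tumour_radius <= 0 or min(self.brain_semiaxes) <= 0:
            raise ValueError("voxel size, radii and semi-axes must be positive")
        # Tumour strictly inside the brain: check a dense set of sphere points.
        c = np.asarray(self.tumour_centre) - np.asarray(self.brain_centre)
        pts = c + self.tumour_radius * _fibonacci_directions(2048)
        if np.any(np.sum((pts / np.asarray(self.brain_semiaxes)) ** 2, axis=1) >= 1.0):
            raise ValueError("tumour is not strictly inside the brain ellipsoid")

    @property
    def affine(self) -> np.ndarray:
        A = np.eye(4)
        A[:3, :3] *= self.voxel_size
        A[:3, 3] = -self.voxel_size * (np.asarray(self.shape) - 1) / 2.0
        return A


def make_phantom_masks(spec: PhantomSpec) -> tuple[Volume, Volume]:
    """Binary brain-ellipsoid and tumour-sphere masks (voxel-centre membership)."""
    coords = grid_world_coords(spec.shape, spec.affine)
    rel = (coords - np.asarray(spec.brain_centre)) / np.asarray(spec.brain_semiaxes)
    brain = (np.sum(rel**2, axis=-1) <= 1.0).astype(np.uint8)
    d2 = np.sum((coords - np.asarray(spec.tumour_centre)) ** 2, axis=-1)
    tumour = (d2 <= spec.tumour_radius**2).astype(np.uint8)
    return Volume(brain, spec.affine), Volume(tumour, spec.affine)


def make_bundle(
    spec: PhantomSpec,
    geometry: str = "arc",
    n_streamlines: int = 24,
    seed: int = 0,
    jitter: float = 2.0,
    step: float = 2.0,
    arc_centre: tuple[float, float, float] = (-6.0, 0.0, 0.0),
    arc_radius: float = 24.0,
    angle_span_deg: float = 120.0,
    straight_axis: int = 0,
    straight_centre: tuple[float, float, float] = (0.0, 0.0, 0.0),
    straight_half_length: float = 30.0,
) -> list[np.ndarray]:
    """Smooth synthetic streamline bundle through the brain phantom.

    ``"arc"`` follows a circular arc in the y = const plane; ``"straight"``
    a straight line along a coordinate axis.  Each streamline is the
    centreline displaced by a seeded Gaussian cross-sectional offset of
    standard deviation ``jitter`` mm (a tube of parallel trajectories, so
    vertex tangents remain analytic).  With ``jitter = 0`` and
    ``n_streamlines = 1`` the bundle is exactly the sampled centreline.
    """
    rng = np.random.default_rng(_seed_list(seed) + [17])
    streamlines = []
    if geometry == "arc":
        half = np.deg2rad(angle_span_deg) / 2.0
        n_pts = max(2, int(np.ceil(2 * half * arc_radius / step)) + 1)
        alpha = np.linspace(-half, half, n_pts)
        centre = np.asarray(arc_centre, dtype=float)
        for _ in range(n_streamlines):
            dr, dy = (rng.normal(0.0, jitter, size=2) if jitter > 0 else (0.0, 0.0))
            pts = centre + np.stack(
                [
                    (arc_radius + dr) * np.cos(alpha),
                    np.full_like(alpha, dy),
                    (arc_radius + dr) * np.sin(alpha),
                ],
                axis=1,
            )
            streamlines.append(pts)
    elif geometry == "straight":
        axis = int(straight_axis)
        n_pts = max(2, int(np.ceil(2 * straight_half_length / step)) + 1)
        t = np.linspace(-straight_half_length, straight_half_length, n_pts)
        centre = np.asarray(straight_centre, dtype=float)
        perp = [i for i in range(3) if i != axis]
        for _ in range(n_streamlines):
            offs = rng.normal(0.0, jitter, size=2) if jitter > 0 else np.zeros(2)
            pts = np.tile(centre, (n_pts, 1))
            pts[:, axis] += t
            pts[:, perp[0]] += offs[0]
            pts[:, perp[1]] += offs[1]
            streamlines.append(pts)
    else:
        raise ValueError(f"unknown bundle geometry {geometry!r}")
    return streamlines


def make_fod_field(
    bundles: list,
    template: SHImage | tuple | PhantomSpec,
    lmax: int = sh.DEFAULT_LMAX,
    noise_level: float = 0.0,
    seed: int = 0,
) -> SHImage:
    """FOD image from bundle tangents: summed delta lobes, noise, unit integral.

    With a single bundle and zero noise this reproduces the bundle's
    normalised TOD exactly.  ``noise_level`` is the standard deviation of
    seeded Gaussian coefficient noise as a fraction of the mean occupied
    c0 magnitude (applied to occupied voxels before normalisation); real
    FODs carry CSD fitting noise with richer structure, this stand-in only
    emulates its magnitude.
    """
    if isinstance(template, PhantomSpec):
        template = (template.shape, template.affine)
    if not bundles:
        if isinstance(template, tuple):
            shape, affine = tuple(template[0])[:3], template[1]
        else:
            shape, affine = tuple(template.shape[:3]), template.affine
        return SHImage(np.zeros(shape + (sh.n_coefficients(lmax),)), affine, lmax)
    tods = [map_streamlines_to_tod(b, template, lmax) for b in bundles]
    total = tods[0]
    for t in tods[1:]:
        total = SHImage(total.data + t.data, total.affine, lmax)
    if noise_level > 0:
        rng = np.random.default_rng(_seed_list(seed) + [23])
        occupied = sh.spherical_integral(total.data) > 0
        if occupied.any():
            scale = noise_level * float(np.mean(np.abs(total.data[occupied, 0])))
            noise = rng.normal(0.0, scale, size=total.data[occupied].shape)
            data = total.data.copy()
            data[occupied] += noise
            total = SHImage(data, total.affine, lmax)
    return normalise_tod(total)


def make_grid_image(spec: PhantomSpec, spacing: int = 8, background: float = 0.25) -> Volume:
    """Structured grid-line pattern inside the brain mask.

    Grid planes every ``spacing`` voxels take value 1, other brain voxels
    ``background``, outside-brain voxels 0 -- so deformed grid lines make
    the warp geometry visible and the fixed brain boundary checkable.
    """
    brain, _ = make_phantom_masks(spec)
    i, j, k = np.indices(spec.shape)
    lines = (i % spacing == 0) | (j % spacing == 0) | (k % spacing == 0)
    data = np.where(lines, 1.0, background) * brain.data
    return Volume(data, spec.affine)


def warp_bundle(bundle, geom: RadialGeometry, params: DeformationParams) -> list[np.ndarray]:
    """Ground-truth displaced bundle: forward-warp every vertex."""
    return [forward_warp(s, geom, params) for s in bundle]


def bundle_mask(bundle, shape, affine, dilate: int = 1) -> np.ndarray:
    """Binary mask of voxels traversed by the bundle (vertices + midpoints)."""
    pts = []
    for s in bundle:
        s = np.asarray(s, dtype=float)
        pts.append(s)
        pts.append(0.5 * (s[:-1] + s[1:]))
    vox = np.rint(world_to_voxel(affine, np.concatenate(pts))).astype(int)
    shape = tuple(shape)[:3]
    keep = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    mask = np.zeros(shape, dtype=bool)
    mask[tuple(vox[keep].T)] = True
    if dilate > 0:
        mask = binary_dilation(mask, iterations=dilate)
    return mask


def make_scene(
    seed: int = 0,
    spec: PhantomSpec | None = None,
    n_subjects: int = 4,
    n_streamlines: int = 24,
    jitter: float = 2.0,
    noise_level: float = 0.05,
    lmax: int = sh.DEFAULT_LMAX,
    params: DeformationParams | None = None,
    crossing: bool = False,
) -> dict:
    """Fully synthetic study scene for the end-to-end pipeline.

    Produces healthy training bundles (one per synthetic subject), a
    patient bundle displaced by the known tumour via the forward model, the
    patient FOD field built from the displaced bundle (plus a crossing
    bundle if requested, emulating a fibre-crossing region), and the
    ground-truth mask of the displaced bundle.
    """
    spec = spec or PhantomSpec(seed=seed)
    params = params or DeformationParams("auto")
    brain, tumour = make_phantom_masks(spec)
    geom = RadialGeometry.from_masks(brain, tumour)
    template = (spec.shape, spec.affine)

    training = [
        make_bundle(spec, "arc", n_streamlines, seed=[seed, i], jitter=jitter)
        for i in range(n_subjects)
    ]
    patient = make_bundle(spec, "arc", n_streamlines, seed=[seed, 500], jitter=jitter)
    warped = warp_bundle(patient, geom, params)
    fod_bundles = [warped]
    if crossing:
        crossing_bundle = make_bundle(
            spec, "straight", n_streamlines, seed=[seed, 900], jitter=jitter
        )
        fod_bundles.append(warp_bundle(crossing_bundle, geom, params))
    fod = make_fod_field(fod_bundles, template, lmax, noise_level, seed=seed)
    truth = bundle_mask(warped, spec.shape, spec.affine, dilate=0)
    return {
        "spec": spec,
        "params": params,
        "brain": brain,
        "tumour": tumour,
        "geom": geom,
        "training_bundles": training,
        "patient_bundle": patient,
        "warped_bundle": warped,
        "fod": fod,
        "truth_mask": truth,
    }
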