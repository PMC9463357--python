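"""Volumetric containers: scalar/mask volumes and 4D SH-coefficient images.

SH images are stored on disk as 4D NIfTI with the coefficient index on the
fourth dimension, l-major / m-ascending ordering (see :mod:`tractfinder.sh`),
and the header description field set to ``lmax=<n>;basis=real-sym`` so the
convention travels with the file.
"""

from __future__ import annotations

import dataclasses

import nibabel as nib
import numpy as np

from . import sh


class GeometryError(ValueError):
    """Image grids/affines that were expected to match do not."""


def voxel_to_world(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    ijk = np.asarray(ijk, dtype=float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def world_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    xyz = np.asarray(xyz, dtype=float)
    return xyz @ inv[:3, :3].T + inv[:3, 3]


def grid_world_coords(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """World-mm coordinates of every voxel centre; shape ``shape + (3,)``."""
    idx = np.indices(shape, dtype=float)
    ijk = np.moveaxis(idx, 0, -1)
    return voxel_to_world(affine, ijk)


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise GeometryError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise GeometryError("affine is singular")
    return affine


@dataclasses.dataclass
class Volume:
    """A 3D volume (mask or scalar map) with a voxel-to-world affine in mm."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), img.affine)

    def save(self, path, dtype=None) -> None:
        data = self.data if dtype is None else self.data.astype(dtype)
        nib.save(nib.Nifti1Image(data, self.affine), str(path))

    def same_grid_as(self, other: "Volume | SHImage", atol: float = 1e-6) -> bool:
        return self.shape == tuple(other.shape[:3]) and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclasses.dataclass
class SHImage:
    """A 3D grid of real even-order SH coefficient vectors (FOD/TOD/atlas)."""

    data: np.ndarray
    affine: np.ndarray
    lmax: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"SHImage data must be 4D, got shape {self.data.shape}")
        inferred = sh.lmax_for_coefficients(self.data.shape[-1])
        if self.lmax is None:
            self.lmax = inferred
        elif self.lmax != inferred:
            raise ValueError(
                f"lmax {self.lmax} inconsistent with {self.data.shape[-1]} coefficients"
            )
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_coefficients(self) -> int:
        return self.data.shape[-1]

    def copy(self) -> "SHImage":
        return SHImage(self.data.copy(), self.affine.copy(), self.lmax)

    def same_grid_as(self, other: "Volume | SHImage", atol: float = 1e-6) -> bool:
        return self.grid_shape == tuple(other.shape[:3]) and np.allclose(
            self.affine, other.affine, atol=atol
        )

    @classmethod
    def load(cls, path) -> "SHImage":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"{path} is not a 4D SH image")
        out = cls(data, img.affine)
        descrip = bytes(img.header["descrip"]).split(b"\x00", 1)[0].decode(errors="replace")
        if descrip.startswith("lmax="):
            stated = int(descrip.split(";", 1)[0].split("=", 1)[1])
            if stated != out.lmax:
                raise ValueError(
                    f"{path}: header states lmax={stated} but volume holds "
                    f"{out.n_coefficients} coefficients (lmax={out.lmax})"
                )
        return out

    def save(self, path, dtype=np.float32) -> None:
        img = nib.Nifti1Image(self.data.astype(dtype), self.affine)
        img.header["descrip"] = f"lmax={self.lmax};basis=real-sym".encode()
        nib.save(img, str(path))


def require_same_grid(a, b, hint: str = "") -> None:
    if not a.same_grid_as(b):
        msg = "images are not on the same grid/affine"
        if hint:
            msg += f"; {hint}"
        raise GeometryError(msg)
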