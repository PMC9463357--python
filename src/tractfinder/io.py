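"""Streamline (TCK) and affine-matrix I/O.

Streamline bundles are lists of ``(n_points, 3)`` float arrays in world mm
(RAS), the TCK convention.  Affines for atlas-to-target registration are
consumed as plain-text 4x4 matrices (one row per line).
"""

from __future__ import annotations

import nibabel as nib
import numpy as np

StreamlineBundle = list  # list of (n, 3) float arrays, world mm


def validate_bundle(bundle) -> list[np.ndarray]:
    bundle = [np.asarray(s, dtype=float) for s in bundle]
    if len(bundle) == 0:
        raise ValueError("streamline bundle is empty")
    for i, s in enumerate(bundle):
        if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
            raise ValueError(f"streamline {i} must be an (n>=2, 3) array, got {s.shape}")
        if not np.all(np.isfinite(s)):
            raise ValueError(f"streamline {i} contains non-finite coordinates")
    return bundle


def load_tck(path) -> list[np.ndarray]:
    tck = nib.streamlines.load(str(path))
    return validate_bundle(list(tck.streamlines))


def save_tck(bundle, path) -> None:
    bundle = validate_bundle(bundle)
    tractogram = nib.streamlines.Tractogram(bundle, affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tractogram, str(path))


def load_affine_text(path) -> np.ndarray:
    A = np.loadtxt(str(path))
    if A.shape == (3, 4):
        A = np.vstack([A, [0.0, 0.0, 0.0, 1.0]])
    if A.shape != (4, 4):
        raise ValueError(f"{path}: expected a 4x4 (or 3x4) affine, got {A.shape}")
    return A


def save_affine_text(A: np.ndarray, path) -> None:
    np.savetxt(str(path), np.asarray(A, dtype=float), fmt="%.17g")
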