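"""Atlas-and-FOD combination: the final scalar tract likelihood map.

Per voxel, the map is the spherical integral of the product of the
(deformed, registered) tract orientation atlas and the target image's
fibre orientation distribution -- by SH orthonormality, simply the dot
product of the two coefficient vectors.  FOD lobes aligned with the
atlas's expected tract orientation contribute strongly; crossing fibres
orthogonal to it are suppressed.
"""

from __future__ import annotations

import numpy as np

from . import sh
from .image import SHImage, Volume, require_same_grid

__all__ = ["compute_tract_map", "threshold_map", "dice"]


def compute_tract_map(
    atlas: SHImage,
    fod: SHImage,
    clamp_negative: bool = True,
    normalise: bool = False,
) -> Volume:
    """Voxel-wise SH inner product of atlas and FOD.

    The inputs must share grid and affine (resample upstream with
    ``apply_affine``/``deform_image`` otherwise); band limits may differ
    (the shorter coefficient vectors are zero-padded, which is exact).
    Truncated SH functions take small negative values, so the raw inner
    product can dip below zero away from genuine overlap; these
    truncation artefacts are clamped to 0 by default since the output is
    presented as a likelihood-like overlap map (``clamp_negative=False``
    keeps the signed values).  ``normalise=True`` rescales the final map
    to [0, 1] by its maximum, for display.
    """
    require_same_grid(atlas, fod, hint="resample with apply_affine or deform_image first")
    values = sh.inner_product(atlas.data, fod.data)
    if clamp_negative:
        values = np.maximum(values, 0.0)
    if normalise:
        peak = float(np.max(values))
        if peak > 0:
            values = values / peak
    return Volume(values, atlas.affine.copy())


def threshold_map(tract_map: Volume | np.ndarray, q: float) -> np.ndarray:
    """Binary mask of voxels with map value >= q (> 0 when q = 0).

    Monotone in ``q``: a larger threshold yields a subset.
    """
    if q < 0:
        raise ValueError("threshold must be non-negative")
    values = tract_map.data if isinstance(tract_map, Volume) else np.asarray(tract_map)
    return (values >= q) & (values > 0)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A^B| / (|A|+|B|) between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
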