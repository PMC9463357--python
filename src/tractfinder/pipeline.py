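"""End-to-end tract segmentation: atlas -> deform -> inner product -> mask."""

from __future__ import annotations

import numpy as np

from . import sh
from .atlas import build_atlas
from .deformation import DeformationParams, RadialGeometry, deform_image
from .image import SHImage, Volume
from .tract_map import compute_tract_map, dice, threshold_map

__all__ = ["segment_tract", "run_synthetic_pipeline", "DEFAULT_THRESHOLD_FRACTION"]

# Fraction of the map maximum used to binarise the likelihood map when an
# absolute threshold is not supplied.  The map itself carries no calibrated
# scale (it is a raw overlap integral), so a relative display-style cut is
# the natural default.
DEFAULT_THRESHOLD_FRACTION = 0.1


def segment_tract(
    atlas: SHImage,
    fod: SHImage,
    brain: Volume,
    tumour: Volume | None = None,
    params: DeformationParams | None = None,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    cache_dir=None,
) -> dict:
    """Deform the atlas for the lesion, combine with the FOD, binarise.

    With no tumour mask the deformation stage is skipped (healthy target).
    Returns the deformed atlas, the scalar tract map and the binary mask.
    """
    params = params or DeformationParams("auto")
    geom = None
    deformed = atlas
    if tumour is not None:
        geom = RadialGeometry.from_masks(brain, tumour, cache_dir=cache_dir)
        deformed = deform_image(atlas, geom, params)
    tract_map = compute_tract_map(deformed, fod)
    mask = threshold_map(tract_map, threshold_fraction * float(np.max(tract_map.data)))
    return {
        "geometry": geom,
        "deformed_atlas": deformed,
        "tract_map": tract_map,
        "mask": mask,
    }


def run_synthetic_pipeline(scene: dict, lmax: int = sh.DEFAULT_LMAX) -> dict:
    """Run the full pipeline on a synthetic scene and score it.

    Builds the atlas from the scene's healthy training bundles, deforms it
    with the scene's tumour (lambda auto unless the scene says otherwise),
    maps it against the scene FOD and reports the Dice overlap of the
    thresholded map with the ground-truth displaced-bundle mask.
    """
    spec = scene["spec"]
    atlas = build_atlas(scene["training_bundles"], (spec.shape, spec.affine), lmax)
    result = segment_tract(
        atlas,
        scene["fod"],
        scene["brain"],
        scene["tumour"],
        params=scene["params"],
    )
    result["atlas"] = atlas
    result["dice"] = dice(result["mask"], scene["truth_mask"])
    return result
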