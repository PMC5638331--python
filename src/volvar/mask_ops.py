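"""Segmentation-mask operations: threshold/binarize, physical volume, Dice.

These mirror the mask handling of a registration-based volumetry pipeline:
probabilistic ROI labels warped into participant space are thresholded and
binarized, volumes are voxel counts scaled by the voxel size, and run-to-run
consistency is summarized by the Dice similarity coefficient.
"""

from __future__ import annotations

import numpy as np

from .images import LabelImage, ProbabilityImage

__all__ = ["threshold_binarize", "mask_volume", "dice"]

#: Relative tolerance for voxel-dimension compatibility between two grids.
VOXEL_DIM_RTOL = 1e-6


def threshold_binarize(img: ProbabilityImage, threshold: float = 0.5) -> LabelImage:
    """Binarize a probability image: voxels in ``[threshold, 1]`` map to 1.

    The lower bound is inclusive, matching the closed-interval [0.5, 1] -> 1
    mapping conventionally used when binarizing warped probabilistic labels.

    Parameters
    ----------
    img
        Probability image with values in [0, 1].
    threshold
        Inclusive lower bound, required to lie in (0, 1].
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    mask = (img.data >= threshold).astype(np.int32)
    return LabelImage(mask, img.voxel_dims.copy(), np.asarray(img.affine).copy())


def mask_volume(img: LabelImage, label: int) -> float:
    """Physical volume in mm^3 of all voxels equal to ``label``.

    An absent label is legal and yields 0.0; no rounding is applied to the
    voxel count times voxel volume product.
    """
    count = int(np.count_nonzero(img.data == label))
    return count * img.voxel_volume_mm3


def _check_compatible(a: LabelImage, b: LabelImage) -> None:
    if a.data.shape != b.data.shape:
        raise ValueError(f"grid shape mismatch: {a.data.shape} vs {b.data.shape}")
    if not np.allclose(a.voxel_dims, b.voxel_dims, rtol=VOXEL_DIM_RTOL, atol=0.0):
        raise ValueError(f"voxel dimension mismatch: {a.voxel_dims} vs {b.voxel_dims}")


def dice(a: LabelImage, b: LabelImage, label: int) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) for one label.

    ``A`` and ``B`` are the voxel sets equal to ``label`` in each image.
    Raises if the grids are incompatible or if the label is absent from both
    images (the 0/0 case is undefined rather than 0 or 1); one empty mask
    against a non-empty one gives 0.0.
    """
    _check_compatible(a, b)
    mask_a = a.data == label
    mask_b = b.data == label
    na = int(np.count_nonzero(mask_a))
    nb = int(np.count_nonzero(mask_b))
    if na + nb == 0:
        raise ValueError(f"label {label} absent from both images; Dice is undefined")
    inter = int(np.count_nonzero(mask_a & mask_b))
    return 2.0 * inter / (na + nb)
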