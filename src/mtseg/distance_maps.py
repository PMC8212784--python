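"""Ground-truth distance maps for the distance-transform regression decoder.

For each of the three foreground classes (necrosis, edema, enhancing
tumor) the target is the unsigned interior Euclidean distance transform:
zero outside the class, and inside it the distance (voxels, or mm when a
spacing is supplied) to the nearest voxel not of that class.  Each
channel is divided by its own maximum so the deepest interior voxel maps
to 1 — the scale the sigmoid-activated decoder head can reach, and
invariant to tumor size.  An absent class yields an all-zero channel.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["ground_truth_distance_maps"]


def ground_truth_distance_maps(
    mask: np.ndarray,
    spacing: tuple[float, float, float] | None = None,
    normalize: bool = True,
) -> np.ndarray:
    """Per-class normalized distance maps from a one-hot mask.

    Parameters
    ----------
    mask
        (D, H, W, 4) one-hot array (background, necrosis, edema,
        enhancing); channels must sum to 1 at every voxel.
    spacing
        Optional voxel spacing for anisotropic distances; default treats
        voxels as isotropic units.
    normalize
        Divide each channel by its maximum (default).  With
        ``normalize=False`` raw distances are returned.

    Returns
    -------
    (D, H, W, 3) array in [0, 1] (channels: necrosis, edema, enhancing).
    """
    mask = np.asarray(mask)
    if mask.ndim != 4 or mask.shape[-1] != 4:
        raise ValueError(f"expected (D, H, W, 4) one-hot mask, got {mask.shape}")
    sums = mask.sum(axis=-1)
    if not np.allclose(sums, 1.0):
        raise ValueError("one-hot channels must sum to 1 at every voxel")

    out = np.zeros(mask.shape[:3] + (3,), dtype=np.float32)
    for c in range(3):
        cls = mask[..., c + 1] > 0.5
        if not cls.any():
            continue
        # EDT of the class support: distance to the nearest non-class voxel.
        dist = ndimage.distance_transform_edt(cls, sampling=spacing)
        if normalize:
            dist = dist / dist.max()
        out[..., c] = dist
    return out
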