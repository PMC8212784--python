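"""BraTS-layout case I/O and preprocessing.

Covers reading/writing the per-case NIfTI quadruple (FLAIR, T1, T1-CE,
T2) plus segmentation, per-modality Z-score standardization, modality
stacking into a 4-channel volume, one-hot label encoding for the label
set {0 background, 1 necrosis, 2 edema, 4 enhancing tumor}, and 3D patch
extraction (deterministic grid tiling for inference, seeded tumor-biased
random sampling for training).

Arrays are channel-last: images are (D, H, W, 4) and one-hot masks
(D, H, W, 4) with channel order background, necrosis, edema, enhancing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "MODALITIES",
    "VALID_LABELS",
    "MultimodalVolume",
    "PatchPair",
    "read_case",
    "write_case",
    "zscore_normalize",
    "stack_modalities",
    "encode_labels_onehot",
    "decode_onehot",
    "extract_patches",
    "grid_origins",
]

MODALITIES = ("flair", "t1", "t1ce", "t2")
VALID_LABELS = (0, 1, 2, 4)
# one-hot channel <-> label value; channel 3 carries label 4 (enhancing tumor)
_LABEL_TO_CHANNEL = {0: 0, 1: 1, 2: 2, 4: 3}
_CHANNEL_TO_LABEL = np.array([0, 1, 2, 4], dtype=np.int16)


@dataclass
class MultimodalVolume:
    """A 4-channel intensity volume with geometry metadata.

    ``data`` has shape (D, H, W, 4), channel order FLAIR, T1, T1-CE, T2.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[-1] != 4:
            raise ValueError(f"expected (D, H, W, 4) data, got shape {self.data.shape}")

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class PatchPair:
    """Congruent image/mask sub-volumes and their offset in the parent."""

    image: np.ndarray  # (d, h, w, 4)
    mask: np.ndarray | None  # (d, h, w, 4) one-hot, or None at inference
    origin: tuple[int, int, int]


def _nifti(path: Path) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, img.affine, spacing


def write_case(case_dir: str | Path, case_id: str, image: MultimodalVolume, labels: np.ndarray | None) -> None:
    """Write one case in BraTS naming: <id>_flair/_t1/_t1ce/_t2[/_seg].nii.gz."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    for k, mod in enumerate(MODALITIES):
        nib.save(
            nib.Nifti1Image(np.asarray(image.data[..., k], dtype=np.float32), image.affine),
            str(case_dir / f"{case_id}_{mod}.nii.gz"),
        )
    if labels is not None:
        nib.save(
            nib.Nifti1Image(np.asarray(labels, dtype=np.int16), image.affine),
            str(case_dir / f"{case_id}_seg.nii.gz"),
        )


def read_case(case_dir: str | Path) -> tuple[MultimodalVolume, np.ndarray | None]:
    """Read a BraTS-layout case directory.

    Channels come back in fixed order FLAIR, T1, T1-CE, T2 regardless of
    directory listing order.  The segmentation is optional (validation
    cases); label values are checked against {0, 1, 2, 4}.
    """
    case_dir = Path(case_dir)
    if not case_dir.is_dir():
        raise FileNotFoundError(f"case directory not found: {case_dir}")

    def find(suffix: str) -> Path | None:
        hits = sorted(
            p
            for p in case_dir.iterdir()
            if p.name.endswith((f"_{suffix}.nii.gz", f"_{suffix}.nii"))
        )
        return hits[0] if hits else None

    channels, affine, spacing = [], None, None
    for mod in MODALITIES:
        path = find(mod)
        if path is None:
            raise FileNotFoundError(f"missing modality '{mod}' in {case_dir}")
        data, aff, sp = _nifti(path)
        channels.append(np.asarray(data, dtype=np.float32))
        affine, spacing = aff, sp
    shapes = {c.shape for c in channels}
    if len(shapes) != 1:
        raise ValueError(f"modality shapes differ in {case_dir}: {sorted(shapes)}")
    image = MultimodalVolume(np.stack(channels, axis=-1), spacing=spacing, affine=affine)

    seg_path = find("seg")
    labels = None
    if seg_path is not None:
        labels, _, _ = _nifti(seg_path)
        labels = np.asarray(np.rint(labels), dtype=np.int16)
        bad = np.setdiff1d(np.unique(labels), VALID_LABELS)
        if bad.size:
            raise ValueError(f"unexpected label values {bad.tolist()} in {seg_path}")
        if labels.shape != image.spatial_shape:
            raise ValueError(
                f"segmentation shape {labels.shape} != image shape {image.spatial_shape}"
            )
    return image, labels


def zscore_normalize(volume: np.ndarray, nonzero_only: bool = False) -> np.ndarray:
    """Standardize one modality channel to zero mean and unit variance.

    Statistics are computed over the whole volume by default; with
    ``nonzero_only`` only the non-zero (brain) voxels define mean/sd and
    background voxels are standardized with those brain statistics.  A
    constant volume (sd = 0) returns all zeros with a warning.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.size == 0:
        raise ValueError("empty volume")
    sel = volume[volume != 0] if nonzero_only else volume
    if sel.size == 0:
        sel = volume
    mean, sd = float(sel.mean()), float(sel.std())
    if sd == 0.0:
        warnings.warn("constant volume: z-score undefined, returning zeros", stacklevel=2)
        return np.zeros_like(volume, dtype=np.float32)
    return ((volume - mean) / sd).astype(np.float32)


def stack_modalities(flair: np.ndarray, t1: np.ndarray, t1ce: np.ndarray, t2: np.ndarray, **meta) -> MultimodalVolume:
    """Stack four single-modality volumes into the fixed channel order."""
    vols = [np.asarray(v) for v in (flair, t1, t1ce, t2)]
    shapes = [v.shape for v in vols]
    if len(set(shapes)) != 1:
        raise ValueError(f"modality shapes differ: {shapes}")
    return MultimodalVolume(np.stack(vols, axis=-1), **meta)


def encode_labels_onehot(labels: np.ndarray) -> np.ndarray:
    """One-hot encode a {0,1,2,4} label volume to 4 channels (label 4 -> channel 3)."""
    labels = np.asarray(labels)
    bad = np.setdiff1d(np.unique(labels), VALID_LABELS)
    if bad.size:
        raise ValueError(f"unexpected label values {bad.tolist()}")
    onehot = np.zeros(labels.shape + (4,), dtype=np.float32)
    for value, ch in _LABEL_TO_CHANNEL.items():
        onehot[..., ch] = labels == value
    return onehot


def decode_onehot(onehot: np.ndarray) -> np.ndarray:
    """Invert :func:`encode_labels_onehot` (argmax, then channel 3 -> label 4)."""
    onehot = np.asarray(onehot)
    if onehot.ndim != 4 or onehot.shape[-1] != 4:
        raise ValueError(f"expected (D, H, W, 4) one-hot mask, got {onehot.shape}")
    return _CHANNEL_TO_LABEL[np.argmax(onehot, axis=-1)]


def grid_origins(volume_shape: tuple[int, int, int], patch_shape: tuple[int, int, int], stride: tuple[int, int, int] | None = None) -> list[tuple[int, int, int]]:
    """Origins of an overlapping grid covering every voxel at least once.

    Starts advance by ``stride`` (default: patch shape, i.e. no overlap)
    and the final start per axis is clamped so the last patch ends at the
    volume boundary.
    """
    stride = stride or patch_shape
    axes = []
    for size, p, s in zip(volume_shape, patch_shape, stride):
        if p > size:
            raise ValueError(f"patch extent {p} exceeds volume extent {size}")
        starts = list(range(0, size - p + 1, s))
        if starts[-1] != size - p:
            starts.append(size - p)
        axes.append(starts)
    return [(a, b, c) for a in axes[0] for b in axes[1] for c in axes[2]]


def extract_patches(
    image: MultimodalVolume | np.ndarray,
    mask: np.ndarray | None,
    patch_shape: tuple[int, int, int],
    mode: str = "grid",
    n_patches: int = 0,
    tumor_fraction: float = 0.5,
    stride: tuple[int, int, int] | None = None,
    seed: int = 0,
) -> list[PatchPair]:
    """Cut congruent image/mask patches.

    ``grid`` mode tiles the volume deterministically with overlap so the
    union of patches covers it; ``random`` mode draws ``n_patches``
    seeded origins, forcing a ``tumor_fraction`` of them to contain at
    least one foreground mask voxel whenever the mask has any.
    """
    data = image.data if isinstance(image, MultimodalVolume) else np.asarray(image)
    vol_shape = data.shape[:3]
    patch_shape = tuple(patch_shape)
    if any(p > s for p, s in zip(patch_shape, vol_shape)):
        raise ValueError(f"patch shape {patch_shape} exceeds volume shape {vol_shape}")
    if mask is not None and mask.shape[:3] != vol_shape:
        raise ValueError("image and mask spatial shapes differ")

    def cut(origin: tuple[int, int, int]) -> PatchPair:
        sl = tuple(slice(o, o + p) for o, p in zip(origin, patch_shape))
        return PatchPair(
            image=data[sl],
            mask=None if mask is None else mask[sl],
            origin=origin,
        )

    if mode == "grid":
        return [cut(o) for o in grid_origins(vol_shape, patch_shape, stride)]
    if mode != "random":
        raise ValueError(f"unknown mode {mode!r} (expected 'grid' or 'random')")

    rng = np.random.default_rng(seed)
    max_start = [s - p for s, p in zip(vol_shape, patch_shape)]
    fg = None
    if mask is not None:
        fg_mask = mask[..., 1:].sum(axis=-1) > 0 if mask.ndim == 4 else mask > 0
        fg = np.argwhere(fg_mask)
        if fg.size == 0:
            fg = None
    pairs: list[PatchPair] = []
    for i in range(n_patches):
        force_tumor = fg is not None and rng.random() < tumor_fraction
        if force_tumor:
            voxel = fg[rng.integers(len(fg))]
            origin = tuple(
                int(np.clip(v - rng.integers(0, p), 0, m))
                for v, p, m in zip(voxel, patch_shape, max_start)
            )
        else:
            origin = tuple(int(rng.integers(0, m + 1)) for m in max_start)
        pairs.append(cut(origin))
    return pairs
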