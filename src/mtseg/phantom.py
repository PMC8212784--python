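"""Synthetic multimodal brain-tumor phantoms with BraTS-style nested labels.

Each phantom is a skull-stripped "brain" ellipsoid on a zero background,
optionally carrying a nested tumor: an edema ellipsoid enclosing a tumor
core, whose outer shell is enhancing tumor (ring enhancement) and whose
inner part is necrosis.  Label conventions follow the BraTS datasets:
0 background, 1 necrosis, 2 edema, 4 enhancing tumor.  Four modality
channels (FLAIR, T1, T1-CE, T2) are rendered from a per-tissue contrast
table plus Gaussian noise, so the modality-dependent appearance of real
gliomas (edema bright on FLAIR/T2, enhancing rim bright on T1-CE,
necrosis dark on T1/T1-CE) is reproduced at the level a segmentation
network can exploit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .brats_io import MODALITIES, MultimodalVolume, write_case

__all__ = ["PhantomSpec", "DEFAULT_CONTRAST", "generate_case", "generate_dataset"]

# Mean intensity (arbitrary units) per tissue and modality.
# Rows: tissue; columns: FLAIR, T1, T1-CE, T2.
DEFAULT_CONTRAST: dict[str, tuple[float, float, float, float]] = {
    "background": (0.0, 0.0, 0.0, 0.0),
    "brain": (100.0, 100.0, 100.0, 100.0),
    "necrosis": (120.0, 70.0, 60.0, 140.0),
    "edema": (170.0, 105.0, 100.0, 165.0),
    "enhancing": (130.0, 110.0, 185.0, 130.0),
}

_LABEL_OF_TISSUE = {"necrosis": 1, "edema": 2, "enhancing": 4}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic case.

    ``subregion_radii`` are the nominal semi-axes (voxels) of the edema,
    core and inner-core (necrosis) ellipsoids and must be strictly
    decreasing; the enhancing rim is the shell between core and inner
    core.  ``brain_radius_fraction`` scales the brain ellipsoid semi-axes
    relative to half the volume extent.
    """

    volume_shape: tuple[int, int, int] = (64, 64, 64)
    brain_radius_fraction: float = 0.85
    tumor_present: bool = True
    subregion_radii: tuple[float, float, float] = (13.0, 8.0, 5.0)
    modality_contrast_table: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONTRAST)
    )
    noise_sd: float = 10.0
    radius_jitter: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if len(self.volume_shape) != 3 or any(s < 8 for s in self.volume_shape):
            raise ValueError(f"volume_shape must be 3 axes of >= 8 voxels, got {self.volume_shape}")
        if not (0.0 < self.brain_radius_fraction <= 1.0):
            raise ValueError("brain_radius_fraction must lie in (0, 1]")
        r_ed, r_core, r_inner = self.subregion_radii
        if not (r_ed > r_core > r_inner > 0):
            raise ValueError(
                f"subregion radii must be strictly decreasing and positive, got {self.subregion_radii}"
            )
        brain_semi = self._brain_semiaxes()
        if r_ed * (1.0 + self.radius_jitter) >= min(brain_semi):
            raise ValueError(
                "edema radius (with jitter) does not fit inside the brain ellipsoid: "
                f"{r_ed * (1.0 + self.radius_jitter):.1f} >= {min(brain_semi):.1f}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        missing = {"background", "brain", "necrosis", "edema", "enhancing"} - set(
            self.modality_contrast_table
        )
        if missing:
            raise ValueError(f"contrast table missing tissues: {sorted(missing)}")

    def _brain_semiaxes(self) -> np.ndarray:
        return self.brain_radius_fraction * (np.asarray(self.volume_shape, float) / 2.0)


def _ellipsoid_mask(shape: tuple[int, int, int], center: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def generate_case(spec: PhantomSpec) -> tuple[MultimodalVolume, np.ndarray]:
    """Render one phantom: a 4-channel intensity volume and its label volume.

    Deterministic in ``spec`` (including ``spec.seed``).  Returns the
    image as a :class:`MultimodalVolume` (channel-last) and the labels as
    an integer array over {0, 1, 2, 4}.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.volume_shape)
    center_vol = np.asarray(shape, float) / 2.0 - 0.5
    brain_semi = spec._brain_semiaxes()

    brain = _ellipsoid_mask(shape, center_vol, brain_semi)
    labels = np.zeros(shape, dtype=np.int16)

    if spec.tumor_present:
        r_ed, r_core, r_inner = spec.subregion_radii
        # Per-axis jitter stands in for orientation variability while the
        # ellipsoids stay axis-aligned.
        jit = rng.uniform(1.0 - spec.radius_jitter, 1.0 + spec.radius_jitter, size=3)
        ed_semi = r_ed * jit
        core_semi = r_core * jit
        inner_semi = r_inner * jit
        # Center drawn so the edema ellipsoid fits inside the brain ellipsoid.
        slack = np.maximum(brain_semi - ed_semi, 0.0)
        # Keep within an inner box of the brain ellipsoid (conservative but simple).
        offset = rng.uniform(-0.5, 0.5, size=3) * slack
        tumor_center = center_vol + offset

        edema = _ellipsoid_mask(shape, tumor_center, ed_semi) & brain
        core = _ellipsoid_mask(shape, tumor_center, core_semi) & brain
        inner = _ellipsoid_mask(shape, tumor_center, inner_semi) & brain
        labels[edema] = 2
        labels[core & ~inner] = 4
        labels[inner] = 1

    data = np.zeros(shape + (4,), dtype=np.float32)
    table = spec.modality_contrast_table
    tissue_masks = {
        "brain": brain & (labels == 0),
        "necrosis": labels == 1,
        "edema": labels == 2,
        "enhancing": labels == 4,
    }
    for name, mask in tissue_masks.items():
        data[mask] = np.asarray(table[name], dtype=np.float32)
    if spec.noise_sd > 0:
        noise = rng.normal(0.0, spec.noise_sd, size=data.shape).astype(np.float32)
        data[brain] += noise[brain]  # background stays exactly 0 (skull-stripped convention)

    image = MultimodalVolume(data=data, spacing=(1.0, 1.0, 1.0), affine=np.eye(4))
    return image, labels


def generate_dataset(
    n_cases: int,
    root: str | Path,
    spec: PhantomSpec | None = None,
    seed: int = 0,
    overwrite: bool = False,
    tumor_free_fraction: float = 0.0,
) -> list[dict]:
    """Write ``n_cases`` phantoms in BraTS directory layout under ``root``.

    One folder per case holding the four modality NIfTI files and the
    segmentation.  Per-case seeds are spawned deterministically from
    ``seed``, so the dataset is a pure function of (spec, seed).  A
    manifest (also written to ``root/manifest.json``) lists case ids and
    file paths.  ``tumor_free_fraction`` makes a deterministic leading
    fraction of cases tumor-free (e.g. to emulate LGG cases without
    enhancing tumor use a spec variant instead).
    """
    if n_cases < 0:
        raise ValueError("n_cases must be non-negative")
    spec = spec or PhantomSpec()
    root = Path(root)
    manifest: list[dict] = []
    if n_cases == 0:
        return manifest
    if root.exists() and any(root.iterdir()) and not overwrite:
        raise FileExistsError(f"refusing to write into non-empty directory {root} (use overwrite)")
    root.mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(seed).generate_state(n_cases) % (2**31)
    n_tumor_free = int(round(tumor_free_fraction * n_cases))
    for i in range(n_cases):
        case_id = f"phantom_{i:03d}"
        case_spec = replace(
            spec, seed=int(seeds[i]), tumor_present=spec.tumor_present and i >= n_tumor_free
        )
        image, labels = generate_case(case_spec)
        case_dir = root / case_id
        write_case(case_dir, case_id, image, labels)
        manifest.append(
            {
                "case_id": case_id,
                "dir": str(case_dir),
                "files": {m: str(case_dir / f"{case_id}_{m}.nii.gz") for m in MODALITIES}
                | {"seg": str(case_dir / f"{case_id}_seg.nii.gz")},
                "seed": int(seeds[i]),
                "tumor_present": bool(case_spec.tumor_present),
            }
        )
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
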