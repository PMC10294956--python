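"""Seeded synthetic 4-phase tumor phantoms.

Emulates the structure of a multi-phase glioma dataset — four co-registered
phase volumes plus a multi-label tumor mask — without any anatomical or MRI
physics realism.  The "tumor" is an ellipsoid whose interior texture is
smoothed Gaussian noise (smoothing length controls run structure, hence the
run-length features) plus a radial intensity gradient (controls the
histogram moments), with per-class parameter defaults so two classes are
separable through exactly the two feature families the transform measures.

Class A is the high-grade-like surrogate (coarser texture: longer runs,
stronger gradient); class B the low-grade-like surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import PHASE_LABELS, PhaseVolume, save_nifti_volume

#: Per-phase texture of one class: (noise_std, smoothing_length,
#: intensity_mean, gradient_strength), intensities in arbitrary MR units.
CLASS_TEXTURES: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "A": {
        "T1": (8.0, 3.0, 120.0, 45.0),
        "T2": (9.0, 3.0, 140.0, 50.0),
        "T1ce": (8.0, 2.5, 160.0, 55.0),
        "FLAIR": (9.0, 3.0, 130.0, 45.0),
    },
    "B": {
        "T1": (8.0, 1.0, 100.0, 15.0),
        "T2": (9.0, 1.0, 120.0, 18.0),
        "T1ce": (8.0, 1.0, 125.0, 16.0),
        "FLAIR": (9.0, 1.0, 110.0, 15.0),
    },
}

DEFAULT_SHAPE = (64, 64, 32)


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = DEFAULT_SHAPE
    class_label: str = "A"
    tumor_center: tuple[float, float, float] | None = None
    tumor_radii: tuple[float, float, float] | None = None
    texture: dict[str, tuple[float, float, float, float]] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_TEXTURES:
            raise ValueError(f"class_label must be A or B, got "
                             f"{self.class_label!r}")
        n, m, l = self.shape
        if self.tumor_center is None:
            self.tumor_center = (n / 2.0, m / 2.0, l / 2.0)
        if self.tumor_radii is None:
            self.tumor_radii = (n * 0.3, m * 0.3, l * 0.3)
        if self.texture is None:
            self.texture = CLASS_TEXTURES[self.class_label]
        for c, r, s in zip(self.tumor_center, self.tumor_radii, self.shape):
            if c - r < 0 or c + r > s:
                raise ValueError(
                    f"ellipsoid (center {self.tumor_center}, radii "
                    f"{self.tumor_radii}) exceeds volume shape {self.shape}"
                )


def _ellipsoid_radius(shape, center, radii) -> np.ndarray:
    """Normalized ellipsoid radius field: <= 1 inside the tumor."""
    grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
    r2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return np.sqrt(r2)


def generate_phantom(spec: PhantomSpec):
    """One synthetic case: four PhaseVolume objects and a label volume.

    Interior texture per phase: mean + gradient * (1 - r) + smoothed unit
    noise * noise_std, clipped at 0; background exactly 0.  The label
    volume marks three concentric shells with the conventional glioma
    labels 1 (core), 4 (enhancing ring), 2 (outer edema), exercising the
    mask collapse.  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    r = _ellipsoid_radius(spec.shape, spec.tumor_center, spec.tumor_radii)
    inside = r <= 1.0
    if not inside.any():
        raise ValueError("degenerate ellipsoid: no interior voxels")

    labels = np.zeros(spec.shape, dtype=np.int16)
    labels[r <= 1.0] = 2
    labels[r <= 0.75] = 4
    labels[r <= 0.45] = 1

    phases = []
    for phase in PHASE_LABELS:
        noise_std, smooth_len, mean, gradient = spec.texture[phase]
        noise = rng.standard_normal(spec.shape)
        if smooth_len > 0:
            noise = gaussian_filter(noise, sigma=smooth_len)
            sd = noise.std()
            if sd > 0:  # restore unit variance lost to smoothing
                noise /= sd
        vol = mean + gradient * (1.0 - r) + noise_std * noise
        vol = np.clip(vol, 0.0, None)
        vol[~inside] = 0.0
        phases.append(PhaseVolume(vol, phase_label=phase))
    return phases, labels


def case_seed(master_seed: int, index: int) -> int:
    """Deterministic per-case seed below 2**31."""
    return int(
        np.random.SeedSequence([master_seed, index]).generate_state(1)[0]
        % (2 ** 31)
    )


def generate_cohort_specs(n_per_class: int,
                          shape: tuple[int, int, int] = DEFAULT_SHAPE,
                          seed: int = 0) -> list[PhantomSpec]:
    """Specs for a balanced two-class cohort (class A cases first)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    specs = []
    for idx, label in enumerate(["A"] * n_per_class + ["B"] * n_per_class):
        specs.append(PhantomSpec(shape=shape, class_label=label,
                                 seed=case_seed(seed, idx)))
    return specs


def generate_cohort(n_per_class: int, shape=DEFAULT_SHAPE, seed: int = 0,
                    out_dir: str | Path = ".") -> pd.DataFrame:
    """Write a cohort as NIfTI files plus a manifest CSV.

    Manifest columns: case_id, one path column per phase, mask path and
    class label — the layout the batch transform consumes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, spec in enumerate(generate_cohort_specs(n_per_class, shape, seed)):
        case_id = f"case_{idx:03d}_{spec.class_label}"
        case_dir = out_dir / case_id
        case_dir.mkdir(exist_ok=True)
        phases, labels = generate_phantom(spec)
        row = {"case_id": case_id}
        for vol in phases:
            p = case_dir / f"{vol.phase_label.lower()}.nii.gz"
            save_nifti_volume(vol.intensities, p)
            row[vol.phase_label.lower()] = str(p)
        mask_path = case_dir / "mask.nii.gz"
        save_nifti_volume(labels, mask_path)
        row["mask"] = str(mask_path)
        row["label"] = spec.class_label
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
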