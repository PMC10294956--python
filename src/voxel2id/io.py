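"""NIfTI phase-volume and tumor-mask handling.

Loads co-registered MRI phase volumes (T1, T2, T1ce, FLAIR) and the tumor
label mask, collapses the multi-label mask to a binary volume-of-interest,
multiplies it into each phase, and zeroes "null" slices whose residual
intensity variation is below a threshold.  All arrays are arranged with
slices along the third axis; slice indices are 0-based throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

PHASE_LABELS = ("T1", "T2", "T1ce", "FLAIR")

#: Default null-slice threshold, relative to the volume maximum intensity.
DEFAULT_TAU_REL = 1e-6


class VolumeError(ValueError):
    """Raised for unreadable, mis-shaped or out-of-contract volumes."""


@dataclass
class PhaseVolume:
    """One 3D MRI phase: non-negative intensities, shape (N, M, L)."""

    intensities: np.ndarray
    phase_label: str
    source_path: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3:
            raise VolumeError(
                f"phase volume must be 3D, got {arr.ndim}D shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise VolumeError(f"{self.phase_label}: non-finite intensities")
        if arr.min() < 0:
            raise VolumeError(
                f"{self.phase_label}: negative intensities (min {arr.min():g})"
            )
        self.intensities = arr

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[2]


@dataclass
class TumorMask:
    """Binary volume of interest: 1 on tumor voxels, 0 on background."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise VolumeError(f"mask values must be 0/1, found {vals[:10]}")
        self.labels = arr.astype(np.uint8)


@dataclass
class MaskedVolume:
    """A phase volume after mask multiplication and null-slice cleaning."""

    intensities: np.ndarray
    phase_label: str
    cleaned_slice_indices: list[int] = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[2]


def load_nifti_volume(path, phase_label: str) -> PhaseVolume:
    """Load a 3D NIfTI file as a :class:`PhaseVolume`.

    The affine is consulted only to bring the array to the RAS axis order
    (slices along the third axis); no resampling is performed.  Accepts any
    integer or floating scalar dtype, ``.nii`` or ``.nii.gz``.
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise VolumeError(f"cannot read NIfTI {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise VolumeError(f"{path}: non-3D image (shape {img.shape})")
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj, dtype=np.float64)
    try:
        return PhaseVolume(data, phase_label=phase_label, source_path=str(path))
    except VolumeError as exc:
        raise VolumeError(f"{path}: {exc}") from exc


def load_label_volume(path) -> np.ndarray:
    """Load a NIfTI label mask as an integer array (canonical axis order)."""
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise VolumeError(f"cannot read NIfTI {path}: {exc}") from exc
    if len(img.shape) != 3:
        raise VolumeError(f"{path}: non-3D image (shape {img.shape})")
    img = nib.as_closest_canonical(img)
    return np.rint(np.asarray(img.dataobj, dtype=np.float64)).astype(np.int64)


def save_nifti_volume(array: np.ndarray, path) -> None:
    """Write an array as NIfTI with an identity affine."""
    nib.save(nib.Nifti1Image(np.asarray(array), np.eye(4)), str(path))


def binarize_mask(label_volume: np.ndarray) -> TumorMask:
    """Collapse tumor sub-region labels to a single binary mask.

    Background (0) stays 0; every positive label (BraTS uses 1, 2, 4) maps
    to 1, treating the tumor as a single undivided region.
    """
    labels = np.asarray(label_volume)
    if labels.min() < 0:
        raise VolumeError(f"label volume has negative labels (min {labels.min()})")
    return TumorMask((labels > 0).astype(np.uint8))


def apply_tumor_mask(vol: PhaseVolume, mask: TumorMask) -> MaskedVolume:
    """Elementwise product of a phase volume with the binary tumor mask."""
    if vol.intensities.shape != mask.labels.shape:
        raise VolumeError(
            f"shape mismatch: phase {vol.intensities.shape} vs "
            f"mask {mask.labels.shape}"
        )
    return MaskedVolume(
        intensities=vol.intensities * mask.labels,
        phase_label=vol.phase_label,
    )


def clean_null_slices(vol: MaskedVolume, tau: float) -> MaskedVolume:
    """Zero out slices whose intensity standard deviation falls below *tau*.

    Masking leaves some slices with only near-zero residues; such
    "non-zero null" slices carry no tumor texture but would perturb the
    feature rows, so any slice with per-slice population std < tau is
    replaced by an all-zero slice and its 0-based index recorded.
    """
    if tau < 0:
        raise VolumeError(f"tau must be non-negative, got {tau}")
    out = vol.intensities.copy()
    stds = out.std(axis=(0, 1))
    cleaned = [int(k) for k in np.nonzero(stds < tau)[0]]
    if cleaned:
        out[:, :, cleaned] = 0.0
    return MaskedVolume(
        intensities=out,
        phase_label=vol.phase_label,
        cleaned_slice_indices=cleaned,
    )


def default_tau(vol: MaskedVolume, rel: float = DEFAULT_TAU_REL) -> float:
    """Scale-invariant null-slice threshold: ``rel`` times the volume max."""
    vmax = float(vol.intensities.max())
    if vmax == 0.0:
        warnings.warn(f"{vol.phase_label}: all-zero masked volume", stacklevel=2)
    return rel * vmax
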