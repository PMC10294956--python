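"""Assembly of the 2D identity image from a 4-phase 3D tumor volume.

Pipeline per case: binarize the label mask, multiply it into each phase,
zero null slices, quantize each phase volume-wide, extract six FOS and six
run-length features per slice, stack them into a 12 x L matrix per phase,
normalize every feature row independently, and stack the four phase
matrices vertically (T1, T2, T1ce, FLAIR) into the 48 x L identity image.
The transform is a pure function of (inputs, config).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .fos import DEFAULT_GRAY_LEVELS, FOS_FEATURE_NAMES, quantize_volume, slice_fos
from .glrlm import DIRECTIONS, GLRLM_RETAINED_NAMES, select_glrlm_six, slice_glrlm
from .io import (
    DEFAULT_TAU_REL,
    PHASE_LABELS,
    MaskedVolume,
    PhaseVolume,
    VolumeError,
    apply_tumor_mask,
    binarize_mask,
    clean_null_slices,
    default_tau,
)

NORMALIZATION_MODES = ("none", "minmax", "zscore")

ROW_NAMES = FOS_FEATURE_NAMES + GLRLM_RETAINED_NAMES  # fixed 12-row order


@dataclass(frozen=True)
class TransformConfig:
    """Settings of the identity transform.

    gray_levels
        Quantization level count G; the range is [0, per-phase masked
        maximum] so background zeros sit on level 0.
    directions
        Run-length scan directions (degrees); features are averaged
        feature-wise across them.
    normalization
        Row-wise mode applied per phase before stacking: "none",
        "minmax" ((x-min)/(max-min)) or "zscore" ((x-mean)/population std).
    tau_rel
        Null-slice threshold as a fraction of the masked volume maximum.
    include_glrlm
        Disabling it yields the 6-row FOS-only degenerate variant.
    """

    gray_levels: int = DEFAULT_GRAY_LEVELS
    directions: tuple[int, ...] = DIRECTIONS
    normalization: str = "zscore"
    tau_rel: float = DEFAULT_TAU_REL
    phase_order: tuple[str, ...] = PHASE_LABELS
    include_glrlm: bool = True

    def __post_init__(self):
        if self.normalization not in NORMALIZATION_MODES:
            raise ValueError(
                f"normalization must be one of {NORMALIZATION_MODES}, "
                f"got {self.normalization!r}"
            )

    def to_dict(self) -> dict:
        return {
            "gray_levels": self.gray_levels,
            "directions": list(self.directions),
            "normalization": self.normalization,
            "tau_rel": self.tau_rel,
            "phase_order": list(self.phase_order),
            "include_glrlm": self.include_glrlm,
        }

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PhaseFeatureMatrix:
    """12 x L feature matrix of one phase (rows in ROW_NAMES order)."""

    values: np.ndarray
    phase_label: str
    row_names: tuple[str, ...] = ROW_NAMES
    normalization: str = "none"
    cleaned_slice_indices: list[int] = field(default_factory=list)

    @property
    def n_slices(self) -> int:
        return self.values.shape[1]


@dataclass
class IdentityImage:
    """The stacked (12 * n_phases) x L identity image of one case."""

    values: np.ndarray
    phase_order: tuple[str, ...]
    normalization: str
    case_id: str
    row_names: tuple[str, ...] = ROW_NAMES
    config_hash: str = ""
    cleaned_slices: dict[str, list[int]] = field(default_factory=dict)


def phase_feature_matrix(vol: MaskedVolume,
                         config: TransformConfig = TransformConfig()
                         ) -> PhaseFeatureMatrix:
    """Per-slice FOS + run-length features of one cleaned masked phase.

    Column l holds the six FOS values then the six retained run-length
    values of slice l; columns follow slice order.
    """
    if vol.n_slices == 0:
        raise VolumeError(f"{vol.phase_label}: volume has zero slices")
    G = config.gray_levels
    qv = quantize_volume(vol, G)
    cols = []
    for l in range(vol.n_slices):
        sl = qv.levels[:, :, l]
        feats = slice_fos(sl, G).as_array()
        if config.include_glrlm:
            six = select_glrlm_six(slice_glrlm(sl, G, config.directions))
            feats = np.concatenate([feats, six])
        cols.append(feats)
    values = np.column_stack(cols)
    row_names = ROW_NAMES if config.include_glrlm else FOS_FEATURE_NAMES
    return PhaseFeatureMatrix(
        values=values,
        phase_label=vol.phase_label,
        row_names=row_names,
        cleaned_slice_indices=list(vol.cleaned_slice_indices),
    )


def normalize_rows(matrix: PhaseFeatureMatrix, mode: str) -> PhaseFeatureMatrix:
    """Normalize each feature row independently.

    minmax maps a row to [0, 1]; zscore standardizes with the population
    (divide-by-n) std.  A constant row maps to all zeros in both modes,
    so rows dominated by cleaned slices stay finite.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    v = matrix.values
    if mode == "none":
        out = v.copy()
    elif mode == "minmax":
        lo = v.min(axis=1, keepdims=True)
        span = v.max(axis=1, keepdims=True) - lo
        safe = np.where(span == 0, 1.0, span)
        out = np.where(span == 0, 0.0, (v - lo) / safe)
    else:  # zscore
        mu = v.mean(axis=1, keepdims=True)
        sd = v.std(axis=1, keepdims=True)
        safe = np.where(sd == 0, 1.0, sd)
        out = np.where(sd == 0, 0.0, (v - mu) / safe)
    return PhaseFeatureMatrix(
        values=out,
        phase_label=matrix.phase_label,
        row_names=matrix.row_names,
        normalization=mode,
        cleaned_slice_indices=list(matrix.cleaned_slice_indices),
    )


def assemble_identity_image(matrices, case_id: str,
                            phase_order: tuple[str, ...] = PHASE_LABELS
                            ) -> IdentityImage:
    """Vertically stack per-phase matrices in the fixed phase order.

    Dispatch is by phase label, not input position.  All matrices must
    share L and normalization mode.
    """
    by_label = {m.phase_label: m for m in matrices}
    missing = [p for p in phase_order if p not in by_label]
    if missing:
        raise VolumeError(f"missing phase matrices: {missing}")
    ordered = [by_label[p] for p in phase_order]
    Ls = {m.n_slices for m in ordered}
    if len(Ls) != 1:
        raise VolumeError(f"mixed slice counts across phases: {sorted(Ls)}")
    norms = {m.normalization for m in ordered}
    if len(norms) != 1:
        raise VolumeError(f"mixed normalization modes: {sorted(norms)}")
    return IdentityImage(
        values=np.vstack([m.values for m in ordered]),
        phase_order=tuple(phase_order),
        normalization=norms.pop(),
        case_id=case_id,
        row_names=ordered[0].row_names,
        cleaned_slices={m.phase_label: list(m.cleaned_slice_indices)
                        for m in ordered},
    )


def transform_case(phases, mask_labels: np.ndarray,
                   config: TransformConfig = TransformConfig(),
                   case_id: str = "case") -> IdentityImage:
    """End-to-end transform of one 4-phase case into its identity image."""
    mask = binarize_mask(mask_labels)
    matrices = []
    for vol in phases:
        try:
            masked = apply_tumor_mask(vol, mask)
            masked = clean_null_slices(masked,
                                       default_tau(masked, config.tau_rel))
            pm = phase_feature_matrix(masked, config)
            matrices.append(normalize_rows(pm, config.normalization))
        except (VolumeError, ValueError) as exc:
            raise VolumeError(f"phase {vol.phase_label}: {exc}") from exc
    img = assemble_identity_image(matrices, case_id, config.phase_order)
    img.config_hash = config.hash()
    return img


def export_identity(image: IdentityImage, path, format: str = "lossless-array"):
    """Write an identity image to disk.

    "lossless-array" stores the exact float matrix plus metadata (phase
    order, normalization, row names, config hash) in an .npz container.
    "image-8bit" rescales min to 0 and max to 255 for visual or 2D
    classifier use and is lossy; a constant matrix maps to all zeros.
    """
    path = str(path)
    if format == "lossless-array":
        meta = json.dumps({
            "case_id": image.case_id,
            "phase_order": list(image.phase_order),
            "normalization": image.normalization,
            "row_names": list(image.row_names),
            "config_hash": image.config_hash,
            "cleaned_slices": image.cleaned_slices,
        })
        np.savez(path, values=image.values, metadata=np.array(meta))
    elif format == "image-8bit":
        from PIL import Image

        v = image.values
        span = v.max() - v.min()
        if span == 0:
            scaled = np.zeros(v.shape, dtype=np.uint8)
        else:
            scaled = np.round((v - v.min()) / span * 255).astype(np.uint8)
        Image.fromarray(scaled, mode="L").save(path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def load_identity(path) -> IdentityImage:
    """Read back a lossless-array export, bit-identical."""
    with np.load(str(path), allow_pickle=False) as npz:
        meta = json.loads(str(npz["metadata"]))
        return IdentityImage(
            values=npz["values"],
            phase_order=tuple(meta["phase_order"]),
            normalization=meta["normalization"],
            case_id=meta["case_id"],
            row_names=tuple(meta["row_names"]),
            config_hash=meta["config_hash"],
            cleaned_slices=meta["cleaned_slices"],
        )
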