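"""Gray level run length matrix (GLRLM) texture features.

A run is a maximal consecutive sequence of pixels with identical quantized
gray level along a scan direction.  The run length matrix p(i, j | theta)
counts runs of level i and exact length j along lines of direction theta
(0, 45, 90 or 135 degrees).  With T = sum p and N the slice pixel count:

    SRE  = sum p / j^2 / T        short runs emphasis
    LRE  = sum j^2 p / T          long runs emphasis
    GLN  = sum_i (sum_j p)^2 / T  gray level non-uniformity
    RLN  = sum_j (sum_i p)^2 / T  run length non-uniformity
    LGRE = sum p / i^2 / T        low gray level runs emphasis
    HGRE = sum i^2 p / T          high gray level runs emphasis
    RP   = T / N                  run percentage

Gray-level weights use 1-based level values (quantized level + 1) so the
1/i^2 weight is defined at level 0.  Of the seven features, HGRE is
computed and exportable but excluded from the identity-image row block.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

DIRECTIONS = (0, 45, 90, 135)

GLRLM_FEATURE_NAMES = ("sre", "lre", "gln", "rln", "lgre", "hgre", "rp")

#: Row order of the retained six inside the identity image.
GLRLM_RETAINED_NAMES = ("sre", "lre", "gln", "rln", "rp", "lgre")


@dataclass
class RunLengthMatrix:
    counts: np.ndarray  # (G, R) non-negative integers
    direction: int
    n_pixels: int
    G: int

    @property
    def R(self) -> int:
        return self.counts.shape[1]

    @property
    def total_runs(self) -> int:
        return int(self.counts.sum())


@dataclass
class GlrlmVector:
    sre: float
    lre: float
    gln: float
    rln: float
    lgre: float
    hgre: float
    rp: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in GLRLM_FEATURE_NAMES])


def _direction_lines(arr: np.ndarray, direction: int) -> Iterable[np.ndarray]:
    """Scan lines of a 2D array for one of the four directions.

    0 deg walks rows left-to-right, 90 deg columns top-down, 45 deg
    anti-diagonals (down-left to up-right), 135 deg main diagonals
    (up-left to down-right).
    Run counting is orientation-symmetric, so only the line partition
    matters, not the walk sense.
    """
    h, w = arr.shape
    if direction == 0:
        return (arr[r, :] for r in range(h))
    if direction == 90:
        return (arr[:, c] for c in range(w))
    if direction == 135:
        return (np.diagonal(arr, offset=o) for o in range(-(h - 1), w))
    if direction == 45:
        flipped = arr[::-1, :]
        return (np.diagonal(flipped, offset=o) for o in range(-(h - 1), w))
    raise ValueError(f"unsupported direction {direction}; expected one of "
                     f"{DIRECTIONS}")


def run_length_matrix(slice_levels: np.ndarray, G: int,
                      direction: int) -> RunLengthMatrix:
    """Count maximal constant runs per gray level and exact length.

    The slice is decomposed into direction lines, the lines are joined
    with a sentinel so the whole slice is segmented in one pass, and the
    (level, length) pairs are accumulated into a G×R matrix with R equal
    to the longest observed run.
    """
    arr = np.asarray(slice_levels)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"slice must be a non-empty 2D array, got {arr.shape}")
    if arr.min() < 0 or arr.max() >= G:
        raise ValueError(
            f"levels outside [0, {G - 1}]: range [{arr.min()}, {arr.max()}]"
        )
    lines = list(_direction_lines(arr.astype(np.int64), direction))
    # sentinel -1 between lines prevents runs from crossing line boundaries
    joined = np.full(sum(len(l) for l in lines) + len(lines), -1,
                     dtype=np.int64)
    pos = 0
    for l in lines:
        joined[pos:pos + len(l)] = l
        pos += len(l) + 1
    boundaries = np.flatnonzero(np.diff(joined)) + 1
    starts = np.concatenate(([0], boundaries))
    lengths = np.diff(np.concatenate((starts, [len(joined)])))
    values = joined[starts]
    keep = values >= 0
    values, lengths = values[keep], lengths[keep]
    R = int(lengths.max()) if lengths.size else 1
    counts = np.zeros((G, R), dtype=np.int64)
    np.add.at(counts, (values, lengths - 1), 1)
    return RunLengthMatrix(counts=counts, direction=direction,
                           n_pixels=int(arr.size), G=G)


def glrlm_vector(rlm: RunLengthMatrix) -> GlrlmVector:
    """The seven run-length features of one matrix.

    All features are 0 by convention when the matrix holds no runs.
    """
    p = rlm.counts.astype(np.float64)
    T = p.sum()
    if T == 0:
        return GlrlmVector(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    j = np.arange(1, rlm.R + 1, dtype=np.float64)  # run lengths
    i = np.arange(1, rlm.G + 1, dtype=np.float64)  # 1-based level values
    level_marg = p.sum(axis=1)   # runs per gray level
    length_marg = p.sum(axis=0)  # runs per length
    return GlrlmVector(
        sre=float(length_marg @ (1.0 / j ** 2)) / T,
        lre=float(length_marg @ j ** 2) / T,
        gln=float(level_marg @ level_marg) / T,
        rln=float(length_marg @ length_marg) / T,
        lgre=float(level_marg @ (1.0 / i ** 2)) / T,
        hgre=float(level_marg @ i ** 2) / T,
        rp=T / rlm.n_pixels,
    )


def directional_average(vectors: Sequence[GlrlmVector]) -> GlrlmVector:
    """Feature-by-feature arithmetic mean across directions."""
    if len(vectors) == 0:
        raise ValueError("empty direction set")
    stacked = np.stack([v.as_array() for v in vectors])
    return GlrlmVector(*stacked.mean(axis=0))


def select_glrlm_six(v: GlrlmVector) -> np.ndarray:
    """The retained features (SRE, LRE, GLN, RLN, RP, LGRE) — HGRE dropped."""
    return np.array([getattr(v, n) for n in GLRLM_RETAINED_NAMES])


def slice_glrlm(slice_levels: np.ndarray, G: int,
                directions: Sequence[int] = DIRECTIONS) -> GlrlmVector:
    """Direction-averaged run-length features for one quantized slice."""
    return directional_average(
        [glrlm_vector(run_length_matrix(slice_levels, G, d))
         for d in directions]
    )
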