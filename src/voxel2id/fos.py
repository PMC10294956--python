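"""Per-slice first-order statistics (FOS).

A masked phase volume is quantized once, volume-wide, onto integer gray
levels [0, G-1].  Each slice then yields a gray-level histogram h(i), a
probability density p(i) = h(i) / n_pixels, and six histogram features:

    mean      mu      = sum_i i p(i)
    std       sigma   = sqrt( sum_i (i - mu)^2 p(i) )
    skewness  mu3     = sigma^-3 sum_i (i - mu)^3 p(i)
    kurtosis  mu4     = sigma^-4 sum_i (i - mu)^4 p(i) - 3   (excess form)
    energy            = sum_i p(i)^2
    entropy           = -sum_i p(i) log2 p(i),  0 log 0 := 0

Background zeros are part of every slice's histogram, so tumor area per
slice (a location/size cue) influences the features.  When sigma = 0 the
standardized moments are defined as 0, keeping cleaned all-zero slices
finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

FOS_FEATURE_NAMES = ("mean", "std", "skewness", "kurtosis", "energy", "entropy")

DEFAULT_GRAY_LEVELS = 256


@dataclass
class QuantizedVolume:
    levels: np.ndarray  # 3D int array in [0, G-1]
    G: int
    quantization_range: tuple[float, float]


@dataclass
class GrayHistogram:
    counts: np.ndarray  # length-G non-negative integers
    n_pixels: int


@dataclass
class IntensityPdf:
    probs: np.ndarray  # length-G, sums to 1


@dataclass
class FosVector:
    mean: float
    std: float
    skewness: float
    kurtosis: float
    energy: float
    entropy: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mean, self.std, self.skewness, self.kurtosis,
             self.energy, self.entropy]
        )


def quantize_volume(vol, G: int = DEFAULT_GRAY_LEVELS) -> QuantizedVolume:
    """Linearly map [0, volume max] onto integer levels {0, ..., G-1}.

    One range per phase volume, so all slices of a phase share a gray
    scale and exact zeros land on level 0.  The map ``floor(x / max * G)``
    (clipped at G-1) is monotone and is the identity on a [0, G-1]-valued
    integer volume whose max is G-1.
    """
    if G < 2:
        raise ValueError(f"G must be >= 2, got {G}")
    arr = np.asarray(vol.intensities if hasattr(vol, "intensities") else vol,
                     dtype=np.float64)
    vmax = float(arr.max())
    if vmax == 0.0:
        warnings.warn("all-zero volume: every voxel quantized to level 0",
                      stacklevel=2)
        levels = np.zeros(arr.shape, dtype=np.int64)
    else:
        levels = np.minimum(np.floor(arr / vmax * G), G - 1).astype(np.int64)
    return QuantizedVolume(levels=levels, G=G, quantization_range=(0.0, vmax))


def slice_histogram(slice_levels: np.ndarray, G: int) -> GrayHistogram:
    """Count occurrences of each gray level over the full slice area."""
    arr = np.asarray(slice_levels)
    if arr.size == 0:
        raise ValueError("empty slice")
    if arr.min() < 0 or arr.max() >= G:
        raise ValueError(
            f"levels outside [0, {G - 1}]: range [{arr.min()}, {arr.max()}]"
        )
    counts = np.bincount(arr.ravel(), minlength=G)
    return GrayHistogram(counts=counts, n_pixels=int(arr.size))


def histogram_pdf(h: GrayHistogram) -> IntensityPdf:
    """Normalize counts by the pixel total."""
    if h.n_pixels <= 0:
        raise ValueError("empty slice")
    return IntensityPdf(probs=h.counts / float(h.n_pixels))


def fos_vector(pdf: IntensityPdf) -> FosVector:
    """The six first-order features of one slice's intensity PDF."""
    p = np.asarray(pdf.probs, dtype=np.float64)
    i = np.arange(p.size, dtype=np.float64)
    mu = float(i @ p)
    d = i - mu
    var = float((d * d) @ p)
    sigma = np.sqrt(var)
    if sigma > 0:
        skew = float((d ** 3) @ p) / sigma ** 3
        kurt = float((d ** 4) @ p) / sigma ** 4 - 3.0
    else:
        skew = 0.0
        kurt = 0.0
    energy = float(p @ p)
    nz = p[p > 0]
    entropy = float(-(nz @ np.log2(nz)))
    return FosVector(mean=mu, std=float(sigma), skewness=skew,
                     kurtosis=kurt, energy=energy, entropy=entropy)


def slice_fos(slice_levels: np.ndarray, G: int) -> FosVector:
    """Histogram → PDF → features for one quantized slice."""
    return fos_vector(histogram_pdf(slice_histogram(slice_levels, G)))
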