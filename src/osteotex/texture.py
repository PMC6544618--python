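"""First-order gray-level histogram texture parameters.

All parameters are functionals of the normalized gray-level histogram
``p[k]``, k = 0..255, of the intensities in a region of interest:

* mean          m = Σ k·p[k]
* sigma         σ = [Σ (k−m)²·p[k]]^{1/2}           (population SD)
* skewness      σ⁻³ Σ (k−m)³·p[k]
* kurtosis      σ⁻⁴ Σ (k−m)⁴·p[k] − 3               (excess)
* energy        Σ p[k]²                              (uniformity; max 1)
* entropy       −Σ p[k]·log p[k], 0·log 0 ≡ 0       (nats by default)
* Nakagami      E²(X²) / Var(X²)                     (population moments)

The Nakagami parameter, borrowed from ultrasound backscatter statistics,
is a concentration measure of the squared-intensity population; in
mineralized tissue it rises as the intensity distribution tightens around
a high mean. All moments are population moments (divide by N, no sample
correction), so histogram-path and raw-pixel-path results coincide.
"""

from __future__ import annotations

import dataclasses
from typing import Literal, Sequence, Union

import numpy as np

__all__ = [
    "GrayHistogram",
    "TextureProfile",
    "EmptyRoiError",
    "DegenerateHistogramError",
    "build_histogram",
    "hist_mean",
    "hist_sigma",
    "hist_skewness",
    "hist_kurtosis",
    "hist_energy",
    "hist_entropy",
    "nakagami_parameter",
    "quartile_fraction",
    "texture_profile",
]

N_LEVELS = 256
_LEVELS = np.arange(N_LEVELS, dtype=float)


class EmptyRoiError(ValueError):
    """The pixel population is empty."""


class DegenerateHistogramError(ValueError):
    """A moment is undefined for this histogram (e.g. zero variance)."""


@dataclasses.dataclass(frozen=True)
class GrayHistogram:
    """Normalized gray-level histogram over the 8-bit range.

    ``p[k]`` is the probability mass at gray level k. ``n_pixels`` counts
    the contributing pixels; it is 0 for analytic histograms obtained by
    discretizing a density, which are allowed to carry less than unit total
    mass (point discretization truncates the tails outside [0, 255]).
    Pixel-built histograms must sum to 1 within 1e-9.
    """

    p: np.ndarray
    n_pixels: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (N_LEVELS,):
            raise ValueError(f"histogram must have {N_LEVELS} bins, got {p.shape}")
        if np.any(p < 0):
            raise ValueError("histogram probabilities must be non-negative")
        total = p.sum()
        if total > 1 + 1e-9 or total <= 0:
            raise ValueError(f"histogram mass {total} outside (0, 1]")
        if self.n_pixels > 0 and abs(total - 1.0) > 1e-9:
            raise ValueError(f"pixel histogram mass {total} != 1 within 1e-9")
        object.__setattr__(self, "p", p)

    @property
    def total_mass(self) -> float:
        return float(self.p.sum())


@dataclasses.dataclass(frozen=True)
class TextureProfile:
    """The seven histogram parameters plus the below-first-quartile fraction."""

    mean: float
    sigma: float
    skewness: float
    kurtosis: float
    energy: float
    entropy: float
    nakagami: float
    quartile_fraction: float

    PARAMETERS = (
        "mean",
        "sigma",
        "skewness",
        "kurtosis",
        "energy",
        "entropy",
        "nakagami",
    )


def _as_pixel_array(pixels: Sequence[int]) -> np.ndarray:
    arr = np.asarray(pixels)
    if arr.size == 0:
        raise EmptyRoiError("empty pixel population")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError("pixel values must be integers")
        arr = arr.astype(np.int64)
    lo, hi = int(arr.min()), int(arr.max())
    if lo < 0 or hi > 255:
        bad = lo if lo < 0 else hi
        raise ValueError(f"pixel value {bad} outside the 8-bit range [0, 255]")
    return arr.ravel()


def build_histogram(pixels: Sequence[int]) -> GrayHistogram:
    """Tally integer gray levels into a normalized 256-bin histogram."""
    arr = _as_pixel_array(pixels)
    counts = np.bincount(arr, minlength=N_LEVELS)
    return GrayHistogram(p=counts / arr.size, n_pixels=int(arr.size))


def hist_mean(h: GrayHistogram) -> float:
    """Σ k·p[k]: the average gray level; exact for pixel-built histograms."""
    return float(_LEVELS @ h.p)


def hist_sigma(h: GrayHistogram) -> float:
    """Probability-weighted population standard deviation about the mean."""
    m = hist_mean(h)
    var = float(((_LEVELS - m) ** 2) @ h.p)
    return float(np.sqrt(max(var, 0.0)))


def _standardized_moment(h: GrayHistogram, order: int) -> float:
    m = hist_mean(h)
    sigma = hist_sigma(h)
    if sigma == 0:
        raise DegenerateHistogramError(
            f"standardized moment of order {order} undefined: sigma is 0"
        )
    return float(((_LEVELS - m) ** order) @ h.p) / sigma**order


def hist_skewness(h: GrayHistogram) -> float:
    """Third standardized central moment (asymmetry)."""
    return _standardized_moment(h, 3)


def hist_kurtosis(h: GrayHistogram) -> float:
    """Fourth standardized central moment minus 3 (excess kurtosis)."""
    return _standardized_moment(h, 4) - 3.0


def hist_energy(h: GrayHistogram) -> float:
    """Σ p[k]² — uniformity; 1 iff exactly one occupied bin."""
    return float(h.p @ h.p)


def hist_entropy(h: GrayHistogram, base: Literal["natural", "log2"] = "natural") -> float:
    """−Σ p[k]·log p[k] with 0·log 0 ≡ 0; natural log by default."""
    p = h.p[h.p > 0]
    ent = -float(p @ np.log(p))
    if base == "log2":
        ent /= np.log(2.0)
    elif base != "natural":
        raise ValueError(f"unknown entropy base {base!r}")
    return ent


def nakagami_parameter(source: Union[GrayHistogram, Sequence[int]]) -> float:
    """E²(X²)/Var(X²) of the gray-level population, population moments.

    Accepts raw pixels or a histogram; the two paths agree to floating
    precision since both use divide-by-N moments.
    """
    if isinstance(source, GrayHistogram):
        w = source.p / source.total_mass
        e2 = float((_LEVELS**2) @ w)
        e4 = float((_LEVELS**4) @ w)
    else:
        arr = _as_pixel_array(source).astype(float)
        sq = arr**2
        e2 = float(sq.mean())
        e4 = float((sq**2).mean())
    var = e4 - e2**2
    if var <= 0:
        raise DegenerateHistogramError(
            "Nakagami parameter undefined: Var(X^2) is 0 (constant population)"
        )
    return e2**2 / var


def quartile_fraction(h: GrayHistogram, max_level: int = 64) -> float:
    """Probability mass at gray levels 0..max_level inclusive.

    The default cutoff 64 is the first quartile of the 8-bit range; the
    fraction proxies the share of low-density bone in the region.
    """
    if not 0 <= max_level <= 255:
        raise ValueError(f"max_level {max_level} outside [0, 255]")
    return float(h.p[: max_level + 1].sum())


def texture_profile(
    pixels: Sequence[int], entropy_base: Literal["natural", "log2"] = "natural"
) -> TextureProfile:
    """Compute all eight fields from one histogram pass over the pixels."""
    h = build_histogram(pixels)
    return TextureProfile(
        mean=hist_mean(h),
        sigma=hist_sigma(h),
        skewness=hist_skewness(h),
        kurtosis=hist_kurtosis(h),
        energy=hist_energy(h),
        entropy=hist_entropy(h, base=entropy_base),
        nakagami=nakagami_parameter(h),
        quartile_fraction=quartile_fraction(h),
    )
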