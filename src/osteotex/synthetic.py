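"""Synthetic micro-CT volumes with prescribed intensity statistics.

Two generators make the whole pipeline testable without scanner data:

* **Cortical cohorts** — annular-cylinder shells (the cross-section of a
  femoral mid-diaphysis) whose voxel intensities are i.i.d. draws from a
  skew-normal moment-matched to a target (mean, sigma, skewness). The
  skew-normal family covers |skewness| < 0.9952..., enough for both diet
  groups' targets. Marrow canal and background sit at level 0. Kurtosis is
  left emergent. Voxels are spatially independent: the downstream analysis
  is histogram-based and order-blind, so spatial texture is out of scope.

* **BMD phantom** — five parallel cylindrical inserts of known mineral
  density (default 200..1000 mg-HA/cm³) mapped linearly to gray levels
  (default 200→60, 1000→220) with additive Gaussian noise, embedded in a
  uniform base material. A label map identifies insert voxels.

Continuous draws are rounded half-to-even and clipped to [0, 255].
Everything is deterministic given (seed, specimen index).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .io import VoxelVolume

__all__ = [
    "GroupSpec",
    "PhantomSpec",
    "MAX_ABS_SKEWNESS",
    "UnattainableSkewnessError",
    "skew_normal_from_moments",
    "generate_cortical_volume",
    "generate_cohort",
    "generate_bmd_phantom",
]

# Supremum of |skewness| for the skew-normal family (shape -> infinity).
_DELTA_SQ_MAX = 2.0 / np.pi
MAX_ABS_SKEWNESS = float(
    0.5 * (4.0 - np.pi) * _DELTA_SQ_MAX**1.5 / (1.0 - _DELTA_SQ_MAX) ** 1.5
)


class UnattainableSkewnessError(ValueError):
    """Requested |skewness| is at or beyond the skew-normal family bound."""


@dataclasses.dataclass(frozen=True)
class GroupSpec:
    """Intensity-moment targets and shell geometry for one diet group.

    Defaults for the two arms are provided by :func:`control_group_spec`
    and :func:`low_mg_group_spec`. Geometry units are voxels/slices.
    """

    label: str
    target_mean: float
    target_sigma: float
    target_skewness: float
    n_specimens: int = 7
    outer_radius: float = 40.0
    canal_radius: float = 20.0
    n_slices: int = 56
    voxel_size_um: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.target_sigma > 0:
            raise ValueError(f"target_sigma must be > 0, got {self.target_sigma}")
        if abs(self.target_skewness) >= MAX_ABS_SKEWNESS:
            raise UnattainableSkewnessError(
                f"|skewness| = {abs(self.target_skewness)} is not attainable by "
                f"the skew-normal family (bound {MAX_ABS_SKEWNESS:.4f})"
            )
        if not 0 <= self.canal_radius < self.outer_radius:
            raise ValueError("need 0 <= canal_radius < outer_radius")


def control_group_spec(**overrides) -> GroupSpec:
    """Basal-diet arm: mean 98.1, sigma 17.8, skewness -0.906, n = 7."""
    base = dict(
        label="control", target_mean=98.1, target_sigma=17.8, target_skewness=-0.906
    )
    base.update(overrides)
    return GroupSpec(**base)


def low_mg_group_spec(**overrides) -> GroupSpec:
    """Low-magnesium arm: mean 105, sigma 12.6, skewness -0.729, n = 7."""
    base = dict(
        label="low_mg", target_mean=105.0, target_sigma=12.6, target_skewness=-0.729
    )
    base.update(overrides)
    return GroupSpec(**base)


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Insert densities and the density-to-gray mapping for the BMD phantom."""

    densities: tuple[float, ...] = (200.0, 400.0, 600.0, 800.0, 1000.0)
    slope: float = 0.2  # gray levels per (mg-HA/cm^3)
    intercept: float = 20.0
    noise_sigma: float = 5.0
    insert_radius: int = 10
    insert_length: int = 40
    background_level: int = 30
    voxel_size_um: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        if not np.all(np.diff(d) > 0):
            raise ValueError("insert densities must be strictly increasing")
        gray = self.slope * d + self.intercept
        if gray.min() < 0 or gray.max() > 255:
            raise ValueError(
                f"mapped gray levels {gray.min():.1f}..{gray.max():.1f} "
                "fall outside [0, 255]"
            )

    @property
    def insert_levels(self) -> np.ndarray:
        return self.slope * np.asarray(self.densities, dtype=float) + self.intercept


def _skewness_of_delta(delta: float) -> float:
    m = delta * np.sqrt(2.0 / np.pi)
    return 0.5 * (4.0 - np.pi) * m**3 / (1.0 - m**2) ** 1.5


def skew_normal_from_moments(
    mean: float, sd: float, skewness: float
) -> tuple[float, float, float]:
    """Skew-normal (location, scale, shape) matching analytic moments.

    The shape is found by bracketed inversion of the standard skewness
    formula in delta = shape/sqrt(1+shape²); scale and location then follow
    in closed form from the matched SD and mean.
    """
    if not sd > 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    if abs(skewness) >= MAX_ABS_SKEWNESS:
        raise UnattainableSkewnessError(
            f"|skewness| = {abs(skewness)} >= family bound {MAX_ABS_SKEWNESS:.4f}"
        )
    if skewness == 0:
        delta = 0.0
    else:
        target = abs(skewness)
        delta = optimize.brentq(
            lambda d: _skewness_of_delta(d) - target,
            0.0,
            1.0 - 1e-12,
            xtol=1e-14,
        )
        delta = float(np.copysign(delta, skewness))
    scale = sd / np.sqrt(1.0 - 2.0 * delta**2 / np.pi)
    location = mean - scale * delta * np.sqrt(2.0 / np.pi)
    shape = delta / np.sqrt(1.0 - delta**2) if abs(delta) < 1 else np.inf
    return float(location), float(scale), float(shape)


def _annulus_mask(outer_radius: float, canal_radius: float) -> np.ndarray:
    size = 2 * (int(np.ceil(outer_radius)) + 4)
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    return (r2 <= outer_radius**2) & (r2 > canal_radius**2)


def generate_cortical_volume(g: GroupSpec, specimen_index: int) -> VoxelVolume:
    """One annular-shell specimen with skew-normal cortical intensities.

    Deterministic given (g.seed, specimen_index); different indices draw
    from independent substreams of the group seed.
    """
    mask = _annulus_mask(g.outer_radius, g.canal_radius)
    n_shell = int(mask.sum())
    if n_shell == 0:
        raise ValueError("geometry leaves no shell voxels")
    loc, scale, shape = skew_normal_from_moments(
        g.target_mean, g.target_sigma, g.target_skewness
    )
    rng = np.random.default_rng(np.random.SeedSequence([g.seed, specimen_index]))
    draws = stats.skewnorm.rvs(
        shape, loc=loc, scale=scale, size=g.n_slices * n_shell, random_state=rng
    )
    levels = np.clip(np.rint(draws), 0, 255).astype(np.uint8)
    data = np.zeros((g.n_slices,) + mask.shape, dtype=np.uint8)
    data[:, mask] = levels.reshape(g.n_slices, n_shell)
    return VoxelVolume(data=data, voxel_size_um=g.voxel_size_um)


def generate_cohort(
    control: GroupSpec, treated: GroupSpec
) -> tuple[list[VoxelVolume], list[VoxelVolume]]:
    """n_specimens volumes per arm, each from its own specimen substream."""
    if control.label == treated.label:
        raise ValueError("the two arms must have distinct labels")
    volumes_a = [
        generate_cortical_volume(control, i) for i in range(control.n_specimens)
    ]
    volumes_b = [
        generate_cortical_volume(treated, i) for i in range(treated.n_specimens)
    ]
    return volumes_a, volumes_b


def generate_bmd_phantom(p: PhantomSpec) -> tuple[VoxelVolume, np.ndarray]:
    """The five-insert phantom volume and an insert label map.

    The label map assigns 0 to base material and 1..len(densities) to the
    inserts, ordered by increasing density along the x axis.
    """
    n = len(p.densities)
    r = p.insert_radius
    pitch = 2 * r + 6  # center-to-center spacing; 6-voxel margin avoids overlap
    ny = 2 * r + 12
    nx = pitch * n + 6
    nz = p.insert_length
    centers_x = [6 + r + i * pitch for i in range(n)]
    cy = ny / 2.0 - 0.5
    yy, xx = np.mgrid[0:ny, 0:nx]

    rng = np.random.default_rng(p.seed)
    levels = p.insert_levels
    mean_plane = np.full((ny, nx), float(p.background_level))
    labels_plane = np.zeros((ny, nx), dtype=np.int32)
    for i, cx in enumerate(centers_x):
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if np.any(labels_plane[disk] != 0):
            raise ValueError("inserts overlap; reduce radius or density count")
        mean_plane[disk] = levels[i]
        labels_plane[disk] = i + 1

    volume = np.broadcast_to(mean_plane, (nz, ny, nx)).copy()
    if p.noise_sigma > 0:
        volume = volume + rng.normal(0.0, p.noise_sigma, size=volume.shape)
    data = np.clip(np.rint(volume), 0, 255).astype(np.uint8)
    label_map = np.broadcast_to(labels_plane, (nz, ny, nx)).copy()
    return VoxelVolume(data=data, voxel_size_um=p.voxel_size_um), label_map
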