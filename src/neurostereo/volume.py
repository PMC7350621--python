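"""Cavalieri-principle volume estimation with a Gundersen-type error estimate.

The reference volume is estimated as V = ΣA × d, where ΣA is the summed
cross-sectional area of systematically sampled sections (every k-th section
with a uniform random start) and d = k × BA is the distance between sampled
sections.  Section areas come from point counting: a square grid of test
points with a uniform random offset is laid over each section, and
A_i = P_i × a(p) with a(p) the area per point (spacing²).

The coefficient of error follows the Gundersen–Jensen estimator for
systematic uniform random sampling (smoothness class m = 1, coefficient
1/240), with the standard point-counting "nugget" variance
ν = 0.0724 · (B̄/√Ā) · √(n · ΣP) added for the within-section noise of the
point counts; B̄/√Ā is the mean boundary-length to √area shape ratio of the
sampled profiles (≈ 3.545 for circles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .geometry import ellipse_polygon
from .sectioning import SectionStack

CIRCLE_SHAPE_RATIO = 2.0 * np.sqrt(np.pi)  # B/√A of a circle ≈ 3.5449


@dataclass(frozen=True)
class PointGrid:
    """Square test-point grid: spacing (µm) and random offset in [0, spacing)²."""

    spacing: float
    offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def area_per_point(self) -> float:
        return self.spacing ** 2

    @classmethod
    def random(cls, spacing: float, rng: np.random.Generator) -> "PointGrid":
        return cls(spacing, tuple(rng.uniform(0.0, spacing, size=2)))


@dataclass(frozen=True)
class SectionAreaEstimate:
    """Point-counted area of one section: A_i = P_i × a(p), exactly."""

    section_index: int
    point_count: int
    area_per_point: float

    @property
    def area(self) -> float:
        return self.point_count * self.area_per_point


@dataclass
class VolumeEstimate:
    """Cavalieri estimate V = ΣA × d with its coefficient of error."""

    sampled_section_indices: list[int]
    d: float
    sum_area: float
    volume: float
    ce: float
    point_counts: list[int] = field(default_factory=list)


def sample_sections_systematic(n_total: int,
                               target_count_range: tuple[int, int] = (8, 12),
                               seed: int | np.random.Generator | None = None,
                               ) -> tuple[list[int], int]:
    """Systematic uniform random sample of section indices.

    Picks the sampling period k so the number of sampled sections falls in
    ``target_count_range`` when feasible, then draws a uniform random start
    in [0, k).  Returns (sorted indices, k); the physical distance between
    sampled sections is d = k × BA.
    """
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    lo, hi = target_count_range
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_total <= lo:
        if n_total < lo:
            warnings.warn(
                f"only {n_total} sections available, below target minimum {lo}; "
                "using all sections")
        return list(range(n_total)), 1
    k = max(1, int(round(n_total / (0.5 * (lo + hi)))))
    # nudge k into the feasible band where possible
    while k > 1 and n_total // k < lo:
        k -= 1
    while int(np.ceil(n_total / k)) > hi and n_total // (k + 1) >= lo:
        k += 1
    start = int(rng.integers(0, k))
    return list(range(start, n_total, k)), k


def point_count_area(region: BaseGeometry, grid: PointGrid) -> SectionAreaEstimate:
    """Count grid points falling inside a planar region.

    Empty or degenerate regions give P_i = 0.
    """
    if region.is_empty or region.area == 0.0:
        return SectionAreaEstimate(-1, 0, grid.area_per_point)
    minx, miny, maxx, maxy = region.bounds
    sp, (ox, oy) = grid.spacing, grid.offset
    ix = np.arange(np.ceil((minx - ox) / sp), np.floor((maxx - ox) / sp) + 1)
    iy = np.arange(np.ceil((miny - oy) / sp), np.floor((maxy - oy) / sp) + 1)
    if len(ix) == 0 or len(iy) == 0:
        return SectionAreaEstimate(-1, 0, grid.area_per_point)
    gx, gy = np.meshgrid(ix * sp + ox, iy * sp + oy)
    inside = shapely.contains_xy(region, gx.ravel(), gy.ravel())
    return SectionAreaEstimate(-1, int(np.sum(inside)), grid.area_per_point)


def surs_variance(counts: np.ndarray, nugget: float = 0.0) -> float:
    """Gundersen–Jensen m = 1 variance of a systematic sample of counts.

    Var_SURS = (3(C₀ − ν) − 4C₁ + C₂) / 240 with C_q = Σ_i x_i x_{i+q}.
    """
    x = np.asarray(counts, dtype=float)
    if len(x) < 3:
        raise ValueError("SURS variance needs at least 3 systematic samples")
    c0 = float(np.sum(x * x))
    c1 = float(np.sum(x[:-1] * x[1:]))
    c2 = float(np.sum(x[:-2] * x[2:]))
    return max((3.0 * (c0 - nugget) - 4.0 * c1 + c2) / 240.0, 0.0)


def point_count_nugget(point_counts: np.ndarray,
                       shape_ratio: float = CIRCLE_SHAPE_RATIO) -> float:
    """Nugget variance of point counting: 0.0724 · (B̄/√Ā) · √(n · ΣP)."""
    p = np.asarray(point_counts, dtype=float)
    total = float(np.sum(p))
    if total <= 0:
        return 0.0
    return 0.0724 * shape_ratio * np.sqrt(len(p) * total)


def gundersen_ce_volume(point_counts, shape_ratio: float = CIRCLE_SHAPE_RATIO,
                        include_nugget: bool = True) -> float:
    """CE of a Cavalieri point-count estimate from the ordered P_i series."""
    p = np.asarray(point_counts, dtype=float)
    if len(p) < 3:
        raise ValueError("CE undefined for fewer than 3 sampled sections")
    total = float(np.sum(p))
    if total <= 0:
        return 0.0
    nu = point_count_nugget(p, shape_ratio) if include_nugget else 0.0
    var = surs_variance(p, nugget=nu)
    return float(np.sqrt(var + nu) / total)


def cavalieri_volume(area_estimates: list[SectionAreaEstimate], d: float,
                     shape_ratio: float = CIRCLE_SHAPE_RATIO,
                     include_nugget: bool = True) -> VolumeEstimate:
    """V = (Σ A_i) × d from per-section point-count area estimates."""
    if not area_estimates:
        raise ValueError("no section area estimates")
    if d <= 0:
        raise ValueError("section interval d must be positive")
    counts = [e.point_count for e in area_estimates]
    sum_area = float(sum(e.area for e in area_estimates))
    ce = (gundersen_ce_volume(counts, shape_ratio, include_nugget)
          if len(counts) >= 3 else float("nan"))
    return VolumeEstimate(
        sampled_section_indices=[e.section_index for e in area_estimates],
        d=d, sum_area=sum_area, volume=sum_area * d, ce=ce,
        point_counts=counts,
    )


def estimate_stack_volume(stack: SectionStack, grid_spacing: float = 60.0,
                          target_sections: tuple[int, int] = (8, 12),
                          seed: int | np.random.Generator | None = None,
                          include_nugget: bool = True) -> VolumeEstimate:
    """Full Cavalieri pipeline on a virtual section stack.

    Systematically samples sections, lays one random-offset grid over the
    whole stack (sections share the offset, as on a real microscope stage)
    and point-counts each sampled cut face.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    indices, k = sample_sections_systematic(stack.n_sections, target_sections, rng)
    grid = PointGrid.random(grid_spacing, rng)
    estimates = []
    ratios = []
    for i in indices:
        sec = stack.sections[i]
        region = ellipse_polygon(*sec.plane_semi_axes)
        est = point_count_area(region, grid)
        estimates.append(SectionAreaEstimate(i, est.point_count, est.area_per_point))
        if region.area > 0:
            ratios.append(region.length / np.sqrt(region.area))
    shape_ratio = float(np.mean(ratios)) if ratios else CIRCLE_SHAPE_RATIO
    return cavalieri_volume(estimates, d=k * stack.block_advance,
                            shape_ratio=shape_ratio,
                            include_nugget=include_nugget)
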