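"""Optical-disector estimation of cell numbers.

The disector scans a known depth h of each thick section inside unbiased
counting frames placed on a systematic X/Y grid.  A nucleus is counted
(contributes to ΣQ⁻) when its focus event falls inside the z counting
window and its profile lies at least partly inside the frame without
touching the forbidden lines — the left and bottom frame edges together
with their infinite extensions (upward from the top-left corner, downward
from the bottom-right corner).  Every frame applied counts toward ΣP, even
with Q⁻ = 0.

The numerical density is

    Nv = ΣQ⁻ / (ΣP · (a/f) · h) · (t̄ / BA)

where a/f is the frame area (default 3492 µm²), h the disector height, t̄
the mean measured section thickness and BA the block advance; the t̄/BA
factor corrects for axial shrinkage of the processed sections.  The total
number is N = Nv × V.

Guard zones (top/bottom slabs excluded from counting, where lost caps and
knife damage concentrate) are chosen from the Z-axis distribution of focus
events, binned in 10% steps of the measured thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from .sectioning import Section, SectionStack
from .volume import surs_variance

DEFAULT_FRAME_AREA = 3492.0  # µm²

# guard fractions (top, bottom) of measured thickness, per cell class
DEFAULT_GUARDS = {
    "neuron": (0.10, 0.20),
    "satellite_glia": (0.20, 0.10),
}


@dataclass
class DisectorConfig:
    """Sampling geometry of the optical disector."""

    frame_area: float = DEFAULT_FRAME_AREA   # a/f, µm²
    step_x: float = 120.0                    # systematic field spacing, µm
    step_y: float = 120.0                    # tuned for ΣQ⁻ ≈ 400-600/ganglion
    block_advance: float = 25.0
    cell_class: str = "neuron"
    frame_placement: str = "inside"          # "inside": whole frame within tissue
                                             # "cover": grid covers the window bbox

    def __post_init__(self) -> None:
        if self.frame_area <= 0:
            raise ValueError("frame_area must be positive")
        side = self.frame_side
        if self.step_x < side or self.step_y < side:
            raise ValueError("steps must be at least the frame side")
        if self.frame_placement not in ("inside", "cover"):
            raise ValueError("frame_placement must be 'inside' or 'cover'")

    @property
    def frame_side(self) -> float:
        return float(np.sqrt(self.frame_area))


@dataclass
class ZHistogram:
    """Percent of focus events per 10%-of-thickness slab, top (0%) down."""

    percentages: np.ndarray  # (10,) summing to 100

    def __post_init__(self) -> None:
        self.percentages = np.asarray(self.percentages, dtype=float)
        if self.percentages.shape != (10,):
            raise ValueError("Z histogram has exactly 10 bins")
        if np.any(self.percentages < 0):
            raise ValueError("histogram bins must be non-negative")
        if abs(self.percentages.sum() - 100.0) > 0.01:
            raise ValueError("histogram bins must sum to 100%")


@dataclass
class CountingWindow:
    """The z counting window left after removing the guard zones."""

    guard_top_fraction: float
    guard_bottom_fraction: float
    height: float                    # h, µm (= (1 − top − bottom) × t̄)
    included_nucleus_fraction: float  # % of focus events inside the window

    @property
    def lower_fraction(self) -> float:
        return self.guard_top_fraction

    @property
    def upper_fraction(self) -> float:
        return 1.0 - self.guard_bottom_fraction


@dataclass
class DisectorTally:
    """Raw sums of one disector run."""

    sum_q: int                      # ΣQ⁻
    sum_frames: int                 # ΣP
    mean_thickness: float           # t̄, µm
    fields: list[tuple[int, float, float, int, float]]  # (section, x, y, Q⁻, t)
    per_section_q: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.sum_q == sum(f[3] for f in self.fields)
        assert self.sum_frames == len(self.fields)


@dataclass
class NumberEstimate:
    """Numerical density, total number and coefficient of error."""

    nv: float         # cells / µm³
    n_total: float
    ce: float


def zaxis_histogram(focal_depths: np.ndarray) -> ZHistogram:
    """Z-axis distribution of focus events.

    ``focal_depths`` is an (M, 2) array of (z, t) pairs with 0 ≤ z ≤ t;
    bin b (1–10) receives events with z/t in [(b−1)/10, b/10), the deepest
    events falling in bin 10.
    """
    pairs = np.asarray(focal_depths, dtype=float).reshape(-1, 2)
    if len(pairs) == 0:
        raise ValueError("no focus events to histogram")
    z, t = pairs[:, 0], pairs[:, 1]
    if np.any(z < 0) or np.any(z > t):
        raise ValueError("focal depths must satisfy 0 <= z <= t")
    frac = np.clip(z / t, 0.0, 1.0 - 1e-12)
    counts = np.bincount((frac * 10).astype(int), minlength=10)
    return ZHistogram(counts / counts.sum() * 100.0)


def select_counting_window(hist: ZHistogram, guard_top: float,
                           guard_bottom: float, mean_thickness: float) -> CountingWindow:
    """Derive the disector window from guards and the Z histogram.

    h = (1 − top − bottom) × t̄; the included fraction is the histogram mass
    between the guards, interpolating linearly inside boundary bins.
    """
    if guard_top < 0 or guard_bottom < 0 or guard_top + guard_bottom >= 1:
        raise ValueError("guard fractions must be >= 0 and sum to < 1")
    lo, hi = guard_top, 1.0 - guard_bottom
    edges = np.linspace(0.0, 1.0, 11)
    mass = 0.0
    for b in range(10):
        left, right = edges[b], edges[b + 1]
        overlap = max(0.0, min(right, hi) - max(left, lo))
        mass += hist.percentages[b] * overlap / 0.1
    h = (1.0 - guard_top - guard_bottom) * mean_thickness
    if h <= 0 or mass <= 0:
        raise ValueError("empty counting window")
    return CountingWindow(guard_top, guard_bottom, h, mass)


# ---------------------------------------------------------------------------
# unbiased counting frame
# ---------------------------------------------------------------------------

def _dist_to_rect(px, py, fx, fy, side):
    dx = np.maximum(np.maximum(fx - px, px - (fx + side)), 0.0)
    dy = np.maximum(np.maximum(fy - py, py - (fy + side)), 0.0)
    return np.hypot(dx, dy)


def _dist_to_forbidden(px, py, fx, fy, side):
    """Distance to the forbidden line of the frame at (fx, fy).

    Forbidden set: left edge extended upward to +∞ ({x = fx, y ≥ fy}),
    the bottom edge ({y = fy, fx ≤ x ≤ fx + side}), and the right edge
    extended downward to −∞ ({x = fx + side, y ≤ fy}).
    """
    # vertical ray up from bottom-left corner
    d1 = np.where(py >= fy, np.abs(px - fx), np.hypot(px - fx, fy - py))
    # bottom segment
    cx = np.clip(px, fx, fx + side)
    d2 = np.hypot(px - cx, py - fy)
    # vertical ray down from bottom-right corner
    d3 = np.where(py <= fy, np.abs(px - (fx + side)),
                  np.hypot(px - (fx + side), py - fy))
    return np.minimum(np.minimum(d1, d2), d3)


def frame_accepts(px, py, radius, fx, fy, side):
    """Gundersen unbiased-frame rule for circular profiles (vectorised).

    A profile is counted when it overlaps the frame interior and does not
    touch the forbidden line; over a tiling of frames every convex profile
    is counted exactly once.
    """
    overlaps = _dist_to_rect(px, py, fx, fy, side) < radius
    touches = _dist_to_forbidden(px, py, fx, fy, side) <= radius
    return overlaps & ~touches


def _frame_origins(section: Section, cfg: DisectorConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Systematic frame origins for one section (uniform random grid phase)."""
    p, q = section.window_semi_axes
    if p <= 0 or q <= 0:
        return np.empty((0, 2))
    ox = rng.uniform(0.0, cfg.step_x)
    oy = rng.uniform(0.0, cfg.step_y)
    side = cfg.frame_side

    def _axis(o, step, half):
        lo = int(np.floor((-half - side - o) / step))
        hi = int(np.ceil((half - o) / step))
        return o + np.arange(lo, hi + 1) * step

    xs = _axis(ox, cfg.step_x, p)
    ys = _axis(oy, cfg.step_y, q)
    gx, gy = np.meshgrid(xs, ys)
    origins = np.column_stack([gx.ravel(), gy.ravel()])
    if cfg.frame_placement == "cover":
        keep = (
            (origins[:, 0] + side >= -p - side) & (origins[:, 0] <= p + side)
            & (origins[:, 1] + side >= -q - side) & (origins[:, 1] <= q + side)
        )
        return origins[keep]
    # "inside": all four frame corners within the section window ellipse
    corners_ok = np.ones(len(origins), dtype=bool)
    for dx in (0.0, side):
        for dy in (0.0, side):
            cx = origins[:, 0] + dx
            cy = origins[:, 1] + dy
            corners_ok &= (cx / p) ** 2 + (cy / q) ** 2 <= 1.0
    return origins[corners_ok]


def optical_disector_tally(stack: SectionStack, config: DisectorConfig,
                           window: CountingWindow,
                           seed: int | np.random.Generator | None = None,
                           section_indices: list[int] | None = None) -> DisectorTally:
    """Run the optical disector over (a systematic subset of) a stack."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if section_indices is None:
        section_indices = list(range(stack.n_sections))
    side = config.frame_side

    fields: list[tuple[int, float, float, int, float]] = []
    per_section_q: list[int] = []
    for si in section_indices:
        sec = stack.sections[si]
        origins = _frame_origins(sec, config, rng)
        if len(origins) == 0:
            continue
        m = sec.class_mask(config.cell_class)
        # half-open z window in fractions of the measured thickness
        zfrac = sec.z[m] / sec.thickness
        in_z = (zfrac >= window.lower_fraction) & (zfrac < window.upper_fraction)
        px, py = sec.xy[m][in_z, 0], sec.xy[m][in_z, 1]
        pr = sec.radii[m][in_z]

        q_per_frame = np.zeros(len(origins), dtype=int)
        if len(px):
            for fi, (fx, fy) in enumerate(origins):
                acc = frame_accepts(px, py, pr, fx, fy, side)
                q_per_frame[fi] = int(np.sum(acc))
        for fi, (fx, fy) in enumerate(origins):
            fields.append((si, float(fx), float(fy), int(q_per_frame[fi]),
                           sec.thickness))
        per_section_q.append(int(q_per_frame.sum()))

    if not fields:
        raise ValueError("no counting frames could be placed")
    return DisectorTally(
        sum_q=int(sum(f[3] for f in fields)),
        sum_frames=len(fields),
        mean_thickness=float(np.mean([f[4] for f in fields])),
        fields=fields,
        per_section_q=per_section_q,
    )


def estimate_nv(tally: DisectorTally, config: DisectorConfig,
                window: CountingWindow) -> float:
    """Nv = ΣQ⁻ / (ΣP · (a/f) · h) · (t̄ / BA), cells per µm³."""
    if tally.sum_frames <= 0:
        raise ValueError("ΣP must be positive")
    if window.height <= 0:
        raise ValueError("disector height must be positive")
    return (tally.sum_q
            / (tally.sum_frames * config.frame_area * window.height)
            * (tally.mean_thickness / config.block_advance))


def ce_number(tally: DisectorTally) -> float:
    """CE of the number estimate: √(1/ΣQ⁻ + Var_SURS(Q_i)/(ΣQ⁻)²)."""
    if tally.sum_q <= 0:
        raise ValueError("CE undefined for ΣQ⁻ = 0")
    q = np.asarray(tally.per_section_q, dtype=float)
    surs = surs_variance(q) if len(q) >= 3 else 0.0
    return float(np.sqrt(1.0 / tally.sum_q + surs / tally.sum_q ** 2))


def estimate_total_number(nv: float, volume: float,
                          tally: DisectorTally | None = None) -> NumberEstimate:
    """N = Nv × V, with the CE carried over from the tally when given."""
    if nv < 0 or volume < 0:
        raise ValueError("Nv and V must be non-negative")
    ce = ce_number(tally) if tally is not None and tally.sum_q > 0 else float("nan")
    return NumberEstimate(nv=nv, n_total=nv * volume, ce=ce)


def disector_pipeline(stack: SectionStack, volume: float,
                      cell_class: str = "neuron",
                      config: DisectorConfig | None = None,
                      target_sections: tuple[int, int] = (8, 12),
                      seed: int | np.random.Generator | None = None,
                      guards: tuple[float, float] | None = None) -> tuple[NumberEstimate, DisectorTally, CountingWindow]:
    """Histogram → guards → tally → Nv → N on one stack.

    The Z histogram is built from the same systematically sampled sections
    that are then counted, mirroring bench practice.
    """
    from .volume import sample_sections_systematic

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if config is None:
        config = DisectorConfig(cell_class=cell_class,
                                block_advance=stack.block_advance)
    indices, _ = sample_sections_systematic(stack.n_sections, target_sections, rng)
    pairs = stack.focal_depth_pairs(cell_class)
    if len(pairs) == 0:
        raise ValueError(f"stack contains no {cell_class} profiles")
    hist = zaxis_histogram(pairs)
    if guards is None:
        guards = DEFAULT_GUARDS.get(cell_class, (0.10, 0.10))
    t_bar = float(np.mean([stack.sections[i].thickness for i in indices]))
    window = select_counting_window(hist, guards[0], guards[1], t_bar)
    tally = optical_disector_tally(stack, config, window, rng, indices)
    nv = estimate_nv(tally, config, window)
    return estimate_total_number(nv, volume, tally), tally, window
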