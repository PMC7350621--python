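"""Virtual serial sectioning of ganglion phantoms.

The block is advanced a fixed distance BA (default 25 µm) per cut along the
long (x) axis, with the first cut at the rostral pole of the tissue, so a
ganglion of extent L yields ceil(L / BA) sections.  Processing shrinks each
section in the axial direction: the measured thickness t is
``shrinkage_factor × BA`` on average (default 0.92 × 25 ≈ 23 µm) with small
per-section noise, and never exceeds BA.

Each cell generates exactly one "comes into focus" event: the leading (top)
edge of its nucleus sphere entering the focal plane.  The event is assigned
to the section containing that edge, at an axial depth scaled into the
section's measured thickness (z increases downward into the section,
0 ≤ z ≤ t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

from .geometry import Ellipsoid, PointPattern2D, ellipse_polygon
from .phantom import GanglionPhantom


@dataclass
class Section:
    """One virtual section and the focus events it contains."""

    index: int
    x_start: float                 # block coordinate of the section's top face, µm
    thickness: float               # measured thickness t, µm
    plane_semi_axes: tuple[float, float]   # cut-face ellipse at the top face
    window_semi_axes: tuple[float, float]  # widest profile ellipse in the slab
    cell_ids: np.ndarray           # (M,) indices into the phantom arrays
    xy: np.ndarray                 # (M, 2) in-plane coordinates, µm
    z: np.ndarray                  # (M,) focus-event depth within section, µm
    radii: np.ndarray              # (M,) nucleus radius, µm
    cell_class: np.ndarray         # (M,)
    apoptotic: np.ndarray          # (M,) bool

    @property
    def n_profiles(self) -> int:
        return len(self.z)

    @property
    def plane_area(self) -> float:
        p, q = self.plane_semi_axes
        return np.pi * p * q

    def window_polygon(self, n_vertices: int = 256) -> Polygon:
        # circumscribe so every profile inside the true ellipse is inside
        # the polygonal window as well
        scale = 1.0 / np.cos(np.pi / n_vertices)
        p, q = self.window_semi_axes
        return ellipse_polygon(p * scale, q * scale, n_vertices=n_vertices)

    def class_mask(self, cell_class: str | None) -> np.ndarray:
        if cell_class is None:
            return np.ones(self.n_profiles, dtype=bool)
        return self.cell_class == cell_class


@dataclass
class SectionStack:
    """Ordered serial sections of one phantom."""

    block_advance: float
    shrinkage_factor: float
    ellipsoid: Ellipsoid
    sections: list[Section]

    @property
    def n_sections(self) -> int:
        return len(self.sections)

    @property
    def mean_thickness(self) -> float:
        return float(np.mean([s.thickness for s in self.sections]))

    def total_profiles(self, cell_class: str | None = None) -> int:
        return int(sum(np.sum(s.class_mask(cell_class)) for s in self.sections))

    def focal_depth_pairs(self, cell_class: str | None = None) -> np.ndarray:
        """(M, 2) array of (z, t) pairs pooled over sections."""
        rows = []
        for s in self.sections:
            m = s.class_mask(cell_class)
            if np.any(m):
                rows.append(np.column_stack([s.z[m], np.full(m.sum(), s.thickness)]))
        if not rows:
            return np.empty((0, 2))
        return np.vstack(rows)


def section_phantom(phantom: GanglionPhantom, block_advance: float = 25.0,
                    shrinkage_factor: float = 0.92, seed: int | None = 0,
                    thickness_noise_sd: float = 0.01) -> SectionStack:
    """Cut a phantom into serial sections.

    Parameters
    ----------
    block_advance : microtome feed per section, µm (> 0).
    shrinkage_factor : axial shrinkage of processed tissue, in (0, 1];
        measured thickness averages ``shrinkage_factor × block_advance``.
    seed : controls the small per-section thickness noise.
    thickness_noise_sd : relative sd of per-section thickness.
    """
    if block_advance <= 0:
        raise ValueError("block_advance must be positive")
    if not 0 < shrinkage_factor <= 1:
        raise ValueError("shrinkage_factor must be in (0, 1]")

    ell = phantom.ellipsoid
    n_sections = int(np.ceil(ell.extent_x / block_advance))
    rng = np.random.default_rng(seed)

    if phantom.n_cells == 0:
        warnings.warn("sectioning an empty phantom")

    # leading (top) edge of each nucleus along the cutting axis
    lead = phantom.positions[:, 0] - phantom.radii if phantom.n_cells else np.empty(0)
    x0 = -ell.a
    idx = np.floor((lead - x0) / block_advance).astype(int) if phantom.n_cells else np.empty(0, int)
    # cells whose nucleus pokes past the first cut face stay in section 0
    idx = np.clip(idx, 0, n_sections - 1)

    thicknesses = shrinkage_factor * block_advance * (
        1.0 + thickness_noise_sd * rng.standard_normal(n_sections)
    )
    thicknesses = np.clip(thicknesses, 0.5 * block_advance, block_advance)

    sections: list[Section] = []
    r_max = float(np.max(phantom.radii)) if phantom.n_cells else 0.0
    for j in range(n_sections):
        xs = x0 + j * block_advance
        t = float(thicknesses[j])
        m = idx == j
        ids = np.nonzero(m)[0]
        depth_raw = np.clip(lead[m] - xs, 0.0, block_advance * (1 - 1e-12))
        z = depth_raw / block_advance * t
        # widest cut ellipse reachable by any profile in this slab: evaluate
        # at the in-slab x closest to the equator, padded by the nucleus radius
        lo, hi = xs - r_max, xs + block_advance + r_max
        x_widest = min(max(0.0, lo), hi)
        sections.append(Section(
            index=j, x_start=xs, thickness=t,
            plane_semi_axes=ell.profile_semi_axes(xs),
            window_semi_axes=ell.profile_semi_axes(x_widest),
            cell_ids=ids,
            xy=phantom.positions[m][:, 1:3].copy(),
            z=z,
            radii=phantom.radii[m].copy(),
            cell_class=phantom.cell_class[m].copy(),
            apoptotic=phantom.apoptotic[m].copy(),
        ))

    return SectionStack(block_advance=block_advance,
                        shrinkage_factor=shrinkage_factor,
                        ellipsoid=ell, sections=sections)


def extract_section_points(stack: SectionStack, section_index: int,
                           cell_class: str = "neuron") -> PointPattern2D:
    """In-plane coordinates of one class in one section, with its window."""
    if not 0 <= section_index < stack.n_sections:
        raise IndexError(f"section index {section_index} out of range")
    sec = stack.sections[section_index]
    m = sec.class_mask(cell_class)
    return PointPattern2D(points=sec.xy[m], window=sec.window_polygon())
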