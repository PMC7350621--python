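"""Reference 2-D point patterns for calibrating the spatial classifier.

These generators produce the three textbook arrangements in a square
window: a jittered square lattice (regular), a homogeneous Poisson process
(complete spatial randomness) and a Thomas cluster process (clustered).
They are the planar counterparts of the 3-D phantom arrangements and are
used to verify that the Voronoi CV classifier lands in the expected band
for each.
"""

from __future__ import annotations

import numpy as np

from .geometry import PointPattern2D, square_window


def poisson_pattern(n_mean: float, side: float,
                    rng: np.random.Generator) -> PointPattern2D:
    """Homogeneous Poisson (CSR) pattern with expected count ``n_mean``."""
    n = rng.poisson(n_mean)
    pts = rng.uniform(0.0, side, size=(int(n), 2))
    return PointPattern2D(pts, square_window(side))


def jittered_lattice_pattern(n_target: float, side: float,
                             rng: np.random.Generator,
                             jitter_fraction: float = 0.05) -> PointPattern2D:
    """Square lattice with ~n_target points and Gaussian positional jitter.

    The jitter sd is ``jitter_fraction`` of the lattice pitch; points
    jittered outside the window are wrapped back (toroidal correction) so
    the count is preserved.
    """
    pitch = side / np.sqrt(n_target)
    coords = np.arange(pitch / 2.0, side, pitch)
    gx, gy = np.meshgrid(coords, coords)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts = pts + rng.normal(0.0, jitter_fraction * pitch, size=pts.shape)
    pts = np.mod(pts, side)
    return PointPattern2D(pts, square_window(side))


def thomas_pattern(n_parents_mean: float, offspring_mean: float,
                   cluster_sd: float, side: float,
                   rng: np.random.Generator) -> PointPattern2D:
    """Thomas cluster pattern: Poisson parents, Gaussian offspring.

    Offspring falling outside the window are wrapped toroidally, keeping
    the intensity homogeneous in expectation.
    """
    n_parents = max(1, int(rng.poisson(n_parents_mean)))
    parents = rng.uniform(0.0, side, size=(n_parents, 2))
    n_off = rng.poisson(offspring_mean, size=n_parents)
    pts = np.repeat(parents, n_off, axis=0)
    pts = pts + rng.normal(0.0, cluster_sd, size=pts.shape)
    pts = np.mod(pts, side)
    return PointPattern2D(pts, square_window(side))
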