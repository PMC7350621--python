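"""Ground-truthed virtual ganglion phantoms.

A phantom is a 3-D population of cell somata (neurons plus satellite glial
cells) inside an ellipsoidal ganglion.  Because the generator knows the true
volume, the true per-class counts, the true spatial arrangement and the true
apoptosis labels, every downstream estimator can be validated against known
truth — no microscopy required.

Spatial arrangements
--------------------
regular    jittered 3-D cubic lattice (Gaussian jitter, sd = 5% of the
           lattice pitch by default), the idealisation of the evenly spaced
           somata seen in healthy ganglia;
random     homogeneous Poisson process (complete spatial randomness);
clustered  Thomas process — Poisson parents with isotropic Gaussian
           offspring — restricted to the ellipsoid.

Satellite glia are scattered in a thin shell around their neuron, emulating
the capsule of small dark nuclei that ensheathes each ganglionic soma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .config import StudyConfig, GroupEffect
from .geometry import Ellipsoid

NEURON = "neuron"
GLIA = "satellite_glia"


@dataclass(frozen=True)
class CellSoma:
    """A single cell body: centre (µm), nucleus radius (µm), class, label."""

    center: tuple[float, float, float]
    nucleus_radius: float
    cell_class: str
    apoptotic: bool


@dataclass
class GanglionPhantom:
    """Ground-truth cell population of one virtual ganglion.

    Cells are stored as flat arrays for speed; ``cells`` materialises the
    record view when object access is more convenient.
    """

    group: str
    animal_index: int
    ellipsoid: Ellipsoid
    positions: np.ndarray      # (N, 3) µm
    radii: np.ndarray          # (N,) nucleus radius µm
    cell_class: np.ndarray     # (N,) of {"neuron", "satellite_glia"}
    apoptotic: np.ndarray      # (N,) bool
    config: StudyConfig | None = None

    @property
    def n_cells(self) -> int:
        return len(self.radii)

    @property
    def true_volume(self) -> float:
        return self.ellipsoid.volume

    @property
    def true_counts(self) -> dict[str, int]:
        return {
            NEURON: int(np.sum(self.cell_class == NEURON)),
            GLIA: int(np.sum(self.cell_class == GLIA)),
        }

    @property
    def cells(self) -> list[CellSoma]:
        return [
            CellSoma(tuple(self.positions[i]), float(self.radii[i]),
                     str(self.cell_class[i]), bool(self.apoptotic[i]))
            for i in range(self.n_cells)
        ]

    def mask(self, cell_class: str) -> np.ndarray:
        return self.cell_class == cell_class


# ---------------------------------------------------------------------------
# point-process generators restricted to an ellipsoid
# ---------------------------------------------------------------------------

def _uniform_in_ellipsoid(n: int, ell: Ellipsoid, rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. uniform points in the ellipsoid (rejection from the box)."""
    out = np.empty((n, 3))
    got = 0
    while got < n:
        m = max(int((n - got) / 0.5) + 16, 32)  # ball/box fill ≈ 0.52
        cand = rng.uniform(-1.0, 1.0, size=(m, 3))
        keep = cand[np.sum(cand**2, axis=1) <= 1.0]
        take = min(len(keep), n - got)
        out[got:got + take] = keep[:take]
        got += take
    out[:, 0] *= ell.a
    out[:, 1] *= ell.b
    out[:, 2] *= ell.c
    return out


def poisson_positions(mean_count: float, ell: Ellipsoid,
                      rng: np.random.Generator) -> np.ndarray:
    """Homogeneous Poisson process with expected count ``mean_count``."""
    n = rng.poisson(mean_count)
    return _uniform_in_ellipsoid(int(n), ell, rng)


def lattice_positions(target_count: float, ell: Ellipsoid,
                      rng: np.random.Generator,
                      jitter_fraction: float = 0.05) -> np.ndarray:
    """Jittered cubic lattice with ~target_count points inside the ellipsoid.

    The lattice is centred on the origin so that a lattice plane always
    passes through each mid-plane of the ganglion.
    """
    if target_count <= 0:
        return np.empty((0, 3))
    pitch = (ell.volume / target_count) ** (1.0 / 3.0)
    ks = [np.arange(-int(np.ceil(s / pitch)), int(np.ceil(s / pitch)) + 1)
          for s in (ell.a, ell.b, ell.c)]
    gx, gy, gz = np.meshgrid(*ks, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()]).astype(float) * pitch
    pts += rng.normal(0.0, jitter_fraction * pitch, size=pts.shape)
    return pts[ell.contains(pts)]


def thomas_positions(target_count: float, ell: Ellipsoid,
                     rng: np.random.Generator,
                     parents: float = 25.0,
                     offspring_mean: float | None = None,
                     cluster_sd: float = 15.0) -> np.ndarray:
    """Thomas cluster process restricted to the ellipsoid."""
    if target_count <= 0:
        return np.empty((0, 3))
    if offspring_mean is None:
        offspring_mean = target_count / parents
    n_parents = max(1, int(rng.poisson(parents)))
    centres = _uniform_in_ellipsoid(n_parents, ell, rng)
    n_off = rng.poisson(offspring_mean, size=n_parents)
    pts = np.repeat(centres, n_off, axis=0)
    pts = pts + rng.normal(0.0, cluster_sd, size=pts.shape)
    return pts[ell.contains(pts)]


def _glia_positions(neuron_pos: np.ndarray, neuron_r: np.ndarray,
                    mean_per_neuron: float, ell: Ellipsoid,
                    rng: np.random.Generator) -> np.ndarray:
    """Satellite cells scattered in a shell around each neuron soma."""
    if len(neuron_pos) == 0 or mean_per_neuron <= 0:
        return np.empty((0, 3))
    counts = rng.poisson(mean_per_neuron, size=len(neuron_pos))
    centres = np.repeat(neuron_pos, counts, axis=0)
    base_r = np.repeat(neuron_r, counts)
    m = len(centres)
    # random direction on the sphere, shell just outside the perikaryon
    v = rng.normal(size=(m, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    dist = 2.0 * base_r + np.abs(rng.normal(0.0, 2.0, size=m))
    pts = centres + v * dist[:, None]
    return pts[ell.contains(pts)]


# ---------------------------------------------------------------------------
# phantom generation
# ---------------------------------------------------------------------------

def _animal_rng(config: StudyConfig, group: str, animal_index: int) -> np.random.Generator:
    gi = list(config.groups).index(group)
    ss = np.random.SeedSequence(config.seed, spawn_key=(gi, animal_index))
    return np.random.default_rng(ss)


def generate_phantom(config: StudyConfig, group: str,
                     animal_index: int = 0) -> GanglionPhantom:
    """Generate one animal's ground-truth ganglion.

    Deterministic given (config.seed, group, animal_index).  The group's
    effect multipliers scale the expected neuron/glia counts directly and
    the ganglion volume via a cube-root scaling of all three semi-axes;
    realised counts carry Poisson noise, apoptosis labels are i.i.d.
    Bernoulli with the group's probability.
    """
    effect: GroupEffect = config.effect_for(group)
    rng = _animal_rng(config, group, animal_index)

    s = effect.volume ** (1.0 / 3.0)
    a0, b0, c0 = config.ellipsoid_semi_axes
    ell = Ellipsoid(a0 * s, b0 * s, c0 * s)

    n_neuron_mean = config.neuron_count_true * effect.neurons
    if config.neuron_count_true > 0 and n_neuron_mean <= 0:
        raise ValueError("scaled neuron count is non-positive")

    pattern = config.pattern_for(group)
    if n_neuron_mean == 0:
        neuron_pos = np.empty((0, 3))
    elif pattern == "random":
        neuron_pos = poisson_positions(n_neuron_mean, ell, rng)
    elif pattern == "regular":
        neuron_pos = lattice_positions(n_neuron_mean, ell, rng,
                                       config.jitter_fraction)
    elif pattern == "clustered":
        parents, offspring, sd = config.cluster_params
        neuron_pos = thomas_positions(n_neuron_mean, ell, rng,
                                      parents=parents,
                                      offspring_mean=offspring,
                                      cluster_sd=sd)
    else:  # pragma: no cover - config validation rejects this earlier
        raise ValueError(f"unknown pattern {pattern!r}")

    mu, sigma = config.soma_radius_dist
    neuron_r = rng.lognormal(mu, sigma, size=len(neuron_pos))

    glia_mean = config.glia_per_neuron_mean * effect.glia / max(effect.neurons, 1e-12)
    glia_pos = _glia_positions(neuron_pos, neuron_r, glia_mean, ell, rng)
    gmu, gsigma = config.glia_radius_dist
    glia_r = rng.lognormal(gmu, gsigma, size=len(glia_pos))

    positions = np.vstack([neuron_pos, glia_pos]) if len(glia_pos) else neuron_pos
    radii = np.concatenate([neuron_r, glia_r])
    cls = np.array([NEURON] * len(neuron_pos) + [GLIA] * len(glia_pos))
    apoptotic = rng.random(len(radii)) < config.apoptosis_for(group)

    if len(radii) == 0:
        warnings.warn(f"phantom for {group}/{animal_index} has no cells")

    return GanglionPhantom(
        group=group, animal_index=animal_index, ellipsoid=ell,
        positions=positions.reshape(-1, 3), radii=radii, cell_class=cls,
        apoptotic=apoptotic, config=config,
    )
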