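"""Study design configuration for simulated ganglion experiments.

The default design mirrors a six-arm rat experiment: cage control, curcumin,
chronic sleep deprivation (CSD), CSD + curcumin, grid-floor control (tank
stress without sleep loss) and grid floor + curcumin, six animals per arm.
Group effects are expressed as multiplicative scalings of the control truth
(volume, neuron number, satellite-glia number), per-group apoptosis
probabilities, and a per-group spatial arrangement of neuron somata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import yaml

DEFAULT_GROUPS = (
    "control",
    "curcumin",
    "CSD",
    "CSD+curcumin",
    "grid_floor",
    "grid_floor+curcumin",
)


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative group effects relative to the control ground truth."""

    volume: float = 1.0
    neurons: float = 1.0
    glia: float = 1.0

    def __post_init__(self) -> None:
        if min(self.volume, self.neurons, self.glia) <= 0:
            raise ValueError("effect multipliers must be positive")


# Sleep deprivation reduces ganglion volume by ~32%, neuron number by ~13%
# and satellite-glia number by ~26% relative to cage controls; curcumin
# co-treatment largely prevents the losses and on its own produces a small,
# non-significant increase.  Apoptosis probabilities preserve the ordering
# CSD >> CSD+curcumin ≈ control; their magnitudes are simulator parameters.
DEFAULT_EFFECTS: Mapping[str, GroupEffect] = {
    "control": GroupEffect(),
    "curcumin": GroupEffect(1.05, 1.05, 1.02),
    "CSD": GroupEffect(1.0 - 0.3193, 1.0 - 0.1263, 1.0 - 0.2645),
    "CSD+curcumin": GroupEffect(0.95, 0.98, 0.95),
    "grid_floor": GroupEffect(),
    "grid_floor+curcumin": GroupEffect(1.05, 1.05, 1.02),
}

DEFAULT_APOPTOSIS: Mapping[str, float] = {
    "control": 0.02,
    "curcumin": 0.01,
    "CSD": 0.20,
    "CSD+curcumin": 0.08,
    "grid_floor": 0.03,
    "grid_floor+curcumin": 0.015,
}

DEFAULT_PATTERNS: Mapping[str, str] = {
    "control": "regular",
    "curcumin": "regular",
    "CSD": "random",
    "CSD+curcumin": "regular",
    "grid_floor": "regular",
    "grid_floor+curcumin": "regular",
}

VALID_PATTERNS = ("regular", "random", "clustered")


@dataclass
class StudyConfig:
    """Everything the phantom generator needs to emulate one study arm.

    Parameters
    ----------
    groups : group labels; effects/apoptosis/pattern maps must cover them.
    animals_per_group : animals simulated per arm.
    ellipsoid_semi_axes : control-ganglion semi-axes (a, b, c) in µm; the
        long axis a is the sectioning axis.
    neuron_count_true : expected neuron number in the control arm.
    glia_per_neuron_mean : mean satellite cells per neuron (Poisson).
    soma_radius_dist : (log-mean, log-sd) of the neuron nucleus radius, µm.
    pattern / cluster_params : default spatial arrangement and Thomas-process
        parameters (parents per phantom, offspring per parent, cluster sd µm).
    jitter_fraction : lattice jitter sd as a fraction of the lattice pitch.
    apoptosis_prob / effect_multipliers / group_patterns : per-group maps.
    seed : base seed; per-animal streams are spawned from it.
    """

    groups: Sequence[str] = DEFAULT_GROUPS
    animals_per_group: int = 6
    ellipsoid_semi_axes: tuple[float, float, float] = (300.0, 200.0, 150.0)
    neuron_count_true: int = 10_000
    glia_per_neuron_mean: float = 3.0
    soma_radius_dist: tuple[float, float] = (1.61, 0.15)  # exp(1.61) ≈ 5 µm
    glia_radius_dist: tuple[float, float] = (0.69, 0.20)  # exp(0.69) ≈ 2 µm
    pattern: str = "regular"
    cluster_params: tuple[float, float, float] = (25.0, 400.0, 15.0)
    jitter_fraction: float = 0.05
    apoptosis_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_APOPTOSIS)
    )
    effect_multipliers: Mapping[str, GroupEffect] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    group_patterns: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PATTERNS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.animals_per_group < 0:
            raise ValueError("animals_per_group must be >= 0")
        if self.neuron_count_true < 0:
            raise ValueError("neuron_count_true must be >= 0")
        if self.glia_per_neuron_mean < 0:
            raise ValueError("glia_per_neuron_mean must be >= 0")
        if min(self.ellipsoid_semi_axes) <= 0:
            raise ValueError("ellipsoid semi-axes must be positive")
        if self.pattern not in VALID_PATTERNS:
            raise ValueError(f"pattern must be one of {VALID_PATTERNS}")
        for g in self.groups:
            p = self.apoptosis_prob.get(g, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"apoptosis_prob[{g}] outside [0, 1]")
            pat = self.group_patterns.get(g, self.pattern)
            if pat not in VALID_PATTERNS:
                raise ValueError(f"pattern for group {g} must be one of {VALID_PATTERNS}")

    def effect_for(self, group: str) -> GroupEffect:
        if group not in self.groups:
            raise KeyError(f"unknown group label: {group!r}")
        return self.effect_multipliers.get(group, GroupEffect())

    def pattern_for(self, group: str) -> str:
        if group not in self.groups:
            raise KeyError(f"unknown group label: {group!r}")
        return self.group_patterns.get(group, self.pattern)

    def apoptosis_for(self, group: str) -> float:
        if group not in self.groups:
            raise KeyError(f"unknown group label: {group!r}")
        return float(self.apoptosis_prob.get(group, 0.0))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = list(self.groups)
        d["effect_multipliers"] = {
            g: asdict(e) for g, e in self.effect_multipliers.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        if "effect_multipliers" in d:
            d["effect_multipliers"] = {
                g: GroupEffect(**e) if not isinstance(e, GroupEffect) else e
                for g, e in d["effect_multipliers"].items()
            }
        for key in ("ellipsoid_semi_axes", "soma_radius_dist", "glia_radius_dist",
                    "cluster_params"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
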