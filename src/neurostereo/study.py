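"""End-to-end simulated-study driver.

Generates every animal of every group, runs the Cavalieri volume estimator,
the optical disector for neurons and satellite glia, the TUNEL-style
apoptotic index and the Voronoi spatial classifier, then assembles
per-animal and per-group tables and the group comparisons.

Seed policy: each animal's random streams are spawned from the master seed
via ``numpy.random.SeedSequence(master_seed, spawn_key=(group_index,
animal_index, stage))``, so changing one animal's stream leaves every other
animal untouched and the whole report is reproducible bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import StudyConfig
from .phantom import GanglionPhantom, generate_phantom, NEURON, GLIA
from .sectioning import SectionStack, extract_section_points, section_phantom
from .number import disector_pipeline
from .stats import (ComparisonResult, FieldCount, apoptotic_index,
                    compare_groups, levene_variance_test)
from .volume import estimate_stack_volume
from .voronoi import summarize_pattern

TUNEL_N_FIELDS = 10
TUNEL_FIELD_SIDE = 100.0  # µm


@dataclass
class StudyReport:
    """Per-animal estimates, per-group summaries and statistical comparisons."""

    per_animal: pd.DataFrame
    group_summary: pd.DataFrame
    comparisons: dict[str, ComparisonResult]
    config: StudyConfig
    master_seed: int

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_animal.to_csv(out / "per_animal.csv", index=False)
        self.group_summary.to_csv(out / "group_summary.csv", index=False)
        stats_rows = []
        for name, c in self.comparisons.items():
            stats_rows.append({
                "endpoint": name, "design": c.design, "test": c.test_used,
                "statistic": c.statistic, "p_value": c.p_value,
                "significant": c.significant, "levene_p": c.levene_p,
            })
            if c.posthoc is not None:
                c.posthoc.to_csv(out / f"posthoc_{name}.csv", index=False)
        pd.DataFrame(stats_rows).to_csv(out / "comparisons.csv", index=False)
        manifest = {
            "master_seed": self.master_seed,
            "config": self.config.to_dict(),
            "n_animals": int(len(self.per_animal)),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _stage_rng(master_seed: int, gi: int, ai: int, stage: int) -> np.random.Generator:
    ss = np.random.SeedSequence(master_seed, spawn_key=(gi, ai, stage))
    return np.random.default_rng(ss)


def _tunel_fields(stack: SectionStack, rng: np.random.Generator,
                  n_fields: int = TUNEL_N_FIELDS,
                  field_side: float = TUNEL_FIELD_SIDE) -> list[FieldCount]:
    """Count apoptotic vs total neurons in randomly placed square fields."""
    candidates = [s for s in stack.sections if np.any(s.class_mask(NEURON))]
    fields: list[FieldCount] = []
    attempts = 0
    while len(fields) < n_fields and attempts < 50 * n_fields:
        attempts += 1
        sec = candidates[int(rng.integers(len(candidates)))]
        m = sec.class_mask(NEURON)
        xy, apo = sec.xy[m], sec.apoptotic[m]
        p, q = sec.window_semi_axes
        cx = rng.uniform(-p, p - field_side) if p > field_side else -p
        cy = rng.uniform(-q, q - field_side) if q > field_side else -q
        inside = ((xy[:, 0] >= cx) & (xy[:, 0] < cx + field_side)
                  & (xy[:, 1] >= cy) & (xy[:, 1] < cy + field_side))
        total = int(inside.sum())
        if total == 0:
            continue
        fields.append(FieldCount(len(fields), int(apo[inside].sum()), total))
    if not fields:
        raise ValueError("could not place any TUNEL field with cells")
    return fields


def simulate_animal(config: StudyConfig, group: str, animal_index: int,
                    master_seed: int) -> dict:
    """Full estimator pipeline for one animal; returns a report row."""
    gi = list(config.groups).index(group)
    base = dict(group=group, animal=animal_index)

    phantom: GanglionPhantom = generate_phantom(config, group, animal_index)
    stack = section_phantom(
        phantom,
        seed=_stage_rng(master_seed, gi, animal_index, 0),
    )

    vol = estimate_stack_volume(stack, seed=_stage_rng(master_seed, gi, animal_index, 1))

    est_n, tally_n, _ = disector_pipeline(
        stack, vol.volume, cell_class=NEURON,
        seed=_stage_rng(master_seed, gi, animal_index, 2))
    est_g, tally_g, _ = disector_pipeline(
        stack, vol.volume, cell_class=GLIA,
        seed=_stage_rng(master_seed, gi, animal_index, 3))

    tunel = apoptotic_index(
        _tunel_fields(stack, _stage_rng(master_seed, gi, animal_index, 4)))

    # central section carries the densest, most representative neuron map
    central = max(range(stack.n_sections),
                  key=lambda i: np.sum(stack.sections[i].class_mask(NEURON)))
    pattern = extract_section_points(stack, central, NEURON)
    vor = summarize_pattern(pattern)

    base.update(
        volume_um3=vol.volume, ce_volume=vol.ce,
        n_neuron=est_n.n_total, ce_neuron=est_n.ce,
        n_glia=est_g.n_total, ce_glia=est_g.ce,
        sum_q_neuron=tally_n.sum_q, sum_q_glia=tally_g.sum_q,
        apoptotic_index=tunel.animal_index,
        voronoi_cv=vor.cv, voronoi_class=vor.classification,
        mean_polygon_area=vor.mean_area,
        true_volume=phantom.true_volume,
        true_n_neuron=phantom.true_counts[NEURON],
        true_n_glia=phantom.true_counts[GLIA],
    )
    return base


ENDPOINT_DESIGNS = {
    "volume_um3": "pairwise",
    "n_neuron": "pairwise",
    "n_glia": "pairwise",
    "apoptotic_index": "one_way",
    "mean_polygon_area": "one_way",
}


def run_study(config: StudyConfig, master_seed: int = 0,
              outdir: str | Path | None = None) -> StudyReport:
    """Simulate the whole multi-group experiment and compare the groups."""
    rows = []
    for group in config.groups:
        for ai in range(config.animals_per_group):
            rows.append(simulate_animal(config, group, ai, master_seed))
    per_animal = pd.DataFrame(rows)

    numeric = [c for c in per_animal.columns
               if c not in ("group", "animal", "voronoi_class")]
    gb = per_animal.groupby("group", sort=False)[numeric]
    summary = gb.mean().add_suffix("_mean")
    sem = gb.sem().add_suffix("_sem")
    group_summary = pd.concat([summary, sem], axis=1).reset_index()

    comparisons: dict[str, ComparisonResult] = {}
    for endpoint, design in ENDPOINT_DESIGNS.items():
        values = {g: d[endpoint].to_numpy()
                  for g, d in per_animal.groupby("group", sort=False)}
        comparisons[endpoint] = compare_groups(values, design=design,
                                               endpoint=endpoint)
    # variance structure of the spatial endpoint
    cv_values = {g: d["voronoi_cv"].to_numpy()
                 for g, d in per_animal.groupby("group", sort=False)}
    comparisons["voronoi_cv_levene"] = levene_variance_test(
        cv_values, endpoint="voronoi_cv")

    report = StudyReport(per_animal, group_summary, comparisons, config,
                         master_seed)
    if outdir is not None:
        report.write(outdir)
    return report
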