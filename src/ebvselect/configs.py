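"""YAML config loaders for trait declarations, index specs and simulations."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .phenotypes import TraitDefinition
from .selection import IndexEntry, IndexSpec, MatingConstraints
from .simulate import SimulationConfig, TraitSpec


def load_trait_definitions(path) -> list[TraitDefinition]:
    """Trait declarations: list of {name, scale, fixed_effects, polarity}."""
    data = yaml.safe_load(Path(path).read_text())
    out = []
    for item in data.get("traits", data if isinstance(data, list) else []):
        out.append(TraitDefinition(
            name=item["name"],
            scale=item.get("scale", "continuous"),
            fixed_effects=tuple(item.get("fixed_effects", ())),
            polarity=item.get("polarity", "high_is_desirable"),
        ))
    return out


def load_index_spec(path) -> IndexSpec:
    """Index spec: {era, entries: [{trait, relative_weight, genetic_sd}]}."""
    data = yaml.safe_load(Path(path).read_text())
    entries = tuple(
        IndexEntry(trait=e["trait"],
                   relative_weight=float(e["relative_weight"]),
                   genetic_sd=float(e.get("genetic_sd", 1.0)))
        for e in data["entries"]
    )
    return IndexSpec(era=str(data.get("era", "unnamed")), entries=entries)


def load_sim_config(path) -> SimulationConfig:
    """Simulation config in YAML; keys mirror SimulationConfig fields."""
    data = yaml.safe_load(Path(path).read_text())
    traits = tuple(
        TraitSpec(t["name"], t.get("scale", "continuous"),
                  float(t.get("h2", 0.5)), float(t.get("incidence", 0.5)))
        for t in data.get("traits", [])
    ) or SimulationConfig.__dataclass_fields__["traits"].default
    caps_data = data.get("caps", {})
    caps = MatingConstraints(
        max_litters_per_sire=int(caps_data.get("max_litters_per_sire", 8)),
        max_litters_per_dam=int(caps_data.get("max_litters_per_dam", 4)),
        forbid_repeat_pairs=bool(caps_data.get("forbid_repeat_pairs", True)),
        max_predicted_f=caps_data.get("max_predicted_f"),
    )
    corr = data.get("genetic_correlations")
    kwargs = {
        k: data[k]
        for k in ("n_founder_males", "n_founder_females", "litters_per_year",
                  "litter_size_mean", "generations", "selection",
                  "n_breeding_males", "n_breeding_females", "index_weights",
                  "year_effects", "sex_effects")
        if k in data
    }
    return SimulationConfig(
        seed=int(data["seed"]), traits=traits, caps=caps,
        genetic_correlations=np.asarray(corr, dtype=float) if corr is not None else None,
        **kwargs,
    )
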