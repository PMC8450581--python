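"""Published reference values from a long-running guide-dog breeding program.

A large North American guide-dog colony has reported heritability
estimates for its health and behavior traits together with the relative
weights those traits received in its overall selection index as the index
was revised over the years. These values are shipped as fixtures: they
exercise the heritability screen (every reported trait clears the 15%
candidacy threshold) and provide realistic index weights for examples and
tests. Genetic standard deviations were not published, so index
construction from these weights requires user-supplied SDs (tests use 1).
"""

from __future__ import annotations

from .selection import IndexEntry, IndexSpec

#: heritability estimates on the percentage scale
HERITABILITY_PCT: dict[str, int] = {
    "success": 46,
    "health": 44,
    "elbow_quality": 63,
    "epilepsy": 62,
    "soft_trachea": 61,
    "tricuspid_valve_dysplasia": 56,
    "hip_quality": 52,
    "skin": 39,
    "mast_cell_cancer": 28,
    "activated_by_stress": 56,
    "noise_sensitivity": 54,
    "thunderstorm_phobia": 50,
    "inhibited_by_stress": 48,
    "harness_sensitivity": 47,
    "body_awareness": 36,
    "self_modulation": 34,
    "object_fear": 32,
}

#: relative index weights (percent) by era; each era sums to 100
INDEX_RELATIVE_WEIGHTS_PCT: dict[int, dict[str, int]] = {
    2010: {"success": 20, "elbow_quality": 14, "epilepsy": 15,
           "hip_quality": 14, "skin": 18, "mast_cell_cancer": 19},
    2014: {"success": 23, "epilepsy": 12, "skin": 21, "mast_cell_cancer": 11,
           "thunderstorm_phobia": 15, "harness_sensitivity": 18},
    2016: {"success": 35, "epilepsy": 8, "skin": 21, "mast_cell_cancer": 14,
           "harness_sensitivity": 10, "body_awareness": 12},
    2019: {"success": 8, "hip_quality": 8, "skin": 25, "mast_cell_cancer": 12,
           "noise_sensitivity": 7, "harness_sensitivity": 7,
           "body_awareness": 19, "self_modulation": 7, "object_fear": 7},
}


def index_spec(era: int, genetic_sd: dict[str, float] | None = None) -> IndexSpec:
    """Build an :class:`IndexSpec` for one published index era.

    ``genetic_sd`` maps trait → genetic standard deviation (defaults to 1
    for every trait, i.e. weights interpreted on the genetic-SD scale).
    """
    weights = INDEX_RELATIVE_WEIGHTS_PCT[era]
    genetic_sd = genetic_sd or {}
    entries = tuple(
        IndexEntry(trait=t, relative_weight=w / 100.0,
                   genetic_sd=genetic_sd.get(t, 1.0))
        for t, w in weights.items()
    )
    return IndexSpec(era=str(era), entries=entries)
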