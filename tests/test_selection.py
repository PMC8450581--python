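"""Selection index, genetic trend, candidate screening and mate allocation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

import ebvselect as ev
from ebvselect.reference_program import INDEX_RELATIVE_WEIGHTS_PCT, index_spec
from ebvselect.selection import SelectionError


def _spec(entries, era="test"):
    return ev.IndexSpec(era=era, entries=tuple(
        ev.IndexEntry(t, w, sd) for t, w, sd in entries))


# -- index construction -------------------------------------------------------

def test_standardized_weight_arithmetic():
    spec = ev.standardize_weights(_spec([("hip_quality", 0.08, 1.0),
                                         ("skin", 0.25, 0.5)]))
    assert spec.entries[0].standardized_weight == pytest.approx(0.08)
    assert spec.entries[1].standardized_weight == pytest.approx(0.5)


def test_nonpositive_sd_or_weight_rejected():
    with pytest.raises(SelectionError, match="genetic SD"):
        ev.standardize_weights(_spec([("t", 0.5, 0.0)]))
    with pytest.raises(SelectionError, match="must be positive"):
        ev.standardize_weights(_spec([("t", -0.5, 1.0)]))


def test_weights_not_summing_to_one_warns():
    with pytest.warns(UserWarning, match="sum to 0.500"):
        _spec([("t", 0.5, 1.0)])


def test_reference_program_era_weights_sum_to_100():
    for era, weights in INDEX_RELATIVE_WEIGHTS_PCT.items():
        assert sum(weights.values()) == 100, era
    spec = ev.standardize_weights(index_spec(2019))
    assert spec.entries[0].standardized_weight == pytest.approx(0.08)


def test_index_contribution_invariant_to_trait_units():
    """Rescaling a trait's units (EBVs x10, genetic SD x10) leaves every
    dog's index unchanged."""
    ebvs = pd.DataFrame({"dog_id": ["A", "A", "B", "B"],
                         "trait": ["t1", "t2", "t1", "t2"],
                         "ebv": [1.0, -2.0, 0.3, 0.7]})
    s1 = ev.score_index(ebvs, _spec([("t1", 0.5, 1.0), ("t2", 0.5, 2.0)]))
    scaled = ebvs.copy()
    scaled.loc[scaled["trait"] == "t1", "ebv"] *= 10.0
    s2 = ev.score_index(scaled, _spec([("t1", 0.5, 10.0), ("t2", 0.5, 2.0)]))
    for dog in ("A", "B"):
        assert abs(s1[dog] - s2[dog]) < 1e-12


def test_score_index_zeros_and_symmetry():
    ebvs = pd.DataFrame({"dog_id": ["A", "A"], "trait": ["t1", "t2"],
                         "ebv": [1.0, -1.0]})
    spec = _spec([("t1", 0.5, 1.0), ("t2", 0.5, 1.0)])
    assert ev.score_index(ebvs, spec)["A"] == pytest.approx(0.0)
    zero = ebvs.assign(ebv=0.0)
    assert ev.score_index(zero, spec)["A"] == 0.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.floats(-5, 5, allow_nan=False))
def test_index_is_linear_in_ebvs(alpha):
    ebvs = pd.DataFrame({"dog_id": ["A", "A", "B", "B"],
                         "trait": ["t1", "t2", "t1", "t2"],
                         "ebv": [1.0, 0.5, -0.2, 2.0]})
    spec = _spec([("t1", 0.6, 1.0), ("t2", 0.4, 0.5)])
    base = ev.score_index(ebvs, spec)
    scaled = ev.score_index(ebvs.assign(ebv=alpha * ebvs["ebv"]), spec)
    for dog in base:
        assert scaled[dog] == pytest.approx(alpha * base[dog], abs=1e-9)


def test_missing_ebv_policies():
    ebvs = pd.DataFrame({"dog_id": ["A", "A", "B"],
                         "trait": ["t1", "t2", "t1"],
                         "ebv": [1.0, 1.0, 1.0]})
    spec = _spec([("t1", 0.5, 1.0), ("t2", 0.5, 1.0)])
    with pytest.warns(UserWarning, match="excluding 1 dog"):
        scores = ev.score_index(ebvs, spec)
    assert set(scores) == {"A"}
    scores = ev.score_index(ebvs, spec, missing="zero")
    assert scores["B"] == pytest.approx(0.5)


def test_index_ranks_dogs_like_true_weighted_merit():
    """EBV-based index ranking tracks the true weighted breeding value
    (rank correlation > 0.4 at h2 ~ 0.5, n ~ 500)."""
    cfg = ev.SimulationConfig(
        seed=17, generations=3, litters_per_year=24,
        traits=(ev.TraitSpec("t1", "continuous", 0.5),
                ev.TraitSpec("t2", "continuous", 0.5)),
        selection="random",
    )
    colony = ev.run_program(cfg)
    ped = colony.pedigree
    ainv = ev.a_inverse(ped, ev.inbreeding(ped))
    frames = []
    from ebvselect.simulate import colony_design
    for trait in ("t1", "t2"):
        d = colony_design(colony, trait)
        res = ev.blup_linear(d, ainv, ev.VarianceComponents(0.5, 0.5))
        frames.append(pd.DataFrame({"dog_id": ped.ids, "trait": trait,
                                    "ebv": res.ebv}))
    spec = _spec([("t1", 0.5, np.sqrt(0.5)), ("t2", 0.5, np.sqrt(0.5))])
    scores = ev.score_index(pd.concat(frames), spec)
    w = 0.5 / np.sqrt(0.5)
    truth = colony.true_bv.pivot(index="dog_id", columns="trait",
                                 values="true_bv").mul(w).sum(axis=1)
    dogs = list(scores)
    rho = spearmanr([scores[d] for d in dogs], truth.loc[dogs]).statistic
    assert len(dogs) > 450
    assert rho > 0.4


# -- genetic trend ------------------------------------------------------------

def test_trend_single_cohort():
    out = ev.genetic_trend({"A": 1.0, "B": 3.0}, {"A": 0, "B": 0})
    assert out.loc[0, "mean"] == 2.0
    assert out.loc[0, "n"] == 2


def test_truncation_selection_produces_rising_trend():
    cfg = ev.SimulationConfig(
        seed=23, generations=8, litters_per_year=12,
        n_founder_males=12, n_founder_females=24,
        n_breeding_males=6, n_breeding_females=12,
        traits=(ev.TraitSpec("t", "continuous", 0.5),), selection="index",
    )
    colony = ev.run_program(cfg)
    merged = colony.true_bv.merge(colony.dogs[["dog_id", "generation"]])
    values = dict(zip(merged["dog_id"], merged["true_bv"]))
    cohorts = dict(zip(merged["dog_id"], merged["generation"]))
    breeders = {d for ids in colony.breeders.values() for d in ids}
    trend = ev.genetic_trend(values, cohorts, breeders)
    assert (trend["mean"].diff().dropna() > 0).all()   # strictly increasing
    # selected breeders sit above their cohort mean wherever they exist
    has = trend["n_breeders"] > 0
    assert (trend.loc[has, "mean_breeders"] >= trend.loc[has, "mean"]).all()


# -- candidate selection ------------------------------------------------------

def _sexed_pedigree(n_female=20, n_male=5, flags=None):
    recs = []
    for i in range(n_female):
        recs.append(ev.IndividualRecord(
            f"F{i:02d}", sex=ev.FEMALE,
            status_flags=frozenset(flags.get(f"F{i:02d}", ()) if flags else ())))
    for i in range(n_male):
        recs.append(ev.IndividualRecord(
            f"M{i:02d}", sex=ev.MALE,
            status_flags=frozenset(flags.get(f"M{i:02d}", ()) if flags else ())))
    return ev.Pedigree(recs)


def test_top_nine_females_after_screening():
    flags = {"F00": {"cryptorchidism"}, "F01": {"excluded-weight"}}
    ped = _sexed_pedigree(flags=flags)
    index = {f"F{i:02d}": 20.0 - i for i in range(20)}
    index.update({f"M{i:02d}": float(i) for i in range(5)})
    sel = ev.select_candidates(index, ped, n_female=9, n_male=3,
                               screen_flags={"cryptorchidism", "excluded-weight"})
    females = [c.id for c in sel if c.sex == ev.FEMALE]
    assert len(females) == 9
    assert "F00" not in females and "F01" not in females
    floor = min(index[f] for f in females)
    excluded = [index[f"F{i:02d}"] for i in range(2, 20)
                if f"F{i:02d}" not in females]
    assert all(floor >= v for v in excluded)


def test_all_flagged_returns_empty_with_warning():
    ped = _sexed_pedigree(n_female=3, n_male=0,
                          flags={f"F{i:02d}": {"bad"} for i in range(3)})
    with pytest.warns(UserWarning, match="only 0 eligible"):
        sel = ev.select_candidates({f"F{i:02d}": 1.0 for i in range(3)},
                                   ped, n_female=2, n_male=0,
                                   screen_flags={"bad"})
    assert sel == []


def test_tie_break_prefers_less_related_candidate():
    """Two females with equal index: the full sib of an active breeder
    loses to the unrelated one."""
    recs = [
        ev.IndividualRecord("S", sex=ev.MALE),
        ev.IndividualRecord("D", sex=ev.FEMALE),
        ev.IndividualRecord("BREEDER", "S", "D", ev.MALE),
        ev.IndividualRecord("SIB", "S", "D", ev.FEMALE),
        ev.IndividualRecord("OUTSIDER", sex=ev.FEMALE),
    ]
    ped = ev.Pedigree(recs)
    index = {"SIB": 1.0, "OUTSIDER": 1.0}
    sel = ev.select_candidates(index, ped, n_female=1, n_male=0,
                               current_breeders=["BREEDER"])
    assert [c.id for c in sel] == ["OUTSIDER"]


# -- mate allocation ----------------------------------------------------------

def _candidates(n_dams, n_sires, ped=None):
    cands = [ev.Candidate(f"DAM{i}", ev.FEMALE, float(n_dams - i))
             for i in range(n_dams)]
    cands += [ev.Candidate(f"SIRE{i}", ev.MALE, 1.0) for i in range(n_sires)]
    return cands


def _founder_ped(ids_sex):
    return ev.Pedigree([
        ev.IndividualRecord(i, sex=s, status_flags=frozenset(fl))
        for i, s, fl in ids_sex
    ])


def test_minimal_predicted_f_sire_wins():
    recs = [
        ev.IndividualRecord("GS", sex=ev.MALE),
        ev.IndividualRecord("GD", sex=ev.FEMALE),
        ev.IndividualRecord("DAM0", "GS", "GD", ev.FEMALE),
        ev.IndividualRecord("SIRE_KIN", "GS", "GD", ev.MALE),   # full sib: F=0.25
        ev.IndividualRecord("SIRE_FAR", sex=ev.MALE),            # unrelated: F=0
    ]
    ped = ev.Pedigree(recs)
    cands = [ev.Candidate("DAM0", ev.FEMALE, 1.0),
             ev.Candidate("SIRE_KIN", ev.MALE, 1.0),
             ev.Candidate("SIRE_FAR", ev.MALE, 1.0)]
    plan = ev.propose_matings(cands, ped, None)
    assert plan.pairs[0].sire == "SIRE_FAR"
    assert plan.pairs[0].predicted_f == 0.0


def test_carrier_pair_rejected_with_reason():
    ped = _founder_ped([("DAM0", ev.FEMALE, {"carrier:prcd"}),
                        ("SIRE0", ev.MALE, {"carrier:prcd"})])
    cands = [ev.Candidate("DAM0", ev.FEMALE, 1.0),
             ev.Candidate("SIRE0", ev.MALE, 1.0)]
    plan = ev.propose_matings(cands, ped, None)
    assert plan.pairs == []
    assert plan.unpaired == [("DAM0", "carrier×carrier")]


def test_one_carrier_is_allowed_but_affected_never():
    ped = _founder_ped([("DAM0", ev.FEMALE, {"carrier:prcd"}),
                        ("SIRE0", ev.MALE, set()),
                        ("DAM1", ev.FEMALE, {"affected:prcd"})])
    cands = [ev.Candidate("DAM0", ev.FEMALE, 2.0),
             ev.Candidate("DAM1", ev.FEMALE, 1.0),
             ev.Candidate("SIRE0", ev.MALE, 1.0)]
    plan = ev.propose_matings(cands, ped, None)
    assert [(p.sire, p.dam) for p in plan.pairs] == [("SIRE0", "DAM0")]
    assert ("DAM1", "affected") in plan.unpaired


def test_sire_cap_limits_pairs():
    ped = _founder_ped([(f"DAM{i}", ev.FEMALE, set()) for i in range(10)]
                       + [("SIRE0", ev.MALE, set())])
    plan = ev.propose_matings(_candidates(10, 1), ped, None)
    assert len(plan.pairs) == 8                      # default sire cap
    assert sorted(plan.unpaired) == [("DAM8", "sire cap"), ("DAM9", "sire cap")]
    assert plan.validate(ev.MatingConstraints())


def test_equal_usage_among_always_feasible_sires():
    ped = _founder_ped([(f"DAM{i}", ev.FEMALE, set()) for i in range(6)]
                       + [(f"SIRE{i}", ev.MALE, set()) for i in range(3)])
    constraints = ev.MatingConstraints(max_litters_per_sire=100,
                                       max_litters_per_dam=100,
                                       forbid_repeat_pairs=False)
    plan = ev.propose_matings(_candidates(6, 3), ped, None,
                              constraints=constraints, n_litters=13)
    use = [plan.usage[f"SIRE{i}"] for i in range(3)]
    assert sum(use) == 13
    assert max(use) - min(use) <= 1


def test_repeat_pairs_respect_history():
    ped = _founder_ped([("DAM0", ev.FEMALE, set()), ("SIRE0", ev.MALE, set()),
                        ("SIRE1", ev.MALE, set())])
    cands = [ev.Candidate("DAM0", ev.FEMALE, 1.0),
             ev.Candidate("SIRE0", ev.MALE, 1.0),
             ev.Candidate("SIRE1", ev.MALE, 1.0)]
    plan = ev.propose_matings(cands, ped, None, history=[("SIRE0", "DAM0")])
    assert plan.pairs[0].sire == "SIRE1"
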