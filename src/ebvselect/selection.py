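"""Selection indexes, candidate screening and constrained mate allocation.

The overall selection index is a weighted sum of per-trait EBVs. Each
trait enters with a *relative* weight (its programmatic importance, e.g.
the share of rejections it causes) divided by the trait's genetic
standard deviation, so a trait's contribution is invariant to its
measurement units:

    standardized_weight_i = relative_weight_i / genetic_sd_i
    index(dog)            = sum_i standardized_weight_i * EBV_i(dog)

Candidate selection takes the top-index dogs per sex after removing dogs
with disqualifying screening flags, preferring the dog less related to
the current breeder pool among ties. Mate allocation is a greedy pass
over dams in index order: each dam is paired with the feasible sire of
minimal predicted litter inbreeding, breaking ties by least lifetime
usage so stud dogs are used as equally as possible.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Callable, Collection, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import FEMALE, MALE, InbreedingTable, Pedigree, kinship


class SelectionError(ValueError):
    """Invalid index specification or selection input."""


# -- selection index ----------------------------------------------------------

@dataclass(frozen=True)
class IndexEntry:
    trait: str
    relative_weight: float
    genetic_sd: float
    standardized_weight: float | None = None


@dataclass(frozen=True)
class IndexSpec:
    """A dated selection-index definition."""

    era: str
    entries: tuple[IndexEntry, ...]

    def __post_init__(self):
        object.__setattr__(self, "entries", tuple(self.entries))
        total = sum(e.relative_weight for e in self.entries)
        if self.entries and abs(total - 1.0) > 1e-6:
            warnings.warn(
                f"relative weights of index {self.era!r} sum to {total:.3f}, not 1",
                stacklevel=3,
            )

    @property
    def traits(self) -> tuple[str, ...]:
        return tuple(e.trait for e in self.entries)


def standardize_weights(spec: IndexSpec) -> IndexSpec:
    """Fill in standardized weights (relative weight / genetic SD)."""
    entries = []
    for e in spec.entries:
        if e.relative_weight <= 0:
            raise SelectionError(f"relative weight for {e.trait!r} must be positive")
        if e.genetic_sd <= 0:
            raise SelectionError(f"genetic SD for {e.trait!r} must be positive")
        entries.append(replace(e, standardized_weight=e.relative_weight / e.genetic_sd))
    return IndexSpec(era=spec.era, entries=tuple(entries))


def score_index(
    ebvs: pd.DataFrame,
    spec: IndexSpec,
    missing: str = "exclude",
) -> dict[str, float]:
    """Per-dog index value from an EBV table (columns dog_id, trait, ebv).

    A dog missing the EBV for any index trait is excluded with a warning
    (default) or has that term zero-imputed (``missing='zero'``).
    """
    spec = standardize_weights(spec)
    wide = ebvs.pivot_table(index="dog_id", columns="trait", values="ebv",
                            aggfunc="first")
    needed = [e.trait for e in spec.entries]
    absent = [t for t in needed if t not in wide.columns]
    if absent:
        if missing == "exclude":
            raise SelectionError(f"no EBVs at all for index traits {absent}")
        for t in absent:
            wide[t] = np.nan
    sub = wide[needed]
    incomplete = sub.isna().any(axis=1)
    if missing == "exclude":
        if incomplete.any():
            warnings.warn(
                f"excluding {int(incomplete.sum())} dog(s) missing index-trait EBVs",
                stacklevel=2,
            )
        sub = sub.loc[~incomplete]
    elif missing == "zero":
        sub = sub.fillna(0.0)
    else:
        raise SelectionError(f"unknown missing policy {missing!r}")
    w = np.array([e.standardized_weight for e in spec.entries])
    scores = sub.to_numpy() @ w
    return {dog: float(s) for dog, s in zip(sub.index, scores)}


# -- genetic trend ------------------------------------------------------------

def genetic_trend(
    values: Mapping[str, float],
    cohorts: Mapping[str, int],
    breeders: Collection[str] | None = None,
) -> pd.DataFrame:
    """Mean and median merit per birth cohort, overall and breeders-only."""
    df = pd.DataFrame(
        {"value": pd.Series(values), "cohort": pd.Series(cohorts)}
    ).dropna()
    breeders = set(breeders or ())
    rows = []
    for cohort, grp in df.groupby("cohort"):
        sel = grp.loc[grp.index.isin(breeders), "value"]
        rows.append({
            "cohort": cohort,
            "n": len(grp),
            "mean": grp["value"].mean(),
            "median": grp["value"].median(),
            "n_breeders": len(sel),
            "mean_breeders": sel.mean() if len(sel) else np.nan,
            "median_breeders": sel.median() if len(sel) else np.nan,
        })
    return pd.DataFrame(rows).set_index("cohort")


# -- candidate selection ------------------------------------------------------

@dataclass(frozen=True)
class Candidate:
    id: str
    sex: str
    index: float


def _tie_broken(order: list[tuple[str, float]], n: int, ped: Pedigree,
                current_breeders: Sequence[str]) -> list[tuple[str, float]]:
    """Reorder exact index ties so the dog less related to the active
    breeder pool comes first (then lexical id, for determinism)."""
    if not current_breeders or len(order) <= n:
        return order
    out: list[tuple[str, float]] = []
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and order[j][1] == order[i][1]:
            j += 1
        group = order[i:j]
        if len(group) > 1 and i < n < j:
            def mean_kin(item):
                dog = item[0]
                return float(np.mean([kinship(ped, dog, b) for b in current_breeders]))
            group = sorted(group, key=lambda it: (mean_kin(it), it[0]))
        out.extend(group)
        i = j
    return out


def select_candidates(
    index: Mapping[str, float],
    ped: Pedigree,
    n_female: int = 9,
    n_male: int = 3,
    screen_flags: Collection[str] = (),
    current_breeders: Sequence[str] = (),
) -> list[Candidate]:
    """Top-index breeding candidates per sex after flag-based screening.

    Dogs carrying any flag in ``screen_flags`` (reproductive abnormality,
    disqualifying conformation, excluded weight, ...) are removed before
    ranking. Among dogs with exactly equal index straddling the cut, the
    one with lower mean kinship to ``current_breeders`` is preferred.
    Returns fewer than requested (with a warning) when eligibility runs
    short.
    """
    if not index:
        raise SelectionError("empty index")
    screen = set(screen_flags)
    out: list[Candidate] = []
    for sex, want in ((FEMALE, n_female), (MALE, n_male)):
        eligible = [
            (dog, val) for dog, val in index.items()
            if dog in ped and ped.record(dog).sex == sex
            and not (ped.record(dog).status_flags & screen)
        ]
        eligible.sort(key=lambda t: (-t[1], t[0]))
        eligible = _tie_broken(eligible, want, ped, current_breeders)
        if len(eligible) < want:
            warnings.warn(
                f"only {len(eligible)} eligible {sex} candidates (requested {want})",
                stacklevel=2,
            )
        out.extend(Candidate(dog, sex, val) for dog, val in eligible[:want])
    return out


# -- mate allocation ----------------------------------------------------------

@dataclass(frozen=True)
class MatingConstraints:
    """Litter caps and pairing rules for one planning horizon.

    Defaults follow the practical guideline of at most 8 litters per sire
    and 4 per dam ('3 or 4'), never repeating a pairing, excluding
    affected dogs and allowing at most one carrier per pair.
    """

    max_litters_per_sire: int = 8
    max_litters_per_dam: int = 4
    forbid_repeat_pairs: bool = True
    max_predicted_f: float | None = None

    def __post_init__(self):
        if self.max_litters_per_sire < 1 or self.max_litters_per_dam < 1:
            raise SelectionError("litter caps must be >= 1")


@dataclass(frozen=True)
class MatingPair:
    sire: str
    dam: str
    predicted_f: float
    rationale: str = ""


@dataclass
class MatingPlan:
    pairs: list[MatingPair]
    usage: Counter
    unpaired: list[tuple[str, str]] = field(default_factory=list)  # (dam, reason)

    def validate(self, constraints: MatingConstraints,
                 history: Collection[frozenset] = ()) -> bool:
        """Self-audit: re-check every constraint against the emitted plan."""
        history = set(history)
        seen = set()
        sire_use: Counter = Counter()
        dam_use: Counter = Counter()
        for pr in self.pairs:
            key = frozenset((pr.sire, pr.dam))
            if constraints.forbid_repeat_pairs and (key in seen or key in history):
                return False
            seen.add(key)
            sire_use[pr.sire] += 1
            dam_use[pr.dam] += 1
            if (constraints.max_predicted_f is not None
                    and pr.predicted_f > constraints.max_predicted_f):
                return False
        return (all(v <= constraints.max_litters_per_sire for v in sire_use.values())
                and all(v <= constraints.max_litters_per_dam for v in dam_use.values()))


def _carrier_state(ped: Pedigree, dog: str) -> tuple[bool, bool]:
    flags = ped.record(dog).status_flags
    affected = any(f.startswith("affected:") for f in flags)
    carrier = any(f.startswith("carrier:") for f in flags)
    return affected, carrier


def propose_matings(
    candidates: Sequence[Candidate],
    ped: Pedigree,
    F: InbreedingTable | None,
    history: Iterable[tuple[str, str]] = (),
    constraints: MatingConstraints = MatingConstraints(),
    kinship_fn: Callable[[str, str], float] | None = None,
    n_litters: int | None = None,
) -> MatingPlan:
    """Greedy constrained mate allocation.

    Dams are visited in index order; each dam is paired with the sire of
    minimal predicted litter inbreeding among sires that (1) have not
    been bred with her before, (2) pass the carrier rule — no affected
    dog in any pair, at most one carrier — and (3) are under their litter
    cap. Ties go to the least-used sire, then lexical id. Planning
    proceeds in rounds (one litter per dam per round) until ``n_litters``
    litters are scheduled or no feasible pair remains; dams left without
    any litter are reported with a reason code.
    """
    kin = kinship_fn or (lambda a, b: kinship(ped, a, b))
    dams = sorted((c for c in candidates if c.sex == FEMALE),
                  key=lambda c: (-c.index, c.id))
    sires = sorted((c for c in candidates if c.sex == MALE),
                   key=lambda c: (-c.index, c.id))
    if not dams or not sires:
        raise SelectionError("need at least one dam and one sire")

    hist_pairs: set[frozenset] = set()
    hist_use: Counter = Counter()
    for s, d in history:
        hist_pairs.add(frozenset((s, d)))
        hist_use[s] += 1

    affected = {c.id for c in candidates if _carrier_state(ped, c.id)[0]}
    carrier = {c.id for c in candidates if _carrier_state(ped, c.id)[1]}

    target = n_litters if n_litters is not None else len(dams)
    pairs: list[MatingPair] = []
    planned = set(hist_pairs)
    sire_use: Counter = Counter({s.id: hist_use.get(s.id, 0) for s in sires})
    dam_use: Counter = Counter()
    reasons: dict[str, set[str]] = {d.id: set() for d in dams}

    progressed = True
    while len(pairs) < target and progressed:
        progressed = False
        for dam in dams:
            if len(pairs) >= target:
                break
            if dam_use[dam.id] >= constraints.max_litters_per_dam:
                reasons[dam.id].add("dam cap")
                continue
            if dam.id in affected:
                reasons[dam.id].add("affected")
                continue
            best = None
            for sire in sires:
                if sire.id in affected:
                    reasons[dam.id].add("affected")
                    continue
                if dam.id in carrier and sire.id in carrier:
                    reasons[dam.id].add("carrier×carrier")
                    continue
                if sire_use[sire.id] >= constraints.max_litters_per_sire:
                    reasons[dam.id].add("sire cap")
                    continue
                key = frozenset((sire.id, dam.id))
                if constraints.forbid_repeat_pairs and key in planned:
                    reasons[dam.id].add("repeat pair")
                    continue
                pf = float(kin(sire.id, dam.id))
                if (constraints.max_predicted_f is not None
                        and pf > constraints.max_predicted_f):
                    reasons[dam.id].add("predicted F cap")
                    continue
                cand = (pf, sire_use[sire.id], sire.id)
                if best is None or cand < best:
                    best = cand
            if best is None:
                continue
            pf, _, sire_id = best
            pairs.append(MatingPair(
                sire=sire_id, dam=dam.id, predicted_f=pf,
                rationale=f"min predicted F={pf:.4f}, usage tie-break",
            ))
            planned.add(frozenset((sire_id, dam.id)))
            sire_use[sire_id] += 1
            dam_use[dam.id] += 1
            progressed = True

    unpaired = [
        (d.id, "; ".join(sorted(reasons[d.id])) or "no feasible sire")
        for d in dams if dam_use[d.id] == 0
    ]
    plan = MatingPlan(pairs=pairs, usage=sire_use + dam_use, unpaired=unpaired)
    assert plan.validate(constraints, hist_pairs)
    return plan
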