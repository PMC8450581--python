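"""Closed-colony breeding simulator with additive polygenic traits.

The simulator generates synthetic colonies with the statistical structure
the analysis modules assume, and doubles as the test bed for the
program-level claims (inbreeding-rate bounds under litter caps, genetic
trends under index selection, heritability recovery).

Model
-----
* Discrete, non-overlapping generations. Each cycle, replacement breeders
  are chosen from the newest cohort, mated under the litter caps and the
  minimal-predicted-inbreeding rule, and produce the next cohort.
* True breeding values are multivariate normal across traits with
  additive variances h² (total phenotypic variance normalized to 1 per
  trait) and a configurable genetic correlation matrix. Offspring BV =
  parent average + Mendelian deviation with per-trait variance
  0.5·sigma2_a·(1 − (F_sire + F_dam)/2).
* Phenotype latent value = BV + optional year/sex effects + residual.
  ``ordinal5`` traits cut the latent value at the standard-normal
  quintiles (1 = least desirable); ``binary`` traits threshold it at the
  configured incidence.
* Litter sizes are Poisson (default mean 6.8) truncated at one pup;
  the default 30 litters/cycle gives roughly 200 pups per year.

The engine keeps the full numerator-relationship matrix incrementally
(tabular recursion), so inbreeding coefficients and pairwise kinships are
exact at every step; the analysis-side Meuwissen–Luo and recursive
kinship routines therefore provide an independent numerical cross-check.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import ebv as ebv_mod
from .pedigree import (FEMALE, MALE, IndividualRecord, InbreedingTable,
                       Pedigree, a_inverse, inbreeding, inbreeding_rate)
from .phenotypes import DesignSet, PhenotypeRecord, TraitDefinition, write_phenotypes
from .reml import VarianceComponents
from .selection import Candidate, MatingConstraints, propose_matings, select_candidates

SELECTION_MODES = ("random", "phenotypic", "true_bv", "index", "ebv_index")


class SimulationError(ValueError):
    """Invalid simulation configuration or impossible state."""


@dataclass(frozen=True)
class TraitSpec:
    """True genetic architecture of one simulated trait."""

    name: str
    scale: str = "continuous"
    h2: float = 0.5
    incidence: float = 0.5       # P(score = 1) for binary traits

    def __post_init__(self):
        if not 0.0 < self.h2 < 1.0:
            raise SimulationError(f"h2 for {self.name!r} must be in (0, 1)")
        if self.scale == "binary" and not 0.0 < self.incidence < 1.0:
            raise SimulationError("binary incidence must be in (0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Demography, genetic architecture and selection policy of a colony.

    Defaults describe the reference closed-colony scenario: ~30 litters
    per cycle with mean litter size 6.8 (≈200 pups/year), sire cap 8 and
    dam cap 4 litters, and a breeder pool of 15 males / 32 females —
    the 38♂/82♀ pool of a 520-pup colony scaled to 200 pups.
    """

    seed: int
    n_founder_males: int = 15
    n_founder_females: int = 32
    litters_per_year: int = 30
    litter_size_mean: float = 6.8
    generations: int = 10
    traits: tuple[TraitSpec, ...] = (TraitSpec("hip_quality", "ordinal5", 0.52),)
    genetic_correlations: np.ndarray | None = None
    caps: MatingConstraints = field(default_factory=MatingConstraints)
    selection: str = "index"
    n_breeding_males: int = 15
    n_breeding_females: int = 32
    index_weights: Mapping[str, float] | None = None
    year_effects: Mapping[int, Mapping[str, float]] | None = None
    sex_effects: Mapping[str, float] | None = None    # shift added for males

    def __post_init__(self):
        if self.selection not in SELECTION_MODES:
            raise SimulationError(f"unknown selection mode {self.selection!r}")
        object.__setattr__(self, "traits", tuple(self.traits))
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise SimulationError("duplicate trait names")

    @property
    def trait_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.traits)

    def genetic_covariance(self) -> np.ndarray:
        """Sigma_a = diag(sd) R diag(sd) with sd_t = sqrt(h2_t)."""
        sd = np.sqrt([t.h2 for t in self.traits])
        t = len(sd)
        R = (np.eye(t) if self.genetic_correlations is None
             else np.asarray(self.genetic_correlations, dtype=float))
        if R.shape != (t, t) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1.0):
            raise SimulationError("genetic correlation matrix must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise SimulationError("genetic correlation matrix is not positive semi-definite")
        return sd[:, None] * R * sd[None, :]

    def standardized_weights(self) -> np.ndarray:
        """Index weights per trait; default equal relative weights / genetic SD."""
        if self.index_weights is not None:
            return np.array([self.index_weights.get(t.name, 0.0) for t in self.traits])
        t = len(self.traits)
        return np.array([(1.0 / t) / np.sqrt(tr.h2) for tr in self.traits])


@dataclass(frozen=True)
class Dog:
    """Minimal per-animal state the simulator carries around."""

    id: str
    sex: str
    generation: int
    sire_id: str | None
    dam_id: str | None
    bv: np.ndarray
    f: float = 0.0


def _genetic_factor(cov: np.ndarray) -> np.ndarray:
    """Square root of a PSD covariance via its eigendecomposition."""
    w, U = np.linalg.eigh(cov)
    return U * np.sqrt(np.clip(w, 0.0, None))


#: standard-normal quintile cut points for 5-class ordinal scoring
ORDINAL5_THRESHOLDS = tuple(float(x) for x in norm.ppf([0.2, 0.4, 0.6, 0.8]))


def _score_latent(latent: float, trait: TraitSpec) -> float:
    if trait.scale == "ordinal5":
        return float(1 + np.searchsorted(ORDINAL5_THRESHOLDS, latent))
    if trait.scale == "binary":
        thr = float(norm.ppf(1.0 - trait.incidence))
        return float(latent > thr)
    return float(latent)


def simulate_founders(config: SimulationConfig,
                      rng: np.random.Generator | None = None) -> list[Dog]:
    """Unrelated, non-inbred base-population founders with MVN breeding values."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    fac = _genetic_factor(config.genetic_covariance())
    t = len(config.traits)
    dogs = []
    sexes = [MALE] * config.n_founder_males + [FEMALE] * config.n_founder_females
    for k, sex in enumerate(sexes):
        bv = fac @ rng.standard_normal(t)
        dogs.append(Dog(id=f"G00_{k:04d}", sex=sex, generation=0,
                        sire_id=None, dam_id=None, bv=bv, f=0.0))
    return dogs


def simulate_progeny(
    sire: Dog,
    dam: Dog,
    config: SimulationConfig,
    rng: np.random.Generator,
    id: str,
    sex: str | None = None,
    pair_kinship: float = 0.0,
) -> Dog:
    """One offspring: parent-average BV plus a Mendelian deviation.

    The Mendelian deviation has per-trait variance
    0.5·sigma2_a·(1 − (F_sire + F_dam)/2), correlated across traits by the
    configured genetic correlation matrix. The offspring's own inbreeding
    coefficient equals the parents' kinship (``pair_kinship``).
    """
    if sire.sex == dam.sex:
        raise SimulationError(f"same-sex pair {sire.id} × {dam.id}")
    fac = _genetic_factor(config.genetic_covariance())
    k = 0.5 * (1.0 - 0.5 * (sire.f + dam.f))
    mend = np.sqrt(max(k, 0.0)) * (fac @ rng.standard_normal(len(config.traits)))
    bv = 0.5 * (sire.bv + dam.bv) + mend
    sex = sex if sex is not None else (MALE if rng.random() < 0.5 else FEMALE)
    return Dog(id=id, sex=sex, generation=max(sire.generation, dam.generation) + 1,
               sire_id=sire.id, dam_id=dam.id, bv=bv, f=float(pair_kinship))


def _phenotype(dog: Dog, config: SimulationConfig, rng: np.random.Generator,
               year: int) -> list[PhenotypeRecord]:
    recs = []
    for j, tr in enumerate(config.traits):
        shift = 0.0
        if config.year_effects and year in config.year_effects:
            shift += config.year_effects[year].get(tr.name, 0.0)
        if config.sex_effects and dog.sex == MALE:
            shift += config.sex_effects.get(tr.name, 0.0)
        latent = dog.bv[j] + shift + rng.normal(0.0, np.sqrt(1.0 - tr.h2))
        recs.append(PhenotypeRecord(
            dog_id=dog.id, trait=tr.name, score=_score_latent(latent, tr),
            covariates={"sex": dog.sex, "year": year},
        ))
    return recs


@dataclass
class SimulatedColony:
    """Everything a simulation run produced, in analysis-ready form."""

    dogs: pd.DataFrame                 # dog_id, sire, dam, sex, generation, f, index_ebv
    true_bv: pd.DataFrame              # dog_id, trait, true_bv
    phenotypes: list[PhenotypeRecord]
    summary: pd.DataFrame              # per-generation engine bookkeeping
    breeders: dict[int, list[str]]     # generation -> dogs used as parents
    config: SimulationConfig | None = None
    termination: str | None = None
    _ped: Pedigree | None = None

    @property
    def pedigree(self) -> Pedigree:
        if self._ped is None:
            recs = [
                IndividualRecord(
                    id=r.dog_id,
                    sire_id=None if r.sire in ("", "0") else r.sire,
                    dam_id=None if r.dam in ("", "0") else r.dam,
                    sex=r.sex, cohort=int(r.generation),
                )
                for r in self.dogs.itertuples(index=False)
            ]
            self._ped = Pedigree(recs)
        return self._ped

    @property
    def success_trait(self) -> str | None:
        traits = (self.config.traits if self.config is not None else ())
        for tr in traits:
            if tr.scale == "binary":
                return tr.name
        return None


class _Engine:
    def __init__(self, config: SimulationConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.fac = _genetic_factor(config.genetic_covariance())
        self.t = len(config.traits)
        cap = 256
        self.A = np.zeros((cap, cap))
        self.dogs: list[Dog] = []
        self.pos: dict[str, int] = {}
        self.phen: list[PhenotypeRecord] = []
        self.phen_score: dict[str, np.ndarray] = {}
        self.index_ebv: dict[str, float] = {}
        self.breeders: dict[int, list[str]] = {}
        self.rows: list[dict] = []

    # -- relationship bookkeeping --------------------------------------------

    def _grow(self, need: int) -> None:
        cap = self.A.shape[0]
        if need <= cap:
            return
        while cap < need:
            cap *= 2
        newA = np.zeros((cap, cap))
        n = len(self.dogs)
        newA[:n, :n] = self.A[:n, :n]
        self.A = newA

    def add(self, dog: Dog) -> Dog:
        i = len(self.dogs)
        self._grow(i + 1)
        A = self.A
        if dog.sire_id is None and dog.dam_id is None:
            A[i, i] = 1.0
            f = 0.0
        else:
            s, d = self.pos[dog.sire_id], self.pos[dog.dam_id]
            row = 0.5 * (A[s, :i] + A[d, :i])
            A[i, :i] = row
            A[:i, i] = row
            A[i, i] = 1.0 + 0.5 * A[s, d]
            f = A[i, i] - 1.0
        dog = replace(dog, f=float(f))
        self.dogs.append(dog)
        self.pos[dog.id] = i
        return dog

    def kin(self, a: str, b: str) -> float:
        return 0.5 * self.A[self.pos[a], self.pos[b]]

    # -- phenotyping ----------------------------------------------------------

    def phenotype(self, dog: Dog, year: int) -> None:
        recs = _phenotype(dog, self.cfg, self.rng, year)
        self.phen.extend(recs)
        self.phen_score[dog.id] = np.array([r.score for r in recs])

    # -- selection scores ------------------------------------------------------

    def _pedigree(self) -> Pedigree:
        recs = [
            IndividualRecord(id=d.id, sire_id=d.sire_id, dam_id=d.dam_id,
                             sex=d.sex, cohort=d.generation)
            for d in self.dogs
        ]
        return Pedigree(recs)

    def _ebv_scores(self, ped: Pedigree) -> np.ndarray:
        """Index over BLUP EBVs fitted to all phenotypes recorded so far."""
        ftab = InbreedingTable(
            F={d.id: d.f for d in self.dogs},
            by_cohort_mean={},
        )
        ainv = a_inverse(ped, ftab)
        w = self.cfg.standardized_weights()
        total = np.zeros(len(self.dogs))
        by_trait: dict[str, list[PhenotypeRecord]] = {}
        for r in self.phen:
            by_trait.setdefault(r.trait, []).append(r)
        for j, tr in enumerate(self.cfg.traits):
            recs = by_trait.get(tr.name, [])
            y = np.array([r.score for r in recs], dtype=float)
            rows = np.array([ped.index(r.dog_id) for r in recs], dtype=np.int64)
            design = DesignSet(
                y=y, X=np.ones((len(y), 1)), columns=("(Intercept)",),
                animal_rows=rows, n_animals=ped.n,
                trait=TraitDefinition(tr.name, tr.scale if tr.scale != "ordinal5" else "ordinal5"),
            )
            vc = VarianceComponents(sigma2_a=tr.h2, sigma2_e=1.0 - tr.h2)
            res = ebv_mod.blup_linear(design, ainv, vc)
            # blup solutions are in pedigree order; map back to engine order
            total += w[j] * np.array([res.ebv[ped.index(d.id)] for d in self.dogs])
        return total

    def scores(self, pool: list[Dog], ped: Pedigree) -> dict[str, float]:
        mode = self.cfg.selection
        w = self.cfg.standardized_weights()
        if mode == "random":
            return {d.id: float(self.rng.random()) for d in pool}
        if mode == "phenotypic":
            return {d.id: float(w @ self.phen_score[d.id]) for d in pool}
        if mode == "true_bv":
            return {d.id: float(d.bv.sum()) for d in pool}
        if mode == "index":
            return {d.id: float(w @ d.bv) for d in pool}
        # ebv_index
        all_scores = self._ebv_scores(ped)
        for d, s in zip(self.dogs, all_scores):
            self.index_ebv[d.id] = float(s)
        return {d.id: float(all_scores[self.pos[d.id]]) for d in pool}

    # -- one generation --------------------------------------------------------

    def litter_size(self) -> int:
        while True:
            k = int(self.rng.poisson(self.cfg.litter_size_mean))
            if k >= 1:
                return k

    def run(self) -> SimulatedColony:
        cfg = self.cfg
        for dog in simulate_founders(cfg, self.rng):
            self.phenotype(self.add(dog), year=0)
        self._summarize(0)
        termination = None
        for g in range(1, cfg.generations + 1):
            pool = [d for d in self.dogs if d.generation == g - 1]
            ped = self._pedigree()
            idx = self.scores(pool, ped)
            candidates = select_candidates(
                idx, ped,
                n_female=cfg.n_breeding_females, n_male=cfg.n_breeding_males,
                current_breeders=self.breeders.get(g - 2, ()),
            )
            if not any(c.sex == MALE for c in candidates) or \
               not any(c.sex == FEMALE for c in candidates):
                termination = f"no breeding candidates in generation {g - 1}"
                break
            plan = propose_matings(
                candidates, ped, None, history=(),
                constraints=cfg.caps, kinship_fn=self.kin,
                n_litters=cfg.litters_per_year,
            )
            if not plan.pairs:
                termination = f"no feasible matings in generation {g - 1}"
                break
            used = sorted({p.sire for p in plan.pairs} | {p.dam for p in plan.pairs})
            self.breeders[g - 1] = used
            serial = 0
            for pair in plan.pairs:
                sire = self.dogs[self.pos[pair.sire]]
                dam = self.dogs[self.pos[pair.dam]]
                for _ in range(self.litter_size()):
                    pup = simulate_progeny(
                        sire, dam, cfg, self.rng,
                        id=f"G{g:02d}_{serial:04d}",
                        pair_kinship=pair.predicted_f,
                    )
                    serial += 1
                    self.phenotype(self.add(pup), year=g)
            self._summarize(g)
        return self._finish(termination)

    def _summarize(self, g: int) -> None:
        cohort = [d for d in self.dogs if d.generation == g]
        row = {
            "generation": g,
            "n_dogs": len(cohort),
            "mean_f": float(np.mean([d.f for d in cohort])),
        }
        bv = np.array([d.bv for d in cohort])
        for j, tr in enumerate(self.cfg.traits):
            row[f"mean_bv_{tr.name}"] = float(bv[:, j].mean())
            row[f"median_bv_{tr.name}"] = float(np.median(bv[:, j]))
            if tr.scale == "binary":
                scores = np.array([self.phen_score[d.id][j] for d in cohort])
                row[f"success_fraction_{tr.name}"] = float(scores.mean())
        self.rows.append(row)

    def _finish(self, termination: str | None) -> SimulatedColony:
        dogs = pd.DataFrame({
            "dog_id": [d.id for d in self.dogs],
            "sire": [d.sire_id or "0" for d in self.dogs],
            "dam": [d.dam_id or "0" for d in self.dogs],
            "sex": [d.sex for d in self.dogs],
            "generation": [d.generation for d in self.dogs],
            "f": [d.f for d in self.dogs],
            "index_ebv": [self.index_ebv.get(d.id, np.nan) for d in self.dogs],
        })
        true_bv = pd.DataFrame({
            "dog_id": np.repeat([d.id for d in self.dogs], self.t),
            "trait": list(self.cfg.trait_names) * len(self.dogs),
            "true_bv": np.concatenate([d.bv for d in self.dogs]),
        })
        return SimulatedColony(
            dogs=dogs, true_bv=true_bv, phenotypes=self.phen,
            summary=pd.DataFrame(self.rows), breeders=self.breeders,
            config=self.cfg, termination=termination,
        )


def run_program(config: SimulationConfig) -> SimulatedColony:
    """Run the six-step loop for the configured number of generations:
    phenotype → (optionally estimate EBVs) → select → mate under
    constraints → next generation. Terminates early, with the partial
    colony and a reason, if no feasible matings remain."""
    return _Engine(config).run()


# -- program-level metrics -----------------------------------------------------

def program_metrics(colony: SimulatedColony) -> pd.DataFrame:
    """Per-generation program report recomputed from the raw records.

    Inbreeding is recomputed from the pedigree (independent of the
    engine's running bookkeeping); ΔF is given both as the plain mean-F
    difference (percentage points) and as the classical standardized rate
    against the remaining heterozygosity. Genetic merit is summarized
    overall and for the breeders actually used; for binary 'success'
    traits the cost metric pups-per-success is reported.
    """
    ped = colony.pedigree
    ftab = inbreeding(ped)
    gens = sorted(colony.dogs["generation"].unique())
    if len(gens) < 2:
        raise SimulationError("need at least two generations for program metrics")
    bv = colony.true_bv.merge(
        colony.dogs[["dog_id", "generation"]], on="dog_id", how="left"
    )
    success = colony.success_trait
    succ_by_dog: dict[str, float] = {}
    if success is not None:
        succ_by_dog = {r.dog_id: r.score for r in colony.phenotypes
                       if r.trait == success}
    rows = []
    prev_f = None
    for g in gens:
        cohort_ids = colony.dogs.loc[colony.dogs["generation"] == g, "dog_id"]
        mf = ftab.by_cohort_mean[int(g)]
        row: dict[str, object] = {
            "generation": int(g),
            "n_dogs": int(len(cohort_ids)),
            "mean_f": mf,
            "delta_f_endpoint": np.nan if prev_f is None else 100.0 * (mf - prev_f),
            "delta_f_classical": (np.nan if prev_f is None
                                  else 100.0 * (mf - prev_f) / (1.0 - prev_f)),
        }
        used = set(colony.breeders.get(int(g), []))
        for trait, grp in bv[bv["generation"] == g].groupby("trait"):
            row[f"mean_bv_{trait}"] = grp["true_bv"].mean()
            row[f"median_bv_{trait}"] = grp["true_bv"].median()
            sel = grp[grp["dog_id"].isin(used)]
            row[f"mean_bv_breeders_{trait}"] = (sel["true_bv"].mean()
                                                if len(sel) else np.nan)
        ebvs = colony.dogs.loc[colony.dogs["generation"] == g, "index_ebv"]
        row["mean_index_ebv"] = float(ebvs.mean()) if ebvs.notna().any() else np.nan
        if success is not None:
            scores = np.array([succ_by_dog[i] for i in cohort_ids])
            n_succ = int(scores.sum())
            row["success_fraction"] = scores.mean()
            row["pups_per_success"] = (len(scores) / n_succ) if n_succ else np.nan
        rows.append(row)
        prev_f = mf
    return pd.DataFrame(rows)


def colony_design(colony: SimulatedColony, trait_name: str,
                  fixed_effects: Sequence[str] = ()) -> DesignSet:
    """Analysis-ready design for one simulated trait, via the standard
    phenotype pipeline (the simulator's output is its own test input)."""
    from .phenotypes import build_design

    spec = next(t for t in colony.config.traits if t.name == trait_name)
    tdef = TraitDefinition(spec.name, spec.scale, tuple(fixed_effects))
    return build_design(colony.phenotypes, tdef, colony.pedigree)


def colony_inbreeding_rate(colony: SimulatedColony,
                           method: str = "endpoint"):
    """Endpoint (or classical) inbreeding rate over the whole run."""
    ftab = inbreeding(colony.pedigree)
    gens = sorted(ftab.by_cohort_mean)
    return inbreeding_rate(ftab, gens[0], gens[-1], method=method)


# -- serialization -------------------------------------------------------------

def write_colony(colony: SimulatedColony, outdir) -> None:
    """Write a colony in the exact formats the analysis modules read."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ped_frame = colony.dogs.rename(columns={"dog_id": "id", "generation": "cohort"})
    ped_frame["flags"] = ""
    ped_frame[["id", "sire", "dam", "sex", "cohort", "flags"]].to_csv(
        out / "pedigree.csv", index=False)
    colony.dogs.to_csv(out / "dogs.csv", index=False)
    write_phenotypes(colony.phenotypes, out / "phenotypes.csv")
    colony.true_bv.to_csv(out / "true_bv.tsv", sep="\t", index=False)
    colony.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    program_metrics(colony).to_csv(out / "metrics.tsv", sep="\t", index=False)
    breeders = pd.DataFrame(
        [(g, d) for g, ids in sorted(colony.breeders.items()) for d in ids],
        columns=["generation", "dog_id"],
    )
    breeders.to_csv(out / "breeders.csv", index=False)
    cfg = colony.config
    meta = {
        "termination": colony.termination,
        "success_trait": colony.success_trait,
        "traits": ([{"name": t.name, "scale": t.scale, "h2": t.h2,
                     "incidence": t.incidence} for t in cfg.traits]
                   if cfg else []),
        "seed": cfg.seed if cfg else None,
    }
    (out / "colony.json").write_text(json.dumps(meta, indent=2))


def read_colony(outdir) -> SimulatedColony:
    """Reload a serialized colony; metrics recomputed from it match the
    in-memory colony's metrics."""
    out = Path(outdir)
    dogs = pd.read_csv(out / "dogs.csv",
                       dtype={"dog_id": str, "sire": str, "dam": str})
    from .phenotypes import load_phenotypes

    meta = json.loads((out / "colony.json").read_text())
    traits = tuple(TraitSpec(t["name"], t["scale"], t["h2"], t["incidence"])
                   for t in meta["traits"])
    tdefs = [TraitDefinition(t.name, t.scale) for t in traits]
    phen = load_phenotypes(out / "phenotypes.csv", tdefs)
    true_bv = pd.read_csv(out / "true_bv.tsv", sep="\t", dtype={"dog_id": str})
    summary = pd.read_csv(out / "summary.tsv", sep="\t")
    brd = pd.read_csv(out / "breeders.csv", dtype={"dog_id": str})
    breeders = {int(g): grp["dog_id"].tolist()
                for g, grp in brd.groupby("generation")}
    cfg = (SimulationConfig(seed=meta["seed"], traits=traits)
           if meta["seed"] is not None else None)
    return SimulatedColony(dogs=dogs, true_bv=true_bv, phenotypes=phen,
                           summary=summary, breeders=breeders, config=cfg,
                           termination=meta["termination"])
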