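"""Uniformly coded phenotype storage and fixed-effect design construction.

Traits are recorded in a long-format table (one row per dog per trait)
and declared with an explicit measurement scale:

* ``ordinal5`` — five ordered classes, 1 (least desirable) to 5 (most
  desirable), analyzed as a linear score;
* ``binary`` — 0/1 outcome destined for the threshold (liability) model;
* ``continuous`` — unrestricted numeric score.

``build_design`` turns a set of records into the response vector, the
fixed-effect incidence matrix (intercept, one-hot categoricals with the
first level as reference, centered continuous covariates) and the map
from observation rows to pedigree positions that the mixed-model solvers
consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

SCALES = ("ordinal5", "binary", "continuous")

#: covariates treated as categorical unless the trait declares otherwise
DEFAULT_CATEGORICAL = frozenset({"sex", "season", "year"})


class PhenotypeError(ValueError):
    """Invalid phenotype data or trait declaration."""


@dataclass(frozen=True)
class TraitDefinition:
    """Declaration of a trait's scale and fixed-effect model.

    ``polarity`` records the scoring convention (5 / high = most
    desirable); it is carried through to reports, not used in math.
    ``categorical`` optionally overrides which fixed effects are treated
    as factors (default: sex/season/year plus any non-numeric covariate).
    """

    name: str
    scale: str = "continuous"
    fixed_effects: tuple[str, ...] = ()
    polarity: str = "high_is_desirable"
    categorical: frozenset[str] | None = None

    def __post_init__(self):
        if self.scale not in SCALES:
            raise PhenotypeError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        object.__setattr__(self, "fixed_effects", tuple(self.fixed_effects))

    def validate_score(self, score: float) -> bool:
        if self.scale == "ordinal5":
            return float(score).is_integer() and 1 <= score <= 5
        if self.scale == "binary":
            return score in (0, 1, 0.0, 1.0)
        return np.isfinite(score)


@dataclass(frozen=True)
class PhenotypeRecord:
    dog_id: str
    trait: str
    score: float
    covariates: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class DesignSet:
    """Response, fixed-effect design and animal incidence for one trait."""

    y: np.ndarray
    X: np.ndarray
    columns: tuple[str, ...]
    animal_rows: np.ndarray          # observation row -> pedigree position
    n_animals: int
    trait: TraitDefinition | None = None
    dog_ids: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.y) != self.X.shape[0] or len(self.y) != len(self.animal_rows):
            raise PhenotypeError("design components have inconsistent row counts")

    @property
    def n(self) -> int:
        return len(self.y)


# -- IO -----------------------------------------------------------------------

def load_phenotypes(path, traits: Sequence[TraitDefinition],
                    dialect: Mapping | None = None) -> list[PhenotypeRecord]:
    """Load a long-format phenotype CSV/TSV, validating against trait scales.

    Required columns: dog_id, trait, score. Every other column is kept as
    a covariate. Rows with unknown trait tokens or off-scale scores raise
    with their (1-based) data row numbers.
    """
    dialect = dict(dialect or {})
    delim = dialect.get("delimiter")
    if delim is None:
        delim = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=delim)
    required = {"dog_id", "trait", "score"}
    if not required.issubset(df.columns):
        raise PhenotypeError(
            f"phenotype file must have columns {sorted(required)}; got {list(df.columns)}"
        )
    by_name = {t.name: t for t in traits}
    covar_cols = [c for c in df.columns if c not in required]
    bad_trait, bad_score = [], []
    records = []
    for rownum, row in enumerate(df.itertuples(index=False), start=1):
        tdef = by_name.get(row.trait)
        if tdef is None:
            bad_trait.append((rownum, row.trait))
            continue
        if not tdef.validate_score(row.score):
            bad_score.append((rownum, row.trait, row.score))
            continue
        cov = {c: getattr(row, c) for c in covar_cols}
        records.append(PhenotypeRecord(str(row.dog_id), row.trait, float(row.score), cov))
    if bad_trait:
        raise PhenotypeError(f"undeclared trait tokens at rows {bad_trait}")
    if bad_score:
        listing = ", ".join(f"row {r}: {t}={s!r}" for r, t, s in bad_score)
        raise PhenotypeError(f"scores off the declared scale: {listing}")
    return records


def phenotypes_to_frame(records: Iterable[PhenotypeRecord]) -> pd.DataFrame:
    records = list(records)
    covar_names = sorted({c for r in records for c in r.covariates})
    data = {
        "dog_id": [r.dog_id for r in records],
        "trait": [r.trait for r in records],
        "score": [r.score for r in records],
    }
    for c in covar_names:
        data[c] = [r.covariates.get(c, "") for r in records]
    return pd.DataFrame(data)


def write_phenotypes(records: Iterable[PhenotypeRecord], path,
                     delimiter: str = ",") -> None:
    """Write records in the canonical long format (stable column order)."""
    phenotypes_to_frame(records).to_csv(path, sep=delimiter, index=False)


# -- encoding and design ------------------------------------------------------

def encode_trait(records: Iterable[PhenotypeRecord],
                 trait: TraitDefinition) -> tuple[np.ndarray, dict]:
    """Extract the numeric response for one trait.

    Ordinal 1–5 scores pass through as linear scores; binary as 0/1.
    Metadata flags responses with no variation, which downstream model
    fits must refuse.
    """
    sub = [r for r in records if r.trait == trait.name]
    if not sub:
        raise PhenotypeError(f"no records for trait {trait.name!r}")
    y = np.array([r.score for r in sub], dtype=float)
    meta = {
        "trait": trait.name,
        "scale": trait.scale,
        "polarity": trait.polarity,
        "n": len(y),
        "dog_ids": tuple(r.dog_id for r in sub),
        "has_variation": bool(np.ptp(y) > 0),
    }
    return y, meta


def _is_categorical(name: str, values: pd.Series, trait: TraitDefinition) -> bool:
    if trait.categorical is not None:
        return name in trait.categorical
    if name in DEFAULT_CATEGORICAL:
        return True
    return not pd.api.types.is_numeric_dtype(values)


def build_design(records: Iterable[PhenotypeRecord], trait: TraitDefinition,
                 ped: Pedigree, on_missing: str = "drop",
                 intercept: bool = True) -> DesignSet:
    """Build the response/fixed-effect/animal-incidence triple for a trait.

    Categorical covariates are one-hot encoded with the first (sorted)
    level as the reference; continuous covariates are centered. Records
    missing a declared covariate are dropped with a warning (or rejected
    when ``on_missing='error'``). Dogs absent from the pedigree are an
    error — EBVs are undefined without a pedigree link.
    """
    sub = [r for r in records if r.trait == trait.name]
    if not sub:
        raise PhenotypeError(f"no records for trait {trait.name!r}")

    missing_dogs = sorted({r.dog_id for r in sub if r.dog_id not in ped})
    if missing_dogs:
        raise PhenotypeError(f"dogs absent from pedigree: {missing_dogs}")

    cov = pd.DataFrame([dict(r.covariates) for r in sub])
    for c in trait.fixed_effects:
        if c not in cov.columns or cov[c].isna().all():
            raise PhenotypeError(f"covariate {c!r} entirely missing from records")
    keep = np.ones(len(sub), dtype=bool)
    for c in trait.fixed_effects:
        keep &= cov[c].notna().to_numpy()
    n_drop = int((~keep).sum())
    if n_drop:
        if on_missing == "error":
            raise PhenotypeError(f"{n_drop} records missing declared covariates")
        warnings.warn(
            f"dropping {n_drop} record(s) of trait {trait.name!r} with missing covariates",
            stacklevel=2,
        )
    sub = [r for r, k in zip(sub, keep) if k]
    cov = cov.loc[keep].reset_index(drop=True) if len(cov) else cov

    y = np.array([r.score for r in sub], dtype=float)
    blocks: list[np.ndarray] = []
    names: list[str] = []
    if intercept:
        blocks.append(np.ones((len(sub), 1)))
        names.append("(Intercept)")
    for c in trait.fixed_effects:
        col = cov[c]
        if _is_categorical(c, col, trait):
            levels = sorted(map(str, col.unique()))
            for lev in levels[1:]:  # first level is the reference
                blocks.append((col.astype(str) == lev).to_numpy(dtype=float)[:, None])
                names.append(f"{c}[{lev}]")
        else:
            v = col.to_numpy(dtype=float)
            blocks.append((v - v.mean())[:, None])
            names.append(c)
    X = np.hstack(blocks) if blocks else np.empty((len(sub), 0))
    animal_rows = np.array([ped.index(r.dog_id) for r in sub], dtype=np.int64)
    return DesignSet(
        y=y, X=X, columns=tuple(names), animal_rows=animal_rows,
        n_animals=ped.n, trait=trait, dog_ids=tuple(r.dog_id for r in sub),
    )
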