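"""Pedigree machinery for closed breeding colonies.

The pedigree is the backbone of every downstream computation in an
EBV-selection program: coefficients of inbreeding (Wright's F) and kinships
drive mate allocation, while the sparse inverse of the additive
(numerator) relationship matrix A structures the mixed-model equations
used for breeding-value estimation.

Conventions
-----------
* Unknown parents are treated as unrelated, non-inbred members of the base
  population (no unknown-parent groups).
* Individuals are kept in a stable topological order: parents always
  precede offspring, and the order is deterministic given the input row
  order (so a written file reloads to the identical ordering).
* Inbreeding coefficients are computed with the Meuwissen & Luo
  linear-time recursion; A⁻¹ is assembled directly from Henderson's
  parent-contribution rules with full accounting for parental inbreeding.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

MALE = "male"
FEMALE = "female"

#: tokens accepted as "parent unknown" in input files
UNKNOWN_TOKENS = frozenset({"", "0", ".", "na", "nan", "none", "unknown"})

_SEX_TOKENS = {
    "male": MALE, "m": MALE, "1": MALE,
    "female": FEMALE, "f": FEMALE, "2": FEMALE,
}


class PedigreeError(ValueError):
    """Structural or validation problem in a pedigree."""


class CycleError(PedigreeError):
    """An individual is its own ancestor."""

    def __init__(self, cycle: Sequence[str]):
        self.cycle = list(cycle)
        msg = " -> ".join([*self.cycle, self.cycle[0]])
        super().__init__(f"pedigree contains a cycle: {msg}")


@dataclass(frozen=True)
class IndividualRecord:
    """One row of a pedigree.

    ``sire_id``/``dam_id`` are ``None`` when the parent is unknown.
    ``status_flags`` carries screening annotations such as
    ``excluded-weight``, ``carrier:<locus>``, ``affected:<locus>`` or
    ``previously-bred-with:<id>``.
    """

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str | None = None
    cohort: int | None = None
    status_flags: frozenset[str] = field(default_factory=frozenset)


class Pedigree:
    """A validated, topologically ordered collection of individuals."""

    def __init__(self, records: Iterable[IndividualRecord]):
        records = list(records)
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dups = [i for i in ids if i in seen or seen.add(i)]
            raise PedigreeError(f"duplicate ids: {sorted(set(dups))}")
        by_id = {r.id: r for r in records}

        missing = sorted(
            {p for r in records for p in (r.sire_id, r.dam_id)
             if p is not None and p not in by_id}
        )
        if missing:
            raise PedigreeError(f"referenced parents not in pedigree: {missing}")

        bad_sex = []
        for r in records:
            if r.sire_id is not None and by_id[r.sire_id].sex == FEMALE:
                bad_sex.append((r.id, "sire", r.sire_id))
            if r.dam_id is not None and by_id[r.dam_id].sex == MALE:
                bad_sex.append((r.id, "dam", r.dam_id))
        if bad_sex:
            listing = "; ".join(f"{c}: {role} {p}" for c, role, p in bad_sex)
            raise PedigreeError(f"sex-inconsistent parents: {listing}")

        ordered = self._toposort(records, by_id)
        self._pos = {r.id: k for k, r in enumerate(ordered)}
        self.sire_idx = np.array(
            [self._pos[r.sire_id] if r.sire_id is not None else -1 for r in ordered],
            dtype=np.int64,
        )
        self.dam_idx = np.array(
            [self._pos[r.dam_id] if r.dam_id is not None else -1 for r in ordered],
            dtype=np.int64,
        )
        gen = self._generations(ordered)
        self.records: tuple[IndividualRecord, ...] = tuple(
            r if r.cohort is not None else replace(r, cohort=int(gen[k]))
            for k, r in enumerate(ordered)
        )
        self._kin_cache: dict[tuple[int, int], float] = {}

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _toposort(records, by_id):
        """Kahn's algorithm with input order as priority (stable, deterministic)."""
        order_in = {r.id: k for k, r in enumerate(records)}
        children: dict[str, list[str]] = {r.id: [] for r in records}
        indeg = {}
        for r in records:
            parents = [p for p in (r.sire_id, r.dam_id) if p is not None]
            indeg[r.id] = len(parents)
            for p in set(parents):
                children[p].append(r.id)
            # a repeated parent (selfed) still needs both edges resolved once
            if r.sire_id is not None and r.sire_id == r.dam_id:
                indeg[r.id] = 1
        ready = [(order_in[i], i) for i, d in indeg.items() if d == 0]
        heapq.heapify(ready)
        out = []
        while ready:
            _, i = heapq.heappop(ready)
            out.append(by_id[i])
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    heapq.heappush(ready, (order_in[c], c))
        if len(out) != len(records):
            stuck = {i for i, d in indeg.items() if d > 0}
            raise CycleError(_find_cycle(stuck, by_id))
        return out

    @staticmethod
    def _generations(ordered):
        pos = {r.id: k for k, r in enumerate(ordered)}
        gen = np.zeros(len(ordered), dtype=np.int64)
        for k, r in enumerate(ordered):
            pg = [gen[pos[p]] for p in (r.sire_id, r.dam_id) if p is not None]
            gen[k] = 1 + max(pg) if pg else 0
        return gen

    # -- basic accessors ------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return self.n

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def index(self, id: str) -> int:
        try:
            return self._pos[id]
        except KeyError:
            raise PedigreeError(f"unknown individual: {id!r}") from None

    def __contains__(self, id: str) -> bool:
        return id in self._pos

    def record(self, id: str) -> IndividualRecord:
        return self.records[self.index(id)]

    def generation_numbers(self) -> dict[str, int]:
        """1 + max(parent generation); founders are generation 0."""
        gen = self._generations(self.records)
        return {r.id: int(gen[k]) for k, r in enumerate(self.records)}

    def append(self, record: IndividualRecord) -> "Pedigree":
        """Return a new pedigree with one extra individual."""
        return Pedigree([*self.records, record])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sire": [r.sire_id or "0" for r in self.records],
                "dam": [r.dam_id or "0" for r in self.records],
                "sex": [r.sex or "" for r in self.records],
                "cohort": [r.cohort for r in self.records],
                "flags": [";".join(sorted(r.status_flags)) for r in self.records],
            }
        )


def _find_cycle(stuck: set[str], by_id) -> list[str]:
    start = sorted(stuck)[0]
    seen: dict[str, int] = {}
    path: list[str] = []
    node = start
    while node not in seen:
        seen[node] = len(path)
        path.append(node)
        r = by_id[node]
        nxt = [p for p in (r.sire_id, r.dam_id) if p is not None and p in stuck]
        if not nxt:  # pragma: no cover - stuck nodes always have a stuck parent
            break
        node = nxt[0]
    return path[seen.get(node, 0):]


# -- file IO ------------------------------------------------------------------

def _normalize_parent(tok: str) -> str | None:
    return None if tok.strip().lower() in UNKNOWN_TOKENS else tok.strip()


def load_pedigree(path, dialect: Mapping | None = None) -> Pedigree:
    """Load a pedigree CSV/TSV with columns id,sire,dam[,sex,cohort,flags].

    The delimiter is taken from ``dialect['delimiter']`` when given, else
    inferred from the file extension (``.tsv`` → tab, otherwise comma).
    Unknown parents may be encoded as ``0``, empty, ``NA`` or ``unknown``.
    """
    dialect = dict(dialect or {})
    delim = dialect.get("delimiter")
    if delim is None:
        delim = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(
            f"pedigree file must have columns {sorted(required)}; got {list(df.columns)}"
        )
    records = []
    for row in df.itertuples(index=False):
        sex = getattr(row, "sex", "") or ""
        sex_norm = _SEX_TOKENS.get(sex.strip().lower()) if sex.strip() else None
        cohort_tok = str(getattr(row, "cohort", "")).strip()
        cohort = int(float(cohort_tok)) if cohort_tok else None
        flags_tok = str(getattr(row, "flags", "")).strip()
        flags = frozenset(t for t in flags_tok.split(";") if t)
        records.append(
            IndividualRecord(
                id=row.id.strip(),
                sire_id=_normalize_parent(row.sire),
                dam_id=_normalize_parent(row.dam),
                sex=sex_norm,
                cohort=cohort,
                status_flags=flags,
            )
        )
    return Pedigree(records)


def load_plink_fam(path) -> Pedigree:
    """Import a PLINK .fam file (family id and phenotype columns ignored)."""
    df = pd.read_csv(
        path, sep=r"\s+", dtype=str, header=None,
        names=["fid", "id", "sire", "dam", "sex", "pheno"],
    )
    records = [
        IndividualRecord(
            id=row.id,
            sire_id=_normalize_parent(row.sire),
            dam_id=_normalize_parent(row.dam),
            sex=_SEX_TOKENS.get(str(row.sex).strip().lower()),
        )
        for row in df.itertuples(index=False)
    ]
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path, delimiter: str = ",") -> None:
    """Write the canonical pedigree table (topological order, 0 = unknown)."""
    ped.to_frame().to_csv(path, sep=delimiter, index=False)


# -- inbreeding and kinship ---------------------------------------------------

@dataclass(frozen=True)
class InbreedingTable:
    """Per-individual inbreeding coefficients plus per-cohort means."""

    F: dict[str, float]
    by_cohort_mean: dict[int, float]

    @classmethod
    def from_cohort_means(cls, means: Mapping[int, float]) -> "InbreedingTable":
        """Build a cohort-level table (e.g. from published generation means)."""
        return cls(F={}, by_cohort_mean={int(k): float(v) for k, v in means.items()})

    def as_array(self, ped: Pedigree) -> np.ndarray:
        return np.array([self.F[i] for i in ped.ids], dtype=float)


def _mendelian_d(sire_idx, dam_idx, F):
    """Within-family (Mendelian sampling) variance scalars D_i.

    D_i = 0.5 - 0.25 (F_s + F_d) with both parents known; unknown parents
    contribute as non-inbred base individuals.
    """
    n = len(F)
    D = np.empty(n, dtype=float)
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        if s < 0 and d < 0:
            D[i] = 1.0
        elif s < 0:
            D[i] = 0.75 - 0.25 * F[d]
        elif d < 0:
            D[i] = 0.75 - 0.25 * F[s]
        else:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
    return D


def inbreeding_array(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients in pedigree order (Meuwissen & Luo recursion).

    For each individual i the diagonal A_ii = 1 + F_i is accumulated as
    Σ_j L_ij² D_j over the ancestors j of i, where L is the gene-flow
    (Cholesky) factor of A and D the Mendelian variance scalars.
    """
    n = ped.n
    s_arr, d_arr = ped.sire_idx, ped.dam_idx
    F = np.zeros(n, dtype=float)
    D = np.empty(n, dtype=float)
    for i in range(n):
        si, di = s_arr[i], d_arr[i]
        if si < 0 and di < 0:
            D[i] = 1.0
        elif si < 0:
            D[i] = 0.75 - 0.25 * F[di]
        elif di < 0:
            D[i] = 0.75 - 0.25 * F[si]
        else:
            D[i] = 0.5 - 0.25 * (F[si] + F[di])
        if si < 0 or di < 0:
            F[i] = 0.0
            continue
        # walk ancestors in decreasing topological index
        L = {i: 1.0}
        heap = [-i]
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            lj = L.pop(j)
            aii += lj * lj * D[j]
            for p in (s_arr[j], d_arr[j]):
                if p >= 0:
                    if p in L:
                        L[p] += 0.5 * lj
                    else:
                        L[p] = 0.5 * lj
                        heapq.heappush(heap, -int(p))
        F[i] = aii - 1.0
    return F


def inbreeding(ped: Pedigree) -> InbreedingTable:
    """Coefficient of inbreeding for every individual; founders get F = 0."""
    F = inbreeding_array(ped)
    table = {r.id: float(F[k]) for k, r in enumerate(ped.records)}
    cohorts: dict[int, list[float]] = {}
    for k, r in enumerate(ped.records):
        cohorts.setdefault(int(r.cohort), []).append(F[k])
    by_cohort = {c: float(np.mean(v)) for c, v in sorted(cohorts.items())}
    return InbreedingTable(F=table, by_cohort_mean=by_cohort)


def _kinship_idx(ped: Pedigree, i: int, j: int) -> float:
    cache = ped._kin_cache
    s_arr, d_arr = ped.sire_idx, ped.dam_idx

    def kin(a: int, b: int) -> float:
        if a < 0 or b < 0:
            return 0.0
        if a > b:
            a, b = b, a
        key = (a, b)
        v = cache.get(key)
        if v is not None:
            return v
        if a == b:
            v = 0.5 * (1.0 + kin(int(s_arr[a]), int(d_arr[a])))
        else:
            # b is later in topological order, hence not an ancestor of a
            v = 0.5 * (kin(a, int(s_arr[b])) + kin(a, int(d_arr[b])))
        cache[key] = v
        return v

    return kin(i, j)


def kinship(ped: Pedigree, a: str, b: str) -> float:
    """Coefficient of kinship (coancestry) between two individuals.

    ``kinship(x, x) = (1 + F_x)/2`` and the predicted inbreeding
    coefficient of a litter out of (a, b) equals ``kinship(a, b)``.
    """
    return _kinship_idx(ped, ped.index(a), ped.index(b))


def predicted_litter_f(ped: Pedigree, sire: str, dam: str) -> float:
    """Predicted inbreeding of offspring of the pair, before any mating."""
    return kinship(ped, sire, dam)


def relationship_matrix(ped: Pedigree) -> np.ndarray:
    """Dense numerator-relationship matrix A by the tabular recursion.

    Quadratic in pedigree size; intended for moderate pedigrees and as the
    backing store of the simulator. ``inbreeding`` is the linear-time path.
    """
    n = ped.n
    A = np.zeros((n, n), dtype=float)
    s_arr, d_arr = ped.sire_idx, ped.dam_idx
    for i in range(n):
        s, d = s_arr[i], d_arr[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def a_inverse(ped: Pedigree, table: InbreedingTable | None = None) -> sparse.csr_matrix:
    """Sparse A⁻¹ from Henderson's rules, accounting for inbreeding.

    Each individual contributes 1/D_i to its own diagonal, −1/(2 D_i) to
    the individual×parent cells and 1/(4 D_i) to the parent×parent cells,
    where D_i is the Mendelian sampling variance scalar given parental F.
    """
    F = table.as_array(ped) if table is not None else inbreeding_array(ped)
    n = ped.n
    D = _mendelian_d(ped.sire_idx, ped.dam_idx, F)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        di = 1.0 / D[i]
        parents = [p for p in (ped.sire_idx[i], ped.dam_idx[i]) if p >= 0]
        rows.append(i); cols.append(i); vals.append(di)
        for p in parents:
            rows += [i, p]
            cols += [p, i]
            vals += [-0.5 * di, -0.5 * di]
        for p in parents:
            for q in parents:
                rows.append(int(p)); cols.append(int(q)); vals.append(0.25 * di)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


# -- inbreeding rate ----------------------------------------------------------

@dataclass(frozen=True)
class InbreedingRate:
    """Per-generation inbreeding rate between two cohorts.

    ``rate`` is in percentage points of mean F per generation; ``delta_f``
    is the same rate as a fraction; ``ne`` is the implied effective
    population size 1/(2 ΔF), ``None`` when ΔF ≤ 0.
    """

    method: str
    rate: float
    delta_f: float
    ne: float | None


def inbreeding_rate(
    table: InbreedingTable,
    from_cohort: int,
    to_cohort: int,
    method: str = "endpoint",
) -> InbreedingRate:
    """Rate of inbreeding increase between two cohorts.

    ``endpoint`` is the arithmetic used when quoting 'mean F rose from a to
    b over k generations': (F_to − F_from)/(to − from), reported in
    percentage points per generation. ``classical`` is the standardized
    rate ΔF = (F_t − F_{t−1})/(1 − F_{t−1}) averaged over the observed
    cohort steps (per unit cohort).
    """
    means = table.by_cohort_mean
    for c in (from_cohort, to_cohort):
        if c not in means:
            raise ValueError(f"cohort {c} not present in inbreeding table")
    if to_cohort <= from_cohort:
        raise ValueError("to_cohort must exceed from_cohort")
    if method == "endpoint":
        frac = (means[to_cohort] - means[from_cohort]) / (to_cohort - from_cohort)
    elif method == "classical":
        cohorts = sorted(c for c in means if from_cohort <= c <= to_cohort)
        steps = []
        for prev, cur in zip(cohorts, cohorts[1:]):
            step = (means[cur] - means[prev]) / (1.0 - means[prev])
            steps.append(step / (cur - prev))
        frac = float(np.mean(steps))
    else:
        raise ValueError(f"unknown method {method!r}")
    ne = 1.0 / (2.0 * frac) if frac > 0 else None
    return InbreedingRate(method=method, rate=100.0 * frac, delta_f=frac, ne=ne)
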