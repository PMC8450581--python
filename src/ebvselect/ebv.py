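"""Estimated breeding values from Henderson's mixed-model equations.

Linear traits are solved exactly from the sparse MME

    [ X'X   X'Z          ] [b]   [X'y]
    [ Z'X   Z'Z + lam A⁻¹] [a] = [Z'y],   lam = sigma2_e / sigma2_a,

so every pedigree member — phenotyped or not — receives an EBV. Binary
traits are handled by the liability threshold model fitted with Gibbs
sampling (truncated-normal data augmentation; residual variance fixed at
1 for identifiability). ``summarize`` attaches the accuracy derived from
prediction-error variance and the percentile rank within a declared
reference cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, sparse
from scipy.sparse.linalg import splu

from .pedigree import InbreedingTable
from .phenotypes import DesignSet
from .reml import VarianceComponents

DENSE_CUTOFF = 2000  # below this many equations, solve densely


class EbvError(ValueError):
    """Invalid input to breeding-value estimation."""


@dataclass(frozen=True)
class BlupResult:
    """Solutions of the mixed-model equations for one trait."""

    ebv: np.ndarray                      # one entry per pedigree member
    fixed_effects: dict[str, float]
    vc: VarianceComponents
    trait: str | None = None
    pev: np.ndarray | None = None        # prediction-error variance per animal
    residuals: np.ndarray | None = None

    def as_mapping(self, ids: Sequence[str]) -> dict[str, float]:
        return {i: float(v) for i, v in zip(ids, self.ebv)}


def _check_fixed_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    if X.shape[1] == 0:
        return
    _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = [columns[j] for j in piv[rank:]]
        raise EbvError(f"singular fixed-effect block; confounded columns: {bad}")


def _mme(design: DesignSet, ainv: sparse.spmatrix, lam: float):
    n, p, q = design.n, design.X.shape[1], ainv.shape[0]
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), design.animal_rows)), shape=(n, q)
    )
    X = design.X
    C11 = sparse.csr_matrix(X.T @ X) if p else sparse.csr_matrix((0, 0))
    C12 = sparse.csr_matrix(X.T @ Z) if p else sparse.csr_matrix((0, q))
    C22 = (Z.T @ Z) + lam * sparse.csr_matrix(ainv)
    C = sparse.bmat([[C11, C12], [C12.T, C22]], format="csc")
    rhs = np.concatenate([X.T @ design.y if p else np.empty(0), Z.T @ design.y])
    return C, rhs, Z


def blup_linear(
    design: DesignSet,
    ainv: sparse.spmatrix,
    vc: VarianceComponents,
    compute_pev: bool = False,
) -> BlupResult:
    """Solve the MME for fixed effects and EBVs of all pedigree members.

    With no phenotype records every EBV is the prior mean 0. The system is
    solved densely below ``DENSE_CUTOFF`` equations and by sparse LU above
    it; both routes are exact.
    """
    q = ainv.shape[0]
    trait_name = design.trait.name if design.trait else None
    if design.n == 0:
        pev = (np.full(q, vc.sigma2_a) if compute_pev else None)
        return BlupResult(ebv=np.zeros(q), fixed_effects={}, vc=vc,
                          trait=trait_name, pev=pev)
    _check_fixed_rank(design.X, design.columns)
    p = design.X.shape[1]
    C, rhs, Z = _mme(design, ainv, vc.lam)
    m = C.shape[0]
    if m <= DENSE_CUTOFF:
        Cd = C.toarray()
        cho = linalg.cho_factor(Cd)
        sol = linalg.cho_solve(cho, rhs)
        if compute_pev:
            Cinv = linalg.cho_solve(cho, np.eye(m))
            pev = vc.sigma2_e * np.diag(Cinv)[p:]
        else:
            pev = None
    else:
        lu = splu(C)
        sol = lu.solve(rhs)
        if compute_pev:
            pev = np.empty(q)
            eye_block = np.zeros((m, 512))
            for start in range(0, q, 512):
                stop = min(start + 512, q)
                blk = eye_block[:, : stop - start]
                blk[:] = 0.0
                blk[p + np.arange(start, stop), np.arange(stop - start)] = 1.0
                pev[start:stop] = vc.sigma2_e * lu.solve(blk)[
                    p + np.arange(start, stop), np.arange(stop - start)
                ]
        else:
            pev = None
    b, a = sol[:p], sol[p:]
    resid = design.y - (design.X @ b if p else 0.0) - Z @ a
    fixed = dict(zip(design.columns, map(float, b)))
    return BlupResult(ebv=a, fixed_effects=fixed, vc=vc, trait=trait_name,
                      pev=pev, residuals=resid)


def blup_multitrait(
    designs: Sequence[DesignSet],
    ainv: sparse.spmatrix,
    G: np.ndarray,
    R: np.ndarray,
) -> list[BlupResult]:
    """Multi-trait BLUP with user-supplied genetic (G) and residual (R)
    covariance matrices, for traits recorded on the same observations.

    The Kronecker-structured MME is assembled densely; intended for the
    moderate systems where known covariances are actually available.
    Covariance estimation is deliberately out of scope.
    """
    t = len(designs)
    G = np.asarray(G, dtype=float)
    R = np.asarray(R, dtype=float)
    if G.shape != (t, t) or R.shape != (t, t):
        raise EbvError("G and R must be t x t for t traits")
    base = designs[0]
    for d in designs[1:]:
        if (d.n != base.n or not np.array_equal(d.animal_rows, base.animal_rows)
                or d.X.shape != base.X.shape or not np.allclose(d.X, base.X)):
            raise EbvError("multi-trait solve requires identical designs across traits")
    _check_fixed_rank(base.X, base.columns)
    n, p, q = base.n, base.X.shape[1], ainv.shape[0]
    Z = sparse.csr_matrix((np.ones(n), (np.arange(n), base.animal_rows)), shape=(n, q))
    W = np.hstack([base.X, Z.toarray()])
    Rinv = np.linalg.inv(R)
    Ginv = np.linalg.inv(G)
    WtW = W.T @ W
    C = np.kron(Rinv, WtW)
    Ad = np.asarray(ainv.todense())
    prior = np.kron(Ginv, Ad)
    idx_a = np.concatenate([k * (p + q) + p + np.arange(q) for k in range(t)])
    C[np.ix_(idx_a, idx_a)] += prior
    Y = np.column_stack([d.y for d in designs])        # n x t
    rhs = (W.T @ Y @ Rinv).T.reshape(-1)               # trait-major
    sol = np.linalg.solve(C, rhs)
    out = []
    for k, d in enumerate(designs):
        blk = sol[k * (p + q): (k + 1) * (p + q)]
        b, a = blk[:p], blk[p:]
        resid = d.y - (d.X @ b if p else 0.0) - Z @ a
        vc = VarianceComponents(sigma2_a=float(G[k, k]), sigma2_e=float(R[k, k]))
        out.append(BlupResult(ebv=a, fixed_effects=dict(zip(d.columns, map(float, b))),
                              vc=vc, trait=d.trait.name if d.trait else None,
                              residuals=resid))
    return out


# -- threshold (liability) model ----------------------------------------------

@dataclass(frozen=True)
class GibbsConfig:
    """Chain settings for the threshold model.

    Defaults follow common practice for single-trait threshold analyses:
    10,000 rounds, 2,000 burn-in, thinning 10. The seed is mandatory so
    that analyses are reproducible. ``sigma2_a`` initializes (or, with
    ``sample_variance=False``, fixes) the genetic variance on the
    liability scale; the residual variance is fixed at 1.
    """

    seed: int
    n_iter: int = 10_000
    burn_in: int = 2_000
    thin: int = 10
    sigma2_a: float = 0.5
    sample_variance: bool = True
    nu0: float = 4.0

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise EbvError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise EbvError("thinning interval must be >= 1")


@dataclass(frozen=True)
class GibbsResult:
    """Posterior summaries of the threshold-model chain."""

    ebv: np.ndarray                       # posterior-mean liabilities (q,)
    fixed_effects: dict[str, float]
    sigma2_a_mean: float
    ess: dict[str, float]
    n_samples: int
    trait: str | None = None


def gibbs_threshold(
    design: DesignSet,
    ainv: sparse.spmatrix,
    chain: GibbsConfig,
) -> GibbsResult:
    """Threshold-model EBVs for a binary trait via Gibbs sampling.

    Data augmentation draws the latent liabilities from truncated normals
    around the current location, then fixed and genetic effects jointly
    from their Gaussian full conditional; optionally the genetic variance
    from its scaled inverse chi-square full conditional. Returns
    posterior-mean EBVs on the liability scale with effective-sample-size
    diagnostics (per-parameter ESS via arviz).
    """
    y = design.y
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise EbvError(
            "threshold model needs a binary response with both classes present; "
            f"observed classes {classes.tolist()}"
        )
    _check_fixed_rank(design.X, design.columns)
    rng = np.random.default_rng(chain.seed)
    n, p, q = design.n, design.X.shape[1], ainv.shape[0]
    Z = sparse.csr_matrix((np.ones(n), (np.arange(n), design.animal_rows)), shape=(n, q))
    W = np.hstack([design.X, Z.toarray()])
    WtW = W.T @ W
    Ad = np.asarray(ainv.todense())
    pos = y == 1.0

    theta = np.zeros(p + q)
    sa = float(chain.sigma2_a)
    s0 = float(chain.sigma2_a)
    liab = np.where(pos, 0.5, -0.5)

    keep = 0
    ebv_sum = np.zeros(q)
    b_sum = np.zeros(p)
    sa_chain: list[float] = []
    track = min(q, 5)
    a_chain: list[np.ndarray] = []

    from scipy.special import ndtr, ndtri

    tiny = np.finfo(float).tiny
    for it in range(chain.n_iter):
        mu = W @ theta
        # inverse-CDF draw from the truncated normal around mu:
        # y=1 -> liability > 0, y=0 -> liability <= 0
        p0 = ndtr(-mu)                    # P(liab <= 0 | mu)
        u = rng.random(n)
        u = np.where(pos, p0 + u * (1.0 - p0), u * p0)
        liab = mu + ndtri(np.clip(u, tiny, 1.0 - 1e-16))
        C = WtW.copy()
        C[p:, p:] += Ad / sa
        cho = linalg.cho_factor(C)
        mean = linalg.cho_solve(cho, W.T @ liab)
        z = rng.standard_normal(p + q)
        # C = R'R (upper Cholesky); mean + R^-1 z has covariance C^-1
        theta = mean + linalg.solve_triangular(cho[0], z, lower=cho[1])
        if chain.sample_variance:
            a = theta[p:]
            scale = a @ (Ad @ a) + chain.nu0 * s0
            sa = scale / rng.chisquare(q + chain.nu0)
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0:
            keep += 1
            ebv_sum += theta[p:]
            b_sum += theta[:p]
            sa_chain.append(sa)
            a_chain.append(theta[p: p + track].copy())
    import arviz  # heavy import; only needed for diagnostics

    ess = {"sigma2_a": float(arviz.ess(np.asarray(sa_chain)[None, :]))}
    a_arr = np.asarray(a_chain)
    for j in range(track):
        ess[f"a[{j}]"] = float(arviz.ess(a_arr[None, :, j]))
    fixed = dict(zip(design.columns, (b_sum / keep).tolist()))
    return GibbsResult(
        ebv=ebv_sum / keep, fixed_effects=fixed,
        sigma2_a_mean=float(np.mean(sa_chain)), ess=ess, n_samples=keep,
        trait=design.trait.name if design.trait else None,
    )


# -- reporting ----------------------------------------------------------------

def accuracy_from_pev(pev: np.ndarray, F: np.ndarray, sigma2_a: float) -> np.ndarray:
    """r = sqrt(1 - PEV / ((1 + F) sigma2_a)), clamped into [0, 1].

    An animal with no information has PEV = (1 + F) sigma2_a, hence r = 0;
    an animal whose breeding value were known exactly would have r = 1.
    """
    rel = 1.0 - pev / ((1.0 + np.asarray(F)) * sigma2_a)
    return np.sqrt(np.clip(rel, 0.0, 1.0))


def summarize(
    ebvs: Mapping[str, float],
    vc: VarianceComponents,
    pev: Mapping[str, float],
    F: InbreedingTable,
    cohort: Sequence[str],
    trait: str | None = None,
) -> pd.DataFrame:
    """Per-dog EBV report: value, accuracy, percentile within a cohort.

    The percentile is 100 x (number of cohort members with strictly lower
    EBV) / (cohort size) — ties do not raise a dog's rank.
    """
    cohort = list(cohort)
    if not cohort:
        raise EbvError("reference cohort is empty")
    missing = [c for c in cohort if c not in ebvs]
    if missing:
        raise EbvError(f"cohort members without EBVs: {missing[:5]}")
    cohort_vals = np.sort(np.array([ebvs[c] for c in cohort], dtype=float))
    rows = []
    for dog, val in ebvs.items():
        p_i = pev[dog]
        acc = float(accuracy_from_pev(np.array([p_i]),
                                      np.array([F.F.get(dog, 0.0)]),
                                      vc.sigma2_a)[0])
        below = int(np.searchsorted(cohort_vals, val, side="left"))
        rows.append(
            {"dog_id": dog, "trait": trait, "ebv": float(val), "accuracy": acc,
             "percentile": 100.0 * below / len(cohort)}
        )
    return pd.DataFrame(rows)
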