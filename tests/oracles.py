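"""Independent oracles: naive quadratic pedigree recursions and a dense
generalized-least-squares route to BLUP, kept deliberately separate from
the package's own algorithms."""

import numpy as np


def tabular_relationship(sire_idx, dam_idx):
    """Numerator relationship matrix by the elementwise tabular method."""
    n = len(sire_idx)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire_idx[i], dam_idx[i]
        for j in range(i):
            a_js = A[j, s] if s >= 0 else 0.0
            a_jd = A[j, d] if d >= 0 else 0.0
            A[i, j] = A[j, i] = 0.5 * (a_js + a_jd)
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def dense_gls_ebv(y, X, animal_rows, A, sigma2_a, sigma2_e):
    """Fixed effects by GLS and EBVs by the selection-index identity
    a_hat = sigma2_a A Z' V^{-1} (y - X b_hat), V = Z A Z' sigma2_a + I sigma2_e.
    """
    n = len(y)
    q = A.shape[0]
    Z = np.zeros((n, q))
    Z[np.arange(n), animal_rows] = 1.0
    V = Z @ A @ Z.T * sigma2_a + np.eye(n) * sigma2_e
    Vi = np.linalg.inv(V)
    if X.shape[1]:
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        resid = y - X @ b
    else:
        b = np.empty(0)
        resid = y
    ebv = sigma2_a * (A @ Z.T @ (Vi @ resid))
    return b, ebv
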