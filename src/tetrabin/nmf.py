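"""Non-negative matrix factorization of the transposed TNF matrix.

The 136 x n matrix V = T^T (contigs as columns) is factored as V ~ W H with
W (136 x k) a non-negative basis of tetramer-usage patterns and H (k x n)
non-negative per-contig coefficients. Updates are the classic Euclidean
multiplicative rules

    W <- W * (V H^T) / (W H H^T),   H <- H * (W^T V) / (W^T W H),

which keep both factors non-negative and never increase the squared
reconstruction error. Factors are initialized deterministically by NNDSVD.
The pipeline consumes H^T (n x k) as the per-contig feature block in place
of the raw 136-dimensional frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_EPS = 1e-10  # denominator stabilizer; the bare update rules have no guard


@dataclass
class NMFFactors:
    W: np.ndarray  # (m, k) basis
    H: np.ndarray  # (k, n) coefficients
    k: int
    objective_history: list[float] = field(default_factory=list)

    @property
    def coefficients(self) -> np.ndarray:
        """Per-column features H^T (n x k)."""
        return self.H.T


def nndsvd_init(V: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Plain NNDSVD initialization (zeros kept, no fill-in).

    Splits each of the k leading singular triplets into its non-negative
    parts and keeps the dominant side, giving a deterministic, sparse,
    non-negative starting point.
    """
    U, S, Vt = np.linalg.svd(V, full_matrices=False)
    m, n = V.shape
    W = np.zeros((m, k))
    H = np.zeros((k, n))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    H[0, :] = np.sqrt(S[0]) * np.abs(Vt[0, :])
    for j in range(1, k):
        u, v = U[:, j], Vt[j, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        pos, neg = n_up * n_vp, n_un * n_vn
        if pos >= neg:
            scale = np.sqrt(S[j] * pos)
            if pos > 0:
                W[:, j] = scale * up / n_up
                H[j, :] = scale * vp / n_vp
        else:
            scale = np.sqrt(S[j] * neg)
            W[:, j] = scale * un / n_un
            H[j, :] = scale * vn / n_vn
    return W, H


def nmf_decompose(
    V: np.ndarray,
    k: int = 10,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
) -> NMFFactors:
    """Factor a non-negative matrix by Euclidean multiplicative updates.

    Stops at ``max_iter`` or when the relative decrease of the squared
    reconstruction error falls below ``tol``. Deterministic: NNDSVD
    initialization does not consume randomness (``seed`` is accepted for
    interface uniformity).
    """
    V = np.asarray(V, dtype=np.float64)
    if np.any(V < 0):
        raise ValueError("V must be non-negative")
    m, n = V.shape
    if not (1 <= k <= min(m, n)):
        raise ValueError(f"k={k} out of range [1, {min(m, n)}]")

    W, H = nndsvd_init(V, k)
    # Multiplicative updates can never move an entry that starts at exactly
    # zero; raise NNDSVD's structural zeros to a negligible positive floor so
    # the iteration can reach optima outside the initial sparsity pattern.
    floor = 1e-6 * V.mean() if V.mean() > 0 else 1e-6
    W[W == 0] = floor
    H[H == 0] = floor
    history: list[float] = []
    prev = None
    for _ in range(max_iter):
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        err = float(np.linalg.norm(V - W @ H) ** 2)
        history.append(err)
        if prev is not None and prev > 0 and (prev - err) / prev < tol:
            break
        prev = err
    return NMFFactors(W=W, H=H, k=k, objective_history=history)


def reconstruction_error(V: np.ndarray, factors: NMFFactors) -> float:
    """Relative Frobenius reconstruction error ||V - WH||_F / ||V||_F."""
    return float(np.linalg.norm(V - factors.W @ factors.H) / np.linalg.norm(V))


def rank_scan(
    V: np.ndarray,
    k_values,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Relative reconstruction error for each candidate rank, sorted by k.

    Used to pick the coefficient dimension: the error curve flattens past
    the effective rank of the tetramer-usage structure.
    """
    out = []
    for k in sorted(k_values):
        factors = nmf_decompose(V, k=k, max_iter=max_iter, tol=tol, seed=seed)
        out.append((k, reconstruction_error(V, factors)))
    return out
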