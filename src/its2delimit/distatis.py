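"""DISTATIS: fuse several distance tables into one compromise matrix.

Each distance table D_k is converted to a cross-product matrix
S_k = -1/2 Xi Delta Xi' (Torgerson double-centering, with Delta = D_k
element-squared by default), normalised to unit first eigenvalue
(MFA norm), and the tables are weighted by the first eigenvector of
their RV-coefficient matrix. The compromise S+ = sum_k alpha_k S~_k is
the best aggregate of the tables; d+_ij = s+_ii + s+_jj - 2 s+_ij turns
it back into a distance table for tree building.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DistanceMatrix

PSD_TOL = 1e-8


def double_center(
    d: DistanceMatrix,
    masses: np.ndarray | None = None,
    square_first: bool = True,
) -> np.ndarray:
    """Distance-to-cross-product transform S = -1/2 Xi Delta Xi'.

    ``masses`` are positive row weights summing to one (uniform by
    default); Xi = I - 1 m'. Row and column weighted means of S are zero.
    """
    n = len(d)
    if masses is None:
        masses = np.full(n, 1.0 / n)
    masses = np.asarray(masses, dtype=float)
    if masses.shape != (n,) or np.any(masses <= 0):
        raise ValueError("masses must be positive, one per taxon")
    if abs(masses.sum() - 1.0) > 1e-10:
        raise ValueError(f"masses sum to {masses.sum():.12f}, expected 1")
    delta = d.values ** 2 if square_first else d.values.copy()
    xi = np.eye(n) - np.outer(np.ones(n), masses)
    return -0.5 * xi @ delta @ xi.T


def mfa_normalize(s: np.ndarray, tol: float = 1e-12) -> tuple[np.ndarray, float]:
    """Scale a cross-product matrix to unit first eigenvalue (MFA norm)."""
    s = np.asarray(s, dtype=float)
    if not np.allclose(s, s.T, atol=1e-8):
        raise ValueError("cross-product matrix must be symmetric")
    lam1 = float(np.linalg.eigvalsh(s)[-1])
    if lam1 <= tol:
        raise ValueError(f"degenerate table: first eigenvalue {lam1:g} <= {tol:g}")
    return s / lam1, lam1


def rv_coefficient(s1: np.ndarray, s2: np.ndarray) -> float:
    """Matrix correlation RV = tr(S1 S2) / sqrt(tr(S1 S1) tr(S2 S2))."""
    s1 = np.asarray(s1, float)
    s2 = np.asarray(s2, float)
    if s1.shape != s2.shape:
        raise ValueError("RV coefficient requires same-shape matrices")
    n1 = float((s1 * s1).sum())
    n2 = float((s2 * s2).sum())
    if n1 <= 0 or n2 <= 0:
        raise ValueError("RV coefficient undefined for zero-norm input")
    return float((s1 * s2).sum() / np.sqrt(n1 * n2))


@dataclass
class CompromiseResult:
    """Everything the integration step computes."""

    tables: list[str]
    labels: list[str]
    cross_products: list[np.ndarray]
    normalized: list[np.ndarray]
    first_eigenvalues: list[float]
    rv_matrix: np.ndarray
    alpha: np.ndarray
    compromise: np.ndarray
    compromise_distance: DistanceMatrix
    n_factors_kept: int
    factor_scores: np.ndarray = field(default=None, repr=False)
    eigenvalues: np.ndarray = field(default=None, repr=False)
    negative_eigenmass: float = 0.0


def compromise_to_distance(
    s_plus: np.ndarray, labels: list[str], neg_tol: float = -1e-8
) -> DistanceMatrix:
    """Invert a cross-product matrix to distances: d_ij = s_ii+s_jj-2s_ij."""
    s_plus = np.asarray(s_plus, float)
    diag = np.diag(s_plus)
    d = diag[:, None] + diag[None, :] - 2.0 * s_plus
    if d.min() < neg_tol:
        raise ValueError(
            f"negative squared distance {d.min():g}: input is not PSD"
        )
    d = np.clip(d, 0.0, None)
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(labels, d)


def compute_compromise(
    tables: list[DistanceMatrix],
    table_names: list[str] | None = None,
    masses: np.ndarray | None = None,
    square_first: bool = True,
    n_factors_kept: int = 2,
) -> CompromiseResult:
    """Run the full integration: center, normalise, weight, and sum.

    Tables must share a label set; orders are reconciled to the first
    table. The table weights alpha are the (positive) Perron eigenvector
    of the RV matrix rescaled to sum one.
    """
    if len(tables) < 2:
        raise ValueError("need at least two tables")
    if table_names is None:
        table_names = [f"table{k+1}" for k in range(len(tables))]
    labels = tables[0].labels
    ref = set(labels)
    aligned = [tables[0]]
    for t in tables[1:]:
        if set(t.labels) != ref:
            missing = sorted(ref ^ set(t.labels))
            raise ValueError(f"label mismatch between tables: {missing}")
        aligned.append(t.reorder(labels))

    cross, normed, lam1s = [], [], []
    for t in aligned:
        s = double_center(t, masses=masses, square_first=square_first)
        s_t, lam1 = mfa_normalize(s)
        cross.append(s)
        normed.append(s_t)
        lam1s.append(lam1)

    K = len(aligned)
    C = np.eye(K)
    for a in range(K):
        for b in range(a + 1, K):
            C[a, b] = C[b, a] = rv_coefficient(normed[a], normed[b])

    evals, evecs = np.linalg.eigh(C)
    perron = evecs[:, -1]
    if perron.sum() < 0:
        perron = -perron
    if np.any(perron < -1e-10):
        raise ValueError("Perron eigenvector has mixed signs; RV matrix invalid")
    alpha = np.clip(perron, 0.0, None)
    alpha = alpha / alpha.sum()

    s_plus = sum(a_k * s_k for a_k, s_k in zip(alpha, normed))
    # With squared distances, the transform back to d+ is elementwise the
    # alpha-weighted mean of the normalized squared tables, so d+ is
    # non-negative even when non-Euclidean inputs (edit distances, model
    # distances) make the compromise indefinite. The indefiniteness only
    # affects the factor decomposition; its mass is reported.
    d_plus = compromise_to_distance(s_plus, labels)

    w, v = np.linalg.eigh(s_plus)
    neg_mass = float(-w[w < -PSD_TOL].sum())
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    kept = min(n_factors_kept, len(w))
    scores = v[:, :kept] * np.sqrt(np.clip(w[:kept], 0.0, None))

    return CompromiseResult(
        tables=list(table_names),
        labels=list(labels),
        cross_products=cross,
        normalized=normed,
        first_eigenvalues=lam1s,
        rv_matrix=C,
        alpha=alpha,
        compromise=s_plus,
        compromise_distance=d_plus,
        n_factors_kept=kept,
        factor_scores=scores,
        eigenvalues=w,
        negative_eigenmass=neg_mass,
    )
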