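"""Sparse-representation feature ranking via orthogonal matching pursuit.

The cohort feature table is treated as a dictionary whose atoms are the
z-scored, unit-normalised feature columns; the class label vector
(encoded -1/+1) is the target signal ``s`` in ``s = D @ beta``.  OMP
greedily builds a sparse ``beta`` and its entries — the sparse
representation coefficients (SRCs) — weight feature importance.  The
returned ranking places OMP-selected features first (descending |beta|)
and extends past the support by descending absolute correlation with the
target, so a downstream incremental feature sweep can use any length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rf_core import ValidationError

__all__ = ["SRCRanking", "standardize", "omp", "rank_by_src"]


@dataclass
class SRCRanking:
    """Descending-importance permutation of feature indices."""

    order: np.ndarray  # permutation of range(n_features)
    beta: np.ndarray  # SRC per feature, 0 off the OMP support
    abs_corr: np.ndarray  # |<target, atom>| per feature
    n_nonzero: int

    def __post_init__(self) -> None:
        n = self.beta.size
        if sorted(self.order.tolist()) != list(range(n)):
            raise ValidationError("order is not a permutation")


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Column z-scoring (population sd). Returns (Xs, mean, sd, zero_variance_flags).

    Zero-variance columns are left at 0 and flagged; as dictionary atoms
    they are never selectable.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D table with >= 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    flat = sd == 0
    sd_safe = np.where(flat, 1.0, sd)
    Xs = (X - mean) / sd_safe
    Xs[:, flat] = 0.0
    return Xs, mean, sd, flat


def omp(
    dictionary: np.ndarray,
    target: np.ndarray,
    max_atoms: int,
    tol: float = 1e-6,
) -> tuple[np.ndarray, list[float]]:
    """Orthogonal matching pursuit.

    ``dictionary`` holds unit-normalised atoms as columns.  Per iteration
    the atom with the largest absolute inner product with the residual is
    added (ties broken by lowest index), the coefficients are refit by
    least squares on the active set, and the residual updated.  Stops at
    ``max_atoms`` atoms, residual norm <= ``tol``, a zero best
    correlation, or a rank-deficient active set (offending atom dropped).

    Returns ``(beta, residual_norms)`` where ``residual_norms`` starts at
    ``||target||`` and is nonincreasing.
    """
    D = np.asarray(dictionary, dtype=np.float64)
    y = np.asarray(target, dtype=np.float64).ravel()
    if D.ndim != 2 or D.shape[0] != y.size:
        raise ValidationError("dictionary/target shape mismatch")
    if max_atoms < 1:
        raise ValidationError("max_atoms must be >= 1")
    n, m = D.shape
    beta = np.zeros(m)
    active: list[int] = []
    residual = y.copy()
    norms = [float(np.linalg.norm(residual))]
    coef = np.zeros(0)
    while len(active) < min(max_atoms, n, m):
        corr = D.T @ residual
        corr[active] = 0.0
        best = int(np.argmax(np.abs(corr)))  # argmax takes the lowest index on ties
        if corr[best] == 0.0:
            break
        trial = active + [best]
        A = D[:, trial]
        sol, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        if rank < len(trial):
            break  # offending atom dropped; support frozen
        active = trial
        coef = sol
        residual = y - A @ coef
        norms.append(float(np.linalg.norm(residual)))
        if norms[-1] <= tol:
            break
    beta[active] = coef
    return beta, norms


def rank_by_src(
    X: np.ndarray,
    labels: np.ndarray,
    max_atoms: int | None = None,
    tol: float = 1e-6,
) -> SRCRanking:
    """Rank features by SRC importance.

    Features on the OMP support come first, by descending ``|beta|``;
    the remainder follow by descending absolute target-atom correlation.
    All ties break towards the lower original feature index.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels).ravel()
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError("need binary labels with both classes present")
    y = np.where(labels == classes.max(), 1.0, -1.0)
    Xs, _, _, flat = standardize(X)
    col_norm = np.linalg.norm(Xs, axis=0)
    col_norm[col_norm == 0] = 1.0
    atoms = Xs / col_norm
    if max_atoms is None:
        max_atoms = X.shape[0]
    beta, _ = omp(atoms, y, max_atoms=max_atoms, tol=tol)
    abs_corr = np.abs(atoms.T @ y)
    abs_corr[flat] = 0.0
    n_feat = X.shape[1]
    idx = np.arange(n_feat)
    on_support = beta != 0
    # stable sorts with index tie-break: sort by (-key, index)
    sup = idx[on_support]
    sup = sup[np.lexsort((sup, -np.abs(beta[sup])))]
    rest = idx[~on_support]
    rest = rest[np.lexsort((rest, -abs_corr[rest]))]
    order = np.concatenate([sup, rest])
    return SRCRanking(order=order, beta=beta, abs_corr=abs_corr, n_nonzero=int(on_support.sum()))
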