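"""Constrained ordination and permutational multivariate ANOVA on
distance matrices.

CAP (canonical analysis of principal coordinates) follows the two-step
construction of Anderson & Willis: principal coordinates of the
dissimilarity matrix, then canonical discriminant analysis of group
membership on the first m axes, with m chosen (when not given) to minimise
leave-one-out misclassification.  The reported delta^2 values are squared
canonical correlations between the m-dimensional ordination and the group
indicator space.

PERMANOVA uses the direct distance-based sums of squares: SS_total is the
sum of squared dissimilarities over all pairs divided by n, SS_within the
analogous within-group sum, pseudo-F their ratio on (a-1, n-a) degrees of
freedom, and the p-value a label-permutation tail probability with the +1
correction so p is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .diversity import DistanceMatrix


@dataclass
class PcoaResult:
    eigenvalues: np.ndarray          # all eigenvalues, descending
    coordinates: np.ndarray          # n x k, axes with positive eigenvalues
    negative_eigenvalue_mass: float  # |sum of negative eigenvalues|


@dataclass
class CapResult:
    n_pco_axes_used: int
    squared_canonical_correlations: np.ndarray
    sample_scores: np.ndarray
    loo_misclassification_rate: float
    groups: list


@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def pcoa(d: DistanceMatrix) -> PcoaResult:
    """Principal coordinate analysis by Gower double-centering.

    Negative eigenvalues (non-Euclidean input) are retained in
    ``eigenvalues`` and summarised in ``negative_eigenvalue_mass``; only
    positive-eigenvalue axes yield coordinates.
    """
    n = d.n
    a = -0.5 * d.values**2
    centering = np.eye(n) - np.ones((n, n)) / n
    gower = centering @ a @ centering
    eigval, eigvec = np.linalg.eigh((gower + gower.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > 1e-9 * max(eigval.max(), 1.0)
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    return PcoaResult(
        eigenvalues=eigval,
        coordinates=coords,
        negative_eigenvalue_mass=float(-eigval[eigval < 0].sum()),
    )


def _canonical_correlations(coords: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Squared canonical correlations between centered coordinates and
    centered group indicators, via orthonormal bases and an SVD."""
    groups, codes = np.unique(labels, return_inverse=True)
    dummies = np.eye(len(groups))[codes]
    qx, _ = np.linalg.qr(coords - coords.mean(axis=0))
    qy, _ = np.linalg.qr(dummies - dummies.mean(axis=0))
    # rank-deficient blocks contribute zero columns; drop them
    qx = qx[:, np.abs(qx).max(axis=0) > 1e-12]
    qy = qy[:, np.abs(qy).max(axis=0) > 1e-12]
    sv = np.linalg.svd(qx.T @ qy, compute_uv=False)
    k = min(len(groups) - 1, qx.shape[1])
    return np.clip(sv[:k] ** 2, 0.0, 1.0)


def _loo_error(coords: np.ndarray, labels: np.ndarray) -> float:
    """Leave-one-out misclassification of linear discriminant analysis on
    the given ordination coordinates."""
    n = coords.shape[0]
    wrong = 0
    for i in range(n):
        mask = np.arange(n) != i
        lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=1e-6)
        lda.fit(coords[mask], labels[mask])
        wrong += lda.predict(coords[i : i + 1])[0] != labels[i]
    return wrong / n


def cap(
    d: DistanceMatrix,
    groups,
    m: int | str = "auto",
    max_m: int | None = None,
) -> CapResult:
    """Canonical analysis of principal coordinates for group discrimination.

    Parameters
    ----------
    d : DistanceMatrix
    groups : per-sample labels aligned with ``d.sample_ids``
    m : int or "auto"
        Number of PCoA axes carried into the discriminant step.  ``"auto"``
        picks the m with the lowest leave-one-out misclassification rate
        (smallest m on ties).
    """
    labels = np.asarray(list(groups))
    if len(labels) != d.n:
        raise ValueError("groups length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("CAP needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    pco = pcoa(d)
    available = pco.coordinates.shape[1]
    limit = min(available, d.n - 2 if max_m is None else max_m)
    if isinstance(m, int):
        if not 1 <= m < d.n:
            raise ValueError("m must be in [1, n_samples)")
        m_used = min(m, available)
        loo = _loo_error(pco.coordinates[:, :m_used], labels)
    else:
        errors = [
            _loo_error(pco.coordinates[:, :k], labels) for k in range(1, limit + 1)
        ]
        m_used = int(np.argmin(errors)) + 1   # argmin takes the smallest m on ties
        loo = errors[m_used - 1]
    coords = pco.coordinates[:, :m_used]
    delta_sq = _canonical_correlations(coords, labels)

    # canonical sample scores: project onto discriminant directions
    groups_u, codes = np.unique(labels, return_inverse=True)
    dummies = np.eye(len(groups_u))[codes]
    qx, rx = np.linalg.qr(coords - coords.mean(axis=0))
    qy, _ = np.linalg.qr(dummies - dummies.mean(axis=0))
    u, _, _ = np.linalg.svd(qx.T @ qy)
    scores = qx @ u[:, : len(delta_sq)]
    return CapResult(
        n_pco_axes_used=m_used,
        squared_canonical_correlations=delta_sq,
        sample_scores=scores,
        loo_misclassification_rate=float(loo),
        groups=list(uniq),
    )


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from squared dissimilarities and integer labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if len(idx) < 2:
            continue
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_between = ss_total - ss_within
    df_between, df_within = n_groups - 1, n - n_groups
    if ss_within <= 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(
    d: DistanceMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    p = (#{permuted F >= observed F} + 1) / (n_permutations + 1).
    """
    labels = np.asarray(list(groups))
    if len(labels) != d.n:
        raise ValueError("groups length does not match distance matrix")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    if n_permutations < 99:
        raise ValueError("use at least 99 permutations")
    counts = np.bincount(codes)
    if counts.min() < 2:
        import warnings

        warnings.warn("groups of size 1 contribute no within-group sum of squares")
    d2 = d.values**2
    f_obs, r2 = _permanova_f(d2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f_perm, _ = _permanova_f(d2, rng.permutation(codes), len(uniq))
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_permutations)
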