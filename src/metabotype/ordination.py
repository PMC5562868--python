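"""Beta-diversity statistics for pathway-abundance tables.

Rarefaction to even depth, Bray-Curtis dissimilarity, classical
principal-coordinate analysis (PCoA) and one-way PERMANOVA — the
chain used to compare inferred functional profiles between sample
groups.

PCoA is classical scaling: double-center the squared distances and
eigen-decompose. Negative eigenvalues (non-Euclidean distances such
as Bray-Curtis produce them) are reported explicitly and excluded
from the coordinates rather than silently corrected. PERMANOVA
partitions the sum of squared distances between and within groups and
assesses the pseudo-F by seeded label permutation.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

from .containers import FeatureMatrix
from .discrimination import OrdinationResult

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "rarefy",
    "bray_curtis",
    "pcoa",
    "permanova",
]


@dataclasses.dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with sample ids."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("id count does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


@dataclasses.dataclass
class PermanovaResult:
    """One-way PERMANOVA (adonis) summary."""

    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int
    n_groups: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def rarefy(
    counts: FeatureMatrix, depth: int | None = None, seed: int = 0
) -> tuple[FeatureMatrix, list[str]]:
    """Subsample every row without replacement to exactly ``depth`` counts.

    ``depth=None`` uses the minimum row total. Samples whose total is
    below the depth are dropped; their ids are returned alongside the
    rarefied table. Deterministic given ``seed``.
    """
    X = counts.intensities.to_numpy()
    if not np.issubdtype(X.dtype, np.integer):
        if not np.allclose(X, np.round(X)):
            raise ValueError("rarefaction requires integer counts")
        X = np.round(X).astype(np.int64)
    if np.any(X < 0):
        raise ValueError("counts must be non-negative")
    totals = X.sum(axis=1)
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    keep = totals >= depth
    dropped = counts.sample_ids[~keep].tolist()
    rng = np.random.default_rng(seed)
    kept_rows = X[keep]
    out = np.empty_like(kept_rows)
    for i, row in enumerate(kept_rows):
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    sub = counts.subset_samples(counts.sample_ids[keep])
    rarefied = sub.with_intensities(
        pd.DataFrame(out, index=sub.sample_ids, columns=sub.feature_ids)
    )
    return rarefied, dropped


def bray_curtis(m: FeatureMatrix | np.ndarray) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(a,b) = Σ|a−b| / Σ(a+b), in [0, 1]."""
    if isinstance(m, FeatureMatrix):
        X = m.intensities.to_numpy(dtype=float)
        ids = m.sample_ids.tolist()
    else:
        X = np.asarray(m, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
    if np.any(X < 0):
        raise ValueError("Bray-Curtis requires non-negative abundances")
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    if zero_rows.size:
        names = [ids[i] for i in zero_rows]
        raise ValueError(f"all-zero abundance row(s) {names[:5]}; distance undefined")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(d, ids)


def pcoa(d: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for the
    positive eigenvalues only; explained fractions are relative to the
    sum of positive eigenvalues, so they sum to 1 over all positive
    axes. Negative eigenvalues are returned in
    ``negative_eigenvalues``. Sign convention: the largest-magnitude
    coordinate on each axis is positive.
    """
    D = d.values
    n = d.n
    B = -0.5 * (D**2)
    B = B - B.mean(axis=0, keepdims=True) - B.mean(axis=1, keepdims=True) + B.mean()
    eigvals, eigvecs = eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(np.abs(eigvals).max(), 1.0) * 1e-10
    positive = eigvals > tol
    negative = eigvals[eigvals < -tol]
    lam = eigvals[positive]
    V = eigvecs[:, positive]
    coords = V * np.sqrt(lam)
    for j in range(coords.shape[1]):
        lead = np.argmax(np.abs(coords[:, j]))
        if coords[lead, j] < 0:
            coords[:, j] *= -1
    explained = lam / lam.sum() if lam.size else lam
    if n_axes is not None:
        coords = coords[:, :n_axes]
        explained = explained[:n_axes]
    cols = [f"PCo{j + 1}" for j in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=d.ids, columns=cols),
        explained=np.asarray(explained),
        negative_eigenvalues=negative,
    )


def _permanova_stats(
    D2: np.ndarray, group_codes: np.ndarray, n_groups: int
) -> tuple[float, float]:
    """(pseudo-F, R²) from squared distances and integer group codes."""
    n = D2.shape[0]
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(group_codes == g)
        if idx.size > 1:
            sub = D2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0 or df_within == 0:
        f = np.inf if ss_between > 0 else 0.0
    else:
        f = (ss_between / df_between) / (ss_within / df_within)
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2)


def permanova(
    d: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA (adonis) on a distance matrix.

    ``grouping`` assigns every sample to a group (sequence aligned
    with ``d.ids`` or a mapping id → group). The p-value is
    (1 + #{permuted F ≥ observed F}) / (1 + n_permutations) under
    seeded label permutations; R² = SS_between / SS_total.
    """
    if isinstance(grouping, dict):
        groups = np.asarray([grouping[i] for i in d.ids])
    else:
        groups = np.asarray(list(grouping))
    if len(groups) != d.n:
        raise ValueError("grouping length does not match the distance matrix")
    labels, codes = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("PERMANOVA requires at least 2 groups")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    D2 = d.values**2
    f_obs, r2 = _permanova_stats(D2, codes, len(labels))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        f_perm, _ = _permanova_stats(D2, perm, len(labels))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_f=f_obs,
        r_squared=r2,
        p_value=float(p),
        n_permutations=n_permutations,
        n_groups=len(labels),
    )
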