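"""Population-level summaries of multipoint-correlation discrimination.

Across a set of analyzed neurons this module builds the pairwise
discrimination matrix (fraction of neurons whose responses distinguish each
stimulus pair), embeds it with classical (Torgerson) multidimensional
scaling so that inter-point distance corresponds to the fraction of
discriminating neurons, and compares MCDI time courses between groups of
neurons with per-bin Wilcoxon rank-sum tests under Benjamini-Hochberg
correction across the 40 analysis bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .discrimination import MCDIResults, bh_fdr
from .textures import KINDS

__all__ = [
    "DiscriminationMatrix",
    "EmbeddingResult",
    "pair_discrimination_matrix",
    "mds_embed",
    "GroupComparison",
    "compare_groups",
    "population_time_course",
]


@dataclass(frozen=True)
class DiscriminationMatrix:
    """Average pair-specific discrimination across neurons."""

    kinds: tuple[str, ...]
    fractions: pd.DataFrame  # symmetric, diagonal 0, entries in [0, 1]
    n_neurons: int


def pair_discrimination_matrix(
    results: list[MCDIResults] | list[pd.DataFrame],
) -> DiscriminationMatrix:
    """Entry (i, j) = fraction of neurons discriminating kinds i and j.

    Accepts fitted :class:`MCDIResults` or raw 0/1 pair matrices.
    """
    if not results:
        raise ValueError("need at least one neuron")
    mats = [
        r.pair_specific if isinstance(r, MCDIResults) else r for r in results
    ]
    kinds = tuple(mats[0].index)
    acc = sum(m.to_numpy(dtype=float) for m in mats) / len(mats)
    acc = (acc + acc.T) / 2.0
    np.fill_diagonal(acc, 0.0)
    return DiscriminationMatrix(
        kinds, pd.DataFrame(acc, index=kinds, columns=kinds), len(mats)
    )


@dataclass(frozen=True)
class EmbeddingResult:
    kinds: tuple[str, ...]
    coordinates: np.ndarray  # (n_points, k)
    eigenvalues: np.ndarray  # all n eigenvalues of the centered Gram matrix
    variance_explained_2d: float
    stress: float  # residual sum of squared distance errors / total

    def distances(self) -> np.ndarray:
        d = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((d**2).sum(axis=-1))


def mds_embed(matrix: DiscriminationMatrix, k: int = 3) -> EmbeddingResult:
    """Classical (Torgerson) multidimensional scaling of the discrimination
    matrix treated as a distance matrix.

    Double-centers the squared distances, eigendecomposes, keeps the top
    ``k`` nonnegative eigenvalues.  ``variance_explained_2d`` is the share
    of the positive-eigenvalue total carried by the first two dimensions.
    Negative eigenvalues (non-Euclidean input) are truncated and reported.
    """
    D = matrix.fractions.to_numpy(dtype=float)
    n = D.shape[0]
    if k > n - 1:
        raise ValueError(f"k must be at most n_points - 1 = {n - 1}")
    if not np.allclose(D, D.T) or np.any(D < 0):
        raise ValueError("distance matrix must be symmetric and nonnegative")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = np.maximum(vals[:k], 0.0)
    coords = vecs[:, :k] * np.sqrt(pos)
    total_pos = np.sum(np.maximum(vals, 0.0))
    ve2 = float(np.maximum(vals[:2], 0).sum() / total_pos) if total_pos > 0 else 1.0
    fitted = np.sqrt(
        np.maximum(
            (coords[:, None, :] - coords[None, :, :]) .__pow__(2).sum(-1), 0
        )
    )
    denom = (D**2).sum()
    stress = float(((D - fitted) ** 2).sum() / denom) if denom > 0 else 0.0
    return EmbeddingResult(matrix.kinds, coords, vals, ve2, stress)


@dataclass(frozen=True)
class GroupComparison:
    bin_centers_ms: np.ndarray
    p_per_bin: np.ndarray
    q: float
    significant_bins: np.ndarray
    n_a: int
    n_b: int


def compare_groups(
    group_a: np.ndarray,
    group_b: np.ndarray,
    bin_centers_ms: np.ndarray | None = None,
    level: float = 0.05,
) -> GroupComparison:
    """Per-bin two-tailed Wilcoxon rank-sum comparison of MCDI time courses.

    ``group_a`` and ``group_b`` are (n_neurons, n_bins) arrays.  The exact
    null distribution is used for small tie-free samples and the
    tie-corrected normal approximation otherwise; p-values are BH-corrected
    across bins.  Bins where every value in both groups is identical give
    p = 1.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the time grid")
    nbins = a.shape[1]
    p = np.ones(nbins)
    for i in range(nbins):
        x, y = a[:, i], b[:, i]
        if np.ptp(np.concatenate([x, y])) == 0:
            p[i] = 1.0
            continue
        p[i] = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q, mask = bh_fdr(p, level)
    if bin_centers_ms is None:
        bin_centers_ms = np.arange(nbins, dtype=float)
    return GroupComparison(np.asarray(bin_centers_ms), p, q, mask, a.shape[0], b.shape[0])


def population_time_course(
    courses: np.ndarray, percentiles: tuple[float, ...] = (25.0, 50.0, 75.0)
) -> pd.DataFrame:
    """Mean, median and percentile summaries of per-neuron MCDI time courses."""
    c = np.atleast_2d(np.asarray(courses, dtype=float))
    out = {"mean": c.mean(axis=0)}
    for q in percentiles:
        out[f"p{q:g}"] = np.percentile(c, q, axis=0)
    return pd.DataFrame(out)
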