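"""Hellinger distances, principal coordinates analysis and ANOSIM.

The Hellinger distance between two compositions a and b is

    HD(a, b) = sqrt( sum_i (sqrt(a_i) - sqrt(b_i))^2 )

i.e. the Euclidean distance between square-root-transformed
compositions, bounded by sqrt(2) for disjoint supports.  A ``halved``
flag switches to the sqrt(.../2) convention bounded by 1; the two differ
only by the constant factor sqrt(2), so rank-based analyses (ANOSIM) and
PCoA group structure are unaffected by the choice.

PCoA is classical metric scaling: Gower double-centering of -D^2/2
followed by an eigendecomposition, with coordinates scaled by the square
root of the (positive) eigenvalues.  ANOSIM compares mean between-group
vs within-group distance ranks; its permutation p-value uses the add-one
estimator and, on small instances, exact enumeration of all distinct
label assignments.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import comb
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .alpha import _check_composition
from .tables import CompositionTable


def hellinger_distance(a, b, halved: bool = False) -> float:
    """Hellinger distance between two compositions over the same feature set."""
    a = _check_composition(a)
    b = _check_composition(b)
    if a.shape != b.shape:
        raise ValueError("compositions must cover the same features")
    d2 = float(((np.sqrt(a) - np.sqrt(b)) ** 2).sum())
    if halved:
        d2 /= 2.0
    return math.sqrt(d2)


def pairwise_distances(composition: CompositionTable, halved: bool = False) -> DistanceMatrix:
    """Hellinger distance matrix over all sample pairs."""
    root = np.sqrt(composition.values.to_numpy(dtype=float).T)  # samples x features
    d = pdist(root, metric="euclidean")
    if halved:
        d = d / math.sqrt(2.0)
    return DistanceMatrix(squareform(d), ids=composition.sample_ids)


@dataclass(frozen=True)
class PcoaResult:
    coordinates: pd.DataFrame        # samples x retained axes
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray # over positive eigenvalues, per retained axis


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PcoaResult:
    """Principal coordinates analysis of a distance matrix.

    Axes with non-positive eigenvalues are dropped (none arise for
    Hellinger distances, which are Euclidean-embeddable); if ``n_axes``
    exceeds the positive-eigenvalue count, fewer axes are returned with
    a warning.
    """
    d = dm.data
    n = d.shape[0]
    if n_axes is None:
        n_axes = n - 1
    if not 1 <= n_axes <= n - 1:
        raise ValueError(f"n_axes must be in [1, {n - 1}]")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]))
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} axes "
            f"instead of {n_axes}"
        )
        n_axes = max(n_pos, 0)
    coords = eigvecs[:, :n_axes] * np.sqrt(eigvals[:n_axes])
    columns = [f"PC{i + 1}" for i in range(n_axes)]
    total_pos = eigvals[pos].sum() if n_pos else 1.0
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=columns),
        eigenvalues=eigvals,
        proportion_explained=eigvals[:n_axes] / total_pos,
    )


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    method: str                  # "exact" or "permutation"
    groups: tuple[str, ...]


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = len(ranks)
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim(
    dm: DistanceMatrix,
    labels,
    n_permutations: int = 999,
    seed: int | None = None,
    exact: bool | None = None,
) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/4) with
    M = n(n-1)/2 pairwise distances ranked with mid-rank ties.  The
    p-value is (1 + #{R_perm >= R_obs}) / (1 + n_permutations) over
    seeded label permutations, or an exact enumeration over all distinct
    two-group label assignments when there are few enough (``exact=None``
    auto-selects enumeration below 20,000 assignments).
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n != dm.shape[0]:
        raise ValueError("labels length must match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")

    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm.data[iu])
    codes = np.searchsorted(uniq, labels)
    r_obs = _anosim_r(ranks, codes[iu[0]] == codes[iu[1]])

    n_assignments = math.inf
    if len(uniq) == 2:
        n_assignments = comb(n, counts[0], exact=True)
    if exact is None:
        exact = n_assignments <= 20_000
    if exact and len(uniq) != 2:
        raise ValueError("exact enumeration implemented for two groups only")

    if exact:
        hits = 0
        for members in itertools.combinations(range(n), int(counts[0])):
            perm = np.ones(n, dtype=int)
            perm[list(members)] = 0
            r = _anosim_r(ranks, perm[iu[0]] == perm[iu[1]])
            if r >= r_obs - 1e-12:
                hits += 1
        p = hits / n_assignments
        return AnosimResult(r_obs, float(p), int(n_assignments), "exact", tuple(map(str, uniq)))

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        r = _anosim_r(ranks, perm[iu[0]] == perm[iu[1]])
        if r >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(r_obs, float(p), n_permutations, "permutation", tuple(map(str, uniq)))
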