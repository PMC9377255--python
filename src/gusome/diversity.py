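"""Community diversity statistics on abundance tables.

Shannon entropy (alpha diversity, base-2 by default), Bray-Curtis
dissimilarity (beta diversity), classical principal-coordinates analysis
of the resulting distance matrix, and PERMANOVA for group differences.
The ordination is unconstrained classical PCoA: a distance-constrained
ordination with no constraints reduces to exactly this.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


def shannon_index(props: Sequence[float], base: float = 2.0) -> float:
    """Shannon diversity -sum p log_base p over positive entries.

    Input abundances are renormalized internally; negatives are rejected.
    """
    p = np.asarray(props, dtype=float)
    if np.any(p < 0):
        raise ValueError("negative abundance")
    total = p.sum()
    if total <= 0:
        raise ValueError("abundance vector sums to zero")
    p = p[p > 0] / total
    return float(-np.sum(p * np.log(p) / np.log(base)))


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("negative abundance")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.sum(np.abs(x - y)) / denom)


def distance_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis distances between the rows (samples)."""
    ids = list(table.index)
    n = len(ids)
    D = np.zeros((n, n))
    vals = table.to_numpy(dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = bray_curtis(vals[i], vals[j])
    return pd.DataFrame(D, index=ids, columns=ids)


@dataclass
class PcoaResult:
    coordinates: np.ndarray  # samples x axes (positive-eigenvalue axes only)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # over positive eigenvalues


def pcoa(dist: np.ndarray | pd.DataFrame, atol: float = 1e-10) -> PcoaResult:
    """Classical metric scaling of a distance matrix.

    Double-centres the squared-distance Gram matrix and eigendecomposes;
    axes are ordered by eigenvalue, coordinates use positive eigenvalues
    only (negative eigenvalues are reported, not embedded), and each axis
    is oriented so its first nonzero loading is positive.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    pos = evals > atol
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    for k in range(coords.shape[1]):  # deterministic sign convention
        col = coords[:, k]
        nz = np.nonzero(np.abs(col) > atol)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    pos_sum = evals[pos].sum()
    prop = evals[pos] / pos_sum if pos_sum > 0 else np.array([])
    return PcoaResult(coords, evals, prop)


def permanova(
    dist: np.ndarray | pd.DataFrame,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> dict:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F compares among-group to within-group sums of squared
    distances; the p-value uses the add-one permutation convention
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm), so p is never zero.
    """
    D = np.asarray(dist, dtype=float)
    labels = np.asarray(groups)
    n = D.shape[0]
    if labels.shape[0] != n:
        raise ValueError("group labels do not match distance matrix")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    D2 = D**2

    def pseudo_f(lab: np.ndarray) -> float:
        sst = D2[np.triu_indices(n, 1)].sum() / n
        ssw = 0.0
        for g in uniq:
            idx = np.flatnonzero(lab == g)
            if idx.size > 1:
                sub = D2[np.ix_(idx, idx)]
                ssw += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
        ssa = sst - ssw
        a = uniq.size
        denom = ssw / (n - a)
        return np.inf if denom == 0 else (ssa / (a - 1)) / denom

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if pseudo_f(labels[rng.permutation(n)]) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return {
        "pseudo_F": float(f_obs),
        "p_value": float(p),
        "n_permutations": int(n_perm),
        "n_samples": int(n),
        "n_groups": int(uniq.size),
    }
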