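"""Distance-matrix statistics: PERMANOVA, Mantel, and principal coordinates.

All three operate on labelled square distance matrices (pandas DataFrames as
produced by :func:`limnoch4.community.braycurtis`).  PERMANOVA and Mantel are
implemented directly so that an exhaustive-enumeration mode is available for
small designs (``n_perm="all"``), which the permutation p-value must reproduce
in the limit; scikit-bio's equivalents serve as independent cross-checks in
the test suite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform


class DistanceError(ValueError):
    pass


def _check_square(dm: pd.DataFrame) -> np.ndarray:
    a = np.asarray(dm, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise DistanceError("distance matrix must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise DistanceError("distance matrix must be symmetric")
    if not np.allclose(np.diag(a), 0, atol=1e-12):
        raise DistanceError("distance matrix must have a zero diagonal")
    return a


# ----------------------------------------------------------------------
# PERMANOVA
# ----------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    exhaustive: bool


def _pseudo_F(d2: np.ndarray, labels: np.ndarray, levels: np.ndarray) -> float:
    """One-way pseudo-F from squared distances (total minus within partition)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for lev in levels:
        idx = np.flatnonzero(labels == lev)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    a = len(levels)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dm: pd.DataFrame,
    groups,
    n_perm: int | str = 999,
    seed: int | None = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    ``groups`` is a label per sample, aligned with ``dm``'s index.  With
    ``n_perm="all"`` every distinct relabelling is enumerated and the p-value
    is exact (identity included in the numerator and denominator); otherwise
    p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    d = _check_square(dm)
    labels = np.asarray(pd.Series(groups, index=dm.index).loc[dm.index])
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise DistanceError("need at least two groups")
    if (counts < 2).any():
        small = levels[counts < 2].tolist()
        raise DistanceError(f"groups of size 1 not testable: {small}")
    d2 = d**2
    f_obs = _pseudo_F(d2, labels, levels)

    if n_perm == "all":
        hits = total = 0
        seen = set()
        for perm in itertools.permutations(labels):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            if _pseudo_F(d2, np.asarray(perm), levels) >= f_obs - 1e-12:
                hits += 1
        return PermanovaResult(float(f_obs), hits / total, total, True)

    rng = np.random.default_rng(seed)
    hits = 0
    lab = labels.copy()
    for _ in range(int(n_perm)):
        rng.shuffle(lab)
        if _pseudo_F(d2, lab, levels) >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + int(n_perm))
    return PermanovaResult(float(f_obs), p, int(n_perm), False)


# ----------------------------------------------------------------------
# Mantel
# ----------------------------------------------------------------------

@dataclass
class MantelResult:
    rho: float
    p_value: float
    n_permutations: int
    degenerate: bool = False


def mantel(
    dmA: pd.DataFrame,
    dmB: pd.DataFrame,
    method: str = "spearman",
    n_perm: int | str = 999,
    seed: int | None = 0,
) -> MantelResult:
    """Mantel test between two distance matrices over the same samples.

    Correlates the condensed (upper-triangle) entries — Spearman rank by
    default — and obtains the p-value by simultaneously permuting the rows and
    columns of the second matrix.  A zero-variance condensed vector yields a
    flagged null result rather than an error.
    """
    a = _check_square(dmA)
    b = _check_square(dmB)
    if list(dmA.index) != list(dmB.index):
        raise DistanceError("matrices must share labels in the same order")
    n = a.shape[0]
    if n < 3:
        raise DistanceError("need at least three samples")
    condA = squareform(a, checks=False)
    condB = squareform(b, checks=False)
    if np.ptp(condA) == 0 or np.ptp(condB) == 0:
        return MantelResult(float("nan"), float("nan"), 0, degenerate=True)

    if method == "spearman":
        ra = stats.rankdata(condA)
        rb = stats.rankdata(condB)
    elif method == "pearson":
        ra, rb = condA, condB
    else:
        raise DistanceError(f"unknown method {method!r}")
    rb_sq = squareform(rb, checks=False)

    def corr(vecB: np.ndarray) -> float:
        return float(np.corrcoef(ra, vecB)[0, 1])

    rho_obs = corr(rb)

    if n_perm == "all":
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            p_idx = np.asarray(perm)
            vec = squareform(rb_sq[np.ix_(p_idx, p_idx)], checks=False)
            total += 1
            if abs(corr(vec)) >= abs(rho_obs) - 1e-12:
                hits += 1
        return MantelResult(rho_obs, hits / total, total)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(int(n_perm)):
        p_idx = rng.permutation(n)
        vec = squareform(rb_sq[np.ix_(p_idx, p_idx)], checks=False)
        if abs(corr(vec)) >= abs(rho_obs) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + int(n_perm))
    return MantelResult(rho_obs, p, int(n_perm))


# ----------------------------------------------------------------------
# Principal coordinates analysis
# ----------------------------------------------------------------------

@dataclass
class Ordination:
    coordinates: pd.DataFrame      # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray        # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray


def pcoa(dm: pd.DataFrame) -> Ordination:
    """Classical metric multidimensional scaling of a distance matrix.

    Gower-centers -D^2/2 and eigendecomposes it.  Axes are ordered by
    eigenvalue; coordinates exist for positive eigenvalues only and are scaled
    by sqrt(eigenvalue).  Negative eigenvalues (non-Euclidean distances) are
    reported as-is, without Lingoes/Cailliez correction; the proportion
    explained uses the sum of positive eigenvalues as denominator.
    """
    d = _check_square(dm)
    n = d.shape[0]
    if n < 3:
        raise DistanceError("need at least three samples")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > max(eigval.max(), 0) * 1e-12
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    axes = [f"PC{i + 1}" for i in range(pos.sum())]
    prop = np.where(eigval > 0, eigval, 0.0)
    prop = prop / prop.sum()
    if (eigval < -1e-8 * abs(eigval).max()).any():
        warnings.warn("negative eigenvalues present (non-Euclidean distances)")
    return Ordination(
        pd.DataFrame(coords, index=dm.index, columns=axes), eigval, prop
    )
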