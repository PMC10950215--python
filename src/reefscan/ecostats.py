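"""Community statistics for benthic cover tables.

Implements the analysis battery used for reef-transition monitoring:
Shannon diversity H and equitability E per survey; Shapiro-Wilk normality
checks and one-way ANOVA with Tukey HSD on square-root transformed covers;
Bray-Curtis dissimilarities; ANOSIM (rank-based, permutation significance,
run on untransformed covers); and non-metric multidimensional scaling
(Kruskal stress-1, SMACOF with isotonic regression, run on square-root
transformed covers).  The transform split — ANOSIM untransformed, nMDS on
square roots — is deliberate and preserved throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "DiversityResult",
    "CommunityMatrix",
    "AnosimResult",
    "NmdsResult",
    "AnovaResult",
    "shannon",
    "community_matrix",
    "sqrt_transform",
    "normality_test",
    "anova_tukey",
    "bray_curtis",
    "anosim",
    "nmds",
]


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityResult:
    """Shannon index H (nats), equitability E = H / ln(S), category count S."""

    H: float
    E: float
    S: int

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        return round(self.H, ndigits), round(self.E, ndigits)


def shannon(cover: Sequence[float] | pd.Series, S: int | None = None) -> DiversityResult:
    """Shannon diversity of a cover vector.

    Covers are normalized to proportions p_i; H = -sum p_i ln p_i with
    0 ln 0 = 0.  The equitability denominator uses ``S`` categories
    (default: the full length of the vector, zero covers included, so a
    10-group table always normalizes by ln 10).
    """
    p = np.asarray(cover, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("cover must be a nonempty 1-D vector")
    if (p < 0).any():
        raise ValueError("covers must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero cover vector")
    p = p / total
    nz = p > 0
    H = float(-(p[nz] * np.log(p[nz])).sum())
    S = int(S if S is not None else p.size)
    if S < 2:
        raise ValueError("S must be >= 2 for equitability")
    return DiversityResult(H=H, E=H / math.log(S), S=S)


# ---------------------------------------------------------------------------
# Community matrix and transforms
# ---------------------------------------------------------------------------

@dataclass
class CommunityMatrix:
    """Samples x categories percent-cover matrix with sample metadata.

    ``meta`` carries one row per sample (survey, transect, method).  The
    ``transformed`` flag guards against applying the square-root transform
    twice.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    transformed: bool = False

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("cover values must be nonnegative")
        if len(self.values) != len(self.meta):
            raise ValueError("values and meta row counts differ")
        if not self.transformed:
            sums = self.values.sum(axis=1)
            bad = sums[(sums - 100.0).abs() > 0.5]
            if len(bad):
                raise ValueError(f"row sums deviate from 100: {bad.to_dict()}")

    @property
    def labels(self) -> np.ndarray:
        """Survey grouping labels (survey + method for the 2019 pair)."""
        lab = self.meta["survey"].astype(str)
        if "method" in self.meta and self.meta["method"].nunique() > 1:
            lab = lab + "-" + self.meta["method"].astype(str)
        return lab.to_numpy()


def community_matrix(table: pd.DataFrame, categories: Sequence[str] | None = None
                     ) -> CommunityMatrix:
    """Pivot a long cover table into a samples x categories matrix."""
    wide = table.pivot_table(index=["survey", "transect", "method"],
                             columns="category", values="cover_pct",
                             fill_value=0.0, aggfunc="sum")
    if categories is not None:
        wide = wide.reindex(columns=list(categories), fill_value=0.0)
    meta = wide.index.to_frame(index=False)
    return CommunityMatrix(wide.reset_index(drop=True), meta)


def sqrt_transform(matrix: CommunityMatrix) -> CommunityMatrix:
    """Element-wise square root of covers; refuses to run twice."""
    if matrix.transformed:
        raise ValueError("matrix already square-root transformed")
    return CommunityMatrix(np.sqrt(matrix.values), matrix.meta.copy(),
                           transformed=True)


# ---------------------------------------------------------------------------
# Univariate tests
# ---------------------------------------------------------------------------

def normality_test(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk test; returns (W, p).  Constant input is an error."""
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant input has no defined normality statistic")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AnovaResult:
    """One-way ANOVA with Tukey HSD post hoc.

    ``tukey`` has one row per group pair (diff, adjusted p, reject);
    ``letters`` assigns compact same-letter groupings: two groups that share
    a letter are not significantly different.
    """

    F: float
    p: float
    tukey: pd.DataFrame
    letters: dict[str, str]


def _compact_letters(groups: Sequence[str], tukey: pd.DataFrame) -> dict[str, str]:
    """Insert-and-absorb compact letter display from pairwise rejections."""
    ns = {frozenset((a, b)) for a, b, rej in
          zip(tukey["group1"], tukey["group2"], tukey["reject"]) if not rej}
    letters: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letters:
            if all(frozenset((g, h)) in ns for h in s):
                s.add(g)
                placed = True
        if not placed:
            letters.append({g})
    # absorb subsets
    letters = [s for i, s in enumerate(letters)
               if not any(i != j and s < t for j, t in enumerate(letters))]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for s, ch in zip(letters, alphabet):
        for g in s:
            out[g] += ch
    return {g: "".join(sorted(v)) for g, v in out.items()}


def anova_tukey(values_by_group: dict[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA plus Tukey HSD pairwise comparisons.

    Apply to square-root transformed covers of one benthic group across
    survey years.  Requires >= 2 groups with >= 2 replicates each.
    """
    groups = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if len(groups) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    F, p = sps.f_oneway(*arrays)
    flat = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
    if np.ptp(flat) == 0:
        # identical data in every group: F = 0, nothing significant
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
        tukey = pd.DataFrame({"group1": [a for a, _ in pairs],
                              "group2": [b for _, b in pairs],
                              "meandiff": 0.0, "p_adj": 1.0, "reject": False})
        return AnovaResult(0.0, 1.0, tukey, _compact_letters(groups, tukey))
    res = pairwise_tukeyhsd(flat, labels)
    uniq = list(res.groupsunique)
    pairs = [(uniq[i], uniq[j]) for i in range(len(uniq))
             for j in range(i + 1, len(uniq))]
    tukey = pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "meandiff": np.asarray(res.meandiffs, dtype=float),
        "p_adj": np.asarray(res.pvalues, dtype=float),
        "reject": np.asarray(res.reject, dtype=bool),
    })
    return AnovaResult(float(F), float(p), tukey,
                       _compact_letters(groups, tukey))


# ---------------------------------------------------------------------------
# Multivariate: Bray-Curtis, ANOSIM, nMDS
# ---------------------------------------------------------------------------

def bray_curtis(matrix: CommunityMatrix | np.ndarray | pd.DataFrame) -> np.ndarray:
    """Square symmetric Bray-Curtis dissimilarity matrix.

    d(x, y) = sum|x_i - y_i| / sum(x_i + y_i); zero diagonal, values in [0, 1].
    """
    x = matrix.values if isinstance(matrix, CommunityMatrix) else matrix
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative data")
    return squareform(pdist(x, metric="braycurtis"))


@dataclass(frozen=True)
class AnosimResult:
    """ANOSIM statistic and permutation significance."""

    R: float
    p: float
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-9 <= self.R <= 1.0 + 1e-9):
            raise ValueError("R outside [-1, 1]")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p outside (0, 1]")


def _anosim_r(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    within = rank_matrix[iu][same[iu]]
    between = rank_matrix[iu][~same[iu]]
    denom = n * (n - 1) / 4.0
    return float((between.mean() - within.mean()) / denom)


def anosim(
    dissim: np.ndarray,
    labels: Sequence[str],
    n_permutations: int = 9999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities on a dissimilarity matrix.

    All pairwise dissimilarities are ranked (average ranks on ties);
    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    so R is invariant under any monotone transform of the dissimilarities.
    Significance is the +1-corrected permutation p-value under random
    relabeling, deterministic per seed.  Run this on UNtransformed covers.
    """
    d = np.asarray(dissim, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if d.shape != (n, n):
        raise ValueError("dissimilarity matrix shape must match labels")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
        raise ValueError("not a valid dissimilarity matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs >= 2 groups")
    if (counts < 2).any():
        small = uniq[counts < 2]
        raise ValueError(f"groups of size 1 are not allowed: {list(small)}")

    iu = np.triu_indices(n, k=1)
    ranks_flat = sps.rankdata(d[iu])
    rank_matrix = np.zeros_like(d)
    rank_matrix[iu] = ranks_flat
    rank_matrix = rank_matrix + rank_matrix.T

    r_obs = _anosim_r(rank_matrix, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _anosim_r(rank_matrix, labels[perm]) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return AnosimResult(R=r_obs, p=float(p), n_permutations=n_permutations,
                        seed=seed)


@dataclass
class NmdsResult:
    """Non-metric MDS ordination: coordinates, Kruskal stress-1, diagnostics."""

    coordinates: np.ndarray
    stress: float
    n_restarts: int
    converged: bool
    stress_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stress < 0:
            raise ValueError("stress must be nonnegative")


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:k]
    return v[:, idx] * np.sqrt(np.maximum(w[idx], 0.0))


def _nmds_single(d: np.ndarray, x0: np.ndarray, max_iter: int, tol: float
                 ) -> tuple[np.ndarray, float, bool, list[float]]:
    """One SMACOF run with isotonic disparities; returns stress-1 history."""
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    order = np.argsort(d[iu], kind="stable")
    x = x0.copy()
    history: list[float] = []
    converged = False
    last = np.inf
    for _ in range(max_iter):
        dist = squareform(pdist(x))
        dv = dist[iu]
        # isotonic (monotone nondecreasing) regression of distances on the
        # rank order of the input dissimilarities
        fit = isotonic_regression(dv[order]).x
        disp = np.empty_like(dv)
        disp[order] = fit
        # scale disparities so sum d_hat^2 = sum d^2 (Kruskal's convention)
        ssd = (dv ** 2).sum()
        disp *= np.sqrt(ssd / max((disp ** 2).sum(), 1e-300))
        stress = float(np.sqrt(((dv - disp) ** 2).sum() / max(ssd, 1e-300)))
        history.append(stress)
        if abs(last - stress) < tol:
            converged = True
            break
        last = stress
        # Guttman transform toward the disparities
        dmat = np.zeros((n, n))
        dmat[iu] = disp
        dmat = dmat + dmat.T
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dmat / np.where(dist > 0, dist, 1.0), 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = (b @ x) / n
    return x, history[-1] if history else float("inf"), converged, history


def nmds(
    dissim: np.ndarray,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> NmdsResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Alternates isotonic regression of configuration distances on the rank
    order of the dissimilarities with Guttman (SMACOF) configuration
    updates.  ``n_restarts`` random starts plus one classical-scaling start
    are run and the best (lowest-stress) solution returned; stress is
    non-increasing within a run.  Apply to square-root transformed covers.
    """
    d = np.asarray(dissim, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T):
        raise ValueError("dissim must be a square symmetric matrix")
    if n < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} samples")
    rng = np.random.default_rng(seed)
    scale = max(d.max(), 1e-12)
    starts = [_classical_mds(d, k)]
    starts += [rng.standard_normal((n, k)) * scale for _ in range(n_restarts)]
    best: tuple[np.ndarray, float, bool, list[float]] | None = None
    for x0 in starts:
        res = _nmds_single(d, x0, max_iter, tol)
        if best is None or res[1] < best[1]:
            best = res
    x, stress, converged, history = best  # type: ignore[misc]
    x = x - x.mean(axis=0)
    return NmdsResult(coordinates=x, stress=stress, n_restarts=n_restarts + 1,
                      converged=converged, stress_history=history)
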