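"""Comparative analysis of repeat landscapes and mutation-rate profiles.

Given normalized copy-number profiles for a panel of lines, this module
builds the matrix of motifs present in every line, summarizes it by PCA,
clusters lines by k-medoids with silhouette-based selection of the cluster
count, and relates per-copy mutation rates to motif features (unit length,
GC content) with rank tests, linear models, two-way ANOVA and pairwise
genotype correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score
import statsmodels.api as sm
import statsmodels.formula.api as smf

from ._pam import pam
from .normalization import NormalizedProfile
from .scanner import Motif

__all__ = [
    "SharedKmerMatrix",
    "ClusteringResult",
    "build_shared_matrix",
    "pca_scores",
    "kmedoids_select",
    "gc_extremes",
    "kruskal_wallis_by_group",
    "fit_rate_vs_length",
    "gc_anova",
    "pairwise_rate_correlations",
]


@dataclass
class SharedKmerMatrix:
    """Copy numbers of motifs with nonzero copy number in every line.

    ``matrix`` is lines x motifs (pandas DataFrame, columns sorted
    lexicographically by canonical unit); no entry is zero.
    """

    matrix: pd.DataFrame

    @property
    def lines(self) -> List[str]:
        return list(self.matrix.index)

    @property
    def motifs(self) -> List[str]:
        return list(self.matrix.columns)


@dataclass
class ClusteringResult:
    n_pcs: int
    k_grid: List[int]
    silhouette_by_k: Dict[int, float]
    best_k: int
    assignments: pd.Series  # line_id -> cluster label (of best_k solution)
    medoids: np.ndarray


def build_shared_matrix(profiles: Mapping[str, NormalizedProfile]) -> SharedKmerMatrix:
    """Matrix of motifs with copy number > 0 in all lines, lexicographic order."""
    if len(profiles) < 2:
        raise ValueError("need at least two lines")
    shared = None
    for prof in profiles.values():
        present = {m for m, c in prof.copy_number.items() if c > 0}
        shared = present if shared is None else shared & present
    if not shared:
        raise ValueError("no motif has nonzero copy number in every line")
    cols = sorted(m.unit for m in shared)
    data = {
        line: [prof[c] for c in cols] for line, prof in profiles.items()
    }
    mat = pd.DataFrame.from_dict(data, orient="index", columns=cols).sort_index()
    return SharedKmerMatrix(matrix=mat)


def pca_scores(
    matrix: pd.DataFrame, n_pcs: int = 10, scale: bool = False, log_transform: bool = False
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Column-centered PCA of a lines x motifs matrix.

    Signs are fixed by making each component's largest-magnitude loading
    positive, so scores are fully deterministic.  Returns (scores,
    variance_explained_fraction per PC).  ``scale`` standardizes columns to
    unit variance; ``log_transform`` applies log10(x + 1) first.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two lines")
    if log_transform:
        X = np.log10(X + 1.0)
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    if not np.any(X):
        import warnings

        warnings.warn("input matrix has zero variance; all PCA scores are 0")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    n_pcs = min(n_pcs, len(s))
    # sign convention: largest-|loading| entry of each PC positive
    for i in range(n_pcs):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u[:, :n_pcs] * s[:n_pcs]
    total_var = (s**2).sum()
    var_frac = (s[:n_pcs] ** 2) / total_var if total_var > 0 else np.zeros(n_pcs)
    cols = [f"PC{i + 1}" for i in range(n_pcs)]
    return pd.DataFrame(scores, index=matrix.index, columns=cols), var_frac


def kmedoids_select(
    scores: pd.DataFrame,
    k_grid: Sequence[int] = tuple(range(2, 13)),
    seed: int = 0,
    restarts: int = 20,
) -> ClusteringResult:
    """k-medoids over a grid of k, choosing k by mean silhouette width.

    PAM with Euclidean distances on the PC scores; for each k the best of
    ``restarts`` random initializations is kept, and best_k maximizes the
    average silhouette across lines.  Values of k >= n_lines are skipped
    with a warning.
    """
    X = scores.to_numpy(dtype=float)
    n = X.shape[0]
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    rng = np.random.default_rng(seed)
    sil: Dict[int, float] = {}
    solutions: Dict[int, Tuple[np.ndarray, np.ndarray]] = {}
    for k in k_grid:
        if k >= n:
            import warnings

            warnings.warn(f"skipping k={k}: must be < number of lines ({n})")
            continue
        labels, medoids, _ = pam(dist, k, restarts=restarts, rng=rng)
        if len(np.unique(labels)) < 2:
            sil[k] = float("-inf")  # degenerate: silhouette undefined
        else:
            sil[k] = float(silhouette_score(dist, labels, metric="precomputed"))
        solutions[k] = (labels, medoids)
    if not sil:
        raise ValueError("no feasible k in grid")
    best_k = max(sil, key=lambda k: (sil[k], -k))
    labels, medoids = solutions[best_k]
    return ClusteringResult(
        n_pcs=X.shape[1],
        k_grid=list(sil),
        silhouette_by_k=sil,
        best_k=best_k,
        assignments=pd.Series(labels, index=scores.index, name="cluster"),
        medoids=medoids,
    )


def gc_extremes(
    u_j: Mapping[str, float], n: int = 10, min_k: int = 4
) -> Tuple[float, float]:
    """Mean motif GC of the top-n and bottom-n |u_j| motifs.

    Motifs shorter than ``min_k`` bp are excluded (extreme GC values are
    unavoidable for 1-2 bp units).  Ranking is by |u_j| descending with
    lexicographic tie-break.  Returns (mean GC of the n highest-|u| motifs,
    mean GC of the n lowest).
    """
    eligible = [(unit, rate) for unit, rate in u_j.items() if len(unit) >= min_k]
    if len(eligible) < 2 * n:
        raise ValueError(
            f"need at least {2 * n} motifs with k >= {min_k}, have {len(eligible)}"
        )
    ranked = sorted(eligible, key=lambda t: (-abs(t[1]), t[0]))
    top = [Motif(unit).gc for unit, _ in ranked[:n]]
    bottom = [Motif(unit).gc for unit, _ in ranked[-n:]]
    return float(np.mean(top)), float(np.mean(bottom))


def kruskal_wallis_by_group(groups: Mapping[str, Sequence[float]]) -> Tuple[float, float]:
    """Kruskal-Wallis H (ties-corrected) and chi-square p across groups.

    With every value tied the statistic is defined as 0 (no rank variation).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    samples = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(samples)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*samples)
    return float(H), float(p)


def fit_rate_vs_length(u_j: Mapping[str, float]) -> Dict[str, float]:
    """OLS of per-copy rate on unit length: u_j ~ k.

    Returns slope, intercept, their p-values (slope p under the t test) and
    r squared.
    """
    if len(u_j) < 3:
        raise ValueError("need at least 3 motifs for the regression")
    k = np.array([len(unit) for unit in u_j], dtype=float)
    y = np.array(list(u_j.values()), dtype=float)
    X = sm.add_constant(k)
    fit = sm.OLS(y, X).fit()
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "p_slope": float(fit.pvalues[1]),
        "r_squared": float(fit.rsquared),
    }


def gc_anova(table: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA of motif GC content on genotype x rate category.

    ``table`` needs columns ``gc`` (response), ``genotype`` and
    ``category`` (e.g. "high"/"low" |u_j|).  Type-II sums of squares with
    an interaction term; returns the statsmodels ANOVA table.
    """
    for col in ("gc", "genotype", "category"):
        if col not in table:
            raise ValueError(f"missing column {col!r}")
    fit = smf.ols("gc ~ C(genotype) * C(category)", data=table).fit()
    return sm.stats.anova_lm(fit, typ=2)


def pairwise_rate_correlations(
    u_by_genotype: Mapping[str, Mapping[str, float]],
    drop_motifs: Iterable[str] = (),
) -> pd.DataFrame:
    """Pearson correlations of u_j between genotype pairs on shared motifs.

    ``drop_motifs`` removes named motifs before correlating (useful to test
    the influence of a single dominant motif).  Rows: genotype_a,
    genotype_b, n_shared, r.
    """
    drop = set(drop_motifs)
    names = sorted(u_by_genotype)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = (set(u_by_genotype[a]) & set(u_by_genotype[b])) - drop
            if not shared:
                raise ValueError(f"no shared motifs between {a} and {b}")
            shared = sorted(shared)
            va = np.array([u_by_genotype[a][m] for m in shared])
            vb = np.array([u_by_genotype[b][m] for m in shared])
            r = float(stats.pearsonr(va, vb)[0]) if len(shared) > 1 else float("nan")
            rows.append({"genotype_a": a, "genotype_b": b, "n_shared": len(shared), "r": r})
    return pd.DataFrame(rows)
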