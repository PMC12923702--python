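"""Edge-wise two-group inference with max-T familywise correction.

Each edge (region pair) of the connectivity matrices is compared between
groups with a two-sample t statistic (pooled variance by default, Welch by
flag).  Familywise error across all edges is controlled by the max-T
permutation procedure: group labels are shuffled, the maximum |t| over
edges is recorded per shuffle, and each edge's corrected p-value is the
fraction of shuffles whose maximum reaches its observed |t| (with the
(b+1)/(n+1) estimator, so p-values are never zero).  Region-level
summaries (degree over significant edges, eigenvector centrality) and
Cohen's d effect sizes accompany the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EdgeComparison",
    "edge_permutation_test",
    "permutation_test_columns",
    "direction_proportions",
    "degree_from_significance",
    "eigenvector_centrality",
    "ec_group_difference",
    "cohens_d",
]


@dataclass(frozen=True)
class EdgeComparison:
    """Result of an edge-wise max-T permutation comparison."""

    t_stat: np.ndarray          # region x region, symmetric, 0 diagonal
    p_fwe: np.ndarray           # same shape
    significant: np.ndarray     # boolean mask, same shape
    alpha: float
    n_permutations: int
    seed: int
    group_labels: tuple[str, str] = ("A", "B")

    @property
    def n_regions(self) -> int:
        return self.t_stat.shape[0]

    @property
    def n_significant_edges(self) -> int:
        return int(self.significant[np.triu_indices(self.n_regions, 1)].sum())


def _stack_upper(matrices: list, n_regions: int | None = None) -> tuple[np.ndarray, int]:
    vals = [m.values if hasattr(m, "values") else np.asarray(m, float) for m in matrices]
    r = vals[0].shape[0]
    for v in vals:
        if v.shape != (r, r):
            raise ValueError("all matrices must have the same shape")
    iu = np.triu_indices(r, 1)
    return np.stack([v[iu] for v in vals]), r


def _perm_tstats(
    data: np.ndarray,
    member_a: np.ndarray,
    welch: bool,
) -> np.ndarray:
    """t statistics (group a - group b) for many label assignments at once.

    data: subjects x features; member_a: assignments x subjects boolean.
    Returns assignments x features.
    """
    n1 = member_a.sum(axis=1, keepdims=True).astype(float)
    n2 = member_a.shape[1] - n1
    a = member_a.astype(float)
    b = 1.0 - a
    sum_a, sum_b = a @ data, b @ data
    sq_a, sq_b = a @ data**2, b @ data**2
    mean_a, mean_b = sum_a / n1, sum_b / n2
    var_a = (sq_a - n1 * mean_a**2) / (n1 - 1)
    var_b = (sq_b - n2 * mean_b**2) / (n2 - 1)
    var_a = np.maximum(var_a, 0.0)
    var_b = np.maximum(var_b, 0.0)
    if welch:
        se = np.sqrt(var_a / n1 + var_b / n2)
    else:
        sp2 = ((n1 - 1) * var_a + (n2 - 1) * var_b) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / se
    return np.where(se == 0, 0.0, t)


def permutation_test_columns(
    data_a: np.ndarray,
    data_b: np.ndarray,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    welch: bool = False,
    chunk: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """max-T permutation test over the columns of two subject x feature arrays.

    Returns (t_obs, p_fwe) per column.  The null shuffles group labels
    ``n_perm`` times and records the maximum |t| over columns per shuffle;
    p_fwe = (1 + #{perm: max|t| >= |t_obs|}) / (n_perm + 1), two-tailed.
    """
    data_a, data_b = np.atleast_2d(np.asarray(data_a, float)), np.atleast_2d(
        np.asarray(data_b, float)
    )
    n1, n2 = data_a.shape[0], data_b.shape[0]
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    data = np.vstack([data_a, data_b])
    obs = np.zeros((1, n1 + n2), dtype=bool)
    obs[0, :n1] = True
    t_obs = _perm_tstats(data, obs, welch)[0]

    rng = np.random.default_rng(seed)
    base = obs[0]
    max_t = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        perms = np.stack([rng.permutation(base) for _ in range(m)])
        t = _perm_tstats(data, perms, welch)
        max_t[done: done + m] = np.abs(t).max(axis=1)
        done += m
    exceed = (max_t[:, None] >= np.abs(t_obs)[None, :] - 1e-12).sum(axis=0)
    p_fwe = (1.0 + exceed) / (n_perm + 1.0)
    return t_obs, p_fwe


def edge_permutation_test(
    matrices_a: list,
    matrices_b: list,
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
    welch: bool = False,
) -> EdgeComparison:
    """Edge-wise two-group max-T permutation test on connectivity matrices."""
    ua, r = _stack_upper(matrices_a)
    ub, r2 = _stack_upper(matrices_b)
    if r != r2:
        raise ValueError("group matrices differ in size")
    t_obs, p_fwe = permutation_test_columns(
        ua, ub, n_perm=n_perm, alpha=alpha, seed=seed, welch=welch
    )
    iu = np.triu_indices(r, 1)
    t_mat = np.zeros((r, r))
    p_mat = np.ones((r, r))
    t_mat[iu] = t_obs
    p_mat[iu] = p_fwe
    t_mat += t_mat.T
    p_mat = np.minimum(p_mat, p_mat.T)
    np.fill_diagonal(p_mat, 1.0)
    sig = p_mat < alpha
    np.fill_diagonal(sig, False)
    return EdgeComparison(
        t_stat=t_mat, p_fwe=p_mat, significant=sig,
        alpha=alpha, n_permutations=n_perm, seed=seed,
    )


def direction_proportions(cmp: EdgeComparison) -> tuple[float, float]:
    """Percent of significant edges stronger in group a vs group b.

    Returns (pct_stronger_a, pct_stronger_b); (nan, nan) when no edge is
    significant.
    """
    iu = np.triu_indices(cmp.n_regions, 1)
    sig = cmp.significant[iu]
    if not sig.any():
        return (float("nan"), float("nan"))
    t = cmp.t_stat[iu][sig]
    pct_a = 100.0 * (t > 0).sum() / len(t)
    return (pct_a, 100.0 - pct_a)


def degree_from_significance(cmp: EdgeComparison) -> np.ndarray:
    """Per-region count of significant edges (row sums of the mask)."""
    return cmp.significant.sum(axis=1).astype(int)


def eigenvector_centrality(matrix) -> np.ndarray:
    """Leading eigenvector of a symmetric nonnegative matrix, unit norm,
    oriented nonnegative (Perron-Frobenius)."""
    values = matrix.values if hasattr(matrix, "values") else np.asarray(matrix, float)
    if not np.allclose(values, values.T):
        raise ValueError("matrix must be symmetric")
    if (values < 0).any():
        raise ValueError("matrix must be nonnegative")
    if not values.any():
        raise ValueError("all-zero matrix has no centrality")
    w, v = np.linalg.eigh(values)
    vec = v[:, -1]
    if vec.sum() < 0:
        vec = -vec
    return vec / np.linalg.norm(vec)


def ec_group_difference(ec_a: np.ndarray, ec_b: np.ndarray) -> np.ndarray:
    """Mean eigenvector centrality of group a minus group b, per region."""
    ec_a, ec_b = np.atleast_2d(ec_a), np.atleast_2d(ec_b)
    if ec_a.shape[1] != ec_b.shape[1]:
        raise ValueError("region counts differ")
    return ec_a.mean(axis=0) - ec_b.mean(axis=0)


def cohens_d(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """Cohen's d with pooled (n-1 weighted) standard deviation."""
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    if min(len(a), len(b)) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD")
    return float((a.mean() - b.mean()) / np.sqrt(sp2))
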