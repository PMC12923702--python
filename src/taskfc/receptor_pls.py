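"""Receptor-availability PLS with variable importance and spin-test nulls.

Molecular predictors (per-region receptor availabilities, z-scored then
rescaled to [0, 1]) are related to functional responses (per-region
group-difference maps, column-standardized) by a two-block PLS regression
(NIPALS with deflation).  Reported per component: the share of the total
X-Y cross-covariance (squared singular value of the deflated
cross-covariance matrix over the squared Frobenius norm of the original)
and the share of Y variance explained.  VIP scores summarize each
predictor's importance across components (sum of squared VIPs equals the
number of predictors).

Spatial inference uses spin permutations: the parcel centroids of one
hemisphere are randomly rotated (the mirrored rotation is applied to the
other hemisphere), parcels are re-assigned to rotated parcels within
their hemisphere by the minimum-total-distance bijection, and subcortical
regions -- which cannot be spherically rotated -- are permuted among
themselves.  Recomputing a statistic under these maps yields a null that
preserves spatial autocorrelation.  The default component-significance
statistic is the cross-covariance magnitude captured by the component
(squared singular value of centered X'Y): it is what alignment between
the predictor and response maps actually changes, whereas share-type
statistics are dominated by the response block's internal rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import ParcelGeometry

__all__ = [
    "PlsResult",
    "SpinNull",
    "normalize_receptor",
    "pls_fit",
    "vip",
    "build_spin_null",
    "spin_pvalue",
    "spearman_spin",
    "network_mean_scores",
]


@dataclass(frozen=True)
class PlsResult:
    """Fitted PLS decomposition with per-component summaries."""

    x_weights: np.ndarray       # predictors x components
    x_scores: np.ndarray        # regions x components (predictor scores)
    y_scores: np.ndarray        # regions x components (response scores)
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    cov_share: np.ndarray       # per component, fraction of ||X'Y||_F^2
    y_variance_share: np.ndarray  # per component, fraction of ||Y||_F^2
    singular_values: np.ndarray = field(default=None)  # of centered X'Y
    vip: np.ndarray = field(default=None)

    @property
    def n_components(self) -> int:
        return self.x_weights.shape[1]


@dataclass(frozen=True)
class SpinNull:
    """Archive of spin permutation maps (each a region-index bijection)."""

    maps: np.ndarray            # n_perm x n_regions
    seed: int
    n_cortical: int

    def __post_init__(self) -> None:
        n = self.maps.shape[1]
        for row in self.maps[: min(5, len(self.maps))]:
            if len(np.unique(row)) != n:
                raise ValueError("spin maps must be bijections")

    @property
    def n_perm(self) -> int:
        return self.maps.shape[0]


def normalize_receptor(raw: np.ndarray) -> np.ndarray:
    """z-score across regions, then min-max rescale to [0, 1]."""
    x = np.asarray(raw, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("constant receptor map cannot be normalized")
    z = (x - x.mean()) / x.std(ddof=1)
    return (z - z.min()) / (z.max() - z.min())


def pls_fit(X: np.ndarray, Y: np.ndarray, n_components: int = 2) -> PlsResult:
    """Two-block PLS regression (NIPALS, deflation-based); deterministic.

    X is centered internally (its [0, 1] scaling is preserved in reported
    scores via the centered matrix); Y is expected column-standardized.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with equal row counts")
    if X.shape[0] < 10:
        raise ValueError("need at least 10 regions")
    if n_components > min(X.shape[1], Y.shape[1], X.shape[0] - 1):
        raise ValueError("too many components for the data")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < X.shape[1]:
        raise ValueError("rank-deficient X after centering")
    # cross-covariance shares from the SVD of the original X'Y: squared
    # singular values partition ||X'Y||_F^2 exactly, so shares sum to <= 1
    sv = np.linalg.svd(Xc.T @ Yc, compute_uv=False)
    total_cov = float(np.sum(sv**2))
    total_y = np.linalg.norm(Yc, "fro") ** 2

    p, q = X.shape[1], Y.shape[1]
    W = np.zeros((p, n_components))
    T = np.zeros((X.shape[0], n_components))
    U = np.zeros((X.shape[0], n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros((q, n_components))
    cov_share = np.zeros(n_components)
    y_share = np.zeros(n_components)
    Xd, Yd = Xc.copy(), Yc.copy()
    for a in range(n_components):
        C = Xd.T @ Yd
        uu, ss, vv = np.linalg.svd(C, full_matrices=False)
        w = uu[:, 0]
        # deterministic sign: largest-|w| entry positive
        if w[np.argmax(np.abs(w))] < 0:
            w = -w
        t = Xd @ w
        tt = t @ t
        if tt == 0:
            raise ValueError("degenerate component: zero X scores")
        qv = (Yd.T @ t) / tt
        u = Yd @ qv
        pv = (Xd.T @ t) / tt
        cov_share[a] = sv[a] ** 2 / total_cov if total_cov > 0 else 0.0
        y_share[a] = (tt * (qv @ qv)) / total_y if total_y > 0 else 0.0
        W[:, a], T[:, a], U[:, a], P[:, a], Q[:, a] = w, t, u, pv, qv
        Xd = Xd - np.outer(t, pv)
        Yd = Yd - np.outer(t, qv)
    res = PlsResult(
        x_weights=W, x_scores=T, y_scores=U, x_loadings=P, y_loadings=Q,
        cov_share=cov_share, y_variance_share=y_share, singular_values=sv,
    )
    object.__setattr__(res, "vip", vip(res))
    return res


def vip(res: PlsResult) -> np.ndarray:
    """Variable importance in projection, per predictor.

    VIP_j = sqrt( p * sum_a SS_a (w_ja/||w_a||)^2 / sum_a SS_a ), with SS_a
    the Y variance explained by component a.  Sum of squared VIPs = p.
    """
    W = res.x_weights
    ss = res.y_variance_share
    p = W.shape[0]
    wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    denom = ss.sum()
    if denom == 0:
        return np.zeros(p)
    return np.sqrt(p * (wn**2 @ ss) / denom)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation (QR of a Gaussian, det +1)."""
    A = rng.standard_normal((3, 3))
    Qm, R = np.linalg.qr(A)
    Qm = Qm @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Qm) < 0:
        Qm[:, 0] = -Qm[:, 0]
    return Qm


def _match_rotated(orig: np.ndarray, rotated: np.ndarray) -> np.ndarray:
    """Assign each original parcel a distinct rotated parcel.

    Returns perm with perm[i] = index of the source parcel whose value
    region i receives.  Uses the minimum-total-distance bijection
    (Hungarian algorithm), which resolves assignment conflicts optimally
    and reduces the resampling displacement relative to greedy matching;
    an identity rotation yields the identity map.
    """
    from scipy.optimize import linear_sum_assignment

    d = np.linalg.norm(orig[:, None] - rotated[None, :], axis=-1)
    rows, cols = linear_sum_assignment(d)
    perm = np.empty(len(orig), dtype=np.int64)
    perm[rows] = cols
    return perm


def build_spin_null(
    geometry: ParcelGeometry, n_perm: int = 10_000, seed: int = 0
) -> SpinNull:
    """Spin permutation maps preserving hemisphere and cortical class."""
    coords = geometry.coords
    cort = geometry.is_cortical
    if len(np.unique(coords, axis=0)) != len(coords):
        raise ValueError("duplicate centroids; geometry is degenerate")
    left = np.flatnonzero(cort & (geometry.hemisphere == "L"))
    right = np.flatnonzero(cort & (geometry.hemisphere == "R"))
    sub = np.flatnonzero(~cort)
    mirror = np.diag([-1.0, 1.0, 1.0])
    rng = np.random.default_rng(seed)
    maps = np.empty((n_perm, len(coords)), dtype=np.int64)
    for p in range(n_perm):
        rot = _random_rotation(rng)
        rot_mirrored = mirror @ rot @ mirror
        perm = np.arange(len(coords))
        for idx, R in ((left, rot), (right, rot_mirrored)):
            if len(idx):
                local = _match_rotated(coords[idx], coords[idx] @ R.T)
                perm[idx] = idx[local]
        if len(sub):
            perm[sub] = sub[rng.permutation(len(sub))]
        maps[p] = perm
    return SpinNull(maps=maps, seed=seed, n_cortical=int(cort.sum()))


def spin_pvalue(empirical_stat: float, null_stats: np.ndarray) -> float:
    """Two-tailed permutation p: (1 + #{|null| >= |empirical|}) / (n + 1)."""
    null_stats = np.asarray(null_stats, dtype=float)
    if len(null_stats) < 100:
        raise ValueError("need at least 100 null values")
    exceed = int((np.abs(null_stats) >= abs(empirical_stat) - 1e-15).sum())
    return (1.0 + exceed) / (len(null_stats) + 1.0)


def spearman_spin(
    predictor_score: np.ndarray,
    response: np.ndarray,
    spin: SpinNull,
) -> tuple[float, float, float]:
    """Spearman rho, parametric p, and spin p (response rows re-mapped)."""
    x = np.asarray(predictor_score, float)
    y = np.asarray(response, float)
    if len(x) != len(y):
        raise ValueError("misaligned regions")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant vector")
    rho, p = stats.spearmanr(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    # spearman under each map = pearson of ranks with permuted response ranks
    rxc = rx - rx.mean()
    null = np.empty(spin.n_perm)
    for i, perm in enumerate(spin.maps):
        ryp = ry[perm]
        null[i] = np.corrcoef(rxc, ryp)[0, 1]
    return float(rho), float(p), spin_pvalue(float(rho), null)


def network_mean_scores(scores: np.ndarray, partition) -> dict[str, float]:
    """Mean region score per network; overlapping regions count in each."""
    out = {}
    for net in partition.networks:
        members = partition.members(net)
        if len(members) == 0:
            raise ValueError(f"empty network {net!r}")
        out[net] = float(np.mean(np.asarray(scores, float)[members]))
    return out
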