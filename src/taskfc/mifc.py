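"""Mutual-information functional connectivity (miFC).

Connectivity between two regions is measured as the mutual information (in
bits) between their BOLD timeseries.  The default estimator is a plug-in
histogram on equiprobable (quantile) bins of each marginal: it is
deterministic, invariant under strictly monotone transforms of either
input, and fast enough for all region pairs of a 214-parcel atlas.  Like
every fixed-resolution discretization it estimates the mutual information
of the *binned* variables, a lower bound on the continuous MI; a k-nearest
neighbour (KSG) scheme is available for absolute continuous-MI estimates.

Timeseries are z-scored before estimation; when the estimate is restricted
to a condition's volumes, the restricted segment is re-z-scored so the
estimator always sees standardized input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .cohort import RegionalTimeseries

__all__ = [
    "MifcMatrix",
    "ContrastMatrix",
    "zscore_timeseries",
    "mutual_information",
    "mifc_matrix",
    "contrast_mifc",
]

#: minimum samples per histogram bin implied by the estimator floor
FLOOR_FACTOR = 8


@dataclass(frozen=True)
class MifcMatrix:
    """Symmetric region x region mutual-information matrix in bits."""

    values: np.ndarray
    n_volumes_used: int
    n_bins: int
    scheme: str = "quantile"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if not np.isfinite(v).all():
            raise ValueError("values must be finite")
        if not np.allclose(v, v.T):
            raise ValueError("values must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ContrastMatrix:
    """Entrywise difference of two condition miFC matrices (bits)."""

    values: np.ndarray
    condition_a: str
    condition_b: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.isfinite(v).all() or not np.allclose(v, v.T):
            raise ValueError("contrast values must be finite and symmetric")
        object.__setattr__(self, "values", v)


def zscore_timeseries(ts: RegionalTimeseries) -> RegionalTimeseries:
    """Standardize each region column to mean 0, SD 1 (sample SD, n-1)."""
    data = ts.data
    if data.shape[0] < 2:
        raise ValueError("need at least 2 volumes to z-score")
    sd = data.std(axis=0, ddof=1)
    tol = 1e-12 * np.maximum(1.0, np.abs(data).max(axis=0))
    bad = np.flatnonzero(sd <= tol)
    if bad.size:
        raise ValueError(f"zero-variance region(s): {bad.tolist()}")
    return replace(ts, data=(data - data.mean(axis=0)) / sd)


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equiprobable bin labels via average-tie ranks; deterministic."""
    n = len(x)
    ranks = stats.rankdata(x, method="average")
    labels = np.ceil(ranks * n_bins / n).astype(np.int64) - 1
    return np.clip(labels, 0, n_bins - 1)


def _mi_from_counts(counts: np.ndarray, n: int) -> np.ndarray:
    """Plug-in MI in bits from joint count array (..., B, B)."""
    p = counts / n
    px = p.sum(axis=-1, keepdims=True)
    py = p.sum(axis=-2, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return np.nansum(terms, axis=(-2, -1))


def mutual_information(
    x: np.ndarray,
    y: np.ndarray,
    n_bins: int = 8,
    scheme: str = "quantile",
) -> float:
    """Mutual information between two sample vectors, in bits.

    scheme="quantile" (default): plug-in histogram on equiprobable bins of
    each marginal.  scheme="knn": Kraskov-style k-nearest-neighbour
    estimator (k=4) of the continuous MI, via scikit-learn; ``n_bins`` is
    ignored for this scheme.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 8:
        raise ValueError("need at least 8 samples")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("inputs contain NaN")
    if scheme == "knn":
        from sklearn.feature_selection import mutual_info_regression

        nats = mutual_info_regression(
            x.reshape(-1, 1), y, n_neighbors=4, random_state=0
        )[0]
        return float(max(nats, 0.0) / np.log(2))
    if scheme != "quantile":
        raise ValueError(f"unknown scheme {scheme!r}")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    bx = _quantile_bins(x, n_bins)
    by = _quantile_bins(y, n_bins)
    counts = np.bincount(bx * n_bins + by, minlength=n_bins * n_bins)
    return float(_mi_from_counts(counts.reshape(n_bins, n_bins), len(x)))


def _pairwise_mi(data: np.ndarray, n_bins: int) -> np.ndarray:
    """All-pairs plug-in MI for a volumes x regions matrix (vectorized)."""
    n_vol, n_reg = data.shape
    ranks = stats.rankdata(data, method="average", axis=0)
    labels = np.clip(
        np.ceil(ranks * n_bins / n_vol).astype(np.int64) - 1, 0, n_bins - 1
    ).T.copy()
    b2 = n_bins * n_bins
    out = np.zeros((n_reg, n_reg))
    for i in range(n_reg - 1):
        rest = labels[i + 1:]
        codes = labels[i] * n_bins + rest  # (n_reg-i-1, n_vol)
        offs = np.arange(rest.shape[0])[:, None] * b2
        counts = np.bincount((codes + offs).ravel(), minlength=rest.shape[0] * b2)
        mi = _mi_from_counts(counts.reshape(-1, n_bins, n_bins), n_vol)
        out[i, i + 1:] = mi
        out[i + 1:, i] = mi
    return out


def mifc_matrix(
    ts: RegionalTimeseries,
    volume_indices: np.ndarray | None = None,
    n_bins: int = 8,
    floor_factor: int = FLOOR_FACTOR,
) -> MifcMatrix:
    """Pairwise miFC over (optionally restricted) volumes; diagonal 0.

    The (restricted) segment is z-scored before estimation.  Restriction to
    fewer than ``floor_factor * n_bins`` volumes is rejected: with fewer
    samples per bin the plug-in estimate is dominated by bias.
    """
    data = ts.data
    if volume_indices is not None:
        idx = np.unique(np.asarray(volume_indices, dtype=int))
        if idx.size and (idx[0] < 0 or idx[-1] >= data.shape[0]):
            raise ValueError("volume indices out of range")
        floor = floor_factor * n_bins
        if idx.size < floor:
            raise ValueError(
                f"{idx.size} volumes selected; the estimator floor is {floor} "
                f"({floor_factor} x {n_bins} bins)"
            )
        data = data[idx]
    sub = replace(ts, data=data)
    data = zscore_timeseries(sub).data
    values = _pairwise_mi(data, n_bins)
    np.fill_diagonal(values, 0.0)
    return MifcMatrix(values=values, n_volumes_used=data.shape[0], n_bins=n_bins)


def contrast_mifc(
    ts: RegionalTimeseries,
    indices_a: np.ndarray,
    indices_b: np.ndarray,
    n_bins: int = 8,
    condition_a: str = "a",
    condition_b: str = "b",
    floor_factor: int = FLOOR_FACTOR,
) -> ContrastMatrix:
    """Condition-vs-condition miFC contrast: miFC(a) - miFC(b), entrywise."""
    ma = mifc_matrix(ts, indices_a, n_bins, floor_factor)
    mb = mifc_matrix(ts, indices_b, n_bins, floor_factor)
    return ContrastMatrix(
        values=ma.values - mb.values,
        condition_a=condition_a,
        condition_b=condition_b,
    )
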