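"""Missing-value imputation and resampling-based tight clustering.

Peptides commonly identified in at least 4 of the 8 kinase-dead conditions
are retained; their remaining missing log2 ratios are imputed by 5-nearest
-neighbour averaging.  The complete matrix is then mined for tight
clusters: repeated k-means on subsamples yields a co-membership matrix
(how often two peptides co-cluster when both are drawn); maximal sets
whose pairwise co-membership clears a threshold, and which are stable
across consecutive cluster numbers k, are extracted sequentially, most
stable first.  Peptides matching no stable pattern remain "scattered"
rather than being forced into a cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .errors import ValidationError

logger = logging.getLogger(__name__)


def filter_min_observed(
    log2_frame: pd.DataFrame, min_conditions: int = 4
) -> tuple[pd.DataFrame, int]:
    """Keep peptides observed in >= min_conditions columns; count exclusions."""
    keep = log2_frame.notna().sum(axis=1) >= min_conditions
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info(
            "excluded %d peptide(s) observed in fewer than %d conditions",
            n_excluded, min_conditions,
        )
    return log2_frame.loc[keep], n_excluded


def knn_impute(log2_frame: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Impute missing log2 ratios by unweighted k-nearest-neighbour averaging.

    Neighbour distance is Euclidean over co-observed conditions, scaled by
    sqrt(n_conditions / n_overlap) so sparse overlaps are comparable to
    dense ones; candidate neighbours must share >= 2 observed conditions.
    A missing cell becomes the mean of the k nearest peptides observing
    that condition; with fewer than k eligible donors the peptide's own
    row mean is used.  Observed values are never altered.
    """
    X = log2_frame.to_numpy(dtype=float)
    n, m = X.shape
    obs = np.isfinite(X)
    if not (~obs).any():
        return log2_frame.copy()

    Xz = np.where(obs, X, 0.0)
    O = obs.astype(float)
    # pairwise sums over co-observed conditions, all-pairs at once
    overlap = O @ O.T
    sq = (Xz ** 2) @ O.T + O @ (Xz ** 2).T - 2.0 * (Xz @ Xz.T)
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.sqrt(np.maximum(sq, 0.0) * (m / overlap))
    dist[overlap < 2] = np.inf
    np.fill_diagonal(dist, np.inf)

    out = X.copy()
    row_means = np.nanmean(np.where(obs, X, np.nan), axis=1)
    for i in np.flatnonzero((~obs).any(axis=1)):
        order = np.argsort(dist[i], kind="stable")
        for j in np.flatnonzero(~obs[i]):
            donors = [
                r for r in order
                if np.isfinite(dist[i, r]) and obs[r, j]
            ][:k]
            if len(donors) >= k:
                out[i, j] = X[donors, j].mean()
            else:
                out[i, j] = row_means[i]
    return pd.DataFrame(out, index=log2_frame.index, columns=log2_frame.columns)


@dataclass(frozen=True)
class TightClusterParams:
    k0: int = 10                    # initial cluster number for the scans
    n_subsamples: int = 50          # B resampling draws per scan
    subsample_fraction: float = 0.7
    alpha_comembership: float = 0.8  # pairwise co-membership floor in a tight set
    beta_stability: float = 0.7      # Jaccard floor across consecutive k
    n_clusters_target: int = 8
    min_cluster_size: int = 5
    n_init: int = 10                # k-means restarts per subsample
    max_k_steps: int = 3            # how far k may climb past k0 per extraction
    standardize_rows: bool = True   # cluster response *patterns*, not magnitudes
    seed: int = 0

    def validate(self) -> None:
        if self.k0 < 2:
            raise ValidationError("k0 must be >= 2")
        if not 0 < self.subsample_fraction <= 1:
            raise ValidationError("subsample_fraction must lie in (0, 1]")
        for name in ("alpha_comembership", "beta_stability"):
            if not 0 < getattr(self, name) <= 1:
                raise ValidationError(f"{name} must lie in (0, 1]")
        if self.n_subsamples < 1 or self.n_clusters_target < 1:
            raise ValidationError("n_subsamples and n_clusters_target must be >= 1")


@dataclass
class TightClusterResult:
    clusters: list[list[str]]          # extraction order = decreasing stability
    scattered: list[str]
    co_membership: pd.DataFrame        # first full-set scan at k0
    params: TightClusterParams = field(default_factory=TightClusterParams)

    @property
    def assignment(self) -> pd.Series:
        """Cluster label per peptide; -1 for scattered."""
        labels = {}
        for c, members in enumerate(self.clusters):
            for key in members:
                labels[key] = c
        for key in self.scattered:
            labels[key] = -1
        return pd.Series(labels)


def _comembership(
    X: np.ndarray, k: int, params: TightClusterParams, rng: np.random.Generator
) -> np.ndarray:
    """Average co-clustering frequency over subsampled k-means runs."""
    n = X.shape[0]
    size = max(k + 1, int(round(params.subsample_fraction * n)))
    size = min(size, n)
    co = np.zeros((n, n))
    both = np.zeros((n, n))
    for _ in range(params.n_subsamples):
        idx = rng.choice(n, size=size, replace=False)
        km = KMeans(
            n_clusters=k,
            n_init=params.n_init,
            random_state=int(rng.integers(2 ** 31)),
        )
        labels = km.fit_predict(X[idx])
        same = labels[:, None] == labels[None, :]
        both[np.ix_(idx, idx)] += 1.0
        co[np.ix_(idx, idx)] += same
    with np.errstate(invalid="ignore"):
        D = np.where(both > 0, co / np.maximum(both, 1.0), 0.0)
    np.fill_diagonal(D, 1.0)
    return D


def _tight_candidates(
    D: np.ndarray, params: TightClusterParams, top: int = 3
) -> list[frozenset[int]]:
    """Maximal high-co-membership sets via a complete-linkage cut.

    Complete linkage at distance 1 - alpha guarantees every pair inside a
    group has co-membership >= alpha.
    """
    n = D.shape[0]
    if n < 2:
        return []
    dist = 1.0 - np.clip((D + D.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="complete")
    groups = fcluster(Z, t=1.0 - params.alpha_comembership, criterion="distance")
    sets = [
        frozenset(np.flatnonzero(groups == g))
        for g in np.unique(groups)
    ]
    sets = [s for s in sets if len(s) >= params.min_cluster_size]
    sets.sort(key=lambda s: (-len(s), sorted(s)))
    return sets[:top]


def _jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b) if (a or b) else 0.0


def _trim_outlier_members(X: np.ndarray, members: frozenset[int]) -> frozenset[int]:
    """Drop members far from the set's centroid (Tukey fence on distances).

    k-means assigns every point somewhere, so a scattered peptide that
    merely lies nearest to a tight cluster's centroid co-clusters with it
    in every run; such hangers-on are distance outliers relative to the
    cluster's internal cohesion and are trimmed before reporting.
    """
    idx = sorted(members)
    if len(idx) < 4:
        return members
    centroid = X[idx].mean(axis=0)
    d = np.linalg.norm(X[idx] - centroid, axis=1)
    q1, q3 = np.percentile(d, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    return frozenset(i for i, di in zip(idx, d) if di <= fence)


def tight_cluster(
    log2_complete: pd.DataFrame, params: TightClusterParams | None = None
) -> TightClusterResult:
    """Sequentially extract tight, stable clusters from a complete matrix.

    For the current candidate k, co-membership matrices are built at k and
    k + 1; the candidate pair with the highest Jaccard overlap, if it
    clears ``beta_stability``, yields the next tight cluster (ties broken
    by larger set, then lexicographic order), which is removed before the
    search repeats with k reduced by one.  If no stable pair exists, k is
    raised (up to ``max_k_steps`` past the start) before giving up.
    Remaining peptides are reported as scattered.  Deterministic under the
    params seed.
    """
    params = params or TightClusterParams()
    params.validate()
    if log2_complete.isna().any().any():
        raise ValidationError("tight clustering requires a complete (imputed) matrix")
    if len(log2_complete) <= params.k0:
        raise ValidationError(
            f"need more than k0={params.k0} peptides, got {len(log2_complete)}"
        )

    rng = np.random.default_rng(params.seed)
    keys = np.array(log2_complete.index)
    X = log2_complete.to_numpy(dtype=float)
    if params.standardize_rows:
        # similar *patterns* of change should cluster together regardless of
        # magnitude; rows are centred and scaled (zero-variance rows to 0)
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        X = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    remaining = np.arange(len(keys))
    clusters: list[list[str]] = []
    co_first: pd.DataFrame | None = None

    k = params.k0
    k_ceiling = params.k0 + params.max_k_steps
    while len(clusters) < params.n_clusters_target and len(remaining) > max(
        k + 1, 2 * params.min_cluster_size
    ):
        sub = X[remaining]
        D_a = _comembership(sub, k, params, rng)
        if co_first is None:
            co_first = pd.DataFrame(D_a, index=keys[remaining], columns=keys[remaining])
        D_b = _comembership(sub, k + 1, params, rng)
        cand_a = _tight_candidates(D_a, params)
        cand_b = _tight_candidates(D_b, params)

        best: tuple[float, int, list] | None = None
        best_set: frozenset[int] | None = None
        for a in cand_a:
            for b in cand_b:
                j = _jaccard(a, b)
                score = (j, len(a), [-i for i in sorted(a)])
                if j >= params.beta_stability and (best is None or score > best):
                    best, best_set = score, a
        if best_set is not None:
            best_set = _trim_outlier_members(sub, best_set)
            if len(best_set) < params.min_cluster_size:
                k += 1
                continue
            members = remaining[sorted(best_set)]
            clusters.append(list(keys[members]))
            remaining = np.array(
                [i for i in remaining if i not in set(members)], dtype=int
            )
            k = max(2, k - 1)
            k_ceiling = k + params.max_k_steps
        else:
            if k + 1 > k_ceiling:
                break
            k += 1

    if co_first is None:
        co_first = pd.DataFrame(
            np.eye(len(keys)), index=keys, columns=keys
        )
    return TightClusterResult(
        clusters=clusters,
        scattered=list(keys[remaining]),
        co_membership=co_first,
        params=params,
    )
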