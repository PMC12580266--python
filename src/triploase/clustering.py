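"""Expression-profile clustering: z-scored group means, fuzzy c-means, and
k-means sub-clustering.

Profiles are built over group means (one value per cross group).  Fuzzy
c-means follows the standard Bezdek updates with Euclidean distance and
fuzzification parameter m (default 2): membership u_ij = 1 / sum_k
(d_ij/d_ik)^(2/(m-1)), centers = sum(u^m x) / sum(u^m).  Genes are assigned
to their argmax cluster only when the maximum membership reaches the
threshold (default 0.7); otherwise they are left unassigned.  Sub-clusters
within a cluster of interest use Lloyd's k-means (best of several seeded
restarts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .types import CrossDesign, ExpressionMatrix, ValidationError

__all__ = [
    "standardize_profiles",
    "fuzzy_cmeans",
    "assign_members",
    "kmeans_subcluster",
    "ClusterModel",
    "select_cluster_peaking_at",
]


def standardize_profiles(
    matrix: ExpressionMatrix, design: CrossDesign, per_sample: bool = False
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene z-scores over group-mean profiles.

    Each gene's vector of group means is centered and scaled by its sample
    standard deviation (ddof=1).  Constant genes (SD = 0) get an all-zero
    profile and are flagged; they should be excluded from clustering.
    ``per_sample=True`` standardizes replicate-level values instead.

    Returns (profiles, flagged) where ``flagged`` is a boolean Series.
    """
    matrix.check_design(design)
    if per_sample:
        prof = matrix.values[design.samples].astype(float)
    else:
        means = {g: matrix.values[design.samples_of(g)].mean(axis=1) for g in design.groups}
        prof = pd.DataFrame(means)
    arr = prof.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flagged = pd.Series(sd.ravel() == 0, index=prof.index, name="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (arr - mu) / sd, 0.0)
    return pd.DataFrame(z, index=prof.index, columns=prof.columns), flagged


@dataclass
class ClusterModel:
    """Fitted fuzzy c-means model."""

    centers: np.ndarray            # c x n_features
    membership: pd.DataFrame       # genes x c, rows sum to 1
    m: float
    threshold: float
    objective_path: list = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return self.centers.shape[0]


def _kmeanspp_init(x: np.ndarray, c: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centers by squared distance."""
    n = x.shape[0]
    centers = [x[rng.integers(n)]]
    for _ in range(1, c):
        d2 = np.min(
            ((x[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(-1), axis=1
        )
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(n)])
            continue
        centers.append(x[rng.choice(n, p=d2 / total)])
    return np.asarray(centers)


def _memberships(x: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
    zero = d2 <= 1e-300
    u = np.zeros_like(d2)
    any_zero = zero.any(axis=1)
    # exact hit on a center: full membership there (split across exact ties)
    u[any_zero] = zero[any_zero] / zero[any_zero].sum(axis=1, keepdims=True)
    rest = ~any_zero
    if rest.any():
        power = 1.0 / (m - 1.0)
        inv = d2[rest] ** -power
        u[rest] = inv / inv.sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int = 5,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    threshold: float = 0.7,
) -> ClusterModel:
    """Fuzzy c-means over gene profiles.

    Iterates membership and center updates until the objective
    J = sum_ij u_ij^m d_ij^2 changes by less than ``tol`` (or ``max_iter``).
    The recorded objective path is non-increasing.  Requires at least ``c``
    distinct profiles.
    """
    if c < 1:
        raise ValidationError("c must be >= 1")
    if m <= 1.0:
        raise ValidationError("fuzzification parameter m must be > 1")
    x = profiles.to_numpy(dtype=float)
    if len(np.unique(x, axis=0)) < c:
        raise ValidationError(f"need at least {c} distinct profiles")
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_init(x, c, rng)

    path: list[float] = []
    prev = np.inf
    for _ in range(max_iter):
        u = _memberships(x, centers, m)
        um = u ** m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        obj = float((um * d2).sum())
        path.append(obj)
        if abs(prev - obj) < tol:
            break
        prev = obj
    u = _memberships(x, centers, m)
    membership = pd.DataFrame(
        u, index=profiles.index, columns=[f"cluster{i + 1}" for i in range(c)]
    )
    return ClusterModel(
        centers=centers, membership=membership, m=m, threshold=threshold,
        objective_path=path,
    )


def assign_members(model: ClusterModel, threshold: float | None = None) -> pd.Series:
    """Hard assignment: argmax cluster when max membership >= threshold,
    otherwise ``unassigned``."""
    if threshold is None:
        threshold = model.threshold
    u = model.membership.to_numpy()
    best = u.argmax(axis=1)
    ok = u.max(axis=1) >= threshold
    labels = np.where(ok, model.membership.columns.to_numpy()[best], "unassigned")
    return pd.Series(labels, index=model.membership.index, name="cluster")


def select_cluster_peaking_at(
    model: ClusterModel, profiles: pd.DataFrame, group: str
) -> str:
    """Cluster whose center attains its maximum at the given group column.

    Among clusters peaking at that group, the one with the highest center
    value there is returned (used to pick the paternal-excess-high cluster).
    """
    cols = list(profiles.columns)
    if group not in cols:
        raise ValidationError(f"group {group!r} not among profile columns")
    gi = cols.index(group)
    peaks = model.centers.argmax(axis=1)
    candidates = np.flatnonzero(peaks == gi)
    if candidates.size == 0:
        candidates = np.array([int(model.centers[:, gi].argmax())])
    best = candidates[np.argmax(model.centers[candidates, gi])]
    return model.membership.columns[best]


def kmeans_subcluster(
    profiles: pd.DataFrame, k: int = 10, seed: int = 0, n_init: int = 10
) -> pd.Series:
    """K-means sub-clustering (Lloyd's algorithm, best of n_init restarts).

    Labels are ``C1``..``Ck``.  ``k`` equal to the number of points puts
    each point in its own sub-cluster.
    """
    x = profiles.to_numpy(dtype=float)
    if k < 1 or k > x.shape[0]:
        raise ValidationError(f"k={k} outside 1..{x.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x)
    return pd.Series([f"C{i + 1}" for i in labels], index=profiles.index, name="subcluster")
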