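"""Recursive patient partitioning by ECG-feature similarity.

Patients are clustered with a Dirichlet-process Gaussian mixture (variational
stick-breaking, truncated), and clusters in which one class dominates the
other — population at least ``ratio`` times the other class's — are pooled
into a merged group.  The dominance ratio starts at 2 and is halved each
iteration, so with the defaults the recursion runs at most twice (once the
ratio reaches 1 every cluster is dominated) and yields at most two merged
groups, one per iteration.

New patients are routed to the merged group with the nearest centroid in the
z-scored training feature space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import BayesianGaussianMixture


@dataclass(frozen=True)
class PartitionConfig:
    init_dominance_ratio: float = 2.0
    decay: float = 0.5
    max_components: int = 20
    covariance_type: str = "diag"
    concentration_prior: float | None = None
    #: prior precision on component means; shrinks weakly-supported components
    #: toward the data mean so pure noise is not carved into spurious clusters
    mean_precision_prior: float = 10.0
    min_cluster_size: int = 5
    pca_components: int | None = 20   # project before clustering; None = off
    seed: int = 0
    merge_policy: str = "single"   # 'single': one merged group per iteration;
                                   # 'by_class': scar- and noscar-dominated pools
    no_partitioning: bool = False  # ablation: everyone in one group

    def validate(self) -> None:
        if self.init_dominance_ratio < 1.0:
            raise ValueError("init_dominance_ratio must be >= 1")
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must be in (0, 1)")
        if self.merge_policy not in ("single", "by_class"):
            raise ValueError("merge_policy must be 'single' or 'by_class'")


@dataclass(frozen=True)
class MergedGroup:
    members: np.ndarray       # row indices into the training matrix
    centroid: np.ndarray      # in z-scored feature space
    iteration: int
    dominance_ratio: float
    #: centroids of the constituent clusters pooled into this group; a merged
    #: group can be multi-modal, so routing goes through these rather than
    #: the (possibly hollow) group centroid
    cluster_centroids: np.ndarray | None = None

    def routing_centroids(self) -> np.ndarray:
        if self.cluster_centroids is not None and len(self.cluster_centroids):
            return self.cluster_centroids
        return self.centroid[None, :]


@dataclass(frozen=True)
class PartitionModel:
    groups: tuple[MergedGroup, ...]
    scale_mean: np.ndarray
    scale_sd: np.ndarray
    config: PartitionConfig
    n_iterations: int

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.scale_mean.size:
            raise ValueError(
                f"dimension mismatch: expected {self.scale_mean.size}, got {X.shape[1]}"
            )
        return (X - self.scale_mean) / self.scale_sd

    def assign_group(self, x: np.ndarray) -> int:
        """Route an ECG to the merged group with the nearest centroid.

        Distance is Euclidean in the model's z-scored space, taken to the
        nearest constituent cluster centroid of each merged group; ties break
        deterministically toward the lowest group index.
        """
        return int(self.assign_groups(np.atleast_2d(x))[0])

    def assign_groups(self, X: np.ndarray) -> np.ndarray:
        Z = self.transform(X)
        centroids = []
        owner = []
        for gid, g in enumerate(self.groups):
            rc = g.routing_centroids()
            centroids.append(rc)
            owner.extend([gid] * len(rc))
        C = np.concatenate(centroids, axis=0)
        owner = np.asarray(owner)
        d = ((Z[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        # owner is sorted by group id, so argmin's first-hit rule breaks ties
        # toward the lowest group index
        return owner[d.argmin(axis=1)]


def is_dominated(scar_count: int, noscar_count: int, ratio: float) -> bool:
    """True iff either class's population is >= ratio times the other's.

    Multiplicative form (no division), so empty clusters are vacuously
    dominated; they are dissolved upstream anyway.
    """
    if scar_count < 0 or noscar_count < 0:
        raise ValueError("counts must be non-negative")
    return scar_count >= ratio * noscar_count or noscar_count >= ratio * scar_count


def fit_dpgmm(X: np.ndarray, config: PartitionConfig) -> np.ndarray:
    """Cluster rows of ``X`` with a truncated DP Gaussian mixture.

    Returns integer cluster labels.  The matrix is first projected onto its
    top ``pca_components`` principal components (variational mixtures lose
    sensitivity when hundreds of nearly-noise dimensions drown the
    between-cluster variance, which concentrates in the top components).
    Clusters smaller than ``min_cluster_size`` are dissolved into the nearest
    surviving cluster (by centroid distance); the effective number of
    clusters is data-driven.
    """
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in clustering input")
    n = X.shape[0]
    if n < 2:
        return np.zeros(n, dtype=int)
    if X.var(axis=0).max() < 1e-12:  # degenerate geometry: one point cloud
        return np.zeros(n, dtype=int)
    k_pca = config.pca_components
    if k_pca is not None and X.shape[1] > k_pca and n > k_pca:
        X = PCA(n_components=k_pca, random_state=config.seed).fit_transform(X)
    n_components = int(min(config.max_components, n))
    bgm = BayesianGaussianMixture(
        n_components=n_components,
        weight_concentration_prior_type="dirichlet_process",
        weight_concentration_prior=config.concentration_prior,
        mean_precision_prior=config.mean_precision_prior,
        covariance_type=config.covariance_type,
        max_iter=500,
        reg_covar=1e-4,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter on tiny inputs
        labels = bgm.fit_predict(X)

    # dissolve undersized clusters
    uniq, counts = np.unique(labels, return_counts=True)
    surviving = uniq[counts >= config.min_cluster_size]
    if surviving.size == 0:
        return np.zeros(n, dtype=int)
    if surviving.size < uniq.size:
        centroids = np.stack([X[labels == k].mean(axis=0) for k in surviving])
        small = ~np.isin(labels, surviving)
        d = ((X[small, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        labels = labels.copy()
        labels[small] = surviving[d.argmin(axis=1)]
    # relabel to 0..K-1
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def recursive_partition(
    X: np.ndarray, labels: np.ndarray, config: PartitionConfig | None = None
) -> PartitionModel:
    """Run the recursive cluster-and-merge procedure on one region's labels.

    Iteration k uses dominance ratio ``init * decay**k``: the unassigned
    patients are clustered, every dominated cluster is pooled into the
    iteration's merged group(s), and undominated patients carry over.  Once
    the ratio drops to 1 or below every cluster is dominated (max >= min), so
    termination is guaranteed; with the defaults (2.0, 0.5) there are at most
    two iterations and two merged groups.
    """
    config = config or PartitionConfig()
    config.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels).astype(int)
    if X.shape[0] != y.size:
        raise ValueError("labels must align with the rows of X")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in partition input")

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mean) / sd

    if len(np.unique(y)) < 2:
        warnings.warn("all patients share one class; single merged group", stacklevel=2)
        groups = (
            MergedGroup(
                members=np.arange(len(y)),
                centroid=Z.mean(axis=0),
                iteration=0,
                dominance_ratio=config.init_dominance_ratio,
            ),
        )
        return PartitionModel(groups, mean, sd, config, n_iterations=1)

    if config.no_partitioning:
        groups = (
            MergedGroup(
                members=np.arange(len(y)),
                centroid=Z.mean(axis=0),
                iteration=0,
                dominance_ratio=float("inf"),
            ),
        )
        return PartitionModel(groups, mean, sd, config, n_iterations=0)

    remaining = np.arange(len(y))
    groups: list[MergedGroup] = []
    k = 0
    while remaining.size > 0:
        ratio = config.init_dominance_ratio * config.decay**k
        sub_cfg = PartitionConfig(
            **{**config.__dict__, "seed": (config.seed + 7919 * k) % (2**31 - 1)}
        )
        if remaining.size < max(10, 2 * config.min_cluster_size):
            cluster_labels = np.zeros(remaining.size, dtype=int)
        else:
            cluster_labels = fit_dpgmm(Z[remaining], sub_cfg)

        pooled: dict[str, list[np.ndarray]] = {"scar": [], "noscar": [], "single": []}
        undominated: list[np.ndarray] = []
        for c in np.unique(cluster_labels):
            members = remaining[cluster_labels == c]
            scar = int(y[members].sum())
            noscar = members.size - scar
            if is_dominated(scar, noscar, ratio) or ratio <= 1.0:
                if config.merge_policy == "single":
                    pooled["single"].append(members)
                else:
                    pooled["scar" if scar >= noscar else "noscar"].append(members)
            else:
                undominated.append(members)
        for key in ("single", "scar", "noscar"):
            if pooled[key]:
                members = np.concatenate(pooled[key])
                groups.append(
                    MergedGroup(
                        members=np.sort(members),
                        centroid=Z[members].mean(axis=0),
                        iteration=k,
                        dominance_ratio=ratio,
                        cluster_centroids=np.stack(
                            [Z[m].mean(axis=0) for m in pooled[key]]
                        ),
                    )
                )
        remaining = (
            np.sort(np.concatenate(undominated)) if undominated else np.array([], dtype=int)
        )
        k += 1
        if k > 100:  # unreachable with decay < 1; defensive
            raise RuntimeError("recursive partition failed to terminate")

    return PartitionModel(tuple(groups), mean, sd, config, n_iterations=k)
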