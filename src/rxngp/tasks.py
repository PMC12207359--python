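"""Meta-learning task construction and episode sampling.

Three ways of carving a reaction dataset into tasks are supported,
mirroring increasingly hard generalization settings:

* random splits — an 80:20 train/test partition whose pools are chopped
  into disjoint fixed-size tasks;
* substrate-based splits — unique substrates are clustered (MACCS keys,
  2-D manifold embedding, k-means) and evaluated leave-one-cluster-out
  (LOCO), so test substrates are structurally unlike training ones;
* time-based splits — train on reactions up to a cutoff year, test on
  reactions from a later window.

Every sampler is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "Task",
    "Episode",
    "LocoPlan",
    "random_task_partition",
    "chunk_into_tasks",
    "sample_episode",
    "substrate_clusters",
    "loco_plan",
    "time_split",
]


@dataclass(frozen=True)
class Task:
    task_id: str
    indices: np.ndarray
    split_role: str  # train | valid | test

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size == 0:
            raise ValueError(f"task {self.task_id}: empty index list")
        if len(np.unique(idx)) != idx.size:
            raise ValueError(f"task {self.task_id}: duplicate indices")
        object.__setattr__(self, "indices", idx)

    def __len__(self):
        return int(self.indices.size)


@dataclass(frozen=True)
class Episode:
    """A support/query partition of (a subset of) one task."""

    support: np.ndarray
    query: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.support, dtype=int)
        q = np.asarray(self.query, dtype=int)
        if s.size == 0 or q.size == 0:
            raise ValueError("support and query must both be non-empty")
        if np.intersect1d(s, q).size:
            raise ValueError("support and query overlap")
        object.__setattr__(self, "support", s)
        object.__setattr__(self, "query", q)


@dataclass(frozen=True)
class LocoPlan:
    """Leave-one-cluster-out schedule: each cluster is the test task once."""

    cluster_labels: np.ndarray
    combinations: tuple = field(default_factory=tuple)


def chunk_into_tasks(indices: np.ndarray, task_size: int, role: str,
                     rng: np.random.Generator, prefix: str) -> list[Task]:
    """Shuffle a pool of row indices and split it into covering tasks.

    The pool is divided into ``len(pool) // task_size`` near-equal tasks
    (remainder rows are spread across tasks), so the union of the tasks
    is exactly the pool.
    """
    indices = np.asarray(indices, dtype=int)
    if task_size < 2:
        raise ValueError("task_size must be >= 2")
    if task_size > indices.size:
        raise ValueError(
            f"task_size {task_size} exceeds pool size {indices.size}")
    shuffled = rng.permutation(indices)
    n_tasks = max(1, indices.size // task_size)
    return [Task(f"{prefix}{i}", chunk, role)
            for i, chunk in enumerate(np.array_split(shuffled, n_tasks))]


def random_task_partition(n_records: int, task_size: int, seed: int,
                          train_frac: float = 0.8,
                          valid_frac: float = 0.1) -> dict:
    """Random 80:20 train/test partition chopped into meta-learning tasks.

    ``valid_frac`` of the training pool is set aside as validation tasks.
    Returns ``{"train": [...], "valid": [...], "test": [...]}``; the three
    groups of tasks are disjoint and jointly cover ``range(n_records)``.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError("train_frac must be in (0, 1)")
    if not (0.0 <= valid_frac < 1.0):
        raise ValueError("valid_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_records)
    n_train_pool = int(round(train_frac * n_records))
    train_pool, test_pool = perm[:n_train_pool], perm[n_train_pool:]
    n_valid = int(round(valid_frac * n_train_pool))
    valid_pool, train_pool = train_pool[:n_valid], train_pool[n_valid:]
    out = {
        "train": chunk_into_tasks(train_pool, task_size, "train", rng, "train-"),
        "test": chunk_into_tasks(test_pool, min(task_size, test_pool.size),
                                 "test", rng, "test-"),
    }
    out["valid"] = (chunk_into_tasks(valid_pool, min(task_size, valid_pool.size),
                                     "valid", rng, "valid-")
                    if valid_pool.size else [])
    return out


def sample_episode(task: Task, support_size: int, query_size: int,
                   seed: int, stratified: bool = True,
                   y: np.ndarray | None = None) -> Episode:
    """Draw a disjoint support/query episode from a task without replacement.

    With ``stratified=True`` (the default) the support set is guaranteed
    to contain at least one example of each class, so GP fine-tuning and
    prototype computation always see both classes; ``y`` must then be the
    full label vector indexed by dataset row.
    """
    if support_size < 1 or query_size < 1:
        raise ValueError("support_size and query_size must be >= 1")
    if support_size + query_size > len(task):
        raise ValueError(
            f"episode needs {support_size + query_size} rows but task "
            f"{task.task_id} has {len(task)}")
    rng = np.random.default_rng(seed)
    if not stratified:
        picked = rng.choice(task.indices, size=support_size + query_size,
                            replace=False)
        return Episode(picked[:support_size], picked[support_size:])
    if y is None:
        raise ValueError("stratified sampling requires the label vector y")
    y = np.asarray(y)
    labels = y[task.indices]
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError(
            f"task {task.task_id} is single-class; cannot stratify")
    if support_size < classes.size:
        raise ValueError("support_size smaller than the number of classes")
    # proportional allocation with at least one slot per class
    support_parts = []
    counts = np.array([np.sum(labels == c) for c in classes])
    alloc = np.maximum(1, np.floor(support_size * counts / counts.sum()).astype(int))
    while alloc.sum() > support_size:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < support_size:
        alloc[np.argmax(counts - alloc)] += 1
    for c, k in zip(classes, alloc):
        pool_c = task.indices[labels == c]
        if k > pool_c.size:
            raise ValueError(
                f"task {task.task_id}: class {c} has only {pool_c.size} rows")
        support_parts.append(rng.choice(pool_c, size=k, replace=False))
    support = rng.permutation(np.concatenate(support_parts))
    remaining = np.setdiff1d(task.indices, support)
    query = rng.choice(remaining, size=query_size, replace=False)
    return Episode(support, query)


def substrate_clusters(maccs_matrix: np.ndarray, n_clusters: int = 6,
                       n_components: int = 2, seed: int = 0,
                       n_neighbors: int = 15, min_dist: float = 0.1) -> np.ndarray:
    """Cluster substrates by structure: MACCS keys -> 2-D UMAP -> k-means.

    Rows are deduplicated before embedding, so identical substrates are
    guaranteed identical cluster labels; each unique substrate is embedded
    once and reactions inherit their substrate's label.
    """
    M = np.atleast_2d(np.asarray(maccs_matrix, dtype=float))
    n = M.shape[0]
    if n_clusters >= n:
        raise ValueError("need more substrates than clusters")
    uniq, inverse = np.unique(M, axis=0, return_inverse=True)
    n_uniq = uniq.shape[0]
    if n_clusters > n_uniq:
        raise ValueError(
            f"only {n_uniq} unique substrates for {n_clusters} clusters")
    if n_uniq > n_components + 1:
        import umap  # deferred: numba-backed import is slow

        emb = umap.UMAP(n_components=n_components,
                        n_neighbors=min(n_neighbors, n_uniq - 1),
                        min_dist=min_dist,
                        random_state=seed).fit_transform(uniq)
    else:
        emb = uniq
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit(emb)
    return km.labels_[inverse]


def loco_plan(cluster_labels: np.ndarray) -> LocoPlan:
    """Build the leave-one-cluster-out combination schedule.

    With k clusters there are exactly k (train clusters, test cluster)
    combinations, each cluster serving as the test cluster once.
    """
    labels = np.asarray(cluster_labels, dtype=int)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("LOCO needs at least two clusters")
    combos = tuple(
        (tuple(int(c) for c in clusters if c != test_c), int(test_c))
        for test_c in clusters)
    return LocoPlan(cluster_labels=labels, combinations=combos)


def time_split(years: np.ndarray, task_size: int, seed: int,
               train_max_year: int = 2020, test_min_year: int = 2023) -> dict:
    """Chronological split: train on old reactions, test on recent ones.

    Rows with ``year <= train_max_year`` form the training pool (chopped
    into tasks); rows with ``year >= test_min_year`` form the single test
    task; rows in the gap are excluded and counted.
    """
    if train_max_year >= test_min_year:
        raise ValueError("train_max_year must precede test_min_year")
    years = np.asarray(years, dtype=int)
    idx = np.arange(years.size)
    train_pool = idx[years <= train_max_year]
    test_pool = idx[years >= test_min_year]
    n_excluded = years.size - train_pool.size - test_pool.size
    if test_pool.size == 0:
        raise ValueError(
            f"no rows with year >= {test_min_year}: empty test task")
    if train_pool.size == 0:
        raise ValueError(
            f"no rows with year <= {train_max_year}: empty training pool")
    rng = np.random.default_rng(seed)
    return {
        "train": chunk_into_tasks(train_pool, min(task_size, train_pool.size),
                                  "train", rng, "train-"),
        "test": Task("test-0", test_pool, "test"),
        "n_excluded": int(n_excluded),
    }
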