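"""K-means over PSD vectors with random-label initialization and restarts.

The algorithm is the classic two-step Lloyd iteration, but initialized the
way the source method does it: every point receives a uniformly random
initial label (all k labels guaranteed present), centroids are computed
from those labels, and assignment/update steps alternate until the labels
stop changing.  The whole computation is repeated for a number of
independent restarts and the model with the smallest total within-cluster
sum of squared Euclidean distances is kept.

The objective is the SUM OF SQUARED distances: the source text says "total
sum of the distances", but it also defines centroids as coordinate means,
which are only optimal for the squared objective, so the squared reading
is the internally consistent one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spectraclust.spectra import SpectrumSet


@dataclass
class ClusterModel:
    """A fitted K-means partition of a SpectrumSet.

    Invariants (checked by the test suite): every cluster is non-empty,
    each centroid is the mean of its assigned spectra, and each label is
    the argmin of Euclidean distance to the centroids (ties to the lowest
    cluster index).
    """

    k: int
    centroids: np.ndarray  # (k, n)
    labels: np.ndarray  # (m,) ints in [0, k)
    objective: float  # total within-cluster sum of squared distances
    distances: np.ndarray  # (m,) Euclidean distance of each point to its centroid
    n_restarts: int = 1
    seed: int | None = None
    n_iter_per_restart: list[int] = field(default_factory=list)
    #: per-restart objective traces (objective after each assignment step)
    traces: list[list[float]] = field(default_factory=list)
    restart_objectives: list[float] = field(default_factory=list)
    converged: bool = True


def _initial_labels(m: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random labels with all k values guaranteed present."""
    labels = np.concatenate([np.arange(k), rng.integers(0, k, size=m - k)])
    rng.shuffle(labels)
    return labels.astype(np.intp)


def _update_centroids(
    X: np.ndarray, labels: np.ndarray, k: int, prev: np.ndarray | None
) -> np.ndarray:
    """Mean per cluster; an emptied cluster is reseeded to the point
    farthest from its previous centroid (objective-neutral: the cluster
    has no members, and the grabbed point can only get closer)."""
    n = X.shape[1]
    counts = np.bincount(labels, minlength=k).astype(float)
    sums = np.zeros((k, n))
    np.add.at(sums, labels, X)
    centroids = np.empty((k, n))
    nonempty = counts > 0
    centroids[nonempty] = sums[nonempty] / counts[nonempty, None]
    taken: set[int] = set()
    for j in np.flatnonzero(~nonempty):
        if prev is None:  # initial labels always cover all k
            raise RuntimeError("empty cluster before first centroid update")
        d = np.linalg.norm(X - prev[j], axis=1)
        order = np.argsort(-d, kind="stable")
        pick = next(int(p) for p in order if int(p) not in taken)
        taken.add(pick)
        centroids[j] = X[pick]
    return centroids


def kmeans_single(
    spectra: SpectrumSet, k: int, rng: np.random.Generator, max_iter: int = 300
) -> ClusterModel:
    """One K-means run from a random label initialization.

    Iterates (centroid update, nearest-centroid assignment) until the
    labels are unchanged or ``max_iter`` is reached.  Assignment ties go
    to the lowest cluster index.
    """
    X = spectra.spectra
    m = X.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > m:
        raise ValueError(f"k={k} exceeds the number of spectra m={m}")
    labels = _initial_labels(m, k, rng)
    centroids: np.ndarray | None = None
    trace: list[float] = []
    converged = False
    n_iter = 0
    d2 = np.empty((m, k))
    for n_iter in range(1, max_iter + 1):
        centroids = _update_centroids(X, labels, k, centroids)
        diff = X[:, None, :] - centroids[None, :, :]
        np.einsum("mkn,mkn->mk", diff, diff, out=d2)
        new_labels = np.argmin(d2, axis=1)  # argmin ties -> lowest index
        trace.append(float(d2[np.arange(m), new_labels].sum()))
        if np.array_equal(new_labels, labels):
            converged = True
            break
        labels = new_labels
    if not converged:
        # max_iter hit: make centroids consistent with the final labels
        centroids = _update_centroids(X, labels, k, centroids)
    assert centroids is not None
    dist = np.linalg.norm(X - centroids[labels], axis=1)
    obj = float(np.sum(dist**2))
    return ClusterModel(
        k=k,
        centroids=centroids,
        labels=labels,
        objective=obj,
        distances=dist,
        n_restarts=1,
        n_iter_per_restart=[n_iter],
        traces=[trace],
        restart_objectives=[obj],
        converged=converged,
    )


def kmeans_fit(
    spectra: SpectrumSet,
    k: int,
    restarts: int = 50,
    seed: int = 0,
    max_iter: int = 300,
) -> ClusterModel:
    """Multi-restart K-means; returns the restart with the lowest objective.

    Restart ``r`` draws its random stream from an independent child of
    ``seed`` via :class:`numpy.random.SeedSequence`, so results are
    deterministic given ``(spectra, k, restarts, seed)``.
    """
    if restarts < 1:
        raise ValueError(f"restarts must be >= 1, got {restarts}")
    children = np.random.SeedSequence(seed).spawn(restarts)
    best: ClusterModel | None = None
    iters: list[int] = []
    traces: list[list[float]] = []
    objs: list[float] = []
    for child in children:
        model = kmeans_single(spectra, k, np.random.default_rng(child), max_iter=max_iter)
        iters.extend(model.n_iter_per_restart)
        traces.extend(model.traces)
        objs.extend(model.restart_objectives)
        if best is None or model.objective < best.objective:
            best = model
    assert best is not None
    best.n_restarts = restarts
    best.seed = seed
    best.n_iter_per_restart = iters
    best.traces = traces
    best.restart_objectives = objs
    return best


def objective(spectra: SpectrumSet, model: ClusterModel) -> float:
    """Recompute the total within-cluster sum of squared distances."""
    X = spectra.spectra
    if model.centroids.shape[1] != X.shape[1]:
        raise ValueError(
            f"centroid dimension {model.centroids.shape[1]} != spectrum length {X.shape[1]}"
        )
    if len(model.labels) != X.shape[0]:
        raise ValueError("model labels do not cover the spectra rows")
    diff = X - model.centroids[model.labels]
    return float(np.sum(diff * diff))
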