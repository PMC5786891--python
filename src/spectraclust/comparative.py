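"""Evaluation analyses: group decomposition across k, and discovered-vs-
reference centroid comparison.

``decomposition`` counts, for each value of k, how many distinct clusters
each annotated group is spread over — groups that fragment quickly as k
grows are more internally diverse.

``msd_matrix`` compares each discovered cluster against reference
centroids built from the true group labels: the entry for (cluster j,
centroid c) is the mean over cluster j's members of the squared spectral
distance to c.  The first column uses each cluster's own discovered
centroid.  A centroid-to-centroid Euclidean distance matrix is exported
separately since the member-mean construction can be read two ways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from spectraclust.clustering import ClusterModel
from spectraclust.sequence_io import GroupTable, cluster_name
from spectraclust.spectra import SpectrumSet

logger = logging.getLogger(__name__)

#: Column name for the own-discovered-centroid column of the MSD matrix.
OWN_COLUMN = "own_centroid"


@dataclass(frozen=True)
class ReferenceComparison:
    """MSD matrix of discovered clusters vs. their own and reference centroids.

    ``matrix`` rows are ``C-1`` … ``C-k``; the first column is the mean
    squared distance of each cluster's members to its own centroid, the
    remaining columns to each reference group centroid.
    """

    matrix: pd.DataFrame
    references: dict[str, np.ndarray]


def decomposition(
    assignments: Mapping[int, Sequence[int] | np.ndarray],
    ids: Sequence[str],
    groups: GroupTable,
    level: str | None = None,
) -> pd.DataFrame:
    """Distinct-cluster counts per group for each value of k.

    ``assignments`` maps k to a label vector aligned with ``ids``.
    Returns a DataFrame indexed by k with one column per group label.
    Raises ``KeyError`` if any id lacks a group annotation.
    """
    if not assignments:
        raise ValueError("assignments mapping is empty")
    group_of = groups.labels(level)
    missing = [i for i in ids if i not in group_of.index]
    if missing:
        raise KeyError(f"id(s) missing from group table: {missing[:5]}")
    labels_per_id = np.array([group_of.loc[i] for i in ids])
    group_names = sorted(set(labels_per_id))
    rows = {}
    for k, labels in sorted(assignments.items()):
        labels = np.asarray(labels)
        if labels.shape[0] != len(ids):
            raise ValueError(f"label vector for k={k} has length {labels.shape[0]}, expected {len(ids)}")
        rows[k] = {
            g: int(len(np.unique(labels[labels_per_id == g]))) for g in group_names
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")[group_names]
    frame.index.name = "k"
    return frame


def reference_centroids(
    spectra: SpectrumSet, groups: GroupTable, level: str | None = None
) -> dict[str, np.ndarray]:
    """Mean spectrum per true group; empty groups are skipped with a warning."""
    group_of = groups.labels(level)
    missing = [i for i in spectra.ids if i not in group_of.index]
    if missing:
        raise KeyError(f"id(s) missing from group table: {missing[:5]}")
    labels = np.array([group_of.loc[i] for i in spectra.ids])
    centroids: dict[str, np.ndarray] = {}
    for g in sorted(set(group_of)):
        mask = labels == g
        if not mask.any():
            logger.warning("group %r has no member among the spectra; skipped", g)
            continue
        centroids[g] = spectra.spectra[mask].mean(axis=0)
    return centroids


def msd_matrix(
    spectra: SpectrumSet,
    model: ClusterModel,
    refs: Mapping[str, np.ndarray],
) -> ReferenceComparison:
    """Mean squared distance of each cluster's members to each centroid.

    Columns: the cluster's own discovered centroid first, then each
    reference group centroid.
    """
    X = spectra.spectra
    n = X.shape[1]
    if model.centroids.shape[1] != n:
        raise ValueError("model centroid dimension does not match the spectra")
    for name, ref in refs.items():
        if np.asarray(ref).shape != (n,):
            raise ValueError(f"reference centroid {name!r} has wrong dimension")
    ref_names = list(refs)
    rows = []
    for j in range(model.k):
        members = X[model.labels == j]
        row = {OWN_COLUMN: float(np.mean(np.sum((members - model.centroids[j]) ** 2, axis=1)))}
        for name in ref_names:
            row[name] = float(np.mean(np.sum((members - np.asarray(refs[name])) ** 2, axis=1)))
        rows.append(row)
    matrix = pd.DataFrame(rows, index=[cluster_name(j) for j in range(model.k)])
    matrix.index.name = "cluster"
    return ReferenceComparison(matrix=matrix, references={k: np.asarray(v) for k, v in refs.items()})


def centroid_distance_matrix(
    model: ClusterModel, refs: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Euclidean distance between each discovered centroid and each reference centroid."""
    rows = {}
    for j in range(model.k):
        rows[cluster_name(j)] = {
            name: float(np.linalg.norm(model.centroids[j] - np.asarray(ref)))
            for name, ref in refs.items()
        }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "cluster"
    return frame
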