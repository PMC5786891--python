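"""Radial 2-D visualization of a spectral clustering.

The main centroid (unweighted mean of the k cluster centroids) sits at
the origin.  Cluster centroids are sorted by their distance to the main
centroid; the ι-th closest is placed on the ray at angle ι·2π/k at its
true distance.  Within each cluster, member sequences are sorted by their
distance δ to their own centroid and the rank-r member is placed at angle
r·2π/(cluster size) around the centroid, offset by δ.  Distances on the
plot are therefore exact spectral distances; angles only spread points
out.  No jitter or collision avoidance is applied, so radii stay readable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from spectraclust.clustering import ClusterModel
from spectraclust.sequence_io import GroupTable, cluster_name
from spectraclust.spectra import SpectrumSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RadialLayout:
    """Plot coordinates for a fitted model.

    ``clusters`` has one row per cluster in ι (sorted) order with columns
    ``cluster`` (original 0-based label), ``iota``, ``d``, ``theta``,
    ``x``, ``y``.  ``sequences`` has one row per sequence in input order
    with columns ``id``, ``cluster``, ``iota``, ``delta``, ``theta``,
    ``x``, ``y`` (``theta`` is the within-cluster angle; ``x``, ``y`` are
    absolute coordinates).
    """

    main_centroid: np.ndarray
    cluster_order: np.ndarray  # original cluster ids, ascending by d
    clusters: pd.DataFrame
    sequences: pd.DataFrame


def main_centroid(model: ClusterModel) -> np.ndarray:
    """Unweighted mean of the k cluster centroids (not of the m sequences)."""
    if model.centroids.shape[0] < 1:
        raise ValueError("model has no centroids")
    return model.centroids.mean(axis=0)


def centroid_polar(
    model: ClusterModel, M: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Polar coordinates of the cluster centroids around the main centroid.

    Returns ``(order, d, theta)`` where ``order[ι]`` is the original
    cluster index with the ι-th smallest distance ``d[ι]`` to ``M`` and
    ``theta[ι] = ι·2π/k``.  Distance ties keep original cluster order.
    """
    if model.centroids.shape[1] != M.shape[0]:
        raise ValueError("main centroid dimension does not match the model")
    dists = np.linalg.norm(model.centroids - M, axis=1)
    order = np.argsort(dists, kind="stable")
    k = model.k
    theta = np.arange(k) * (2.0 * np.pi / k)
    return order, dists[order], theta


def layout(model: ClusterModel, spectra: SpectrumSet) -> RadialLayout:
    """Compute the full radial layout for a model fitted on ``spectra``."""
    X = spectra.spectra
    if X.shape[0] != len(model.labels):
        raise ValueError("model labels do not cover the spectra rows")
    if np.any(model.labels < 0) or np.any(model.labels >= model.k):
        raise ValueError("sequence label outside the model's cluster range")
    M = main_centroid(model)
    order, d_sorted, theta_c = centroid_polar(model, M)
    xc = d_sorted * np.cos(theta_c)
    yc = d_sorted * np.sin(theta_c)
    clusters = pd.DataFrame(
        {
            "cluster": order,
            "iota": np.arange(model.k),
            "d": d_sorted,
            "theta": theta_c,
            "x": xc,
            "y": yc,
        }
    )
    iota_of = np.empty(model.k, dtype=int)
    iota_of[order] = np.arange(model.k)

    m = X.shape[0]
    delta = np.linalg.norm(X - model.centroids[model.labels], axis=1)
    theta_z = np.empty(m)
    xs = np.empty(m)
    ys = np.empty(m)
    for j in range(model.k):
        members = np.flatnonzero(model.labels == j)
        if members.size == 0:
            continue
        rank_order = members[np.argsort(delta[members], kind="stable")]
        angles = np.arange(members.size) * (2.0 * np.pi / members.size)
        iota = iota_of[j]
        theta_z[rank_order] = angles
        xs[rank_order] = delta[rank_order] * np.cos(angles) + xc[iota]
        ys[rank_order] = delta[rank_order] * np.sin(angles) + yc[iota]
    sequences = pd.DataFrame(
        {
            "id": spectra.ids,
            "cluster": model.labels,
            "iota": iota_of[model.labels],
            "delta": delta,
            "theta": theta_z,
            "x": xs,
            "y": ys,
        }
    )
    return RadialLayout(
        main_centroid=M, cluster_order=order, clusters=clusters, sequences=sequences
    )


def render(
    radial: RadialLayout,
    groups: GroupTable | None = None,
    path: str | Path | None = None,
    level: str | None = None,
    ax=None,
    title: str | None = None,
):
    """Render the radial layout as a scatter plot; writes PNG/SVG by extension.

    Cluster centroids are labeled ``C-1`` … ``C-k`` in ι order.  If a
    group table is given, sequences are colored by their label at
    ``level`` (default: first level); ids missing from the table fall back
    to a neutral style with a logged warning.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 8))
    else:
        fig = ax.figure

    ax.scatter([0.0], [0.0], marker="X", s=140, c="black", zorder=5, label="main centroid")
    ax.scatter(
        radial.clusters["x"],
        radial.clusters["y"],
        marker="D",
        s=70,
        c="tab:red",
        zorder=4,
        label="cluster centroids",
    )
    for _, row in radial.clusters.iterrows():
        ax.annotate(
            cluster_name(int(row["iota"])),
            (row["x"], row["y"]),
            textcoords="offset points",
            xytext=(6, 6),
            fontsize=9,
        )

    seqs = radial.sequences
    if groups is None:
        ax.scatter(seqs["x"], seqs["y"], s=22, c="tab:blue", alpha=0.8, zorder=3)
    else:
        labels = []
        missing = 0
        for seq_id in seqs["id"]:
            if seq_id in groups:
                labels.append(groups.labels(level).loc[seq_id])
            else:
                labels.append(None)
                missing += 1
        if missing:
            logger.warning("%d sequence(s) missing from group table; drawn in gray", missing)
        uniq = sorted({lab for lab in labels if lab is not None})
        cmap = plt.get_cmap("tab20")
        color_of = {lab: cmap(i % 20) for i, lab in enumerate(uniq)}
        markers = ["o", "s", "^", "v", "<", ">", "*", "P", "h", "8"]
        marker_of = {lab: markers[i % len(markers)] for i, lab in enumerate(uniq)}
        for lab in uniq:
            mask = [l == lab for l in labels]
            ax.scatter(
                seqs.loc[mask, "x"],
                seqs.loc[mask, "y"],
                s=26,
                color=color_of[lab],
                marker=marker_of[lab],
                alpha=0.85,
                zorder=3,
                label=str(lab),
            )
        fallback = [l is None for l in labels]
        if any(fallback):
            ax.scatter(
                seqs.loc[fallback, "x"],
                seqs.loc[fallback, "y"],
                s=22,
                color="0.6",
                marker="o",
                zorder=3,
                label="(no group)",
            )
        ax.legend(loc="upper right", fontsize=8)

    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    if title:
        ax.set_title(title)
    if path is not None:
        path = Path(path)
        try:
            fig.savefig(path, dpi=150, bbox_inches="tight")
        finally:
            plt.close(fig)
    return fig
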