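"""Binding-site detection from blind-docking poses.

Blind docking scatters ligands over the whole receptor surface; the engines
score poses but do not say *where* each ligand bound, which makes site
assignment a manual chore.  This module groups best-pose centroids by
single-linkage proximity and reports the dense groups as binding-site
clusters: a site only counts as a cluster when **more than** ``min_members``
poses land there (strictly exclusive threshold; a 10-pose site with the
default threshold of 10 is a low-density site, an 11-pose site is a cluster).

Each cluster carries a targeted-docking grid box centred on its centroid
(15 × 15 × 15 Å, 0.375 Å spacing by default), ready to feed back into the
engine for a focused screen.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .docking import DockedPose
from .geometry import Box

DEFAULT_LINKAGE_CUTOFF = 5.0  # Å; of the order of a binding-pocket radius
DEFAULT_MIN_MEMBERS = 10  # strict lower bound: clusters have > this many poses
DEFAULT_BOX_EDGE = 15.0  # Å, targeted-docking cube edge
DEFAULT_SPACING = 0.375  # Å, AutoDock grid spacing


@dataclass
class SiteCluster:
    cluster_id: int  # 1-based, ordered by descending member count
    members: list[str]  # ligand ids
    centroid: np.ndarray  # (3,) Å, mean of member pose centroids
    box: Box

    @property
    def member_count(self) -> int:
        return len(self.members)


def _single_linkage_labels(points: np.ndarray, cutoff: float) -> np.ndarray:
    """Component label per point: single-linkage clusters cut at ``cutoff``.

    Equivalent to connected components of the graph joining points at
    pairwise distance <= cutoff.
    """
    n = len(points)
    if n == 1:
        return np.zeros(1, dtype=int)
    dense = squareform(pdist(points)) <= cutoff
    np.fill_diagonal(dense, False)
    _, labels = connected_components(csr_matrix(dense), directed=False)
    return labels


def cluster_sites(
    poses: Sequence[DockedPose],
    linkage_cutoff: float = DEFAULT_LINKAGE_CUTOFF,
    min_members_exclusive: int = DEFAULT_MIN_MEMBERS,
    box_edge: float = DEFAULT_BOX_EDGE,
    spacing: float = DEFAULT_SPACING,
) -> tuple[list[SiteCluster], list[str]]:
    """Group pose centroids into binding-site clusters.

    Parameters
    ----------
    poses : one (best) pose per ligand.
    linkage_cutoff : Å; poses whose centroids are within this distance are
        linked, and linked components form candidate sites.
    min_members_exclusive : a component is a cluster only when its member
        count is **strictly greater** than this.
    box_edge, spacing : geometry of the targeted-docking box derived per
        cluster.

    Returns ``(clusters, unclustered)``: clusters sorted by descending member
    count (ties broken by centroid x, then y, then z) and numbered from 1,
    plus the ligand ids left in low-density sites.  Clusters and unclustered
    ids partition the input.
    """
    if not poses:
        return [], []
    if linkage_cutoff <= 0:
        raise ValueError("linkage_cutoff must be > 0")
    points = np.array([p.centroid for p in poses])
    labels = _single_linkage_labels(points, linkage_cutoff)

    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)

    candidates = []
    unclustered: list[str] = []
    for members in groups.values():
        if len(members) > min_members_exclusive:
            centroid = points[members].mean(axis=0)
            candidates.append((members, centroid))
        else:
            unclustered.extend(poses[i].ligand_id for i in members)

    candidates.sort(key=lambda mc: (-len(mc[0]), mc[1][0], mc[1][1], mc[1][2]))
    clusters = [
        SiteCluster(
            cluster_id=cid,
            members=[poses[i].ligand_id for i in members],
            centroid=centroid,
            box=targeted_box_from_centroid(centroid, box_edge, spacing),
        )
        for cid, (members, centroid) in enumerate(candidates, start=1)
    ]
    return clusters, unclustered


def targeted_box_from_centroid(
    centroid: np.ndarray, edge: float = DEFAULT_BOX_EDGE, spacing: float = DEFAULT_SPACING
) -> Box:
    return Box(centre=tuple(float(c) for c in centroid), edges=(edge, edge, edge), spacing=spacing)


def targeted_box_from_cluster(
    c: SiteCluster, edge: float = DEFAULT_BOX_EDGE, spacing: float = DEFAULT_SPACING
) -> Box:
    """Targeted-docking grid box centred on a cluster's centroid."""
    if c.member_count == 0:
        raise ValueError("cluster has no members")
    return targeted_box_from_centroid(c.centroid, edge, spacing)


def write_cluster_report(
    clusters: Sequence[SiteCluster], unclustered: Sequence[str], path: str | Path
) -> None:
    """TSV report: one row per cluster plus a trailing row for low-density ligands."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember_count\tcentroid_x\tcentroid_y\tcentroid_z\tmembers\n")
        for c in clusters:
            cx, cy, cz = c.centroid
            fh.write(
                f"{c.cluster_id}\t{c.member_count}\t{cx:.3f}\t{cy:.3f}\t{cz:.3f}\t"
                f"{','.join(c.members)}\n"
            )
        if unclustered:
            fh.write(f"unclustered\t{len(unclustered)}\t\t\t\t{','.join(unclustered)}\n")
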