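"""Hierarchical agglomerative clustering of receptor conformations.

Frames from all production replicas of a system are pooled (with a stride
keeping the O(n²) distance matrix desk-sized), pairwise receptor-Cα RMSD
is computed with optimal superposition, and average-linkage agglomerative
clustering is cut either at a distance threshold ε or at a fixed cluster
count. The most populated cluster's medoid frame — the member minimizing
mean RMSD to the cluster — supplies the reference contact map for
saliency attribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._geom import pairwise_rmsd_matrix
from .constants import ROLE_RECEPTOR
from .contacts import ContactMap, compute_contact_map
from .errors import ConfigurationError, ValidationError
from .trajio import MolecularSystem, TrajectoryEnsemble

__all__ = ["ClusterResult", "cluster_conformations", "representative_contact_map"]


@dataclass
class ClusterResult:
    """Frame-level cluster assignment over the pooled (strided) ensemble."""

    labels: np.ndarray                 # (n_used,) dense ids from 0
    frame_refs: list[tuple[int, int]]  # (member_idx, frame_idx) per used frame
    sizes: np.ndarray                  # per-cluster frame counts
    representatives: np.ndarray        # per-cluster index into frame_refs (medoid)
    linkage: str
    metric: str
    stop: str
    stride: int

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def largest_cluster(self) -> int:
        # ties broken by lower cluster id (argmax returns first maximum)
        return int(np.argmax(self.sizes))


def cluster_conformations(trajectories: list[TrajectoryEnsemble],
                          linkage_method: str = "average",
                          epsilon: float = 2.5, k: int | None = None,
                          stride: int | None = None,
                          max_frames: int = 1500) -> ClusterResult:
    """Average-linkage clustering on pairwise receptor-Cα RMSD.

    Stop criterion: ``k`` clusters if given, else distance threshold
    ``epsilon`` (Å). ``stride`` defaults to the smallest value keeping at
    most ``max_frames`` pooled frames. Deterministic: scipy's linkage is
    deterministic, and medoids break ties by the lowest frame index.
    """
    if not trajectories:
        raise ValidationError("no trajectories to cluster")
    system = trajectories[0].source_system
    total = sum(t.n_frames for t in trajectories)
    if stride is None:
        stride = max(1, math.ceil(total / max_frames))
    refs = [(mi, fi) for mi, t in enumerate(trajectories)
            for fi in range(0, t.n_frames, stride)]
    if len(refs) < 2:
        raise ValidationError(f"stride {stride} leaves fewer than 2 frames")

    ca = system.calpha_indices(ROLE_RECEPTOR)
    if len(ca) == 0:
        raise ConfigurationError("no receptor Cα atoms")
    coords = np.stack([trajectories[mi].frames[fi][ca] for mi, fi in refs])
    dist = pairwise_rmsd_matrix(coords)

    z = linkage(squareform(dist, checks=False), method=linkage_method)
    if k is not None:
        raw = fcluster(z, t=k, criterion="maxclust")
    else:
        raw = fcluster(z, t=epsilon, criterion="distance")
    # relabel densely in order of first appearance (frame order)
    remap: dict[int, int] = {}
    labels = np.empty(len(raw), dtype=int)
    for i, r in enumerate(raw):
        if r not in remap:
            remap[r] = len(remap)
        labels[i] = remap[r]
    n_clusters = len(remap)
    sizes = np.bincount(labels, minlength=n_clusters)

    reps = np.empty(n_clusters, dtype=int)
    for c in range(n_clusters):
        members = np.nonzero(labels == c)[0]
        mean_d = dist[np.ix_(members, members)].mean(axis=1)
        reps[c] = members[int(np.argmin(mean_d))]   # first minimum = lowest index

    stop = f"maxclust={k}" if k is not None else f"epsilon={epsilon}A"
    return ClusterResult(labels=labels, frame_refs=refs, sizes=sizes,
                         representatives=reps, linkage=linkage_method,
                         metric="receptor-CA-RMSD", stop=stop, stride=stride)


def representative_contact_map(result: ClusterResult,
                               trajectories: list[TrajectoryEnsemble],
                               system: MolecularSystem,
                               cutoff: float = 4.5, min_seq_sep: int = 3) -> ContactMap:
    """Contact map of the medoid frame of the most populated cluster."""
    rep = result.representatives[result.largest_cluster()]
    mi, fi = result.frame_refs[rep]
    return compute_contact_map(trajectories[mi].frames[fi], system,
                               cutoff=cutoff, min_seq_sep=min_seq_sep,
                               source="cluster-representative")
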