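"""Associate MSM macrostates with whole-structure conformations.

The MSM lives in a reduced torsion space; to interpret its macrostates as
full-protein conformations, the trajectory frames are clustered on
whole-scaffold pairwise RMSD with the Jarvis–Patrick method, average
structures of the clusters are computed by iterative alignment, and each
macrostate representative is matched to the cluster average with the
minimum backbone RMSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_superpose, apply_transform
from .structure import TrajectoryEnsemble

__all__ = [
    "StructureClustering",
    "AssociationRecord",
    "pairwise_rmsd_matrix",
    "jarvis_patrick",
    "average_structure",
    "associate_macrostates",
]


@dataclass
class StructureClustering:
    labels: np.ndarray                 # cluster id per frame
    weights_pct: dict[int, float]      # cluster id → % of frames
    averages: dict[int, np.ndarray]    # cluster id → average coordinates

    def __post_init__(self) -> None:
        total = sum(self.weights_pct.values())
        if abs(total - 100.0) > 0.1:
            raise ValueError(f"cluster weights sum to {total}, expected 100")


@dataclass
class AssociationRecord:
    macrostate: int
    cluster: int
    source_label: str
    weight_pct: float
    rmsd_A: float

    def __post_init__(self) -> None:
        if self.rmsd_A < 0:
            raise ValueError("RMSD must be ≥ 0")


def pairwise_rmsd_matrix(traj: TrajectoryEnsemble, subset=None) -> np.ndarray:
    """Symmetric frame × frame minimum RMSD matrix (Kabsch-aligned)."""
    n = traj.n_frames
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, rmsd = kabsch_superpose(traj.frames[j], traj.frames[i], subset)
            out[i, j] = out[j, i] = rmsd
    return out


def jarvis_patrick(
    pairwise_rmsd: np.ndarray,
    n_neighbors: int = 10,
    min_shared: int = 3,
) -> StructureClustering:
    """Jarvis–Patrick clustering on a pairwise distance matrix.

    Two frames join iff each lists the other among its K nearest
    neighbors and they share at least ``min_shared`` common neighbors;
    clusters are the connected components of the join graph.  Weights are
    component sizes as percentages of all frames.  Averages are filled in
    by the caller (see :func:`cluster_trajectory`).
    """
    import scipy.sparse.csgraph

    d = np.asarray(pairwise_rmsd, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("pairwise matrix must be square and symmetric")
    if np.any(np.abs(np.diag(d)) > 1e-8):
        raise ValueError("pairwise matrix must have a zero diagonal")
    if n_neighbors >= n:
        raise ValueError(f"n_neighbors={n_neighbors} must be < n frames ({n})")
    # K nearest neighbors per frame (self excluded); distances tied with the
    # K-th nearest are all included so equidistant frames are treated alike
    neighbor_sets = []
    for i in range(n):
        others = np.argsort(d[i], kind="stable")
        others = others[others != i]
        radius = d[i, others[n_neighbors - 1]]
        neighbor_sets.append(
            set(int(j) for j in others if d[i, j] <= radius + 1e-12)
        )
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if j in neighbor_sets[i] and i in neighbor_sets[j]:
                if len(neighbor_sets[i] & neighbor_sets[j]) >= min_shared:
                    adj[i, j] = adj[j, i] = True
    n_comp, labels = scipy.sparse.csgraph.connected_components(adj, directed=False)
    # relabel components by decreasing size (ties: lowest first-frame index)
    sizes = np.bincount(labels, minlength=n_comp)
    first = [int(np.flatnonzero(labels == c)[0]) for c in range(n_comp)]
    order = sorted(range(n_comp), key=lambda c: (-sizes[c], first[c]))
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in labels], dtype=int)
    weights = {
        cid: 100.0 * int((labels == cid).sum()) / n
        for cid in range(n_comp)
    }
    return StructureClustering(labels=labels, weights_pct=weights, averages={})


def average_structure(
    frames: np.ndarray,
    subset=None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Iterative mean structure: align every frame onto the running mean
    (Kabsch, over ``subset``), re-average, repeat to convergence ``tol`` Å."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[0] < 1:
        raise ValueError("frames must be (n_frames, n_atoms, 3) with ≥ 1 frame")
    if frames.shape[0] == 1:
        return frames[0].copy()
    mean = frames[0].copy()
    for _ in range(max_iter):
        aligned = np.empty_like(frames)
        for f in range(frames.shape[0]):
            rot, trans, _ = kabsch_superpose(frames[f], mean, subset)
            aligned[f] = apply_transform(frames[f], rot, trans)
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    return mean


def cluster_trajectory(
    traj: TrajectoryEnsemble,
    subset=None,
    n_neighbors: int = 10,
    min_shared: int = 3,
) -> StructureClustering:
    """Jarvis–Patrick clustering of a trajectory plus per-cluster averages."""
    d = pairwise_rmsd_matrix(traj, subset)
    clustering = jarvis_patrick(d, n_neighbors, min_shared)
    for cid in clustering.weights_pct:
        members = np.flatnonzero(clustering.labels == cid)
        clustering.averages[cid] = average_structure(traj.frames[members], subset)
    return clustering


def associate_macrostates(
    representatives: dict[int, np.ndarray],
    clustering: StructureClustering,
    subset=None,
    source_label: str = "",
    max_rmsd: float | None = None,
) -> list[AssociationRecord]:
    """Match each macrostate representative to its minimum-RMSD cluster average.

    Ties break toward the larger cluster weight, then the lower cluster id.
    ``max_rmsd`` (off by default) rejects matches above the cutoff, mirroring
    the possibility that a trajectory provides no matching structure.
    """
    if not clustering.averages:
        raise ValueError("clustering has no average structures")
    records = []
    for macro_id in sorted(representatives):
        rep = np.asarray(representatives[macro_id], dtype=float)
        best = None
        for cid, avg in sorted(clustering.averages.items()):
            if avg.shape != rep.shape:
                raise ValueError(
                    f"cluster {cid} average has shape {avg.shape}, "
                    f"macrostate {macro_id} representative {rep.shape}"
                )
            _, _, rmsd = kabsch_superpose(rep, avg, subset)
            key = (rmsd, -clustering.weights_pct[cid], cid)
            if best is None or key < best[0]:
                best = (key, cid, rmsd)
        _, cid, rmsd = best
        if max_rmsd is not None and rmsd > max_rmsd:
            continue
        records.append(AssociationRecord(
            macrostate=macro_id,
            cluster=cid,
            source_label=source_label,
            weight_pct=clustering.weights_pct[cid],
            rmsd_A=rmsd,
        ))
    return records


def association_table_to_tsv(records, path) -> None:
    import pandas as pd

    pd.DataFrame([
        {"macrostate": r.macrostate, "cluster": r.cluster,
         "source_label": r.source_label, "weight_pct": r.weight_pct,
         "rmsd_A": r.rmsd_A}
        for r in records
    ]).to_csv(path, sep="\t", index=False, float_format="%.6f")
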