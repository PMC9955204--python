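"""Residue-coupling allostery analysis: correlation matrix, distance-gated
graph, and shortest communication pathways.

Couplings are normalized cross-correlations of Cα displacement vectors
(dot-product form), computed after rigid-body alignment of every frame to
the mean structure.  A residue graph keeps an edge only when the mean
Cα–Cα distance is within a cutoff (default 12 Å = 1.2 nm) and the
coupling is non-zero; edge weights are −ln|C_ij| so strong coupling makes
short paths, and the minimum-weight path between two residues is the
dominant allosteric communication route.

This deterministic estimator stands in for a trained neural relational
inference model: only the correlation/pathway outputs are consumed
downstream, and the estimator is pluggable should a learned back-end be
added.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .geometry import apply_transform, kabsch_superpose
from .macrostates import average_structure
from .structure import TrajectoryEnsemble, select_atoms

__all__ = [
    "CouplingMatrix",
    "PathResult",
    "coupling_matrix",
    "coarse_grain_nodes",
    "build_graph",
    "shortest_path",
    "DEFAULT_CUTOFF_A",
    "DEFAULT_REPORT_THRESHOLD",
]

DEFAULT_CUTOFF_A = 12.0          # 1.2 nm Cα–Cα interaction cutoff
DEFAULT_REPORT_THRESHOLD = 0.6   # |C| display threshold for reporting


@dataclass
class CouplingMatrix:
    residues: list[int]
    values: np.ndarray           # symmetric, unit diagonal, entries in [-1, 1]
    undefined: list[int]         # residues with zero displacement variance

    def __post_init__(self) -> None:
        c = self.values
        n = len(self.residues)
        if c.shape != (n, n):
            raise ValueError("coupling matrix shape must match residue count")
        defined = [i for i, r in enumerate(self.residues) if r not in self.undefined]
        sub = c[np.ix_(defined, defined)]
        if not np.allclose(sub, sub.T, atol=1e-10):
            raise ValueError("coupling matrix must be symmetric")
        if np.any(np.abs(sub) > 1.0 + 1e-10):
            raise ValueError("couplings must lie in [-1, 1]")
        if defined and not np.allclose(np.diag(c)[defined], 1.0, atol=1e-10):
            raise ValueError("coupling diagonal must be 1")


@dataclass
class PathResult:
    residues: list[int]
    total_weight: float
    edge_weights: list[float]
    found: bool = True

    def __post_init__(self) -> None:
        if self.found and abs(sum(self.edge_weights) - self.total_weight) > 1e-9:
            raise ValueError("total weight must equal the sum of edge weights")


def coupling_matrix(
    ca_traj: TrajectoryEnsemble,
    residues=None,
    align: bool = True,
) -> CouplingMatrix:
    """Normalized displacement cross-correlations between Cα atoms.

    C_ij = ⟨Δr_i · Δr_j⟩ / √(⟨|Δr_i|²⟩ ⟨|Δr_j|²⟩), Δr the displacement
    from the mean structure after global Kabsch alignment of every frame
    (``align=False`` skips the alignment; useful for controlled fixtures).
    Residues with zero variance are flagged undefined and excluded from
    graph construction.
    """
    if ca_traj.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate couplings")
    ca_idx = select_atoms(ca_traj.topology, "CA")
    res_of_idx = ca_traj.topology.res_ids[ca_idx]
    if residues is not None:
        keep = np.isin(res_of_idx, list(residues))
        ca_idx = ca_idx[keep]
        res_of_idx = res_of_idx[keep]
    coords = ca_traj.frames[:, ca_idx, :]
    if align:
        mean = average_structure(coords)
        aligned = np.empty_like(coords)
        for f in range(coords.shape[0]):
            rot, trans, _ = kabsch_superpose(coords[f], mean)
            aligned[f] = apply_transform(coords[f], rot, trans)
        coords = aligned
    mean = coords.mean(axis=0)
    disp = coords - mean                      # (frames, residues, 3)
    inner = np.einsum("fid,fjd->ij", disp, disp) / disp.shape[0]
    var = np.diag(inner).copy()
    undefined = [int(res_of_idx[i]) for i in np.flatnonzero(var < 1e-14)]
    var_safe = np.where(var < 1e-14, 1.0, var)
    c = inner / np.sqrt(np.outer(var_safe, var_safe))
    np.fill_diagonal(c, 1.0)
    c = np.clip(0.5 * (c + c.T), -1.0, 1.0)
    return CouplingMatrix(residues=[int(r) for r in res_of_idx], values=c,
                          undefined=undefined)


def coarse_grain_nodes(residues, offset: int | None = None):
    """Alternating-residue node subsets for two half-resolution runs.

    With ``offset`` None, returns ``(subset0, subset1)``: every second
    residue starting at the first and at the second.  Downstream results
    are computed per subset and merged by union, each edge tagged with its
    run of origin.
    """
    residues = sorted(int(r) for r in residues)
    if len(residues) < 2:
        raise ValueError("need at least 2 residues to coarse-grain")
    if offset is not None:
        if offset not in (0, 1):
            raise ValueError("offset must be 0 or 1")
        return residues[offset::2]
    return residues[0::2], residues[1::2]


def mean_distance_matrix(ca_traj: TrajectoryEnsemble, residues=None) -> tuple[list[int], np.ndarray]:
    """Mean Cα–Cα distances (Å) over frames, (residues, matrix)."""
    ca_idx = select_atoms(ca_traj.topology, "CA")
    res_of_idx = ca_traj.topology.res_ids[ca_idx]
    if residues is not None:
        keep = np.isin(res_of_idx, list(residues))
        ca_idx = ca_idx[keep]
        res_of_idx = res_of_idx[keep]
    coords = ca_traj.frames[:, ca_idx, :]
    diff = coords[:, :, None, :] - coords[:, None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=-1)).mean(axis=0)
    return [int(r) for r in res_of_idx], d


def build_graph(
    coupling: CouplingMatrix,
    mean_distances: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF_A,
    min_abs_coupling: float = 0.0,
) -> nx.Graph:
    """Distance-gated residue graph with weights −ln|C_ij|.

    An edge (i, j) exists iff the mean Cα–Cα distance is ≤ ``cutoff`` Å
    and |C_ij| > ``min_abs_coupling``; undefined residues carry no edges.
    Edge attributes: ``weight`` (−ln|C|), ``coupling``, ``distance_A``.
    """
    n = len(coupling.residues)
    mean_distances = np.asarray(mean_distances, dtype=float)
    if mean_distances.shape != (n, n):
        raise ValueError("distance matrix must conform to the coupling matrix")
    g = nx.Graph()
    g.add_nodes_from(coupling.residues)
    undef = set(coupling.undefined)
    for i in range(n):
        for j in range(i + 1, n):
            ri, rj = coupling.residues[i], coupling.residues[j]
            if ri in undef or rj in undef:
                continue
            cij = float(coupling.values[i, j])
            if mean_distances[i, j] > cutoff or abs(cij) <= min_abs_coupling:
                continue
            if cij == 0.0:
                continue
            g.add_edge(ri, rj, weight=float(-np.log(abs(cij))),
                       coupling=cij, distance_A=float(mean_distances[i, j]))
    return g


def shortest_path(graph: nx.Graph, source: int = 768, target: int = 976) -> PathResult:
    """Dijkstra minimum-weight path with lexicographic tie-breaking.

    Returns an explicit not-found result (``found=False``) when the pair
    is disconnected, never an exception.
    """
    for node in (source, target):
        if node not in graph:
            raise KeyError(f"residue {node} is not a node of the graph")
    # heap entries are (distance, path-as-tuple): with non-negative weights
    # the first pop of a node is its shortest distance, and among equal
    # distances the lexicographically smallest path — a deterministic
    # tie-break networkx does not guarantee
    finalized: dict[int, tuple[float, tuple[int, ...]]] = {}
    heap: list[tuple[float, tuple[int, ...]]] = [(0.0, (source,))]
    while heap:
        dist, path = heapq.heappop(heap)
        node = path[-1]
        if node in finalized:
            continue
        finalized[node] = (dist, path)
        if node == target:
            break
        for nbr in sorted(graph.neighbors(node)):
            if nbr not in finalized:
                w = graph.edges[node, nbr]["weight"]
                heapq.heappush(heap, (dist + w, path + (nbr,)))
    if target not in finalized:
        return PathResult(residues=[], total_weight=float("inf"),
                          edge_weights=[], found=False)
    dist, path = finalized[target]
    edge_weights = [
        float(graph.edges[path[i], path[i + 1]]["weight"])
        for i in range(len(path) - 1)
    ]
    return PathResult(residues=list(path), total_weight=float(sum(edge_weights)),
                      edge_weights=edge_weights)


def coupling_to_tsv(coupling: CouplingMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(coupling.values, index=coupling.residues,
                 columns=coupling.residues).to_csv(path, sep="\t",
                                                   float_format="%.6f")


def graph_to_tsv(graph: nx.Graph, path) -> None:
    import pandas as pd

    rows = [
        {"res_i": u, "res_j": v, "distance_A": d["distance_A"],
         "coupling": d["coupling"], "weight": d["weight"]}
        for u, v, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["res_i", "res_j", "distance_A", "coupling",
                                "weight"]).to_csv(path, sep="\t", index=False,
                                                  float_format="%.6f")
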