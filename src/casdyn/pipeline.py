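"""End-to-end orchestration of the analysis stages.

Order: featurize → tICA → k-means discretization → MSM (implied
timescales, Bayesian ensemble, CK test) → PCCA++ macrostates →
macrostate–structure association → allostery graph/path → markers →
pucker table.  A failed stage is recorded in the report and later
independent stages are still attempted.  Every stochastic stage consumes
a named seed from the config, so reruns are numerically identical.
"""

from __future__ import annotations

import json
import logging
import os
import time
import traceback
from dataclasses import dataclass, field

import numpy as np

from . import allostery as allo
from . import macrostates as macro
from . import markers as mk
from . import msm as msm_mod
from . import tica as tica_mod
from .config import RunConfig, cumulative_time_us, validate_config
from .geometry import featurize_torsions, pucker_table, pucker_table_to_tsv
from .structure import domain_composition, read_structure, read_trajectory

__all__ = ["RunReport", "run_pipeline", "write_demo_inputs"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class StageStatus:
    status: str                       # "ok" | "failed" | "disabled"
    outputs: list[str] = field(default_factory=list)
    headline: dict = field(default_factory=dict)
    error: str = ""
    seconds: float = 0.0


@dataclass
class RunReport:
    stages: dict[str, StageStatus] = field(default_factory=dict)
    derived: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        def clean(obj):
            if isinstance(obj, dict):
                return {str(k): clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return clean(obj.tolist())
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating, float)):
                v = float(obj)
                return v if np.isfinite(v) else str(v)
            return obj

        payload = {
            "derived": clean(self.derived),
            "stages": {
                name: {
                    "status": s.status, "outputs": s.outputs,
                    "headline": clean(s.headline), "error": s.error,
                    "seconds": round(s.seconds, 3),
                }
                for name, s in self.stages.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _stage(report: RunReport, name: str):
    """Decorator-ish context: run fn, catch failure into the report."""
    class _Ctx:
        def __init__(self):
            self.t0 = time.perf_counter()

        def ok(self, outputs=(), **headline):
            report.stages[name] = StageStatus(
                "ok", list(outputs), headline,
                seconds=time.perf_counter() - self.t0)

        def failed(self, exc):
            logger.warning("stage %s failed: %s", name, exc)
            report.stages[name] = StageStatus(
                "failed", error=f"{type(exc).__name__}: {exc}",
                seconds=time.perf_counter() - self.t0)

        def disabled(self):
            report.stages[name] = StageStatus("disabled")

    return _Ctx()


def _write_tsv(path, header, rows):
    import pandas as pd

    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False,
                                              float_format=_FLOAT_FMT)


def run_pipeline(cfg: RunConfig, out_dir: str | os.PathLike) -> RunReport:
    """Run all enabled stages; returns (and writes) the run report."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    report = RunReport()
    report.derived = validate_config(cfg)

    topology = read_structure(cfg.topology)
    traj = read_trajectory(list(cfg.trajectories), topology, cfg.frame_stride_ns)

    features = None
    ctx = _stage(report, "featurize")
    try:
        features = featurize_torsions(traj, cfg.feature_residue_range)
        comp = domain_composition(features.residues, cfg.domain_map)
        path = os.path.join(out_dir, "domain_composition.tsv")
        _write_tsv(path, ["domain", "pct"], sorted(comp.items()))
        ctx.ok([path], n_features=features.values.shape[1],
               n_frames=features.n_frames, composition=comp)
    except Exception as exc:
        ctx.failed(exc)

    tica_model = projection = None
    ctx = _stage(report, "tica")
    if features is not None:
        try:
            tica_model = tica_mod.estimate_tica(
                features, cfg.tica.lag_frames, cfg.tica.n_dims, cfg.tica.reg)
            projection = tica_model.training_projection
            selected, scores = tica_mod.feature_contributions(
                tica_model, cfg.tica.threshold)
            vamp2 = tica_mod.vamp2_score(features, cfg.tica.lag_frames,
                                         cfg.tica.n_dims)
            path = os.path.join(out_dir, "tica_contributions.tsv")
            _write_tsv(path, ["residue", "score", "selected"],
                       [(r, s, r in selected) for r, s in sorted(scores.items())])
            ctx.ok([path], eigenvalues=tica_model.eigenvalues[: cfg.tica.n_dims],
                   vamp2=vamp2, selected_residues=selected)
        except Exception as exc:
            ctx.failed(exc)

    disc = None
    ctx = _stage(report, "discretize")
    if projection is not None:
        try:
            k = min(cfg.msm.n_clusters, projection.shape[0])
            disc = msm_mod.kmeans(projection, k=k, seed=cfg.msm.seed)
            ctx.ok([], k=k, inertia=disc.inertia)
        except Exception as exc:
            ctx.failed(exc)

    model = ensemble = grouping = None
    ctx = _stage(report, "msm")
    if disc is not None:
        try:
            counts = msm_mod.count_matrix(disc.assignments, cfg.msm.lag_frames)
            model = msm_mod.estimate_msm(counts, frame_stride_ns=cfg.frame_stride_ns)
            ensemble = msm_mod.bayesian_sample(
                counts, cfg.msm.n_bayes_samples, seed=cfg.msm.seed,
                frame_stride_ns=cfg.frame_stride_ns)
            lags = sorted({max(1, cfg.msm.lag_frames // 2), cfg.msm.lag_frames,
                           cfg.msm.lag_frames * 2})
            its = msm_mod.implied_timescales(
                disc.assignments, lags, frame_stride_ns=cfg.frame_stride_ns)
            path = os.path.join(out_dir, "implied_timescales.tsv")
            _write_tsv(path, ["lag_ns", "t1_ns", "t2_ns", "t3_ns"],
                       [(r["lag_ns"], *np.pad(r["timescales"], (0, 3))[:3])
                        for r in its])
            ctx.ok([path], timescales_ns=model.timescales(3),
                   n_active=int(model.active_set.size))
        except Exception as exc:
            ctx.failed(exc)

    ctx = _stage(report, "ck_test")
    if model is not None and ensemble is not None:
        try:
            pre_grouping = msm_mod.pcca(model, min(cfg.msm.n_macrostates,
                                                   model.transition_matrix.shape[0]))
            ck = msm_mod.ck_test(model, ensemble, disc.assignments, pre_grouping,
                                 factors=cfg.msm.ck_factors)
            ctx.ok([], passed=ck["passed"], fraction_inside=ck["fraction_inside"])
        except Exception as exc:
            ctx.failed(exc)

    ctx = _stage(report, "pcca")
    if model is not None:
        try:
            grouping = msm_mod.pcca(model, min(cfg.msm.n_macrostates,
                                               model.transition_matrix.shape[0]))
            times, rates = msm_mod.macrostate_transition_times(model, grouping)
            path = os.path.join(out_dir, "macrostate_mfpt_ns.tsv")
            _write_tsv(path, ["from", "to", "mfpt_ns", "rate_per_ns"],
                       [(a + 1, b + 1, times[a, b], rates[a, b])
                        for a in range(grouping.m) for b in range(grouping.m)
                        if a != b])
            ctx.ok([path], n_macrostates=grouping.m,
                   populations=[float(model.stationary[grouping.assignments == a].sum())
                                for a in range(grouping.m)])
        except Exception as exc:
            ctx.failed(exc)

    ctx = _stage(report, "fes")
    if model is not None and projection is not None and projection.shape[1] >= 2:
        try:
            active_frames = np.isin(disc.assignments, model.active_set)
            weights = msm_mod.frame_weights(disc.assignments, model)
            grid = msm_mod.free_energy_surface(
                projection[active_frames][:, :2], weights[active_frames],
                bins=cfg.msm.fes_bins)
            path = os.path.join(out_dir, "fes_kT.tsv")
            rows = []
            for i in range(grid.free_energy.shape[0]):
                for j in range(grid.free_energy.shape[1]):
                    f = grid.free_energy[i, j]
                    if np.isfinite(f):
                        rows.append((
                            0.5 * (grid.x_edges[i] + grid.x_edges[i + 1]),
                            0.5 * (grid.y_edges[j] + grid.y_edges[j + 1]), f))
            _write_tsv(path, ["bin_x", "bin_y", "F_kT"], rows)
            ctx.ok([path], n_occupied_bins=len(rows))
        except Exception as exc:
            ctx.failed(exc)

    ctx = _stage(report, "macrostate_association")
    if cfg.macrostates.enabled and grouping is not None and disc is not None:
        try:
            stride = max(1, traj.n_frames // cfg.macrostates.max_frames)
            sub_idx = np.arange(0, traj.n_frames, stride)
            sub = type(traj)(topology=traj.topology,
                             frames=traj.frames[sub_idx],
                             frame_stride_ns=traj.frame_stride_ns * stride)
            clustering = macro.cluster_trajectory(
                sub, n_neighbors=min(cfg.macrostates.n_neighbors,
                                     sub.n_frames - 1),
                min_shared=cfg.macrostates.min_shared)
            # representative frame per macrostate: highest PCCA++ membership
            reps = {}
            state_of_frame = disc.assignments
            active_pos = {s: i for i, s in enumerate(model.active_set)}
            for a in range(grouping.m):
                memb = np.array([
                    grouping.memberships[active_pos[s], a]
                    if s in active_pos else 0.0
                    for s in state_of_frame
                ])
                reps[a + 1] = traj.frames[int(np.argmax(memb))]
            records = macro.associate_macrostates(
                reps, clustering, source_label="synthetic",
                max_rmsd=cfg.macrostates.max_rmsd)
            path = os.path.join(out_dir, "macrostate_association.tsv")
            macro.association_table_to_tsv(records, path)
            ctx.ok([path], n_clusters=len(clustering.weights_pct),
                   associations=[(r.macrostate, r.cluster, r.rmsd_A)
                                 for r in records])
        except Exception as exc:
            ctx.failed(exc)
    elif not cfg.macrostates.enabled:
        ctx.disabled()

    ctx = _stage(report, "allostery")
    if cfg.allostery.enabled:
        try:
            lo, hi = cfg.allostery.residue_range
            resids = [r for r in sorted(set(topology.res_ids))
                      if lo <= r <= hi]
            coupling = allo.coupling_matrix(traj, resids)
            res_list, dmat = allo.mean_distance_matrix(traj, resids)
            graph = allo.build_graph(coupling, dmat, cutoff=cfg.allostery.cutoff_A)
            result = allo.shortest_path(graph, cfg.allostery.source,
                                        cfg.allostery.target)
            cpath = os.path.join(out_dir, "coupling_matrix.tsv")
            gpath = os.path.join(out_dir, "allostery_edges.tsv")
            ppath = os.path.join(out_dir, "allostery_path.tsv")
            allo.coupling_to_tsv(coupling, cpath)
            allo.graph_to_tsv(graph, gpath)
            _write_tsv(ppath, ["order", "residue"],
                       list(enumerate(result.residues)))
            ctx.ok([cpath, gpath, ppath], path_found=result.found,
                   path_residues=result.residues,
                   path_weight=result.total_weight)
        except Exception as exc:
            ctx.failed(exc)
    else:
        ctx.disabled()

    ctx = _stage(report, "markers")
    if cfg.markers.enabled:
        try:
            rows = []
            skipped = []
            for group in mk.builtin_markers():
                for marker in group.markers:
                    try:
                        profile = mk.profile_marker(
                            traj, marker, cfg.markers.n_components,
                            seed=cfg.markers.seed)
                    except KeyError:
                        skipped.append(marker.label)
                        continue
                    for ci, (mean, sd, amp) in enumerate(profile.fit):
                        rows.append((marker.label, ci, mean, sd, amp))
            path = os.path.join(out_dir, "marker_fits.tsv")
            _write_tsv(path, ["marker", "component", "mean_A", "sd_A",
                              "amplitude"], rows)
            ctx.ok([path], n_fitted=len(rows), skipped=skipped)
        except Exception as exc:
            ctx.failed(exc)
    else:
        ctx.disabled()

    ctx = _stage(report, "pucker")
    if cfg.pucker.enabled:
        try:
            records = pucker_table(traj, cfg.pucker.residues,
                                   dict(cfg.pucker.strands))
            path = os.path.join(out_dir, "pucker_table.tsv")
            pucker_table_to_tsv(records, path)
            regimes = {}
            for r in records:
                regimes[r.regime] = regimes.get(r.regime, 0) + 1
            ctx.ok([path], n_records=len(records), regimes=regimes)
        except Exception as exc:
            ctx.failed(exc)
    else:
        ctx.disabled()

    report.to_json(os.path.join(out_dir, "run_report.json"))
    return report


# ---------------------------------------------------------------------------
# Shipped synthetic demo


def write_demo_inputs(directory: str | os.PathLike, seed: int = 0,
                      n_frames: int = 400) -> str:
    """Write the synthetic end-to-end demo inputs; returns the config path.

    A 6-residue peptide whose backbone torsions hop between four
    metastable basins following a known block-structured Markov chain
    (two weakly coupled 2-state blocks).  The full pipeline on this input
    recovers four macrostates matching the planted states.
    """
    import yaml

    from .structure import write_structure, write_trajectory_pdb
    from .synthetic import MarkovChainSpec, block_transition_matrix, markov_backbone_trajectory

    directory = str(directory)
    os.makedirs(directory, exist_ok=True)
    t_true = block_transition_matrix(n_blocks=2, block_size=2,
                                     intra=0.08, inter=0.02)
    spec = MarkovChainSpec(transition_matrix=t_true, initial_state=0, seed=seed)
    traj, states = markov_backbone_trajectory(spec, n_frames, n_residues=6,
                                              torsion_noise_deg=5.0)
    top_path = os.path.join(directory, "topology.pdb")
    traj_path = os.path.join(directory, "trajectory.pdb")
    write_structure(traj.topology, top_path)
    write_trajectory_pdb(traj, traj_path)
    np.savetxt(os.path.join(directory, "true_states.tsv"), states, fmt="%d",
               header="state", comments="")
    cfg = {
        "topology": top_path,
        "trajectories": [traj_path],
        "frame_stride_ns": 1.0,
        "feature_residue_range": [1, 6],
        "domain_map": {"toy": ["1-6"]},
        "tica": {"lag_frames": 2, "n_dims": 3, "threshold": 0.195},
        "msm": {"lag_frames": 2, "n_clusters": 20, "n_macrostates": 4,
                "n_bayes_samples": 30, "seed": seed, "ck_factors": [2, 3]},
        "allostery": {"enabled": True, "residue_range": [1, 6],
                      "cutoff_nm": 2.0, "source": 1, "target": 6},
        "markers": {"enabled": False},
        "macrostates": {"enabled": True, "max_frames": 120},
        "pucker": {"enabled": False},
        "replica_bookkeeping": {"n_conditions": 2, "n_replicas": 16,
                                "ns_per_replica": 100},
    }
    cfg_path = os.path.join(directory, "config.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return cfg_path
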