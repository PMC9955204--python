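"""Run configuration: YAML parsing, validation, and derived bookkeeping."""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import yaml

from .structure import CAS9_DOMAIN_MAP, DomainMap

__all__ = ["RunConfig", "load_config", "validate_config", "cumulative_time_us"]


@dataclass
class TicaSettings:
    lag_frames: int = 50
    n_dims: int = 4
    threshold: float = 0.195
    reg: float = 1e-8


@dataclass
class MsmSettings:
    lag_frames: int = 50
    n_clusters: int = 100
    n_macrostates: int = 4
    n_bayes_samples: int = 100
    seed: int = 0
    ck_factors: tuple[int, ...] = (2, 3, 4, 5)
    fes_bins: int = 50


@dataclass
class AllosterySettings:
    enabled: bool = True
    residue_range: tuple[int, int] = (767, 984)
    cutoff_nm: float = 1.2
    report_threshold: float = 0.6
    source: int = 768
    target: int = 976

    @property
    def cutoff_A(self) -> float:
        return self.cutoff_nm * 10.0


@dataclass
class MarkerSettings:
    enabled: bool = True
    n_components: int = 1
    seed: int = 0


@dataclass
class MacrostateSettings:
    enabled: bool = True
    max_frames: int = 150
    n_neighbors: int = 10
    min_shared: int = 3
    max_rmsd: float | None = None


@dataclass
class PuckerSettings:
    enabled: bool = False
    residues: tuple[int, ...] = ()
    strands: dict = field(default_factory=dict)


@dataclass
class ReplicaBookkeeping:
    """Enhanced-sampling bookkeeping (no simulation is run here)."""

    n_conditions: int = 2
    n_replicas: int = 16
    ns_per_replica: float = 100.0


@dataclass
class RunConfig:
    topology: str = ""
    trajectories: tuple[str, ...] = ()
    frame_stride_ns: float = 1.0
    feature_residue_range: tuple[int, int] | None = None
    domain_map: DomainMap = field(default_factory=lambda: CAS9_DOMAIN_MAP)
    tica: TicaSettings = field(default_factory=TicaSettings)
    msm: MsmSettings = field(default_factory=MsmSettings)
    allostery: AllosterySettings = field(default_factory=AllosterySettings)
    markers: MarkerSettings = field(default_factory=MarkerSettings)
    macrostates: MacrostateSettings = field(default_factory=MacrostateSettings)
    pucker: PuckerSettings = field(default_factory=PuckerSettings)
    replica_bookkeeping: ReplicaBookkeeping = field(default_factory=ReplicaBookkeeping)


def cumulative_time_us(bk: ReplicaBookkeeping) -> float:
    """n_conditions × n_replicas × ns_per_replica, in μs."""
    return bk.n_conditions * bk.n_replicas * bk.ns_per_replica / 1000.0


def _tuple2(v):
    if v is None:
        return None
    a, b = v
    return (int(a), int(b))


def load_config(path: str | os.PathLike) -> RunConfig:
    """Parse a YAML run configuration (plain hierarchical keys)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig()
    cfg.topology = raw.get("topology", "")
    cfg.trajectories = tuple(raw.get("trajectories", ()))
    cfg.frame_stride_ns = float(raw.get("frame_stride_ns", 1.0))
    cfg.feature_residue_range = _tuple2(raw.get("feature_residue_range"))
    if "domain_map" in raw:
        cfg.domain_map = DomainMap.from_config(raw["domain_map"])
    for section, cls in (
        ("tica", TicaSettings), ("msm", MsmSettings),
        ("allostery", AllosterySettings), ("markers", MarkerSettings),
        ("macrostates", MacrostateSettings), ("pucker", PuckerSettings),
        ("replica_bookkeeping", ReplicaBookkeeping),
    ):
        if section in raw:
            data = dict(raw[section])
            if "residue_range" in data:
                data["residue_range"] = _tuple2(data["residue_range"])
            if "residues" in data:
                data["residues"] = tuple(int(r) for r in data["residues"])
            if "ck_factors" in data:
                data["ck_factors"] = tuple(int(k) for k in data["ck_factors"])
            setattr(cfg, section, cls(**data))
    return cfg


def validate_config(cfg: RunConfig, check_paths: bool = True) -> dict:
    """Validate cross-field constraints; returns derived quantities.

    Raises ValueError naming the offending key on the first violation.
    """
    def positive(name, value):
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")

    positive("frame_stride_ns", cfg.frame_stride_ns)
    positive("tica.lag_frames", cfg.tica.lag_frames)
    positive("tica.n_dims", cfg.tica.n_dims)
    positive("msm.lag_frames", cfg.msm.lag_frames)
    positive("msm.n_clusters", cfg.msm.n_clusters)
    positive("msm.n_macrostates", cfg.msm.n_macrostates)
    positive("replica_bookkeeping.n_conditions", cfg.replica_bookkeeping.n_conditions)
    positive("replica_bookkeeping.n_replicas", cfg.replica_bookkeeping.n_replicas)
    positive("replica_bookkeeping.ns_per_replica", cfg.replica_bookkeeping.ns_per_replica)
    if cfg.msm.n_bayes_samples < 0:
        raise ValueError("msm.n_bayes_samples must be ≥ 0")
    if cfg.tica.threshold < 0:
        raise ValueError("tica.threshold must be ≥ 0")
    if cfg.allostery.enabled:
        positive("allostery.cutoff_nm", cfg.allostery.cutoff_nm)
        lo, hi = cfg.allostery.residue_range
        if lo > hi:
            raise ValueError("allostery.residue_range start exceeds end")
    if check_paths:
        for key, path in (("topology", cfg.topology),
                          *((f"trajectories[{i}]", p)
                            for i, p in enumerate(cfg.trajectories))):
            if path and not os.path.exists(path):
                raise ValueError(f"{key}: file not found: {path}")
    derived = {
        "cumulative_time_us": cumulative_time_us(cfg.replica_bookkeeping),
        "tica_lag_ns": cfg.tica.lag_frames * cfg.frame_stride_ns,
        "msm_lag_ns": cfg.msm.lag_frames * cfg.frame_stride_ns,
    }
    return derived
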