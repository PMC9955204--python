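"""Geometric kernels: distances, dihedrals, Kabsch superposition, torsion
featurization, and nucleic-acid delta/pseudorotation analysis.

The pucker analysis follows the classic five-membered-ring pseudorotation
parameterization: the endocyclic torsions obey
``νj = τm · cos(P + 144°·(j − 2))`` and the phase/amplitude are recovered
from measured torsions by the two-argument arctangent inversion.  Phase
regimes are interpreted as in the Cas9 R-loop analysis: A-form below 100°,
B-form at and above 100°, and the R-loop-associated regime above 270°.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure import Structure, TrajectoryEnsemble

__all__ = [
    "FeatureMatrix",
    "PuckerRecord",
    "distance",
    "dihedral",
    "kabsch_superpose",
    "featurize_torsions",
    "pseudorotation",
    "delta_torsion",
    "classify_pucker",
    "pucker_table",
    "FlatRingError",
]

logger = logging.getLogger(__name__)

_PSEUDO_DENOM = 2.0 * (np.sin(np.deg2rad(36.0)) + np.sin(np.deg2rad(72.0)))

RING_TORSION_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),  # ν0
    ("O4'", "C1'", "C2'", "C3'"),  # ν1
    ("C1'", "C2'", "C3'", "C4'"),  # ν2
    ("C2'", "C3'", "C4'", "O4'"),  # ν3
    ("C3'", "C4'", "O4'", "C1'"),  # ν4
)

DELTA_ATOMS = ("C5'", "C4'", "C3'", "O3'")


class FlatRingError(ValueError):
    """Raised when the sugar ring is planar and the pucker is undefined."""


@dataclass
class FeatureMatrix:
    """Frames × features matrix of sin/cos-expanded torsions.

    ``feature_labels`` carries per-column provenance as
    (residue index, torsion name, "sin"|"cos") tuples.
    """

    values: np.ndarray
    feature_labels: list[tuple[int, str, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames × features)")
        if len(self.feature_labels) != self.values.shape[1]:
            raise ValueError("feature_labels length must equal column count")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def residues(self) -> list[int]:
        """Residues contributing at least one feature, ascending."""
        return sorted({lab[0] for lab in self.feature_labels})


@dataclass
class PuckerRecord:
    res_id: int
    strand: str
    frame: int
    delta_deg: float
    phase_deg: float
    amplitude_deg: float
    regime: str


# ---------------------------------------------------------------------------
# Elementary kernels


def distance(a, b) -> float:
    """Euclidean distance between two points (Å)."""
    return float(np.linalg.norm(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in degrees, in (−180, 180] (IUPAC sign).

    Positive when, looking down the p2→p3 axis, the far bond rotates
    clockwise relative to the near bond (standard atan2 convention).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    norm_b2 = np.linalg.norm(b2)
    if norm_b2 < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise ValueError("degenerate geometry: collinear or coincident points")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2) / norm_b2)
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    subset=None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` is optimally aligned; the RMSD is
    computed over ``subset`` (all atoms when None) after the transform.
    The rotation is proper (determinant +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if subset is None:
        subset = np.arange(mobile.shape[0])
    subset = np.asarray(subset, dtype=int)
    if subset.size < 3:
        raise ValueError("superposition needs at least 3 points")
    x = mobile[subset]
    y = reference[subset]
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    h = (x - xc).T @ (y - yc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = yc - rot @ xc
    moved = x @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ rotation.T + translation


# ---------------------------------------------------------------------------
# Torsion featurization


def _backbone_index(structure: Structure):
    """res_id → {atom_name: atom_index} for backbone atoms, in residue order."""
    table: dict[int, dict[str, int]] = {}
    for i, a in enumerate(structure.atoms):
        if a.name in ("N", "CA", "C"):
            table.setdefault(a.res_id, {})[a.name] = i
    return table


def backbone_torsion_atom_indices(structure: Structure, residue_range=None):
    """Atom-index quadruples for every defined φ/ψ in the residue range.

    φ(i) = C(i−1)–N(i)–CA(i)–C(i); ψ(i) = N(i)–CA(i)–C(i)–N(i+1).
    Terminal residues lacking a neighbour simply miss that angle.
    Returns a list of ``(res_id, torsion_name, (i1, i2, i3, i4))``.
    """
    table = _backbone_index(structure)
    res_ids = sorted(table)
    if residue_range is not None:
        lo, hi = residue_range
        wanted = [r for r in res_ids if lo <= r <= hi]
    else:
        wanted = res_ids
    out = []
    for r in wanted:
        this = table.get(r, {})
        prev = table.get(r - 1, {})
        nxt = table.get(r + 1, {})
        if not {"N", "CA", "C"} <= set(this):
            logger.info("residue %d missing backbone atoms; torsions skipped", r)
            continue
        if "C" in prev:
            out.append((r, "phi", (prev["C"], this["N"], this["CA"], this["C"])))
        if "N" in nxt:
            out.append((r, "psi", (this["N"], this["CA"], this["C"], nxt["N"])))
    return out


def featurize_torsions(
    traj: TrajectoryEnsemble,
    residue_range: tuple[int, int] | None = None,
) -> FeatureMatrix:
    """Backbone φ/ψ torsions of the residue range, sin/cos expanded.

    One (sin, cos) column pair per defined torsion per residue; terminal
    residues contribute only their defined angle.  Column provenance maps
    every feature back to its residue.
    """
    quads = backbone_torsion_atom_indices(traj.topology, residue_range)
    if not quads:
        raise ValueError("no defined backbone torsions in the requested range")
    n_frames = traj.n_frames
    values = np.empty((n_frames, 2 * len(quads)))
    labels: list[tuple[int, str, str]] = []
    for k, (res_id, name, (i1, i2, i3, i4)) in enumerate(quads):
        for f in range(n_frames):
            ang = np.deg2rad(dihedral(
                traj.frames[f, i1], traj.frames[f, i2],
                traj.frames[f, i3], traj.frames[f, i4],
            ))
            values[f, 2 * k] = np.sin(ang)
            values[f, 2 * k + 1] = np.cos(ang)
        labels.append((res_id, name, "sin"))
        labels.append((res_id, name, "cos"))
    return FeatureMatrix(values=values, feature_labels=labels)


# ---------------------------------------------------------------------------
# Sugar pucker


def pseudorotation(torsions) -> tuple[float, float]:
    """Pseudorotation (phase P in [0, 360), amplitude τm) from ν0…ν4.

    Inverts νj = τm cos(P + 144°(j−2)):
    tan P = ((ν4+ν1) − (ν3+ν0)) / (2 ν2 (sin 36° + sin 72°)), with the
    quadrant resolved by a two-argument arctangent using the sign of ν2.
    """
    v = np.asarray(torsions, dtype=float)
    if v.shape != (5,):
        raise ValueError("expected exactly five torsions ν0…ν4")
    if not np.all(np.isfinite(v)):
        raise ValueError("torsions must be finite")
    y = ((v[4] + v[1]) - (v[3] + v[0])) / _PSEUDO_DENOM  # = τm sin P
    x = v[2]                                             # = τm cos P
    amplitude = float(np.hypot(x, y))
    if amplitude < 1e-12:
        raise FlatRingError("flat ring: pseudorotation phase undefined")
    phase = float(np.degrees(np.arctan2(y, x)) % 360.0)
    return phase, amplitude


def delta_torsion(structure: Structure, res_id: int, frame_coords: np.ndarray | None = None) -> float:
    """Delta backbone torsion C5'–C4'–C3'–O3' of a nucleotide, in [0, 360)."""
    coords = structure.coords if frame_coords is None else np.asarray(frame_coords)
    try:
        idx = [structure.atom_index(res_id, name) for name in DELTA_ATOMS]
    except KeyError as exc:
        raise KeyError(f"residue {res_id}: missing delta atom ({exc})") from exc
    ang = dihedral(*(coords[i] for i in idx)) % 360.0
    if ang >= 360.0 - 1e-9:  # float round-off of tiny negative angles
        ang = 0.0
    return float(ang)


def classify_pucker(phase_deg: float) -> str:
    """Pucker regime from the pseudorotation phase.

    R-loop-associated above 270°, otherwise B-form at/above 100°, otherwise
    A-form.  Precedence R-loop > B-form resolves the overlap of the >270°
    and >100° windows.
    """
    if not 0.0 <= phase_deg < 360.0:
        raise ValueError("phase must lie in [0, 360)")
    if phase_deg > 270.0:
        return "R-loop"
    if phase_deg >= 100.0:
        return "B-form"
    return "A-form"


def ring_torsions(structure: Structure, res_id: int, frame_coords: np.ndarray | None = None) -> np.ndarray:
    """Measured endocyclic torsions ν0…ν4 (degrees, signed) of a sugar ring."""
    coords = structure.coords if frame_coords is None else np.asarray(frame_coords)
    out = np.empty(5)
    for j, names in enumerate(RING_TORSION_ATOMS):
        idx = [structure.atom_index(res_id, n) for n in names]
        out[j] = dihedral(*(coords[i] for i in idx))
    return out


def pucker_table(
    traj: TrajectoryEnsemble,
    nucleic_res_ids,
    strand_labels: dict[int, str] | None = None,
) -> list[PuckerRecord]:
    """Per-residue, per-frame delta + pseudorotation records.

    Residues with missing sugar atoms or an undefined (flat) pucker are
    skipped with a log entry, never fabricated.
    """
    import warnings as _warnings

    nucleic_res_ids = list(nucleic_res_ids)
    if not nucleic_res_ids:
        _warnings.warn("no nucleic residues given; pucker table empty", stacklevel=2)
        return []
    strand_labels = strand_labels or {}
    records: list[PuckerRecord] = []
    for frame in range(traj.n_frames):
        coords = traj.frames[frame]
        for res_id in nucleic_res_ids:
            try:
                v = ring_torsions(traj.topology, res_id, coords)
                phase, amp = pseudorotation(v)
                delta = delta_torsion(traj.topology, res_id, coords)
            except FlatRingError:
                logger.info("residue %d frame %d: flat ring, skipped", res_id, frame)
                continue
            except KeyError as exc:
                logger.info("residue %d frame %d: %s", res_id, frame, exc)
                continue
            records.append(PuckerRecord(
                res_id=res_id,
                strand=strand_labels.get(res_id, "other"),
                frame=frame,
                delta_deg=delta,
                phase_deg=phase,
                amplitude_deg=amp,
                regime=classify_pucker(phase),
            ))
    return records


def pucker_table_to_tsv(records, path) -> None:
    import pandas as pd

    df = pd.DataFrame([
        {
            "resid": r.res_id, "strand": r.strand, "frame": r.frame,
            "delta_deg": r.delta_deg, "phase_deg": r.phase_deg,
            "amplitude_deg": r.amplitude_deg, "regime": r.regime,
        }
        for r in records
    ], columns=["resid", "strand", "frame", "delta_deg", "phase_deg",
                "amplitude_deg", "regime"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
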