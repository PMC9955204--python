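"""Synthetic inputs with known ground truth for every pipeline stage.

The original study analyses microsecond-scale molecular-dynamics
trajectories of the Cas9--sgRNA--dsDNA complex, which are far too large to
ship or regenerate.  This module produces small surrogates that carry the
statistical structure each downstream stage assumes:

* discrete Markov chains with a known transition matrix (ground truth for
  the MSM estimator),
* overdamped Langevin trajectories on multi-well potentials (metastable
  scalar features, as torsion projections behave),
* toy Cα chains with a prescribed displacement covariance (ground truth
  for the residue-coupling / allostery analysis),
* sugar-ring torsion sets and 3-D nucleotide fragments with a chosen
  pseudorotation phase/amplitude (ground truth for the pucker analysis),
* Gaussian-mixture distance series (ground truth for the marker
  histogram/fit machinery).

Every generator is a pure function of its spec plus a seed: reruns are
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarkovChainSpec",
    "LangevinSpec",
    "ToyChainSpec",
    "SugarPuckerSpec",
    "simulate_markov_chain",
    "simulate_double_well",
    "generate_chain_trajectory",
    "generate_sugar_ring",
    "generate_distance_series",
    "block_transition_matrix",
    "backbone_from_torsions",
    "build_nucleotide",
    "markov_backbone_trajectory",
]

_CA_SPACING = 3.8  # typical Cα–Cα distance, Å


def _validate_stochastic(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"transition matrix must be square, got shape {m.shape}")
    if np.any(m < 0):
        raise ValueError("transition matrix has negative entries")
    if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("transition matrix rows must sum to 1 within 1e-12")
    return m


@dataclass(frozen=True)
class MarkovChainSpec:
    """A discrete-time Markov chain: the ground truth behind an MSM."""

    transition_matrix: np.ndarray
    initial_state: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        m = _validate_stochastic(self.transition_matrix)
        object.__setattr__(self, "transition_matrix", m)
        if not 0 <= self.initial_state < m.shape[0]:
            raise ValueError("initial_state out of range")

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]


@dataclass(frozen=True)
class LangevinSpec:
    """Overdamped Langevin dynamics on a 1-D multi-well potential.

    ``well_centers`` are the potential minima (arbitrary units);
    ``barrier_height`` is the barrier between adjacent wells in kT (exact
    for two wells, a lower bound for three or more); ``noise_scale`` sets
    the diffusion amplitude (stationary density ∝ exp(-V/noise_scale²)).
    """

    well_centers: tuple[float, ...]
    barrier_height: float = 2.0
    noise_scale: float = 1.0
    timestep: float = 1e-3
    start: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "well_centers", tuple(float(c) for c in self.well_centers))
        if len(self.well_centers) < 1:
            raise ValueError("at least one well center required")
        if self.barrier_height < 0:
            raise ValueError("barrier_height must be ≥ 0")
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")


@dataclass(frozen=True)
class ToyChainSpec:
    """A toy Cα chain whose frames are base + correlated Gaussian noise.

    ``displacement_covariance`` is an (n_residues × n_residues) symmetric
    PSD matrix; each Cartesian component of the per-residue displacements
    is drawn independently from it, so the residue–residue displacement
    correlation of the ensemble equals the normalized covariance.
    """

    n_residues: int
    displacement_covariance: np.ndarray
    n_frames: int = 100
    base_coordinates: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be ≥ 1")
        cov = np.asarray(self.displacement_covariance, dtype=float)
        if cov.shape != (self.n_residues, self.n_residues):
            raise ValueError("covariance must be n_residues × n_residues")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-10 * max(1.0, eig.max()):
            raise ValueError("covariance must be positive semi-definite")
        object.__setattr__(self, "displacement_covariance", cov)
        if self.base_coordinates is None:
            base = np.zeros((self.n_residues, 3))
            base[:, 0] = _CA_SPACING * np.arange(self.n_residues)
        else:
            base = np.asarray(self.base_coordinates, dtype=float)
            if base.shape != (self.n_residues, 3):
                raise ValueError("base_coordinates must be n_residues × 3")
            d = np.linalg.norm(base[:, None, :] - base[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() < 1.0:
                raise ValueError("base geometry has residues closer than 1 Å")
        object.__setattr__(self, "base_coordinates", base)


@dataclass(frozen=True)
class SugarPuckerSpec:
    """Pseudorotation phase P (deg, [0, 360)) and amplitude τm (deg, ≥ 0)."""

    phase_P: float
    amplitude_tau_m: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phase_P < 360.0:
            raise ValueError("phase_P must lie in [0, 360)")
        if self.amplitude_tau_m < 0:
            raise ValueError("amplitude_tau_m must be ≥ 0")


# ---------------------------------------------------------------------------
# Markov chains


def simulate_markov_chain(spec: MarkovChainSpec, length: int) -> np.ndarray:
    """Sample a state sequence of ``length`` steps from the chain."""
    if length < 1:
        raise ValueError("length must be ≥ 1")
    rng = np.random.default_rng(spec.seed)
    t = spec.transition_matrix
    cdf = np.cumsum(t, axis=1)
    states = np.empty(length, dtype=np.int64)
    states[0] = spec.initial_state
    u = rng.random(length - 1)
    s = spec.initial_state
    for i in range(1, length):
        s = int(np.searchsorted(cdf[s], u[i - 1], side="right"))
        s = min(s, t.shape[0] - 1)  # guard against u == 1.0 round-off
        states[i] = s
    return states


def block_transition_matrix(
    n_blocks: int = 2,
    block_size: int = 2,
    intra: float = 0.1,
    inter: float = 1e-3,
) -> np.ndarray:
    """Row-stochastic matrix of weakly coupled metastable blocks.

    Within a block, states hop with probability ``intra``; a block is left
    with total probability ``inter`` (spread uniformly over the other
    states).  Small ``inter`` produces the spectral gap PCCA++ relies on.
    """
    n = n_blocks * block_size
    t = np.zeros((n, n))
    for i in range(n):
        bi = i // block_size
        others_in = [j for j in range(n) if j // block_size == bi and j != i]
        others_out = [j for j in range(n) if j // block_size != bi]
        for j in others_in:
            t[i, j] = intra / max(len(others_in), 1)
        for j in others_out:
            t[i, j] = inter / max(len(others_out), 1)
        t[i, i] = 1.0 - t[i].sum()
    return t


# ---------------------------------------------------------------------------
# Langevin dynamics


def _potential_gradient(x: float, spec: LangevinSpec) -> float:
    c = np.asarray(spec.well_centers)
    if len(c) == 1:
        return x - c[0]  # harmonic, unit curvature
    if len(c) == 2:
        a, b = sorted(c)
        m, w = 0.5 * (a + b), 0.5 * (b - a)
        # V = h ((x-m)^2 - w^2)^2 / w^4 : zero at wells, exactly h at midpoint
        return 4.0 * spec.barrier_height * ((x - m) ** 2 - w**2) * (x - m) / w**4
    # ≥3 wells: product form, barriers ≥ h between adjacent wells
    g = 0.5 * np.min(np.diff(np.sort(c)))
    p = np.prod((x - c) / g)
    grad = 0.0
    for i in range(len(c)):
        others = np.prod(np.delete(x - c, i) / g)
        grad += others / g
    return 2.0 * spec.barrier_height * p * grad


def simulate_double_well(spec: LangevinSpec, n_steps: int) -> np.ndarray:
    """Euler–Maruyama integration; returns the scalar trajectory."""
    if n_steps < 1:
        raise ValueError("n_steps must be ≥ 1")
    rng = np.random.default_rng(spec.seed)
    dt = spec.timestep
    x = float(spec.start) if spec.start is not None else float(spec.well_centers[0])
    out = np.empty(n_steps)
    noise = rng.standard_normal(n_steps) * spec.noise_scale * np.sqrt(2.0 * dt)
    for i in range(n_steps):
        x = x - _potential_gradient(x, spec) * dt + noise[i]
        out[i] = x
    return out


# ---------------------------------------------------------------------------
# Toy Cα chains


def generate_chain_trajectory(spec: ToyChainSpec):
    """Frames = base coordinates + correlated Gaussian displacements.

    Returns a :class:`casdyn.structure.TrajectoryEnsemble` whose topology
    is a poly-glycine Cα trace, so the full pipeline (PDB writer included)
    can consume it.
    """
    from .structure import Structure, TrajectoryEnsemble, Atom

    rng = np.random.default_rng(spec.seed)
    cov = spec.displacement_covariance
    # eigh-based square root: stable for PSD matrices with zero eigenvalues
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = v * np.sqrt(w)
    z = rng.standard_normal((spec.n_frames, 3, spec.n_residues))
    disp = np.einsum("ij,fcj->fci", root, z)  # (frames, 3, residues)
    frames = spec.base_coordinates[None, :, :] + disp.transpose(0, 2, 1)
    atoms = [
        Atom(name="CA", res_id=i + 1, res_name="GLY", chain_id="A",
             coord=tuple(spec.base_coordinates[i]))
        for i in range(spec.n_residues)
    ]
    topology = Structure(atoms=atoms)
    return TrajectoryEnsemble(topology=topology, frames=np.asarray(frames), frame_stride_ns=1.0)


# ---------------------------------------------------------------------------
# Sugar pucker

_PSEUDOROTATION_DENOM = 2.0 * (np.sin(np.deg2rad(36.0)) + np.sin(np.deg2rad(72.0)))


def generate_sugar_ring(spec: SugarPuckerSpec) -> np.ndarray:
    """Five endocyclic torsions ν0…ν4 (degrees) for the given pucker.

    νj = τm · cos(P + 144°·(j − 2)), the standard five-membered-ring
    pseudorotation parameterization.
    """
    j = np.arange(5)
    return spec.amplitude_tau_m * np.cos(
        np.deg2rad(spec.phase_P + 144.0 * (j - 2))
    )


# ---------------------------------------------------------------------------
# Gaussian-mixture distance series


def generate_distance_series(
    component_means,
    component_sds,
    weights,
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """I.i.d. Gaussian-mixture samples (Å), one seeded stream per call."""
    means = np.asarray(component_means, dtype=float)
    sds = np.asarray(component_sds, dtype=float)
    w = np.asarray(weights, dtype=float)
    if not (means.shape == sds.shape == w.shape):
        raise ValueError("means, sds and weights must have equal lengths")
    if np.any(sds <= 0):
        raise ValueError("component sds must be > 0")
    if not np.isclose(w.sum(), 1.0, atol=1e-9):
        raise ValueError("weights must sum to 1")
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(w), size=n, p=w)
    return rng.standard_normal(n) * sds[comp] + means[comp]


# ---------------------------------------------------------------------------
# 3-D builders (internal-coordinate construction)

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: new atom D with |CD| = bond, ∠BCD = angle, φ(ABCD) = dihedral."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def backbone_from_torsions(phi_psi: np.ndarray) -> list[tuple[str, int, str, np.ndarray]]:
    """Build an N/CA/C/O backbone with the requested (φ, ψ) per residue.

    ``phi_psi`` is (n_residues, 2) in degrees; φ of residue 1 and ψ of the
    last residue are ignored (undefined at chain termini).  ω is fixed at
    180° (trans peptide).  Returns (atom_name, res_id, res_name, coord)
    records for a poly-alanine-like glycine chain.
    """
    phi_psi = np.asarray(phi_psi, dtype=float)
    n_res = phi_psi.shape[0]
    atoms: list[tuple[str, int, str, np.ndarray]] = []
    # seed geometry for residue 1
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_ANGLE_N_CA_C)
    c = ca + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        res_id = i + 1
        atoms.append(("N", res_id, "GLY", n))
        atoms.append(("CA", res_id, "GLY", ca))
        atoms.append(("C", res_id, "GLY", c))
        psi = phi_psi[i, 1] if i < n_res - 1 else 0.0
        # carbonyl O: dihedral N-CA-C-O = psi + 180
        o = _place_atom(n, ca, c, _BOND_C_O, _ANGLE_CA_C_O, psi + 180.0)
        atoms.append(("O", res_id, "GLY", o))
        if i == n_res - 1:
            break
        n_next = _place_atom(n, ca, c, _BOND_C_N, _ANGLE_CA_C_N, psi)
        ca_next = _place_atom(ca, c, n_next, _BOND_N_CA, _ANGLE_C_N_CA, 180.0)
        phi_next = phi_psi[i + 1, 0]
        c_next = _place_atom(c, n_next, ca_next, _BOND_CA_C, _ANGLE_N_CA_C, phi_next)
        n, ca, c = n_next, ca_next, c_next
    return atoms


def markov_backbone_trajectory(
    spec: MarkovChainSpec,
    length: int,
    n_residues: int = 6,
    torsion_noise_deg: float = 5.0,
):
    """Peptide trajectory whose backbone torsions encode a Markov chain.

    Each chain state is mapped to a distinct (φ, ψ) basin; every frame is
    built from the current state's torsions plus small Gaussian noise.
    This is the end-to-end fixture: featurize → tICA → k-means → MSM →
    PCCA++ should recover the generating states.

    Returns ``(TrajectoryEnsemble, state_sequence)``.
    """
    from .structure import Structure, TrajectoryEnsemble, Atom

    states = simulate_markov_chain(spec, length)
    rng = np.random.default_rng(spec.seed + 1)
    # well-separated basins on the Ramachandran torus
    basin_phi = np.linspace(-150.0, 90.0, spec.n_states)
    basin_psi = np.linspace(150.0, -90.0, spec.n_states)
    frames = []
    template = None
    for s in states:
        phi_psi = np.tile([basin_phi[s], basin_psi[s]], (n_residues, 1))
        phi_psi += rng.standard_normal((n_residues, 2)) * torsion_noise_deg
        records = backbone_from_torsions(phi_psi)
        if template is None:
            template = records
        frames.append(np.array([r[3] for r in records]))
    from .structure import Atom as _Atom

    atoms = [
        _Atom(name=name, res_id=res_id, res_name=res_name, chain_id="A", coord=tuple(xyz))
        for name, res_id, res_name, xyz in template
    ]
    traj = TrajectoryEnsemble(
        topology=Structure(atoms=atoms),
        frames=np.asarray(frames),
        frame_stride_ns=1.0,
    )
    return traj, states


# -- nucleotide fragment builder --------------------------------------------

_RING_ATOMS = ("O4'", "C1'", "C2'", "C3'", "C4'")
# ν indices measured over the ring: ν0 = C4'-O4'-C1'-C2', ν1 = O4'-C1'-C2'-C3',
# ν2 = C1'-C2'-C3'-C4', ν3 = C2'-C3'-C4'-O4', ν4 = C3'-C4'-O4'-C1'


def _ring_coords(phase_param: float, q: float) -> dict[str, np.ndarray]:
    """Pentagon ring with out-of-plane displacements encoding the pucker."""
    r = 1.17  # pentagon radius giving ~1.5 Å ring bonds
    coords = {}
    for k, name in enumerate(_RING_ATOMS):
        theta = 2.0 * np.pi * k / 5.0
        z = q * np.cos(np.deg2rad(phase_param) + 4.0 * np.pi * k / 5.0)
        coords[name] = np.array([r * np.cos(theta), r * np.sin(theta), z])
    return coords


def _measure_pucker(coords: dict[str, np.ndarray]) -> tuple[float, float]:
    from .geometry import RING_TORSION_ATOMS, dihedral, pseudorotation

    v = [dihedral(*(coords[n] for n in names)) for names in RING_TORSION_ATOMS]
    return pseudorotation(v)


def build_nucleotide(
    phase_P: float,
    amplitude_tau_m: float = 38.0,
    delta_deg: float | None = None,
    res_id: int = 1,
    res_name: str = "DA",
    chain_id: str = "B",
    origin: np.ndarray | None = None,
):
    """Synthetic deoxyribose fragment with a prescribed pucker.

    The five ring atoms sit on a regular pentagon with out-of-plane
    displacements; the displacement phase and amplitude are calibrated by
    a short fixed-point loop so that the pseudorotation (P, τm) measured
    from the endocyclic torsions matches the request to well under 0.1°.
    C5' (on C4') and O3' (on C3') are attached so that the delta torsion
    C5'–C4'–C3'–O3' equals ``delta_deg`` exactly (NeRF construction); a P
    atom hangs off O3' so the fragment also serves distance-marker tests.

    Returns a list of Atom records (casdyn.structure.Atom).
    """
    from .structure import Atom

    if amplitude_tau_m <= 0:
        raise ValueError("amplitude_tau_m must be > 0 for a 3-D ring")
    phase_param = float(phase_P)
    q = amplitude_tau_m * 0.0155  # initial deg → Å guess, refined below
    coords = _ring_coords(phase_param, q)
    for _ in range(25):
        p_meas, amp_meas = _measure_pucker(coords)
        dphi = (phase_P - p_meas + 180.0) % 360.0 - 180.0
        q *= amplitude_tau_m / amp_meas
        phase_param += dphi
        coords = _ring_coords(phase_param, q)
        if abs(dphi) < 1e-10 and abs(amp_meas - amplitude_tau_m) < 1e-10:
            break
    c4, c3, o4 = coords["C4'"], coords["C3'"], coords["O4'"]
    # exocyclic atoms: C5' off C4', O3' off C3'
    c5 = _place_atom(c3, o4, c4, 1.51, 109.0, -120.0)
    if delta_deg is None:
        delta_deg = 120.0
    o3 = _place_atom(c5, c4, c3, 1.42, 110.0, delta_deg)
    p = _place_atom(c4, c3, o3, 1.60, 119.0, -100.0)
    shift = np.asarray(origin, dtype=float) if origin is not None else np.zeros(3)
    out = []
    for name in ("P", "C5'", "C4'", "O4'", "C1'", "C2'", "C3'", "O3'"):
        xyz = {"P": p, "C5'": c5, "O3'": o3, **coords}[name]
        out.append(Atom(name=name, res_id=res_id, res_name=res_name,
                        chain_id=chain_id, coord=tuple(xyz + shift)))
    return out
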