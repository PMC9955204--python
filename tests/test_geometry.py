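import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from casdyn.geometry import (
    FlatRingError,
    classify_pucker,
    delta_torsion,
    dihedral,
    distance,
    featurize_torsions,
    kabsch_superpose,
    pseudorotation,
    pucker_table,
    ring_torsions,
)
from casdyn.structure import Structure, TrajectoryEnsemble
from casdyn.synthetic import (
    SugarPuckerSpec,
    backbone_from_torsions,
    build_nucleotide,
    generate_sugar_ring,
)


def _rotate(points, axis, angle_deg):
    axis = np.asarray(axis, dtype=float)
    axis /= np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    r = np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)
    return np.asarray(points) @ r.T


class TestDistanceDihedral:
    def test_pythagorean_distance(self):
        assert distance((0, 0, 0), (3, 4, 0)) == pytest.approx(5.0)
        assert distance((1, 1, 1), (1, 1, 1)) == 0.0

    def test_planar_cis_and_trans(self):
        p1, p2, p3 = [0, 1, 0], [0, 0, 0], [1, 0, 0]
        assert dihedral(p1, p2, p3, [1, 1, 0]) == pytest.approx(0.0, abs=1e-9)
        assert dihedral(p1, p2, p3, [1, -1, 0]) == pytest.approx(180.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [60.0, -60.0, 85.0, 179.5])
    def test_constructed_rotation_recovers_angle(self, angle):
        # place p4 by rotating the cis position about the p2-p3 axis
        p1, p2, p3 = np.array([0., 1, 0]), np.array([0., 0, 0]), np.array([1., 0, 0])
        p4_cis = np.array([1.0, 1.0, 0.0])
        p4 = _rotate((p4_cis - p3)[None], [1, 0, 0], angle)[0] + p3
        assert dihedral(p1, p2, p3, p4) == pytest.approx(angle, abs=1e-6)

    def test_collinear_geometry_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_dihedral_invariant_under_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((4, 3)) * 3
        try:
            ref = dihedral(*pts)
        except ValueError:
            return
        axis = rng.standard_normal(3)
        moved = _rotate(pts, axis, rng.uniform(0, 360)) + rng.standard_normal(3)
        assert dihedral(*moved) == pytest.approx(ref, abs=1e-9)


class TestKabsch:
    def test_identical_clouds_have_zero_rmsd(self, rng):
        x = rng.standard_normal((10, 3))
        _, _, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_is_removable(self, rng):
        x = rng.standard_normal((8, 3))
        y = _rotate(x, [1, 2, 3], 90.0) + np.array([5.0, -3.0, 2.0])
        _, _, rmsd = kabsch_superpose(y, x)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_grid_minimum(self, rng):
        # brute-force oracle: exhaustive search over axis-angle rotations
        x = rng.standard_normal((4, 3))
        y = x + rng.standard_normal((4, 3)) * 0.3
        _, _, rmsd = kabsch_superpose(y, x)
        best = np.inf
        from scipy.spatial.transform import Rotation

        for rv in Rotation.create_group("O").as_rotvec():  # coarse seed grid
            for _ in range(200):
                r = Rotation.from_rotvec(rv + rng.standard_normal(3) * 0.1)
                moved = (y - y.mean(0)) @ r.as_matrix().T
                d = moved - (x - x.mean(0))
                best = min(best, float(np.sqrt(np.mean(np.sum(d**2, -1)))))
        assert rmsd <= best + 1e-3

    def test_aligned_rmsd_never_exceeds_raw(self, rng):
        for _ in range(5):
            x = rng.standard_normal((6, 3))
            y = rng.standard_normal((6, 3))
            _, _, aligned = kabsch_superpose(y, x)
            raw = float(np.sqrt(np.mean(np.sum((y - x) ** 2, -1))))
            assert aligned <= raw + 1e-12

    def test_rotation_is_proper(self, rng):
        x = rng.standard_normal((5, 3))
        y = -x  # mirror image tempts an improper solution
        rot, _, _ = kabsch_superpose(y, x)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestFeaturizeTorsions:
    def test_static_trajectory_has_constant_columns(self):
        records = backbone_from_torsions(np.tile([-60.0, -45.0], (4, 1)))
        from casdyn.structure import Atom

        atoms = [Atom(n, r, rn, "A", tuple(c)) for n, r, rn, c in records]
        s = Structure(atoms=atoms)
        traj = TrajectoryEnsemble(topology=s, frames=np.stack([s.coords] * 3))
        fm = featurize_torsions(traj)
        assert np.allclose(fm.values.std(axis=0), 0.0, atol=1e-12)

    def test_three_residue_angle_count(self):
        records = backbone_from_torsions(np.tile([-60.0, -45.0], (3, 1)))
        from casdyn.structure import Atom

        atoms = [Atom(n, r, rn, "A", tuple(c)) for n, r, rn, c in records]
        s = Structure(atoms=atoms)
        traj = TrajectoryEnsemble(topology=s, frames=s.coords[None])
        fm = featurize_torsions(traj)
        # residue 1: psi only; residue 2: phi+psi; residue 3: phi only
        torsions = {(lab[0], lab[1]) for lab in fm.feature_labels}
        assert torsions == {(1, "psi"), (2, "phi"), (2, "psi"), (3, "phi")}
        assert fm.values.shape == (1, 8)  # 4 torsions × sin/cos

    def test_constructed_torsions_are_recovered(self):
        phi_psi = np.array([[0.0, -45.0], [-60.0, 120.0], [75.0, 0.0]])
        records = backbone_from_torsions(phi_psi)
        from casdyn.structure import Atom

        atoms = [Atom(n, r, rn, "A", tuple(c)) for n, r, rn, c in records]
        s = Structure(atoms=atoms)
        traj = TrajectoryEnsemble(topology=s, frames=s.coords[None])
        fm = featurize_torsions(traj)
        by_label = {
            (lab[0], lab[1], lab[2]): fm.values[0, j]
            for j, lab in enumerate(fm.feature_labels)
        }
        assert by_label[(2, "phi", "sin")] == pytest.approx(np.sin(np.deg2rad(-60)), abs=1e-6)
        assert by_label[(2, "psi", "cos")] == pytest.approx(np.cos(np.deg2rad(120)), abs=1e-6)

    def test_sin_cos_identity_per_angle_pair(self, peptide_trajectory):
        traj, _, _ = peptide_trajectory
        fm = featurize_torsions(traj)
        sin_cols = fm.values[:, 0::2]
        cos_cols = fm.values[:, 1::2]
        assert np.allclose(sin_cols**2 + cos_cols**2, 1.0, atol=1e-12)


class TestPseudorotation:
    def test_flat_ring_is_undefined(self):
        with pytest.raises(FlatRingError):
            pseudorotation(np.zeros(5))

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(0.0, 359.999), st.floats(0.5, 60.0))
    def test_generate_then_invert_is_identity(self, phase, amp):
        v = generate_sugar_ring(SugarPuckerSpec(phase, amp))
        p, a = pseudorotation(v)
        assert p == pytest.approx(phase, abs=1e-9)
        assert a == pytest.approx(amp, abs=1e-9)

    @pytest.mark.parametrize("phase,regime", [
        (50.0, "A-form"), (0.0, "A-form"), (99.99, "A-form"),
        (100.0, "B-form"), (162.0, "B-form"), (270.0, "B-form"),
        (270.01, "R-loop"), (300.0, "R-loop"), (359.9, "R-loop"),
    ])
    def test_pucker_regimes(self, phase, regime):
        assert classify_pucker(phase) == regime

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.0, 359.999))
    def test_classification_is_total(self, phase):
        assert classify_pucker(phase) in ("A-form", "B-form", "R-loop")


class TestNucleotideGeometry:
    @pytest.mark.parametrize("delta", [0.0, 85.0, 180.0, 120.0])
    def test_delta_torsion_matches_construction(self, delta):
        atoms = build_nucleotide(phase_P=18.0, delta_deg=delta)
        s = Structure(atoms=list(atoms))
        assert delta_torsion(s, 1) == pytest.approx(delta % 360.0, abs=1e-6)

    def test_built_ring_reproduces_requested_pucker(self):
        for phase, amp in [(18.0, 35.0), (144.0, 38.0), (350.0, 40.0)]:
            atoms = build_nucleotide(phase_P=phase, amplitude_tau_m=amp)
            s = Structure(atoms=list(atoms))
            p, a = pseudorotation(ring_torsions(s, 1))
            assert p == pytest.approx(phase, abs=1e-6)
            assert a == pytest.approx(amp, abs=1e-6)

    def test_all_c3_endo_duplex_classifies_a_form(self):
        atoms = []
        for i, phase in enumerate([9.0, 18.0, 27.0]):
            atoms += build_nucleotide(phase_P=phase, res_id=i + 1,
                                      origin=np.array([8.0 * i, 0.0, 0.0]))
        s = Structure(atoms=atoms)
        traj = TrajectoryEnsemble(topology=s, frames=s.coords[None])
        records = pucker_table(traj, [1, 2, 3], {1: "tDNA", 2: "tDNA", 3: "ntDNA"})
        assert len(records) == 3
        assert all(r.regime == "A-form" for r in records)
        assert {r.strand for r in records} == {"tDNA", "ntDNA"}

    def test_single_r_loop_residue_detected(self):
        atoms = build_nucleotide(phase_P=18.0, res_id=1)
        atoms += build_nucleotide(phase_P=350.0, res_id=2,
                                  origin=np.array([9.0, 0.0, 0.0]))
        s = Structure(atoms=atoms)
        traj = TrajectoryEnsemble(topology=s, frames=s.coords[None])
        records = pucker_table(traj, [1, 2])
        regimes = [r.regime for r in records]
        assert regimes.count("R-loop") == 1

    def test_empty_residue_list_gives_empty_table(self):
        s = Structure(atoms=list(build_nucleotide(18.0)))
        traj = TrajectoryEnsemble(topology=s, frames=s.coords[None])
        with pytest.warns(UserWarning):
            assert pucker_table(traj, []) == []
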