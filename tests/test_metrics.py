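"""Superposition, RMSD/RMSF, contact maps/occupancy, hydrogen bonds."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from vacuform.core import (
    AtomRecord,
    Phase,
    ReplicaSet,
    StructureModel,
    TrajectoryEnsemble,
)
from vacuform.errors import DataError, DegenerateFitError
from vacuform.metrics import (
    average_structure,
    contact_map,
    contact_occupancy,
    hydrogen_bond_count,
    kabsch_superpose,
    rmsd_series,
    rmsf_per_residue,
)

from conftest import make_structure


def replica_set(topology, frame_sets, phase=Phase.BULK):
    reps = []
    for i, frames in enumerate(frame_sets):
        frames = np.asarray(frames, dtype=float)
        reps.append(TrajectoryEnsemble(topology, frames,
                                       np.arange(len(frames)) + 1.0,
                                       replica_id=f"r{i}", phase=phase))
    return ReplicaSet(reps)


class TestKabsch:
    def test_identical_sets_give_zero_and_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 3, (10, 3))
        R, t, rmsd = kabsch_superpose(x, x)
        assert rmsd == pytest.approx(0, abs=1e-10)
        assert np.allclose(R, np.eye(3), atol=1e-10)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 3, (10, 3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = x @ Rz.T + np.array([5.0, -2.0, 1.0])
        _, _, rmsd = kabsch_superpose(moved, x)
        assert rmsd == pytest.approx(0, abs=1e-9)
        assert np.linalg.det(kabsch_superpose(moved, x)[0]) == pytest.approx(1.0)

    def test_four_point_toy_matches_quaternion_oracle(self):
        # independent oracle: Horn's quaternion method via scipy.align_vectors
        ref = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        mob = ref.copy()
        mob[3] += [0.4, -0.2, 0.3]
        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True)
        mob = mob @ rot.as_matrix().T + [1.0, 2.0, -3.0]
        _, _, rmsd = kabsch_superpose(mob, ref)
        est, rssd = Rotation.align_vectors(ref - ref.mean(0),
                                           mob - mob.mean(0))
        oracle = rssd / np.sqrt(len(ref))
        assert rmsd == pytest.approx(oracle, abs=1e-10)

    def test_degenerate_inputs_raise(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateFitError):
            kabsch_superpose(line, line)
        with pytest.raises(DegenerateFitError):
            kabsch_superpose(line[:2], line[:2])


class TestRmsdSeries:
    def test_static_copies_of_reference_are_zero(self, toy_dimer):
        rs = replica_set(toy_dimer, [[toy_dimer.coords] * 3] * 2)
        out = rmsd_series(rs, toy_dimer)
        assert np.allclose(out.mean, 0, atol=1e-9)
        assert np.allclose(out.spread, 0, atol=1e-9)

    def test_uniform_displacement_is_removed_but_distortion_is_not(self, toy_dimer):
        # translating every atom is a rigid motion → rmsd 0; moving one
        # atom by d leaves rmsd d/sqrt(n) approximately
        rs = replica_set(toy_dimer, [[toy_dimer.coords + 5.0]])
        assert rmsd_series(rs, toy_dimer).mean[0] == pytest.approx(0, abs=1e-9)

    def test_gaussian_jitter_matches_chi_expectation(self, toy_dimer):
        # per-atom sigma per coordinate → E[rmsd] ≈ sigma*sqrt(3) for many atoms
        sigma = 0.5
        rng = np.random.default_rng(5)
        frames = [[toy_dimer.coords
                   + rng.normal(0, sigma, toy_dimer.coords.shape)
                   for _ in range(10)] for _ in range(3)]
        out = rmsd_series(replica_set(toy_dimer, frames), toy_dimer,
                          selection="all")
        assert np.mean(out.mean) == pytest.approx(sigma * np.sqrt(3), rel=0.10)

    def test_misaligned_times_raise(self, toy_dimer):
        r1 = TrajectoryEnsemble(toy_dimer, [toy_dimer.coords], [1.0])
        r2 = TrajectoryEnsemble(toy_dimer, [toy_dimer.coords], [2.0])
        with pytest.raises(DataError):
            rmsd_series(ReplicaSet([r1, r2]), toy_dimer)


class TestAverageStructure:
    def test_static_trajectory_average_is_the_frame(self, toy_dimer):
        rs = replica_set(toy_dimer, [[toy_dimer.coords] * 4])
        avg = average_structure(rs)
        assert np.allclose(avg.coords, toy_dimer.coords, atol=1e-9)

    def test_rigid_motions_average_congruent_to_original(self, toy_dimer):
        rot = Rotation.from_euler("y", 70, degrees=True).as_matrix()
        frames = [toy_dimer.coords,
                  toy_dimer.coords @ rot.T + [4.0, 1.0, -2.0]]
        avg = average_structure(replica_set(toy_dimer, [frames]))
        _, _, rmsd = kabsch_superpose(avg.coords, toy_dimer.coords)
        assert rmsd == pytest.approx(0, abs=1e-6)

    def test_frame_order_invariance(self, toy_dimer):
        rng = np.random.default_rng(2)
        frames = [toy_dimer.coords + rng.normal(0, 0.3, toy_dimer.coords.shape)
                  for _ in range(6)]
        a = average_structure(replica_set(toy_dimer, [frames]))
        b = average_structure(replica_set(toy_dimer, [frames[::-1]]))
        _, _, rmsd = kabsch_superpose(a.coords, b.coords)
        assert rmsd == pytest.approx(0, abs=1e-4)


class TestRmsf:
    def test_static_ensemble_is_zero(self, toy_dimer):
        rs = replica_set(toy_dimer, [[toy_dimer.coords] * 3])
        avg = average_structure(rs)
        out = rmsf_per_residue(rs, avg)
        assert np.allclose(out.rmsf, 0, atol=1e-9)

    def test_single_alternating_atom_reports_its_amplitude(self, toy_dimer):
        d = 0.8
        ca = [i for i, a in enumerate(toy_dimer.atoms) if a.name == "CA"][0]
        plus, minus = toy_dimer.coords.copy(), toy_dimer.coords.copy()
        plus[ca, 0] += d
        minus[ca, 0] -= d
        rs = replica_set(toy_dimer, [[plus, minus] * 4])
        avg = average_structure(rs, selection="calpha")
        out = rmsf_per_residue(rs, avg)
        moved = out[(out.chain == "A") & (out.resid == 1)].rmsf.iloc[0]
        # superposition absorbs a small part of the single-atom motion
        # (one of 48 fitted centres), so the estimate sits just below d
        assert moved == pytest.approx(d, rel=0.05)
        assert out[(out.chain == "A") & (out.resid == 2)].rmsf.iloc[0] < 0.1

    def test_gaussian_jitter_converges_to_sigma_sqrt3(self, toy_dimer):
        sigma = 0.3
        rng = np.random.default_rng(11)
        frames = [toy_dimer.coords + rng.normal(0, sigma, toy_dimer.coords.shape)
                  for _ in range(200)]
        rs = replica_set(toy_dimer, [frames])
        avg = average_structure(rs, selection="calpha")
        out = rmsf_per_residue(rs, avg)
        assert out.rmsf.mean() == pytest.approx(sigma * np.sqrt(3), rel=0.10)

    def test_pooling_equals_concatenation(self, toy_dimer):
        rng = np.random.default_rng(3)
        frames = [toy_dimer.coords + rng.normal(0, 0.2, toy_dimer.coords.shape)
                  for _ in range(8)]
        split = replica_set(toy_dimer, [frames[:4], frames[4:]])
        concat = replica_set(toy_dimer, [frames])
        avg = average_structure(concat, selection="calpha")
        a = rmsf_per_residue(split, avg)
        b = rmsf_per_residue(concat, avg)
        assert np.allclose(a.rmsf, b.rmsf, atol=1e-12)


class TestContacts:
    @pytest.mark.parametrize("gap,expected", [(3.4, True), (3.6, False)])
    def test_cutoff_gates_contact(self, gap, expected):
        atoms = [AtomRecord(1, "CA", "C", 0, "GLY", "A", np.zeros(3), 1.7),
                 AtomRecord(2, "CA", "C", 1, "GLY", "A",
                            np.array([gap, 0.0, 0.0]), 1.7)]
        s = StructureModel(atoms)
        cm = contact_map(s.coords, s, cutoff=3.5)
        assert bool(cm[0, 1]) is expected

    def test_matches_all_pairs_brute_force(self, toy_dimer):
        cm = contact_map(toy_dimer.coords, toy_dimer, cutoff=3.5)
        labels = [(c, ri) for c, ri, _, _ in toy_dimer.residues()]
        coords = toy_dimer.coords
        groups = [toy_dimer.residue_atom_indices(c, ri) for c, ri in labels]
        n = len(labels)
        oracle = np.eye(n, dtype=bool)
        for i in range(n):
            for j in range(i + 1, n):
                d = np.sqrt(((coords[groups[i]][:, None]
                              - coords[groups[j]][None]) ** 2).sum(-1)).min()
                oracle[i, j] = oracle[j, i] = d <= 3.5
        assert np.array_equal(cm, oracle)

    def test_occupancy_trivial_fractions(self, toy_dimer):
        rs = replica_set(toy_dimer, [[toy_dimer.coords] * 2] * 4)
        occ = contact_occupancy(rs)
        assert np.all(np.diag(occ.matrix) == 1.0)
        assert np.allclose(occ.matrix, occ.matrix.T)
        cm = contact_map(toy_dimer.coords, toy_dimer)
        assert np.array_equal(occ.matrix == 1.0, cm)

    def test_occupancy_monotone_in_cutoff(self, toy_dimer):
        rs = replica_set(toy_dimer, [[toy_dimer.coords] * 2])
        small = contact_occupancy(rs, cutoff=3.0).matrix
        large = contact_occupancy(rs, cutoff=5.0).matrix
        assert np.all(large >= small)

    def test_programmed_bernoulli_rate_recovered(self, toy_dimer):
        from vacuform.synth import PhaseSpec, designated_pairs, generate_phase_ensemble

        pairs = designated_pairs(toy_dimer, n_pairs=1)
        spec = PhaseSpec(phase=Phase.BULK, n_frames=50, n_replicas=8,
                         jitter_sigma=0.05, contact_pairs=pairs,
                         contact_probs=[0.3], seed=99)
        rs = generate_phase_ensemble(toy_dimer, spec)
        occ = contact_occupancy(rs)
        labels = {lab[:2]: k for k, lab in enumerate(occ.residue_labels)}
        i, j = labels[pairs[0][0]], labels[pairs[0][1]]
        n = 50 * 8
        ci = 3 * np.sqrt(0.3 * 0.7 / n)
        assert abs(occ.matrix[i, j] - 0.3) <= ci

    def test_empty_window_is_an_error(self, toy_dimer):
        rs = replica_set(toy_dimer, [[toy_dimer.coords] * 3])
        with pytest.raises(DataError):
            contact_occupancy(rs, window=(3, 3))


def hbond_fixture(da_dist, angle_deg):
    """N–H···O geometry: donor N at origin, H along +x, acceptor O at
    `da_dist` from N, rotated `angle_deg` off the N–H axis."""
    theta = np.radians(angle_deg)
    acceptor = da_dist * np.array([np.cos(theta), np.sin(theta), 0.0])
    atoms = [
        AtomRecord(1, "N", "N", 0, "GLY", "A", np.zeros(3), 1.55),
        AtomRecord(2, "H", "H", 0, "GLY", "A", np.array([1.0, 0, 0]), 1.20),
        AtomRecord(3, "CA", "C", 0, "GLY", "A", np.array([-1.4, 0.5, 0]), 1.70),
        AtomRecord(4, "O", "O", 1, "GLY", "A", acceptor, 1.52),
        AtomRecord(5, "CA", "C", 1, "GLY", "A", acceptor + [1.2, 0.8, 0], 1.70),
    ]
    return StructureModel(atoms)


class TestHydrogenBonds:
    @pytest.mark.parametrize("dist,angle,expected", [
        (2.9, 0.0, 1),    # collinear, within range
        (4.0, 0.0, 0),    # too far
        (2.9, 45.0, 0),   # angle gate
    ])
    def test_geometric_gates(self, dist, angle, expected):
        s = hbond_fixture(dist, angle)
        out = hydrogen_bond_count(s.coords, s)
        assert out.count == expected
        assert not out.proxy_mode

    def test_hydrogen_free_input_uses_flagged_proxy(self, toy_dimer):
        out = hydrogen_bond_count(toy_dimer.coords, toy_dimer)
        assert out.proxy_mode
        assert out.count > 0
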