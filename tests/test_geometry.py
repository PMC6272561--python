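"""Geometry analytics: superposition, rings, stacking, contacts, H-bonds."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from conftest import make_atoms, multi_frame_ensemble, single_frame_ensemble
from coopbind import geometry
from coopbind.geometry import (
    GeometryError,
    RingSystem,
    SeriesSummary,
    backbone_rmsd_series,
    classify_stacking,
    close_contact_fraction,
    detect_stacking,
    distance_series,
    hydrogen_bonds,
    kabsch_superpose,
    perceive_rings,
    ring_pair_geometry,
    rmsf_per_residue,
)
from coopbind.model_io import Frame, Topology


def rot_z(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array(
        [[math.cos(t), -math.sin(t), 0], [math.sin(t), math.cos(t), 0], [0, 0, 1]]
    )


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        _, _, rmsd = kabsch_superpose(pts, pts, range(5))
        assert rmsd == 0.0

    def test_rigid_invariance(self):
        pts = np.random.default_rng(1).normal(size=(6, 3))
        moved = pts @ rot_z(90).T + np.array([5.0, 0, 0])
        rot, trans, rmsd = kabsch_superpose(moved, pts, range(6))
        assert rmsd < 1e-12
        assert np.isclose(np.linalg.det(rot), 1.0)

    def test_matches_brute_force_optimizer(self):
        # fixed 4-point sets; oracle = numerical minimization over rotations
        x = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 2.0, 0.3], [0.2, 0.1, 1.8]])
        y = np.array([[0.1, 0, 0], [1.4, 0.2, 0], [0.3, 1.9, 0.5], [0, 0, 2.0]])

        xc, yc = x - x.mean(0), y - y.mean(0)

        def objective(v):
            r = Rotation.from_rotvec(v).as_matrix()
            return np.mean(np.sum((xc @ r.T - yc) ** 2, axis=1))

        best = min(
            (
                minimize(objective, v0, method="Nelder-Mead",
                         options={"xatol": 1e-12, "fatol": 1e-14}).fun
                for v0 in [np.zeros(3), [1, 1, 1], [-2, 0.5, 0.1], [0, 3, 0]]
            )
        )
        oracle_rmsd = math.sqrt(best)
        _, _, rmsd = kabsch_superpose(x, y, range(4))
        assert abs(rmsd - oracle_rmsd) < 1e-6

    def test_proper_rotation_even_for_reflected_input(self):
        pts = np.random.default_rng(2).normal(size=(5, 3))
        mirrored = pts * np.array([1, 1, -1])
        rot, _, _ = kabsch_superpose(mirrored, pts, range(5))
        assert np.isclose(np.linalg.det(rot), 1.0)

    def test_collinear_selection_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(GeometryError, match="non-collinear"):
            kabsch_superpose(line, line, range(4))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_rmsd_invariant_under_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(5, 3))
        y = rng.normal(size=(5, 3))
        r = Rotation.random(rng=rng).as_matrix()
        t = rng.normal(size=3) * 10
        _, _, rmsd1 = kabsch_superpose(x, y, range(5))
        _, _, rmsd2 = kabsch_superpose(x @ r.T + t, y, range(5))
        assert abs(rmsd1 - rmsd2) < 1e-8


class TestRmsdSeries:
    def test_rigid_motions_give_zero(self):
        top = Topology(atoms=make_atoms(5))
        base = np.random.default_rng(3).normal(size=(5, 3))
        coords = [
            base @ rot_z(30 * k).T + np.array([k, 0.0, 0]) for k in range(4)
        ]
        ens = multi_frame_ensemble(top, coords)
        series, summary = backbone_rmsd_series(ens, Frame(1, base), range(5))
        assert max(series) < 1e-12
        assert summary.n_frames == 4

    def test_single_frame_equal_reference(self):
        top = Topology(atoms=make_atoms(4))
        base = np.random.default_rng(4).normal(size=(4, 3))
        ens = single_frame_ensemble(top, base)
        series, summary = backbone_rmsd_series(ens, Frame(1, base), range(4))
        assert series == [0.0]
        assert summary.sample_std == 0.0

    def test_jittered_mean_matches_chi_expectation(self):
        # E[rmsd^2] = sigma^2 (3N-6)/N after removing 6 rigid dof
        n, sigma, frames = 60, 0.2, 200
        top = Topology(atoms=make_atoms(n))
        rng = np.random.default_rng(5)
        base = rng.normal(scale=4.0, size=(n, 3))
        coords = [base + rng.normal(0, sigma, (n, 3)) for _ in range(frames)]
        ens = multi_frame_ensemble(top, coords)
        series, summary = backbone_rmsd_series(ens, Frame(1, base), range(n))
        expected = sigma * math.sqrt((3 * n - 6) / n)
        assert abs(summary.mean - expected) < 3 * summary.standard_error + 0.01


class TestRmsf:
    def _one_jittered_atom(self, sigma, frames, seed=6):
        # atoms 0-3 form a rigid anchor; atom 4 (own residue) jitters
        top = Topology(
            atoms=make_atoms(5, residue_number=[1, 1, 1, 1, 2])
        )
        rng = np.random.default_rng(seed)
        base = np.array(
            [[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3], [5.0, 5, 5]]
        )
        coords = []
        for _ in range(frames):
            c = base.copy()
            c[4] += rng.normal(0, sigma, 3)
            coords.append(c)
        return multi_frame_ensemble(top, coords)

    def test_identical_frames_zero(self):
        top = Topology(atoms=make_atoms(4))
        base = np.random.default_rng(7).normal(size=(4, 3))
        ens = multi_frame_ensemble(top, [base, base, base])
        assert all(v < 1e-12 for v in rmsf_per_residue(ens).values())

    def test_single_frame_rejected(self):
        top = Topology(atoms=make_atoms(4))
        ens = single_frame_ensemble(
            top, np.random.default_rng(8).normal(size=(4, 3))
        )
        with pytest.raises(GeometryError, match="two frames"):
            rmsf_per_residue(ens)

    def test_two_frame_displacement_halves(self):
        ens = self._one_jittered_atom(0.0, 2)
        c2 = ens.frames[1].coordinates.copy()
        c2[4, 0] += 1.0
        ens.frames[1].coordinates = c2
        vals = rmsf_per_residue(ens, align_selection=[0, 1, 2, 3])
        assert math.isclose(vals[("A", 2, "RES")], 0.5, abs_tol=1e-9)

    def test_isotropic_jitter_recovers_sigma_sqrt3(self):
        sigma, frames = 0.5, 400
        ens = self._one_jittered_atom(sigma, frames)
        vals = rmsf_per_residue(ens, align_selection=[0, 1, 2, 3])
        expected = sigma * math.sqrt(3)
        # chi-distributed estimator: rel. s.e. ~ 1/sqrt(2*frames) per dof
        se = expected / math.sqrt(2 * 3 * frames)
        assert abs(vals[("A", 2, "RES")] - expected) < 3 * se + 0.02


class TestRingPerception:
    def test_benzene_single_ring(self, benzene_topology, hexagon):
        rings = perceive_rings(benzene_topology, Frame(1, hexagon))
        assert len(rings) == 1
        assert len(rings[0].member_atoms) == 6

    def test_naphthalene_two_rings_vs_enumeration(self):
        # fused 6-cycles sharing the (0,1) edge
        bonds = {(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0),
                 (1, 6), (6, 7), (7, 8), (8, 9), (9, 0)}
        top = Topology(atoms=make_atoms(10), bonds=frozenset(bonds))
        # oracle: brute-force enumeration of all simple cycles of length 5/6
        g = nx.Graph(list(bonds))
        all_cycles = {
            frozenset(c) for c in nx.simple_cycles(g) if len(c) in (5, 6)
        }
        assert len(all_cycles) == 2  # the 10-cycle is excluded by length
        # planar coordinates: two fused regular-ish hexagons
        coords = np.zeros((10, 3))
        coords[0] = (0, -0.7, 0)
        coords[1] = (0, 0.7, 0)
        for k, i in enumerate((2, 3, 4, 5)):
            ang = math.pi / 5 * (k + 1)
            coords[i] = (1.4 * math.sin(ang), 0.7 - 2.2 * k / 3, 0)
        coords[2] = (1.2, 1.4, 0)
        coords[3] = (2.4, 0.7, 0)
        coords[4] = (2.4, -0.7, 0)
        coords[5] = (1.2, -1.4, 0)
        coords[6] = (-1.2, 1.4, 0)
        coords[7] = (-2.4, 0.7, 0)
        coords[8] = (-2.4, -0.7, 0)
        coords[9] = (-1.2, -1.4, 0)
        rings = perceive_rings(top, Frame(1, coords))
        assert len(rings) == 2
        assert {frozenset(r.member_atoms) for r in rings} == all_cycles

    def test_bent_ring_excluded(self, benzene_topology, hexagon):
        bent = hexagon.copy()
        bent[0, 2] = 1.0  # push one member far out of plane
        assert perceive_rings(benzene_topology, Frame(1, bent)) == []

    def test_explicit_definitions_override(self, hexagon):
        atoms = make_atoms(6)
        top = Topology(
            atoms=atoms,
            bonds=frozenset((i, (i + 1) % 6) for i in range(6)),
            ring_definitions=[[0, 1, 2, 3, 4, 5]],
        )
        bent = hexagon.copy()
        bent[0, 2] = 1.0
        rings = perceive_rings(top, Frame(1, bent))
        assert len(rings) == 1  # explicit entry skips the planarity filter


class TestRingPairGeometry:
    def _ring_pair(self, hexagon, offset, rotation=None):
        coords_b = hexagon.copy() if rotation is None else hexagon @ rotation.T
        coords_b = coords_b + offset
        coords = np.vstack([hexagon, coords_b])
        ring_a = RingSystem(0, tuple(range(6)), "receptor")
        ring_b = RingSystem(1, tuple(range(6, 12)), "ligand1")
        return Frame(1, coords), ring_a, ring_b

    def test_parallel_offset(self, hexagon):
        frame, a, b = self._ring_pair(hexagon, np.array([0, 0, 4.0]))
        d, ang = ring_pair_geometry(frame, a, b)
        assert math.isclose(d, 4.0, abs_tol=1e-9)
        assert math.isclose(ang, 0.0, abs_tol=1e-9)

    def test_perpendicular_planes(self, hexagon):
        rot_x90 = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float)
        frame, a, b = self._ring_pair(hexagon, np.array([5.0, 0, 0]), rot_x90)
        d, ang = ring_pair_geometry(frame, a, b)
        assert math.isclose(d, 5.0, abs_tol=1e-9)
        assert math.isclose(ang, 90.0, abs_tol=1e-9)

    def test_explicit_31_degree_tilt(self, hexagon):
        t = math.radians(31.0)
        rot = np.array(
            [[1, 0, 0], [0, math.cos(t), -math.sin(t)], [0, math.sin(t), math.cos(t)]]
        )
        frame, a, b = self._ring_pair(hexagon, np.array([0, 0, 5.0]), rot)
        _, ang = ring_pair_geometry(frame, a, b)
        assert abs(ang - 31.0) < 1e-6

    def test_symmetry_under_swap(self, hexagon):
        rng = np.random.default_rng(11)
        rot = Rotation.random(rng=rng).as_matrix()
        frame, a, b = self._ring_pair(hexagon, np.array([1.0, 2.0, 3.0]), rot)
        assert ring_pair_geometry(frame, a, b) == ring_pair_geometry(frame, b, a)

    def test_antiparallel_normals_fold_to_zero(self, hexagon):
        flip = np.diag([1.0, -1.0, -1.0])  # reverses the plane normal
        frame, a, b = self._ring_pair(hexagon, np.array([0, 0, 4.0]), flip)
        _, ang = ring_pair_geometry(frame, a, b)
        assert math.isclose(ang, 0.0, abs_tol=1e-9)

    def test_collinear_members_rejected(self):
        coords = np.vstack(
            [np.stack([np.arange(6), np.zeros(6), np.zeros(6)], axis=1),
             np.random.default_rng(1).normal(size=(6, 3))]
        )
        a = RingSystem(0, tuple(range(6)), "receptor")
        b = RingSystem(1, tuple(range(6, 12)), "ligand1")
        with pytest.raises(GeometryError, match="collinear"):
            ring_pair_geometry(Frame(1, coords), a, b)


class TestStackingDetection:
    def _two_ring_system(self, hexagon, distance):
        coords = np.vstack([hexagon, hexagon + np.array([0, 0, distance])])
        atoms = make_atoms(6, partition="receptor") + make_atoms(6, partition="ligand1")
        for i, a in enumerate(atoms):
            object.__setattr__(a, "serial", i + 1)
        bonds = set()
        for base in (0, 6):
            bonds |= {(base + i, base + (i + 1) % 6) for i in range(6)}
        top = Topology(atoms=atoms, bonds=frozenset(bonds))
        ens = multi_frame_ensemble(top, [coords] * 5)
        rings = perceive_rings(top, ens.frames[0])
        return ens, rings

    def test_just_inside_cutoff_always_detected(self, hexagon):
        ens, rings = self._two_ring_system(hexagon, 6.99)
        records, summaries = detect_stacking(ens, rings)
        assert summaries[0].occupancy == 1.0
        assert len(records) == 5

    def test_just_outside_cutoff_never_detected(self, hexagon):
        ens, rings = self._two_ring_system(hexagon, 7.01)
        records, summaries = detect_stacking(ens, rings)
        assert records == []
        assert summaries[0].occupancy == 0.0
        assert summaries[0].distance_qualifying is None

    def test_same_partition_pairs_skipped_by_default(self, hexagon):
        ens, rings = self._two_ring_system(hexagon, 4.0)
        for r in rings:
            object.__setattr__(r, "owner_partition", "receptor")
        _, summaries = detect_stacking(ens, rings)
        assert summaries == []
        _, summaries = detect_stacking(ens, rings, cross_partition_only=False)
        assert len(summaries) == 1

    def test_synthetic_recovery_within_three_se(self):
        from coopbind.synth import SyntheticSpec, build_toy_complex, generate_ensemble

        spec = SyntheticSpec(
            seed=42, n_frames=200, jitter_sigma=0.2,
            receptor_n_residues=4, n_aromatic_residues=1,
            stacking_targets=[(5.07, 40.0)],
        )
        top, base = build_toy_complex(spec)
        ens, manifest = generate_ensemble(top, base, spec)
        rings = perceive_rings(top, base)
        _, summaries = detect_stacking(ens, rings)
        pair = manifest.stacking_pairs[0]
        target_members = {
            frozenset(pair["receptor_ring_atoms"]),
            frozenset(pair["ligand_ring_atoms"]),
        }
        match = next(
            s for s in summaries
            if {
                frozenset(rings[s.ring_a].member_atoms),
                frozenset(rings[s.ring_b].member_atoms),
            }
            == target_members
        )
        d = match.distance_qualifying
        assert abs(d.mean - 5.07) < 3 * d.standard_error + 0.02
        a = match.angle_qualifying
        assert abs(a.mean - 40.0) < 3 * a.standard_error + 0.5


class TestClassification:
    @pytest.mark.parametrize(
        "angle,expected",
        [(16.0, "parallel"), (31.0, "tilted"), (58.0, "tilted"),
         (52.0, "tilted"), (90.0, "perpendicular"), (0.0, "parallel"),
         (61.0, "perpendicular")],
    )
    def test_thresholds(self, angle, expected):
        assert classify_stacking(angle) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(GeometryError):
            classify_stacking(-1.0)
        with pytest.raises(GeometryError):
            classify_stacking(95.0)


class TestCloseContacts:
    def _system(self):
        # residues 1 and 2 (one heavy atom each) + one-atom ligand
        atoms = make_atoms(2, residue_number=[1, 2]) + make_atoms(1, partition="ligand1")
        for i, a in enumerate(atoms):
            object.__setattr__(a, "serial", i + 1)
        return Topology(atoms=atoms)

    def test_far_residue_absent(self):
        top = self._system()
        coords = np.array([[0.0, 0, 0], [20, 0, 0], [2, 0, 0]])
        ens = multi_frame_ensemble(top, [coords] * 3)
        profile = close_contact_fraction(ens, "ligand1")
        assert ("A", 2, "RES") not in profile.fractions
        assert profile.fractions[("A", 1, "RES")] == 1.0

    def test_seven_of_ten_frames(self):
        top = self._system()
        frames = []
        for k in range(10):
            lig_x = 3.0 if k < 7 else 8.0
            frames.append(np.array([[0.0, 0, 0], [20, 0, 0], [lig_x, 0, 0]]))
        ens = multi_frame_ensemble(top, frames)
        profile = close_contact_fraction(ens, "ligand1")
        assert profile.fractions[("A", 1, "RES")] == 0.7

    def test_hydrogens_ignored(self):
        atoms = make_atoms(1) + make_atoms(1, element="H") + make_atoms(
            1, partition="ligand1"
        )
        for i, a in enumerate(atoms):
            object.__setattr__(a, "serial", i + 1)
        top = Topology(atoms=atoms)
        # hydrogen is close, heavy atom is not
        coords = np.array([[10.0, 0, 0], [2.0, 0, 0], [0, 0, 0]])
        ens = multi_frame_ensemble(top, [coords])
        profile = close_contact_fraction(ens, "ligand1")
        assert profile.fractions == {}

    def test_monotone_in_cutoff(self, toy_ensemble):
        ens, _ = toy_ensemble
        p5 = close_contact_fraction(ens, "ligand1", cutoff=5.0, include_zero=True)
        p6 = close_contact_fraction(ens, "ligand1", cutoff=6.0, include_zero=True)
        for key, frac in p5.fractions.items():
            assert p6.fractions[key] >= frac

    def test_unknown_partition(self, toy_ensemble):
        ens, _ = toy_ensemble
        with pytest.raises(Exception):
            close_contact_fraction(ens, "ligand9")

    def test_deterministic(self, toy_ensemble):
        ens, _ = toy_ensemble
        a = close_contact_fraction(ens, "ligand1")
        b = close_contact_fraction(ens, "ligand1")
        assert a.fractions == b.fractions


class TestHydrogenBonds:
    def _donor_system(self, pair_distances, angle_deg=170.0):
        # donor N (0) with H (1); acceptor O (2); per-frame N...O distances
        atoms = (
            make_atoms(1, element="N")
            + make_atoms(1, element="H")
            + make_atoms(1, element="O", partition="ligand1")
        )
        for i, a in enumerate(atoms):
            object.__setattr__(a, "serial", i + 1)
        top = Topology(atoms=atoms, bonds=frozenset({(0, 1)}))
        frames = []
        t = math.radians(180.0 - angle_deg)
        c = math.cos(t)
        for d in pair_distances:
            h = np.array([1.0, 0, 0])
            # choose |H-A| so that |N-A| = d while the D-H...A angle holds
            length = -c + math.sqrt(c * c - 1.0 + d * d)
            o = h + length * np.array([c, math.sin(t), 0])
            frames.append(np.vstack([[0.0, 0, 0], h, o]))
        return multi_frame_ensemble(top, frames)

    def test_ideal_bond_full_occupancy(self):
        ens = self._donor_system([2.83] * 4, angle_deg=170.0)
        (rec,) = hydrogen_bonds(ens, donors=[0], acceptors=[2])
        assert rec.occupancy == 1.0
        assert math.isclose(rec.heavy_atom_distance, 2.83, abs_tol=1e-9)

    def test_long_pair_zero_occupancy(self):
        ens = self._donor_system([3.8] * 4)
        (rec,) = hydrogen_bonds(ens, donors=[0], acceptors=[2])
        assert rec.occupancy == 0.0

    def test_half_occupancy(self):
        ens = self._donor_system([3.16, 4.5, 3.16, 4.5])
        (rec,) = hydrogen_bonds(ens, donors=[0], acceptors=[2])
        assert rec.occupancy == 0.5
        assert math.isclose(rec.heavy_atom_distance, 3.16, abs_tol=1e-9)

    def test_angle_screen_rejects_bent_geometry(self):
        ens = self._donor_system([2.9] * 3, angle_deg=90.0)
        (rec,) = hydrogen_bonds(ens, donors=[0], acceptors=[2])
        assert rec.occupancy == 0.0

    def test_donor_without_hydrogen_rejected_in_angle_mode(self):
        atoms = make_atoms(1, element="N") + make_atoms(
            1, element="O", partition="ligand1"
        )
        object.__setattr__(atoms[1], "serial", 2)
        top = Topology(atoms=atoms)
        ens = multi_frame_ensemble(top, [np.array([[0.0, 0, 0], [3, 0, 0]])])
        with pytest.raises(GeometryError, match="no bonded hydrogen"):
            hydrogen_bonds(ens, donors=[0], acceptors=[1])
        recs = hydrogen_bonds(ens, donors=[0], acceptors=[1], use_angle=False)
        assert recs[0].occupancy == 1.0


class TestDistanceSeries:
    def test_fixed_distance(self):
        top = Topology(atoms=make_atoms(2))
        coords = np.array([[0.0, 0, 0], [5.24, 0, 0]])
        ens = multi_frame_ensemble(top, [coords] * 6)
        s = distance_series(ens, 0, 1)
        assert math.isclose(s.mean, 5.24, abs_tol=1e-12)
        assert s.sample_std < 1e-12

    def test_two_frames_arithmetic(self):
        top = Topology(atoms=make_atoms(2))
        ens = multi_frame_ensemble(
            top,
            [np.array([[0.0, 0, 0], [3, 0, 0]]), np.array([[0.0, 0, 0], [5, 0, 0]])],
        )
        s = distance_series(ens, 0, 1)
        assert math.isclose(s.mean, 4.0, abs_tol=1e-12)
        assert math.isclose(s.sample_std, math.sqrt(2), abs_tol=1e-12)

    def test_same_atom_rejected(self, toy_ensemble):
        ens, _ = toy_ensemble
        with pytest.raises(GeometryError):
            distance_series(ens, 3, 3)

    def test_jittered_pair_recovers_target(self, toy_ensemble):
        ens, manifest = toy_ensemble
        hb = manifest.hbond_pairs[0]
        s = distance_series(ens, hb["donor"], hb["acceptor"])
        # jittered distance is biased upward by ~sigma^2/d (noncentral chi)
        assert abs(s.mean - hb["target_length"]) < 3 * s.standard_error + 0.01


class TestSeriesSummary:
    def test_requires_values(self):
        with pytest.raises(GeometryError):
            SeriesSummary.from_values([])

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_matches_numpy(self, values):
        s = SeriesSummary.from_values(values)
        assert math.isclose(s.mean, float(np.mean(values)), abs_tol=1e-9)
        if len(values) > 1:
            assert math.isclose(
                s.sample_std, float(np.std(values, ddof=1)), abs_tol=1e-9
            )
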