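"""SASA quadrature, buried interface area, windowing, contacts, drift."""

import numpy as np
import pytest

from ectodimer.metrics import (ContactSpec, MissingRadiusError, buried_area_pair,
                               buried_interface_area, contact_distance,
                               contact_series, interface_series, sasa,
                               window_average, arm_drift)
from ectodimer.modelbuild import DimerModel, remove_ligand
from ectodimer.structio import Chain, Structure, Trajectory
from ectodimer.synthetic import (PseudoTrajectoryParams, ToyDimerParams,
                                 hinge_residue, make_pseudo_trajectory,
                                 make_toy_dimer, toy_domain_maps)

from conftest import make_residue


def _atoms_structure(specs, chain="A", resname="GLY") -> Structure:
    return Structure(chains=[Chain(chain, [make_residue(1, resname, specs)])])


def two_sphere_reference(r1, r2, d, probe) -> float:
    """Closed-form accessible area of two intersecting probe-expanded spheres."""
    R1, R2 = r1 + probe, r2 + probe
    if d >= R1 + R2:
        return 4 * np.pi * (R1 ** 2 + R2 ** 2)
    h1 = R1 - (d ** 2 + R1 ** 2 - R2 ** 2) / (2 * d)
    h2 = R2 - (d ** 2 + R2 ** 2 - R1 ** 2) / (2 * d)
    return 4 * np.pi * R1 ** 2 - 2 * np.pi * R1 * h1 \
        + 4 * np.pi * R2 ** 2 - 2 * np.pi * R2 * h2


class TestSasa:
    def test_single_sphere_analytic(self):
        s = _atoms_structure([("CA", "C", (0, 0, 0), 1.9)])
        res = sasa(s, probe=1.4, points=960)
        exact = 4 * np.pi * (1.9 + 1.4) ** 2
        assert abs(res.total - exact) / exact < 0.01

    def test_distant_atoms_additive(self):
        s = _atoms_structure([("CA", "C", (0, 0, 0), 1.7),
                              ("CB", "C", (50, 0, 0), 1.9)])
        res = sasa(s)
        exact = 4 * np.pi * ((1.7 + 1.4) ** 2 + (1.9 + 1.4) ** 2)
        assert abs(res.total - exact) / exact < 0.01

    @pytest.mark.parametrize("d", [1.0, 2.5, 4.0, 5.5])
    def test_two_overlapping_spheres_match_cap_formula(self, d):
        s = _atoms_structure([("CA", "C", (0, 0, 0), 1.7),
                              ("CB", "C", (d, 0, 0), 1.9)])
        res = sasa(s, probe=1.4, points=960)
        exact = two_sphere_reference(1.7, 1.9, d, 1.4)
        assert abs(res.total - exact) / exact < 0.015

    def test_quadrature_refinement_stable(self):
        rng = np.random.default_rng(0)
        specs = [(f"C{i}", "C", tuple(rng.normal(0, 2.5, 3))) for i in range(12)]
        s = Structure(chains=[Chain("A", [make_residue(1, "XXX", specs)])])
        coarse = sasa(s, points=960).total
        fine = sasa(s, points=1920).total
        assert abs(fine - coarse) / fine < 0.005

    def test_missing_radius_names_atom(self):
        s = _atoms_structure([("QQ", "Qq", (0, 0, 0))])
        with pytest.raises(MissingRadiusError, match="QQ"):
            sasa(s)

    def test_matches_biotite_reference_implementation(self):
        """Cross-check against an independent Shrake–Rupley implementation."""
        biotite_struc = pytest.importorskip("biotite.structure")
        import biotite.structure as struc

        rng = np.random.default_rng(1)
        n = 25
        xyz = rng.normal(0, 4.0, (n, 3))
        arr = struc.AtomArray(n)
        arr.coord = xyz.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, n + 1)
        arr.res_name[:] = "GLY"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        ref = struc.sasa(arr, probe_radius=1.4, point_number=1000,
                         vdw_radii="Single").sum()
        specs = [("CA", "C", tuple(p), 1.7) for p in xyz]
        chain = Chain("A", [make_residue(i + 1, "GLY", [specs[i]]) for i in range(n)])
        mine = sasa(Structure(chains=[chain]), probe=1.4, points=960).total
        # vdW sets differ slightly (1.70 vs biotite's single-atom carbon radius)
        assert abs(mine - ref) / ref < 0.05


class TestBuriedArea:
    def test_zero_at_large_separation(self):
        model = make_toy_dimer(ToyDimerParams())
        far = model.copy()
        for res in far.structure.chain("B").residues:
            for a in res.atoms:
                a.coords = a.coords + np.array([100.0, 0, 0])
        assert buried_interface_area(far, domain_maps=toy_domain_maps(30)) == \
            pytest.approx(0.0, abs=0.1)

    def test_symmetric_under_subunit_swap(self):
        model = make_toy_dimer(ToyDimerParams(gap=2.0))
        a = model.subunit("A")
        b = model.subunit("B")
        assert buried_area_pair(a, b) == pytest.approx(buried_area_pair(b, a),
                                                       abs=1e-9)

    def test_monotone_in_gap(self):
        areas = [buried_interface_area(make_toy_dimer(ToyDimerParams(gap=g)),
                                       domain_maps=toy_domain_maps(30))
                 for g in (0.0, 5.0, 10.0)]
        assert areas[0] > areas[1] > areas[2] >= 0.0

    def test_monotone_under_translation_apart(self):
        base = make_toy_dimer(ToyDimerParams())
        areas = []
        for shift in (0.0, 0.5, 1.0, 1.5, 6.0):
            m = base.copy()
            for res in m.structure.chain("B").residues:
                for a in res.atoms:
                    a.coords = a.coords + np.array([shift, 0.0, 0.0])
            areas.append(buried_interface_area(m, domain_maps=toy_domain_maps(30)))
        assert all(x > y for x, y in zip(areas[:4], areas[1:4]))
        assert areas[-1] == pytest.approx(0.0, abs=0.1)

    def test_ligand_excluded_by_default(self):
        model = make_toy_dimer(ToyDimerParams())
        s = model.structure.copy()
        lig = Chain("L", [make_residue(1, "GLY",
                                       [("CA", "C", (3.5, 2.0, 0.0), 1.9)])])
        s.chains.append(lig)
        with_lig = DimerModel(s, ("A", "B"), ["L"])
        dmaps = toy_domain_maps(30)
        a_with = buried_interface_area(with_lig, domain_maps=dmaps)
        a_without = buried_interface_area(remove_ligand(with_lig, "L"),
                                          domain_maps=dmaps)
        assert a_with == pytest.approx(a_without, abs=1e-9)
        assert buried_interface_area(with_lig, domain_maps=dmaps,
                                     include_ligands=True) > a_with


class TestWindowAverage:
    def test_constant_series_unchanged(self):
        t = np.arange(10) * 20.0
        v = np.full(10, 7.5)
        assert np.allclose(window_average(t, v, 200.0), 7.5)

    def test_linear_ramp_preserved_in_interior(self):
        t = np.arange(21) * 20.0
        v = 3.0 * t + 1.0
        w = window_average(t, v, 200.0)
        interior = slice(5, 16)
        assert np.allclose(w[interior], v[interior], atol=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(2)
        t = np.sort(rng.uniform(0, 1000, 40))
        v = rng.normal(size=40)
        w = window_average(t, v, 150.0)
        for i in range(40):
            members = [v[j] for j in range(40) if abs(t[j] - t[i]) <= 75.0]
            assert w[i] == pytest.approx(np.mean(members), abs=1e-12)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            window_average(np.arange(3.0), np.arange(3.0), 0.0)

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            window_average(np.array([0.0, 2.0, 1.0]), np.zeros(3), 1.0)


class TestInterfaceSeries:
    def test_identical_frames_constant_series(self):
        model = make_toy_dimer(ToyDimerParams())
        frames = [model.structure.copy() for _ in range(4)]
        traj = Trajectory.from_structures(frames, spacing_ns=20.0)
        ser = interface_series(traj, ("A", "B"), domain_maps=toy_domain_maps(30),
                               points=240)
        assert np.allclose(ser.areas, ser.areas[0])
        assert np.allclose(ser.windowed, ser.areas[0])

    def test_single_frame_equals_static_metric(self):
        model = make_toy_dimer(ToyDimerParams())
        traj = Trajectory.from_structures([model.structure.copy()])
        dmaps = toy_domain_maps(30)
        ser = interface_series(traj, ("A", "B"), domain_maps=dmaps, points=240)
        static = buried_interface_area(model, domain_maps=dmaps, points=240)
        assert len(ser.areas) == 1
        assert ser.areas[0] == pytest.approx(static, abs=1e-9)

    def test_closed_to_open_windowed_series_decreases(self):
        traj = make_pseudo_trajectory(PseudoTrajectoryParams())
        ser = interface_series(traj, ("A", "B"), domain_maps=toy_domain_maps(30),
                               points=240, window=200.0)
        assert np.all(np.diff(ser.windowed) < 0.0)


class TestContacts:
    def _pair(self, d, name_b="O", elem_b="O"):
        a = Chain("A", [make_residue(194, "GLN", [
            ("CD", "C", (-1.2, 0, 0)), ("OE1", "O", (-1.8, 1.1, 0)),
            ("NE2", "N", (0.0, 0.0, 0.0))])])
        b = Chain("B", [make_residue(213, "CYS", [(name_b, elem_b, (d, 0.0, 0.0))])])
        return Structure(chains=[a, b])

    def test_hbond_at_2p9_satisfied(self):
        s = self._pair(2.9)
        spec = ContactSpec("hbond", {"chain": "A", "resi": 194},
                           {"chain": "B", "resi": 213})
        assert contact_distance(s, spec) == pytest.approx(2.9)
        assert contact_distance(s, spec) <= spec.cutoff

    def test_pair_at_8A_fails_all_kinds(self):
        s = self._pair(8.0)
        for kind in ("hbond", "salt-bridge", "cation-pi"):
            spec = ContactSpec(kind, {"chain": "A", "resi": 194},
                               {"chain": "B", "resi": 213})
            assert contact_distance(s, spec) > spec.cutoff

    def test_hbond_uses_polar_atoms_only(self):
        # carbon at 2 Å must not register; nearest N/O pair is 2.9 Å
        s = self._pair(2.9)
        s.chain("B").residues[0].atoms.append(
            make_residue(1, "X", [("CB", "C", (2.0, 0, 0))]).atoms[0])
        spec = ContactSpec("hbond", {"chain": "A", "resi": 194},
                           {"chain": "B", "resi": 213})
        assert contact_distance(s, spec) == pytest.approx(2.9)

    def test_cation_pi_uses_ring_centroid(self):
        ring = []
        for k in range(6):
            ang = np.radians(60 * k)
            ring.append((f"C{k}", "C", (1.4 * np.cos(ang), 1.4 * np.sin(ang), 0.0)))
        tyr = Chain("B", [make_residue(251, "TYR", ring)])
        arg = Chain("A", [make_residue(285, "ARG", [("NH1", "N", (0.0, 0.0, 4.0))])])
        s = Structure(chains=[arg, tyr])
        spec = ContactSpec("cation-pi", {"chain": "A", "resi": 285},
                           {"chain": "B", "resi": 251})
        assert contact_distance(s, spec) == pytest.approx(4.0)

    def test_distance_kind_requires_cutoff(self):
        with pytest.raises(ValueError):
            ContactSpec("distance", {}, {})

    def test_series_on_static_trajectory(self):
        s = self._pair(2.9)
        traj = Trajectory.from_structures([s.copy(), s.copy(), s.copy()])
        spec = ContactSpec("hbond", {"chain": "A", "resi": 194},
                           {"chain": "B", "resi": 213})
        ser = contact_series(traj, spec)
        assert np.allclose(ser.distances, 2.9)
        assert ser.fraction_satisfied() == 1.0


class TestArmDrift:
    def _static_traj(self, n_frames=4):
        model = make_toy_dimer(ToyDimerParams())
        return Trajectory.from_structures(
            [model.structure.copy() for _ in range(n_frames)])

    def test_static_trajectory_all_zero(self):
        traj = self._static_traj()
        m = hinge_residue(30)
        drift = arm_drift(traj, "B", (1, m - 1), "A", (1, 30))
        assert np.allclose(drift, 0.0, atol=1e-9)

    def test_linear_displacement_gives_linear_drift(self):
        model = make_toy_dimer(ToyDimerParams())
        m = hinge_residue(30)
        frames = []
        for k in range(5):
            f = model.structure.copy()
            for res in f.chain("B").residues:
                if res.number < m:
                    for a in res.atoms:
                        a.coords = a.coords + np.array([0.5 * k, 0, 0])
            frames.append(f)
        traj = Trajectory.from_structures(frames)
        drift = arm_drift(traj, "B", (1, m - 1), "A", (1, 30))
        assert drift[0] == pytest.approx(0.0, abs=1e-9)
        ratios = drift[1:] / drift[1]
        assert np.allclose(ratios, [1, 2, 3, 4], atol=1e-6)

    def test_invariant_under_global_rigid_motion_of_frames(self):
        from scipy.spatial.transform import Rotation
        from ectodimer.geometry import Transform

        model = make_toy_dimer(ToyDimerParams())
        m = hinge_residue(30)
        rng = np.random.default_rng(3)
        frames = []
        for k in range(4):
            f = model.structure.copy()
            quat = rng.normal(size=4)
            t = Transform(Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix(),
                          rng.normal(scale=20.0, size=3))
            frames.append(f.transformed(t))
        traj = Trajectory.from_structures(frames)
        drift = arm_drift(traj, "B", (1, m - 1), "A", (1, 30))
        assert np.allclose(drift, 0.0, atol=1e-6)
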