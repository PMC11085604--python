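"""Contact, deviation, size, surface, and disulfide analyses."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgnano import (SimulationConfig, System, contact_probability,
                    contacts_count_series, native_contact_fraction,
                    radius_of_gyration, rmsd, rmsd_series, rmsf, sasa,
                    ss_distance_distribution)
from cgnano.analysis import nanoparticle_centers, _protein_points
from cgnano.dynamics import Trajectory


def _traj_from_frames(frames):
    frames = np.asarray(frames, float)
    cfg = SimulationConfig(n_steps=max(len(frames) - 1, 1), save_every=1)
    return Trajectory(frames, np.arange(len(frames), dtype=float) + 1.0,
                      [None] * len(frames), np.zeros(len(frames)), cfg)


class TestContactProbability:
    def test_permanent_contact_probability_one(self, explicit_complex,
                                               make_static_trajectory):
        trajs = [make_static_trajectory(explicit_complex) for _ in range(3)]
        cp = contact_probability(trajs, explicit_complex,
                                 perspective="protein")
        assert cp.values.shape == (explicit_complex.n_res, 1)
        np.testing.assert_allclose(cp.values, 1.0)

    def test_indicator_mean_over_trajectories(self, explicit_complex):
        """In contact in exactly half the single-frame trajectories -> 0.5."""
        x_in = explicit_complex.coords()
        x_out = x_in.copy()
        x_out[:2 * explicit_complex.n_res] += 500.0
        trajs = [_traj_from_frames([x_in, x_in]) for _ in range(10)]
        trajs += [_traj_from_frames([x_out, x_out]) for _ in range(10)]
        cp = contact_probability(trajs, explicit_complex,
                                 perspective="fullerene")
        np.testing.assert_allclose(cp.values, 0.5)
        assert cp.n_trajectories == 20

    def test_matches_brute_force_loop(self, explicit_trajectory):
        traj, sys_ = explicit_trajectory
        cutoff = 8.0
        cp = contact_probability([traj], sys_, cutoff=cutoff,
                                 perspective="fullerene")
        centers0 = nanoparticle_centers(sys_, traj.frames[0])
        brute = np.zeros(len(centers0))
        for frame in traj.frames:
            centers = nanoparticle_centers(sys_, frame)
            prot = _protein_points(sys_, frame)
            for c_i, c in enumerate(centers):
                d = np.linalg.norm(prot - c, axis=1)
                if (d <= cutoff).any():
                    brute[c_i] += 1
        brute /= traj.n_frames
        np.testing.assert_allclose(cp.values[:, 0], brute, atol=1e-12)

    def test_monotone_in_cutoff(self, explicit_trajectory):
        traj, sys_ = explicit_trajectory
        prev = None
        for cutoff in (4.0, 6.0, 8.0, 12.0):
            cp = contact_probability([traj], sys_, cutoff=cutoff,
                                     perspective="protein")
            if prev is not None:
                assert np.all(cp.values >= prev - 1e-12)
            prev = cp.values
            assert np.all((cp.values >= 0) & (cp.values <= 1))

    def test_mismatched_system_rejected(self, explicit_trajectory,
                                        implicit_complex,
                                        make_static_trajectory):
        traj, _ = explicit_trajectory
        with pytest.raises(ValueError):
            contact_probability([traj], implicit_complex)


class TestContactCounts:
    def test_separated_all_zero(self, make_static_trajectory):
        from cgnano import build_toy_pocket_complex
        sys_ = build_toy_pocket_complex(n_residues=6, model="explicit",
                                        offset=(300.0, 0, 0))
        traj = make_static_trajectory(sys_, n_frames=3)
        np.testing.assert_array_equal(contacts_count_series(traj, sys_), 0)

    def test_pinned_site_counts_one(self, make_static_trajectory):
        from cgnano import build_toy_pocket_complex
        sys_ = build_toy_pocket_complex(n_residues=6, model="implicit",
                                        offset=(300.0, 0, 0))
        x = sys_.coords()
        n = sys_.n_res
        # pin one side chain inside the cutoff of the sphere center; its
        # residue (and only it) registers a contact
        x[n] = sys_.sphere.center + np.array([7.0, 0.0, 0.0])
        sys_.set_coords(x)
        traj = make_static_trajectory(sys_, n_frames=3)
        np.testing.assert_array_equal(contacts_count_series(traj, sys_), 1)

    def test_scripted_counts_match_brute_force(self, explicit_trajectory):
        traj, sys_ = explicit_trajectory
        counts = contacts_count_series(traj, sys_, cutoff=8.0)
        assert len(counts) == traj.n_frames
        for f_i, frame in enumerate(traj.frames):
            centers = nanoparticle_centers(sys_, frame)
            n = sys_.n_res
            hit = 0
            flanks = sys_.protein.pg_flanks()
            pg = 0.5 * (frame[flanks[:, 0]] + frame[flanks[:, 1]])
            for i in range(n):
                pts = [frame[i], frame[n + i]]
                pts += [pg[j] for j in range(len(flanks))
                        if i in flanks[j]]
                d = np.linalg.norm(
                    np.asarray(pts)[:, None, :] - centers[None, :, :],
                    axis=-1)
                if (d <= 8.0).any():
                    hit += 1
            assert counts[f_i] == hit


class TestRMSD:
    def test_identity_is_zero(self, helix10):
        assert rmsd(helix10.ca_xyz, helix10.ca_xyz) == pytest.approx(0.0)

    def test_rigid_motion_removed(self, helix10):
        R = Rotation.from_euler("xyz", [0.4, -0.9, 1.7]).as_matrix()
        moved = helix10.ca_xyz @ R.T + np.array([4.0, 5.0, -6.0])
        assert rmsd(moved, helix10.ca_xyz) == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_grid_oracle(self):
        """Small distorted toy: Kabsch equals an exhaustive rotation search."""
        rng = np.random.default_rng(8)
        ref = rng.normal(size=(4, 3)) * 3.0
        mob = ref + rng.normal(scale=0.4, size=ref.shape)
        got = rmsd(mob, ref)
        # random-quaternion search with shrinking local refinement
        # (independent of the SVD route)
        qrng = np.random.default_rng(123)
        refc = ref - ref.mean(axis=0)
        mobc = mob - mob.mean(axis=0)

        def value(q):
            Rm = Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()
            return np.sqrt(((mobc @ Rm.T - refc) ** 2).sum(axis=1).mean())

        qs = qrng.normal(size=(5000, 4))
        vals = [value(q) for q in qs]
        best_q = qs[int(np.argmin(vals))]
        best = min(vals)
        scale = 0.3
        for _ in range(40):
            cand = best_q + qrng.normal(size=(500, 4)) * scale
            for q in cand:
                v = value(q)
                if v < best:
                    best, best_q = v, q
            scale *= 0.7
        assert got == pytest.approx(best, abs=1e-6)
        assert got <= best + 1e-12

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            rmsd(np.zeros((2, 3)), np.ones((2, 3)))

    def test_series_over_trajectory(self, explicit_trajectory):
        traj, sys_ = explicit_trajectory
        sel = np.arange(sys_.n_res)
        series = rmsd_series(traj, traj.frames[0][sel], sel)
        assert series[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(series >= 0)


class TestRMSF:
    def test_static_trajectory_zero(self, explicit_complex,
                                    make_static_trajectory):
        traj = make_static_trajectory(explicit_complex, n_frames=5)
        sel = np.arange(explicit_complex.n_res)
        np.testing.assert_allclose(rmsf([traj], sel), 0.0, atol=1e-12)

    def test_known_oscillation_amplitude(self):
        """A site alternating +/-1 Å about its mean has RMSF exactly 1."""
        # non-collinear heavy anchors pin the superposition uniquely
        rng = np.random.default_rng(0)
        base = rng.normal(size=(6, 3)) * 5.0
        frames = []
        for k in range(10):
            f = base.copy()
            f[3, 1] = base[3, 1] + (1.0 if k % 2 == 0 else -1.0)
            frames.append(f)
        traj = _traj_from_frames(frames)
        prof = rmsf([traj], np.arange(6),
                    masses=np.array([1e9, 1e9, 1e9, 1e-9, 1e9, 1e9]))
        assert prof[3] == pytest.approx(1.0, abs=1e-6)

    def test_matches_two_pass_computation(self, explicit_trajectory):
        traj, sys_ = explicit_trajectory
        sel = np.arange(sys_.n_res)
        prof = rmsf([traj], sel, n_iter=1)
        from cgnano.analysis import kabsch_superpose
        X = traj.frames[:, sel, :]
        fitted = np.array([kabsch_superpose(f, X[0]) for f in X])
        mean = fitted.mean(axis=0)
        brute = np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose(prof, brute, atol=1e-12)

    def test_frame_order_invariant(self, explicit_trajectory):
        traj, sys_ = explicit_trajectory
        sel = np.arange(sys_.n_res)
        a = rmsf([traj], sel)
        rev = _traj_from_frames(traj.frames[::-1])
        b = rmsf([rev], sel)
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_single_frame_rejected(self, explicit_complex,
                                   make_static_trajectory):
        traj = make_static_trajectory(explicit_complex, n_frames=2)
        traj.frames = traj.frames[:1]
        with pytest.raises(ValueError):
            rmsf([traj], np.arange(explicit_complex.n_res))


class TestRadiusOfGyration:
    def test_single_point(self):
        rg, mx = radius_of_gyration([[1.0, 2.0, 3.0]])
        assert rg == 0.0 and mx == 0.0

    def test_two_equal_masses(self):
        rg, mx = radius_of_gyration([[0, 0, 0], [4.0, 0, 0]])
        assert rg == pytest.approx(2.0)
        assert mx == pytest.approx(2.0)

    def test_unit_square(self):
        pts = [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]]
        rg, mx = radius_of_gyration(pts)
        assert rg == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-12)
        assert mx == pytest.approx(1.0 / np.sqrt(2.0), abs=1e-12)

    def test_mass_weighting(self):
        rg, _ = radius_of_gyration([[0, 0, 0], [3.0, 0, 0]],
                                   masses=[3.0, 1.0])
        # com at 0.75; rg = sqrt((3*0.75^2 + 1*2.25^2)/4)
        assert rg == pytest.approx(np.sqrt((3 * 0.5625 + 5.0625) / 4.0))


class TestSASA:
    def test_isolated_sphere_closed_form(self):
        total, per = sasa([[0, 0, 0]], [2.0], probe=1.4)
        exact = 4.0 * np.pi * 3.4 ** 2
        assert total == pytest.approx(exact, rel=1e-6)

    def test_distant_spheres_additive(self):
        total, per = sasa([[0, 0, 0], [100.0, 0, 0]], [2.0, 3.0], probe=1.4)
        exact = 4 * np.pi * (3.4 ** 2 + 4.4 ** 2)
        assert total == pytest.approx(exact, rel=1e-6)

    def test_overlapping_dimer_matches_spherical_cap_formula(self):
        # two equal spheres, center distance < 2R: exposed area of each is
        # 4 pi R^2 - 2 pi R h with cap height h = R - d/2 (analytic)
        R, d = 3.4, 4.0
        total, per = sasa([[0, 0, 0], [d, 0, 0]], [2.0, 2.0], probe=1.4,
                          n_points=4000)
        h = R - d / 2.0
        exact_each = 4 * np.pi * R ** 2 - 2 * np.pi * R * h
        np.testing.assert_allclose(per, exact_each, rtol=0.02)

    def test_convergence_under_point_doubling(self, explicit_complex):
        n = explicit_complex.n_res
        coords = explicit_complex.coords()[n:2 * n]
        radii = np.full(n, 1.75)
        t1, _ = sasa(coords, radii, n_points=960)
        t2, _ = sasa(coords, radii, n_points=1920)
        assert abs(t2 - t1) / t2 < 0.005

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sasa([[0, 0, 0]], [0.0])
        with pytest.raises(ValueError):
            sasa([[0, 0, 0]], [1.0], n_points=0)


class TestNativeContacts:
    def test_reference_frame_is_one(self, explicit_trajectory):
        traj, sys_ = explicit_trajectory
        sel = np.arange(sys_.n_res)
        q = native_contact_fraction(traj, traj.frames[0][sel], selection=sel)
        assert q[0] == pytest.approx(1.0)
        assert np.all((q >= 0) & (q <= 1))

    def test_half_broken_toy(self):
        # 6 sites on a line, native set at cutoff 8 with separation >= 3:
        # pairs (0,3),(1,4),(2,5),(0,4),(1,5),(0,5) at spacing 2.0
        base = np.zeros((6, 3))
        base[:, 0] = np.arange(6) * 2.0
        # native set: d<=8 -> separations 3 (d=6) and 4 (d=8): 5 pairs
        moved = base.copy()
        moved[5, 0] += 100.0  # breaks (2,5),(1,5),(0,5): 2 of 5 remain...
        traj = _traj_from_frames([base, moved])
        q = native_contact_fraction(traj, base, cutoff=8.0,
                                    min_sequence_separation=3)
        assert q[0] == 1.0
        # native pairs: (0,3),(1,4),(2,5),(0,4),(1,5) -> moving site 5
        # breaks (2,5) and (1,5), leaving 3/5
        assert q[1] == pytest.approx(3.0 / 5.0)

    def test_empty_native_set_rejected(self):
        base = np.zeros((4, 3))
        base[:, 0] = np.arange(4) * 50.0
        traj = _traj_from_frames([base])
        with pytest.raises(ValueError):
            native_contact_fraction(traj, base, cutoff=8.0)


class TestSSDistances:
    def test_degenerate_and_median(self, implicit_complex):
        prot = implicit_complex.protein
        n = prot.n_residues
        sys_ = System(protein=prot.copy())
        sys_.protein.sequence = "C" + "A" * (n - 2) + "C"
        x = sys_.coords()
        f1 = x.copy()
        f2 = x.copy()
        # place the two Cys side chains at controlled separations
        f1[n] = 0.0
        f1[2 * n - 1] = [3.0, 0, 0]
        f2[n] = 0.0
        f2[2 * n - 1] = [5.0, 0, 0]
        traj = _traj_from_frames([f1, f2])
        dist = ss_distance_distribution([traj], sys_, pairs=[(0, n - 1)])
        assert dist[(0, n - 1)]["quantiles"][50] == pytest.approx(4.0)
        np.testing.assert_array_equal(np.sort(dist[(0, n - 1)]["samples"]),
                                      [3.0, 5.0])

    def test_pooling_equals_concatenation(self, implicit_complex):
        prot = implicit_complex.protein
        n = prot.n_residues
        sys_ = System(protein=prot.copy())
        sys_.protein.sequence = "CC" + "A" * (n - 2)
        rng = np.random.default_rng(3)
        trajs = []
        expected = []
        for _ in range(3):
            frames = np.tile(sys_.coords(), (4, 1, 1))
            frames[:, n, 0] = 0.0
            sep = rng.uniform(3, 8, 4)
            frames[:, n + 1, :] = 0.0
            frames[:, n + 1, 0] = frames[:, n, 0] + sep
            frames[:, n, 1:] = 0.0
            expected.extend(np.abs(sep - 0.0))
            trajs.append(_traj_from_frames(frames))
        dist = ss_distance_distribution(trajs, sys_, pairs=[(0, 1)])
        np.testing.assert_allclose(np.sort(dist[(0, 1)]["samples"]),
                                   np.sort(expected), atol=1e-9)

    def test_non_cys_pair_rejected(self, explicit_complex):
        with pytest.raises(ValueError):
            ss_distance_distribution([], explicit_complex, pairs=[(0, 1)])
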