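"""Effective-energy terms: values, symmetries, analytic forces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cgnano import (EnergyWeights, FixtureSpec, GayBerneParams, System,
                    build_synthetic_peptide, build_toy_pocket_complex,
                    compute_internal_coordinates, disulfide_energy,
                    excluded_volume_energy, forces, gay_berne_energy,
                    temperature_factor, total_energy)
from cgnano.energy import bonded_energy, disulfide_potential
from cgnano.params import ForceFieldParams


class TestGayBerne:
    def test_zero_at_sigma(self):
        p = GayBerneParams(epsilon=2.0, sigma0=4.2)
        assert gay_berne_energy(4.2, p) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_depth_in_spherical_limit(self):
        p = GayBerneParams(epsilon=1.7, sigma0=3.9)
        r_min = 2.0 ** (1.0 / 6.0) * 3.9
        assert gay_berne_energy(r_min, p) == pytest.approx(-1.7, abs=1e-12)

    def test_direct_evaluation(self):
        # 4 * (0.8^12 - 0.8^6), evaluated by hand
        p = GayBerneParams(epsilon=1.0, sigma0=4.0)
        assert gay_berne_energy(5.0, p) == pytest.approx(-0.773698093056,
                                                         abs=1e-12)

    def test_spherical_limit_is_lennard_jones_on_dense_grid(self):
        p = GayBerneParams(epsilon=1.3, sigma0=4.1)
        r = np.linspace(3.0, 100.0, 4000)
        lj = 4 * 1.3 * ((4.1 / r) ** 12 - (4.1 / r) ** 6)
        np.testing.assert_allclose(gay_berne_energy(r, p), lj, atol=1e-12)

    def test_singular_shift_rejected(self):
        p = GayBerneParams(epsilon=1.0, sigma0=3.0, sigma=5.0)
        with pytest.raises(ValueError):
            gay_berne_energy(1.5, p)
        with pytest.raises(ValueError):
            gay_berne_energy(float("nan"), GayBerneParams())

    def test_anisotropic_orientation_reduces_to_spherical_for_kappa_one(self):
        p = GayBerneParams(epsilon=1.0, sigma0=4.0,
                           anisotropy_ratios=(1.0, 1.0, 2.0, 1.0))
        u = np.array([0.0, 0.0, 1.0])
        iso = gay_berne_energy(5.0, GayBerneParams(epsilon=1.0, sigma0=4.0))
        assert gay_berne_energy(5.0, p, orientations=(u, u)) == \
            pytest.approx(iso, abs=1e-12)


class TestTemperatureFactor:
    def test_unity_at_reference(self):
        for n in (2, 3, 4):
            assert temperature_factor(n, 300.0, 300.0) == 1.0

    def test_value_at_simulation_temperature(self):
        # direct evaluation of the cumulant coefficient at 260 K
        assert temperature_factor(2, 260.0, 300.0) == pytest.approx(
            1.0947682553722926, abs=1e-12)

    @given(st.integers(2, 5))
    @settings(derandomize=True, max_examples=20)
    def test_strictly_decreasing_in_temperature(self, n):
        T = np.linspace(100.0, 900.0, 60)
        f = np.array([temperature_factor(n, t) for t in T])
        assert np.all(np.diff(f) < 0)
        assert np.all(f[T < 300.0] > 1.0)
        assert np.all(f[T > 300.0] < 1.0)

    def test_vanishes_at_high_temperature(self):
        assert temperature_factor(3, 1e5) < 1e-3

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            temperature_factor(1, 300.0)


class TestBondedEnergy:
    def test_zero_at_reference_geometry(self, helix10):
        params = ForceFieldParams(theta0=90.0, tor_a=(), tor_b=())
        geo = compute_internal_coordinates(helix10)
        terms = bonded_energy(helix10, geo, params)
        assert terms["U_bond"] == pytest.approx(0.0, abs=1e-12)
        assert terms["U_b"] == pytest.approx(0.0, abs=1e-12)
        assert terms["U_rot"] == pytest.approx(0.0, abs=1e-10)

    def test_single_stretched_bond(self, helix10):
        # 0.1 Å stretch with k=100 -> 1/2 * 100 * 0.01 = 0.5 kcal/mol
        params = ForceFieldParams(k_bond_bb=100.0, k_bond_sc=0.0,
                                  k_theta=0.0, tor_a=(), tor_b=(),
                                  k_alpha=0.0, k_beta=0.0)
        geo = compute_internal_coordinates(helix10)
        geo.d_bb = geo.d_bb.copy()
        geo.d_bb[3] += 0.1
        assert bonded_energy(helix10, geo, params)["U_bond"] == \
            pytest.approx(0.5, abs=1e-9)

    def test_torsion_cosine_endpoints(self, helix10):
        params = ForceFieldParams(tor_a=(1.0,), tor_b=())
        geo = compute_internal_coordinates(helix10)
        geo.gamma = np.zeros_like(geo.gamma)
        assert bonded_energy(helix10, geo, params)["U_tor"] == \
            pytest.approx(len(geo.gamma) * 1.0)
        geo.gamma = np.full_like(geo.gamma, 180.0)
        assert bonded_energy(helix10, geo, params)["U_tor"] == \
            pytest.approx(-len(geo.gamma) * 1.0)

    def test_missing_residue_type_named(self, helix10):
        params = ForceFieldParams()
        params.d_sc0 = {k: v for k, v in params.d_sc0.items() if k != "A"}
        geo = compute_internal_coordinates(helix10)
        with pytest.raises(KeyError, match="A"):
            bonded_energy(helix10, geo, params)


class TestExcludedVolume:
    def test_unit_ratio(self):
        params = ForceFieldParams(eps_rep=1.0, sigma_rep=3.4)
        e = excluded_volume_energy([[0, 0, 0]], [[3.4, 0, 0]], params)
        assert e == pytest.approx(1.0, abs=1e-12)

    def test_double_distance(self):
        params = ForceFieldParams(eps_rep=1.0, sigma_rep=2.0)
        e = excluded_volume_energy([[0, 0, 0]], [[4.0, 0, 0]], params)
        assert e == pytest.approx(2.0 ** -12, abs=1e-15)

    def test_everywhere_nonnegative(self):
        rng = np.random.default_rng(0)
        params = ForceFieldParams()
        for _ in range(20):
            sc = rng.uniform(-8, 8, (4, 3))
            pg = rng.uniform(-8, 8, (3, 3))
            assert excluded_volume_energy(sc, pg, params) >= 0.0

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            excluded_volume_energy([[0, 0, 0]], [[0, 0, 0]],
                                   ForceFieldParams())


class TestDisulfide:
    def test_well_minimum_and_flag(self):
        params = ForceFieldParams()
        sc = np.array([[0, 0, 0], [params.d_ss0, 0, 0]], float)
        e, flags = disulfide_energy([(0, 1)], "CC", sc, params)
        assert e == pytest.approx(-params.ss_depth, abs=1e-12)
        assert flags == [True]

    def test_plateau_and_unbonded_flag(self):
        params = ForceFieldParams()
        sc = np.array([[0, 0, 0], [80.0, 0, 0]], float)
        e, flags = disulfide_energy([(0, 1)], "CC", sc, params)
        assert e == 0.0
        assert flags == [False]

    def test_non_cysteine_pair_rejected(self):
        with pytest.raises(ValueError, match="Cys"):
            disulfide_energy([(0, 1)], "CA", np.zeros((2, 3)),
                             ForceFieldParams())

    def test_continuity_and_smoothness_at_joins(self):
        params = ForceFieldParams()
        joins = [params.d_ss0 - params.ss_x_barrier,
                 params.d_ss0 + params.ss_x_barrier,
                 params.d_ss0 + params.ss_x_plateau]
        eps = 1e-9
        for d in joins:
            ul, dul = disulfide_potential(d - eps, params)
            ur, dur = disulfide_potential(d + eps, params)
            assert abs(ul - ur) < 1e-8
            assert abs(dul - dur) < 1e-6

    def test_derivative_matches_central_difference(self):
        params = ForceFieldParams()
        d = np.linspace(1.5, 9.5, 4001)
        joins = np.array([params.d_ss0 - params.ss_x_barrier,
                          params.d_ss0 + params.ss_x_barrier,
                          params.d_ss0 + params.ss_x_plateau])
        # away from the joins the pieces are polynomial (C2), so central
        # differences converge; at a join the curvature jumps and the
        # straddling stencil is only first-order accurate
        keep = np.abs(d[1:-1, None] - joins).min(axis=1) > 0.01
        u = np.array([disulfide_potential(x, params)[0] for x in d])
        num = (u[2:] - u[:-2]) / (d[2] - d[0])
        ana = np.array([disulfide_potential(x, params)[1] for x in d[1:-1]])
        assert np.abs(num - ana)[keep].max() < 1e-3


class TestAssembly:
    def test_zero_weights_no_nanoparticle_gives_zero(self, helix10):
        w = EnergyWeights(**{f: 0.0 for f in EnergyWeights().__dict__})
        sys_ = System(protein=helix10.copy(), weights=w)
        assert total_energy(sys_, T=260.0).total == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_doubling_weight_doubles_contribution(self, helix10):
        sys_ = System(protein=helix10.copy())
        bd1 = total_energy(sys_, T=260.0)
        sys_2 = System(protein=helix10.copy(),
                       weights=EnergyWeights(w_SC=2.0))
        bd2 = total_energy(sys_2, T=260.0)
        assert bd2.total - bd1.total == pytest.approx(
            bd1.terms["U_SCSC"], rel=1e-9)

    def test_breakdown_resums_to_total(self, explicit_complex):
        bd = total_energy(explicit_complex, T=260.0)
        assert bd.total == pytest.approx(bd.resum(), abs=1e-9)
        # temperature scaling applied to the torsional term
        f2 = temperature_factor(2, 260.0)
        assert bd.scales["U_tor"] == pytest.approx(f2)
        assert bd.scales["U_nano"] == 1.0

    def test_pluggable_terms_disabled_by_default(self, helix10):
        bd = total_energy(System(protein=helix10.copy()))
        assert bd.terms["U_pp_el"] == 0.0
        assert {"U_pp_el", "U_corr3", "U_turn3"} <= bd.disabled

    def test_pluggable_term_enters_with_f2_scaling(self, helix10):
        sys_ = System(protein=helix10.copy(),
                      pp_el_term=lambda s, x: 10.0)
        bd0 = total_energy(System(protein=helix10.copy()), T=260.0)
        bd = total_energy(sys_, T=260.0)
        f2 = temperature_factor(2, 260.0)
        assert bd.total - bd0.total == pytest.approx(10.0 * f2, rel=1e-12)


def _numeric_forces(system, T=260.0, h=1e-5):
    x0 = system.coords()
    F = np.zeros_like(x0)
    for i in range(x0.shape[0]):
        for k in range(3):
            xp = x0.copy()
            xp[i, k] += h
            xm = x0.copy()
            xm[i, k] -= h
            F[i, k] = -(total_energy(system, T=T, coords=xp).total
                        - total_energy(system, T=T, coords=xm).total) / (2 * h)
    return F


ONE_HOT_TERMS = ["w_SC", "w_SCp", "w_pp_VDW", "w_tor", "w_b", "w_rot",
                 "w_bond", "w_ssbond"]


class TestForces:
    @pytest.mark.parametrize("active", ONE_HOT_TERMS)
    def test_each_term_matches_finite_differences(self, active):
        weights = EnergyWeights(**{f: 0.0 for f in EnergyWeights().__dict__})
        setattr(weights, active, 1.0)
        prot = build_synthetic_peptide(
            FixtureSpec(kind="ideal_helix", n_residues=7,
                        sequence="ACAACCA", seed=2, jitter=0.15))
        sys_ = System(protein=prot, weights=weights)
        F = forces(sys_, T=260.0)
        Fn = _numeric_forces(sys_)
        scale = max(np.abs(Fn).max(), 1.0)
        assert np.abs(F - Fn).max() / scale < 1e-4

    def test_nanoparticle_terms_match_finite_differences(self):
        sys_ = build_toy_pocket_complex(n_residues=6, model="explicit")
        F = forces(sys_, T=260.0)
        Fn = _numeric_forces(sys_)
        assert np.abs(F - Fn).max() / np.abs(Fn).max() < 1e-4

    def test_implicit_sphere_forces_match_finite_differences(self):
        sys_ = build_toy_pocket_complex(n_residues=6, model="implicit")
        F = forces(sys_, T=260.0)
        Fn = _numeric_forces(sys_)
        assert np.abs(F - Fn).max() / np.abs(Fn).max() < 1e-4

    def test_stationary_at_minimum(self, minimized_helix):
        F = forces(minimized_helix, T=300.0)
        assert np.abs(F).max() < 1e-3

    def test_translation_invariance(self, explicit_complex):
        F1 = forces(explicit_complex, T=260.0)
        x = explicit_complex.coords() + np.array([7.0, -2.0, 3.0])
        sys2 = explicit_complex.copy()
        sys2.set_coords(x)
        if sys2.sphere is not None:
            pytest.skip("implicit sphere breaks translation invariance")
        F2 = forces(sys2, T=260.0)
        np.testing.assert_allclose(F1, F2, atol=1e-8)

    def test_isolated_system_net_force_and_torque_vanish(self, helix10):
        sys_ = System(protein=helix10.copy())
        F = forces(sys_, T=260.0)
        np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-9)
        torque = np.cross(sys_.coords(), F).sum(axis=0)
        np.testing.assert_allclose(torque, 0.0, atol=1e-8)

    def test_nan_term_is_named(self, helix10):
        sys_ = System(protein=helix10.copy(),
                      pp_el_term=lambda s, x: float("nan"))
        with pytest.raises(ValueError, match="U_pp_el"):
            total_energy(sys_)


class TestPairSymmetry:
    @given(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
           st.sampled_from("ACDEFGHIKLMNPQRSTVWY"),
           st.floats(5.0, 30.0))
    @settings(derandomize=True, max_examples=60)
    def test_pair_energy_symmetric_under_exchange(self, ti, tj, r):
        """Swapping the residue types of a pair leaves its energy unchanged."""
        params = ForceFieldParams()
        assert gay_berne_energy(r, params.gb_pair(ti, tj)) == \
            gay_berne_energy(r, params.gb_pair(tj, ti))
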