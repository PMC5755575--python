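"""Debye–Waller factors, structure-factor assembly, least squares, HAR loop."""

import numpy as np
import pytest

from conftest import adp_error, coord_error_angstrom
from harkit.crystal_io import (AtomSite, CrystalStructure, ReflectionSet,
                               SymOp, UnitCell, grow_fragment, u_cart_to_cif)
from harkit.refine import (RefinementOptions, build_environment, debye_waller,
                           har_iterate, optimal_scale, polar_axes,
                           prune_reflections, refine_lsq, structure_factor_sum)
from harkit.scatter import FormFactorSet, compute_form_factor_set
from harkit.synthetic import (GaussianDensityProvider, ToySpec,
                              make_toy_crystal, perturb_model,
                              simulate_reflections)
from harkit.atomdens import PromoleculeDensityProvider


class TestDebyeWaller:
    def test_zero_u_is_unity(self):
        cell = UnitCell(10, 10, 10)
        assert debye_waller([(1, 2, 3)], 0.0, cell)[0] == 1.0

    def test_cubic_isotropic_closed_form(self):
        # a = 10 Å, h = (1,0,0): s = 0.05 Å⁻¹, T = exp(-8π²·0.01·0.0025)
        cell = UnitCell(10, 10, 10)
        T = debye_waller([(1, 0, 0)], 0.01, cell)[0]
        assert T == pytest.approx(np.exp(-8 * np.pi**2 * 0.01 * 0.05**2), rel=1e-12)
        assert T == pytest.approx(0.99803, abs=1e-5)

    def test_iso_and_equivalent_tensor_agree_in_monoclinic(self):
        cell = UnitCell(4.265, 12.796, 7.490, 90, 100.77, 90)
        u = 0.015
        u6 = u_cart_to_cif(np.eye(3) * u, cell)
        hkl = np.array([[1, 2, 3], [3, -1, 2], [0, 4, -2]])
        assert np.allclose(debye_waller(hkl, u, cell),
                           debye_waller(hkl, u6, cell), atol=1e-12)

    def test_always_in_unit_interval(self):
        cell = UnitCell(6, 7, 8, 80, 95, 100)
        u6 = np.array([0.02, 0.03, 0.015, 0.004, -0.003, 0.002])
        T = debye_waller(np.array([[3, 2, 1], [5, 5, 5]]), u6, cell)
        assert np.all((T > 0) & (T <= 1))


class TestStructureFactorSum:
    def _one_atom_set(self, cell, hkl, fval=6.0):
        vals = np.full((1, len(hkl)), fval, complex)
        return FormFactorSet(["C1"], ["C"], hkl, vals)

    def test_atom_at_origin_modulus_equals_f(self):
        cell = UnitCell(8, 8, 8)
        st = CrystalStructure(cell, [SymOp.identity()],
                              [AtomSite("C1", "C", [0, 0, 0], u_iso=0.0)])
        hkl = np.array([[1, 0, 0], [2, 1, 0], [3, 2, 1], [-1, 0, 2]])
        fs = self._one_atom_set(cell, hkl)
        F = structure_factor_sum(st, fs, 1.0, hkl)
        assert np.allclose(np.abs(F), 6.0)

    def test_quarter_cell_pair_extinction(self):
        # identical atoms at ±(1/4,0,0): F(1,0,0) = f(e^{iπ/2}+e^{-iπ/2}) = 0
        cell = UnitCell(8, 8, 8)
        st = CrystalStructure(cell, [SymOp.identity()], [
            AtomSite("C1", "C", [0.25, 0, 0], u_iso=0.0),
            AtomSite("C2", "C", [0.75, 0, 0], u_iso=0.0),
        ])
        hkl = np.array([[1, 0, 0], [2, 0, 0]])
        vals = np.full((2, len(hkl)), 6.0, complex)
        fs = FormFactorSet(["C1", "C2"], ["C", "C"], hkl, vals)
        F = structure_factor_sum(st, fs, 1.0, hkl)
        assert abs(F[0]) < 1e-12
        assert abs(F[1]) == pytest.approx(12.0, rel=1e-12)

    def test_gaussian_toy_matches_analytic_oracle(self, diatomic):
        from harkit.synthetic import closed_form_structure_factors

        st, model, prov, refl = diatomic
        frag = grow_fragment(st)
        fs = compute_form_factor_set(st, frag, refl.hkl, provider=prov,
                                     mode="hirshfeld")
        F = structure_factor_sum(st, fs, 1.0, refl.hkl)
        F_oracle = closed_form_structure_factors(st, model, refl.hkl)
        scale = np.max(np.abs(F_oracle))
        assert np.max(np.abs(F - F_oracle)) / scale < 1e-10


class TestOptimalScale:
    def test_equal_sets_unity(self):
        F = np.array([3.0, 5.0, 1.0])
        assert optimal_scale(F, F) == pytest.approx(1.0)

    def test_doubled_data(self):
        F = np.array([3.0, 5.0, 1.0])
        w = np.array([2.0, 0.5, 1.0])
        assert optimal_scale(2 * F, F, w) == pytest.approx(2.0)

    def test_matches_numeric_minimizer(self):
        rng = np.random.default_rng(3)
        Fo, Fc = rng.uniform(1, 10, 50), rng.uniform(1, 10, 50)
        w = rng.uniform(0.1, 2, 50)
        k = optimal_scale(Fo, Fc, w)
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda kk: np.sum(w * (Fo - kk * Fc) ** 2))
        assert k == pytest.approx(res.x, abs=1e-10)

    def test_zero_model_rejected(self):
        with pytest.raises(ValueError):
            optimal_scale(np.ones(3), np.zeros(3))


class TestPruning:
    def test_default_three_sigma(self):
        rs = ReflectionSet(np.array([[1, 0, 0], [2, 0, 0]]),
                           np.array([2.0, 10.0]), np.array([1.0, 0.1]))
        kept, report = prune_reflections(rs)
        assert len(kept) == 1 and report["removed"] == 1

    def test_well_measured_all_kept(self):
        n = 30
        hkl = np.column_stack([np.arange(1, n + 1), np.zeros(n, int), np.zeros(n, int)])
        F = np.linspace(1, 10, n)
        rs = ReflectionSet(hkl, F, 0.01 * F)
        kept, report = prune_reflections(rs)
        assert report["kept"] == n

    def test_filter_matches_direct_count(self):
        rng = np.random.default_rng(5)
        n = 1000
        hkl = rng.integers(-9, 10, (n, 3))
        hkl[np.all(hkl == 0, axis=1)] = [1, 1, 1]
        F = rng.uniform(0, 5, n)
        sig = rng.uniform(0.1, 2, n)
        rs = ReflectionSet(hkl, F, sig)
        kept, report = prune_reflections(rs, "F>3sig")
        assert report["kept"] == int(np.sum(F > 3 * sig))

    def test_empty_result_is_error(self):
        rs = ReflectionSet(np.array([[1, 0, 0]]), np.array([1.0]), np.array([5.0]))
        with pytest.raises(ValueError):
            prune_reflections(rs)


class TestLsqCycle:
    def test_stationary_at_truth(self, diatomic):
        st, model, prov, refl = diatomic
        work = st.copy()
        frag = grow_fragment(work)
        fs = compute_form_factor_set(work, frag, refl.hkl, provider=prov,
                                     mode="hirshfeld")
        state, log = refine_lsq(work, refl, fs, RefinementOptions())
        assert log[0]["max_shift_xyz"] < 1e-8
        assert coord_error_angstrom(work, st) < 1e-8

    def test_descent_from_displaced_start(self, diatomic):
        st, model, prov, refl = diatomic
        work = st.copy()
        work.sites[0].xyz[0] += 0.01 / st.cell.a  # ~0.01 Å displacement
        frag = grow_fragment(work)
        fs = compute_form_factor_set(work, frag, refl.hkl, provider=prov,
                                     mode="hirshfeld")
        state, log = refine_lsq(work, refl, fs, RefinementOptions())
        wr2s = [c["wr2"] for c in log]
        assert all(b <= a * (1 + 1e-12) for a, b in zip(wr2s, wr2s[1:]))
        assert wr2s[-1] < 1e-10

    def test_su_calibrated_against_noise_spread(self, diatomic):
        # parameter s.u. vs spread of refined values over noise realizations
        st, model, prov, _ = diatomic
        vals, sus = [], []
        for seed in range(25):
            refl = simulate_reflections(st, prov, 0.7, 0.02, seed=seed)
            work = st.copy()
            res = har_iterate(work, refl, RefinementOptions(), provider=prov)
            vals.append(res.structure.sites[0].xyz[0])
            sus.append(res.structure.sites[0].su_xyz[0])
        spread = np.std(vals, ddof=1)
        mean_su = np.mean(sus)
        assert 0.6 < spread / mean_su < 1.6


class TestHarIterate:
    def test_noise_free_recovery(self, diatomic):
        st, model, prov, refl = diatomic
        start = perturb_model(st, 0.05, 0.005, seed=7)
        res = har_iterate(start, refl, RefinementOptions(), provider=prov)
        assert res.converged
        assert coord_error_angstrom(res.structure, st) < 1e-4
        assert adp_error(res.structure, st) < 1e-5
        assert res.r1 < 1e-4

    def test_h_adp_fixed_mode(self, polar_xh):
        st, model, prov, refl = polar_xh
        start = perturb_model(st, 0.01, 0.001, seed=8)
        h_u_before = start.site_by_label("H1").u_aniso.copy()
        res = har_iterate(start, refl, RefinementOptions(h_adp_mode="fixed"),
                          provider=prov)
        h = res.structure.site_by_label("H1")
        assert np.allclose(h.u_aniso, h_u_before)  # U untouched
        # but the coordinates did refine
        assert res.converged

    def test_iam_nesting_with_spherical_provider(self, diatomic):
        """HAR with a promolecule density equals the IAM refinement."""
        st, model, prov, refl = diatomic
        start = perturb_model(st, 0.01, 0.001, seed=9)
        har = har_iterate(start.copy(), refl,
                          RefinementOptions(mode="har"),
                          provider=PromoleculeDensityProvider())
        iam = har_iterate(start.copy(), refl, RefinementOptions(mode="iam"))
        for a, b in zip(har.structure.sites, iam.structure.sites):
            assert np.max(np.abs(a.xyz - b.xyz)) < 1e-6
            assert np.max(np.abs(a.u_aniso - b.u_aniso)) < 1e-6
        assert har.scale == pytest.approx(iam.scale, abs=1e-6)

    def test_iam_bias_direction_on_polar_data(self, polar_xh):
        st, model, prov, refl = polar_xh

        def bond(s):
            d = s.cell.frac_to_cart(s.sites[1].xyz - s.sites[0].xyz)
            return float(np.linalg.norm(d))

        start = perturb_model(st, 0.01, 0.001, seed=10)
        iam = har_iterate(start.copy(), refl, RefinementOptions(mode="iam"))
        har = har_iterate(start.copy(), refl, RefinementOptions(), provider=prov)
        assert bond(iam.structure) < bond(st)  # spherical model foreshortens
        assert abs(bond(har.structure) - bond(st)) < 0.01

    def test_recovery_through_numerical_quadrature_route(self):
        """The grid-integrated Hirshfeld path (no closed-form shortcut)
        converges to the generating model."""
        st, model = make_toy_crystal(ToySpec("diatomic_P1"))
        prov = GaussianDensityProvider(model, st)
        refl = simulate_reflections(st, prov, 0.5, 0.0, seed=14)
        start = perturb_model(st, 0.02, 0.002, seed=15)
        from conftest import adp_error, coord_error_angstrom

        res = har_iterate(start, refl,
                          RefinementOptions(force_quadrature=True),
                          provider=prov)
        assert res.converged
        assert coord_error_angstrom(res.structure, st) < 1e-5
        assert adp_error(res.structure, st) < 1e-6
        assert res.r1 < 1e-5

    def test_r_factors_invariant_under_reindexing(self, diatomic):
        st, model, prov, refl = diatomic
        res = har_iterate(st.copy(), refl, RefinementOptions(), provider=prov)
        # re-index every reflection by the inversion operation
        refl2 = ReflectionSet(-refl.hkl, refl.value, refl.sigma)
        res2 = har_iterate(st.copy(), refl2, RefinementOptions(), provider=prov)
        assert res2.r1 == pytest.approx(res.r1, abs=1e-12)
        assert res2.wr2 == pytest.approx(res.wr2, abs=1e-12)

    def test_mirror_constraints_respected(self, mirror_site):
        st, model, prov, refl = mirror_site
        start = perturb_model(st, 0.03, 0.003, seed=11)
        o_start = start.site_by_label("O1")
        assert abs(o_start.xyz[1]) < 1e-12  # perturbation kept it on the mirror
        res = har_iterate(start, refl, RefinementOptions(), provider=prov)
        o = res.structure.site_by_label("O1")
        assert abs(o.xyz[1]) < 1e-10
        assert abs(o.u_aniso[3]) < 1e-12 and abs(o.u_aniso[5]) < 1e-12
        assert res.r1 < 1e-6  # model fits despite the floating polar origin

    def test_polar_axes_detection(self, mirror_site, diatomic):
        st_pm, *_ = mirror_site
        st_p1bar, *_ = diatomic
        assert polar_axes(st_pm.symops).shape[1] == 2  # x and z float in Pm
        assert polar_axes(st_p1bar.symops).shape[1] == 0


class TestEnvironment:
    def test_radius_zero_empty(self, diatomic):
        st, *_ = diatomic
        frag = grow_fragment(st)
        env = build_environment(st, frag, RefinementOptions(cluster_radius=0.0))
        assert len(env) == 0

    def test_neutral_crystal_environment_is_neutral(self):
        st, model = make_toy_crystal(ToySpec("diatomic_P1"))
        prov = GaussianDensityProvider(model, st)
        frag = grow_fragment(st)
        from harkit.atomdens import molecular_grid
        from harkit.partition import atomic_multipoles

        grid = molecular_grid(frag, "standard")
        mult = atomic_multipoles(frag, prov.density(frag, grid.points), grid)
        opts = RefinementOptions(cluster_radius=6.0,
                                 environment_kind="charges_dipoles")
        env = build_environment(st, frag, opts, mult)
        assert len(env) > 0
        assert abs(env.total_charge) < 1e-3

    def test_entry_count_matches_bruteforce(self):
        st, _ = make_toy_crystal(ToySpec("ionic_P1"))
        frag = grow_fragment(st)
        opts = RefinementOptions(cluster_radius=8.0,
                                 environment_kind="charges_dipoles")
        env = build_environment(st, frag, opts)
        cnt = 0
        for s in st.sites:
            for a in range(-3, 4):
                for b in range(-3, 4):
                    for c in range(-3, 4):
                        p = st.cell.frac_to_cart(s.xyz + np.array([a, b, c], float))
                        dmin = np.min(np.linalg.norm(frag.positions - p, axis=1))
                        if 1e-3 < dmin <= 8.0:
                            cnt += 1
        assert len(env) == cnt
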