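"""Agreement statistics, residual maps, fractal curves, rigid-bond test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st_h

from harkit.crystal_io import (AtomSite, CrystalStructure, ReflectionSet,
                               SymOp, UnitCell, u_cart_to_cif)
from harkit.metrics import (ResidualMap, adp_ratio_stats, bond_comparison,
                            dmsda, fractal_dimension_curve, r_factors,
                            residual_map, wrmsd)
from harkit.refine import RefinementOptions, har_iterate
from harkit.synthetic import (GaussianDensityProvider, ToySpec,
                              closed_form_structure_factors, make_toy_crystal,
                              simulate_reflections)


class TestRFactors:
    def test_perfect_fit_zero(self):
        F = np.array([3.0, 7.0, 2.0])
        r1, wr2, gof = r_factors(2 * F, F, 2.0)
        assert r1 == 0 and wr2 == 0

    def test_hand_arithmetic(self):
        r1, wr2, _ = r_factors([10.0, 10.0], [9.0, 11.0], 1.0, [1.0, 1.0])
        assert r1 == pytest.approx(0.1)
        assert wr2 == pytest.approx(np.sqrt(2 / 200))

    def test_sigma_scaling_moves_gof_not_r1(self):
        rng = np.random.default_rng(0)
        Fo = rng.uniform(1, 10, 40)
        Fc = Fo * (1 + rng.normal(0, 0.05, 40))
        sig = 0.1 * Fo
        r1a, _, gofa = r_factors(Fo, Fc, 1.0, 1 / sig**2, n_param=2)
        r1b, _, gofb = r_factors(Fo, Fc, 1.0, 1 / (sig / 2) ** 2, n_param=2)
        assert r1a == r1b
        assert gofb == pytest.approx(2 * gofa)

    def test_bruteforce_recomputation(self):
        rng = np.random.default_rng(1)
        Fo, Fc = rng.uniform(1, 9, 25), rng.uniform(1, 9, 25)
        w = rng.uniform(0.5, 2, 25)
        k = 1.3
        r1, wr2, gof = r_factors(Fo, Fc, k, w, n_param=4)
        # independent naive loops
        num = den = wnum = wden = chi = 0.0
        for fo, fc, wi in zip(Fo, Fc, w):
            num += abs(fo - k * fc)
            den += fo
            wnum += wi * (fo - k * fc) ** 2
            wden += wi * fo**2
            chi += wi * (fo - k * fc) ** 2
        assert r1 == pytest.approx(num / den, abs=1e-12)
        assert wr2 == pytest.approx(np.sqrt(wnum / wden), abs=1e-12)
        assert gof == pytest.approx(np.sqrt(chi / 21), abs=1e-12)


class TestWrmsd:
    def test_identical_zero(self):
        v = [1.0, 2.0, 3.0]
        assert wrmsd(v, v, [0.1] * 3, [0.1] * 3) == 0.0

    def test_unit_deviation_is_one(self):
        assert wrmsd([1.0], [0.0], [0.6], [0.8]) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        v = wrmsd([1.0, 2.0, 2.0], [0.0, 0.0, 0.0], [1.0, 1.0, 2.0], [0.0] * 3)
        assert v == pytest.approx(np.sqrt(2), abs=1e-12)

    @given(c=st_h.floats(0.01, 100))
    def test_scale_invariance(self, c):
        vx = np.array([1.0, 2.5, -0.3])
        vn = np.array([0.8, 2.9, 0.1])
        sx = np.array([0.2, 0.3, 0.15])
        sn = np.array([0.1, 0.25, 0.2])
        assert wrmsd(c * vx, c * vn, c * sx, c * sn) == pytest.approx(
            wrmsd(vx, vn, sx, sn), rel=1e-9)


def _toy_pair(seed=0, scale=1.0, aniso_h=True):
    """Two structures with matched labels and randomised ADPs + s.u.s."""
    rng = np.random.default_rng(seed)
    cell = UnitCell(7, 8, 9, 90, 100, 90)

    def build(mult):
        sites = []
        for i, (lab, el, xyz) in enumerate([
            ("C1", "C", [0.1, 0.2, 0.3]), ("O1", "O", [0.3, 0.25, 0.35]),
            ("H1", "H", [0.15, 0.28, 0.42]),
        ]):
            diag = rng.uniform(0.01, 0.03, 3) * mult
            off = rng.uniform(-0.003, 0.003, 3)
            u6 = np.concatenate([diag, off])
            s = AtomSite(lab, el, xyz, u_aniso=u6)
            s.su_u_aniso = rng.uniform(0.0005, 0.002, 6)
            s.su_xyz = rng.uniform(0.0001, 0.0005, 3)
            sites.append(s)
        return CrystalStructure(cell, [SymOp.identity()], sites)

    return build(1.0), build(scale)


class TestAdpRatioStats:
    def test_identical_models(self):
        a, _ = _toy_pair(0)
        c = adp_ratio_stats(a, a, "non-H")
        assert c.ratio_mean == pytest.approx(1.0)
        assert c.diag_diff_mean == 0.0 and c.offdiag_diff_mean == 0.0
        assert c.wrmsd == 0.0

    def test_uniform_scaling(self):
        a, _ = _toy_pair(1)
        b = a.copy()
        for s in b.sites:
            s.u_aniso = s.u_aniso * 1.1
            s.su_u_aniso = np.full(6, 1e-3)
        for s in a.sites:
            s.su_u_aniso = np.full(6, 1e-3)
        c = adp_ratio_stats(b, a, "non-H")
        assert c.ratio_mean == pytest.approx(1.10, abs=1e-12)
        assert c.ratio_sd == pytest.approx(0.0, abs=1e-12)

    def test_bruteforce_recomputation(self):
        a, b = _toy_pair(2, scale=1.07)
        c = adp_ratio_stats(a, b, "non-H", pooled=True)
        ratios, dd, od = [], [], []
        for sa, sb in zip(a.sites, b.sites):
            if sa.element == "H":
                continue
            for i in range(3):
                ratios.append(sa.u_aniso[i] / sb.u_aniso[i])
                dd.append(abs(sa.u_aniso[i] - sb.u_aniso[i]))
            for i in range(3, 6):
                od.append(abs(sa.u_aniso[i] - sb.u_aniso[i]))
        assert c.ratio_mean == pytest.approx(np.mean(ratios), abs=1e-12)
        assert c.ratio_sd == pytest.approx(np.std(ratios, ddof=1), abs=1e-12)
        assert c.diag_diff_mean == pytest.approx(np.mean(dd), abs=1e-12)
        assert c.offdiag_diff_mean == pytest.approx(np.mean(od), abs=1e-12)

    def test_unmatched_labels_error(self):
        a, b = _toy_pair(3)
        b.sites[0].label = "Zz9"
        with pytest.raises(ValueError, match="unmatched"):
            adp_ratio_stats(a, b, "non-H")

    def test_h_class_partition(self):
        a, b = _toy_pair(4, scale=1.2)
        ch = adp_ratio_stats(a, b, "H")
        cn = adp_ratio_stats(a, b, "non-H")
        assert ch.n_atoms == 1 and cn.n_atoms == 2


class TestDmsda:
    def test_identical_tensors_zero(self):
        cell = UnitCell(10, 10, 10)
        u6 = u_cart_to_cif(np.diag([0.02, 0.01, 0.015]), cell)
        sites = [AtomSite("C1", "C", [0.1, 0.1, 0.1], u_aniso=u6),
                 AtomSite("C2", "C", [0.1 + 1.5 / 10, 0.1, 0.1], u_aniso=u6)]
        st = CrystalStructure(cell, [SymOp.identity()], sites)
        rep = dmsda(st)
        assert len(rep.bonds) == 1
        assert rep.bonds[0][3] == pytest.approx(0.0, abs=1e-15)

    def test_hand_projection_along_x(self):
        cell = UnitCell(10, 10, 10)
        ua = u_cart_to_cif(np.diag([0.02, 0.01, 0.01]), cell)
        ub = u_cart_to_cif(np.diag([0.01, 0.01, 0.01]), cell)
        sites = [AtomSite("C1", "C", [0.1, 0.1, 0.1], u_aniso=ua),
                 AtomSite("C2", "C", [0.1 + 1.5 / 10, 0.1, 0.1], u_aniso=ub)]
        st = CrystalStructure(cell, [SymOp.identity()], sites)
        rep = dmsda(st)
        assert abs(rep.bonds[0][3]) == pytest.approx(0.01, abs=1e-12)

    def test_tls_rigid_body_passes_rigid_bond_test(self):
        # pure rigid-body (T + L) motion satisfies the rigid-bond condition
        cell = UnitCell(12, 12, 12)
        rng = np.random.default_rng(6)
        A = rng.normal(0, 0.05, (3, 3))
        T = A @ A.T + 0.01 * np.eye(3)
        B = rng.normal(0, 0.02, (3, 3))
        L = B @ B.T + 1e-4 * np.eye(3)  # rad²
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [2.3, 1.2, 0.1],
                           [1.6, 2.4, 0.8]])
        sites = []
        for i, r in enumerate(coords):
            S = np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0]])
            U = T + S @ L @ S.T
            sites.append(AtomSite(f"C{i+1}", "C", cell.cart_to_frac(r),
                                  u_aniso=u_cart_to_cif(U, cell)))
        st = CrystalStructure(cell, [SymOp.identity()], sites)
        rep = dmsda(st)
        assert len(rep.bonds) >= 2
        assert all(abs(b[3]) < 1e-6 for b in rep.bonds)

    def test_antisymmetric_under_bond_swap(self):
        cell = UnitCell(10, 10, 10)
        ua = u_cart_to_cif(np.diag([0.02, 0.01, 0.01]), cell)
        ub = u_cart_to_cif(np.diag([0.012, 0.013, 0.014]), cell)
        s1 = [AtomSite("A1", "C", [0.1, 0.1, 0.1], u_aniso=ua),
              AtomSite("A2", "C", [0.25, 0.1, 0.1], u_aniso=ub)]
        s2 = [AtomSite("A1", "C", [0.1, 0.1, 0.1], u_aniso=ub),
              AtomSite("A2", "C", [0.25, 0.1, 0.1], u_aniso=ua)]
        d1 = dmsda(CrystalStructure(cell, [SymOp.identity()], s1)).bonds[0][3]
        d2 = dmsda(CrystalStructure(cell, [SymOp.identity()], s2)).bonds[0][3]
        assert d1 == pytest.approx(-d2, abs=1e-15)


class TestBondComparison:
    def test_identical_structures(self):
        a, _ = _toy_pair(7)
        out = bond_comparison(a, a)
        for stx in out.values():
            assert stx["ratio_mean"] == pytest.approx(1.0)
            assert stx["absdiff_mean"] == 0.0

    def test_known_offset_ratio(self):
        cell = UnitCell(10, 10, 10)

        def build(r):
            return CrystalStructure(cell, [SymOp.identity()], [
                AtomSite("O1", "O", [0.1, 0.1, 0.1], u_iso=0.01,
                         su_xyz=[1e-4] * 3),
                AtomSite("H1", "H", [0.1 + r / 10, 0.1, 0.1], u_iso=0.02,
                         su_xyz=[1e-4] * 3),
            ])

        out = bond_comparison(build(0.9), build(1.0))
        st = out["O-H"]
        assert st["ratio_mean"] == pytest.approx(0.90, abs=1e-10)
        assert st["absdiff_mean"] == pytest.approx(0.10, abs=1e-10)


class TestResidualMap:
    def _refined(self, preset="diatomic_P1", refl=None):
        st, model = make_toy_crystal(ToySpec(preset))
        prov = GaussianDensityProvider(model, st)
        if refl is None:
            refl = simulate_reflections(st, prov, 0.7, 0.0, seed=21)
        res = har_iterate(st.copy(), refl, RefinementOptions(), provider=prov)
        return st, model, prov, res

    def test_selfconsistent_model_zero_map(self):
        st, model, prov, res = self._refined()
        m = residual_map(st, res.reflections, res, grid_step=0.25)
        assert max(abs(m.min), abs(m.max)) < 1e-10
        assert abs(m.mean) < 1e-12

    def test_injected_feature_located(self):
        st, model = make_toy_crystal(ToySpec("diatomic_P1"))
        prov = GaussianDensityProvider(model, st)
        base = simulate_reflections(st, prov, 0.7, 0.0, seed=22)
        extra = np.array([0.62, 0.31, 0.55])
        K = st.cell.k_vectors(base.hkl)
        k2 = (K**2).sum(axis=1)
        add = 2.0 * np.exp(-np.pi**2 * k2 / 8.0) * np.exp(
            2j * np.pi * (base.hkl @ extra))
        F = closed_form_structure_factors(st, model, base.hkl)
        refl = ReflectionSet(base.hkl, np.abs(F + add), base.sigma)
        res = har_iterate(st.copy(), refl, RefinementOptions(), provider=prov)
        m = residual_map(st, res.reflections, res, grid_step=0.2)
        ijk = np.unravel_index(np.argmax(m.values), m.values.shape)
        frac = np.array(ijk) / np.array(m.values.shape)
        d = frac - extra
        d -= np.round(d)
        step = max(st.cell.a, st.cell.b, st.cell.c) / min(m.values.shape)
        assert np.linalg.norm(st.cell.frac_to_cart(d)) < 2 * step

    def test_grid_step_guard(self):
        st, model, prov, res = self._refined()
        with pytest.raises(ValueError, match="alias"):
            residual_map(st, res.reflections, res, grid_step=0.5)


class TestFractalDimension:
    def test_white_noise_peaks_at_three_near_zero(self):
        rng = np.random.default_rng(0)
        m = ResidualMap(rng.normal(0, 0.05, (32, 32, 32)), UnitCell(6, 6, 6),
                        0.2, 0)
        lv, df = fractal_dimension_curve(m)
        i0 = np.argmin(np.abs(lv))
        assert df[i0] == pytest.approx(3.0, abs=0.15)
        assert abs(lv[np.argmax(df)]) < 0.02  # peak at ρ0 ≈ 0

    def test_flat_map_degenerate(self):
        m = ResidualMap(np.zeros((16, 16, 16)), UnitCell(6, 6, 6), 0.2, 0)
        lv, df = fractal_dimension_curve(m)
        assert len(lv) == 0 and len(df) == 0

    def test_scaling_covariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 0.03, (24, 24, 24))
        m1 = ResidualMap(vals, UnitCell(6, 6, 6), 0.2, 0)
        m2 = ResidualMap(2 * vals, UnitCell(6, 6, 6), 0.2, 0)
        lv1, df1 = fractal_dimension_curve(m1)
        lv2, df2 = fractal_dimension_curve(m2)
        assert np.allclose(lv2, 2 * lv1)
        assert np.allclose(df2, df1)

    def test_unmodelled_feature_gives_positive_shoulder(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 0.02, (24, 24, 24))
        # strong localized positive blob
        x = np.arange(24)
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        blob = 0.4 * np.exp(-((X - 12) ** 2 + (Y - 12) ** 2 + (Z - 12) ** 2) / 6)
        m = ResidualMap(vals + blob, UnitCell(6, 6, 6), 0.2, 0)
        lv, df = fractal_dimension_curve(m)
        # support extends further on the positive side
        assert lv[-1] > -lv[0] * 2
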