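"""Validation and comparison statistics for refined models.

Covers agreement factors (R1, wR2, GOF), difference-Fourier residual maps
and their fractal-dimension (Henn–Meindl) curves, ADP comparison measures
(⟨U^ii_X/U^ii_N⟩, ⟨|ΔU|⟩, error-weighted wRMSD), the Hirshfeld rigid-bond
test (DMSDA) and bond-length comparison statistics.

The wRMSD convention: for component lists v_X, v_N with standard
uncertainties σ_X, σ_N,

    wRMSD = sqrt( (1/N) Σ_i (v_X,i − v_N,i)² / (σ²_X,i + σ²_N,i) ),

so wRMSD = 1 means the two determinations agree statistically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .crystal_io import BOND_FACTOR, covalent_radius, u_cif_to_cart

logger = logging.getLogger("harkit")

__all__ = [
    "ResidualMap",
    "AdpComparison",
    "RigidBondReport",
    "r_factors",
    "residual_map",
    "fractal_dimension_curve",
    "wrmsd",
    "adp_ratio_stats",
    "dmsda",
    "bond_comparison",
    "detect_bonds",
]


# ---------------------------------------------------------------------------
# R factors
# ---------------------------------------------------------------------------

def r_factors(F_obs, F_calc_mag, scale, weights=None, n_param: int = 1):
    """(R1, wR2, GOF) between |F_obs| and k·|F_calc|.

    R1  = Σ| |Fo| − k|Fc| | / Σ|Fo|
    wR2 = sqrt( Σ w (|Fo| − k|Fc|)² / Σ w |Fo|² )
    GOF = sqrt( Σ w Δ² / (N_obs − N_param) )
    """
    Fo = np.abs(np.asarray(F_obs, float))
    Fc = np.abs(np.asarray(F_calc_mag, float))
    if len(Fo) == 0:
        raise ValueError("empty reflection set")
    w = np.ones_like(Fo) if weights is None else np.asarray(weights, float)
    d = Fo - scale * Fc
    r1 = float(np.sum(np.abs(d)) / np.sum(Fo))
    wr2 = float(np.sqrt(np.sum(w * d**2) / np.sum(w * Fo**2)))
    gof = float(np.sqrt(np.sum(w * d**2) / max(len(Fo) - n_param, 1)))
    return r1, wr2, gof


# ---------------------------------------------------------------------------
# Residual density maps
# ---------------------------------------------------------------------------

@dataclass
class ResidualMap:
    """Difference-Fourier map Δρ on a uniform unit-cell grid (e·Å⁻³)."""

    values: np.ndarray  # (n1, n2, n3)
    cell: object
    grid_step: float
    n_reflections: int

    @property
    def min(self) -> float:
        return float(self.values.min())

    @property
    def max(self) -> float:
        return float(self.values.max())

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def to_xyz_text(self) -> str:
        """Grid export: fractional x y z and Δρ per line."""
        n1, n2, n3 = self.values.shape
        lines = [f"# residual density map {n1}x{n2}x{n3} e/A^3"]
        for i in range(n1):
            for j in range(n2):
                for k in range(n3):
                    lines.append(
                        f"{i / n1:.6f} {j / n2:.6f} {k / n3:.6f} "
                        f"{self.values[i, j, k]:.6e}"
                    )
        return "\n".join(lines)


def _expand_reflections(structure, hkl, coeff):
    """Symmetry- and Friedel-expand Fourier coefficients (conjugate at −h)."""
    seen = {}
    for h, c in zip(np.asarray(hkl, int), coeff):
        for op in structure.symops:
            R = np.array(op.R, int)
            hr = R.T @ h
            ph = np.exp(-2j * np.pi * np.dot(h, op.tran))
            for hh, cc in ((tuple(hr), c * ph), (tuple(-hr), np.conj(c * ph))):
                if hh not in seen:
                    seen[hh] = cc
    hs = np.array(list(seen.keys()), int)
    cs = np.array(list(seen.values()), complex)
    return hs, cs


def residual_map(structure, reflections, result, grid_step: float = 0.1) -> ResidualMap:
    """Difference Fourier synthesis Δρ = FT[(|Fo|/k − |Fc|)·exp(iφ_calc)].

    Phases come from F_calc of the refined model; the sum runs over the
    observed reflections and their symmetry/Friedel mates; no (000) term, so
    the map mean is zero.
    """
    if grid_step > 0.3:
        raise ValueError("grid_step > 0.3 Å would alias the residual map")
    from .refine import structure_factor_sum

    obs = reflections
    F = structure_factor_sum(result.structure, result.form_factors, 1.0, obs.hkl)
    Fc = np.abs(F)
    phase = np.where(Fc > 1e-12, F / np.maximum(Fc, 1e-12), 1.0)
    coeff = (obs.value / result.scale - Fc) * phase

    hs, cs = _expand_reflections(result.structure, obs.hkl, coeff)
    cell = structure.cell
    dims = []
    for L, hmax in zip((cell.a, cell.b, cell.c), np.abs(hs).max(axis=0)):
        n = max(int(np.ceil(L / grid_step)), 2 * int(hmax) + 2)
        dims.append(n)
    n1, n2, n3 = dims
    grid = np.zeros((n1, n2, n3), complex)
    grid[hs[:, 0] % n1, hs[:, 1] % n2, hs[:, 2] % n3] += cs
    # ρ(x) = (1/V) Σ_h F_h exp(−2πi h·x): inverse FFT convention × N/V
    rho = np.fft.ifftn(grid) * (n1 * n2 * n3 / cell.volume)
    vals = np.real(rho)
    return ResidualMap(vals, cell, grid_step, len(obs))


# ---------------------------------------------------------------------------
# Fractal dimension (Henn–Meindl) curves
# ---------------------------------------------------------------------------

def fractal_dimension_curve(rmap: ResidualMap, n_levels: int = 101,
                            decimations=(1, 2, 4, 8)):
    """Box-counting fractal dimension df(ρ0) across residual-density levels.

    For each level ρ0 the voxel set {|Δρ − ρ0| < half-bin} is box-counted at
    the given decimations and df is the log–log slope of box count vs inverse
    box size.  A well-modelled data set yields a parabola-like curve centred
    at ρ0 = 0 peaking near df = 3.  Returns (levels, df) arrays; a flat map
    yields empty arrays.
    """
    v = rmap.values
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-12:
        logger.warning("flat residual map: fractal dimension undefined")
        return np.array([]), np.array([])
    levels = np.linspace(lo, hi, n_levels)
    df = np.full(n_levels, np.nan)
    shape = np.array(v.shape)
    # iso-surface membership: a voxel belongs to the level set if the surface
    # Δρ = ρ0 passes through its periodic 2×2×2 corner cube
    nb_min = v.copy()
    nb_max = v.copy()
    for ax in range(3):
        for arr, op in ((nb_min, np.minimum), (nb_max, np.maximum)):
            arr[...] = op(arr, np.roll(arr, -1, axis=ax))
    for i, rho0 in enumerate(levels):
        member = (nb_min <= rho0) & (nb_max >= rho0)
        if not member.any():
            continue
        logn, logs = [], []
        for b in decimations:
            nb = np.ceil(shape / b).astype(int)
            count = 0
            occ = member[: nb[0] * b, : nb[1] * b, : nb[2] * b]
            # pad to a multiple of b then OR-reduce blocks
            pad = [(0, nb[d] * b - v.shape[d]) for d in range(3)]
            occp = np.pad(member, pad, constant_values=False)
            blocks = occp.reshape(nb[0], b, nb[1], b, nb[2], b)
            count = int(np.any(blocks, axis=(1, 3, 5)).sum())
            if count > 0:
                logn.append(np.log(count))
                logs.append(np.log(1.0 / b))
        if len(logn) >= 2:
            df[i] = float(np.polyfit(logs, logn, 1)[0])
    valid = ~np.isnan(df)
    return levels[valid], df[valid]


# ---------------------------------------------------------------------------
# wRMSD and ADP comparison
# ---------------------------------------------------------------------------

def wrmsd(values_x, values_n, su_x, su_n) -> float:
    """Error-weighted RMS difference; 1 indicates statistical agreement."""
    vx = np.asarray(values_x, float)
    vn = np.asarray(values_n, float)
    sx = np.asarray(su_x, float)
    sn = np.asarray(su_n, float)
    if not (len(vx) == len(vn) == len(sx) == len(sn)):
        raise ValueError("component lists must have equal length")
    csu2 = sx**2 + sn**2
    ok = csu2 > 0
    if not np.all(ok):
        logger.warning("%d components with zero combined s.u. excluded",
                       int(np.sum(~ok)))
    if not np.any(ok):
        raise ValueError("no components with positive combined s.u.")
    return float(np.sqrt(np.mean((vx[ok] - vn[ok]) ** 2 / csu2[ok])))


@dataclass
class AdpComparison:
    """Summary of an X-vs-N ADP comparison for one atom class."""

    atom_class: str
    n_atoms: int
    ratio_mean: float
    ratio_sd: float
    diag_diff_mean: float
    diag_diff_sd: float
    offdiag_diff_mean: float
    offdiag_diff_sd: float
    wrmsd: float
    per_atom: dict = field(default_factory=dict)


def _matched_aniso_sites(model_x, model_n, atom_class):
    pairs = []
    labels_n = {s.label: s for s in model_n.sites}
    orphans = []
    for sx in model_x.sites:
        is_h = sx.element == "H"
        if atom_class == "H" and not is_h:
            continue
        if atom_class == "non-H" and is_h:
            continue
        sn = labels_n.get(sx.label)
        if sn is None:
            orphans.append(sx.label)
            continue
        if sx.u_aniso is None or sn.u_aniso is None:
            raise ValueError(f"site {sx.label} is not anisotropic in both models")
        pairs.append((sx, sn))
    if orphans:
        raise ValueError(f"unmatched atom labels: {', '.join(orphans)}")
    return pairs


def adp_ratio_stats(model_x, model_n, atom_class: str = "non-H",
                    pooled: bool = True, basis: str = "cif") -> AdpComparison:
    """⟨U^ii_X/U^ii_N⟩, ⟨|ΔU^ii|⟩, ⟨|ΔU^ij|⟩ (i≠j) and wRMSD for one class.

    ``pooled=True`` averages over all components of all atoms; ``False``
    averages per atom first.  ``basis='cif'`` compares the deposited U^ij
    six-vectors; ``'cartesian'`` transforms both models first.
    """
    pairs = _matched_aniso_sites(model_x, model_n, atom_class)
    if not pairs:
        raise ValueError(f"no matched anisotropic atoms in class {atom_class}")

    def six(s, model):
        if basis == "cartesian":
            U = u_cif_to_cart(s.u_aniso, model.cell)
            return np.array([U[0, 0], U[1, 1], U[2, 2], U[0, 1], U[0, 2], U[1, 2]])
        return np.asarray(s.u_aniso, float)

    ratios, ddiffs, odiffs = [], [], []
    vx_all, vn_all, sx_all, sn_all = [], [], [], []
    per_atom = {}
    for sx, sn in pairs:
        ux, un = six(sx, model_x), six(sn, model_n)
        r = ux[:3] / un[:3]
        dd = np.abs(ux[:3] - un[:3])
        od = np.abs(ux[3:] - un[3:])
        per_atom[sx.label] = {"ratio": r.mean(), "diag_diff": dd.mean()}
        if pooled:
            ratios.extend(r)
            ddiffs.extend(dd)
            odiffs.extend(od)
        else:
            ratios.append(r.mean())
            ddiffs.append(dd.mean())
            odiffs.append(od.mean())
        sux = sx.su_u_aniso if sx.su_u_aniso is not None else np.zeros(6)
        sun = sn.su_u_aniso if sn.su_u_aniso is not None else np.zeros(6)
        vx_all.extend(ux)
        vn_all.extend(un)
        sx_all.extend(sux)
        sn_all.extend(sun)

    ratios = np.array(ratios)
    ddiffs = np.array(ddiffs)
    odiffs = np.array(odiffs)
    csu2 = np.array(sx_all) ** 2 + np.array(sn_all) ** 2
    w = wrmsd(vx_all, vn_all, sx_all, sn_all) if np.any(csu2 > 0) else 0.0
    sd = lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
    return AdpComparison(
        atom_class=atom_class,
        n_atoms=len(pairs),
        ratio_mean=float(ratios.mean()), ratio_sd=sd(ratios),
        diag_diff_mean=float(ddiffs.mean()), diag_diff_sd=sd(ddiffs),
        offdiag_diff_mean=float(odiffs.mean()), offdiag_diff_sd=sd(odiffs),
        wrmsd=float(w),
        per_atom=per_atom,
    )


# ---------------------------------------------------------------------------
# Rigid-bond test (DMSDA)
# ---------------------------------------------------------------------------

@dataclass
class RigidBondReport:
    """Mean-squared-displacement differences along bonds, by bond class."""

    bonds: list  # (label_a, label_b, class, delta_z2)
    class_stats: dict  # class -> (mean |Δ|, sd, n)


def detect_bonds(structure, include_h: bool = True):
    """Intramolecular bonds among symmetry-expanded ASU copies, as label pairs.

    Uses the covalent-radius criterion; each bond is reported once with the
    Cartesian bond vector of a representative contact.
    """
    cell = structure.cell
    bonds = {}
    images = []
    for i, s in enumerate(structure.sites):
        for x, op in structure.expand_site(s):
            for sh in ((0, 0, 0), *[(a, b, c) for a in (-1, 0, 1)
                                    for b in (-1, 0, 1) for c in (-1, 0, 1)
                                    if (a, b, c) != (0, 0, 0)]):
                images.append((i, cell.frac_to_cart(x + np.array(sh, float)), op))
    for ii in range(len(images)):
        i, pi, opi = images[ii]
        for jj in range(ii + 1, len(images)):
            j, pj, opj = images[jj]
            if not include_h and (structure.sites[i].element == "H"
                                  or structure.sites[j].element == "H"):
                continue
            d = np.linalg.norm(pi - pj)
            ri = covalent_radius(structure.sites[i].element)
            rj = covalent_radius(structure.sites[j].element)
            if 0.3 < d < BOND_FACTOR * (ri + rj):
                key = tuple(sorted((structure.sites[i].label,
                                    structure.sites[j].label)))
                if key not in bonds:
                    bonds[key] = (i, j, pj - pi, opi, opj)
    return bonds


def dmsda(structure, bond_list=None) -> RigidBondReport:
    """Hirshfeld rigid-bond test: Δ_AB = z²_A − z²_B along each bond.

    z²_A = ûᵀ U_A^cart û with û the unit bond vector (U rotated with the
    generating symmetry operation of the bonded copy).  Rigid bonds between
    non-H atoms should give |Δ| below ~0.001 Å².
    """
    if bond_list is None:
        bond_list = detect_bonds(structure)
    rows = []
    skipped = []
    for key, (i, j, vec, opi, opj) in bond_list.items():
        si, sj = structure.sites[i], structure.sites[j]
        if si.u_aniso is None or sj.u_aniso is None:
            skipped.append(key)
            continue
        u = vec / np.linalg.norm(vec)
        li = opi.cartesian_rotation(structure.cell)
        lj = opj.cartesian_rotation(structure.cell)
        Ui = li @ si.u_cart(structure.cell) @ li.T
        Uj = lj @ sj.u_cart(structure.cell) @ lj.T
        z2i = float(u @ Ui @ u)
        z2j = float(u @ Uj @ u)
        cls = "X-H" if "H" in (si.element, sj.element) else "X-X"
        rows.append((si.label, sj.label, cls, z2i - z2j))
    if skipped:
        logger.warning("rigid-bond test skipped isotropic-only bonds: %s",
                       ", ".join("-".join(k) for k in skipped))
    stats = {}
    for cls in ("X-X", "X-H"):
        vals = np.array([abs(r[3]) for r in rows if r[2] == cls])
        if len(vals):
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            stats[cls] = (float(vals.mean()), sd, len(vals))
    return RigidBondReport(rows, stats)


# ---------------------------------------------------------------------------
# Bond-length comparison
# ---------------------------------------------------------------------------

def bond_comparison(model_x, model_n, bond_class: str = "X-H"):
    """Bond-length statistics per class between two refinements.

    Returns a dict per element-pair class (e.g. 'C-H', 'O-H'): mean X-ray
    length ± sd, ⟨r_X/r_N⟩ ± sd, ⟨|Δr|⟩ ± sd and the error-weighted wRMSD.
    Bonds are matched by atom labels; classes with no bonds are omitted.
    """
    bonds_x = detect_bonds(model_x)
    bonds_n = detect_bonds(model_n)
    common = sorted(set(bonds_x) & set(bonds_n))
    cls_data = {}
    for key in common:
        i, j, vec_x, *_ = bonds_x[key]
        si, sj = model_x.sites[i], model_x.sites[j]
        if bond_class == "X-H" and "H" not in (si.element, sj.element):
            continue
        if bond_class == "X-X" and "H" in (si.element, sj.element):
            continue
        els = sorted([si.element, sj.element], key=lambda e: (e == "H", e))
        cname = f"{els[0]}-{els[1]}"
        in_, jn, vec_n, *_ = bonds_n[key]
        rx = float(np.linalg.norm(vec_x))
        rn = float(np.linalg.norm(vec_n))
        # bond-length s.u. from positional s.u.s projected on the bond
        def bond_su(model, a, b, vec):
            u = vec / np.linalg.norm(vec)
            tot = 0.0
            for s in (model.sites[a], model.sites[b]):
                sig_cart = model.cell.M @ s.su_xyz
                tot += float(np.sum((u * sig_cart) ** 2))
            return np.sqrt(tot)

        sx = bond_su(model_x, i, j, vec_x)
        sn = bond_su(model_n, in_, jn, vec_n)
        cls_data.setdefault(cname, []).append((rx, rn, sx, sn))

    out = {}
    for cname, rowsc in cls_data.items():
        rx = np.array([r[0] for r in rowsc])
        rn = np.array([r[1] for r in rowsc])
        sx = np.array([r[2] for r in rowsc])
        sn = np.array([r[3] for r in rowsc])
        sd = lambda a: float(np.std(a, ddof=1)) if len(a) > 1 else 0.0
        entry = {
            "n": len(rowsc),
            "r_mean": float(rx.mean()), "r_sd": sd(rx),
            "ratio_mean": float(np.mean(rx / rn)), "ratio_sd": sd(rx / rn),
            "absdiff_mean": float(np.mean(np.abs(rx - rn))),
            "absdiff_sd": sd(np.abs(rx - rn)),
        }
        if np.any(sx**2 + sn**2 > 0):
            entry["wrmsd"] = wrmsd(rx, rn, sx, sn)
        out[cname] = entry
    return out
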