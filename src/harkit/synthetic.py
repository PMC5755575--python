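"""Self-contained synthetic crystals with closed-form structure factors.

A Gaussian-atom crystal is a model whose every atomic density is a sum of
isotropic Gaussian shells, optionally displaced from the nucleus to mimic
bonding asphericity.  Every quantity the engine computes numerically —
promolecule densities, Hirshfeld form factors, Debye–Waller-smeared
structure factors — then has a closed form:

    ρ_shell(r) = a (p/π)^{3/2} exp(−p |r − c|²)
    f_shell(h) = a exp(−π² |h*|² / p) exp(2πi h*·(c − R_nucleus))

which makes these models exact oracles for the Fourier machinery, and
simulated reflection data from them the recovery surface for the refinement
engine.  Default shells per element reproduce the free-atom reference
density, so the spherical limit of a toy atom is exactly its IAM atom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .atomdens import free_atom_density
from .crystal_io import (AtomSite, CrystalStructure, ReflectionSet, SymOp,
                         UnitCell, u_cif_to_cart)

__all__ = [
    "GaussianShell",
    "GaussianAtomModel",
    "GaussianDensityProvider",
    "ToySpec",
    "gaussian_density_provider",
    "simulate_reflections",
    "make_toy_crystal",
    "perturb_model",
    "unique_hkl",
    "closed_form_structure_factors",
    "TOY_PRESETS",
]

TOY_PRESETS = ("one_atom_P1", "diatomic_P1", "polar_XH_P1", "ionic_P1",
               "mirror_site_Pm")


@dataclass
class GaussianShell:
    """One isotropic Gaussian density shell: a·(p/π)^{3/2}·exp(−p|r−c|²)."""

    amplitude: float  # electrons
    exponent: float   # p in Å⁻²
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))  # Å, from nucleus

    def __post_init__(self):
        if self.exponent <= 0:
            raise ValueError("shell exponent must be positive")
        self.offset = np.asarray(self.offset, float)


@dataclass
class GaussianAtomModel:
    """Gaussian shells per asymmetric-unit site label."""

    shells: dict  # label -> list[GaussianShell]

    def electron_count(self, label: str) -> float:
        return sum(s.amplitude for s in self.shells[label])

    def total_electrons(self, structure) -> float:
        return sum(self.electron_count(s.label) for s in structure.sites)

    @classmethod
    def spherical_from_elements(cls, structure, n_electrons=None) -> "GaussianAtomModel":
        """Default shells: the free-atom Gaussian expansion of each element.

        ``n_electrons`` optionally overrides the electron count per label
        (e.g. 18 for a K⁺-like ion), rescaling the neutral shape.
        """
        shells = {}
        for site in structure.sites:
            rd = free_atom_density(site.element)
            scale = 1.0
            if n_electrons and site.label in n_electrons:
                scale = n_electrons[site.label] / rd.n_electrons
            shells[site.label] = [
                GaussianShell(amp * scale, p) for amp, p in rd.gaussians
            ]
        return cls(shells)


class GaussianDensityProvider:
    """DensityProvider evaluating a GaussianAtomModel analytically.

    Shell offsets are attached to the nuclei: a symmetry copy of an atom
    carries its offsets rotated by the generating operation, so the density
    follows the model geometry through refinement.  Also exposes the
    closed-form nuclear-referenced form factor for oracle use.
    """

    def __init__(self, model: GaussianAtomModel, structure: CrystalStructure,
                 analytic_form_factors: bool = True):
        self.model = model
        self.structure = structure
        self.analytic_form_factors = analytic_form_factors

    @property
    def cell(self) -> UnitCell:
        return self.structure.cell

    def density(self, fragment, points, environment=None) -> np.ndarray:
        points = np.asarray(points, float)
        out = np.zeros(len(points))
        for a in fragment.atoms:
            label = self.structure.sites[a.parent].label
            lam = a.symop.cartesian_rotation(self.cell)
            for sh in self.model.shells[label]:
                c = a.pos + lam @ sh.offset
                r2 = np.sum((points - c) ** 2, axis=1)
                out += sh.amplitude * (sh.exponent / np.pi) ** 1.5 * np.exp(
                    -np.minimum(sh.exponent * r2, 700.0)
                )
        return out

    def form_factor(self, label: str, k_cart) -> np.ndarray:
        """Closed-form f_A(h) referenced to the nucleus (identity orientation)."""
        k = np.atleast_2d(np.asarray(k_cart, float))
        k2 = np.sum(k**2, axis=1)
        out = np.zeros(len(k), complex)
        for sh in self.model.shells[label]:
            out += sh.amplitude * np.exp(-np.pi**2 * k2 / sh.exponent) * np.exp(
                2j * np.pi * (k @ sh.offset)
            )
        return out

    def form_factor_for_site(self, site, k_cart) -> np.ndarray:
        return self.form_factor(site.label, k_cart)


def gaussian_density_provider(model: GaussianAtomModel,
                              structure: CrystalStructure) -> GaussianDensityProvider:
    """Build the analytic density provider for a Gaussian-atom model."""
    return GaussianDensityProvider(model, structure)


# ---------------------------------------------------------------------------
# Closed-form structure factors (independent oracle)
# ---------------------------------------------------------------------------

def closed_form_structure_factors(structure, model: GaussianAtomModel, hkl) -> np.ndarray:
    """Fully analytic F(h): direct Cartesian sum over symmetry copies & shells.

    Independent of the engine's form-factor/lookup machinery: each symmetry
    copy is placed explicitly, its shell offsets and U tensor rotated in the
    Cartesian frame, and every Gaussian shell contributes its analytic
    Fourier transform times its Debye–Waller factor.
    """
    hkl = np.atleast_2d(np.asarray(hkl, int))
    cell = structure.cell
    K = cell.k_vectors(hkl)
    k2 = np.sum(K**2, axis=1)
    F = np.zeros(len(hkl), complex)
    for site in structure.sites:
        nstab = structure.site_stabilizer_order(site)
        occw = site.occupancy / nstab
        Ucart = site.u_cart(cell)
        for op in structure.symops:
            lam = op.cartesian_rotation(cell)
            xf = op.apply(site.xyz)
            nucleus = cell.frac_to_cart(xf)
            Urot = lam @ Ucart @ lam.T
            T = np.exp(-2 * np.pi**2 * np.einsum("hi,ij,hj->h", K, Urot, K))
            for sh in model.shells[site.label]:
                c = nucleus + lam @ sh.offset
                F += (
                    occw * sh.amplitude
                    * np.exp(-np.pi**2 * k2 / sh.exponent)
                    * T
                    * np.exp(2j * np.pi * (K @ c))
                )
    return F


# ---------------------------------------------------------------------------
# Reflection simulation
# ---------------------------------------------------------------------------

def unique_hkl(structure, resolution: float) -> np.ndarray:
    """Symmetry-unique Miller indices with sinθ/λ ≤ resolution (Å⁻¹)."""
    cell = structure.cell
    hmax = np.ceil(2 * resolution / cell.reciprocal_lengths).astype(int)
    rng = [np.arange(-m, m + 1) for m in hmax]
    H = np.array(np.meshgrid(*rng, indexing="ij")).reshape(3, -1).T
    H = H[np.any(H != 0, axis=1)]
    s = cell.stol(H)
    H = H[s <= resolution + 1e-12]
    rots = [np.array(op.R, int) for op in structure.symops]
    seen = set()
    out = []
    for h in H:
        orbit = []
        for R in rots:
            hr = tuple(R.T @ h)
            orbit.append(hr)
            orbit.append(tuple(-np.array(hr)))
        canon = max(orbit)
        if canon not in seen:
            seen.add(canon)
            out.append(canon)
    out = np.array(sorted(out), int)
    return out


SIGMA_FLOOR_FRAC = 1e-4  # relative σ floor when simulating noise-free data


def simulate_reflections(structure, provider, resolution: float,
                         noise_fraction: float = 0.0, seed: int = 0) -> ReflectionSet:
    """Simulate |F_obs| from the closed-form structure factors.

    |F_obs| = |F_true| (1 + ε), ε ~ N(0, noise_fraction²), σ = max(noise,
    1e-4)·|F_true|.  Seed-reproducible; noise_fraction = 0 gives exact data.
    """
    model = provider.model if hasattr(provider, "model") else provider
    hkl = unique_hkl(structure, resolution)
    F = closed_form_structure_factors(structure, model, hkl)
    Fmag = np.abs(F)
    keep = Fmag > 1e-8 * Fmag.max()
    hkl, Fmag = hkl[keep], Fmag[keep]
    n_param = sum(3 + (6 if s.u_aniso is not None else 1) for s in structure.sites) + 1
    if len(hkl) < 5 * n_param:
        import logging

        logging.getLogger("harkit").warning(
            "only %d reflections for %d parameters (< 5 per parameter)",
            len(hkl), n_param,
        )
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_fraction, len(hkl)) if noise_fraction > 0 else 0.0
    value = Fmag * (1.0 + eps)
    # σ = noise_fraction·|F| with an absolute floor tied to the data's rms |F|
    # so near-extinct reflections do not acquire unbounded weights
    floor = SIGMA_FLOOR_FRAC * float(np.sqrt(np.mean(Fmag**2)))
    sigma = np.maximum(noise_fraction * Fmag, floor)
    return ReflectionSet(hkl, value, sigma)


# ---------------------------------------------------------------------------
# Toy presets
# ---------------------------------------------------------------------------

@dataclass
class ToySpec:
    """Named synthetic study condition."""

    preset: str = "diatomic_P1"
    noise_fraction: float = 0.0
    resolution: float = 1.0  # sinθ/λ limit, Å⁻¹
    seed: int = 0

    def __post_init__(self):
        if self.preset not in TOY_PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {TOY_PRESETS}")
        if self.resolution > 1.5:
            raise ValueError("resolution limited to 1.5 Å⁻¹")


P1_OPS = [SymOp.identity()]
PBAR1_OPS = [SymOp.identity(),
             SymOp(((-1, 0, 0), (0, -1, 0), (0, 0, -1)), (0.0, 0.0, 0.0))]
PM_OPS = [SymOp.identity(),
          SymOp(((1, 0, 0), (0, -1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))]

# Displacement of the hydrogen density centroid towards the bonded atom in
# the polar X—H preset: emulates the bond density that makes spherical-atom
# refinements foreshorten X—H bonds by about 0.1 Å.
XH_CENTROID_SHIFT = 0.10  # Å


def _aniso(cell, u11, u22, u33, u12=0.0, u13=0.0, u23=0.0):
    return np.array([u11, u22, u33, u12, u13, u23])


def make_toy_crystal(spec: ToySpec):
    """Build (CrystalStructure, GaussianAtomModel) for a named preset."""
    p = spec.preset
    if p == "one_atom_P1":
        cell = UnitCell(6.0, 6.0, 6.0)
        sites = [AtomSite("C1", "C", [0.10, 0.20, 0.30], u_iso=0.01)]
        st = CrystalStructure(cell, P1_OPS, sites, "P 1", Z=1)
        model = GaussianAtomModel.spherical_from_elements(st)
    elif p == "diatomic_P1":
        cell = UnitCell(7.0, 7.5, 8.0, 90.0, 95.0, 90.0)
        xc = np.array([0.16, 0.12, 0.10])
        # C=O bond of 1.22 Å along a skew direction
        bond = np.array([0.9, 0.5, 0.35])
        bond = 1.22 * bond / np.linalg.norm(bond)
        xo = cell.cart_to_frac(cell.frac_to_cart(xc) + bond)
        sites = [
            AtomSite("C1", "C", xc, u_aniso=_aniso(cell, 0.010, 0.013, 0.011,
                                                   0.001, -0.001, 0.002)),
            AtomSite("O1", "O", xo, u_aniso=_aniso(cell, 0.014, 0.011, 0.016,
                                                   -0.002, 0.001, 0.001)),
        ]
        st = CrystalStructure(cell, PBAR1_OPS, sites, "P -1", Z=2)
        model = GaussianAtomModel.spherical_from_elements(st)
    elif p == "polar_XH_P1":
        cell = UnitCell(7.0, 7.0, 7.5, 90.0, 92.0, 90.0)
        xo = np.array([0.18, 0.15, 0.12])
        bond = np.array([0.7, 0.55, 0.45])
        bond = 0.97 * bond / np.linalg.norm(bond)  # O—H ≈ 0.97 Å (truth)
        xh = cell.cart_to_frac(cell.frac_to_cart(xo) + bond)
        sites = [
            AtomSite("O1", "O", xo, u_aniso=_aniso(cell, 0.012, 0.010, 0.014,
                                                   0.001, 0.002, -0.001)),
            AtomSite("H1", "H", xh, u_aniso=_aniso(cell, 0.025, 0.030, 0.028,
                                                   0.002, -0.002, 0.001)),
        ]
        st = CrystalStructure(cell, PBAR1_OPS, sites, "P -1", Z=2)
        model = GaussianAtomModel.spherical_from_elements(st)
        # shift the whole H density centroid towards O: bond density surrogate
        shift = -XH_CENTROID_SHIFT * bond / np.linalg.norm(bond)
        for sh in model.shells["H1"]:
            sh.offset = shift.copy()
    elif p == "ionic_P1":
        cell = UnitCell(6.0, 6.5, 6.2)
        sites = [
            AtomSite("K1", "K", [0.0, 0.0, 0.0], u_iso=0.008),
            AtomSite("F1", "F", [0.5, 0.5, 0.5], u_iso=0.010),
        ]
        st = CrystalStructure(cell, P1_OPS, sites, "P 1", Z=1)
        model = GaussianAtomModel.spherical_from_elements(
            st, n_electrons={"K1": 18.0, "F1": 10.0}
        )
    elif p == "mirror_site_Pm":
        cell = UnitCell(6.5, 6.0, 7.0, 90.0, 90.0, 90.0)
        # water-like molecule across the mirror at y = 0 (Z' = 1/2):
        # O on the mirror, one H in the asymmetric unit
        xo = np.array([0.30, 0.0, 0.40])
        oh = np.array([0.60, 0.757, 0.25])
        oh = 0.96 * oh / np.linalg.norm(oh)
        xh = cell.cart_to_frac(cell.frac_to_cart(xo) + oh)
        sites = [
            # mirror site symmetry: U12 = U23 = 0 for the on-mirror atom
            AtomSite("O1", "O", xo, u_aniso=_aniso(cell, 0.011, 0.013, 0.012,
                                                   0.0, 0.001, 0.0)),
            AtomSite("H1", "H", xh, u_aniso=_aniso(cell, 0.024, 0.027, 0.025,
                                                   0.001, 0.002, -0.001)),
        ]
        st = CrystalStructure(cell, PM_OPS, sites, "P m", Z=1)
        model = GaussianAtomModel.spherical_from_elements(st)
    else:  # pragma: no cover
        raise ValueError(p)
    for s in st.sites:
        s.site_multiplicity = len(st.expand_site(s))
    return st, model


# ---------------------------------------------------------------------------
# Model perturbation
# ---------------------------------------------------------------------------

def perturb_model(structure, magnitude_xyz: float, magnitude_u: float,
                  seed: int = 0) -> CrystalStructure:
    """Random starting model: uniform coordinate and diagonal-U displacement.

    Each Cartesian coordinate moves uniformly within ±magnitude_xyz (Å) and
    each diagonal U component within ±magnitude_u (Å²); shifts on special
    positions are projected onto the site-symmetry-invariant subspace.
    """
    if magnitude_xyz < 0 or magnitude_u < 0:
        raise ValueError("perturbation magnitudes must be non-negative")
    rng = np.random.default_rng(seed)
    out = structure.copy()
    cell = out.cell
    for s in out.sites:
        stab = structure.stabilizer(s)
        dx_cart = rng.uniform(-magnitude_xyz, magnitude_xyz, 3)
        dx = cell.cart_to_frac(dx_cart)
        if len(stab) > 1:
            P = np.mean([op.rot for op in stab], axis=0)
            dx = P @ dx
        s.xyz = (s.xyz + dx)
        du = rng.uniform(-magnitude_u, magnitude_u, 3)
        if s.u_aniso is not None:
            d6 = np.concatenate([du, np.zeros(3)])
            if len(stab) > 1:
                from .refine import _u6_transform_matrix

                astar = cell.reciprocal_lengths
                D, Dinv = np.diag(astar), np.diag(1.0 / astar)
                PU = np.mean([_u6_transform_matrix(Dinv @ op.rot @ D)
                              for op in stab], axis=0)
                d6 = PU @ d6
            s.u_aniso = s.u_aniso + d6
        else:
            s.u_iso = max(s.u_iso + du[0], 1e-4)
    return out


# ---------------------------------------------------------------------------
# Fixture export
# ---------------------------------------------------------------------------

def write_fixtures(directory, spec: ToySpec):
    """Write a CIF + SHELX hkl fixture pair with provenance comments."""
    import os

    from .crystal_io import write_cif_result

    st, model = make_toy_crystal(spec)
    provider = GaussianDensityProvider(model, st)
    refl = simulate_reflections(st, provider, spec.resolution,
                                spec.noise_fraction, spec.seed)
    os.makedirs(directory, exist_ok=True)
    header = (f"# synthetic fixture preset={spec.preset} "
              f"noise={spec.noise_fraction} resolution={spec.resolution} "
              f"seed={spec.seed}\n")
    cif_path = os.path.join(directory, f"{spec.preset}.cif")
    with open(cif_path, "w") as fh:
        fh.write(header + write_cif_result(st))
    hkl_path = os.path.join(directory, f"{spec.preset}.hkl")
    with open(hkl_path, "w") as fh:
        for h, v, s in zip(refl.hkl, refl.value, refl.sigma):
            fh.write(f"{h[0]:4d}{h[1]:4d}{h[2]:4d}{v:8.2f}{s:8.2f}\n")
        fh.write(f"{0:4d}{0:4d}{0:4d}{0.0:8.2f}{0.0:8.2f}\n")
    return cif_path, hkl_path
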