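"""Atomic scattering factors: Hirshfeld (aspherical) and IAM (spherical).

A Hirshfeld atom scattering factor is the Fourier transform of the
stockholder-partitioned atomic density, referenced to the nucleus so that
positional parameters carry the lattice phases:

    f_A(h) = ∫ w_A(r) ρ(r) exp(2πi h*·(r − R_A)) dV,

evaluated by quadrature on the shared molecular grid.  At h → 0 it tends to
the (real, positive) Hirshfeld electron population of the atom.

Because Hirshfeld atoms are aspherical, symmetry copies scatter with the
rotated index: the copy generated by (R, t) contributes f_A(Rᵀh).  Form
factors are therefore evaluated once on the closure of the unique reflection
list under {Rᵀ} and looked up analytically afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .atomdens import free_atom_density, molecular_grid
from .partition import hirshfeld_weights_all

logger = logging.getLogger("harkit")

__all__ = [
    "FormFactorSet",
    "DispersionTerms",
    "hirshfeld_form_factor",
    "iam_form_factor",
    "symmetry_form_factor",
    "apply_dispersion",
    "expand_hkl_closure",
    "compute_form_factor_set",
]

_CHUNK = 256  # reflections per exponential block (memory control)


@dataclass
class DispersionTerms:
    """Anomalous-dispersion corrections f′, f″ (electrons) per element."""

    terms: dict  # element -> (f_prime, f_double_prime)

    def get(self, element):
        return self.terms.get(element)


@dataclass
class FormFactorSet:
    """Complex scattering factor per (asymmetric-unit atom, reflection).

    ``values[i, j]`` is f for atom ``labels[i]`` at ``hkl[j]``; ``hkl`` is the
    symmetry-closed index set.  ``elements`` maps rows to element symbols for
    dispersion handling.
    """

    labels: list
    elements: list
    hkl: np.ndarray
    values: np.ndarray
    grid_level: str = ""
    provenance: str = ""
    dispersion_applied: bool = False
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, int).reshape(-1, 3)
        if not self._index:
            self._index = {tuple(h): j for j, h in enumerate(self.hkl)}

    def lookup(self, atom_index: int, hkl) -> complex:
        key = tuple(int(v) for v in hkl)
        j = self._index.get(key)
        if j is not None:
            return self.values[atom_index, j]
        if not self.dispersion_applied:
            jneg = self._index.get(tuple(-v for v in key))
            if jneg is not None:  # Friedel relation
                return np.conj(self.values[atom_index, jneg])
        raise KeyError(
            f"form factor for {key} not available; compute form factors on the "
            "symmetry-expanded index set"
        )

    def rows_for(self, hkl_array) -> np.ndarray:
        """Column indices for an (N,3) index array (must all be present)."""
        out = np.empty(len(hkl_array), int)
        for i, h in enumerate(np.asarray(hkl_array, int)):
            j = self._index.get(tuple(h))
            if j is None:
                raise KeyError(
                    f"form factor for {tuple(h)} missing from the expanded set"
                )
            out[i] = j
        return out

    def to_table(self) -> str:
        lines = ["atom       h   k   l        Re_f        Im_f"]
        for i, lab in enumerate(self.labels):
            for j, h in enumerate(self.hkl):
                v = self.values[i, j]
                lines.append(
                    f"{lab:<8s} {h[0]:3d} {h[1]:3d} {h[2]:3d}  {v.real:10.5f}  {v.imag:10.5f}"
                )
        return "\n".join(lines)


def expand_hkl_closure(hkl_unique, symops) -> np.ndarray:
    """Closure of an index list under {R_sᵀ} and Friedel negation."""
    seen = {}
    out = []
    hkl_unique = np.asarray(hkl_unique, int)
    rots = [np.array(op.R, int) for op in symops]
    for h in hkl_unique:
        for R in rots:
            for hh in (R.T @ h, -(R.T @ h)):
                key = tuple(int(v) for v in hh)
                if key not in seen:
                    seen[key] = len(out)
                    out.append(key)
    return np.array(out, int)


def hirshfeld_form_factor(atom_index, k_vectors, rho, grid, fragment,
                          weights=None) -> np.ndarray:
    """Quadrature Fourier transform of one Hirshfeld atom.

    ``k_vectors``: (N,3) Cartesian reciprocal vectors (|k| = 1/d, Å⁻¹);
    ``rho``: molecular density on ``grid.points``.
    """
    if weights is None:
        weights = hirshfeld_weights_all(grid.points, fragment)
    wrho = grid.weights * weights[atom_index] * np.asarray(rho, float)
    center = np.asarray(fragment.positions, float)[atom_index]
    rel = grid.points - center
    k_vectors = np.atleast_2d(np.asarray(k_vectors, float))
    out = np.empty(len(k_vectors), complex)
    for start in range(0, len(k_vectors), _CHUNK):
        kk = k_vectors[start:start + _CHUNK]
        phase = np.exp(2j * np.pi * (rel @ kk.T))
        out[start:start + _CHUNK] = wrho @ phase
    return out


def iam_form_factor(element, s) -> np.ndarray:
    """Spherical free-atom form factor at s = sinθ/λ by radial Hankel transform.

        f(s) = 4π ∫ ρ⁰(r) r² sin(4πsr)/(4πsr) dr
    """
    rd = free_atom_density(element)
    s = np.asarray(s, float)
    scalar = s.ndim == 0
    s = np.atleast_1d(s)
    # log-dense radial quadrature (resolves the tight core term)
    n = 400
    x, w = np.polynomial.legendre.leggauss(n)
    # map [-1,1] -> r in [1e-5, 12] logarithmically
    la, lb = np.log(1e-5), np.log(12.0)
    lr = 0.5 * (x + 1) * (lb - la) + la
    r = np.exp(lr)
    wr = w * 0.5 * (lb - la) * r  # dr = r d(ln r)
    rho = rd.analytic(r)
    q = 4 * np.pi * s[:, None] * r[None, :]
    kern = np.where(q > 1e-12, np.sin(q) / np.where(q > 1e-12, q, 1.0), 1.0)
    f = 4 * np.pi * (kern * (rho * r**2 * wr)[None, :]).sum(axis=1)
    return f[0] if scalar else f


def symmetry_form_factor(f_set: FormFactorSet, atom_index: int, symop, hkl) -> complex:
    """Form factor of the symmetry copy generated by ``symop``: f_A(R_sᵀ h)."""
    R = np.array(symop.R, int)
    hrot = R.T @ np.asarray(hkl, int)
    return f_set.lookup(atom_index, hrot)


def apply_dispersion(f_set: FormFactorSet, terms: DispersionTerms | None) -> FormFactorSet:
    """Add f′ + i·f″ per element, once (guarded by the applied flag)."""
    if terms is None:
        return f_set
    if f_set.dispersion_applied:
        raise ValueError("dispersion terms already applied to this FormFactorSet")
    values = f_set.values.copy()
    for i, el in enumerate(f_set.elements):
        t = terms.get(el)
        if t is not None:
            fp, fpp = t
            values[i] += fp + 1j * fpp
    return FormFactorSet(
        f_set.labels, f_set.elements, f_set.hkl, values,
        f_set.grid_level, f_set.provenance, dispersion_applied=True,
    )


def compute_form_factor_set(
    structure,
    fragment,
    hkl_unique,
    provider=None,
    mode: str = "hirshfeld",
    grid_level: str = "standard",
    environment=None,
    dispersion: DispersionTerms | None = None,
    force_quadrature: bool = False,
) -> FormFactorSet:
    """Form factors for every asymmetric-unit atom on the symmetry-closed set.

    ``mode='hirshfeld'``: stockholder partition of the provider density on a
    molecular Becke grid; a provider that exposes closed-form factors
    (``analytic_form_factors`` + ``form_factor_for_site``) is used directly
    unless ``force_quadrature``.  ``mode='iam'``: spherical free-atom factors
    (grid free).  Only ASU atoms receive form factors; the rest of the
    fragment contributes density through the partition weights.
    """
    hkl = expand_hkl_closure(hkl_unique, structure.symops)
    kvec = structure.cell.k_vectors(hkl)
    labels = [s.label for s in structure.sites]
    elements = [s.element for s in structure.sites]

    if mode == "iam":
        svals = 0.5 * np.linalg.norm(kvec, axis=1)
        values = np.empty((len(labels), len(hkl)), complex)
        cache = {}
        for i, el in enumerate(elements):
            if el not in cache:
                cache[el] = iam_form_factor(el, svals)
            values[i] = cache[el]
        fs = FormFactorSet(labels, elements, hkl, values, "analytic", "iam")
        return apply_dispersion(fs, dispersion) if dispersion else fs

    if mode != "hirshfeld":
        raise ValueError("mode must be 'hirshfeld' or 'iam'")
    if provider is None:
        raise ValueError("hirshfeld mode needs a DensityProvider")

    if (getattr(provider, "analytic_form_factors", False)
            and hasattr(provider, "form_factor_for_site")
            and not force_quadrature):
        values = np.empty((len(labels), len(hkl)), complex)
        for i, site in enumerate(structure.sites):
            values[i] = provider.form_factor_for_site(site, kvec)
        fs = FormFactorSet(labels, elements, hkl, values, "analytic",
                           "hirshfeld/analytic")
        return apply_dispersion(fs, dispersion) if dispersion else fs

    grid = molecular_grid(fragment, grid_level)
    rho = provider.density(fragment, grid.points, environment=environment)
    weights = hirshfeld_weights_all(grid.points, fragment)
    asu_idx = fragment.asu_atom_indices(structure)

    # Shared-phase evaluation: exp(2πi p·Bh) = Π_j A_j^{h_j} with
    # A_j = exp(2πi (Bᵀp)_j), so the plane-wave matrix is assembled from
    # per-axis integer-power tables and the atom sums become one matmul.
    cell = structure.cell
    ufrac = grid.points @ cell.B  # (n_pts, 3): (Bᵀ p)
    hmin = hkl.min(axis=0)
    hmax = hkl.max(axis=0)
    tables = []
    for j in range(3):
        m = np.arange(hmin[j], hmax[j] + 1)
        tables.append(np.exp(2j * np.pi * np.outer(ufrac[:, j], m)))
    wrho_rows = np.empty((len(asu_idx), len(grid.points)))
    for i, j in enumerate(asu_idx):
        if j is None:
            raise ValueError(f"site {labels[i]} has no fragment atom")
        wrho_rows[i] = grid.weights * weights[j] * rho
    # Friedel economy: evaluate one member of each ±h pair, conjugate the other
    index = {tuple(h): j for j, h in enumerate(map(tuple, hkl))}
    partner = np.full(len(hkl), -1)
    reps = []
    for j, h in enumerate(map(tuple, hkl)):
        nj = index.get(tuple(-v for v in h))
        if nj is not None and nj < j:
            partner[j] = nj
        else:
            reps.append(j)
    reps = np.array(reps, int)
    values = np.empty((len(labels), len(hkl)), complex)
    wrho_c = wrho_rows.astype(complex)
    for start in range(0, len(reps), _CHUNK):
        sel = reps[start:start + _CHUNK]
        hh = hkl[sel]
        phase = (
            tables[0][:, hh[:, 0] - hmin[0]]
            * tables[1][:, hh[:, 1] - hmin[1]]
            * tables[2][:, hh[:, 2] - hmin[2]]
        )
        values[:, sel] = wrho_c @ phase
    # reference each atom's factor to its nucleus, then fill Friedel mates
    pops = np.empty(len(labels))
    centers = np.asarray(fragment.positions, float)
    for i, j in enumerate(asu_idx):
        values[i, reps] *= np.exp(-2j * np.pi * (kvec[reps] @ centers[j]))
        pops[i] = np.dot(grid.weights * weights[j], rho)
    mates = np.where(partner >= 0)[0]
    if len(mates):
        values[:, mates] = np.conj(values[:, partner[mates]])

    # zero-frequency sanity check: Hirshfeld populations of the ASU share
    n_grid = grid.integrate(rho)
    n_frag = sum(
        __import__("gemmi").Element(el).atomic_number for el in fragment.elements
    ) - getattr(fragment, "net_charge", 0)
    if n_frag > 0 and abs(n_grid - n_frag) > 0.01 * n_frag:
        raise ValueError(
            f"grid density integrates to {n_grid:.3f} e, expected {n_frag} e "
            "(> 1% off); refine the grid"
        )
    fs = FormFactorSet(labels, elements, hkl, values, str(grid_level), "hirshfeld")
    fs.populations = pops
    return apply_dispersion(fs, dispersion) if dispersion else fs
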