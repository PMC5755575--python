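"""Stockholder (Hirshfeld) partitioning of a molecular electron density.

The stockholder weight of atom A at a point r is the share of the promolecule
density contributed by its free atom,

    w_A(r) = ρ⁰_A(|r − R_A|) / Σ_B ρ⁰_B(|r − R_B|),

so Σ_A w_A = 1 pointwise by construction and the resulting Hirshfeld atoms
are aspherical and overlapping.  Atomic charges and dipoles derived here feed
the point-charge/dipole crystal-field model.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np

from .atomdens import free_atom_density

__all__ = ["AtomicMultipoles", "hirshfeld_weight", "hirshfeld_weights_all",
           "atomic_multipoles", "multipole_table"]


@dataclass
class AtomicMultipoles:
    """Net charge (e) and electron dipole (e·Å, relative to the nucleus)."""

    atom: int
    q: float
    mu: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, float)


def _promolecule_components(points, fragment):
    points = np.asarray(points, float)
    centers = np.asarray(fragment.positions, float)
    comps = np.empty((len(centers), len(points)))
    for i, (el, c) in enumerate(zip(fragment.elements, centers)):
        rd = free_atom_density(el)
        comps[i] = rd(np.linalg.norm(points - c, axis=1))
    return comps


def hirshfeld_weight(points, atom_index: int, fragment) -> np.ndarray:
    """Stockholder weight of one fragment atom at the given Cartesian points."""
    comps = _promolecule_components(points, fragment)
    total = comps.sum(axis=0)
    return comps[atom_index] / total


def hirshfeld_weights_all(points, fragment) -> np.ndarray:
    """Weights for every fragment atom: shape (n_atoms, n_points), columns sum to 1.

    Where the promolecule underflows to zero (points beyond every atom's
    density support) the weight is assigned to the nearest atom; the density
    there is zero, so integrals are unaffected.
    """
    comps = _promolecule_components(points, fragment)
    total = comps.sum(axis=0)
    dead = total <= 0.0
    if np.any(dead):
        centers = np.asarray(fragment.positions, float)
        d = np.linalg.norm(
            np.asarray(points, float)[dead][:, None, :] - centers[None, :, :], axis=-1
        )
        nearest = np.argmin(d, axis=1)
        comps[:, dead] = 0.0
        comps[nearest, np.where(dead)[0]] = 1.0
        total = comps.sum(axis=0)
    return comps / total


def atomic_multipoles(fragment, density, grid, weights=None) -> list:
    """Hirshfeld charges and dipoles of every fragment atom.

    ``density`` is either a DensityProvider (with a ``density(fragment,
    points)`` method) or a plain array of density values on the grid points.

    q_A = Z_A − ∫ w_A ρ dV,  μ_A = −∫ w_A ρ (r − R_A) dV.
    """
    if hasattr(density, "density"):
        rho = density.density(fragment, grid.points)
    else:
        rho = np.asarray(density, float)
    n_e_expected = sum(
        gemmi.Element(el).atomic_number for el in fragment.elements
    ) + getattr(fragment, "net_charge", 0) * -1
    n_e_grid = grid.integrate(rho)
    if abs(n_e_grid - n_e_expected) > 0.01 * max(1.0, abs(n_e_expected)):
        raise ValueError(
            f"grid integral of the density ({n_e_grid:.4f} e) deviates from the "
            f"expected electron count ({n_e_expected} e); refine the grid"
        )
    if weights is None:
        weights = hirshfeld_weights_all(grid.points, fragment)
    out = []
    centers = np.asarray(fragment.positions, float)
    for ia, (el, c) in enumerate(zip(fragment.elements, centers)):
        wrho = weights[ia] * rho * grid.weights
        pop = wrho.sum()
        mu = -(wrho[:, None] * (grid.points - c)).sum(axis=0)
        q = gemmi.Element(el).atomic_number - pop
        out.append(AtomicMultipoles(ia, float(q), mu))
    return out


def multipole_table(fragment, multipoles) -> str:
    """Plain-text table of charges and dipoles for inspection."""
    lines = ["atom  element        q(e)      mu_x      mu_y      mu_z  (e.Å)"]
    for m in multipoles:
        el = fragment.elements[m.atom]
        lines.append(
            f"{m.atom:4d}  {el:>7s}  {m.q:10.5f}  {m.mu[0]:8.5f}  {m.mu[1]:8.5f}  {m.mu[2]:8.5f}"
        )
    tot_q = sum(m.q for m in multipoles)
    lines.append(f"total charge: {tot_q:.5f} e")
    return "\n".join(lines)
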