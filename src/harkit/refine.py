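"""Crystallographic least-squares refinement against |F| and the HAR loop.

The engine follows the two-step economy of Hirshfeld atom refinement: an
outer cycle computes the molecular electron density at the current geometry
and turns it into aspherical atomic form factors; an inner Gauss–Newton
least-squares refines positions, ADPs and one overall scale against the
structure-factor magnitudes with the form factors frozen; the two steps
alternate until the parameter shifts are negligible.

Weights are statistical, w = 1/σ²(F).  Constraints (special positions,
hydrogen-ADP modes, floating origins in polar space groups) are handled by
projecting the parameter space onto the constrained null space, so
constrained directions receive exactly zero shift.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .atomdens import molecular_grid
from .crystal_io import (CrystalStructure, MoleculeFragment, ReflectionSet,
                         SymOp, grow_fragment, u_cif_to_cart)
from .partition import atomic_multipoles, hirshfeld_weights_all
from .scatter import DispersionTerms, compute_form_factor_set

logger = logging.getLogger("harkit")

__all__ = [
    "RefinementOptions",
    "EnvironmentModel",
    "RefinementState",
    "RefinementResult",
    "debye_waller",
    "structure_factor_sum",
    "optimal_scale",
    "lsq_cycle",
    "refine_lsq",
    "har_iterate",
    "build_environment",
    "prune_reflections",
    "polar_axes",
]

BASIS_SETS = ("STO-3G", "def2-SVP", "cc-pVDZ", "def2-TZVP", "cc-pVTZ",
              "def2-TZVPP", "cc-pVQZ")

# Gauss–Newton guards: absolute shift caps protect the early cycles, and a
# step is halved (up to 5 times) whenever it would increase wR2, which keeps
# the inner iteration monotone.
MAX_XYZ_SHIFT = 0.10   # Å
MAX_U_SHIFT = 0.02     # Å²
U_CLAMP = 1e-5         # Å², eigenvalue clamp for non-positive-definite U


@dataclass
class RefinementOptions:
    """User-facing knobs of a refinement run."""

    method: str = "rhf"
    basis: str = "def2-SVP"
    mode: str = "har"  # "har" (aspherical) or "iam" (spherical factors)
    cluster_radius: float = 0.0
    environment_kind: str = "none"  # none | charges_dipoles | explicit_cluster
    h_adp_mode: str = "anisotropic"  # anisotropic | isotropic | fixed
    pruning: str = "F>3sig"
    dispersion: DispersionTerms | None = None
    grid_level: str = "standard"
    fragment_mode: str = "complete_molecules"
    force_quadrature: bool = False  # ignore providers' closed-form factors
    max_outer_cycles: int = 15
    max_inner_cycles: int = 30
    convergence_shift_over_su: float = 0.01

    def __post_init__(self):
        if self.cluster_radius < 0:
            raise ValueError("cluster_radius must be >= 0")
        if self.basis not in BASIS_SETS:
            raise ValueError(f"basis must be one of {BASIS_SETS}")
        if self.h_adp_mode not in ("anisotropic", "isotropic", "fixed"):
            raise ValueError("h_adp_mode must be anisotropic, isotropic or fixed")
        if self.environment_kind not in ("none", "charges_dipoles", "explicit_cluster"):
            raise ValueError("bad environment_kind")
        if self.cluster_radius == 0:
            self.environment_kind = "none"


@dataclass
class EnvironmentModel:
    """Crystal-field surrogate: point charges/dipoles or explicit atoms."""

    kind: str
    positions: np.ndarray
    charges: np.ndarray
    dipoles: np.ndarray
    elements: list = field(default_factory=list)
    radius: float = 0.0
    log: list = field(default_factory=list)

    def __len__(self):
        return len(self.positions)

    @property
    def total_charge(self) -> float:
        return float(np.sum(self.charges)) if len(self.charges) else 0.0


@dataclass
class RefinementResult:
    """Refined model with uncertainties, agreement factors and cycle log."""

    structure: CrystalStructure
    scale: float
    scale_su: float
    r1: float
    wr2: float
    gof: float
    n_obs: int
    n_param: int
    cycles: list
    converged: bool
    environment: EnvironmentModel | None = None

    @property
    def max_shift_over_su(self) -> float:
        return self.cycles[-1]["max_shift_over_su"] if self.cycles else np.inf


# ---------------------------------------------------------------------------
# Debye–Waller factor
# ---------------------------------------------------------------------------

def debye_waller(hkl, adp, cell) -> np.ndarray:
    """Temperature factor T(h) ∈ (0, 1] for one atom.

    ``adp`` is either a scalar U_iso (Å²) or the CIF six-vector
    (U11, U22, U33, U12, U13, U23):

        T(h) = exp(−2π² Σ_ij h_i h_j a*_i a*_j U^ij)

    The isotropic case reduces to exp(−8π² U sin²θ/λ²).
    """
    hkl = np.atleast_2d(np.asarray(hkl, float))
    adp = np.asarray(adp, float)
    if adp.ndim == 0:
        s = cell.stol(hkl)
        ex = -8 * np.pi**2 * float(adp) * s**2
    else:
        u11, u22, u33, u12, u13, u23 = adp
        astar = cell.reciprocal_lengths
        ha = hkl * astar[None, :]
        ex = -2 * np.pi**2 * (
            ha[:, 0] ** 2 * u11 + ha[:, 1] ** 2 * u22 + ha[:, 2] ** 2 * u33
            + 2 * ha[:, 0] * ha[:, 1] * u12
            + 2 * ha[:, 0] * ha[:, 2] * u13
            + 2 * ha[:, 1] * ha[:, 2] * u23
        )
    return np.exp(np.minimum(ex, 0.0))


def clamp_positive_definite(u6, cell) -> tuple[np.ndarray, bool]:
    """Eigenvalue-clamp a CIF U six-vector to ≥ U_CLAMP in the Cartesian frame."""
    from .crystal_io import u_cart_to_cif

    Uc = u_cif_to_cart(u6, cell)
    w, V = np.linalg.eigh(Uc)
    if w.min() >= U_CLAMP:
        return np.asarray(u6, float), False
    w = np.maximum(w, U_CLAMP)
    return u_cart_to_cif(V @ np.diag(w) @ V.T, cell), True


# ---------------------------------------------------------------------------
# Structure factors and derivatives
# ---------------------------------------------------------------------------

def _per_symop_data(structure, f_set, hkl):
    """Precompute per-symop rotated indices, form-factor columns, t-phases."""
    hkl = np.asarray(hkl, int)
    data = []
    for op in structure.symops:
        R = np.array(op.R, int)
        hrot = hkl @ R  # rows: hᵀR = (Rᵀh)ᵀ
        cols = f_set.rows_for(hrot)
        phase_t = np.exp(2j * np.pi * (hkl @ op.tran))
        data.append((op, hrot, cols, phase_t))
    return data


def structure_factor_sum(structure, f_set, scale: float = 1.0, hkl=None) -> np.ndarray:
    """Complex F_calc per reflection.

    F(h) = k Σ_s Σ_A (occ_A / n_stab_A) f_A(R_sᵀh) T_A(R_sᵀh)
           exp(2πi h·(R_s x_A + t_s))

    Special positions are counted once via division by the stabilizer order.
    """
    if hkl is None:
        hkl = f_set.hkl
    hkl = np.asarray(hkl, int)
    per_op = _per_symop_data(structure, f_set, hkl)
    F = np.zeros(len(hkl), complex)
    for ia, site in enumerate(structure.sites):
        occw = site.occupancy / structure.site_stabilizer_order(site)
        adp = site.u_aniso if site.u_aniso is not None else site.u_iso
        for op, hrot, cols, phase_t in per_op:
            T = debye_waller(hrot, adp, structure.cell)
            ph = np.exp(2j * np.pi * (hrot @ site.xyz)) * phase_t
            F += occw * f_set.values[ia, cols] * T * ph
    return scale * F


def optimal_scale(F_obs, F_calc, weights=None) -> float:
    """Least-squares scale k minimising Σ w (|Fo| − k|Fc|)²."""
    Fo = np.abs(np.asarray(F_obs, float))
    Fc = np.abs(np.asarray(F_calc))
    w = np.ones_like(Fo) if weights is None else np.asarray(weights, float)
    denom = np.sum(w * Fc**2)
    if denom <= 0:
        raise ValueError("all |F_calc| are zero; cannot scale")
    return float(np.sum(w * Fo * Fc) / denom)


# ---------------------------------------------------------------------------
# Parameters and constraints
# ---------------------------------------------------------------------------

@dataclass
class ParamMap:
    """Layout of the refinable parameter vector (scale excluded)."""

    entries: list  # (site_index, kind, component); kind in {x, u, uiso}

    @classmethod
    def build(cls, structure, options: RefinementOptions) -> "ParamMap":
        entries = []
        for i, s in enumerate(structure.sites):
            is_h = s.element == "H"
            for c in range(3):
                entries.append((i, "x", c))
            if is_h and options.h_adp_mode == "fixed":
                continue
            if is_h and options.h_adp_mode == "isotropic":
                entries.append((i, "uiso", 0))
                continue
            if s.u_aniso is not None:
                for c in range(6):
                    entries.append((i, "u", c))
            else:
                entries.append((i, "uiso", 0))
        return cls(entries)

    def __len__(self):
        return len(self.entries)

    def describe(self, j: int, structure) -> str:
        i, kind, c = self.entries[j]
        lab = structure.sites[i].label
        name = {"x": ["x", "y", "z"], "u": ["U11", "U22", "U33", "U12", "U13", "U23"],
                "uiso": ["Uiso"]}[kind][c]
        return f"{lab}.{name}"


def polar_axes(symops) -> np.ndarray:
    """Orthonormal basis (columns) of lattice directions fixed by every op."""
    rows = []
    for op in symops:
        rows.append(np.array(op.R, float) - np.eye(3))
    stack = np.vstack(rows)
    ns = scipy.linalg.null_space(stack, rcond=1e-10)
    return ns  # (3, n_polar)


_U_COMPONENTS = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def _u6_transform_matrix(S) -> np.ndarray:
    """6×6 matrix W with (W u6) ≡ vec6(S U3 Sᵀ)."""
    W = np.zeros((6, 6))
    for col, (k, l) in enumerate(_U_COMPONENTS):
        U = np.zeros((3, 3))
        U[k, l] = U[l, k] = 1.0
        V = S @ U @ S.T
        for row, (i, j) in enumerate(_U_COMPONENTS):
            W[row, col] = V[i, j]
    return W


def constraint_matrix(structure, pmap: ParamMap) -> np.ndarray:
    """Null-space basis C: allowed shifts are Δp = C q.

    Encodes site-symmetry invariance on special positions and the
    floating-origin fix of polar space groups (the occupancy-weighted centre
    of the heaviest atoms is held).
    """
    n = len(pmap)
    rows = []
    astar = structure.cell.reciprocal_lengths
    D = np.diag(astar)
    Dinv = np.diag(1.0 / astar)

    # index lookup: (site, kind, comp) -> parameter position
    pos = {e: j for j, e in enumerate(pmap.entries)}

    for i, site in enumerate(structure.sites):
        stab = structure.stabilizer(site)
        if len(stab) <= 1:
            continue
        Px = np.mean([op.rot for op in stab], axis=0)
        Ix = np.eye(3) - Px
        for r in range(3):
            if np.any(np.abs(Ix[r]) > 1e-9):
                row = np.zeros(n)
                for c in range(3):
                    if (i, "x", c) in pos:
                        row[pos[(i, "x", c)]] = Ix[r, c]
                if np.any(row):
                    rows.append(row)
        if (i, "u", 0) in pos:
            PU = np.mean(
                [_u6_transform_matrix(Dinv @ op.rot @ D) for op in stab], axis=0
            )
            IU = np.eye(6) - PU
            for r in range(6):
                if np.any(np.abs(IU[r]) > 1e-9):
                    row = np.zeros(n)
                    for c in range(6):
                        row[pos[(i, "u", c)]] = IU[r, c]
                    rows.append(row)

    # floating origin: Σ_A w_A Δx_A has no component along any polar axis
    pol = polar_axes(structure.symops)
    if pol.shape[1] > 0:
        zmax = max(s.atomic_number for s in structure.sites)
        for kdir in range(pol.shape[1]):
            d = pol[:, kdir]
            row = np.zeros(n)
            for i, site in enumerate(structure.sites):
                if site.atomic_number != zmax:
                    continue
                w = site.occupancy
                for c in range(3):
                    if (i, "x", c) in pos:
                        row[pos[(i, "x", c)]] += w * d[c]
            if np.any(row):
                rows.append(row)

    if not rows:
        return np.eye(n)
    B = np.vstack(rows)
    C = scipy.linalg.null_space(B, rcond=1e-10)
    return C


# ---------------------------------------------------------------------------
# Least-squares cycles
# ---------------------------------------------------------------------------

@dataclass
class RefinementState:
    """Mutable refinement bookkeeping shared across inner cycles."""

    structure: CrystalStructure
    pmap: ParamMap
    C: np.ndarray
    scale: float
    weights: np.ndarray
    cycle: int = 0
    su: np.ndarray | None = None
    scale_su: float = 0.0
    normal_matrix: np.ndarray | None = None
    gradient: np.ndarray | None = None
    last_shift: np.ndarray | None = None
    nonpd_labels: list = field(default_factory=list)


def _calc_F_and_derivs(structure, f_set, hkl, pmap):
    """F_calc and dF/dp (complex) for every parameter in the map."""
    hkl = np.asarray(hkl, int)
    per_op = _per_symop_data(structure, f_set, hkl)
    n_h, n_p = len(hkl), len(pmap)
    F = np.zeros(n_h, complex)
    J = np.zeros((n_h, n_p), complex)
    astar = structure.cell.reciprocal_lengths
    cols_of_site = {}
    for j, (i, kind, c) in enumerate(pmap.entries):
        cols_of_site.setdefault(i, []).append((j, kind, c))

    s2 = structure.cell.stol(hkl) ** 2
    for ia, site in enumerate(structure.sites):
        occw = site.occupancy / structure.site_stabilizer_order(site)
        adp = site.u_aniso if site.u_aniso is not None else site.u_iso
        for op, hrot, cols, phase_t in per_op:
            T = debye_waller(hrot, adp, structure.cell)
            ph = np.exp(2j * np.pi * (hrot @ site.xyz)) * phase_t
            contrib = occw * f_set.values[ia, cols] * T * ph
            F += contrib
            for j, kind, c in cols_of_site.get(ia, []):
                if kind == "x":
                    J[:, j] += contrib * (2j * np.pi * hrot[:, c])
                elif kind == "u":
                    k, l = _U_COMPONENTS[c]
                    mult = 1.0 if k == l else 2.0
                    J[:, j] += contrib * (
                        -2 * np.pi**2 * mult
                        * hrot[:, k] * astar[k] * hrot[:, l] * astar[l]
                    )
                else:  # uiso
                    J[:, j] += contrib * (-8 * np.pi**2 * s2)
    return F, J


def _apply_shift(structure, pmap, shift):
    for j, (i, kind, c) in enumerate(pmap.entries):
        s = structure.sites[i]
        if kind == "x":
            s.xyz[c] += shift[j]
        elif kind == "u":
            s.u_aniso[c] += shift[j]
        else:
            s.u_iso += shift[j]


def _sanitize_adps(state):
    state.nonpd_labels = []
    for s in state.structure.sites:
        if s.u_aniso is not None:
            u6, clamped = clamp_positive_definite(s.u_aniso, state.structure.cell)
            if clamped:
                s.u_aniso = u6
                state.nonpd_labels.append(s.label)
                logger.warning("U of %s clamped to positive definite", s.label)
            s.u_iso = float(np.trace(u_cif_to_cart(s.u_aniso, state.structure.cell)) / 3)
        elif s.u_iso < U_CLAMP:
            s.u_iso = U_CLAMP
            state.nonpd_labels.append(s.label)


def _wr2(Fo, Fc_mag, k, w) -> float:
    num = np.sum(w * (Fo - k * Fc_mag) ** 2)
    den = np.sum(w * Fo**2)
    return float(np.sqrt(num / den))


def lsq_cycle(state: RefinementState, reflections: ReflectionSet, f_set):
    """One constrained Gauss–Newton cycle on Σ w (|Fo| − k|Fc|)².

    Updates positions, ADPs and the scale in place; returns a dict with the
    cycle diagnostics (wR2 before/after, max shift, max shift/su).
    """
    st = state.structure
    Fo = reflections.value
    w = state.weights
    hkl = reflections.hkl

    F, Jc = _calc_F_and_derivs(st, f_set, hkl, state.pmap)
    Fc = np.abs(F)
    if np.all(Fc == 0):
        raise ValueError("all |F_calc| vanish; model is empty")
    state.scale = optimal_scale(Fo, Fc, w)
    k = state.scale
    phase = np.where(Fc > 1e-12, np.conj(F) / np.maximum(Fc, 1e-12), 0.0)
    dFc = np.real(phase[:, None] * Jc)  # d|Fc|/dp

    # model m = k |Fc|; parameter vector [k, p...]
    Jm = np.hstack([Fc[:, None], k * dFc])
    r = Fo - k * Fc
    wr2_before = _wr2(Fo, Fc, k, w)

    Chat = scipy.linalg.block_diag(np.eye(1), state.C)
    A = Jm.T @ (w[:, None] * Jm)
    g = Jm.T @ (w * r)
    A_red = Chat.T @ A @ Chat
    g_red = Chat.T @ g
    # detect singularity before solving
    diag = np.sqrt(np.maximum(np.diag(A_red), 0.0))
    if np.any(diag <= 0) or np.linalg.cond(A_red / np.outer(
            np.maximum(diag, 1e-30), np.maximum(diag, 1e-30))) > 1e12:
        names = []
        full_diag = np.diag(A)
        for j in np.argsort(full_diag)[:3]:
            names.append("scale" if j == 0 else state.pmap.describe(j - 1, st))
        raise np.linalg.LinAlgError(
            "singular normal matrix; unconstrained or degenerate parameters "
            f"(weakest: {', '.join(names)}) — polar-axis origin may be floating"
        )
    dq = np.linalg.solve(A_red, g_red)
    dfull = Chat @ dq

    # absolute shift caps (protect early cycles)
    dscale, dp = dfull[0], dfull[1:]
    cap = 1.0
    cell = st.cell
    for j, (i, kind, c) in enumerate(state.pmap.entries):
        if kind == "x":
            step = abs(dp[j]) * np.linalg.norm(cell.M[:, c])
            if step > MAX_XYZ_SHIFT:
                cap = min(cap, MAX_XYZ_SHIFT / step)
        else:
            if abs(dp[j]) > MAX_U_SHIFT:
                cap = min(cap, MAX_U_SHIFT / abs(dp[j]))
    dp = dp * cap
    dscale = dscale * cap

    # step halving keeps wR2 non-increasing
    accepted = False
    for attempt in range(6):
        trial = st.copy()
        _apply_shift(trial, state.pmap, dp)
        Ftrial = structure_factor_sum(trial, f_set, 1.0, hkl)
        Fct = np.abs(Ftrial)
        kt = optimal_scale(Fo, Fct, w)
        wr2_after = _wr2(Fo, Fct, kt, w)
        if wr2_after <= wr2_before * (1 + 1e-12) or np.max(np.abs(dp)) < 1e-12:
            accepted = True
            break
        dp = dp / 2
        dscale = dscale / 2
    if not accepted:
        dp[:] = 0.0
        wr2_after = wr2_before
        kt = k
    _apply_shift(st, state.pmap, dp)
    state.scale = kt
    _sanitize_adps(state)

    # uncertainties from the inverse reduced normal matrix, GOF-scaled
    n_obs, n_par = len(Fo), 1 + state.C.shape[1]
    gof = np.sqrt(max(np.sum(w * r**2), 0.0) / max(n_obs - n_par, 1))
    cov_red = np.linalg.inv(A_red)
    cov = Chat @ cov_red @ Chat.T * max(gof, 1e-30) ** 2
    su_full = np.sqrt(np.maximum(np.diag(cov), 0.0))
    state.scale_su = su_full[0]
    state.su = su_full[1:]
    state.normal_matrix = A_red
    state.gradient = g_red
    state.last_shift = dp
    state.cycle += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        sos = np.abs(dp) / np.where(state.su > 0, state.su, np.inf)
    max_xyz = max(
        (abs(dp[j]) * np.linalg.norm(cell.M[:, c])
         for j, (i, kind, c) in enumerate(state.pmap.entries) if kind == "x"),
        default=0.0,
    )
    max_u = max(
        (abs(dp[j]) for j, (i, kind, c) in enumerate(state.pmap.entries)
         if kind != "x"),
        default=0.0,
    )
    return {
        "cycle": state.cycle,
        "wr2_before": wr2_before,
        "wr2": wr2_after,
        "scale": state.scale,
        "max_shift_xyz": max_xyz,
        "max_shift_u": max_u,
        "max_shift_over_su": float(np.max(sos)) if len(sos) else 0.0,
        "gof": float(gof),
    }


def _store_uncertainties(state: RefinementState):
    su = state.su
    if su is None:
        return
    for j, (i, kind, c) in enumerate(state.pmap.entries):
        s = state.structure.sites[i]
        if kind == "x":
            s.su_xyz[c] = su[j]
        elif kind == "u":
            if s.su_u_aniso is None:
                s.su_u_aniso = np.zeros(6)
            s.su_u_aniso[c] = su[j]
        else:
            s.su_u_iso = su[j]


def refine_lsq(structure, reflections, f_set, options, weights=None):
    """Inner least-squares to convergence at frozen form factors.

    Returns (state, cycle log).  Convergence: coordinate shifts < 1e-7 Å and
    U shifts < 1e-8 Å², or shift/su below the configured threshold.
    """
    pmap = ParamMap.build(structure, options)
    n_free = 1 + constraint_matrix(structure, pmap).shape[1]
    if len(reflections) <= n_free:
        raise ValueError(
            f"{len(reflections)} reflections for {n_free} parameters; underdetermined"
        )
    state = RefinementState(
        structure=structure,
        pmap=pmap,
        C=constraint_matrix(structure, pmap),
        scale=1.0,
        weights=(1.0 / reflections.sigma**2) if weights is None else weights,
    )
    log = []
    for _ in range(options.max_inner_cycles):
        info = lsq_cycle(state, reflections, f_set)
        log.append(info)
        if (info["max_shift_xyz"] < 1e-7 and info["max_shift_u"] < 1e-8):
            break
        if info["max_shift_over_su"] < options.convergence_shift_over_su / 10:
            break
    _store_uncertainties(state)
    return state, log


# ---------------------------------------------------------------------------
# Reflection pruning
# ---------------------------------------------------------------------------

def prune_reflections(rset: ReflectionSet, predicate="F>3sig"):
    """Apply an observation criterion; default F > 3σ(F).

    ``predicate`` is either a callable on the set returning a mask, or a
    string of the form 'F>nsig'.  Returns (subset, report dict).
    """
    if callable(predicate):
        mask = np.asarray(predicate(rset), bool)
    else:
        m = re.fullmatch(r"\s*F\s*>\s*([\d.]+)\s*sig(?:ma)?\s*", str(predicate))
        if not m:
            raise ValueError(f"cannot parse pruning predicate {predicate!r}")
        nsig = float(m.group(1))
        mask = rset.value > nsig * rset.sigma
    kept = int(mask.sum())
    if kept == 0:
        raise ValueError("pruning removed every reflection")
    report = {"kept": kept, "removed": int(len(rset) - kept), "predicate": str(predicate)}
    logger.info("pruning '%s': kept %d, removed %d", report["predicate"],
                kept, report["removed"])
    sub = rset.subset(mask)
    sub.observed[:] = True
    return sub, report


# ---------------------------------------------------------------------------
# Crystal-field environment
# ---------------------------------------------------------------------------

def build_environment(structure, fragment, options, multipoles=None) -> EnvironmentModel:
    """Whole neighbouring molecules with any atom within the cluster radius.

    ``charges_dipoles`` places the Hirshfeld q/μ of the parent atoms (rotated
    with the generating operation) at the neighbour atomic sites;
    ``explicit_cluster`` returns the atoms themselves for inclusion in the
    density calculation.  A radius of zero yields an empty model.
    """
    radius = options.cluster_radius
    kind = options.environment_kind
    if radius <= 0 or kind == "none":
        return EnvironmentModel("none", np.zeros((0, 3)), np.zeros(0),
                                np.zeros((0, 3)), radius=0.0)
    grown = grow_fragment(structure, "radius_cluster", radius)
    core_n = len(fragment)
    env_atoms = grown.atoms[core_n:]
    if not env_atoms:
        logger.warning("no neighbour molecules within %.2f Å", radius)
        return EnvironmentModel(kind, np.zeros((0, 3)), np.zeros(0),
                                np.zeros((0, 3)), radius=radius)
    positions = np.array([a.pos for a in env_atoms])
    # entries must not sit on top of the fragment
    dmin = np.min(np.linalg.norm(
        positions[:, None, :] - fragment.positions[None, :, :], axis=-1))
    if dmin < 0.5:
        raise ValueError("environment entry within 0.5 Å of a fragment atom")

    elements = [a.element for a in env_atoms]
    charges = np.zeros(len(env_atoms))
    dipoles = np.zeros((len(env_atoms), 3))
    if kind == "charges_dipoles" and multipoles is not None:
        # map ASU multipoles onto neighbour atoms through their parent sites
        by_parent = {}
        for m in multipoles:
            pa = fragment.atoms[m.atom]
            if pa.symop.is_identity and pa.shift == (0, 0, 0):
                by_parent[pa.parent] = m
        for i, a in enumerate(env_atoms):
            m = by_parent.get(a.parent)
            if m is None:
                continue
            charges[i] = m.q
            lam = a.symop.cartesian_rotation(structure.cell)
            dipoles[i] = lam @ m.mu
    return EnvironmentModel(kind, positions, charges, dipoles,
                            elements=elements, radius=radius)


def _selfconsistent_environment(structure, fragment, options, provider, grid_level):
    """Iterate multipoles ↔ density until max |Δq| and |Δμ| < 1e-3 (≤10 cycles)."""
    env = build_environment(structure, fragment, options)
    if options.environment_kind != "charges_dipoles" or len(env) == 0:
        return env
    grid = molecular_grid(fragment, grid_level)
    weights = hirshfeld_weights_all(grid.points, fragment)
    prev_q = prev_mu = None
    for it in range(10):
        rho = provider.density(fragment, grid.points, environment=env)
        mult = atomic_multipoles(fragment, rho, grid, weights)
        q = np.array([m.q for m in mult])
        mu = np.array([m.mu for m in mult])
        env = build_environment(structure, fragment, options, mult)
        env.log.append({"iter": it, "max_q": float(np.max(np.abs(q)))})
        if prev_q is not None and np.max(np.abs(q - prev_q)) < 1e-3 \
                and np.max(np.abs(mu - prev_mu)) < 1e-3:
            break
        prev_q, prev_mu = q, mu
    return env


# ---------------------------------------------------------------------------
# The outer HAR loop
# ---------------------------------------------------------------------------

def har_iterate(structure, reflections, options: RefinementOptions,
                provider=None) -> RefinementResult:
    """Iterate density calculation and least squares to convergence.

    Each outer cycle regrows the fragment from the refined coordinates,
    rebuilds the (optionally self-consistent) crystal-field environment,
    recomputes the Hirshfeld form factors and refines at frozen factors.
    Stops when max |shift/su| < ``convergence_shift_over_su`` (default 0.01)
    or the absolute shifts become negligible; flagged unconverged at
    ``max_outer_cycles``.
    """
    if options.mode == "har" and provider is None:
        raise ValueError("HAR mode requires a DensityProvider")
    work = structure.copy()
    if options.h_adp_mode == "anisotropic":
        for s in work.sites:
            if s.u_aniso is None and s.element == "H":
                s.u_aniso = _iso_as_aniso(s.u_iso, work.cell)
    obs, prune_report = prune_reflections(reflections, options.pruning)
    hkl_unique = obs.hkl

    cycles = []
    converged = False
    env = None
    state = None
    prev_wr2 = np.inf
    osc_count = 0
    for outer in range(1, options.max_outer_cycles + 1):
        fragment = grow_fragment(work, options.fragment_mode,
                                 radius=options.cluster_radius)
        if options.mode == "har":
            env = _selfconsistent_environment(work, fragment, options,
                                              provider, options.grid_level)
            f_set = compute_form_factor_set(
                work, fragment, hkl_unique, provider=provider, mode="hirshfeld",
                grid_level=options.grid_level, environment=env,
                dispersion=options.dispersion,
                force_quadrature=options.force_quadrature,
            )
        else:
            f_set = compute_form_factor_set(
                work, fragment, hkl_unique, mode="iam",
                dispersion=options.dispersion,
            )
        state, inner_log = refine_lsq(work, obs, f_set, options)
        last = inner_log[-1]
        cycles.append({
            "outer": outer,
            "inner_cycles": len(inner_log),
            "wr2": last["wr2"],
            "scale": state.scale,
            "max_shift_xyz": last["max_shift_xyz"],
            "max_shift_u": last["max_shift_u"],
            "max_shift_over_su": last["max_shift_over_su"],
            "gof": last["gof"],
        })
        logger.info("outer %d: wR2=%.5f shift/su=%.3g", outer, last["wr2"],
                    last["max_shift_over_su"])
        if last["max_shift_over_su"] < options.convergence_shift_over_su or (
                last["max_shift_xyz"] < 1e-6 and last["max_shift_u"] < 1e-7):
            converged = True
            break
        if last["wr2"] > prev_wr2 * (1 + 1e-9):
            osc_count += 1
            if osc_count >= 2:
                logger.warning("outer loop oscillating (wR2 %.6f -> %.6f); stopping",
                               prev_wr2, last["wr2"])
                break
        prev_wr2 = last["wr2"]

    from .metrics import r_factors

    F = structure_factor_sum(work, f_set, 1.0, obs.hkl)
    n_par = 1 + state.C.shape[1]
    r1, wr2, gof = r_factors(obs.value, np.abs(F), state.scale, state.weights,
                             n_param=n_par)
    result = RefinementResult(
        structure=work,
        scale=state.scale,
        scale_su=state.scale_su,
        r1=r1, wr2=wr2, gof=gof,
        n_obs=len(obs), n_param=n_par,
        cycles=cycles,
        converged=converged,
        environment=env,
    )
    result.prune_report = prune_report
    result.reflections = obs
    result.form_factors = f_set
    return result


def _iso_as_aniso(u_iso, cell) -> np.ndarray:
    """Equivalent CIF U six-vector of an isotropic U (Cartesian U = u·I)."""
    from .crystal_io import u_cart_to_cif

    return u_cart_to_cif(np.eye(3) * u_iso, cell)
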