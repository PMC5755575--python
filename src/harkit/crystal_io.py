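"""Crystallographic file I/O, symmetry handling and coordinate transforms.

Conventions
-----------
* Fractional coordinates follow the CIF core dictionary; all internal geometry
  is Cartesian in Å (``x_cart = M @ x_frac`` with ``M`` the orthogonalization
  matrix whose columns are the direct-lattice basis vectors).
* Reciprocal vectors carry the crystallographic (2π-free) convention, so the
  Cartesian reciprocal vector of a Miller index ``h`` is ``B @ h`` with
  ``B = inv(M).T`` and ``|B @ h| = 1/d``.
* Anisotropic displacement parameters are the CIF ``U^ij`` six-vectors
  ``(U11, U22, U33, U12, U13, U23)`` in Å².
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction

import gemmi
import numpy as np

logger = logging.getLogger("harkit")

__all__ = [
    "UnitCell",
    "SymOp",
    "AtomSite",
    "CrystalStructure",
    "ReflectionSet",
    "FragmentAtom",
    "MoleculeFragment",
    "CifParseError",
    "HklParseError",
    "parse_cif",
    "parse_hkl",
    "write_cif_result",
    "grow_fragment",
    "orthogonalize",
    "format_su",
    "parse_su_number",
    "covalent_radius",
    "BOND_FACTOR",
]

# Bond detection for molecule completion: d < BOND_FACTOR * (r_cov_A + r_cov_B),
# hydrogen limited to a single bond.  Robust on organic crystals.
BOND_FACTOR = 1.15

# Sites generated by different operations closer than this are the same atom
# (special-position coincidence).
COINCIDENCE_TOL = 0.3  # Å

MAX_FRAGMENT_ATOMS = 10_000


class CifParseError(ValueError):
    """Raised when a CIF document lacks required items or is malformed."""


class HklParseError(ValueError):
    """Raised when a reflection file record cannot be interpreted."""


def covalent_radius(element: str) -> float:
    """Covalent radius in Å from gemmi's element table."""
    el = gemmi.Element(element)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol {element!r}")
    return el.covalent_r


# ---------------------------------------------------------------------------
# Unit cell
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell with derived metric quantities.

    Parameters are lengths in Å and angles in degrees.  Derived attributes:

    ``M``      orthogonalization matrix (columns a, b, c in Cartesian Å)
    ``Minv``   its inverse (Cartesian → fractional)
    ``B``      reciprocal orthogonalization ``inv(M).T`` (columns a*, b*, c*)
    ``G``      direct metric tensor (Å²), ``Gstar`` its inverse (Å⁻²)
    ``volume`` cell volume (Å³)
    """

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        if self.volume <= 0 or not np.isfinite(self.volume):
            raise ValueError("degenerate unit cell (non-positive volume)")

    @property
    def M(self) -> np.ndarray:
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        ca, cb, cg = np.cos([al, be, ga])
        sg = np.sin(ga)
        # standard PDB-style orthogonalization: a along x, b in the xy plane
        v = np.sqrt(max(1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg, 0.0))
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    @property
    def Minv(self) -> np.ndarray:
        return np.linalg.inv(self.M)

    @property
    def B(self) -> np.ndarray:
        return self.Minv.T

    @property
    def G(self) -> np.ndarray:
        return self.M.T @ self.M

    @property
    def Gstar(self) -> np.ndarray:
        return np.linalg.inv(self.G)

    @property
    def volume(self) -> float:
        al, be, ga = np.radians([self.alpha, self.beta, self.gamma])
        ca, cb, cg = np.cos([al, be, ga])
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
        return float(self.a * self.b * self.c * np.sqrt(max(arg, 0.0)))

    @property
    def reciprocal_lengths(self) -> np.ndarray:
        """(a*, b*, c*) lengths in Å⁻¹."""
        return np.linalg.norm(self.B, axis=0)

    # -- geometry helpers ---------------------------------------------------

    def frac_to_cart(self, xyz) -> np.ndarray:
        return np.asarray(xyz, float) @ self.M.T

    def cart_to_frac(self, xyz) -> np.ndarray:
        return np.asarray(xyz, float) @ self.Minv.T

    def k_vectors(self, hkl) -> np.ndarray:
        """Cartesian reciprocal vectors (Å⁻¹, |k| = 1/d) for Miller indices."""
        return np.asarray(hkl, float) @ self.B.T

    def stol(self, hkl) -> np.ndarray:
        """sin(θ)/λ = |h*|/2 for Miller indices."""
        return 0.5 * np.linalg.norm(self.k_vectors(hkl), axis=-1)


def orthogonalize(cell: UnitCell):
    """Return the (frac → Cartesian, Cartesian → frac) transform pair."""
    M = cell.M
    Minv = np.linalg.inv(M)

    def to_cart(x):
        return np.asarray(x, float) @ M.T

    def to_frac(x):
        return np.asarray(x, float) @ Minv.T

    return to_cart, to_frac


# ---------------------------------------------------------------------------
# Symmetry operations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SymOp:
    """Space-group operation x' = R x + t acting on fractional coordinates."""

    R: tuple  # 3x3 of ints (rotation part, fractional basis)
    t: tuple  # 3 translations in [0, 1)

    @classmethod
    def identity(cls) -> "SymOp":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymOp":
        op = gemmi.Op(triplet)
        den = op.DEN
        R = tuple(tuple(int(v // den) for v in row) for row in op.rot)
        t = tuple((v / den) % 1.0 for v in op.tran)
        return cls(R, t)

    @property
    def rot(self) -> np.ndarray:
        return np.array(self.R, float)

    @property
    def tran(self) -> np.ndarray:
        return np.array(self.t, float)

    @property
    def is_identity(self) -> bool:
        return self.R == ((1, 0, 0), (0, 1, 0), (0, 0, 1)) and all(
            abs(v) < 1e-9 for v in self.t
        )

    def apply(self, xyz) -> np.ndarray:
        return np.asarray(xyz, float) @ self.rot.T + self.tran

    def compose(self, other: "SymOp") -> "SymOp":
        """self ∘ other (apply ``other`` first), translation reduced mod 1."""
        R = tuple(
            tuple(int(v) for v in row)
            for row in (self.rot @ other.rot).round().astype(int)
        )
        t = tuple(((self.rot @ other.tran + self.tran) % 1.0).tolist())
        return SymOp(R, t)

    def triplet(self) -> str:
        parts = []
        for i in range(3):
            s = ""
            for j, ax in enumerate("xyz"):
                r = self.R[i][j]
                if r == 0:
                    continue
                sign = "-" if r < 0 else ("+" if s else "")
                s += f"{sign}{ax}" if abs(r) == 1 else f"{sign}{abs(r)}{ax}"
            tr = Fraction(self.t[i]).limit_denominator(24)
            if tr:
                s += f"+{tr}"
            parts.append(s or "0")
        return ",".join(parts)

    def cartesian_rotation(self, cell: UnitCell) -> np.ndarray:
        """Rotation in the Cartesian frame: Λ = M R M⁻¹."""
        return cell.M @ self.rot @ cell.Minv


def symops_from_hall_or_hm(symbol: str) -> list[SymOp]:
    sg = gemmi.SpaceGroup(symbol)
    return [SymOp.from_triplet(op.triplet()) for op in sg.operations()]


# ---------------------------------------------------------------------------
# Atom sites and structures
# ---------------------------------------------------------------------------

@dataclass
class AtomSite:
    """One asymmetric-unit site with displacement parameters.

    ``u_aniso`` is the CIF six-vector (U11, U22, U33, U12, U13, U23) in Å² or
    None for isotropic-only sites; ``u_iso`` is always kept (equivalent value
    for anisotropic sites).
    """

    label: str
    element: str
    xyz: np.ndarray
    u_iso: float = 0.02
    u_aniso: np.ndarray | None = None
    occupancy: float = 1.0
    site_multiplicity: int = 1
    su_xyz: np.ndarray = field(default_factory=lambda: np.zeros(3))
    su_u_iso: float = 0.0
    su_u_aniso: np.ndarray | None = None

    def __post_init__(self):
        self.xyz = np.asarray(self.xyz, float)
        if self.u_aniso is not None:
            self.u_aniso = np.asarray(self.u_aniso, float)
        self.su_xyz = np.asarray(self.su_xyz, float)
        if not (0.0 < self.occupancy <= 1.0 + 1e-9):
            raise ValueError(f"occupancy of {self.label} outside (0, 1]")
        if gemmi.Element(self.element).atomic_number == 0:
            raise ValueError(f"unknown element symbol for site {self.label!r}")

    @property
    def is_anisotropic(self) -> bool:
        return self.u_aniso is not None

    @property
    def atomic_number(self) -> int:
        return gemmi.Element(self.element).atomic_number

    def u_cif_matrix(self) -> np.ndarray:
        """U^ij as a symmetric 3×3 (CIF basis); isotropic expanded on demand."""
        if self.u_aniso is None:
            # equivalent isotropic tensor in the CIF basis is NOT diag(U) in
            # oblique cells; callers needing a tensor should use u_cart
            raise ValueError(f"site {self.label} has no anisotropic U")
        u11, u22, u33, u12, u13, u23 = self.u_aniso
        return np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])

    def u_cart(self, cell: UnitCell) -> np.ndarray:
        """Cartesian displacement tensor ⟨u uᵀ⟩ in Å²."""
        if self.u_aniso is None:
            return np.eye(3) * self.u_iso
        return u_cif_to_cart(self.u_aniso, cell)


def u_cif_to_cart(u6, cell: UnitCell) -> np.ndarray:
    u6 = np.asarray(u6, float)
    u11, u22, u33, u12, u13, u23 = u6
    U = np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]])
    A = cell.M @ np.diag(cell.reciprocal_lengths)
    return A @ U @ A.T

def u_cart_to_cif(Ucart, cell: UnitCell) -> np.ndarray:
    A = cell.M @ np.diag(cell.reciprocal_lengths)
    Ainv = np.linalg.inv(A)
    U = Ainv @ np.asarray(Ucart, float) @ Ainv.T
    return np.array([U[0, 0], U[1, 1], U[2, 2], U[0, 1], U[0, 2], U[1, 2]])


@dataclass
class CrystalStructure:
    """Cell + symmetry + asymmetric-unit sites: the refinable model."""

    cell: UnitCell
    symops: list
    sites: list
    space_group_name: str = "P 1"
    Z: int = 1

    def __post_init__(self):
        if not self.symops:
            self.symops = [SymOp.identity()]

    @property
    def n_symops(self) -> int:
        return len(self.symops)

    def site_by_label(self, label: str) -> AtomSite:
        for s in self.sites:
            if s.label == label:
                return s
        raise KeyError(label)

    def stabilizer(self, site: AtomSite, tol: float = 0.05) -> list:
        """Symmetry operations fixing the site (mod lattice translations)."""
        out = []
        for op in self.symops:
            d = op.apply(site.xyz) - site.xyz
            d -= np.round(d)
            if np.linalg.norm(self.cell.frac_to_cart(d)) < tol:
                out.append(op)
        return out

    def site_stabilizer_order(self, site: AtomSite) -> int:
        return max(len(self.stabilizer(site)), 1)

    def expand_site(self, site: AtomSite):
        """Unique symmetry copies of one site: list of (xyz_frac, SymOp)."""
        copies = []
        for op in self.symops:
            x = op.apply(site.xyz) % 1.0
            xc = self.cell.frac_to_cart(x)
            dup = False
            for xprev, _ in copies:
                d = x - xprev
                d -= np.round(d)
                if np.linalg.norm(self.cell.frac_to_cart(d)) < COINCIDENCE_TOL:
                    dup = True
                    break
            if not dup:
                copies.append((x, op))
        return copies

    def validate_no_clashes(self, tol: float = COINCIDENCE_TOL):
        """No two expanded atoms closer than ``tol`` unless identical."""
        pts, owners = [], []
        for i, s in enumerate(self.sites):
            for x, _ in self.expand_site(s):
                pts.append(x)
                owners.append(i)
        pts = np.array(pts)
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = pts[i] - pts[j]
                d -= np.round(d)
                if np.linalg.norm(self.cell.frac_to_cart(d)) < tol:
                    raise ValueError(
                        f"expanded sites {self.sites[owners[i]].label} and "
                        f"{self.sites[owners[j]].label} clash ({tol} Å rule)"
                    )

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(
            cell=self.cell,
            symops=list(self.symops),
            sites=[
                replace(
                    s,
                    xyz=s.xyz.copy(),
                    u_aniso=None if s.u_aniso is None else s.u_aniso.copy(),
                    su_xyz=s.su_xyz.copy(),
                    su_u_aniso=None if s.su_u_aniso is None else s.su_u_aniso.copy(),
                )
                for s in self.sites
            ],
            space_group_name=self.space_group_name,
            Z=self.Z,
        )


# ---------------------------------------------------------------------------
# Reflections
# ---------------------------------------------------------------------------

@dataclass
class ReflectionSet:
    """Miller indices with |F_obs| and uncertainties (the evidence).

    ``value`` always holds |F| in electrons after dialect conversion;
    ``sigma`` its standard uncertainty; ``observed`` the pruning flag.
    """

    hkl: np.ndarray
    value: np.ndarray
    sigma: np.ndarray
    observed: np.ndarray | None = None

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, int).reshape(-1, 3)
        self.value = np.asarray(self.value, float)
        self.sigma = np.asarray(self.sigma, float)
        if self.observed is None:
            self.observed = np.ones(len(self.value), bool)
        if np.any(self.sigma <= 0):
            raise ValueError("all reflection sigmas must be positive")
        if np.any(np.all(self.hkl == 0, axis=1)):
            raise ValueError("reflection list contains (0,0,0)")

    def __len__(self) -> int:
        return len(self.value)

    def subset(self, mask) -> "ReflectionSet":
        mask = np.asarray(mask, bool)
        return ReflectionSet(
            self.hkl[mask], self.value[mask], self.sigma[mask], self.observed[mask]
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "h": self.hkl[:, 0],
                "k": self.hkl[:, 1],
                "l": self.hkl[:, 2],
                "F": self.value,
                "sigma": self.sigma,
                "observed": self.observed,
            }
        )


# ---------------------------------------------------------------------------
# hkl parsing
# ---------------------------------------------------------------------------

_DIALECTS = ("F", "F2", "shelx_F", "shelx_F2")


def _detect_format(lines) -> str:
    """'fixed' (SHELX 3I4,2F8) or 'free' (whitespace columns)."""
    for ln in lines:
        if not ln.strip():
            continue
        body = ln.rstrip("\n")
        if len(body) >= 28 and all(
            body[i * 4 : i * 4 + 4].strip() or True for i in range(3)
        ):
            # SHELX records are at least 28 chars wide with digit-aligned cols
            try:
                int(body[0:4]); int(body[4:8]); int(body[8:12])
                float(body[12:20]); float(body[20:28])
                return "fixed"
            except ValueError:
                pass
        return "free"
    return "free"


def parse_hkl(text: str, dialect: str = "shelx_F") -> ReflectionSet:
    """Parse a SHELX-style reflection file into a ReflectionSet.

    ``dialect`` is one of ``F``, ``F2``, ``shelx_F``, ``shelx_F2``; the shelx
    variants are fixed-width (3I4, 2F8), the others whitespace-delimited.
    F² dialects are converted to |F| with σ_F = σ_F²/(2|F|); non-positive F²
    is truncated to |F| = 0 with σ_F = sqrt(σ_F²).
    A ``0 0 0`` record terminates parsing.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}")
    lines = text.splitlines()
    layout = "fixed" if dialect.startswith("shelx") else _detect_format(lines)
    squared = dialect.endswith("F2")

    hkl, val, sig = [], [], []
    for lineno, ln in enumerate(lines, 1):
        if not ln.strip():
            continue
        try:
            if layout == "fixed":
                h, k, l = int(ln[0:4]), int(ln[4:8]), int(ln[8:12])
                v, s = float(ln[12:20]), float(ln[20:28])
            else:
                parts = ln.split()
                h, k, l = int(parts[0]), int(parts[1]), int(parts[2])
                v, s = float(parts[3]), float(parts[4])
        except (ValueError, IndexError) as exc:
            raise HklParseError(f"malformed reflection record at line {lineno}: {ln!r}") from exc
        if h == k == l == 0:
            break
        hkl.append((h, k, l))
        val.append(v)
        sig.append(s)

    if not hkl:
        raise HklParseError("reflection file contains no records")

    val = np.array(val)
    sig = np.array(sig)
    if squared:
        F = np.zeros_like(val)
        sF = np.zeros_like(val)
        pos = val > 0
        F[pos] = np.sqrt(val[pos])
        sF[pos] = sig[pos] / (2 * F[pos])
        # negative F²: |F| = 0, σ_F = sqrt(σ_F²)  (simple monotone truncation)
        F[~pos] = 0.0
        sF[~pos] = np.sqrt(np.abs(sig[~pos]))
        n_neg = int(np.sum(~pos))
        if n_neg:
            logger.warning("%d non-positive F² records truncated to |F| = 0", n_neg)
        val, sig = F, sF
    if np.all(val <= 0):
        raise HklParseError("all reflections non-positive; refusing the file")
    sig = np.where(sig <= 0, np.maximum(1e-6 * np.abs(val), 1e-6), sig)
    return ReflectionSet(np.array(hkl), val, sig)


# ---------------------------------------------------------------------------
# CIF parsing
# ---------------------------------------------------------------------------

_SU_RE = re.compile(r"^([-+]?\d*\.?\d+(?:[eE][-+]?\d+)?)(?:\((\d+)\))?$")


def parse_su_number(tok: str) -> tuple[float, float]:
    """Parse CIF '1.0440(12)' notation → (value, standard uncertainty)."""
    tok = tok.strip()
    if tok in (".", "?"):
        return np.nan, 0.0
    m = _SU_RE.match(tok)
    if not m:
        raise CifParseError(f"cannot parse numeric CIF value {tok!r}")
    value = float(m.group(1))
    su = 0.0
    if m.group(2):
        digits = m.group(2)
        frac = m.group(1).split(".")
        ndec = len(frac[1]) if len(frac) > 1 else 0
        su = int(digits) * 10.0 ** (-ndec)
    return value, su


def _cif_get(block, tag):
    v = block.find_value(tag)
    return v


def parse_cif(text: str) -> CrystalStructure:
    """Parse a small-molecule CIF document into a CrystalStructure.

    Requires cell parameters, symmetry (operation loop or H-M symbol) and an
    atom_site loop.  Fractional coordinates are normalised into [0, 1); sites
    without displacement parameters default to U_iso = 0.02 Å² with a warning;
    the aniso loop is joined to the site loop by label.
    """
    doc = gemmi.cif.Document()
    try:
        doc = gemmi.cif.read_string(text)
    except (RuntimeError, ValueError) as exc:
        raise CifParseError(f"CIF syntax error: {exc}") from exc
    block = doc.sole_block() if len(doc) == 1 else doc[0]

    cellvals = {}
    for name in ("a", "b", "c", "angle_alpha", "angle_beta", "angle_gamma"):
        tag = f"_cell_length_{name}" if name in "abc" else f"_cell_{name}"
        raw = _cif_get(block, tag)
        if raw is None:
            if name.startswith("angle"):
                cellvals[name] = 90.0
                continue
            raise CifParseError(f"missing required CIF item {tag}")
        cellvals[name], _ = parse_su_number(raw)
    cell = UnitCell(
        cellvals["a"], cellvals["b"], cellvals["c"],
        cellvals["angle_alpha"], cellvals["angle_beta"], cellvals["angle_gamma"],
    )

    symops = []
    for tag in ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz"):
        col = block.find_loop(tag)
        if col:
            symops = [SymOp.from_triplet(gemmi.cif.as_string(v)) for v in col]
            break
    sg_name = None
    for tag in ("_symmetry_space_group_name_H-M", "_space_group_name_H-M_alt"):
        raw = _cif_get(block, tag)
        if raw is not None:
            sg_name = gemmi.cif.as_string(raw)
            break
    if not symops:
        if sg_name is None:
            symops = [SymOp.identity()]
            sg_name = "P 1"
        else:
            try:
                symops = symops_from_hall_or_hm(sg_name)
            except Exception as exc:
                raise CifParseError(f"unknown space group {sg_name!r}") from exc
    if sg_name is None:
        sg_name = "P 1"

    site_tags = ["label", "type_symbol", "fract_x", "fract_y", "fract_z",
                 "U_iso_or_equiv", "occupancy"]
    table = block.find("_atom_site_", site_tags)
    if len(table) == 0:
        table = block.find("_atom_site_", site_tags[:5])
        if len(table) == 0:
            raise CifParseError("missing _atom_site_ loop (need label, type_symbol, fract_x/y/z)")
        has_uiso = has_occ = False
    else:
        has_uiso = has_occ = True

    aniso = {}
    atags = ["label", "U_11", "U_22", "U_33", "U_12", "U_13", "U_23"]
    at = block.find("_atom_site_aniso_", atags)
    for row in at:
        lab = gemmi.cif.as_string(row[0])
        vals, sus = [], []
        for i in range(1, 7):
            v, su = parse_su_number(row[i])
            vals.append(v)
            sus.append(su)
        aniso[lab] = (np.array(vals), np.array(sus))

    sites = []
    for row in table:
        lab = gemmi.cif.as_string(row[0])
        element = gemmi.cif.as_string(row[1])
        if gemmi.Element(element).atomic_number == 0:
            raise CifParseError(f"unknown element symbol {element!r} for site {lab!r}")
        xyz, su_xyz = np.zeros(3), np.zeros(3)
        for i in range(3):
            xyz[i], su_xyz[i] = parse_su_number(row[2 + i])
        xyz %= 1.0
        u_iso, su_u = 0.02, 0.0
        if has_uiso and row[5] not in (".", "?"):
            u_iso, su_u = parse_su_number(row[5])
        occ = 1.0
        if has_occ and row[6] not in (".", "?"):
            occ, _ = parse_su_number(row[6])
        u_aniso = su_u_aniso = None
        if lab in aniso:
            u_aniso, su_u_aniso = aniso[lab]
        elif not has_uiso or not np.isfinite(u_iso):
            u_iso = 0.02
            logger.warning("site %s has no ADP; defaulting U_iso = 0.02 Å²", lab)
        site = AtomSite(lab, element, xyz, u_iso=u_iso, u_aniso=u_aniso,
                        occupancy=occ, su_xyz=su_xyz, su_u_iso=su_u,
                        su_u_aniso=su_u_aniso)
        sites.append(site)
    if not sites:
        raise CifParseError("empty _atom_site_ loop")

    zraw = _cif_get(block, "_cell_formula_units_Z")
    Z = int(float(zraw)) if zraw is not None else len(symops)

    struct = CrystalStructure(cell, symops, sites, space_group_name=sg_name, Z=Z)
    for s in struct.sites:
        s.site_multiplicity = len(struct.expand_site(s))
    return struct


# ---------------------------------------------------------------------------
# CIF writing
# ---------------------------------------------------------------------------

def format_su(value: float, su: float) -> str:
    """CIF parenthesised s.u. notation: (1.0440, 0.0012) → '1.0440(12)'."""
    if su <= 0 or not np.isfinite(su):
        return f"{float(value):.6f}".rstrip("0").rstrip(".") if value % 1 else str(int(value))
    # round su to 2 significant digits; 1 digit if leading digit >= 2
    exp = int(np.floor(np.log10(su)))
    lead = su / 10.0 ** exp
    ndig = 1 if lead >= 1.95 else 2
    su_r = round(su, -exp + ndig - 1)
    if su_r >= 10.0 ** (exp + ndig):  # rounding carried over
        exp += 1
        su_r = round(su, -exp + ndig - 1)
    dec = max(0, -(exp - ndig + 1))
    digits = int(round(su_r * 10 ** dec))
    return f"{value:.{dec}f}({digits})"


def write_cif_result(structure: CrystalStructure, result=None) -> str:
    """Emit a CIF document for a (refined) structure.

    ``result`` may be a RefinementResult carrying scale, R factors and
    refinement flags; coordinates and U^ij are printed with parenthesised
    standard uncertainties.
    """
    cell = structure.cell
    out = ["data_harkit", ""]
    out.append(f"_cell_length_a    {cell.a:.6f}")
    out.append(f"_cell_length_b    {cell.b:.6f}")
    out.append(f"_cell_length_c    {cell.c:.6f}")
    out.append(f"_cell_angle_alpha {cell.alpha:.6f}")
    out.append(f"_cell_angle_beta  {cell.beta:.6f}")
    out.append(f"_cell_angle_gamma {cell.gamma:.6f}")
    out.append(f"_cell_volume      {cell.volume:.6f}")
    out.append(f"_cell_formula_units_Z {structure.Z}")
    out.append(f"_symmetry_space_group_name_H-M '{structure.space_group_name}'")
    out.append("loop_")
    out.append("_symmetry_equiv_pos_as_xyz")
    for op in structure.symops:
        out.append(f"  '{op.triplet()}'")
    if result is not None:
        out.append("")
        out.append(f"_refine_ls_R_factor_gt        {result.r1:.6f}")
        out.append(f"_refine_ls_wR_factor_ref      {result.wr2:.6f}")
        out.append(f"_refine_ls_goodness_of_fit_ref {result.gof:.4f}")
        out.append(f"_refine_ls_number_reflns      {result.n_obs}")
        out.append(f"_refine_ls_number_parameters  {result.n_param}")
        out.append(f"_refine_ls_extinction_method  none")
        conv = "yes" if result.converged else "no"
        out.append(f"_harkit_refine_converged      {conv}")
        out.append("_harkit_refine_scale          "
                   + format_su(result.scale, result.scale_su))
    out.append("")
    out.append("loop_")
    for tag in ("label", "type_symbol", "fract_x", "fract_y", "fract_z",
                "U_iso_or_equiv", "occupancy"):
        out.append(f"_atom_site_{tag}")
    for s in structure.sites:
        xs = " ".join(format_su(s.xyz[i], s.su_xyz[i]) for i in range(3))
        out.append(f"  {s.label} {s.element} {xs} "
                   f"{format_su(s.u_iso, s.su_u_iso)} {s.occupancy:.4f}")
    aniso_sites = [s for s in structure.sites if s.is_anisotropic]
    if aniso_sites:
        out.append("")
        out.append("loop_")
        for tag in ("label", "U_11", "U_22", "U_33", "U_12", "U_13", "U_23"):
            out.append(f"_atom_site_aniso_{tag}")
        for s in aniso_sites:
            su = s.su_u_aniso if s.su_u_aniso is not None else np.zeros(6)
            us = " ".join(format_su(s.u_aniso[i], su[i]) for i in range(6))
            out.append(f"  {s.label} {us}")
    out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# Fragment growth
# ---------------------------------------------------------------------------

@dataclass
class FragmentAtom:
    """One atom of a grown fragment with its crystallographic provenance."""

    element: str
    pos: np.ndarray  # Cartesian Å
    parent: int  # index into structure.sites
    symop: SymOp
    shift: tuple = (0, 0, 0)  # lattice translation applied after symop

    def __post_init__(self):
        self.pos = np.asarray(self.pos, float)


@dataclass
class MoleculeFragment:
    """A connected chemical entity grown from the asymmetric unit."""

    atoms: list
    net_charge: int = 0
    spin_multiplicity: int = 1

    def __len__(self):
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms])

    @property
    def elements(self) -> list:
        return [a.element for a in self.atoms]

    def asu_atom_indices(self, structure: CrystalStructure) -> list:
        """Fragment index of the identity-op copy of each ASU site."""
        out = []
        for i in range(len(structure.sites)):
            found = None
            for j, a in enumerate(self.atoms):
                if a.parent == i and a.symop.is_identity and a.shift == (0, 0, 0):
                    found = j
                    break
            if found is None:
                for j, a in enumerate(self.atoms):
                    if a.parent == i:
                        found = j
                        break
            out.append(found)
        return out


def _bonded(el_a, pos_a, el_b, pos_b) -> bool:
    d = np.linalg.norm(pos_a - pos_b)
    return 0.3 < d < BOND_FACTOR * (covalent_radius(el_a) + covalent_radius(el_b))


def _gen_images(structure: CrystalStructure, trange=1):
    """All (symop, lattice shift) generators within ±trange cells."""
    shifts = [
        (i, j, k)
        for i in range(-trange, trange + 1)
        for j in range(-trange, trange + 1)
        for k in range(-trange, trange + 1)
    ]
    return [(op, sh) for op in structure.symops for sh in shifts]


def grow_fragment(
    structure: CrystalStructure,
    mode: str = "complete_molecules",
    radius: float = 0.0,
) -> MoleculeFragment:
    """Grow the chemical fragment used for the density calculation.

    ``complete_molecules`` applies symmetry operations and lattice translations
    until every molecule containing an asymmetric-unit atom is whole (bonds:
    d < 1.15 × covalent-radius sum, hydrogen at most one bond).
    ``radius_cluster`` additionally adds every whole molecule having any atom
    within ``radius`` Å of the core.  Each atom records its generating
    operation and lattice shift.
    """
    if mode not in ("complete_molecules", "radius_cluster"):
        raise ValueError("mode must be complete_molecules or radius_cluster")
    if mode == "radius_cluster" and radius < 0:
        raise ValueError("radius must be non-negative")

    cell = structure.cell
    atoms: list[FragmentAtom] = []
    for i, s in enumerate(structure.sites):
        if s.occupancy <= 0:
            logger.warning("site %s has zero occupancy; excluded from fragment", s.label)
            continue
        atoms.append(FragmentAtom(s.element, cell.frac_to_cart(s.xyz), i, SymOp.identity()))
    if not atoms:
        raise ValueError("no occupied sites to grow from")

    images = _gen_images(structure, trange=1)

    def hydrogen_bond_count(idx):
        n = 0
        for j, b in enumerate(atoms):
            if j != idx and _bonded(atoms[idx].element, atoms[idx].pos, b.element, b.pos):
                n += 1
        return n

    # iterative completion
    changed = True
    while changed:
        changed = False
        if len(atoms) > MAX_FRAGMENT_ATOMS:
            raise RuntimeError(
                "fragment growth exceeded 10^4 atoms; likely a covalent network "
                "— use radius_cluster with a smaller radius"
            )
        existing = np.array([a.pos for a in atoms])
        for op, sh in images:
            for i, s in enumerate(structure.sites):
                if s.occupancy <= 0:
                    continue
                xf = op.apply(s.xyz) + np.array(sh, float)
                xc = cell.frac_to_cart(xf)
                d = np.linalg.norm(existing - xc, axis=1)
                if np.min(d) < 0.1:
                    continue  # already present
                # bonded to any current atom?
                cand_bond = None
                for j in np.where(d < 2.6 * BOND_FACTOR)[0]:
                    if _bonded(s.element, xc, atoms[j].element, atoms[j].pos):
                        cand_bond = j
                        break
                if cand_bond is None:
                    continue
                if atoms[cand_bond].element == "H" and hydrogen_bond_count(cand_bond) >= 1:
                    # hydrogen keeps a single bond; never grow through a
                    # saturated H (blocks spurious H...H chains)
                    continue
                atoms.append(FragmentAtom(s.element, xc, i, op, sh))
                existing = np.vstack([existing, xc])
                changed = True

    frag = MoleculeFragment(atoms)

    if mode == "radius_cluster" and radius > 0:
        frag = _add_cluster_molecules(structure, frag, radius)
    return frag


def _molecule_components(frag: MoleculeFragment):
    """Connected components under the bond criterion."""
    n = len(frag.atoms)
    pos = frag.positions
    els = frag.elements
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if _bonded(els[i], pos[i], els[j], pos[j]):
                adj[i].append(j)
                adj[j].append(i)
    seen = np.zeros(n, bool)
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            a = stack.pop()
            comp.append(a)
            for b in adj[a]:
                if not seen[b]:
                    seen[b] = True
                    stack.append(b)
        comps.append(comp)
    return comps


def _add_cluster_molecules(structure, core: MoleculeFragment, radius: float):
    """Add every whole symmetry-image molecule within ``radius`` of the core."""
    cell = structure.cell
    comps = _molecule_components(core)
    core_pos = core.positions
    atoms = list(core.atoms)
    npos = [a.pos for a in atoms]

    # candidate lattice range from radius and cell size
    spans = np.linalg.norm(cell.M, axis=0)
    tr = int(np.ceil(radius / spans.min())) + 1
    added = 0
    for op in structure.symops:
        for sh in [(i, j, k)
                   for i in range(-tr, tr + 1)
                   for j in range(-tr, tr + 1)
                   for k in range(-tr, tr + 1)]:
            for comp in comps:
                newpos = []
                for idx in comp:
                    a = core.atoms[idx]
                    parent = structure.sites[a.parent]
                    base = a.symop.apply(parent.xyz) + np.array(a.shift, float)
                    xf = op.apply(base) + np.array(sh, float)
                    newpos.append(cell.frac_to_cart(xf))
                newpos = np.array(newpos)
                dmin = np.min(
                    np.linalg.norm(newpos[:, None, :] - core_pos[None, :, :], axis=-1)
                )
                if dmin < 1e-3:  # the core itself
                    continue
                if dmin > radius:
                    continue
                # skip if identical to an already-added molecule
                allpos = np.array(npos)
                dup = np.min(np.linalg.norm(
                    allpos[None, :, :] - newpos[:, None, :], axis=-1))
                if dup < 0.1:
                    continue
                for idx, p in zip(comp, newpos):
                    a = core.atoms[idx]
                    comb = op.compose(a.symop)
                    atoms.append(FragmentAtom(a.element, p, a.parent, comb, tuple(sh)))
                    npos.append(p)
                added += 1
                if len(atoms) > MAX_FRAGMENT_ATOMS:
                    raise RuntimeError(
                        "fragment growth exceeded 10^4 atoms; reduce the radius"
                    )
    if added == 0:
        logger.warning("radius_cluster found no neighbour molecules within %.2f Å", radius)
    return MoleculeFragment(atoms, net_charge=core.net_charge,
                            spin_multiplicity=core.spin_multiplicity)
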