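"""Periodic point sets and crystals.

A periodic point set is a finite motif of points in a unit cell, repeated
over all integer combinations of the cell's basis vectors (the lattice).
A periodic crystal additionally carries chemistry per motif point: element
symbol, atomic mass and occupancy.  The module also converts between cell
parameters (a, b, c, alpha, beta, gamma) and basis-vector form, applies
isometries, and reads/writes a minimal CIF dialect with symmetry-operator
expansion.

Conventions: lengths in angstroms, fractional coordinates wrapped to the
half-open interval [0, 1), basis vectors stored as matrix rows, and the
basis kept right-handed (positive determinant).
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._masses import atomic_mass

logger = logging.getLogger(__name__)

#: sites generated by symmetry closer than this (fractional, per axis) merge
MERGE_TOL = 1e-3


class InvalidCellError(ValueError):
    """Cell parameters or basis do not define a positive-volume cell."""


class CIFParseError(ValueError):
    """A CIF block could not be interpreted under the supported dialect."""


def wrap_frac(coords: np.ndarray) -> np.ndarray:
    """Wrap fractional coordinates into [0, 1)."""
    wrapped = coords - np.floor(coords)
    # floor can leave exactly 1.0 for tiny negative inputs
    wrapped[wrapped >= 1.0] -= 1.0
    return wrapped


@dataclass(frozen=True)
class UnitCell:
    """Parallelepiped spanned by n basis row-vectors (angstroms)."""

    basis: np.ndarray

    def __post_init__(self):
        basis = np.array(self.basis, dtype=float)
        if basis.ndim != 2 or basis.shape[0] != basis.shape[1]:
            raise InvalidCellError(f"basis must be square, got shape {basis.shape}")
        det = np.linalg.det(basis)
        if abs(det) < 1e-12 * float(np.prod(np.linalg.norm(basis, axis=1))):
            raise InvalidCellError("degenerate cell: volume is numerically zero")
        if det < 0:
            # reflections do not change any distance-based invariant, so a
            # row swap to restore right-handedness is always safe
            basis = basis[list(range(basis.shape[0] - 2)) + [-1, -2]]
        basis.flags.writeable = False
        object.__setattr__(self, "basis", basis)

    @property
    def dim(self) -> int:
        return self.basis.shape[0]

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.basis)))

    def parameters(self) -> tuple[float, float, float, float, float, float]:
        """Cell parameters (a, b, c, alpha, beta, gamma), lengths in A, angles in degrees.

        Only defined for 3D cells.
        """
        if self.dim != 3:
            raise ValueError("cell parameters are defined for 3D cells only")
        v = self.basis
        a, b, c = np.linalg.norm(v, axis=1)

        def angle(x, y):
            return math.degrees(math.acos(np.clip(np.dot(x, y) / (np.linalg.norm(x) * np.linalg.norm(y)), -1, 1)))

        return a, b, c, angle(v[1], v[2]), angle(v[0], v[2]), angle(v[0], v[1])


@dataclass(frozen=True)
class Motif:
    """Finite set of fractional points in the unit cell, wrapped to [0, 1)."""

    frac_coords: np.ndarray

    def __post_init__(self):
        coords = np.atleast_2d(np.array(self.frac_coords, dtype=float))
        if coords.shape[0] < 1:
            raise ValueError("motif must contain at least one point")
        coords = wrap_frac(coords)
        coords.flags.writeable = False
        object.__setattr__(self, "frac_coords", coords)

    @property
    def point_count(self) -> int:
        return self.frac_coords.shape[0]

    @property
    def dim(self) -> int:
        return self.frac_coords.shape[1]


@dataclass(frozen=True)
class PeriodicSet:
    """Geometry-only periodic point set: motif + lattice of the unit cell."""

    cell: UnitCell
    motif: Motif
    label: str = ""

    def __post_init__(self):
        if self.cell.dim != self.motif.dim:
            raise ValueError(
                f"cell dimension {self.cell.dim} != motif dimension {self.motif.dim}"
            )

    @property
    def dim(self) -> int:
        return self.cell.dim

    @property
    def m(self) -> int:
        return self.motif.point_count


@dataclass(frozen=True)
class PeriodicCrystal:
    """Periodic set plus per-point chemistry (element, mass, occupancy)."""

    geometry: PeriodicSet
    elements: tuple[str, ...]
    masses: tuple[float, ...]
    occupancies: tuple[float, ...] = field(default=())

    def __post_init__(self):
        m = self.geometry.m
        object.__setattr__(self, "elements", tuple(self.elements))
        object.__setattr__(self, "masses", tuple(float(x) for x in self.masses))
        occ = self.occupancies or tuple([1.0] * m)
        object.__setattr__(self, "occupancies", tuple(float(x) for x in occ))
        if not (len(self.elements) == len(self.masses) == len(self.occupancies) == m):
            raise ValueError("chemistry lists must match the motif size")
        if any(x <= 0 for x in self.masses):
            raise ValueError("atomic masses must be positive")
        if any(not (0 < x <= 1) for x in self.occupancies):
            raise ValueError("occupancies must lie in (0, 1]")

    @property
    def label(self) -> str:
        return self.geometry.label


# ---------------------------------------------------------------------------
# cell parameter conversion


def cell_from_parameters(a: float, b: float, c: float,
                         alpha: float, beta: float, gamma: float) -> UnitCell:
    """Build a 3D cell from lengths (A) and angles (degrees), standard setting.

    v1 lies along x, v2 in the xy-plane.  Raises :class:`InvalidCellError`
    when the angle combination cannot be realized by a positive-volume cell.
    """
    if min(a, b, c) <= 0:
        raise InvalidCellError("cell lengths must be positive")
    if not all(0 < x < 180 for x in (alpha, beta, gamma)):
        raise InvalidCellError("cell angles must lie in (0, 180) degrees")
    al, be, ga = (math.radians(x) for x in (alpha, beta, gamma))
    ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
    sg = math.sin(ga)
    # squared volume factor from the Gram determinant
    vol_term = 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg
    if vol_term <= 0:
        raise InvalidCellError(
            f"angles ({alpha}, {beta}, {gamma}) do not define a positive-volume cell"
        )
    basis = np.array([
        [a, 0.0, 0.0],
        [b * cg, b * sg, 0.0],
        [c * cb, c * (ca - cb * cg) / sg, c * math.sqrt(vol_term) / sg],
    ])
    return UnitCell(basis)


def to_cartesian(ps: PeriodicSet) -> np.ndarray:
    """Cartesian motif coordinates (m x n, angstroms)."""
    return ps.motif.frac_coords @ ps.cell.basis


def from_cartesian(cell: UnitCell, cart: np.ndarray) -> np.ndarray:
    """Fractional coordinates (wrapped) of Cartesian points in this cell."""
    return wrap_frac(np.atleast_2d(cart) @ np.linalg.inv(cell.basis))


def apply_isometry(ps: PeriodicSet, rotation: np.ndarray,
                   translation: np.ndarray) -> PeriodicSet:
    """Apply x -> x R^T + t to the whole periodic set.

    ``rotation`` may include a reflection; the basis is re-ordered to stay
    right-handed, which changes no distance-based invariant.
    """
    rotation = np.asarray(rotation, dtype=float)
    n = ps.dim
    if rotation.shape != (n, n) or not np.allclose(
            rotation @ rotation.T, np.eye(n), atol=1e-8):
        raise ValueError("rotation must be an orthogonal matrix")
    translation = np.asarray(translation, dtype=float).reshape(n)
    new_cell = UnitCell(ps.cell.basis @ rotation.T)
    cart = to_cartesian(ps) @ rotation.T + translation
    return PeriodicSet(new_cell, Motif(from_cartesian(new_cell, cart)), ps.label)


# ---------------------------------------------------------------------------
# symmetry expansion


def _parse_symop(text: str):
    """Parse an 'x,y,z'-style operator into (3x3 rotation, translation)."""
    import gemmi

    try:
        op = gemmi.Op(text)
    except Exception as exc:
        raise CIFParseError(f"unparseable symmetry operator: {text!r}") from exc
    rot = np.array(op.rot, dtype=float) / op.DEN
    tran = np.array(op.tran, dtype=float) / op.DEN
    return rot, tran


def expand_symmetry(frac: np.ndarray, operators: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Apply symmetry operators to fractional sites and merge duplicates.

    Returns (expanded fractional coordinates, index of the source site for
    each expanded point).  Generated positions within :data:`MERGE_TOL` per
    fractional axis (single linkage, periodic) are merged.
    """
    ops = [_parse_symop(s) for s in operators] or [(np.eye(frac.shape[1]), np.zeros(frac.shape[1]))]
    points, origin = [], []
    for i, site in enumerate(np.atleast_2d(frac)):
        for rot, tran in ops:
            p = wrap_frac((rot @ site + tran)[None, :])[0]
            # single-linkage merge against points generated so far
            dup = False
            for q in points:
                d = np.abs(p - q)
                if np.all(np.minimum(d, 1 - d) <= MERGE_TOL):
                    dup = True
                    break
            if not dup:
                points.append(p)
                origin.append(i)
    return np.array(points), np.array(origin)


# ---------------------------------------------------------------------------
# CIF reading / writing (minimal dialect)

_CELL_TAGS = ("_cell_length_a", "_cell_length_b", "_cell_length_c",
              "_cell_angle_alpha", "_cell_angle_beta", "_cell_angle_gamma")
_SYMOP_TAGS = ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz")


def _cif_number(raw: str) -> float:
    """Parse a CIF numeric value, dropping a parenthesised uncertainty."""
    return float(raw.split("(")[0])


def parse_cif(text: str, allow_partial: bool = False) -> list[PeriodicCrystal]:
    """Parse a CIF document into one :class:`PeriodicCrystal` per data block.

    Supported tags: the six cell parameters, ``_atom_site_fract_{x,y,z}``,
    ``_atom_site_type_symbol`` / ``_atom_site_label``,
    ``_atom_site_occupancy``, and either symmetry-operator loop.  A
    space-group symbol without an operator list is treated as P1 (with a
    warning).  Blocks containing occupancy < 1 are rejected unless
    ``allow_partial`` is set, in which case such sites are kept as full
    points with a warning.
    """
    import gemmi

    doc = gemmi.cif.read_string(text)
    crystals = []
    for block in doc:
        name = block.name or "<unnamed>"
        raw = [block.find_value(t) for t in _CELL_TAGS]
        if any(v is None for v in raw):
            missing = [t for t, v in zip(_CELL_TAGS, raw) if v is None]
            raise CIFParseError(f"block {name!r}: missing cell parameters {missing}")
        cell = cell_from_parameters(*(_cif_number(v) for v in raw))

        operators: list[str] = []
        for tag in _SYMOP_TAGS:
            col = block.find_loop(tag)
            if len(col) > 0:
                operators = [gemmi.cif.as_string(v) for v in col]
                break
            single = block.find_value(tag)
            if single is not None:
                operators = [gemmi.cif.as_string(single)]
                break
        if not operators:
            if block.find_value("_symmetry_space_group_name_H-M") or \
               block.find_value("_space_group_name_H-M_alt"):
                logger.warning(
                    "block %r: space-group symbol given without operators; treating as P1",
                    name)
            operators = ["x,y,z"]

        table = block.find("_atom_site_", ["fract_x", "fract_y", "fract_z"])
        if len(table) == 0:
            raise CIFParseError(f"block {name!r}: no _atom_site_ loop with fractional coordinates")
        sym_col = block.find_loop("_atom_site_type_symbol")
        lab_col = block.find_loop("_atom_site_label")
        occ_col = block.find_loop("_atom_site_occupancy")

        sites, symbols, occs = [], [], []
        for i, row in enumerate(table):
            sites.append([_cif_number(row[j]) for j in range(3)])
            if len(sym_col) > 0:
                symbols.append(gemmi.cif.as_string(sym_col[i]))
            elif len(lab_col) > 0:
                symbols.append(gemmi.cif.as_string(lab_col[i]))
            else:
                raise CIFParseError(f"block {name!r}: atom sites carry no element symbol or label")
            occs.append(_cif_number(occ_col[i]) if len(occ_col) > 0 else 1.0)

        bad_occ = [o for o in occs if o < 1.0]
        if bad_occ and not allow_partial:
            raise CIFParseError(
                f"block {name!r}: {len(bad_occ)} site(s) with occupancy < 1 "
                "(disordered); pass allow_partial=True to keep them as full points")
        if bad_occ:
            logger.warning("block %r: keeping %d partially occupied site(s) as full points",
                           name, len(bad_occ))

        masses = [atomic_mass(s) for s in symbols]
        frac, origin = expand_symmetry(np.array(sites, dtype=float), operators)
        geometry = PeriodicSet(cell, Motif(frac), label=name)
        crystals.append(PeriodicCrystal(
            geometry,
            elements=tuple(symbols[i] for i in origin),
            masses=tuple(masses[i] for i in origin),
            occupancies=tuple(occs[i] for i in origin),
        ))
    return crystals


def write_cif(crystal: PeriodicCrystal | PeriodicSet,
              default_element: str = "C") -> str:
    """Serialize to the CIF dialect (P1, explicit motif).

    A bare :class:`PeriodicSet` is written with ``default_element`` on every
    site so geometry fixtures round-trip through :func:`parse_cif`.  Only 3D
    structures can be written.
    """
    if isinstance(crystal, PeriodicSet):
        geometry = crystal
        elements = [default_element] * geometry.m
        occupancies = [1.0] * geometry.m
    else:
        geometry = crystal.geometry
        elements = list(crystal.elements)
        occupancies = list(crystal.occupancies)
    if geometry.dim != 3:
        raise ValueError("CIF output supports 3D structures only")
    a, b, c, al, be, ga = geometry.cell.parameters()
    buf = io.StringIO()
    name = geometry.label or "crystinv"
    buf.write(f"data_{name.replace(' ', '_')}\n")
    for tag, val in zip(_CELL_TAGS, (a, b, c, al, be, ga)):
        buf.write(f"{tag} {val:.12g}\n")
    buf.write("loop_\n_symmetry_equiv_pos_as_xyz\n'x, y, z'\n")
    buf.write("loop_\n_atom_site_label\n_atom_site_type_symbol\n"
              "_atom_site_fract_x\n_atom_site_fract_y\n_atom_site_fract_z\n"
              "_atom_site_occupancy\n")
    for i, (el, occ) in enumerate(zip(elements, occupancies)):
        x, y, z = (repr(float(v)) for v in geometry.motif.frac_coords[i])
        buf.write(f"{el}{i + 1} {el} {x} {y} {z} {occ:.6g}\n")
    return buf.getvalue()
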