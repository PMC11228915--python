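"""Isometry invariants of periodic point sets.

The central object is the pointwise distance distribution PDD(S; k): for
each motif point, its sorted distances to the k nearest neighbours in the
*infinite* periodic set (no cutoff radius, no restriction to a cell);
identical rows are collapsed and weighted, and the rows are put in
lexicographic order for a canonical form.  Derived invariants:

* AMD_k  — weighted average of the k-th column (average minimum distances),
* PPC    — point packing coefficient (Vol(U) / (m V_n))^(1/n), the
           asymptotic scale of AMD_k as k grows,
* ADA_k  — deviation of AMD_k from the asymptote PPC * k^(1/n) (angstroms),
* NDA_k  — ADA_k / PPC, unitless and scale-invariant.

All are invariant under isometries (rotations, translations, reflections)
and under re-description of the same set in a larger cell with a duplicated
motif, which makes them usable as continuous coordinates for crystals.

For crystals with chemistry, physical density rho (g/cm^3) and average
atomic mass ATM (u) are provided as map coordinates; at fixed composition
rho is proportional to ATM / PPC^3.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .periodic_model import PeriodicCrystal, PeriodicSet, to_cartesian

#: 1 u / A^3 in g/cm^3 (CODATA)
U_PER_A3_TO_G_PER_CM3 = 1.66053906660

DEFAULT_K = 100


@dataclass(frozen=True)
class NeighbourMatrix:
    """m x k matrix; row p holds d_1(p) <= ... <= d_k(p) in angstroms."""

    distances: np.ndarray
    k: int


@dataclass(frozen=True)
class PDDMatrix:
    """Weighted, canonicalized pointwise distance distribution."""

    weights: np.ndarray
    rows: np.ndarray
    k: int

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("PDD weights must sum to 1")


@dataclass(frozen=True)
class AMDVector:
    """AMD_1..AMD_k, nondecreasing, in angstroms."""

    values: np.ndarray

    @property
    def k(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class InvariantRecord:
    """Per-structure scalar and vector invariants used as map coordinates."""

    label: str
    ppc: float
    amd: np.ndarray
    ada: np.ndarray
    nda: np.ndarray
    density: float | None = None
    atm: float | None = None

    def coordinate(self, name: str) -> float:
        """Look up a named coordinate: 'density', 'ppc', 'atm', 'amd_3', ..."""
        base, _, idx = name.partition("_")
        if base in ("density", "ppc", "atm") and not idx:
            value = getattr(self, base)
            if value is None:
                raise KeyError(f"record {self.label!r} has no {base} (geometry-only)")
            return float(value)
        if base in ("amd", "ada", "nda") and idx:
            j = int(idx)
            vec = getattr(self, base)
            if not 1 <= j <= len(vec):
                raise KeyError(f"{name}: index out of range 1..{len(vec)}")
            return float(vec[j - 1])
        raise KeyError(f"unknown coordinate name: {name!r}")


# ---------------------------------------------------------------------------
# exact periodic k-nearest neighbours


def _min_perpendicular_width(basis: np.ndarray) -> float:
    """Smallest distance between opposite cell faces.

    A lattice vector with integer coefficients of L-infinity norm s has
    Cartesian length at least s times this width, which yields the exact
    termination bound for shell expansion.
    """
    n = basis.shape[0]
    vol = abs(np.linalg.det(basis))
    widths = []
    for i in range(n):
        others = np.delete(basis, i, axis=0)
        gram = others @ others.T
        face = math.sqrt(max(np.linalg.det(gram), 0.0)) if n > 1 else 1.0
        widths.append(vol / face if face > 0 else 0.0)
    return min(widths)


def _translate_points(cart: np.ndarray, basis: np.ndarray, shell: int) -> np.ndarray:
    """Motif copies under all lattice translates with |coeff|_inf <= shell."""
    rng = range(-shell, shell + 1)
    coeffs = np.array(list(itertools.product(rng, repeat=basis.shape[0])))
    shifts = coeffs @ basis
    return (cart[None, :, :] + shifts[:, None, :]).reshape(-1, cart.shape[1])


def knn_distances(ps: PeriodicSet, k: int) -> NeighbourMatrix:
    """Exact distances from each motif point to its k nearest neighbours in
    the infinite periodic set (the point itself excluded).

    Lattice translates are generated in growing L-infinity shells; expansion
    stops only when every point's k-th candidate distance is certified
    against the bound (shell+1) * min_width - max_motif_offset, so no cutoff
    radius is ever assumed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    basis = ps.cell.basis
    cart = to_cartesian(ps)
    m, n = cart.shape
    width = _min_perpendicular_width(basis)
    if width < 1e-12 * float(np.max(np.linalg.norm(basis, axis=1))):
        raise ValueError("degenerate cell: perpendicular width is numerically zero")
    # max Cartesian offset between home-cell motif points
    offset = float(cdist(cart, cart).max()) if m > 1 else 0.0

    shell = 1
    while (2 * shell + 1) ** n * m <= k:
        shell += 1
    while True:
        candidates = _translate_points(cart, basis, shell)
        dist = cdist(cart, candidates)
        # drop each point's zero self-distance, keep k smallest of the rest
        dist = np.sort(dist, axis=1)[:, 1:k + 1]
        if dist[:, -1].max() < (shell + 1) * width - offset:
            return NeighbourMatrix(distances=dist, k=k)
        shell += 1


# ---------------------------------------------------------------------------
# PDD / AMD / PPC / ADA / NDA


def _collapse_rows(distances: np.ndarray, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Group equal rows (tol=0: exact; else single linkage on L-inf <= tol)."""
    m = distances.shape[0]
    if tol == 0:
        uniq, inverse = np.unique(distances, axis=0, return_inverse=True)
        groups = [np.nonzero(inverse == g)[0] for g in range(uniq.shape[0])]
    else:
        # single-linkage connected components of the "L-inf <= tol" graph
        gaps = np.abs(distances[:, None, :] - distances[None, :, :]).max(axis=2)
        adjacency = gaps <= tol
        labels = np.full(m, -1)
        comp = 0
        for start in range(m):
            if labels[start] >= 0:
                continue
            stack = [start]
            labels[start] = comp
            while stack:
                node = stack.pop()
                for nb in np.nonzero(adjacency[node] & (labels < 0))[0]:
                    labels[nb] = comp
                    stack.append(nb)
            comp += 1
        groups = [np.nonzero(labels == g)[0] for g in range(comp)]
    weights = np.array([len(g) / m for g in groups])
    rows = np.array([distances[g].mean(axis=0) for g in groups])
    return weights, rows


#: default row-collapse tolerance (angstroms).  Symmetry-equivalent motif
#: points yield rows equal up to ~1e-15 of floating-point noise, so a strict
#: zero tolerance would fail to merge orbits; 1e-10 sits far above that noise
#: and far below any physically meaningful distance difference.
DEFAULT_COLLAPSE_TOL = 1e-10


def pdd(ps: PeriodicSet, k: int, collapse_tol: float = DEFAULT_COLLAPSE_TOL) -> PDDMatrix:
    """Pointwise distance distribution PDD(S; k), canonicalized.

    Rows of the neighbour matrix are collapsed into weighted groups (group
    weight = group size / m, representative = group mean) and sorted
    lexicographically.  ``collapse_tol=0`` demands bitwise-equal rows;
    positive tolerances merge single-linkage clusters of rows whose
    L-infinity gaps are within tolerance.
    """
    distances = knn_distances(ps, k).distances
    weights, rows = _collapse_rows(distances, collapse_tol)
    order = np.lexsort(rows.T[::-1])
    return PDDMatrix(weights=weights[order], rows=rows[order], k=k)


def amd(ps: PeriodicSet, k: int) -> AMDVector:
    """Average minimum distances AMD_1..AMD_k (weighted PDD column means)."""
    p = pdd(ps, k)
    return AMDVector(values=p.weights @ p.rows)


def unit_ball_volume(n: int) -> float:
    """Volume of the n-dimensional unit ball (2, pi, 4pi/3, ...)."""
    return math.pi ** (n / 2) / math.gamma(n / 2 + 1)


def ppc(ps: PeriodicSet) -> float:
    """Point packing coefficient (Vol(U) / (m V_n))^(1/n), in angstroms."""
    n = ps.dim
    return (ps.cell.volume / (ps.m * unit_ball_volume(n))) ** (1.0 / n)


def ada(ps: PeriodicSet, k: int) -> np.ndarray:
    """Average deviation from asymptotic: AMD_j - PPC * j^(1/n), angstroms."""
    n = ps.dim
    asymptote = ppc(ps) * np.arange(1, k + 1) ** (1.0 / n)
    return amd(ps, k).values - asymptote


def nda(ps: PeriodicSet, k: int) -> np.ndarray:
    """Normalized deviation from asymptotic: ADA / PPC, unitless and
    invariant under uniform scaling of the set."""
    return ada(ps, k) / ppc(ps)


def density_and_atm(crystal: PeriodicCrystal) -> tuple[float, float]:
    """Physical density rho (g/cm^3) and average atomic mass ATM (u).

    rho = mass(U) / Vol(U) converted via 1 u/A^3 = 1.66053906660 g/cm^3;
    ATM = mass(U) / m.  Both are intensive: re-describing the crystal in a
    bigger cell changes neither, and at fixed composition rho * PPC^3 is
    constant under uniform scaling (the cubic-hyperbola law on maps).
    """
    geometry = crystal.geometry
    cell_mass = float(sum(crystal.masses))
    density = cell_mass / geometry.cell.volume * U_PER_A3_TO_G_PER_CM3
    return density, cell_mass / geometry.m


def invariant_record(obj: PeriodicCrystal | PeriodicSet, k: int = DEFAULT_K) -> InvariantRecord:
    """All map-coordinate invariants of one structure."""
    if isinstance(obj, PeriodicCrystal):
        geometry = obj.geometry
        density, atm = density_and_atm(obj)
    else:
        geometry, density, atm = obj, None, None
    amd_vec = amd(geometry, k).values
    n = geometry.dim
    ada_vec = amd_vec - ppc(geometry) * np.arange(1, k + 1) ** (1.0 / n)
    return InvariantRecord(
        label=geometry.label, ppc=ppc(geometry),
        amd=amd_vec, ada=ada_vec, nda=ada_vec / ppc(geometry),
        density=density, atm=atm,
    )


# ---------------------------------------------------------------------------
# serialization


def records_to_csv(records: list[InvariantRecord]) -> str:
    """One structure per CSV row: label, ppc, density, atm, amd_*, ada_*, nda_*."""
    import pandas as pd

    rows = []
    for rec in records:
        row = {"label": rec.label, "ppc": rec.ppc,
               "density": rec.density, "atm": rec.atm}
        for name in ("amd", "ada", "nda"):
            for j, val in enumerate(getattr(rec, name), start=1):
                row[f"{name}_{j}"] = val
        rows.append(row)
    return pd.DataFrame(rows).to_csv(index=False)


def pdd_to_json(p: PDDMatrix) -> str:
    return json.dumps({"k": p.k, "weights": p.weights.tolist(),
                       "rows": p.rows.tolist()})


def pdd_from_json(text: str) -> PDDMatrix:
    data = json.loads(text)
    return PDDMatrix(weights=np.array(data["weights"]),
                     rows=np.array(data["rows"]), k=data["k"])
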