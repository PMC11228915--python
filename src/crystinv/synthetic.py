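"""Synthetic periodic sets: named lattices, random sets, perturbations.

These generators provide every geometry the rest of the package is tested
against, without external data: the classical 2D/3D lattices, random cells
with rejection-sampled motifs, bounded pointwise perturbations (the setting
of the Lipschitz guarantee EMD <= 2*epsilon), and the worked square-lattice
example in which a 0.1 perturbation of alternating columns quadruples the
primitive cell while every nearest-neighbour distance stays inside
[0.8, 1.2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .periodic_model import (Motif, PeriodicSet, UnitCell, from_cartesian,
                             to_cartesian)

LATTICE_NAMES = ("square", "hexagonal2d", "cubic-sc", "cubic-bcc",
                 "cubic-fcc", "hexagonal3d")


@dataclass(frozen=True)
class PerturbationSpec:
    """Bounded displacement of every motif point."""

    epsilon: float
    mode: str = "uniform-ball"  # or "cell-extension"
    seed: int = 0

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.mode not in ("uniform-ball", "cell-extension"):
            raise ValueError(f"unknown perturbation mode: {self.mode!r}")


def make_lattice(name: str, a: float = 1.0) -> PeriodicSet:
    """Standard cell and motif for a named lattice.

    One motif point except bcc (conventional cubic cell, m=2) and fcc
    (conventional cubic cell, m=4).
    """
    if a <= 0:
        raise ValueError("lattice parameter must be positive")
    s32 = math.sqrt(3) / 2
    if name == "square":
        basis, motif = np.eye(2), [[0, 0]]
    elif name == "hexagonal2d":
        basis, motif = [[1, 0], [-0.5, s32]], [[0, 0]]
    elif name == "cubic-sc":
        basis, motif = np.eye(3), [[0, 0, 0]]
    elif name == "cubic-bcc":
        basis, motif = np.eye(3), [[0, 0, 0], [0.5, 0.5, 0.5]]
    elif name == "cubic-fcc":
        basis = np.eye(3)
        motif = [[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]]
    elif name == "hexagonal3d":
        basis, motif = [[1, 0, 0], [-0.5, s32, 0], [0, 0, 1]], [[0, 0, 0]]
    else:
        raise ValueError(f"unknown lattice name: {name!r} (choose from {LATTICE_NAMES})")
    return PeriodicSet(UnitCell(a * np.array(basis, dtype=float)),
                       Motif(np.array(motif, dtype=float)), label=name)


def random_periodic_set(n: int, m: int, seed: int) -> PeriodicSet:
    """Random periodic set: cell lengths uniform in [1, 3] A, angles in
    [60, 120] degrees, m fractional points with pairwise (periodic)
    Cartesian separation >= 0.3 A by rejection sampling."""
    if n not in (2, 3):
        raise ValueError("dimension must be 2 or 3")
    if m < 1:
        raise ValueError("motif size must be >= 1")
    rng = np.random.default_rng(seed)
    while True:
        lengths = rng.uniform(1, 3, size=n)
        angles = rng.uniform(60, 120, size=n * (n - 1) // 2)
        if n == 2:
            g = math.radians(angles[0])
            basis = np.array([[lengths[0], 0],
                              [lengths[1] * math.cos(g), lengths[1] * math.sin(g)]])
        else:
            from .periodic_model import cell_from_parameters
            try:
                basis = cell_from_parameters(*lengths, *angles).basis
            except ValueError:
                continue
        if abs(np.linalg.det(basis)) > 0.1 * float(np.prod(lengths)):
            break
    cell = UnitCell(basis)

    neighbour_shifts = np.array(
        np.meshgrid(*([[-1, 0, 1]] * n))).T.reshape(-1, n) @ cell.basis
    points: list[np.ndarray] = []
    for _ in range(10_000):
        if len(points) == m:
            break
        cand = rng.uniform(0, 1, size=n)
        cand_cart = cand @ cell.basis
        ok = True
        for q in points:
            sep = np.linalg.norm(cand_cart - (q @ cell.basis) + neighbour_shifts, axis=1)
            if sep.min() < 0.3:
                ok = False
                break
        if ok:
            points.append(cand)
    if len(points) < m:
        raise RuntimeError(
            f"could not place {m} points at >= 0.3 A separation; try smaller m")
    return PeriodicSet(cell, Motif(np.array(points)), label=f"rand-n{n}-m{m}-s{seed}")


def supercell(ps: PeriodicSet, reps: tuple[int, ...]) -> PeriodicSet:
    """Re-describe the same periodic set in a reps[0] x ... x reps[-1]
    supercell with a duplicated motif.  The point set is unchanged, so every
    isometry invariant must be unchanged too."""
    if len(reps) != ps.dim or any(r < 1 for r in reps):
        raise ValueError(f"reps must be {ps.dim} positive integers")
    reps_arr = np.array(reps)
    basis = ps.cell.basis * reps_arr[:, None]
    shifts = np.array(list(np.ndindex(*reps)))
    frac = ((ps.motif.frac_coords[None, :, :] + shifts[:, None, :])
            / reps_arr).reshape(-1, ps.dim)
    return PeriodicSet(UnitCell(basis), Motif(frac), label=ps.label + "-super")


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """Uniform point in the n-ball: uniform direction, radius ~ U^(1/n)."""
    direction = rng.normal(size=n)
    direction /= np.linalg.norm(direction)
    return direction * radius * rng.uniform() ** (1.0 / n)


def perturb(ps: PeriodicSet, spec: PerturbationSpec) -> PeriodicSet:
    """Perturb a periodic set per the spec.

    uniform-ball: every motif point displaced by an independent uniform
    vector of norm <= epsilon; the cell is unchanged.  cell-extension: the
    motif is duplicated into a doubled cell along the first axis, then one
    single copy of the first atom is displaced by epsilon — the minimal
    construction that makes the extended cell primitive while moving no
    point farther than epsilon.
    """
    rng = np.random.default_rng(spec.seed)
    eps = spec.epsilon
    if spec.mode == "uniform-ball":
        cart = to_cartesian(ps)
        moved = cart + np.array([_uniform_ball(rng, ps.dim, eps) for _ in cart])
        return PeriodicSet(ps.cell, Motif(from_cartesian(ps.cell, moved)),
                           label=ps.label + "-pert")
    # cell-extension
    basis = ps.cell.basis.copy()
    basis[0] *= 2
    frac = ps.motif.frac_coords.copy()
    frac[:, 0] /= 2
    frac = np.vstack([frac, frac + np.eye(1, ps.dim, 0)[0] * 0.5])
    cell = UnitCell(basis)
    cart = frac @ basis
    cart[0] += _uniform_ball(rng, ps.dim, eps) if eps > 0 else 0.0
    return PeriodicSet(cell, Motif(from_cartesian(cell, cart)),
                       label=ps.label + "-ext")


def fig5_set() -> tuple[PeriodicSet, PeriodicSet]:
    """Unit square lattice and its alternating-column perturbation.

    S has points at all integer (x, y).  In S', for even x only, each
    vertical pair (y=2j, y=2j+1) is pushed apart by 0.1 at each end; odd
    columns are untouched.  The primitive cell grows from area 1 to a 2x2
    cell with a 4-point motif, yet every k=4 neighbour distance stays in
    [0.8, 1.2] and the two orbit rows of PDD(S'; 4) carry weight 1/2 each.
    """
    square = make_lattice("square", 1.0)
    cell = UnitCell(2.0 * np.eye(2))
    cart = np.array([
        [0.0, -0.1],   # even column, lower point moved down
        [0.0, 1.1],    # even column, upper point moved up
        [1.0, 0.0],    # odd column, untouched
        [1.0, 1.0],
    ])
    perturbed = PeriodicSet(cell, Motif(from_cartesian(cell, cart)),
                            label="square-fig5")
    return square, perturbed
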