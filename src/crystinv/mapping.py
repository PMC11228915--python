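"""Continuous invariant-coordinate maps of crystal collections.

Every crystal gets a point in a plane of two isometry-invariant coordinates
(physical density, PPC, AMD_j, ADA_j, NDA_j ...), so a whole collection
becomes a 2D density heatmap — a geographic-style map of structure space in
which near-duplicates land at the same spot and new structures appear at
new spots without disturbing known ones.  Unlike stochastic embeddings,
these projections are deterministic and independent of the input order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .invariants import DEFAULT_K, InvariantRecord, invariant_record
from .periodic_model import PeriodicCrystal

logger = logging.getLogger(__name__)

#: density clip used by the published CSD maps when plotting (rho, .) planes
DENSITY_CLIP_G_CM3 = 4.5


@dataclass(frozen=True)
class MapSpec:
    """Axes, ranges and binning of one invariant-coordinate map."""

    x_coord: str
    y_coord: str
    bins: tuple[int, int] = (512, 512)
    x_range: tuple[float, float] | None = None
    y_range: tuple[float, float] | None = None
    scale: str = "log-count"

    def __post_init__(self):
        if self.bins[0] < 1 or self.bins[1] < 1:
            raise ValueError("bins must be >= 1")
        for rng in (self.x_range, self.y_range):
            if rng is not None and not rng[0] < rng[1]:
                raise ValueError(f"range must be increasing, got {rng}")
        if self.scale not in ("linear", "log-count"):
            raise ValueError(f"unknown scale: {self.scale!r}")


@dataclass(frozen=True)
class MapRaster:
    """Binned counts plus the number of records falling outside the ranges."""

    counts: np.ndarray
    x_edges: np.ndarray
    y_edges: np.ndarray
    n_clipped: int
    spec: MapSpec = field(repr=False, default=None)


def coordinate_table(crystals: list[PeriodicCrystal], k: int = DEFAULT_K) -> list[InvariantRecord]:
    """Invariant records for a collection; per-crystal failures are logged
    and skipped, never fatal."""
    records = []
    for crystal in crystals:
        try:
            records.append(invariant_record(crystal, k))
        except Exception:
            logger.exception("skipping structure %r", crystal.label)
    return records


def rasterize(records: list[InvariantRecord], spec: MapSpec) -> MapRaster:
    """Bin records on the spec's coordinate plane.

    Bins follow the half-open convention [edge_i, edge_{i+1}); records
    outside the ranges are counted in ``n_clipped`` so that
    sum(counts) + n_clipped equals the number of records.
    """
    xs = np.array([r.coordinate(spec.x_coord) for r in records])
    ys = np.array([r.coordinate(spec.y_coord) for r in records])
    nx, ny = spec.bins

    def edges(values, rng, nbins):
        if rng is None:
            lo = float(values.min()) if len(values) else 0.0
            hi = float(values.max()) if len(values) else 1.0
            if lo == hi:
                lo, hi = lo - 0.5, hi + 0.5
            # widen the top so the max value falls inside the half-open grid
            hi = np.nextafter(hi, np.inf)
            rng = (lo, hi)
        if rng[0] >= rng[1]:
            raise ValueError("zero-width range")
        return np.linspace(rng[0], rng[1], nbins + 1)

    x_edges = edges(xs, spec.x_range, nx)
    y_edges = edges(ys, spec.y_range, ny)
    counts = np.zeros((nx, ny), dtype=int)
    n_clipped = 0
    if len(records):
        ix = np.searchsorted(x_edges, xs, side="right") - 1
        iy = np.searchsorted(y_edges, ys, side="right") - 1
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(counts, (ix[inside], iy[inside]), 1)
        n_clipped = int((~inside).sum())
    return MapRaster(counts=counts, x_edges=x_edges, y_edges=y_edges,
                     n_clipped=n_clipped, spec=spec)


_UNITS = {"density": "g/cm$^3$", "ppc": "Å", "amd": "Å",
          "ada": "Å", "nda": "", "atm": "u"}


def _axis_label(name: str) -> str:
    unit = _UNITS.get(name.partition("_")[0], "")
    return f"{name} ({unit})" if unit else name


def render(raster: MapRaster, out_path: str,
           overlay: list[tuple[float, float]] | None = None) -> None:
    """Write the heatmap (and optional scatter overlay) as a PNG.

    Colour is log(1 + count) by default so dense regions and sparse tails
    are both visible; overlay points outside the ranges are clipped by the
    axes, not an error.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    spec = raster.spec
    grid = raster.counts.T.astype(float)
    if spec is None or spec.scale == "log-count":
        grid = np.log1p(grid)
    fig, ax = plt.subplots(figsize=(6, 5))
    mesh = ax.pcolormesh(raster.x_edges, raster.y_edges, grid,
                         cmap="inferno", shading="flat", rasterized=True)
    fig.colorbar(mesh, ax=ax, label="log(1 + count)"
                 if spec is None or spec.scale == "log-count" else "count")
    if overlay:
        pts = np.asarray(overlay, dtype=float)
        ax.scatter(pts[:, 0], pts[:, 1], s=8, c="cyan", edgecolors="none",
                   zorder=3)
        ax.set_xlim(raster.x_edges[0], raster.x_edges[-1])
        ax.set_ylim(raster.y_edges[0], raster.y_edges[-1])
    if spec is not None:
        ax.set_xlabel(_axis_label(spec.x_coord))
        ax.set_ylabel(_axis_label(spec.y_coord))
    fig.savefig(out_path, dpi=150, metadata={"Software": None})
    plt.close(fig)
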