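"""Cross-geometry comparison metrics.

Vessel line density ``rho`` (length per unit volume, um^-2) and migrating
tip density ``n`` (count per unit volume, um^-3) are deposited on a
structured axis-aligned grid, smoothed with two Gaussian passes to reduce
discrete-sampling noise, averaged over grid cells equidistant from the
limbus, and summarised by:

* location of the maximum density,
* location of half-maximum density (outermost crossing, interpolated),
* the vascular front ``d_front``: outermost location with 1% of the
  maximum density — the 'distance to limbus' reported for the assay,
* maximum densities, and
* the vascularized fraction: the volume fraction of in-tissue grid cells
  containing any vessel (computed from the raw, unsmoothed occupancy).

2D domains use cell volume = area x cornea thickness so that densities are
directly comparable between 2D and 3D representations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import TissueDomain
from .network import VesselNetwork

__all__ = [
    "DensityGrid",
    "DensityProfile",
    "FrontMetrics",
    "smooth",
    "profile",
    "front_metrics",
    "vascularized_fraction",
    "network_metrics",
]

DEFAULT_SPACING = 40.0  # um
SMOOTH_SIGMA_CELLS = 1.0
SMOOTH_RADIUS_CELLS = 2


class DensityGrid:
    """Structured axis-aligned grid covering a tissue domain's bounding box.

    Carries the cell -> limbus-distance map and the in-tissue mask used for
    profile averaging and the vascularized fraction.
    """

    def __init__(self, domain: TissueDomain, spacing: float = DEFAULT_SPACING):
        if spacing <= 0:
            raise ValueError("grid spacing must be positive")
        self.domain = domain
        self.spacing = float(spacing)
        lo, hi = domain.bounding_box()
        self.origin = lo
        extent = hi - lo
        shape = np.maximum(np.ceil(extent / spacing - 1e-9).astype(int), 1)
        if domain.is_2d:
            shape[2] = 1
        self.shape = tuple(shape)
        if domain.is_2d:
            self.cell_volume = spacing**2 * domain.thickness
        else:
            self.cell_volume = spacing**3
        centers = [
            lo[d] + (np.arange(self.shape[d]) + 0.5) * spacing for d in range(3)
        ]
        if domain.is_2d:
            centers[2] = np.zeros(1)
        cx, cy, cz = np.meshgrid(*centers, indexing="ij")
        self.cell_centers = np.column_stack([cx.ravel(), cy.ravel(), cz.ravel()])
        self.in_domain = domain.contains(self.cell_centers).reshape(self.shape)
        self.xi = domain.limbus_distance(self.cell_centers).reshape(self.shape)


@dataclass
class DensityProfile:
    """Limbus-equidistant averages: bin centres ``xi`` with mean tip and
    line densities; ``cells`` counts the contributing grid cells per bin
    (zero marks an empty bin)."""

    xi: np.ndarray
    n: np.ndarray
    rho: np.ndarray
    cells: np.ndarray


@dataclass
class FrontMetrics:
    """Scalar summary of a density profile (all locations in um)."""

    d_front: float
    xi_max: float
    xi_halfmax: float
    max_density: float


def _kernel(ndim: int):
    k = np.arange(-SMOOTH_RADIUS_CELLS, SMOOTH_RADIUS_CELLS + 1)
    g = np.exp(-0.5 * (k / SMOOTH_SIGMA_CELLS) ** 2)
    g /= g.sum()
    out = g
    for _ in range(ndim - 1):
        out = np.multiply.outer(out, g)
    return out


def smooth(field: np.ndarray, passes: int = 2) -> np.ndarray:
    """Gaussian smoothing (SD one cell, truncated at two cells) with exact
    total conservation: near array boundaries each cell's mass is
    redistributed over the truncated in-grid kernel support."""
    field = np.asarray(field, dtype=float)
    if (field < 0).any():
        raise ValueError("density fields must be non-negative")
    squeeze2d = field.ndim == 3 and field.shape[2] == 1
    work = field[:, :, 0] if squeeze2d else field
    ker = _kernel(work.ndim)
    w = ndimage.convolve(np.ones_like(work), ker, mode="constant")
    for _ in range(passes):
        work = ndimage.convolve(work / w, ker, mode="constant")
    return work[:, :, None] if squeeze2d else work


def profile(grid: DensityGrid, rho: np.ndarray, n: np.ndarray) -> DensityProfile:
    """Average the density fields over in-tissue cells equidistant from the
    limbus (bin width = grid spacing)."""
    h = grid.spacing
    mask = grid.in_domain.ravel()
    xi = grid.xi.ravel()[mask]
    rho_v = np.asarray(rho).ravel()[mask]
    n_v = np.asarray(n).ravel()[mask]
    nbins = int(np.floor(grid.xi.max() / h)) + 1
    idx = np.clip(np.floor(xi / h).astype(int), 0, nbins - 1)
    counts = np.bincount(idx, minlength=nbins)
    sum_rho = np.bincount(idx, weights=rho_v, minlength=nbins)
    sum_n = np.bincount(idx, weights=n_v, minlength=nbins)
    denom = np.maximum(counts, 1)
    return DensityProfile(
        xi=(np.arange(nbins) + 0.5) * h,
        n=sum_n / denom,
        rho=sum_rho / denom,
        cells=counts,
    )


def front_metrics(xi: np.ndarray, density: np.ndarray) -> FrontMetrics | None:
    """Locations of maximum, half-maximum and 1%-of-maximum density.

    Threshold crossings use linear interpolation between bin centres and
    take the outermost (largest xi) crossing. Returns None for an all-zero
    profile."""
    xi = np.asarray(xi, dtype=float)
    d = np.asarray(density, dtype=float)
    peak = d.max() if len(d) else 0.0
    if peak <= 0:
        return None
    i_max = int(np.argmax(d))
    return FrontMetrics(
        d_front=_outermost_crossing(xi, d, 0.01 * peak),
        xi_max=float(xi[i_max]),
        xi_halfmax=_outermost_crossing(xi, d, 0.5 * peak),
        max_density=float(peak),
    )


def _outermost_crossing(xi, d, thr) -> float:
    above = np.flatnonzero(d >= thr)
    i = int(above[-1])
    if i == len(d) - 1:
        return float(xi[i])
    x0, x1 = xi[i], xi[i + 1]
    y0, y1 = d[i], d[i + 1]
    return float(x0 + (x1 - x0) * (y0 - thr) / (y0 - y1))


def vascularized_fraction(network: VesselNetwork, grid: DensityGrid) -> float:
    """Fraction of in-tissue grid cells occupied by any vessel (raw,
    unsmoothed line density)."""
    rho, _ = network.density_fields(grid)
    mask = grid.in_domain
    total = int(mask.sum())
    if total == 0:
        return 0.0
    occupied = int(((rho > 0) & mask).sum())
    return occupied / total


def network_metrics(
    network: VesselNetwork,
    grid: DensityGrid,
    passes: int = 2,
) -> dict:
    """Full metric suite for one network snapshot.

    Returns a dict with the smoothed tip/line profiles and, for each of the
    two density fields, the front-location summary, plus the vascularized
    fraction (computed from the unsmoothed occupancy)."""
    rho_raw, n_raw = network.density_fields(grid)
    rho_s = smooth(rho_raw, passes)
    n_s = smooth(n_raw, passes)
    prof = profile(grid, rho_s, n_s)
    tip = front_metrics(prof.xi, prof.n)
    line = front_metrics(prof.xi, prof.rho)
    frac = vascularized_fraction(network, grid)
    return {
        "profile": prof,
        "tip": tip,
        "line": line,
        "vascularized_fraction": frac,
        "max_tip_density": tip.max_density if tip else 0.0,
        "max_line_density": line.max_density if line else 0.0,
    }
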