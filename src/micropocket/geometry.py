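"""Tissue domains for the corneal micropocket assay.

Seven parametric cornea-pellet configurations are supported, spanning the
representations commonly used in silico and in vitro (planar strips and
discs, with and without thickness, with extended or finite pellets) up to a
spatially resolved hemispherical cornea:

========================  ==========================================================
kind                      description
========================  ==========================================================
``planar_2d``             rectangle W x H, zero thickness, pellet spans full width
``planar_2d_finite``      rectangle, pellet of width 2*r_p centred laterally
``planar_3d``             box W x H x T, extended pellet
``planar_3d_finite``      box, finite pellet slab of width 2*r_p and thickness T_p
``circle_2d``             disc of radius R, resolved pellet disc
``circle_3d``             cylinder (disc x T), resolved pellet cylinder
``hemisphere``            spherical shell (radii R-T..R, z >= 0), resolved pellet
========================  ==========================================================

Conventions
-----------
All coordinates are Cartesian micrometres. 2D domains are embedded in the
``z = 0`` plane. The limbus (base of the cornea, origin of sprouting) is the
``y = 0`` edge for planar domains, the outer rim for circles and the
equatorial circle for the hemisphere. ``limbus_distance`` returns the
coordinate ``xi`` measured from the limbus toward the pellet: the axial
coordinate (planar), ``R - r`` (circle), or the geodesic arc length
``R * (pi/2 - theta)`` along the mid-surface (hemisphere, ``theta`` the polar
angle from the pole).

The pellet's near interface sits at limbus distance ``h + eps`` in planar and
circular domains (with the default parameters this places the pellet exactly
at the centre of the circular domains and flush with the far edge of the
planar ones). In the hemisphere the pellet centre is placed so that its
top-down 2D-projected height above the limbus equals ``h``, i.e. at polar
angle ``theta_c`` with ``sin(theta_c) = 1 - h/R``, as it would be measured
from an experimental image.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay

__all__ = [
    "DomainKind",
    "GeometryParams",
    "TissueDomain",
    "Mesh",
    "build_domain",
    "OUTER",
    "PELLET",
]

# boundary facet tags
OUTER = 1   # outer cornea surface: no-flux
PELLET = 2  # cornea-pellet interface: Robin flux

_TOL = 1e-6


class DomainKind(str, enum.Enum):
    PLANAR_2D = "planar_2d"
    PLANAR_2D_FINITE = "planar_2d_finite"
    PLANAR_3D = "planar_3d"
    PLANAR_3D_FINITE = "planar_3d_finite"
    CIRCLE_2D = "circle_2d"
    CIRCLE_3D = "circle_3d"
    HEMISPHERE = "hemisphere"


_2D_KINDS = {DomainKind.PLANAR_2D, DomainKind.PLANAR_2D_FINITE, DomainKind.CIRCLE_2D}
_PLANAR_KINDS = {
    DomainKind.PLANAR_2D,
    DomainKind.PLANAR_2D_FINITE,
    DomainKind.PLANAR_3D,
    DomainKind.PLANAR_3D_FINITE,
}
_FINITE_PELLET_PLANAR = {DomainKind.PLANAR_2D_FINITE, DomainKind.PLANAR_3D_FINITE}


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the cornea-pellet system (all lengths in micrometres).

    Defaults follow the reference mouse cornea parameterisation: cornea
    radius ``R`` = 1300, thickness ``T`` = 100, pellet radius ``r_p`` = 200,
    pellet thickness ``T_p`` = 40, pellet height ``h`` = 1000 above the
    limbus and initial-vessel offset ``eps`` = 100.
    """

    kind: DomainKind = DomainKind.HEMISPHERE
    R: float = 1300.0
    T: float = 100.0
    h: float = 1000.0
    eps: float = 100.0
    r_p: float = 200.0
    T_p: float = 40.0
    W: float = 2000.0
    H: float = 1500.0

    def __post_init__(self):
        object.__setattr__(self, "kind", DomainKind(self.kind))
        for name in ("R", "T", "h", "eps", "r_p", "T_p", "W", "H"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.T_p > self.T:
            raise ValueError("pellet thickness T_p must not exceed cornea thickness T")
        if self.eps >= self.h:
            raise ValueError("initial-vessel offset eps must be smaller than pellet height h")
        k = self.kind
        if k in _FINITE_PELLET_PLANAR and self.h + self.eps + 2 * self.r_p > self.H + _TOL:
            raise ValueError("pellet does not fit: h + eps + 2*r_p exceeds domain extent H")
        if k in _PLANAR_KINDS and self.h + self.eps >= self.H:
            raise ValueError("pellet interface h + eps lies outside the planar domain")
        if k in (DomainKind.CIRCLE_2D, DomainKind.CIRCLE_3D):
            if self.h + self.eps + self.r_p > self.R + _TOL:
                raise ValueError("pellet does not fit inside the circular domain")
        if k is DomainKind.HEMISPHERE and self.h >= self.R:
            raise ValueError("hemisphere pellet height h must be smaller than R")

    @property
    def w(self) -> float:
        """Pellet width: full domain width for extended pellets, 2*r_p otherwise."""
        if self.kind in (DomainKind.PLANAR_2D, DomainKind.PLANAR_3D):
            return self.W
        return 2.0 * self.r_p

    @property
    def is_2d(self) -> bool:
        return self.kind in _2D_KINDS


def build_domain(params: GeometryParams, resolve_pellet: bool = False) -> "TissueDomain":
    """Construct a tissue domain; ``resolve_pellet`` excludes the pellet
    interior from the tissue (used with the dynamic VEGF model)."""
    return TissueDomain(params, resolve_pellet=resolve_pellet)


class TissueDomain:
    """One of the seven cornea-pellet configurations.

    Answers vectorised point-membership, repulsive-boundary-distance and
    limbus-coordinate queries and generates tagged finite-element meshes.
    All point arrays are ``(n, 3)`` in micrometres.
    """

    def __init__(self, params: GeometryParams, resolve_pellet: bool = False):
        self.params = params
        self.resolve_pellet = bool(resolve_pellet)
        p = params
        self.kind = p.kind
        self.is_2d = p.is_2d
        # mid-thickness plane / surface
        self.z_mid = 0.0 if self.is_2d else p.T / 2.0
        if p.kind is DomainKind.HEMISPHERE:
            # pellet centre on the mid-surface, at polar angle theta_c such
            # that the top-down projected height R - r_mid*sin(theta_c) of
            # the centre itself equals h (as measured in assay images)
            r_mid = p.R - p.T / 2.0
            self._theta_c = float(np.arcsin((p.R - p.h) / r_mid))
            ax = np.array([np.sin(self._theta_c), 0.0, np.cos(self._theta_c)])
            self.pellet_axis = ax
            self.pellet_centre = r_mid * ax
        elif p.kind in (DomainKind.CIRCLE_2D, DomainKind.CIRCLE_3D):
            self.pellet_centre = np.array([p.R - (p.h + p.eps + p.r_p), 0.0, self.z_mid])
            self.pellet_axis = np.array([0.0, 0.0, 1.0])
        else:
            # planar: slab with near face at y = h + eps
            self.pellet_centre = np.array([p.W / 2.0, p.h + p.eps + p.r_p, self.z_mid])
            self.pellet_axis = np.array([0.0, 0.0, 1.0])

    # ------------------------------------------------------------------ helpers

    def _as_points(self, p) -> np.ndarray:
        q = np.atleast_2d(np.asarray(p, dtype=float))
        if q.shape[1] == 2:
            q = np.hstack([q, np.zeros((len(q), 1))])
        return q

    def in_pellet(self, p) -> np.ndarray:
        """True where points lie strictly inside the pellet region."""
        q = self._as_points(p)
        par = self.params
        k = par.kind
        if k in _PLANAR_KINDS:
            y0 = par.h + par.eps
            m = (q[:, 1] > y0) & (q[:, 1] < y0 + 2 * par.r_p)
            if k in _FINITE_PELLET_PLANAR:
                m &= np.abs(q[:, 0] - par.W / 2.0) < par.r_p
                if k is DomainKind.PLANAR_3D_FINITE:
                    z0 = (par.T - par.T_p) / 2.0
                    m &= (q[:, 2] > z0) & (q[:, 2] < z0 + par.T_p)
            return m
        if k in (DomainKind.CIRCLE_2D, DomainKind.CIRCLE_3D):
            d2 = (q[:, 0] - self.pellet_centre[0]) ** 2 + (q[:, 1] - self.pellet_centre[1]) ** 2
            m = d2 < par.r_p**2
            if k is DomainKind.CIRCLE_3D:
                z0 = (par.T - par.T_p) / 2.0
                m &= (q[:, 2] > z0) & (q[:, 2] < z0 + par.T_p)
            return m
        # hemisphere: cylinder about the local radial axis
        rel = q - self.pellet_centre
        ax = rel @ self.pellet_axis
        rad2 = np.einsum("ij,ij->i", rel, rel) - ax**2
        return (np.abs(ax) < par.T_p / 2.0) & (rad2 < par.r_p**2)

    # --------------------------------------------------------------- membership

    def contains(self, p, tol: float = 1e-9) -> np.ndarray:
        """True iff points are inside the cornea tissue.

        When the pellet is resolved (dynamic VEGF model) its interior does
        not count as tissue.
        """
        q = self._as_points(p)
        par = self.params
        k = par.kind
        if k in _PLANAR_KINDS:
            m = (
                (q[:, 0] >= -tol)
                & (q[:, 0] <= par.W + tol)
                & (q[:, 1] >= -tol)
                & (q[:, 1] <= par.H + tol)
            )
            if not self.is_2d:
                m &= (q[:, 2] >= -tol) & (q[:, 2] <= par.T + tol)
        elif k in (DomainKind.CIRCLE_2D, DomainKind.CIRCLE_3D):
            r2 = q[:, 0] ** 2 + q[:, 1] ** 2
            m = r2 <= (par.R + tol) ** 2
            if not self.is_2d:
                m &= (q[:, 2] >= -tol) & (q[:, 2] <= par.T + tol)
        else:
            r = np.linalg.norm(q, axis=1)
            m = (r >= par.R - par.T - tol) & (r <= par.R + tol) & (q[:, 2] >= -tol)
        if self.resolve_pellet:
            m &= ~self.in_pellet(q)
        return m

    def contains_point(self, p) -> bool:
        return bool(self.contains(p)[0])

    # ------------------------------------------------ repulsive boundary queries

    def boundary_distance(self, p):
        """Distance and interior-pointing unit direction to the repulsive
        boundary set (epithelial + endothelial cornea surfaces only).

        For zero-thickness (2D) domains the repulsive set is empty and the
        distance is ``+inf`` with a zero direction.
        """
        q = self._as_points(p)
        n = len(q)
        if self.is_2d:
            return np.full(n, np.inf), np.zeros((n, 3))
        par = self.params
        if self.kind is DomainKind.HEMISPHERE:
            r = np.linalg.norm(q, axis=1)
            r = np.where(r == 0, 1.0, r)
            d_out = par.R - np.linalg.norm(q, axis=1)
            d_in = np.linalg.norm(q, axis=1) - (par.R - par.T)
            rhat = q / r[:, None]
            outer_closer = d_out <= d_in
            d = np.where(outer_closer, d_out, d_in)
            u = np.where(outer_closer[:, None], -rhat, rhat)
            return d, u
        # planar_3d / circle_3d: the z = 0 and z = T faces
        z = q[:, 2]
        d_lo = z
        d_hi = par.T - z
        lo_closer = d_lo <= d_hi
        d = np.where(lo_closer, d_lo, d_hi)
        u = np.zeros((n, 3))
        u[:, 2] = np.where(lo_closer, 1.0, -1.0)
        return d, u

    # ---------------------------------------------------------- limbus geodesic

    def limbus_distance(self, p) -> np.ndarray:
        """Coordinate ``xi`` along the limbus->pellet geodesic (xi = 0 on the
        limbus)."""
        q = self._as_points(p)
        par = self.params
        if self.kind in _PLANAR_KINDS:
            return q[:, 1].copy()
        if self.kind in (DomainKind.CIRCLE_2D, DomainKind.CIRCLE_3D):
            return par.R - np.hypot(q[:, 0], q[:, 1])
        r = np.linalg.norm(q, axis=1)
        r = np.where(r == 0, 1.0, r)
        cos_theta = np.clip(q[:, 2] / r, -1.0, 1.0)
        theta = np.arccos(cos_theta)  # polar angle from the pole
        return par.R * (np.pi / 2.0 - theta)

    @property
    def max_limbus_distance(self) -> float:
        par = self.params
        if self.kind in _PLANAR_KINDS:
            return par.H
        if self.kind in (DomainKind.CIRCLE_2D, DomainKind.CIRCLE_3D):
            return par.R
        return par.R * np.pi / 2.0

    @property
    def pellet_geodesic_distance(self) -> float:
        """Limbus distance of the pellet centre (hemisphere) or near
        interface (other domains)."""
        if self.kind is DomainKind.HEMISPHERE:
            return float(self.limbus_distance(self.pellet_centre)[0])
        return self.params.h + self.params.eps

    # -------------------------------------------------------------- volume etc.

    @property
    def thickness(self) -> float:
        """Thickness used to convert 2D areal densities to volumetric ones."""
        return self.params.T

    def tissue_measure(self) -> float:
        """Analytic area (2D kinds) or volume of the tissue, pellet excluded
        when resolved."""
        par = self.params
        k = par.kind
        if k in _PLANAR_KINDS:
            area = par.W * par.H
            # the pellet slab may be clipped by the domain extent H
            slab = max(0.0, min(par.h + par.eps + 2 * par.r_p, par.H) - (par.h + par.eps))
            pellet_area = par.w * slab
            if k in _2D_KINDS:
                return area - (pellet_area if self.resolve_pellet else 0.0)
            vol = area * par.T
            t_pel = par.T if k is DomainKind.PLANAR_3D else par.T_p
            return vol - (pellet_area * t_pel if self.resolve_pellet else 0.0)
        if k is DomainKind.CIRCLE_2D:
            return np.pi * par.R**2 - (np.pi * par.r_p**2 if self.resolve_pellet else 0.0)
        if k is DomainKind.CIRCLE_3D:
            return np.pi * par.R**2 * par.T - (
                np.pi * par.r_p**2 * par.T_p if self.resolve_pellet else 0.0
            )
        shell = 2.0 * np.pi / 3.0 * (par.R**3 - (par.R - par.T) ** 3)
        return shell - (np.pi * par.r_p**2 * par.T_p if self.resolve_pellet else 0.0)

    def bounding_box(self):
        """Axis-aligned bounding box (lo, hi), each shape (3,)."""
        par = self.params
        if self.kind in _PLANAR_KINDS:
            hi_z = 0.0 if self.is_2d else par.T
            return np.array([0.0, 0.0, 0.0]), np.array([par.W, par.H, hi_z])
        if self.kind in (DomainKind.CIRCLE_2D, DomainKind.CIRCLE_3D):
            hi_z = 0.0 if self.is_2d else par.T
            return np.array([-par.R, -par.R, 0.0]), np.array([par.R, par.R, hi_z])
        return np.array([-par.R, -par.R, 0.0]), np.array([par.R, par.R, par.R])

    # ------------------------------------------------------------ initial vessel

    def initial_vessel_path(self, node_spacing: float = 10.0, eps: float | None = None):
        """Nodes of the initial limbal vessel at limbus distance ``eps``
        (defaults to the domain's own offset parameter).

        Returns ``(points (n,3), closed)`` -- an open polyline spanning the
        width of planar domains, a closed ring for circle/hemisphere. The
        vessel sits mid-way through the thickness in 3D domains.
        """
        par = self.params
        if eps is None:
            eps = par.eps
        if self.kind in _PLANAR_KINDS:
            n = int(round(par.W / node_spacing)) + 1
            x = np.linspace(0.0, par.W, n)
            pts = np.column_stack([x, np.full(n, eps), np.full(n, self.z_mid)])
            return pts, False
        if self.kind in (DomainKind.CIRCLE_2D, DomainKind.CIRCLE_3D):
            radius = par.R - eps
            n = max(3, int(round(2 * np.pi * radius / node_spacing)))
            ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
            pts = np.column_stack(
                [radius * np.cos(ang), radius * np.sin(ang), np.full(n, self.z_mid)]
            )
            return pts, True
        r_mid = par.R - par.T / 2.0
        theta = np.pi / 2.0 - eps / par.R  # xi = eps on the mid-surface
        ring_r = r_mid * np.sin(theta)
        z = r_mid * np.cos(theta)
        n = max(3, int(round(2 * np.pi * ring_r / node_spacing)))
        ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([ring_r * np.cos(ang), ring_r * np.sin(ang), np.full(n, z)])
        return pts, True

    # -------------------------------------------------------------------- mesh

    def generate_mesh(self, target_edge: float = 30.0) -> "Mesh":
        """Linear-element mesh of the tissue with the pellet carved out and
        boundary facets tagged ``OUTER`` (no-flux) or ``PELLET`` (Robin)."""
        if target_edge <= 0:
            raise ValueError("target_edge must be positive")
        par = self.params
        if target_edge >= min(par.T if not self.is_2d else np.inf, par.R, par.W, par.H):
            raise ValueError("target_edge must be smaller than every domain dimension")
        k = self.kind
        if k in (DomainKind.PLANAR_2D, DomainKind.PLANAR_2D_FINITE):
            return _mesh_planar_2d(self, target_edge)
        if k in (DomainKind.PLANAR_3D, DomainKind.PLANAR_3D_FINITE):
            return _mesh_planar_3d(self, target_edge)
        if k is DomainKind.CIRCLE_2D:
            return _mesh_circle_2d(self, target_edge)
        if k is DomainKind.CIRCLE_3D:
            return _mesh_circle_3d(self, target_edge)
        return _mesh_hemisphere(self, target_edge)


# =========================================================================
# Mesh container
# =========================================================================


@dataclass
class Mesh:
    """Unstructured simplex mesh with tagged boundary facets.

    ``dim`` is the intrinsic dimension (2: triangles with edge facets,
    3: tetrahedra with triangle facets). Vertices are always stored as
    ``(n, 3)`` with 2D meshes embedded at z = 0.
    """

    vertices: np.ndarray
    elements: np.ndarray
    dim: int
    facets: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    facet_tags: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self._measures = None

    @property
    def measures(self) -> np.ndarray:
        """Element areas (2D) or volumes (3D)."""
        if self._measures is None:
            v = self.vertices[self.elements]
            if self.dim == 2:
                a = v[:, 1, :2] - v[:, 0, :2]
                b = v[:, 2, :2] - v[:, 0, :2]
                self._measures = 0.5 * np.abs(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
            else:
                a = v[:, 1] - v[:, 0]
                b = v[:, 2] - v[:, 0]
                c = v[:, 3] - v[:, 0]
                self._measures = np.abs(np.einsum("ij,ij->i", np.cross(a, b), c)) / 6.0
        return self._measures

    @property
    def facet_measures(self) -> np.ndarray:
        """Facet lengths (2D) or areas (3D)."""
        v = self.vertices[self.facets]
        if self.dim == 2:
            return np.linalg.norm(v[:, 1] - v[:, 0], axis=1)
        return 0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)

    def element_centroids(self) -> np.ndarray:
        return self.vertices[self.elements].mean(axis=1)

    def total_measure(self) -> float:
        return float(self.measures.sum())


# =========================================================================
# Meshing helpers
# =========================================================================


def _snapped_axis(breaks, target_edge):
    """1D grid through mandatory break points, subdivided near target_edge."""
    breaks = np.unique(np.asarray(breaks, dtype=float))
    out = [breaks[0]]
    for a, b in zip(breaks[:-1], breaks[1:]):
        n = max(1, int(round((b - a) / target_edge)))
        out.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(out)


def _grid_triangles(nx, ny):
    """Triangulate an nx x ny structured grid of points (row-major y-fast?
    points indexed i*ny + j)."""
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    i = i.ravel()
    j = j.ravel()
    v00 = i * ny + j
    v10 = (i + 1) * ny + j
    v01 = i * ny + j + 1
    v11 = (i + 1) * ny + j + 1
    t1 = np.column_stack([v00, v10, v11])
    t2 = np.column_stack([v00, v11, v01])
    return np.vstack([t1, t2])


def _remove_pellet_elements(domain, verts, elems, dim):
    centroids = verts[elems].mean(axis=1)
    keep = ~domain.in_pellet(centroids)
    return elems[keep]


def _boundary_facets(elements, dim):
    """Facets belonging to exactly one element."""
    if dim == 2:
        faces = np.vstack(
            [elements[:, [0, 1]], elements[:, [1, 2]], elements[:, [2, 0]]]
        )
    else:
        faces = np.vstack(
            [
                elements[:, [0, 1, 2]],
                elements[:, [0, 1, 3]],
                elements[:, [0, 2, 3]],
                elements[:, [1, 2, 3]],
            ]
        )
    key = np.sort(faces, axis=1)
    uniq, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    return faces[idx[counts == 1]]


def _compact(verts, elems, facets):
    used = np.unique(np.concatenate([elems.ravel(), facets.ravel()]))
    remap = -np.ones(len(verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return verts[used], remap[elems], remap[facets]


def _classify_planar(domain, verts, facets, dim, tol=1e-6):
    par = domain.params
    cent = verts[facets].mean(axis=1)
    tags = np.full(len(facets), OUTER, dtype=np.int64)
    on_interface = np.abs(cent[:, 1] - (par.h + par.eps)) < tol
    if par.kind in _FINITE_PELLET_PLANAR:
        on_interface &= np.abs(cent[:, 0] - par.W / 2.0) < par.r_p + tol
        if par.kind is DomainKind.PLANAR_3D_FINITE:
            z0 = (par.T - par.T_p) / 2.0
            on_interface &= (cent[:, 2] > z0 - tol) & (cent[:, 2] < z0 + par.T_p + tol)
        # only facets exposed by the carved pellet belong to the interface;
        # geometric test suffices because interior facets are never boundary
    tags[on_interface] = PELLET
    return tags


def _mesh_planar_2d(domain, edge):
    par = domain.params
    xb = [0.0, par.W]
    if par.kind is DomainKind.PLANAR_2D_FINITE:
        xb += [par.W / 2.0 - par.r_p, par.W / 2.0 + par.r_p]
    yb = [0.0, par.h + par.eps, min(par.h + par.eps + 2 * par.r_p, par.H), par.H]
    x = _snapped_axis(xb, edge)
    y = _snapped_axis(yb, edge)
    X, Y = np.meshgrid(x, y, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
    elems = _grid_triangles(len(x), len(y))
    elems = _remove_pellet_elements(domain, verts, elems, 2)
    facets = _boundary_facets(elems, 2)
    verts, elems, facets = _compact(verts, elems, facets)
    tags = _classify_planar(domain, verts, facets, 2)
    return Mesh(verts, elems, 2, facets, tags)


def _hex_to_tets(hexes):
    """Split hexahedra (8 node ids: (i,j,k) binary order x-fast) into 6 tets
    (Kuhn triangulation, consistent across shared faces of a structured grid)."""
    n0, n1, n2, n3, n4, n5, n6, n7 = hexes.T
    # Kuhn: path permutations of the main diagonal n0-n7
    tets = [
        (n0, n1, n3, n7),
        (n0, n1, n5, n7),
        (n0, n2, n3, n7),
        (n0, n2, n6, n7),
        (n0, n4, n5, n7),
        (n0, n4, n6, n7),
    ]
    return np.vstack([np.column_stack(t) for t in tets])


def _mesh_planar_3d(domain, edge):
    par = domain.params
    xb = [0.0, par.W]
    zb = [0.0, par.T]
    if par.kind is DomainKind.PLANAR_3D_FINITE:
        xb += [par.W / 2.0 - par.r_p, par.W / 2.0 + par.r_p]
        zb += [(par.T - par.T_p) / 2.0, (par.T + par.T_p) / 2.0]
    yb = [0.0, par.h + par.eps, min(par.h + par.eps + 2 * par.r_p, par.H), par.H]
    x = _snapped_axis(xb, edge)
    y = _snapped_axis(yb, edge)
    z = _snapped_axis(zb, min(edge, par.T / 2.0))
    nx, ny, nz = len(x), len(y), len(z)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    hexes = np.column_stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i, j + 1, k),
            nid(i + 1, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i, j + 1, k + 1),
            nid(i + 1, j + 1, k + 1),
        ]
    )
    elems = _hex_to_tets(hexes)
    elems = _remove_pellet_elements(domain, verts, elems, 3)
    facets = _boundary_facets(elems, 3)
    verts, elems, facets = _compact(verts, elems, facets)
    tags = _classify_planar(domain, verts, facets, 3)
    return Mesh(verts, elems, 3, facets, tags)


def _disc_point_set(domain, edge):
    """Point set for a disc with an embedded pellet circle: boundary rings on
    both circles plus a hexagonal interior lattice kept clear of the rings.

    Returns (points (n,2), n_outer_ring, pellet_ring_mask)."""
    par = domain.params
    R, r_p = par.R, par.r_p
    cx, cy = domain.pellet_centre[:2]
    n_out = max(16, int(np.ceil(2 * np.pi * R / edge)))
    ang = np.linspace(0, 2 * np.pi, n_out, endpoint=False)
    outer = np.column_stack([R * np.cos(ang), R * np.sin(ang)])
    n_pel = max(12, int(np.ceil(2 * np.pi * r_p / edge)))
    ang = np.linspace(0, 2 * np.pi, n_pel, endpoint=False)
    pellet = np.column_stack([cx + r_p * np.cos(ang), cy + r_p * np.sin(ang)])
    # hexagonal lattice
    dy = edge * np.sqrt(3) / 2.0
    ys = np.arange(-R, R + dy, dy)
    pts = []
    for row, yv in enumerate(ys):
        xs = np.arange(-R - edge, R + edge, edge) + (0.5 * edge if row % 2 else 0.0)
        pts.append(np.column_stack([xs, np.full(len(xs), yv)]))
    lattice = np.vstack(pts)
    rr = np.hypot(lattice[:, 0], lattice[:, 1])
    keep = rr < R - 0.55 * edge
    d_pel = np.abs(np.hypot(lattice[:, 0] - cx, lattice[:, 1] - cy) - r_p)
    keep &= d_pel > 0.55 * edge
    lattice = lattice[keep]
    points = np.vstack([outer, pellet, lattice])
    pellet_ring = np.zeros(len(points), dtype=bool)
    pellet_ring[n_out : n_out + n_pel] = True
    return points, pellet_ring


def _disc_triangulation(domain, edge):
    """Delaunay triangulation of the disc split into tissue (A) and pellet
    footprint (B) triangle sets conforming to the pellet circle."""
    pts2, pellet_ring = _disc_point_set(domain, edge)
    tri = Delaunay(pts2)
    simplices = tri.simplices
    cent = pts2[simplices].mean(axis=1)
    cx, cy = domain.pellet_centre[:2]
    in_pellet = np.hypot(cent[:, 0] - cx, cent[:, 1] - cy) < domain.params.r_p
    return pts2, simplices[~in_pellet], simplices[in_pellet], pellet_ring


def _mesh_circle_2d(domain, edge):
    pts2, tri_a, tri_b, pellet_ring = _disc_triangulation(domain, edge)
    verts = np.column_stack([pts2, np.zeros(len(pts2))])
    facets = _boundary_facets(tri_a, 2)
    verts, elems, facets = _compact(verts, tri_a, facets)
    cent = verts[facets].mean(axis=1)
    cx, cy = domain.pellet_centre[:2]
    d_pel = np.abs(np.hypot(cent[:, 0] - cx, cent[:, 1] - cy) - domain.params.r_p)
    tags = np.where(d_pel < 0.25 * edge, PELLET, OUTER).astype(np.int64)
    return Mesh(verts, elems, 2, facets, tags)


def _extrude_triangulation(pts3_layers, triangles, removed):
    """Extrude a surface triangulation through a stack of layers into tets.

    ``pts3_layers``: list of (n,3) vertex positions, one per layer interface.
    ``removed``: boolean (n_tri, n_layers-1) marking prisms to omit.
    Prisms are split into 3 tets with diagonals chosen by global vertex
    order, which is consistent across neighbouring prisms.
    """
    n_pts = len(pts3_layers[0])
    n_lay = len(pts3_layers) - 1
    verts = np.vstack(pts3_layers)
    order = np.argsort(triangles, axis=1)
    tri_sorted = np.take_along_axis(triangles, order, axis=1)
    tets = []
    for layer in range(n_lay):
        keep = ~removed[:, layer]
        t = tri_sorted[keep]
        lo = t + layer * n_pts
        hi = t + (layer + 1) * n_pts
        p0, p1, p2 = lo[:, 0], lo[:, 1], lo[:, 2]
        q0, q1, q2 = hi[:, 0], hi[:, 1], hi[:, 2]
        tets.append(np.column_stack([p0, p1, p2, q0]))
        tets.append(np.column_stack([p1, p2, q0, q1]))
        tets.append(np.column_stack([p2, q0, q1, q2]))
    return verts, np.vstack(tets)


def _mesh_circle_3d(domain, edge):
    par = domain.params
    pts2, tri_a, tri_b, _ = _disc_triangulation(domain, edge)
    z0 = (par.T - par.T_p) / 2.0
    z1 = z0 + par.T_p
    zs = _snapped_axis([0.0, z0, z1, par.T], min(edge, par.T / 2.0))
    layers = [np.column_stack([pts2, np.full(len(pts2), z)]) for z in zs]
    triangles = np.vstack([tri_a, tri_b])
    is_b = np.zeros(len(triangles), dtype=bool)
    is_b[len(tri_a):] = True
    mid = 0.5 * (zs[:-1] + zs[1:])
    in_slab = (mid > z0) & (mid < z1)
    removed = np.outer(is_b, in_slab)
    verts, elems = _extrude_triangulation(layers, triangles, removed)
    facets = _boundary_facets(elems, 3)
    verts, elems, facets = _compact(verts, elems, facets)
    cent = verts[facets].mean(axis=1)
    on_top = np.abs(cent[:, 2] - par.T) < _TOL
    on_bot = np.abs(cent[:, 2]) < _TOL
    on_rim = np.hypot(cent[:, 0], cent[:, 1]) > par.R - 0.5 * edge
    tags = np.where(on_top | on_bot | on_rim, OUTER, PELLET).astype(np.int64)
    return Mesh(verts, elems, 3, facets, tags)


def _hemisphere_surface_triangulation(R_param, edge):
    """Triangulation of the hemispherical cap built in an azimuthal
    equidistant projection about the pole: a uniform hexagonal lattice plus
    an exact limbus ring is triangulated with Delaunay in the projected
    plane and mapped back to unit directions.

    The projection keeps radial (geodesic) spacing exact while compressing
    azimuthal spacing by sin(theta)/theta (>= 2/pi), so element quality is
    uniform with no pole slivers."""
    g_max = np.pi / 2.0 * R_param  # geodesic radius of the limbus
    n_ring = max(16, int(np.ceil(2 * np.pi * g_max / edge)))
    ang = np.linspace(0, 2 * np.pi, n_ring, endpoint=False)
    ring = np.column_stack([g_max * np.cos(ang), g_max * np.sin(ang)])
    dy = edge * np.sqrt(3) / 2.0
    ys = np.arange(-g_max, g_max + dy, dy)
    pts = []
    for row, yv in enumerate(ys):
        xs = np.arange(-g_max - edge, g_max + edge, edge) + (
            0.5 * edge if row % 2 else 0.0
        )
        pts.append(np.column_stack([xs, np.full(len(xs), yv)]))
    lattice = np.vstack(pts)
    keep = np.hypot(lattice[:, 0], lattice[:, 1]) < g_max - 0.55 * edge
    pts2 = np.vstack([ring, lattice[keep]])
    tris = Delaunay(pts2).simplices
    g = np.hypot(pts2[:, 0], pts2[:, 1])
    theta = g / R_param  # polar angle from the pole
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(g > 0, pts2[:, 0] / g, 0.0)
        uy = np.where(g > 0, pts2[:, 1] / g, 0.0)
    dirs = np.column_stack(
        [np.sin(theta) * ux, np.sin(theta) * uy, np.cos(theta)]
    )
    return dirs, tris


def _mesh_hemisphere(domain, edge):
    par = domain.params
    dirs, tris = _hemisphere_surface_triangulation(par.R, edge)
    r_mid = par.R - par.T / 2.0
    radii = np.array(
        [par.R - par.T, r_mid - par.T_p / 2.0, r_mid + par.T_p / 2.0, par.R]
    )
    layers = [r * dirs for r in radii]
    removed = np.zeros((len(tris), len(radii) - 1), dtype=bool)
    verts, elems = _extrude_triangulation(layers, tris, removed)
    elems = _remove_pellet_elements(domain, verts, elems, 3)
    facets = _boundary_facets(elems, 3)
    verts, elems, facets = _compact(verts, elems, facets)
    cent = verts[facets].mean(axis=1)
    r = np.linalg.norm(cent, axis=1)
    on_outer = r > par.R - 0.25 * par.T_p
    on_inner = r < par.R - par.T + 0.25 * par.T_p
    on_limbus = cent[:, 2] < 0.5 * edge * 0.25
    tags = np.where(on_outer | on_inner | on_limbus, OUTER, PELLET).astype(np.int64)
    return Mesh(verts, elems, 3, facets, tags)
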