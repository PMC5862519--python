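"""VEGF transport models.

Two treatments of the growth factor driving angiogenesis are provided.

Fixed field
    A time-independent profile that rises linearly with limbus distance
    ``xi``: ``c(xi) = c_p * xi / (h + eps)``, clamped to ``[0, c_p]``. The
    gradient magnitude ``c_p / (h + eps)`` and limbal concentration
    ``c_p * eps / (h + eps)`` are therefore identical across all tissue
    domains, isolating geometric effects on network formation from pellet
    representation.

Dynamic model
    The pellet is a lumped, well-mixed compartment in which most VEGF is
    reversibly bound to the nylon matrix: the free fraction is
    ``c_f = c_p / theta`` with binding parameter ``theta >= 1``. Free VEGF
    decays at rate ``lambda_p`` and leaks through the cornea-pellet
    interface with permeability ``kappa_p``:

        dc_p/dt = -lambda_p c_f - (kappa_p / Omega_p) * Int_dOmega (c_f - c) dA

    In the tissue, VEGF diffuses, decays, is washed into perfused vessels
    and binds to endothelial cells:

        dc/dt = D lap(c) - lambda c - 2 pi R_v rho kappa_v (c - c_b)
                - n k_ec c / (c + c50)

    with no-flux conditions on the outer cornea surfaces and a Robin flux
    ``-D dc/dn = -kappa_p (c_f - c)`` on the pellet interface. The PDE is
    discretised with linear finite elements (lumped mass) and advanced by
    forward Euler with sub-steps bounded by both 0.05 h and the explicit
    stability limit. Vessel line density ``rho`` and tip density ``n`` are
    reconstructed per element from the discrete network.

All internal quantities use a micrometre / hour / nanomolar unit system;
literature values quoted in SI are converted on construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .geometry import PELLET, Mesh, TissueDomain

__all__ = [
    "VegfParams",
    "FixedField",
    "PelletState",
    "TissueField",
    "initial_pellet_concentration",
    "advance_to",
]

# unit conversions
M2_PER_H_TO_UM2_PER_H = 1e12
M_PER_H_TO_UM_PER_H = 1e6
# mol/h per cell -> nM um^3 / h per cell:  mol -> nmol (1e9), nmol/um^3 -> nM (1e15)
MOL_PER_H_TO_NM_UM3_PER_H = 1e24

GRAD_DELTA = 5.0  # um, centred-difference probe offset


@dataclass
class VegfParams:
    """Transport parameters (stored in um / h / nM units).

    Defaults correspond to VEGF165 in the mouse cornea: diffusivity
    D = 2.52e-7 m^2/h, tissue decay 0.8 /h, vessel permeability 3e-4 m/h,
    vessel radius 5 um, EC binding 4e-19 mol/h per cell with half-max 0.65
    nM, pellet binding theta = 30, pellet decay 0.8 /h and interface
    permeability 1.12e-7 m/h.
    """

    D: float = 2.52e-7 * M2_PER_H_TO_UM2_PER_H
    decay: float = 0.8  # 1/h
    kappa_v: float = 3e-4 * M_PER_H_TO_UM_PER_H
    kappa_p: float = 1.12e-7 * M_PER_H_TO_UM_PER_H
    R_v: float = 5.0  # um
    c_b: float = 0.0  # nM
    k_ec: float = 4e-19 * MOL_PER_H_TO_NM_UM3_PER_H
    c_50: float = 0.65  # nM
    theta: float = 30.0
    lambda_p: float = 0.8  # 1/h
    ec_sink_uses_line_density: bool = False  # alternative: EC density rho*EL
    EL: float = 0.05  # 1/um, used only by the alternative EC-sink reading
    max_dt: float = 0.05  # h, PDE sub-step cap

    def __post_init__(self):
        if self.theta < 1.0:
            raise ValueError("binding parameter theta must be >= 1")


def initial_pellet_concentration(mass_ng: float, mw_kda: float, omega_um3: float) -> float:
    """Initial total pellet concentration (nM) from implanted mass.

    ``(m / MW) / Omega_p`` with units resolved: ng / (kDa) / um^3 -> nM.
    300 ng of 45 kDa VEGF in a 200 um x 40 um cylindrical pellet gives
    1.33e6 nM.
    """
    if mass_ng < 0 or mw_kda <= 0 or omega_um3 <= 0:
        raise ValueError("mass must be >= 0; MW and volume positive")
    mol = mass_ng * 1e-9 / (mw_kda * 1000.0)
    molar = mol / (omega_um3 * 1e-15)  # mol / L
    return molar * 1e9


# =========================================================================
# Fixed field
# =========================================================================


class FixedField:
    """Time-independent linear VEGF profile along the limbus coordinate."""

    def __init__(self, domain: TissueDomain, c_p: float, h: float | None = None,
                 eps: float | None = None):
        self.domain = domain
        self.c_p = float(c_p)
        self.h = float(h if h is not None else domain.params.h)
        self.eps = float(eps if eps is not None else domain.params.eps)
        if self.h <= 0 or self.eps <= 0:
            raise ValueError("h and eps must be positive")

    @property
    def gradient_magnitude(self) -> float:
        return self.c_p / (self.h + self.eps)

    def concentration(self, points) -> np.ndarray:
        xi = self.domain.limbus_distance(points)
        return np.clip(self.c_p * xi / (self.h + self.eps), 0.0, self.c_p)

    def sample(self, points):
        """Concentration and centred-difference gradient at points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c = self.concentration(p)
        grad = np.zeros_like(p)
        for d in range(3):
            if self.domain.is_2d and d == 2:
                continue
            dp = np.zeros(3)
            dp[d] = GRAD_DELTA
            grad[:, d] = (
                self.concentration(p + dp) - self.concentration(p - dp)
            ) / (2 * GRAD_DELTA)
        return c, grad


# =========================================================================
# Dynamic model
# =========================================================================


@dataclass
class PelletState:
    """Lumped pellet compartment: total concentration c_p with bound/free
    partition c_f = c_p / theta."""

    c_p: float
    theta: float = 30.0
    lambda_p: float = 0.8
    kappa_p: float = VegfParams.kappa_p
    omega_p: float = np.pi * 200.0**2 * 40.0

    def __post_init__(self):
        if self.theta < 1.0:
            raise ValueError("theta must be >= 1")
        if self.c_p < 0:
            raise ValueError("pellet concentration must be non-negative")

    @property
    def c_f(self) -> float:
        return self.c_p / self.theta

    def step(self, interface_c, interface_weights, dt: float) -> "PelletState":
        """One explicit update of Eq. d c_p/dt; ``interface_c`` are tissue
        concentrations at the interface quadrature nodes with weights
        (areas, um^2; in 2D already scaled by the thickness)."""
        leak = self.kappa_p / self.omega_p * float(
            np.sum(interface_weights * (self.c_f - interface_c))
        )
        c_new = self.c_p + dt * (-self.lambda_p * self.c_f - leak)
        return PelletState(
            max(c_new, 0.0), self.theta, self.lambda_p, self.kappa_p, self.omega_p
        )


class TissueField:
    """Nodal VEGF concentration on a linear finite-element mesh.

    Owns the assembled stiffness/lumped-mass operators, the Robin weights on
    the pellet-interface facets, the per-element vessel sink densities and a
    point-location structure for sampling.
    """

    def __init__(self, domain: TissueDomain, mesh: Mesh, params: VegfParams | None = None):
        self.domain = domain
        self.mesh = mesh
        self.params = params or VegfParams()
        self.thickness = 1.0 if not domain.is_2d else domain.thickness
        n = len(mesh.vertices)
        self.c = np.zeros(n)
        self._assemble()
        self.rho_e = np.zeros(len(mesh.elements))
        self.n_e = np.zeros(len(mesh.elements))
        self._sink_nodal_valid = False
        self._tree = None
        self._warned_outside = False

    # ------------------------------------------------------------- assembly

    def _assemble(self):
        mesh = self.mesh
        verts = mesh.vertices
        elems = mesh.elements
        n = len(verts)
        d = mesh.dim
        vol = mesh.measures
        v = verts[elems]
        if d == 2:
            # P1 gradients on triangles (in-plane coordinates)
            x = v[:, :, 0]
            y = v[:, :, 1]
            bmat = np.stack(
                [y[:, [1, 2, 0]] - y[:, [2, 0, 1]], x[:, [2, 0, 1]] - x[:, [1, 2, 0]]],
                axis=1,
            )  # (m, 2, 3)
            grads = bmat / (2.0 * vol)[:, None, None]
        else:
            e1 = v[:, 1] - v[:, 0]
            e2 = v[:, 2] - v[:, 0]
            e3 = v[:, 3] - v[:, 0]
            J = np.stack([e1, e2, e3], axis=2)  # (m,3,3), columns edges
            Jinv = np.linalg.inv(J)
            gl = np.zeros((len(elems), 3, 4))
            gl[:, :, 1:] = np.transpose(Jinv, (0, 2, 1))
            gl[:, :, 0] = -gl[:, :, 1:].sum(axis=2)
            grads = gl
        ke = np.einsum("mdi,mdj,m->mij", grads, grads, vol)
        rows = np.repeat(elems, d + 1, axis=1).ravel()
        cols = np.tile(elems, (1, d + 1)).ravel()
        K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
        self.K = (self.params.D * K).tocsr()
        # lumped mass
        m = np.zeros(n)
        np.add.at(m, elems.ravel(), np.repeat(vol / (d + 1), d + 1))
        self.mass = m
        # element -> node lumping weights (for sink coefficients)
        self._elem_node_w = vol / (d + 1)
        # Robin weights on pellet facets
        w = np.zeros(n)
        pellet = mesh.facet_tags == PELLET
        fm = mesh.facet_measures[pellet]
        fac = mesh.facets[pellet]
        np.add.at(w, fac.ravel(), np.repeat(fm / fac.shape[1], fac.shape[1]))
        self.robin_w = w
        self._robin_nodes = np.flatnonzero(w)
        # |K| row sums for the Gershgorin stability bound
        self._k_rowsum = np.asarray(np.abs(self.K).sum(axis=1)).ravel()

    # -------------------------------------------------------- vessel sinks

    def set_element_densities(self, rho_e, n_e):
        """Per-element vessel line density (um^-2) and tip density (um^-3),
        reconstructed from the current network."""
        self.rho_e = np.asarray(rho_e, dtype=float)
        self.n_e = np.asarray(n_e, dtype=float)
        self._sink_nodal_valid = False

    def _nodal_sinks(self):
        if not self._sink_nodal_valid:
            p = self.params
            elems = self.mesh.elements
            vessel_e = 2.0 * np.pi * p.R_v * p.kappa_v * self.rho_e
            if p.ec_sink_uses_line_density:
                ec_e = p.k_ec * self.rho_e * p.EL
            else:
                ec_e = p.k_ec * self.n_e
            nv = np.zeros(len(self.mass))
            ne = np.zeros(len(self.mass))
            wv = self._elem_node_w
            k = elems.shape[1]
            np.add.at(nv, elems.ravel(), np.repeat(vessel_e * wv, k))
            np.add.at(ne, elems.ravel(), np.repeat(ec_e * wv, k))
            self._vessel_rate = nv / self.mass  # 1/h
            self._ec_rate = ne / self.mass  # nM/h at saturation
            self._sink_nodal_valid = True
        return self._vessel_rate, self._ec_rate

    # ------------------------------------------------------------- stepping

    def stable_dt(self) -> float:
        p = self.params
        vessel, ec = self._nodal_sinks()
        rate = (
            self._k_rowsum / self.mass
            + p.decay
            + vessel
            + ec / p.c_50
            + p.kappa_p * self.robin_w / self.mass
        )
        return 0.9 * 2.0 / float(rate.max())

    def step(self, c_f: float, dt: float):
        """One forward-Euler sub-step with free pellet concentration c_f."""
        p = self.params
        vessel, ec = self._nodal_sinks()
        c = self.c
        dcdt = (
            -(self.K @ c) / self.mass
            - p.decay * c
            - vessel * (c - p.c_b)
            - ec * c / (c + p.c_50)
            + p.kappa_p * self.robin_w / self.mass * (c_f - c)
        )
        self.c = np.maximum(c + dt * dcdt, 0.0)

    def interface_values(self):
        """Tissue concentrations and quadrature weights on the pellet
        interface (weights in um^2; 2D line weights scaled by thickness)."""
        idx = self._robin_nodes
        return self.c[idx], self.robin_w[idx] * self.thickness

    def tissue_mass(self) -> float:
        """Total dissolved VEGF, nM * um^3."""
        return float(np.sum(self.mass * self.c)) * self.thickness

    # ------------------------------------------------------------- sampling

    def _build_tree(self):
        if self._tree is None:
            cent = self.mesh.element_centroids()
            if self.mesh.dim == 2:
                cent = cent[:, :2]
            self._tree = cKDTree(cent)
            elems = self.mesh.elements
            verts = self.mesh.vertices
            v0 = verts[elems[:, 0]]
            if self.mesh.dim == 2:
                edges = np.stack(
                    [verts[elems[:, k], :2] - v0[:, :2] for k in (1, 2)], axis=2
                )
            else:
                edges = np.stack(
                    [verts[elems[:, k]] - v0 for k in (1, 2, 3)], axis=2
                )
            self._inv_maps = np.linalg.inv(edges)
            self._v0 = v0

    def locate(self, points, k: int = 12):
        """Element index and P1 shape weights for each point.

        Points outside the mesh fall back to the nearest element with
        extrapolated (possibly negative) weights; a single warning is
        emitted per field.
        """
        self._build_tree()
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = self.mesh.dim
        q = p[:, :2] if d == 2 else p
        kq = min(k, len(self.mesh.elements))
        _, cand = self._tree.query(q, k=kq)
        cand = np.atleast_2d(cand)
        n = len(p)
        elem = cand[:, 0].copy()
        lam = np.zeros((n, d))
        found = np.zeros(n, dtype=bool)
        for j in range(kq):
            rem = ~found
            if not rem.any():
                break
            e = cand[rem, j]
            rel = q[rem] - (self._v0[e, :2] if d == 2 else self._v0[e])
            lm = np.einsum("nji,ni->nj", self._inv_maps[e], rel)
            ok = (lm >= -1e-9).all(axis=1) & (lm.sum(axis=1) <= 1 + 1e-9)
            ridx = np.flatnonzero(rem)
            hit = ridx[ok]
            elem[hit] = e[ok]
            lam[hit] = lm[ok]
            found[hit] = True
        if not found.all():
            rem = np.flatnonzero(~found)
            e = cand[rem, 0]
            rel = q[rem] - (self._v0[e, :2] if d == 2 else self._v0[e])
            lam[rem] = np.einsum("nji,ni->nj", self._inv_maps[e], rel)
            if not self._warned_outside:
                warnings.warn(
                    "some sample points fell outside the mesh; "
                    "using nearest-element extrapolation",
                    stacklevel=2,
                )
                self._warned_outside = True
        weights = np.zeros((n, d + 1))
        weights[:, 1:] = lam
        weights[:, 0] = 1.0 - lam.sum(axis=1)
        return elem, weights

    def interpolate(self, elem, weights) -> np.ndarray:
        return np.einsum("nk,nk->n", self.c[self.mesh.elements[elem]], weights)

    def concentration(self, points) -> np.ndarray:
        elem, w = self.locate(points)
        return self.interpolate(elem, w)

    def sample(self, points):
        """Concentration (P1 interpolation) and centred-difference gradient
        (probe offset 5 um per axis) at points."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(p)
        ndim = 2 if self.domain.is_2d else 3
        probes = np.empty((n * (1 + 2 * ndim), 3))
        probes[:n] = p
        for d in range(ndim):
            dp = np.zeros(3)
            dp[d] = GRAD_DELTA
            probes[n * (1 + 2 * d): n * (2 + 2 * d)] = p + dp
            probes[n * (2 + 2 * d): n * (3 + 2 * d)] = p - dp
        elem, w = self.locate(probes)
        vals = self.interpolate(elem, w)
        c = vals[:n]
        grad = np.zeros((n, 3))
        for d in range(ndim):
            hi = vals[n * (1 + 2 * d): n * (2 + 2 * d)]
            lo = vals[n * (2 + 2 * d): n * (3 + 2 * d)]
            grad[:, d] = (hi - lo) / (2 * GRAD_DELTA)
        return c, grad

    def to_vtk(self, path):
        from ._vtk import write_unstructured

        write_unstructured(path, self.mesh, {"vegf_nM": self.c})


def element_densities(field: TissueField, network, sub: float = 5.0):
    """Per-element vessel line density (um^-2) and tip density (um^-3)
    reconstructed from the discrete network: segment length is deposited by
    midpoint sampling of <= ``sub``-um sub-segments, tips by point counts,
    both divided by the element volume (2D: area x cornea thickness).

    Total length and tip count are conserved exactly (every sub-segment and
    tip is assigned to exactly one element)."""
    mesh = field.mesh
    vol = mesh.measures * field.thickness
    rho = np.zeros(len(mesh.elements))
    n = np.zeros(len(mesh.elements))
    if network.n_segments:
        segs = network.segments
        a = network.positions[segs[:, 0]]
        b = network.positions[segs[:, 1]]
        L = network.segment_lengths
        nsub = np.maximum(np.ceil(L / sub).astype(int), 1)
        idx = np.repeat(np.arange(len(L)), nsub)
        starts = np.concatenate([[0], np.cumsum(nsub)[:-1]])
        rank = np.arange(nsub.sum()) - np.repeat(starts, nsub)
        t = (rank + 0.5) / nsub[idx]
        pts = a[idx] + t[:, None] * (b - a)[idx]
        w = (L / nsub)[idx]
        elem, _ = field.locate(pts)
        rho = np.bincount(elem, weights=w, minlength=len(vol)) / vol
    tips = network.tip_ids
    if len(tips):
        elem, _ = field.locate(network.positions[tips])
        n = np.bincount(elem, minlength=len(vol)) / vol
    return rho, n


def advance_to(field: TissueField, pellet: PelletState, t: float, t_target: float):
    """Advance the coupled pellet ODE + tissue PDE from ``t`` to
    ``t_target`` with forward-Euler sub-steps bounded by the stability limit
    and the 0.05 h cap. Returns the updated pellet state."""
    if t_target < t:
        raise ValueError("t_target must not be behind current time")
    dt_cap = min(field.params.max_dt, field.stable_dt())
    remaining = t_target - t
    n_sub = max(1, int(np.ceil(remaining / dt_cap - 1e-12)))
    dt = remaining / n_sub
    for _ in range(n_sub):
        cf = pellet.c_f
        c_i, w_i = field.interface_values()
        field.step(cf, dt)
        pellet = pellet.step(c_i, w_i, dt)
    return pellet
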