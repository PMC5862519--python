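"""Per-time-step vessel network growth rules.

The network is updated at discrete intervals ``dt`` (1 h) by four ordered
sub-stages: tips migrate, nearby tips anastomose, new tips form by
sprouting, and any remaining nearby tips anastomose.

Sprouting
    A node with local VEGF concentration ``c`` sprouts at the average rate
    ``P = P_max * L_s * E_L * c / (c + c_50)`` (``L_s`` the mean length of
    its attached segments); a sprout forms when an independent uniform draw
    ``z`` satisfies ``z < P dt``. Lateral inhibition forces ``P = 0`` within
    a distance ``1/E_L`` (20 um) of any node that has already been selected
    for sprouting (by default this suppression is permanent, mirroring
    Delta-Notch patterning of sprout spacing; an optional finite memory
    window is available). The new tip is offset ``s dt`` from the parent in
    a random direction normal to the parent segment.

Migration
    Tips advance at constant speed ``s`` by a persistent random walk biased
    up the VEGF gradient:

        m = (m_p + chi * grad(c)/|grad(c)|) / (1 + chi)
        x(t + dt) = x(t) + s dt (m + r)/|m + r|

    where ``m_p`` rotates the trailing tangent by an angle drawn from
    N(0, sigma) in a uniformly random plane. A soft-contact repulsion
    ``r = phi(d) u`` with ``phi = phi_max (d_crit - d)/(d_crit + d)``
    deflects tips approaching the epithelial/endothelial surfaces (``d`` the
    boundary distance, ``u`` the interior-pointing distance-map gradient).
    Tips may never leave the tissue: a move that would exit the domain is
    redrawn (new persistence angle) up to ``max_redraws`` times, after which
    the tip waits one step.

Anastomosis
    After migration and after sprouting, any migrating tip closer than
    ``r_ana`` (5 um) to a non-adjacent segment fuses with it: tip-to-tip if
    the nearest feature is a migrating endpoint (both tips de-activate),
    otherwise tip-to-vessel (the tip relocates onto the foot point, the
    segment splits there into a degree-3 junction, and the tip
    de-activates). Tips are audited in uniformly shuffled order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import TissueDomain
from .network import VesselNetwork, point_segment_distance

__all__ = [
    "AngioParams",
    "Simulation",
    "sprout_rate",
    "migration_direction",
    "repulsion_strength",
    "repulsion_vector",
    "persistence_directions",
]


@dataclass
class AngioParams:
    """Growth-rule parameters (micrometre / hour units, angles in degrees)."""

    P_max: float = 0.015  # sprout rate per cell, 1/h
    c_50: float = 0.65  # half-max VEGF for sprouting, nM
    E_L: float = 0.05  # endothelial cells per vessel length, 1/um
    s: float = 10.0  # tip speed, um/h
    chi: float = 0.5  # chemotactic weight (0 de-activates chemotaxis)
    sigma: float = 0.0  # persistence-angle SD, degrees (20 de-activates persistence)
    dt: float = 1.0  # global step, h
    r_ana: float = 5.0  # anastomosis radius, um
    phi_max: float = 5.0  # max boundary repulsion
    d_crit: float = 25.0  # repulsion onset distance, um
    max_redraws: int = 10  # containment backstop attempts
    # inhibition memory: None = a selected node suppresses sprouting within
    # 1/E_L forever; a number limits suppression to that many hours
    inhibition_window: float | None = None

    def __post_init__(self):
        for name in ("P_max", "c_50", "E_L", "s", "chi", "sigma", "r_ana",
                     "phi_max", "d_crit"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.r_ana >= self.d_crit:
            raise ValueError("r_ana must be smaller than d_crit")

    @property
    def inhibition_distance(self) -> float:
        return 1.0 / self.E_L


# =========================================================================
# elementary rules (vectorised, also exposed for direct use in tests)
# =========================================================================


def sprout_rate(c, mean_attached_length, params: AngioParams):
    """Average sprout formation rate P (1/h) at nodes with VEGF ``c`` (nM)."""
    c = np.asarray(c, dtype=float)
    if (c < 0).any():
        raise ValueError("negative VEGF concentration")
    L = np.asarray(mean_attached_length, dtype=float)
    return params.P_max * L * params.E_L * c / (c + params.c_50)


def migration_direction(m_p, grad_c, chi: float):
    """Blend of persistence direction and normalised chemotactic drift;
    the chemotactic term is zero where the gradient vanishes."""
    m_p = np.atleast_2d(np.asarray(m_p, dtype=float))
    g = np.atleast_2d(np.asarray(grad_c, dtype=float))
    gn = np.linalg.norm(g, axis=1)
    ghat = np.where(gn[:, None] > 0, g / np.where(gn == 0, 1.0, gn)[:, None], 0.0)
    return (m_p + chi * ghat) / (1.0 + chi)


def repulsion_strength(d, params: AngioParams):
    """Soft-contact strength phi(d), zero beyond d_crit, phi_max at contact."""
    d = np.asarray(d, dtype=float)
    with np.errstate(invalid="ignore"):
        phi = params.phi_max * (params.d_crit - d) / (params.d_crit + d)
    phi = np.where(np.isfinite(d), phi, 0.0)
    return np.clip(np.where(d >= params.d_crit, 0.0, phi), 0.0, params.phi_max)


def repulsion_vector(domain: TissueDomain, p, params: AngioParams):
    """phi(d) times the interior-pointing distance-map gradient."""
    d, u = domain.boundary_distance(p)
    return repulsion_strength(d, params)[:, None] * u


def persistence_directions(tau, sigma_deg: float, rng, two_d: bool):
    """Rotate unit tangents ``tau`` by angles from N(0, sigma): signed
    in-plane rotation in 2D, rotation in a uniformly random plane containing
    ``tau`` in 3D."""
    if sigma_deg < 0:
        raise ValueError("sigma must be non-negative")
    tau = np.atleast_2d(np.asarray(tau, dtype=float))
    n = len(tau)
    theta = rng.normal(0.0, np.deg2rad(sigma_deg), n)
    if two_d:
        cos, sin = np.cos(theta), np.sin(theta)
        out = np.zeros_like(tau)
        out[:, 0] = cos * tau[:, 0] - sin * tau[:, 1]
        out[:, 1] = sin * tau[:, 0] + cos * tau[:, 1]
        return out
    psi = rng.uniform(0.0, 2 * np.pi, n)
    e1, e2 = _orthonormal_frame(tau)
    perp = np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2
    return np.cos(theta)[:, None] * tau + np.sin(theta)[:, None] * perp


def _orthonormal_frame(tau):
    """Two unit vectors spanning the plane normal to each ``tau``."""
    a = np.zeros_like(tau)
    smallest = np.argmin(np.abs(tau), axis=1)
    a[np.arange(len(tau)), smallest] = 1.0
    e1 = np.cross(tau, a)
    e1 /= np.linalg.norm(e1, axis=1)[:, None]
    e2 = np.cross(tau, e1)
    return e1, e2


# =========================================================================
# simulation driver
# =========================================================================


class Simulation:
    """Orchestrates the ordered sub-stages on a network in a tissue domain.

    ``field`` is any VEGF source exposing ``concentration(points)`` and
    ``sample(points) -> (c, grad)`` (fixed field or finite-element field).
    One RNG stream drives all stochastic draws in a documented fixed order
    (migration angles, anastomosis audit order, sprout uniforms, sprout
    directions), so a run is bitwise reproducible from its seed.
    """

    def __init__(
        self,
        domain: TissueDomain,
        network: VesselNetwork,
        field,
        params: AngioParams | None = None,
        rng: np.random.Generator | int | None = None,
        *,
        anastomosis: bool = True,
        sprouting: bool = True,
        limbal_sprouting_only: bool = False,
        log_events: bool = False,
    ):
        self.domain = domain
        self.network = network
        self.field = field
        self.params = params or AngioParams()
        self.rng = (
            rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        )
        self.anastomosis = anastomosis
        self.sprouting = sprouting
        self.limbal_sprouting_only = limbal_sprouting_only
        self.log_events = log_events
        self.time = 0.0
        self.events: list[tuple] = []
        self._n_initial = network.n_nodes
        self._origin_pos = np.zeros((0, 3))
        self._origin_time = np.zeros(0)

    # ------------------------------------------------------------------ step

    def step(self):
        """One global step: migrate, anastomose, sprout, anastomose."""
        self._migrate_stage(0)
        if self.anastomosis:
            self._anastomose_stage(1)
        # with secondary sprouting de-activated, sprouting may still be
        # permitted at the limbus (initial vessel) only
        if self.sprouting or self.limbal_sprouting_only:
            self._sprout_stage(2)
        if self.anastomosis:
            self._anastomose_stage(3)
        self.time += self.params.dt

    def run(self, duration: float):
        n = int(round(duration / self.params.dt))
        if abs(n * self.params.dt - duration) > 1e-9:
            raise ValueError("duration must be a multiple of dt")
        for _ in range(n):
            self.step()

    def _log(self, stage, kind, i, j=-1):
        if self.log_events:
            self.events.append((self.time, stage, kind, int(i), int(j)))

    # ------------------------------------------------------------- migration

    def _migrate_stage(self, stage: int):
        net = self.network
        par = self.params
        dom = self.domain
        tips = net.tip_ids
        if len(tips) == 0:
            return
        pos = net.positions[tips].copy()
        tau = net.persistence_dirs[tips].copy()
        _, grad = self.field.sample(pos)
        r = repulsion_vector(dom, pos, par)
        two_d = dom.is_2d
        n = len(tips)
        new_pos = np.zeros((n, 3))
        pending = np.ones(n, dtype=bool)
        step_len = par.s * par.dt
        for _attempt in range(par.max_redraws + 1):
            idx = np.flatnonzero(pending)
            if len(idx) == 0:
                break
            m_p = persistence_directions(tau[idx], par.sigma, self.rng, two_d)
            m = migration_direction(m_p, grad[idx], par.chi)
            v = m + r[idx]
            nv = np.linalg.norm(v, axis=1)
            nonzero = nv > 1e-12
            cand = pos[idx] + step_len * v / np.where(nv == 0, 1.0, nv)[:, None]
            ok = nonzero & dom.contains(cand)
            hit = idx[ok]
            new_pos[hit] = cand[ok]
            pending[hit] = False
        moved = ~pending
        if moved.any():
            new_ids = net.move_tips(tips[moved], new_pos[moved])
            if self.log_events:
                for old, new in zip(tips[moved], new_ids):
                    self._log(stage, "migrate", old, new)

    # ------------------------------------------------------------ anastomosis

    def _anastomose_stage(self, stage: int):
        net = self.network
        par = self.params
        while True:
            tips = net.tip_ids
            if len(tips) == 0 or net.n_segments == 0:
                return
            order = self.rng.permutation(len(tips))
            tips = tips[order]
            segs = net.segments
            pos = net._pos
            mid = 0.5 * (pos[segs[:, 0]] + pos[segs[:, 1]])
            l_max = float(net.segment_lengths.max())
            tree = cKDTree(mid)
            cand_lists = tree.query_ball_point(
                pos[tips], par.r_ana + 0.5 * l_max + 1e-9
            )
            events = 0
            for tip, cands in zip(tips, cand_lists):
                if not cands:
                    continue
                if not (net._migrating[tip] and net._alive[tip]):
                    continue
                if self._try_anastomose(tip, np.asarray(cands), stage):
                    events += 1
            if events == 0:
                return
            # splits create new segments: re-audit until quiescent

    def _try_anastomose(self, tip: int, cand, stage: int) -> bool:
        """Re-validate candidate segments against current topology and apply
        the nearest eligible fusion."""
        net = self.network
        par = self.params
        segs = net.segments[cand]
        parent = net._nbr[tip, 0]
        excl = (
            (segs[:, 0] == tip)
            | (segs[:, 1] == tip)
            | (segs[:, 0] == parent)
            | (segs[:, 1] == parent)
            # a tip never fuses with its own vessel (sprout lineage);
            # lineage 0 means "no identity" (hand-built networks)
            | (
                (net._node_lineage[tip] != 0)
                & (net._seg_lineage[cand] == net._node_lineage[tip])
            )
        )
        if excl.all():
            return False
        cand = cand[~excl]
        segs = segs[~excl]
        p = net._pos[tip]
        dist, t, foot = point_segment_distance(
            p[None, :], net._pos[segs[:, 0]], net._pos[segs[:, 1]]
        )
        k = int(np.argmin(dist))
        if dist[k] >= par.r_ana:
            return False
        seg_idx = int(cand[k])
        tk = float(t[k])
        a, b = net.segments[seg_idx]
        endpoint = -1
        if tk <= 1e-9:
            endpoint = int(a)
        elif tk >= 1.0 - 1e-9:
            endpoint = int(b)
        try:
            if endpoint >= 0 and net.has_segment(int(parent), endpoint):
                # the fusion loop already exists; just retire the tip
                net.deactivate(tip)
                self._log(stage, "tip_retired", tip, endpoint)
            elif endpoint >= 0 and net._migrating[endpoint] and net._alive[endpoint]:
                net.merge_tip_into(tip, endpoint)
                net.deactivate(endpoint)
                self._log(stage, "tip_to_tip", tip, endpoint)
            elif endpoint >= 0:
                net.merge_tip_into(tip, endpoint)
                self._log(stage, "tip_to_vessel", tip, endpoint)
            else:
                if np.linalg.norm(foot[k] - net._pos[parent]) < 1e-9:
                    net.deactivate(tip)
                    self._log(stage, "tip_retired", tip, seg_idx)
                else:
                    net.relocate_node(tip, foot[k])
                    net.split_segment_at(seg_idx, tip, tk)
                    net.deactivate(tip)
                    self._log(stage, "tip_to_vessel", tip, seg_idx)
        except ValueError:
            # degenerate merge (coincident nodes); retire the tip instead
            net.deactivate(tip)
            return True
        return True

    # -------------------------------------------------------------- sprouting

    def _sprout_stage(self, stage: int):
        net = self.network
        par = self.params
        dom = self.domain
        eligible = net.alive & ~net.migrating & (net.degrees >= 1)
        if self.limbal_sprouting_only:
            eligible[self._n_initial:] = False
        ids = np.flatnonzero(eligible)
        if len(ids) == 0:
            return
        pos = net.positions[ids]
        c = self.field.concentration(pos)
        P = sprout_rate(np.maximum(c, 0.0), net.mean_attached_length()[ids], par)
        z = self.rng.uniform(size=len(ids))
        cand = z < P * par.dt
        cand_ids = ids[cand]
        if len(cand_ids) == 0:
            return
        cand_pos = pos[cand]
        d_inh = par.inhibition_distance
        if par.inhibition_window is not None:
            active = self._origin_time >= self.time - par.inhibition_window + 1e-9
            self._origin_pos = self._origin_pos[active]
            self._origin_time = self._origin_time[active]
        clear_of_prior = np.ones(len(cand_ids), dtype=bool)
        if len(self._origin_time):
            tree = cKDTree(self._origin_pos)
            dmin, _ = tree.query(cand_pos)
            clear_of_prior = dmin >= d_inh
        # greedy selection in random audit order with mutual inhibition
        order = self.rng.permutation(len(cand_ids))
        acc = np.zeros(len(cand_ids), dtype=bool)
        acc_pos = np.empty((len(cand_ids), 3))
        n_acc = 0
        for k in order:
            if not clear_of_prior[k]:
                continue
            if n_acc:
                if np.min(
                    np.linalg.norm(acc_pos[:n_acc] - cand_pos[k], axis=1)
                ) < d_inh:
                    continue
            acc[k] = True
            acc_pos[n_acc] = cand_pos[k]
            n_acc += 1
        if n_acc == 0:
            return
        sel_ids = cand_ids[acc]
        sel_pos = cand_pos[acc]
        tau = net.tangents(sel_ids)
        if dom.is_2d:
            perp = np.column_stack([-tau[:, 1], tau[:, 0], np.zeros(n_acc)])
            sign = np.where(self.rng.uniform(size=n_acc) < 0.5, 1.0, -1.0)
            dirs = sign[:, None] * perp
        else:
            psi = self.rng.uniform(0.0, 2 * np.pi, n_acc)
            e1, e2 = _orthonormal_frame(tau)
            dirs = np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2
        tip_pos = sel_pos + par.s * par.dt * dirs
        inside = dom.contains(tip_pos)
        if inside.any():
            new_ids = net.add_nodes(
                tip_pos[inside], migrating=True, persist_dirs=dirs[inside]
            )
            net.assign_new_lineages(new_ids)
            net.add_segments(np.column_stack([sel_ids[inside], new_ids]))
            if self.log_events:
                for parent, new in zip(sel_ids[inside], new_ids):
                    self._log(stage, "sprout", parent, new)
        # all selected nodes (even aborted sprouts) inhibit for the window
        self._origin_pos = np.vstack([self._origin_pos, sel_pos])
        self._origin_time = np.concatenate(
            [self._origin_time, np.full(n_acc, self.time)]
        )
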