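"""Discrete vessel-network representation.

A network is a graph of point nodes joined by straight, infinitesimally thin
segments (vessel centrelines). Nodes carry a radius, a ``migrating`` flag
marking active sprout tips (always degree 1) and, for tips, the persistence
direction of the random walk. A constant linear density ``EL`` of
endothelial cells per unit vessel length is assumed on every segment.

Storage is flat numpy arrays with amortised growth so that per-step updates
over many thousands of tips stay vectorised. Nodes are never deleted;
tip merges mark nodes dead instead.
"""

from __future__ import annotations

import numpy as np

from .geometry import TissueDomain

__all__ = [
    "VesselNetwork",
    "create_initial_vessel",
    "point_segment_distance",
]

DEFAULT_RADIUS = 5.0  # um
DEFAULT_EL = 0.05  # endothelial cells per um vessel length


def point_segment_distance(p, a, b):
    """Distance from point(s) ``p`` to finite segment(s) ``a``-``b``.

    Broadcasts over leading dimensions; returns ``(dist, t, foot)`` where
    ``t`` in [0, 1] is the clamped projection parameter and ``foot`` the
    closest point on the segment.
    """
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = np.einsum("...i,...i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(np.einsum("...i,...i", p - a, ab) / denom, 0.0, 1.0)
    foot = a + t[..., None] * ab
    dist = np.linalg.norm(p - foot, axis=-1)
    return dist, t, foot


class VesselNetwork:
    """Graph of nodes and straight segments with vectorised storage."""

    def __init__(self, radius: float = DEFAULT_RADIUS, EL: float = DEFAULT_EL):
        self.radius = float(radius)
        self.EL = float(EL)
        cap = 64
        self._pos = np.zeros((cap, 3))
        self._migrating = np.zeros(cap, dtype=bool)
        self._alive = np.zeros(cap, dtype=bool)
        self._persist = np.zeros((cap, 3))
        self._degree = np.zeros(cap, dtype=np.int64)
        self._len_sum = np.zeros(cap)  # sum of attached segment lengths
        self.n_nodes = 0
        self._seg = np.zeros((cap, 2), dtype=np.int64)
        self._seg_len = np.zeros(cap)
        self.n_segments = 0
        self.total_length = 0.0
        self._seg_keys: set[tuple[int, int]] = set()
        # sprout lineage: each sprout event starts a new vessel id; trail
        # nodes/segments inherit it. Used to exclude a tip's own vessel
        # from anastomosis candidates.
        self._node_lineage = np.zeros(cap, dtype=np.int64)
        self._seg_lineage = np.zeros(cap, dtype=np.int64)
        self._next_lineage = 1
        # first two neighbour node ids per node (-1 = empty), kept for fast
        # tangent estimates when choosing sprout directions
        self._nbr = -np.ones((cap, 2), dtype=np.int64)

    # ------------------------------------------------------------------ views

    @property
    def positions(self) -> np.ndarray:
        return self._pos[: self.n_nodes]

    @property
    def migrating(self) -> np.ndarray:
        return self._migrating[: self.n_nodes]

    @property
    def alive(self) -> np.ndarray:
        return self._alive[: self.n_nodes]

    @property
    def persistence_dirs(self) -> np.ndarray:
        return self._persist[: self.n_nodes]

    @property
    def degrees(self) -> np.ndarray:
        return self._degree[: self.n_nodes]

    @property
    def segments(self) -> np.ndarray:
        return self._seg[: self.n_segments]

    @property
    def segment_lengths(self) -> np.ndarray:
        return self._seg_len[: self.n_segments]

    @property
    def tip_ids(self) -> np.ndarray:
        return np.flatnonzero(self.migrating & self.alive)

    def mean_attached_length(self) -> np.ndarray:
        """L_s: average length of the segments joined to each node (a
        single-segment node uses that segment's length)."""
        deg = np.maximum(self.degrees, 1)
        return self._len_sum[: self.n_nodes] / deg

    # ------------------------------------------------------------------ growth

    def _grow_nodes(self, extra):
        need = self.n_nodes + extra
        cap = len(self._pos)
        if need <= cap:
            return
        new_cap = max(need, 2 * cap)
        for name in ("_pos", "_persist"):
            arr = getattr(self, name)
            out = np.zeros((new_cap, 3))
            out[: self.n_nodes] = arr[: self.n_nodes]
            setattr(self, name, out)
        for name, dtype in (
            ("_migrating", bool),
            ("_alive", bool),
            ("_degree", np.int64),
            ("_len_sum", float),
        ):
            arr = getattr(self, name)
            out = np.zeros(new_cap, dtype=dtype)
            out[: self.n_nodes] = arr[: self.n_nodes]
            setattr(self, name, out)
        nbr = -np.ones((new_cap, 2), dtype=np.int64)
        nbr[: self.n_nodes] = self._nbr[: self.n_nodes]
        self._nbr = nbr
        nl = np.zeros(new_cap, dtype=np.int64)
        nl[: self.n_nodes] = self._node_lineage[: self.n_nodes]
        self._node_lineage = nl

    def _grow_segments(self, extra):
        need = self.n_segments + extra
        cap = len(self._seg)
        if need <= cap:
            return
        new_cap = max(need, 2 * cap)
        seg = np.zeros((new_cap, 2), dtype=np.int64)
        seg[: self.n_segments] = self._seg[: self.n_segments]
        self._seg = seg
        sl = np.zeros(new_cap)
        sl[: self.n_segments] = self._seg_len[: self.n_segments]
        self._seg_len = sl
        lg = np.zeros(new_cap, dtype=np.int64)
        lg[: self.n_segments] = self._seg_lineage[: self.n_segments]
        self._seg_lineage = lg

    def add_node(self, pos, migrating=False, persist_dir=None) -> int:
        self._grow_nodes(1)
        i = self.n_nodes
        self._pos[i] = pos
        self._migrating[i] = migrating
        self._alive[i] = True
        if persist_dir is not None:
            self._persist[i] = persist_dir
        self.n_nodes += 1
        return i

    def add_segment(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("segment endpoints must be distinct")
        length = float(np.linalg.norm(self._pos[j] - self._pos[i]))
        if length <= 0:
            raise ValueError("zero-length segment")
        if self.has_segment(i, j):
            raise ValueError("duplicate segment")
        self._seg_keys.add((min(i, j), max(i, j)))
        self._grow_segments(1)
        s = self.n_segments
        self._seg[s] = (i, j)
        self._seg_len[s] = length
        self.n_segments += 1
        for k in (i, j):
            self._degree[k] += 1
            self._len_sum[k] += length
        self._note_neighbour(i, j)
        self._note_neighbour(j, i)
        self._seg_lineage[s] = self._node_lineage[j]
        self.total_length += length
        return s

    def has_segment(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self._seg_keys

    def _note_neighbour(self, i, j):
        if self._nbr[i, 0] < 0:
            self._nbr[i, 0] = j
        elif self._nbr[i, 1] < 0 and self._nbr[i, 0] != j:
            self._nbr[i, 1] = j

    # ------------------------------------------------------------ batch edits

    def add_nodes(self, pos, migrating=False, persist_dirs=None) -> np.ndarray:
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        k = len(pos)
        self._grow_nodes(k)
        i0 = self.n_nodes
        self._pos[i0 : i0 + k] = pos
        self._migrating[i0 : i0 + k] = migrating
        self._alive[i0 : i0 + k] = True
        if persist_dirs is not None:
            self._persist[i0 : i0 + k] = persist_dirs
        self.n_nodes += k
        return np.arange(i0, i0 + k)

    def add_segments(self, pairs) -> np.ndarray:
        pairs = np.atleast_2d(np.asarray(pairs, dtype=np.int64))
        k = len(pairs)
        lens = np.linalg.norm(
            self._pos[pairs[:, 1]] - self._pos[pairs[:, 0]], axis=1
        )
        if (lens <= 0).any():
            raise ValueError("zero-length segment in batch")
        lo = np.minimum(pairs[:, 0], pairs[:, 1])
        hi = np.maximum(pairs[:, 0], pairs[:, 1])
        self._seg_keys.update(zip(lo.tolist(), hi.tolist()))
        self._grow_segments(k)
        s0 = self.n_segments
        self._seg[s0 : s0 + k] = pairs
        self._seg_len[s0 : s0 + k] = lens
        self.n_segments += k
        np.add.at(self._degree, pairs.ravel(), 1)
        np.add.at(self._len_sum, pairs.ravel(), np.repeat(lens, 2))
        self._seg_lineage[s0 : s0 + k] = self._node_lineage[pairs[:, 1]]
        self.total_length += float(lens.sum())
        # neighbour bookkeeping: each endpoint appears at most once per batch
        for col, other in ((0, 1), (1, 0)):
            i = pairs[:, col]
            j = pairs[:, other]
            slot0_free = self._nbr[i, 0] < 0
            self._nbr[i[slot0_free], 0] = j[slot0_free]
            slot1 = ~slot0_free & (self._nbr[i, 1] < 0) & (self._nbr[i, 0] != j)
            self._nbr[i[slot1], 1] = j[slot1]
        return np.arange(s0, s0 + k)

    def move_tips(self, tips, new_pos) -> np.ndarray:
        """Advance several migrating tips at once (trail growth): append new
        tip nodes, demote the old ones, transfer the migrating flag."""
        tips = np.asarray(tips, dtype=np.int64)
        new_pos = np.atleast_2d(np.asarray(new_pos, dtype=float))
        d = new_pos - self._pos[tips]
        d /= np.linalg.norm(d, axis=1)[:, None]
        new = self.add_nodes(new_pos, migrating=True, persist_dirs=d)
        self._node_lineage[new] = self._node_lineage[tips]
        self._migrating[tips] = False
        self.add_segments(np.column_stack([tips, new]))
        return new

    def assign_new_lineages(self, nodes) -> None:
        nodes = np.asarray(nodes, dtype=np.int64)
        self._node_lineage[nodes] = np.arange(
            self._next_lineage, self._next_lineage + len(nodes)
        )
        self._next_lineage += len(nodes)

    def segment_lineages(self) -> np.ndarray:
        return self._seg_lineage[: self.n_segments]

    def tangents(self, nodes) -> np.ndarray:
        """Fast unit tangent estimate at nodes from the cached first two
        neighbours (chord through the neighbours, or the single attached
        segment direction)."""
        nodes = np.asarray(nodes, dtype=np.int64)
        n1 = self._nbr[nodes, 0]
        n2 = self._nbr[nodes, 1]
        a = np.where((n2 >= 0)[:, None], self._pos[n2], self._pos[nodes])
        t = a - self._pos[n1]
        nrm = np.linalg.norm(t, axis=1)
        # degenerate chord (e.g. symmetric fold-back): fall back to first segment
        bad = nrm < 1e-9
        if bad.any():
            t[bad] = self._pos[nodes[bad]] - self._pos[n1[bad]]
            nrm = np.linalg.norm(t, axis=1)
            nrm[nrm == 0] = 1.0
        return t / nrm[:, None]

    # --------------------------------------------------------- topology edits

    def node_tangent(self, i: int) -> np.ndarray:
        """Unit tangent at a node: mean of unit directions of its attached
        segments (oriented away from lower-id endpoint)."""
        segs = self.segments
        mask = (segs[:, 0] == i) | (segs[:, 1] == i)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError(f"node {i} has no attached segment")
        d = self._pos[segs[idx, 1]] - self._pos[segs[idx, 0]]
        d /= np.linalg.norm(d, axis=1)[:, None]
        # orient consistently before averaging
        ref = d[0]
        d *= np.where(d @ ref < 0, -1.0, 1.0)[:, None]
        t = d.mean(axis=0)
        nrm = np.linalg.norm(t)
        return ref if nrm < 1e-12 else t / nrm

    def insert_sprout(self, parent: int, direction, s: float, dt: float,
                      domain: TissueDomain | None = None):
        """Create a sprout: a new migrating node offset ``s*dt`` from the
        parent along ``direction`` (normal to the parent segment), joined to
        the parent.

        Returns the new tip id, or None if the offset position leaves the
        tissue (sprout aborted, no mutation).
        """
        direction = np.asarray(direction, dtype=float)
        nrm = np.linalg.norm(direction)
        if nrm < 1e-12:
            raise ValueError("degenerate sprout direction")
        direction = direction / nrm
        tangent = self.node_tangent(parent)
        if abs(float(direction @ tangent)) > 1e-6:
            raise ValueError("sprout direction must be normal to the parent segment")
        pos = self._pos[parent] + s * dt * direction
        if domain is not None and not domain.contains_point(pos):
            return None
        tip = self.add_node(pos, migrating=True, persist_dir=direction)
        self._node_lineage[tip] = self._next_lineage
        self._next_lineage += 1
        self._seg_lineage[self.add_segment(parent, tip)] = self._node_lineage[tip]
        return tip

    def move_tip(self, tip: int, new_pos) -> int:
        """Advance a migrating tip: append a node at ``new_pos``, demote the
        old tip to an interior node, transfer the migrating flag. Returns the
        new tip id."""
        if not self._migrating[tip]:
            raise ValueError("node is not a migrating tip")
        d = np.asarray(new_pos, dtype=float) - self._pos[tip]
        nrm = np.linalg.norm(d)
        new = self.add_node(new_pos, migrating=True, persist_dir=d / nrm)
        self._migrating[tip] = False
        self.add_segment(tip, new)
        return new

    def deactivate(self, tip: int):
        self._migrating[tip] = False

    def merge_tip_into(self, tip: int, target: int):
        """Tip-to-tip merge: re-point the tip's trailing segment at
        ``target`` (the tip is moved to be coincident and absorbed)."""
        segs = self.segments
        mask = (segs[:, 0] == tip) | (segs[:, 1] == tip)
        idx = np.flatnonzero(mask)
        if len(idx) != 1:
            raise ValueError("tip must have degree 1")
        s = idx[0]
        a, b = self._seg[s]
        other = b if a == tip else a
        if other == target:
            raise ValueError("cannot merge tip into its own parent")
        old_len = self._seg_len[s]
        new_len = float(np.linalg.norm(self._pos[target] - self._pos[other]))
        if new_len <= 0:
            raise ValueError("merge would create a zero-length segment")
        if self.has_segment(other, target):
            raise ValueError("duplicate segment")
        self._seg_keys.discard((min(int(a), int(b)), max(int(a), int(b))))
        self._seg_keys.add((min(int(other), int(target)), max(int(other), int(target))))
        self._seg[s] = (other, target)
        self._seg_len[s] = new_len
        self.total_length += new_len - old_len
        self._len_sum[other] += new_len - old_len
        self._len_sum[target] += new_len
        self._degree[target] += 1
        self._len_sum[tip] = 0.0
        self._degree[tip] = 0
        self._migrating[tip] = False
        self._alive[tip] = False
        self._nbr[other][self._nbr[other] == tip] = target
        self._note_neighbour(target, other)
        self._nbr[tip] = -1

    def split_segment_at(self, seg_idx: int, junction: int, t: float):
        """Split segment ``seg_idx`` at parameter ``t`` by routing it through
        the existing node ``junction`` (already positioned at the foot
        point). Replaces (a, b) by (a, junction) and appends (junction, b)."""
        a, b = self._seg[seg_idx]
        old_len = self._seg_len[seg_idx]
        len_a = float(np.linalg.norm(self._pos[junction] - self._pos[a]))
        len_b = float(np.linalg.norm(self._pos[b] - self._pos[junction]))
        if len_a <= 0 or len_b <= 0:
            raise ValueError("split point coincides with a segment endpoint")
        self._seg_keys.discard((min(int(a), int(b)), max(int(a), int(b))))
        self._seg_keys.add((min(int(a), int(junction)), max(int(a), int(junction))))
        self._seg_keys.add((min(int(junction), int(b)), max(int(junction), int(b))))
        self._seg[seg_idx] = (a, junction)
        self._seg_len[seg_idx] = len_a
        self._grow_segments(1)
        s2 = self.n_segments
        self._seg[s2] = (junction, b)
        self._seg_len[s2] = len_b
        self.n_segments += 1
        self.total_length += len_a + len_b - old_len
        self._len_sum[a] += len_a - old_len
        self._len_sum[b] += len_b - old_len
        self._len_sum[junction] += len_a + len_b
        self._degree[junction] += 2
        self._nbr[a][self._nbr[a] == b] = junction
        self._nbr[b][self._nbr[b] == a] = junction
        self._note_neighbour(junction, a)
        self._note_neighbour(junction, b)
        return s2

    def relocate_node(self, i: int, new_pos):
        """Move a node and update cached lengths of its attached segments."""
        self._pos[i] = new_pos
        segs = self.segments
        mask = (segs[:, 0] == i) | (segs[:, 1] == i)
        for s in np.flatnonzero(mask):
            a, b = self._seg[s]
            old = self._seg_len[s]
            new = float(np.linalg.norm(self._pos[b] - self._pos[a]))
            self._seg_len[s] = new
            self.total_length += new - old
            self._len_sum[a] += new - old
            self._len_sum[b] += new - old

    # ---------------------------------------------------------------- queries

    def nearest_segment(self, p, excluded=()):
        """Exact nearest finite segment to point ``p``.

        Returns ``(seg_index, distance, t, foot)`` or ``None`` when no
        candidate segment remains after exclusions.
        """
        if self.n_segments == 0:
            return None
        p = np.asarray(p, dtype=float)
        segs = self.segments
        a = self._pos[segs[:, 0]]
        b = self._pos[segs[:, 1]]
        dist, t, foot = point_segment_distance(p[None, :], a, b)
        if len(excluded):
            dist = dist.copy()
            dist[np.asarray(list(excluded), dtype=np.int64)] = np.inf
        k = int(np.argmin(dist))
        if not np.isfinite(dist[k]):
            return None
        return k, float(dist[k]), float(t[k]), foot[k]

    # --------------------------------------------------------------- densities

    def density_fields(self, grid):
        """Vessel line density rho and tip density n on a structured grid.

        ``grid`` provides ``origin``, ``spacing``, ``shape`` (3-tuple; 2D
        grids have shape[2] == 1) and ``cell_volume``. Segment length is
        clipped exactly to the half-open cells, so ``sum(rho) * cell_volume``
        equals the total network length and ``sum(n) * cell_volume`` the tip
        count, for any resolution.
        """
        shape = tuple(grid.shape)
        origin = np.asarray(grid.origin, dtype=float)
        h = float(grid.spacing)
        rho = np.zeros(shape)
        n = np.zeros(shape)
        vol = float(grid.cell_volume)
        if vol <= 0:
            raise ValueError("zero-volume grid cells")
        if self.n_segments:
            segs = self.segments
            a = self._pos[segs[:, 0]]
            b = self._pos[segs[:, 1]]
            L = self._seg_len[: self.n_segments]
            _deposit_segments(rho, origin, h, shape, a, b, L)
            rho /= vol
        tips = self.tip_ids
        if len(tips):
            idx = _cell_index(self._pos[tips], origin, h, shape)
            np.add.at(n, idx, 1.0)
            n /= vol
        return rho, n

    # ------------------------------------------------------------------ audit

    def validate(self, rtol: float = 1e-6):
        """Topology audit; raises AssertionError on inconsistency."""
        segs = self.segments
        assert self.n_segments == 0 or segs.max() < self.n_nodes, "dangling segment reference"
        lens = np.linalg.norm(
            self._pos[segs[:, 1]] - self._pos[segs[:, 0]], axis=1
        )
        assert (lens > 0).all(), "zero-length segment"
        assert np.allclose(lens, self.segment_lengths, rtol=rtol), "stale segment lengths"
        key = np.sort(segs, axis=1)
        assert len(np.unique(key, axis=0)) == len(key), "duplicate segment"
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, segs.ravel(), 1)
        assert (deg == self.degrees).all(), "degree bookkeeping mismatch"
        tips = self.tip_ids
        assert (self.degrees[tips] == 1).all(), "migrating node with degree != 1"
        assert abs(self.total_length - lens.sum()) <= rtol * max(1.0, lens.sum()), (
            "total length bookkeeping mismatch"
        )

    # ------------------------------------------------------------------- I/O

    def to_csv(self, node_path, segment_path):
        import pandas as pd

        nodes = pd.DataFrame(
            {
                "id": np.arange(self.n_nodes),
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "radius": self.radius,
                "migrating": self.migrating.astype(int),
                "alive": self.alive.astype(int),
            }
        )
        nodes.to_csv(node_path, index=False)
        segs = pd.DataFrame(
            {
                "node0": self.segments[:, 0],
                "node1": self.segments[:, 1],
                "length": self.segment_lengths,
            }
        )
        segs.to_csv(segment_path, index=False)

    def to_vtk(self, path):
        from ._vtk import write_polydata

        point_data = {
            "Radius": np.full(self.n_nodes, self.radius),
            "Migrating": self.migrating.astype(float),
        }
        write_polydata(path, self.positions, self.segments, point_data)


# =========================================================================
# helpers
# =========================================================================


def _cell_index(p, origin, h, shape):
    idx = np.floor((p - origin) / h).astype(np.int64)
    out = []
    for d in range(3):
        out.append(np.clip(idx[:, d], 0, shape[d] - 1))
    return tuple(out)


def _deposit_segments(rho, origin, h, shape, a, b, L):
    """Exact clipping of segments to half-open grid cells."""
    short = L < h
    if short.any():
        _deposit_short(rho, origin, h, shape, a[short], b[short], L[short])
    rest = ~short
    if rest.any():
        for aa, bb, ll in zip(a[rest], b[rest], L[rest]):
            _deposit_one(rho, origin, h, shape, aa, bb, ll)


def _deposit_short(rho, origin, h, shape, a, b, L):
    """Vectorised path for segments shorter than one cell (at most one plane
    crossing per axis): split at the crossing parameters, deposit midpoints."""
    m = len(a)
    ts = np.ones((m, 5))
    ts[:, 0] = 0.0
    ia = np.floor((a - origin) / h).astype(np.int64)
    ib = np.floor((b - origin) / h).astype(np.int64)
    for d in range(3):
        cross = ia[:, d] != ib[:, d]
        if not cross.any():
            continue
        plane = origin[d] + np.maximum(ia[cross, d], ib[cross, d]) * h
        denom = b[cross, d] - a[cross, d]
        t = (plane - a[cross, d]) / denom
        ts[cross, 1 + d] = np.clip(t, 0.0, 1.0)
    ts.sort(axis=1)
    t0 = ts[:, :-1]
    t1 = ts[:, 1:]
    seg_len = (t1 - t0) * L[:, None]
    mid = a[:, None, :] + 0.5 * (t0 + t1)[:, :, None] * (b - a)[:, None, :]
    flat_mid = mid.reshape(-1, 3)
    flat_len = seg_len.ravel()
    keep = flat_len > 0
    idx = _cell_index(flat_mid[keep], origin, h, shape)
    np.add.at(rho, idx, flat_len[keep])


def _deposit_one(rho, origin, h, shape, a, b, L):
    ts = [0.0, 1.0]
    for d in range(3):
        lo, hi = sorted((a[d], b[d]))
        k0 = int(np.floor((lo - origin[d]) / h)) + 1
        k1 = int(np.floor((hi - origin[d]) / h))
        denom = b[d] - a[d]
        for k in range(k0, k1 + 1):
            plane = origin[d] + k * h
            ts.append((plane - a[d]) / denom)
    ts = np.clip(np.unique(ts), 0.0, 1.0)
    for t0, t1 in zip(ts[:-1], ts[1:]):
        if t1 <= t0:
            continue
        mid = a + 0.5 * (t0 + t1) * (b - a)
        idx = _cell_index(mid[None, :], origin, h, shape)
        rho[idx] += (t1 - t0) * L


def create_initial_vessel(
    domain: TissueDomain, eps: float | None = None, node_spacing: float = 10.0
) -> VesselNetwork:
    """The pre-existing limbal vessel: a polyline (planar domains) or closed
    ring (circle/hemisphere) at limbus distance ``eps``, mid-way through the
    thickness in 3D domains."""
    pts, closed = domain.initial_vessel_path(node_spacing=node_spacing, eps=eps)
    net = VesselNetwork()
    ids = [net.add_node(p) for p in pts]
    for i, j in zip(ids[:-1], ids[1:]):
        net.add_segment(i, j)
    if closed:
        net.add_segment(ids[-1], ids[0])
    return net
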