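import numpy as np
import pytest

from micropocket import GeometryParams, build_domain
from micropocket.geometry import OUTER, PELLET, DomainKind

ALL_KINDS = [k.value for k in DomainKind]


# --------------------------------------------------------------------- params


@pytest.mark.parametrize(
    "kw",
    [
        {"R": -1.0},
        {"T_p": 200.0},  # thicker than the cornea
        {"eps": 1000.0, "h": 1000.0},  # eps must be < h
        {"kind": "circle_2d", "h": 1200.0},  # pellet would not fit
        {"kind": "hemisphere", "h": 1400.0},
    ],
)
def test_invalid_geometry_rejected(kw):
    with pytest.raises(ValueError):
        GeometryParams(**kw)


def test_unknown_domain_kind_rejected():
    with pytest.raises(ValueError):
        GeometryParams(kind="moebius")


def test_pellet_width_convention():
    assert GeometryParams(kind="planar_2d").w == 2000.0
    assert GeometryParams(kind="planar_2d_finite").w == 400.0


# ------------------------------------------------------------------ placement


def test_circle_pellet_centred_at_default_height():
    # R = h + eps + r_p for the reference parameters: the pellet disc sits
    # exactly at the centre of the circular domain
    dom = build_domain(GeometryParams(kind="circle_2d"))
    assert np.allclose(dom.pellet_centre[:2], 0.0)
    dom7 = build_domain(GeometryParams(kind="circle_2d", h=700.0))
    assert np.allclose(dom7.pellet_centre[:2], [300.0, 0.0])


def test_planar3d_pellet_mid_thickness_clearance():
    dom = build_domain(GeometryParams(kind="planar_3d_finite"), resolve_pellet=True)
    x, y = 1000.0, 1150.0  # inside pellet footprint
    assert dom.in_pellet([[x, y, 50.0]])[0]
    assert not dom.in_pellet([[x, y, 29.0]])[0]  # 30 um clearance each side
    assert not dom.in_pellet([[x, y, 71.0]])[0]


def test_hemisphere_pellet_projected_height():
    # top-down projection of the placed centre must give height h to < 1 um
    for h in (700.0, 1000.0):
        dom = build_domain(GeometryParams(kind="hemisphere", h=h))
        c = dom.pellet_centre
        projected = dom.params.R - np.hypot(c[0], c[1])
        assert abs(projected - h) < 1.0
        # centre on the mid-surface, inside the shell
        assert abs(np.linalg.norm(c) - (dom.params.R - dom.params.T / 2)) < 1e-9
        assert dom.contains_point(c)


# ----------------------------------------------------------------- membership


def test_contains_examples():
    p2 = build_domain(GeometryParams(kind="planar_2d"))
    assert p2.contains_point([1000.0, 750.0, 0.0])
    c2 = build_domain(GeometryParams(kind="circle_2d"))
    assert not c2.contains_point([1301.0, 0.0, 0.0])
    hemi = build_domain(GeometryParams(kind="hemisphere"))
    assert hemi.contains_point([0.0, 0.0, 1250.0])  # mid-thickness on the axis
    assert not hemi.contains_point([0.0, 0.0, 100.0])  # hollow interior
    assert not hemi.contains_point([0.0, 500.0, -5.0])  # below the limbus plane


def test_resolved_pellet_is_not_tissue():
    dom = build_domain(GeometryParams(kind="circle_2d"), resolve_pellet=True)
    assert not dom.contains_point([0.0, 0.0, 0.0])
    unresolved = build_domain(GeometryParams(kind="circle_2d"))
    assert unresolved.contains_point([0.0, 0.0, 0.0])


# ----------------------------------------------------------- boundary distance


def test_boundary_distance_planar3d():
    dom = build_domain(GeometryParams(kind="planar_3d"))
    d, u = dom.boundary_distance([[500.0, 500.0, 50.0], [500.0, 500.0, 10.0]])
    assert d[0] == pytest.approx(50.0)
    assert d[1] == pytest.approx(10.0)
    assert np.allclose(u[1], [0, 0, 1])  # inward normal of the z=0 face


def test_boundary_distance_hemisphere_radial():
    dom = build_domain(GeometryParams(kind="hemisphere"))
    R, T = dom.params.R, dom.params.T
    p = np.array([[0.0, 0.0, R - T / 4]])
    d, u = dom.boundary_distance(p)
    assert d[0] == pytest.approx(T / 4)
    assert np.allclose(u[0], [0, 0, -1])  # closer to the outer surface


def test_boundary_distance_empty_in_2d():
    dom = build_domain(GeometryParams(kind="planar_2d"))
    d, u = dom.boundary_distance([[100.0, 100.0, 0.0]])
    assert np.isinf(d[0])


# -------------------------------------------------------------- limbus metric


def test_limbus_distance_examples():
    p2 = build_domain(GeometryParams(kind="planar_2d"))
    assert p2.limbus_distance([[0.0, 300.0, 0.0]])[0] == pytest.approx(300.0)
    c2 = build_domain(GeometryParams(kind="circle_2d"))
    assert c2.limbus_distance([[1300.0, 0.0, 0.0]])[0] == pytest.approx(0.0)
    hemi = build_domain(GeometryParams(kind="hemisphere"))
    pole = hemi.limbus_distance([[0.0, 0.0, 1250.0]])[0]
    assert pole == pytest.approx(np.pi / 2 * 1300.0)


@pytest.mark.parametrize("kind", ALL_KINDS)
def test_interior_point_queries_consistent(kind, rng):
    """contains / distance / limbus-coordinate sanity on random interior
    points, including the distance-map gradient consistency d(x + delta u)
    = d(x) + delta."""
    dom = build_domain(GeometryParams(kind=kind))
    lo, hi = dom.bounding_box()
    pts = rng.uniform(lo, np.where(hi > lo, hi, lo + 1.0), size=(4000, 3))
    if dom.is_2d:
        pts[:, 2] = 0.0
    inside = dom.contains(pts)
    pts = pts[inside]
    assert len(pts) > 50
    xi = dom.limbus_distance(pts)
    assert (xi >= -1e-9).all()
    assert (xi <= dom.max_limbus_distance + 1e-9).all()
    d, u = dom.boundary_distance(pts)
    assert (d >= 0).all()
    if dom.is_2d:
        return
    sel = d > 1.0  # keep the probe step well-defined
    delta = 0.5
    d2, _ = dom.boundary_distance(pts[sel] + delta * u[sel])
    assert np.allclose(d2, d[sel] + delta, rtol=0.05, atol=1e-6)


def test_initial_vessel_path_counts():
    p2 = build_domain(GeometryParams(kind="planar_2d"))
    pts, closed = p2.initial_vessel_path(10.0)
    assert len(pts) == 201 and not closed
    assert np.allclose(pts[:, 1], 100.0)
    c2 = build_domain(GeometryParams(kind="circle_2d"))
    pts, closed = c2.initial_vessel_path(10.0)
    assert closed
    assert np.allclose(np.hypot(pts[:, 0], pts[:, 1]), 1200.0)
    hemi = build_domain(GeometryParams(kind="hemisphere"))
    pts, closed = hemi.initial_vessel_path(10.0)
    assert closed and hemi.contains(pts).all()
    assert np.allclose(hemi.limbus_distance(pts), 100.0, atol=1e-6)


# ----------------------------------------------------------------------- mesh


def test_mesh_requires_sensible_edge():
    dom = build_domain(GeometryParams(kind="planar_3d"))
    with pytest.raises(ValueError):
        dom.generate_mesh(-1.0)
    with pytest.raises(ValueError):
        dom.generate_mesh(5000.0)


@pytest.mark.parametrize(
    "kind,edge",
    [
        ("planar_2d", 30.0),
        ("planar_2d_finite", 30.0),
        ("circle_2d", 30.0),
        ("planar_3d", 40.0),
        ("planar_3d_finite", 40.0),
        ("circle_3d", 40.0),
        ("hemisphere", 60.0),
    ],
)
def test_mesh_measure_matches_analytic(kind, edge):
    dom = build_domain(GeometryParams(kind=kind), resolve_pellet=True)
    mesh = dom.generate_mesh(edge)
    assert (mesh.measures > 0).all()
    assert mesh.total_measure() == pytest.approx(dom.tissue_measure(), rel=0.02)
    # boundary facets all carry exactly one recognised tag
    assert set(np.unique(mesh.facet_tags)) <= {OUTER, PELLET}
    assert len(mesh.facet_tags) == len(mesh.facets)
    assert (mesh.facet_tags == PELLET).any()


def test_disc_mesh_converges_with_refinement():
    dom = build_domain(GeometryParams(kind="circle_2d"), resolve_pellet=True)
    errs = [
        abs(dom.generate_mesh(e).total_measure() / dom.tissue_measure() - 1.0)
        for e in (120.0, 60.0, 30.0)
    ]
    assert errs[2] < errs[0]
    assert errs[2] < 0.02


def test_circle3d_pellet_interface_area():
    # resolved pellet: cylinder side + two caps
    dom = build_domain(GeometryParams(kind="circle_3d"), resolve_pellet=True)
    mesh = dom.generate_mesh(30.0)
    area = mesh.facet_measures[mesh.facet_tags == PELLET].sum()
    r_p, T_p = 200.0, 40.0
    exact = 2 * np.pi * r_p * T_p + 2 * np.pi * r_p**2
    assert area == pytest.approx(exact, rel=0.02)


def test_circle2d_pellet_interface_length():
    dom = build_domain(GeometryParams(kind="circle_2d"), resolve_pellet=True)
    mesh = dom.generate_mesh(30.0)
    length = mesh.facet_measures[mesh.facet_tags == PELLET].sum()
    assert length == pytest.approx(2 * np.pi * 200.0, rel=0.02)


def test_planar_interface_is_near_face_only():
    # extended pellet: interface spans the full width; finite pellet: w = 2 r_p
    ext = build_domain(GeometryParams(kind="planar_2d"), resolve_pellet=True)
    m = ext.generate_mesh(30.0)
    assert m.facet_measures[m.facet_tags == PELLET].sum() == pytest.approx(2000.0)
    fin = build_domain(GeometryParams(kind="planar_2d_finite"), resolve_pellet=True)
    m = fin.generate_mesh(30.0)
    assert m.facet_measures[m.facet_tags == PELLET].sum() == pytest.approx(400.0)
    # 3D finite: rectangle w x T_p
    fin3 = build_domain(GeometryParams(kind="planar_3d_finite"), resolve_pellet=True)
    m = fin3.generate_mesh(40.0)
    assert m.facet_measures[m.facet_tags == PELLET].sum() == pytest.approx(400.0 * 40.0)
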