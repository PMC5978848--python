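"""Geometry synthesis: surface invariants, Laplacian, geodesic graph."""

import numpy as np
import pytest
from scipy.integrate import dblquad
from scipy.sparse.csgraph import connected_components, dijkstra

from edlimaging import (
    ConductivitySetup,
    GeometryError,
    TriangleSurface,
    build_torso,
    build_ventricle,
    geodesic_graph,
    surface_laplacian,
    winding_fraction,
)
from edlimaging.geometry import _ellipsoid_mesh, _fiber_directions


def ellipsoid_area_oracle(a, b, c):
    """Surface area of an ellipsoid by direct numerical quadrature."""
    def integrand(theta, phi):
        # |r_theta x r_phi| for the standard spherical parameterization
        st, ct, sp, cp = np.sin(theta), np.cos(theta), np.sin(phi), np.cos(phi)
        e = (b * c * st ** 2 * cp) ** 2 + (a * c * st ** 2 * sp) ** 2 \
            + (a * b * st * ct) ** 2
        return np.sqrt(e)
    val, _ = dblquad(integrand, 0, 2 * np.pi, 0, np.pi, epsabs=1e-8)
    return val


class TestSurfaces:
    def test_shell_ventricle_topology(self, shell_ventricle):
        """Two genus-0 boundary components: epicardial shell + cavity wall."""
        s = shell_ventricle.surface
        assert s.is_closed()
        assert s.euler_characteristic() == 4  # 2 components x chi 2
        comps = s.components()
        assert len(comps) == 2
        for ids in comps:
            assert s.submesh(ids).euler_characteristic() == 2
        assert s.signed_volume() > 0  # wall volume, outward from myocardium

    def test_biventricular_topology(self, default_ctx):
        s = default_ctx.ventricle.surface
        assert s.is_closed()
        comps = s.components()
        assert len(comps) == 3
        assert s.euler_characteristic() == 6
        assert s.signed_volume() > 0
        cls = default_ctx.ventricle.sampling.node_class
        assert set(np.unique(cls)) == {"endo", "epi", "septal"}

    def test_degenerate_fiber_rule(self):
        """Zero rotation: the fiber is independent of wall depth."""
        pts = np.tile([[10.0, 0.0, 5.0]], (5, 1))
        depth = np.linspace(0, 1, 5)
        f = _fiber_directions(pts, depth, rotation_deg=0.0)
        assert np.allclose(f, f[0])
        f2 = _fiber_directions(pts, depth, rotation_deg=120.0)
        assert not np.allclose(f2, f2[0])
        assert np.allclose(np.linalg.norm(f2, axis=1), 1.0)

    def test_mesh_convergence_to_analytic_area(self):
        """Refined ellipsoid meshes converge to the quadrature area."""
        semi = (30.0, 30.0, 50.0)
        exact = ellipsoid_area_oracle(*semi)
        areas = [abs(_ellipsoid_mesh(semi, (0, 0, 0), sub, "e").area())
                 for sub in (2, 3, 4)]
        errs = [abs(a - exact) / exact for a in areas]
        assert errs[2] < errs[1] < errs[0]
        assert abs(areas[2] - areas[1]) / areas[2] < 0.01

    def test_wall_thickness_precondition(self):
        with pytest.raises(GeometryError):
            build_ventricle(kind="shell", wall_thickness=40.0,
                            short_axis=33.0)

    def test_too_coarse_rejected(self):
        with pytest.raises(GeometryError):
            build_ventricle(kind="shell", resolution=40.0)


class TestTorso:
    def test_default_conductor(self, shell_vcm):
        assert len(shell_vcm.electrodes) == 120
        labels = {s.label: (si, so) for s, si, so in shell_vcm.compartments}
        assert labels["thorax"] == (0.2, 0.0)
        assert labels["lung_left"] == (0.04, 0.2)
        # bulk heart = sum of isotropic intra- and extracellular values
        setup = ConductivitySetup.preset("isotropic")
        assert labels["ventricle"][0] == pytest.approx(
            setup.sigma_i_t + setup.sigma_e_t) == pytest.approx(0.2)
        assert labels["blood_lv"] == (0.6, 0.2)

    def test_electrodes_on_surface(self, shell_vcm):
        t = shell_vcm.torso
        d = np.min(np.linalg.norm(
            t.vertices[None] - shell_vcm.electrodes[:, None], axis=-1),
            axis=1)
        assert d.max() < 1e-9

    def test_nesting(self, shell_vcm):
        torso = shell_vcm.torso
        for surf, _, _ in shell_vcm.compartments[1:]:
            frac = winding_fraction(surf.vertices, torso.vertices,
                                    torso.faces)
            assert np.all(frac > 0.99)

    def test_lungs_omitted(self, shell_ventricle):
        vcm = build_torso(shell_ventricle, include_lungs=False)
        labels = [s.label for s, _, _ in vcm.compartments]
        assert not any("lung" in x for x in labels)
        vcm.validate()


class TestLaplacian:
    def test_constant_annihilated_and_symmetric(self, shell_ventricle):
        lap = surface_laplacian(shell_ventricle.surface)
        n = shell_ventricle.surface.n_vertices
        assert np.abs(lap @ np.ones(n)).max() == 0.0
        assert (lap - lap.T).nnz == 0 or \
            np.abs((lap - lap.T).toarray()).max() < 1e-12

    def test_linear_field_on_regular_flat_patch(self):
        """Umbrella Laplacian annihilates linear fields on a regular
        triangulated patch (interior vertices)."""
        k = 12
        ii, jj = np.meshgrid(np.arange(k), np.arange(k), indexing="ij")
        # equilateral lattice
        x = ii + 0.5 * jj
        y = np.sqrt(3) / 2 * jj
        pts = np.stack([x.ravel(), y.ravel(), 0 * x.ravel()], axis=1)
        idx = lambda i, j: i * k + j  # noqa: E731
        faces = []
        for i in range(k - 1):
            for j in range(k - 1):
                faces.append([idx(i, j), idx(i + 1, j), idx(i, j + 1)])
                faces.append([idx(i + 1, j), idx(i + 1, j + 1), idx(i, j + 1)])
        surf = TriangleSurface(pts, np.array(faces), "patch")
        # open patch: build the umbrella operator directly from edges
        from scipy.sparse import coo_matrix, diags
        e = surf.edges()
        a = coo_matrix((np.ones(2 * len(e)),
                        (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
                       shape=(len(pts), len(pts))).tocsr()
        lap = a - diags(np.asarray(a.sum(axis=1)).ravel())
        tau = 2.0 * pts[:, 0] - 0.7 * pts[:, 1] + 3.0
        res = lap @ tau
        interior = (ii > 0) & (ii < k - 1) & (jj > 0) & (jj < k - 1)
        assert np.abs(res[interior.ravel()]).max() < 1e-8

    def test_open_surface_rejected(self):
        tri = TriangleSurface(np.eye(3), np.array([[0, 1, 2]]), "open")
        with pytest.raises(GeometryError):
            surface_laplacian(tri)


class TestGeodesicGraph:
    def test_connected_and_transmural_flagged(self, shell_graph, shell_vcm):
        n, _ = connected_components(shell_graph.lengths, directed=False)
        assert n == 1
        assert shell_graph.transmural.nnz > 0
        # transmural edges are about one wall thickness long
        tm_len = shell_graph.transmural.multiply(shell_graph.lengths)
        w = shell_vcm.ventricle.params["wall_thickness"]
        assert tm_len.data.max() < 3.5 * w

    def test_travel_time_weighting(self, shell_graph):
        t1 = shell_graph.travel_times(1.0, 1.0)
        t2 = shell_graph.travel_times(2.0, 1.0)
        surf_mask = shell_graph.lengths - \
            shell_graph.transmural.multiply(shell_graph.lengths)
        assert np.allclose(2 * (t2 - shell_graph.transmural.multiply(t2)
                                ).toarray(),
                           surf_mask.toarray())

    def test_line_graph_distances(self):
        # two triangles sharing an edge: distances follow edge lengths
        pts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0.0]])
        faces = np.array([[0, 1, 2], [0, 2, 3]])
        surf = TriangleSurface(pts, faces, "patch")
        gg = geodesic_graph(surf, np.empty((0, 2), int))
        d = dijkstra(gg.travel_times(1.0, 1.0), indices=0)
        assert d[0] == 0.0
        assert d[1] == pytest.approx(1.0)
        assert d[2] == pytest.approx(np.sqrt(2))

    def test_geodesic_dominates_euclidean(self, shell_graph, shell_vcm):
        rng = np.random.default_rng(0)
        v = shell_vcm.ventricle.surface.vertices
        src = rng.integers(0, len(v), 20)
        d = dijkstra(shell_graph.lengths, directed=False, indices=src)
        for k, i in enumerate(src):
            eu = np.linalg.norm(v - v[i], axis=1)
            assert np.all(d[k] >= eu - 1e-9)

    def test_disconnected_rejected(self, shell_vcm):
        vent = shell_vcm.ventricle
        with pytest.raises(GeometryError):
            geodesic_graph(vent.surface, np.empty((0, 2), int))
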