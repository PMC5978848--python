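"""Fastest-route initial estimates and Levenberg-Marquardt refinement."""

import numpy as np
import pandas as pd
import pytest

from edlimaging import (
    DEFAULT_TEMPLATE,
    SHARP_TEMPLATE,
    TriangleSurface,
    add_noise,
    edl_forward,
    fra_candidates,
    geodesic_graph,
    multifocal_sinus_estimate,
    optimize_activation,
    rank_candidates,
    second_best,
)
from edlimaging.bem import TransferMatrix
from edlimaging.inverse import InitialEstimate, _score_maps


def random_surface_graph(rng, n=40):
    """Random convex triangulation plus a few random transmural links."""
    from scipy.spatial import ConvexHull
    pts = rng.normal(size=(n, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= rng.uniform(20, 40)
    hull = ConvexHull(pts)
    surf = TriangleSurface(pts, hull.simplices, "random")
    k = rng.integers(2, 6)
    pairs = rng.integers(0, n, size=(k, 2))
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    if len(pairs) == 0:
        pairs = np.array([[0, n // 2]])
    return geodesic_graph(surf, pairs)


class TestFRACandidates:
    def test_line_graph(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [1, 1, 0]])
        faces = np.array([[0, 1, 3], [1, 2, 3]])
        g = geodesic_graph(TriangleSurface(pts, faces, "strip"),
                           np.empty((0, 2), int))
        maps = fra_candidates(g, v_surface=1.0, v_transmural=1.0)
        assert maps[0, 0] == 0.0
        assert maps[0, 1] == pytest.approx(1.0)
        assert maps[0, 2] == pytest.approx(2.0)

    def test_shortest_path_axioms(self, shell_graph):
        maps = fra_candidates(shell_graph)
        n = shell_graph.n
        assert np.allclose(np.diag(maps), 0.0)
        rng = np.random.default_rng(5)
        i, j, k = rng.integers(0, n, size=(3, 50))
        assert np.all(maps[i, j] <= maps[i, k] + maps[k, j] + 1e-9)
        assert np.allclose(maps, maps.T, atol=1e-9)  # symmetric weights


class TestRanking:
    def test_self_consistency(self, shell_maps, shell_transfer):
        k = 123
        measured = edl_forward(shell_transfer, shell_maps[k],
                               DEFAULT_TEMPLATE)
        est = rank_candidates(shell_maps, shell_transfer, DEFAULT_TEMPLATE,
                              measured)
        assert est.node == k
        assert est.cor == pytest.approx(1.0, abs=1e-9)
        assert est.rd == pytest.approx(0.0, abs=1e-6)

    def test_top_two_percent_subset(self):
        """1500 candidates -> a 30-member shortlist; the min-RD member of
        the shortlist wins even when a higher-COR candidate exists."""
        rng = np.random.default_rng(0)
        n, nodes = 1500, 40
        maps = rng.uniform(0, 50, size=(n, nodes))
        a = TransferMatrix(rng.normal(size=(12, nodes)), np.zeros((12, 3)),
                           1.0)
        measured = edl_forward(a, maps[7], DEFAULT_TEMPLATE)
        est = rank_candidates(maps, a, DEFAULT_TEMPLATE, measured)
        assert int(np.ceil(0.02 * n)) == 30
        assert est.node == 7
        assert est.rank < 30
        assert len(est.table) == n

    def test_sharp_and_smooth_scorers_agree(self, shell_maps,
                                            shell_transfer):
        """The cumulative-sum scorer (Heaviside) matches the dense path
        evaluated with a very narrow logistic upstroke."""
        from edlimaging.sources import TMPTemplate
        measured = edl_forward(shell_transfer, shell_maps[50],
                               SHARP_TEMPLATE)
        sel = shell_maps[::97]
        c_sharp, r_sharp = _score_maps(shell_transfer, SHARP_TEMPLATE,
                                       measured, sel)
        c_narrow, r_narrow = _score_maps(shell_transfer,
                                         TMPTemplate(width=1e-3),
                                         measured, sel)
        assert np.allclose(c_sharp, c_narrow, atol=5e-3)
        assert np.allclose(r_sharp, r_narrow, atol=5e-3)

    def test_zero_variance_rejected(self, shell_maps, shell_transfer):
        from edlimaging.sources import BSPM
        flat = BSPM(np.zeros((120, 10)), np.arange(10.0))
        with pytest.raises(ValueError):
            rank_candidates(shell_maps, shell_transfer, DEFAULT_TEMPLATE,
                            flat)


class TestSecondBest:
    def _table(self, nodes, cors):
        return pd.DataFrame({"node": nodes, "cor": cors,
                             "rd": np.zeros(len(nodes))})

    def test_empty_when_all_nearby(self):
        pos = np.zeros((5, 3))
        pos[:, 0] = [0.0, 5, 10, 15, 20]
        maps = np.zeros((5, 5))
        est = InitialEstimate(0, maps[0], 0.9, 0.1, 0,
                              self._table(np.arange(5), [.9, .8, .7, .6, .5]),
                              tau_maps=maps)
        assert second_best(est, pos, min_separation=30.0) is None

    def test_returns_other_cluster_head(self):
        pos = np.zeros((6, 3))
        pos[3:, 0] = 50.0
        maps = np.zeros((6, 6))
        est = InitialEstimate(0, maps[0], 0.90, 0.1, 0,
                              self._table(np.array([0, 1, 3, 4, 2, 5]),
                                          [.90, .89, .88, .87, .86, .85]),
                              tau_maps=maps)
        alt = second_best(est, pos, min_separation=30.0)
        assert alt is not None
        assert alt.node == 3  # best-ranked member of the distant cluster
        assert alt.cor == pytest.approx(0.88)


class TestMultifocal:
    def test_single_focus_returns_one(self, shell_maps, shell_transfer):
        measured = edl_forward(shell_transfer, shell_maps[200],
                               DEFAULT_TEMPLATE)
        est = multifocal_sinus_estimate(shell_maps, shell_transfer,
                                        DEFAULT_TEMPLATE, measured,
                                        top_k=40)
        assert len(est.foci) == 1
        assert est.foci[0][0] == 200

    def test_two_separated_foci_recovered(self, shell_maps, shell_transfer,
                                          shell_vcm):
        v = shell_vcm.ventricle.surface.vertices
        cls = shell_vcm.ventricle.sampling.node_class
        endo = np.where(cls == "endo")[0]
        f1 = int(endo[np.argmin(v[endo, 2])])
        f2 = int(endo[np.argmax(np.linalg.norm(v[endo] - v[f1], axis=1))])
        assert np.linalg.norm(v[f1] - v[f2]) > 50.0
        truth = np.minimum(shell_maps[f1], 5.0 + shell_maps[f2])
        measured = edl_forward(shell_transfer, truth, SHARP_TEMPLATE)
        est = multifocal_sinus_estimate(shell_maps, shell_transfer,
                                        SHARP_TEMPLATE, measured)
        assert len(est.foci) >= 2
        found = v[[f for f, _ in est.foci]]
        # every true seed is recovered by one of the returned foci
        for target in (v[f1], v[f2]):
            assert np.min(np.linalg.norm(found - target, axis=1)) < 10.0
        # combined map never above any single-focus component
        tau = est.tau
        for f, o in est.foci:
            assert np.all(tau <= o + shell_maps[f] + 1e-9)


class TestOptimizer:
    def test_stationary_at_truth(self, shell_maps, shell_transfer,
                                 shell_laplacian):
        truth = shell_maps[77]
        measured = edl_forward(shell_transfer, truth, DEFAULT_TEMPLATE)
        res = optimize_activation(truth.copy(), shell_transfer,
                                  DEFAULT_TEMPLATE, measured, 0.0,
                                  shell_laplacian, widths=(2.0,))
        assert np.array_equal(res.tau, truth)
        assert res.residual_norm < 1e-9

    def test_objective_monotone_over_accepted_steps(self, shell_maps,
                                                    shell_transfer,
                                                    shell_laplacian):
        truth = shell_maps[77]
        measured = add_noise(edl_forward(shell_transfer, truth,
                                         DEFAULT_TEMPLATE), 0.02, seed=3)
        init = shell_maps[90]
        res = optimize_activation(init, shell_transfer, DEFAULT_TEMPLATE,
                                  measured, 1e-3, shell_laplacian,
                                  widths=(2.0,), warmup=False, max_iter=25)
        h = res.objective_history
        assert len(h) > 3
        assert np.all(np.diff(h) <= 1e-12)

    def test_inverse_crime_from_fra_estimate(self, shell_maps,
                                             shell_transfer,
                                             shell_laplacian):
        """Noise-free self-generated data: FRA + LM recover the map to
        sub-millisecond RMS."""
        truth = shell_maps[300]
        measured = edl_forward(shell_transfer, truth, DEFAULT_TEMPLATE)
        est = rank_candidates(shell_maps, shell_transfer, DEFAULT_TEMPLATE,
                              measured)
        # optimize with the same template the data was generated with
        res = optimize_activation(est, shell_transfer, DEFAULT_TEMPLATE,
                                  measured, 0.0, shell_laplacian,
                                  widths=(2.0,))
        assert est.node == 300
        assert np.sqrt(np.mean((res.tau - truth) ** 2)) < 1.0

    def test_invalid_lambda(self, shell_maps, shell_transfer,
                            shell_laplacian):
        measured = edl_forward(shell_transfer, shell_maps[0],
                               DEFAULT_TEMPLATE)
        with pytest.raises(ValueError):
            optimize_activation(shell_maps[0], shell_transfer,
                                DEFAULT_TEMPLATE, measured, -1.0,
                                shell_laplacian)
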