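"""Surface Laplacian, dwPLI, global connectivity and graph metrics."""

import numpy as np
import pytest

from pulseloop.analysis import (
    ConnectivityMatrix,
    Epochs,
    binarize_top_proportion,
    dwpli_matrix,
    global_fc,
    graph_metrics,
    laplacian_fd,
)


class TestLaplacian:
    LABELS = ("Fz", "Cz", "Pz", "C3", "C4")

    def _adj(self):
        a = np.zeros((5, 5), bool)
        pairs = [(0, 1), (1, 2), (1, 3), (1, 4)]
        for i, j in pairs:
            a[i, j] = a[j, i] = True
        return a

    def test_uniform_potential_maps_to_zero(self):
        data = np.full((5, 100), 3.3)
        out = laplacian_fd(data, self.LABELS, self._adj())
        assert np.allclose(out, 0.0)

    def test_unit_impulse_spreads_as_minus_one_over_k(self):
        data = np.zeros((5, 1))
        data[1, 0] = 1.0  # impulse on Cz
        out = laplacian_fd(data, self.LABELS, self._adj())
        assert out[1, 0] == pytest.approx(1.0)       # Cz has 4 neighbors, all zero
        assert out[0, 0] == pytest.approx(-1.0)      # Fz's only neighbor is Cz
        assert out[2, 0] == pytest.approx(-1.0)

    def test_isolated_channel_rejected(self):
        a = self._adj()
        a[3, :] = a[:, 3] = False
        with pytest.raises(ValueError):
            laplacian_fd(np.zeros((5, 10)), self.LABELS, a)

    def test_mastoids_passed_through(self):
        labels = ("Fz", "Cz", "A1")
        a = np.zeros((3, 3), bool)
        a[0, 1] = a[1, 0] = True
        data = np.arange(6, dtype=float).reshape(3, 2)
        out = laplacian_fd(data, labels, a)
        assert np.array_equal(out[2], data[2])


def _epochs(data, rate=250.0):
    n = data.shape[-1]
    return Epochs(data=data, times=np.arange(n) / rate, rate=rate,
                  labels=tuple(f"c{i}" for i in range(data.shape[1])))


class TestDwpli:
    RATE = 250.0

    def _trials(self, build, n_trials=120, dur=1.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(dur * self.RATE)
        t = np.arange(n) / self.RATE
        return np.stack([build(rng, t) for _ in range(n_trials)])

    def test_constant_quarter_cycle_lag_saturates(self):
        def build(rng, t):
            ph = rng.uniform(0, 2 * np.pi)
            a = np.sin(2 * np.pi * 10 * t + ph) + 0.2 * rng.standard_normal(t.size)
            b = np.sin(2 * np.pi * 10 * t + ph + np.pi / 2) + 0.2 * rng.standard_normal(t.size)
            return np.stack([a, b])

        m = dwpli_matrix(_epochs(self._trials(build)), (9.0, 11.0))
        assert m.values[0, 1] > 0.9
        assert np.allclose(m.values, m.values.T, equal_nan=True)

    def test_zero_lag_mixture_is_near_zero(self):
        def build(rng, t):
            s = rng.standard_normal(t.size)
            return np.stack([s + 0.1 * rng.standard_normal(t.size),
                             0.6 * s + 0.1 * rng.standard_normal(t.size)])

        m = dwpli_matrix(_epochs(self._trials(build, n_trials=200)), (8.0, 12.0))
        assert abs(m.values[0, 1]) < 0.1

    def test_independent_noise_near_zero(self):
        def build(rng, t):
            return rng.standard_normal((3, t.size))

        m = dwpli_matrix(_epochs(self._trials(build, n_trials=200)), (8.0, 12.0))
        iu = np.triu_indices(3, 1)
        assert np.all(np.abs(m.values[iu]) < 0.1)

    def test_channel_permutation_equivariance(self):
        def build(rng, t):
            ph = rng.uniform(0, 2 * np.pi)
            return np.stack([
                np.sin(2 * np.pi * 10 * t + ph) + 0.3 * rng.standard_normal(t.size),
                np.sin(2 * np.pi * 10 * t + ph + 1.0) + 0.3 * rng.standard_normal(t.size),
                rng.standard_normal(t.size),
            ])

        data = self._trials(build, n_trials=60)
        m = dwpli_matrix(_epochs(data), (9.0, 11.0))
        perm = [2, 0, 1]
        mp = dwpli_matrix(_epochs(data[:, perm]), (9.0, 11.0))
        assert np.allclose(mp.values, m.values[np.ix_(perm, perm)], equal_nan=True)

    def test_single_observation_rejected(self):
        data = np.zeros((1, 2, 100))
        ep = _epochs(data)
        with pytest.raises(ValueError):
            dwpli_matrix(ep, (500.0, 600.0))


def _cm(values):
    v = np.asarray(values, dtype=float)
    v = 0.5 * (v + v.T)
    np.fill_diagonal(v, np.nan)
    return ConnectivityMatrix(v, (4.0, 7.0), tuple(f"c{i}" for i in range(v.shape[0])))


class TestGlobalFc:
    def test_uniform_half(self):
        assert global_fc(_cm(np.full((4, 4), 0.5))) == pytest.approx(0.5)

    def test_three_by_three_mean(self):
        m = np.zeros((3, 3))
        m[0, 1], m[0, 2], m[1, 2] = 0.1, 0.2, 0.3
        assert global_fc(_cm(m + m.T)) == pytest.approx(0.2)

    def test_matches_brute_force_loop(self, rng):
        v = rng.uniform(size=(6, 6))
        m = _cm(v)
        acc = [m.values[i, j] for i in range(6) for j in range(i + 1, 6)]
        assert global_fc(m) == pytest.approx(np.mean(acc))


class TestBinarize:
    def test_keeps_ceil_p_fraction(self, rng):
        m = _cm(rng.uniform(size=(5, 5)))
        adj = binarize_top_proportion(m, 0.2)
        assert adj.sum() // 2 == 2  # ceil(0.2 * 10)

    def test_p_one_gives_complete_graph(self, rng):
        adj = binarize_top_proportion(_cm(rng.uniform(size=(4, 4))), 1.0)
        assert adj.sum() == 4 * 3

    def test_matches_sort_oracle_with_ties(self, rng):
        for trial in range(20):
            v = rng.integers(0, 4, size=(6, 6)).astype(float)  # many ties
            m = _cm(v)
            adj = binarize_top_proportion(m, 0.3)
            iu, ju = np.triu_indices(6, 1)
            order = sorted(range(iu.size), key=lambda e: (-m.values[iu[e], ju[e]], iu[e], ju[e]))
            keep = set(order[: int(np.ceil(0.3 * iu.size))])
            expect = np.zeros((6, 6), bool)
            for e in keep:
                expect[iu[e], ju[e]] = expect[ju[e], iu[e]] = True
            assert np.array_equal(adj, expect)

    def test_invalid_proportion_rejected(self, rng):
        with pytest.raises(ValueError):
            binarize_top_proportion(_cm(rng.uniform(size=(4, 4))), 0.0)


class TestGraphMetrics:
    def test_complete_graph_efficiency_and_clustering_one(self):
        n = 5
        adj = ~np.eye(n, dtype=bool)
        gm = graph_metrics(adj, _cm(np.ones((n, n))))
        assert gm.global_efficiency == pytest.approx(1.0)
        assert gm.clustering_coefficient == pytest.approx(1.0)

    def test_star_more_heterogeneous_than_cycle(self):
        star = np.zeros((5, 5), bool)
        star[0, 1:] = star[1:, 0] = True
        cyc = np.zeros((5, 5), bool)
        for i in range(5):
            cyc[i, (i + 1) % 5] = cyc[(i + 1) % 5, i] = True
        w = _cm(np.ones((5, 5)))
        assert graph_metrics(star, w).degree_heterogeneity > graph_metrics(cyc, w).degree_heterogeneity
        assert graph_metrics(cyc, w).degree_heterogeneity == pytest.approx(0.0)

    def test_matches_bfs_and_triangle_oracle(self, rng):
        from collections import deque

        for trial in range(50):
            n = 10
            v = rng.uniform(size=(n, n))
            m = _cm(v)
            adj = binarize_top_proportion(m, 0.25)
            gm = graph_metrics(adj, m)
            # brute-force efficiency via BFS
            acc = []
            for s in range(n):
                dist = {s: 0}
                q = deque([s])
                while q:
                    u = q.popleft()
                    for vtx in np.flatnonzero(adj[u]):
                        if vtx not in dist:
                            dist[vtx] = dist[u] + 1
                            q.append(vtx)
                for tgt in range(n):
                    if tgt != s:
                        acc.append(1.0 / dist[tgt] if tgt in dist else 0.0)
            assert gm.global_efficiency == pytest.approx(np.mean(acc))
            # brute-force local clustering
            cs = []
            for u in range(n):
                nb = np.flatnonzero(adj[u])
                k = nb.size
                if k < 2:
                    cs.append(0.0)
                    continue
                links = sum(adj[a, b] for ii, a in enumerate(nb) for b in nb[ii + 1:])
                cs.append(2 * links / (k * (k - 1)))
            assert gm.clustering_coefficient == pytest.approx(np.mean(cs))

    def test_empty_graph_yields_zeros(self):
        gm = graph_metrics(np.zeros((4, 4), bool), _cm(np.ones((4, 4))))
        assert gm == type(gm)(0.0, 0.0, 0.0, 0.0)
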