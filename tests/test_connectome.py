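"""Edge features, Fisher z, framewise displacement, anatomical aggregation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import connpls as cp
from connpls.atlas import synthetic_parcellation
from connpls.connectome import _rigid_transform
from connpls.synthetic import generate_timeseries


class TestPearsonFC:
    def test_identical_columns_correlate_perfectly(self, rng):
        x = rng.standard_normal(50)
        ts = np.column_stack([x, x, rng.standard_normal(50)])
        r = cp.pearson_fc(ts)
        assert np.isclose(r[0, 1], 1.0)
        assert np.allclose(np.diag(r), 1.0)

    def test_constant_column_error_names_region(self):
        ts = np.random.default_rng(0).standard_normal((20, 3))
        ts[:, 1] = 5.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            cp.pearson_fc(ts)

    def test_recovers_planted_correlation_from_simulated_series(self):
        C = np.eye(4)
        C[0, 1] = C[1, 0] = 0.6
        r = cp.pearson_fc(generate_timeseries(C, 20000, seed=1))
        assert abs(r[0, 1] - 0.6) < 0.03


class TestFisherZ:
    def test_reference_values(self):
        r = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, -0.5], [0.5, -0.5, 1.0]])
        z = cp.fisher_z(r)
        assert z[0, 1] == 0.0
        # atanh(0.5) from an independent high-precision evaluation
        assert abs(z[0, 2] - 0.5493061443340549) < 1e-12
        assert np.all(np.diag(z) == 0.0)

    @given(st.floats(-0.999, 0.999))
    def test_odd_function_and_monotone(self, r):
        m = np.array([[1.0, r], [r, 1.0]])
        mneg = np.array([[1.0, -r], [-r, 1.0]])
        assert np.isclose(cp.fisher_z(m)[0, 1], -cp.fisher_z(mneg)[0, 1])
        if abs(r) < 0.99:
            bigger = np.array([[1.0, r + 0.005], [r + 0.005, 1.0]])
            assert cp.fisher_z(bigger)[0, 1] > cp.fisher_z(m)[0, 1]

    def test_perfect_correlation_rejected(self):
        r = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="infinite"):
            cp.fisher_z(r)


class TestEdgeVectorization:
    def test_edge_count_identity(self):
        assert cp.n_edges(246) == 30135
        assert cp.n_edges(4) == 6

    def test_canonical_order_n4(self):
        # 1-based pairs in row-major upper-triangle order
        pairs = cp.edge_index(4) + 1
        assert pairs.tolist() == [[1, 2], [1, 3], [1, 4], [2, 3], [2, 4], [3, 4]]
        m = np.zeros((4, 4))
        iu = np.triu_indices(4, 1)
        m[iu] = [10, 20, 30, 40, 50, 60]
        m = m + m.T
        assert cp.vectorize_edges(m).tolist() == [10, 20, 30, 40, 50, 60]

    @given(st.integers(2, 12), st.integers(0, 2**32 - 1))
    def test_roundtrip_is_bit_identical(self, n, seed):
        r = np.random.default_rng(seed).standard_normal((n, n))
        m = r + r.T
        np.fill_diagonal(m, 0.0)
        back = cp.devectorize_edges(cp.vectorize_edges(m), n)
        assert np.array_equal(back, m)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="n\\*\\(n-1\\)/2"):
            cp.devectorize_edges(np.zeros(7), 4)


class TestJenkinsonFD:
    def test_zero_motion_gives_zero_fd(self):
        mt = cp.jenkinson_fd(np.zeros((10, 6)))
        assert np.all(mt.fd_series == 0.0)
        assert not mt.excluded

    def test_pure_translation_reduces_to_step_length(self):
        params = np.zeros((2, 6))
        params[1, 0] = 1.0  # 1 mm in x
        mt = cp.jenkinson_fd(params)
        assert np.isclose(mt.fd_series[0], 1.0)

    def test_rotation_matches_sphere_rms_displacement_oracle(self, rng):
        # RMS displacement of points uniform in a radius-80 solid sphere under
        # the relative rigid transform, by Monte Carlo
        theta = 0.01
        params = np.zeros((2, 6))
        params[1, 5] = theta  # rotation about z
        fd = cp.jenkinson_fd(params).fd_series[0]
        npts = 200_000
        pts = rng.standard_normal((npts, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= 80.0 * rng.random(npts)[:, None] ** (1 / 3)
        R = _rigid_transform(params[1])[:3, :3]
        disp = pts @ (R - np.eye(3)).T
        rms = np.sqrt((disp**2).sum(axis=1).mean())
        assert abs(fd - rms) / rms < 0.01

    def test_invariant_to_common_rigid_offset(self, rng):
        """FD depends only on relative motion between consecutive frames."""

        def decompose(T):
            R, t = T[:3, :3], T[:3, 3]
            ry = np.arcsin(-R[2, 0])
            rx = np.arctan2(R[2, 1], R[2, 2])
            rz = np.arctan2(R[1, 0], R[0, 0])
            return np.array([t[0], t[1], t[2], rx, ry, rz])

        params = 0.05 * rng.standard_normal((6, 6))
        G = _rigid_transform([2.0, -1.0, 0.5, 0.1, -0.05, 0.2])
        shifted = np.array([decompose(_rigid_transform(p) @ G) for p in params])
        a = cp.jenkinson_fd(params).fd_series
        b = cp.jenkinson_fd(shifted).fd_series
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_exclusion_decision_matches_threshold(self):
        params = np.zeros((3, 6))
        params[1, 0] = 0.3
        params[2, 0] = 0.0
        mt = cp.jenkinson_fd(params)  # fd = [0.3, 0.3], mean 0.3 > 0.2
        assert mt.excluded
        assert not cp.jenkinson_fd(params, threshold=0.5).excluded


def _brute_force_block_means(L, labels, include_nonsig):
    """Independent per-block mean over upper-triangle edges."""
    names = []
    for v in labels:
        if v not in names:
            names.append(v)
    out = {}
    n = L.shape[0]
    for a in names:
        for b in names:
            vals = []
            for i in range(n):
                for j in range(i + 1, n):
                    pair = {labels[i], labels[j]} if labels[i] != labels[j] else {labels[i]}
                    if pair == ({a, b} if a != b else {a}):
                        if include_nonsig or L[i, j] != 0:
                            vals.append(L[i, j])
            out[(a, b)] = float(np.mean(vals)) if vals else 0.0
    return out


class TestAggregateLoadings:
    def setup_method(self):
        self.parc = synthetic_parcellation(12)

    def test_constant_loadings_average_to_constant(self):
        L = np.full((12, 12), 0.7)
        np.fill_diagonal(L, 0.0)
        agg = cp.aggregate_loadings(L, self.parc, level="lobe")
        nonempty = agg.edge_counts.to_numpy() > 0
        assert np.allclose(agg.values.to_numpy()[nonempty], 0.7)

    def test_singleton_significant_edge(self):
        labels = self.parc.labels("gyrus").to_numpy()
        L = np.zeros((12, 12))
        i, j = 0, 5
        L[i, j] = L[j, i] = 0.4
        agg = cp.aggregate_loadings(L, self.parc, level="gyrus")
        assert np.isclose(agg.values.loc[labels[i], labels[j]], 0.4)

    @pytest.mark.parametrize("include_nonsig", [False, True])
    def test_matches_brute_force_oracle(self, rng, include_nonsig):
        L = rng.standard_normal((12, 12))
        L = (L + L.T) / 2
        L[rng.random((12, 12)) < 0.6] = 0.0
        L = (L + L.T) / 2
        np.fill_diagonal(L, 0.0)
        labels = self.parc.labels("gyrus").to_numpy()
        agg = cp.aggregate_loadings(L, self.parc, level="gyrus", include_nonsignificant=include_nonsig)
        oracle = _brute_force_block_means(L, labels, include_nonsig)
        for a in agg.values.index:
            for b in agg.values.columns:
                assert np.isclose(agg.values.loc[a, b], oracle[(a, b)]), (a, b)

    def test_lobe_level_consistent_with_count_weighted_gyrus_level(self, rng):
        L = rng.standard_normal((12, 12))
        L = (L + L.T) / 2
        L[np.abs(L) < 0.7] = 0.0
        np.fill_diagonal(L, 0.0)
        gy = cp.aggregate_loadings(L, self.parc, level="gyrus")
        lo = cp.aggregate_loadings(L, self.parc, level="lobe")
        g2l = dict(zip(self.parc.table["gyrus"], self.parc.table["lobe"]))
        for la in lo.values.index:
            for lb in lo.values.columns:
                tot = cnt = 0.0
                for ga in gy.values.index:
                    for gb in gy.values.columns:
                        if g2l[ga] == la and g2l[gb] == lb:
                            w = gy.edge_counts.loc[ga, gb]
                            if ga != gb and g2l[ga] == g2l[gb] == la == lb:
                                w = w / 2  # off-diagonal gyrus blocks appear twice
                            tot += gy.values.loc[ga, gb] * w
                            cnt += w
                expected = tot / cnt if cnt else 0.0
                assert np.isclose(lo.values.loc[la, lb], expected), (la, lb)

    def test_asymmetric_input_rejected(self):
        L = np.zeros((12, 12))
        L[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            cp.aggregate_loadings(L, self.parc)
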