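import numpy as np
import pytest
import scipy.sparse as sp

from microcast.core_data import ContactMap
from microcast.preprocess import (
    aggregate_surrogate,
    build_graph,
    downsample_contacts,
    expected_by_distance,
    extract_windows,
    interpolate_contacts,
    oe_normalize,
    positional_encoding,
    stitch_predictions,
)


def raw_map(dense, res=1000, chrom="chr1"):
    return ContactMap(chrom, res, sp.coo_matrix(np.triu(dense)), state="raw",
                      n_bins=dense.shape[0])


class TestInterpolate:
    def test_constant_stays_constant(self):
        cm = ContactMap("c", 1000, np.full((4, 4), 3.0), state="oe", n_bins=4)
        fine = interpolate_contacts(cm, 200)
        assert fine.resolution == 200 and fine.n_bins == 20
        np.testing.assert_allclose(fine.to_dense(), 3.0)

    def test_identity_when_same_resolution(self):
        cm = raw_map(np.diag([1.0, 2.0]), res=200)
        assert interpolate_contacts(cm, 200) is cm

    def test_linear_between_centers(self):
        # closed-form bilinear oracle between the centers of a 2x2 map
        cm = ContactMap("c", 1000, np.array([[4.0, 0.0], [0.0, 4.0]]), state="oe", n_bins=2)
        fine = interpolate_contacts(cm, 200).to_dense()
        # coarse centers land at fine bins 2 and 7; along the row through
        # center (2, 2) values decrease linearly from 4 toward 0 at (2, 7)
        span = fine[2, 2:8]
        np.testing.assert_allclose(span, np.linspace(4.0, 0.0, 6), atol=1e-12)

    def test_center_values_preserved(self):
        rng = np.random.default_rng(5)
        dense = rng.random((5, 5))
        dense = np.triu(dense) + np.triu(dense, 1).T
        cm = ContactMap("c", 1000, dense, state="oe", n_bins=5)
        fine = interpolate_contacts(cm, 200).to_dense()
        for i in range(5):
            for j in range(i, 5):
                assert fine[5 * i + 2, 5 * j + 2] == pytest.approx(dense[i, j], abs=1e-12)

    def test_non_divisible_rejected(self):
        cm = raw_map(np.eye(3), res=500)
        with pytest.raises(ValueError):
            interpolate_contacts(cm, 200)


class TestOENormalize:
    def test_every_stratum_mean_is_one(self):
        rng = np.random.default_rng(0)
        dense = np.triu(rng.poisson(5, size=(30, 30)).astype(float))
        oe = oe_normalize(raw_map(dense))
        d = oe.upper_coo()
        n = oe.n_bins
        sums = np.bincount(d.col - d.row, weights=d.data, minlength=n)
        for k in range(n):
            if sums[k] > 0:
                assert sums[k] / (n - k) == pytest.approx(1.0, abs=1e-12)

    def test_hand_case_single_stratum(self):
        dense = np.zeros((4, 4))
        dense[0, 1], dense[2, 3] = 2.0, 4.0
        oe = oe_normalize(raw_map(dense))
        # stratum d=1 has 3 slots with entries {2, 4}: mean = 2
        assert oe.get(0, 1) == pytest.approx(1.0)
        assert oe.get(2, 3) == pytest.approx(2.0)

    def test_constant_map_becomes_ones(self):
        dense = np.full((6, 6), 2.5)
        oe = oe_normalize(raw_map(dense))
        np.testing.assert_allclose(oe.to_dense(), 1.0, atol=1e-12)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            oe_normalize(raw_map(np.zeros((3, 3))))

    def test_requires_raw_state(self):
        cm = ContactMap("c", 200, np.eye(3), state="oe", n_bins=3)
        with pytest.raises(ValueError):
            oe_normalize(cm)


class TestPositionalEncoding:
    def test_bin_zero_rows(self):
        pe = positional_encoding(10, 6)
        np.testing.assert_allclose(pe[0::2, 0], 0.0)
        np.testing.assert_allclose(pe[1::2, 0], 1.0)

    def test_data_independent_and_bounded(self):
        a, b = positional_encoding(50, 8), positional_encoding(50, 8)
        np.testing.assert_array_equal(a, b)
        assert np.all(np.abs(a) <= 1.0)

    def test_odd_dim_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(10, 7)


class TestBuildGraph:
    def test_zero_map_gives_identity_adjacency(self):
        fine = ContactMap("c", 200, np.zeros((5, 5)), state="oe", n_bins=5)
        g = build_graph(fine, np.zeros((2, 5)))
        np.testing.assert_array_equal(g.adjacency.toarray(), np.eye(5))

    def test_support_is_map_plus_diagonal(self):
        dense = np.zeros((6, 6))
        dense[0, 3] = 2.0
        dense[1, 2] = 0.5
        fine = ContactMap("c", 200, dense, state="oe", n_bins=6)
        g = build_graph(fine, np.ones((1, 6)), edge_threshold=0.0)
        adj = g.adjacency.toarray()
        expected = np.eye(6)
        expected[0, 3] = expected[3, 0] = 2.0
        expected[1, 2] = expected[2, 1] = 0.5
        np.testing.assert_array_equal(adj, expected)

    def test_node_degree_rowsum(self):
        rng = np.random.default_rng(3)
        dense = np.triu(rng.random((8, 8)) * (rng.random((8, 8)) > 0.5), 1)
        fine = ContactMap("c", 200, dense, state="oe", n_bins=8)
        g = build_graph(fine, np.ones((2, 8)))
        sym = dense + dense.T
        np.testing.assert_allclose(
            np.asarray(g.adjacency.sum(axis=1)).ravel(), sym.sum(axis=1) + 1.0
        )

    def test_dimension_mismatch(self):
        fine = ContactMap("c", 200, np.zeros((5, 5)), state="oe", n_bins=5)
        with pytest.raises(ValueError):
            build_graph(fine, np.zeros((2, 4)))

    def test_positional_rows_appended(self):
        fine = ContactMap("c", 200, np.zeros((5, 5)), state="oe", n_bins=5)
        g = build_graph(fine, np.ones((3, 5)), encoding_dim=4)
        assert g.node_features.shape == (7, 5)


class TestExtractWindows:
    def test_megabase_defaults(self):
        wins = extract_windows(1_000_000)
        assert len(wins) == 16
        assert [w[0] for w in wins[:3]] == [0, 50_000, 100_000]

    def test_bins_per_window(self):
        start, end = extract_windows(250_000)[0]
        assert (end - start) // 200 == 1250

    def test_exact_fit_single_window(self):
        assert extract_windows(250_000) == [(0, 250_000)]

    def test_short_chromosome(self):
        assert extract_windows(100_000) == []
        assert extract_windows(100_000, include_short=True) == [(0, 100_000)]

    def test_tail_right_aligned(self):
        wins = extract_windows(1_020_000)
        assert wins[-1] == (770_000, 1_020_000)
        # full coverage
        assert wins[0][0] == 0 and wins[-1][1] == 1_020_000


class TestDownsample:
    def test_rate_one_is_identity(self):
        cm = raw_map(np.triu(np.arange(16, dtype=float).reshape(4, 4)))
        out = downsample_contacts(cm, cm.total_contacts, seed=0)
        assert (out.matrix != cm.matrix).nnz == 0

    def test_binomial_expectation_over_seeds(self):
        rng = np.random.default_rng(11)
        dense = np.triu(rng.poisson(10, (20, 20)).astype(float))
        cm = raw_map(dense)
        total = cm.total_contacts
        target = total / 10
        draws = [downsample_contacts(cm, target, seed=s).total_contacts for s in range(100)]
        # total ~ Binomial(total, 0.1): se of the mean over 100 seeds
        se = np.sqrt(total * 0.1 * 0.9 / 100)
        assert abs(np.mean(draws) - target) < 3 * se

    def test_single_entry_binomial_distribution(self):
        dense = np.zeros((3, 3))
        dense[0, 1] = 100.0
        cm = raw_map(dense)
        draws = np.array(
            [downsample_contacts(cm, 50, seed=s).total_contacts for s in range(300)]
        )
        assert abs(draws.mean() - 50) < 3 * np.sqrt(100 * 0.25 / 300)
        assert abs(draws.var() - 25) < 10

    def test_deterministic_under_seed(self):
        cm = raw_map(np.triu(np.full((5, 5), 40.0)))
        a = downsample_contacts(cm, 100, seed=3)
        b = downsample_contacts(cm, 100, seed=3)
        assert (a.matrix != b.matrix).nnz == 0

    def test_target_above_total_rejected(self):
        cm = raw_map(np.eye(3))
        with pytest.raises(ValueError):
            downsample_contacts(cm, 10, seed=0)


class TestAggregateSurrogate:
    def test_equal_proportions_expectation(self):
        dense = np.triu(np.full((10, 10), 20.0))
        maps = [raw_map(dense) for _ in range(4)]
        per_total = maps[0].total_contacts
        out = [aggregate_surrogate(maps, 4 * per_total, seed=s) for s in range(30)]
        means = np.mean([o.total_contacts for o in out])
        assert means == pytest.approx(4 * per_total, rel=0.02)

    def test_four_maps_thinned_to_quarter(self):
        dense = np.triu(np.full((10, 10), 100.0))
        maps = [raw_map(dense) for _ in range(4)]
        totals = [
            aggregate_surrogate(maps, 1000, seed=s).total_contacts for s in range(50)
        ]
        assert np.mean(totals) == pytest.approx(1000, rel=0.05)

    def test_empty_map_contributes_zero(self):
        dense = np.triu(np.full((4, 4), 50.0))
        maps = [raw_map(dense), raw_map(np.zeros((4, 4)))]
        out = aggregate_surrogate(maps, 50, seed=1)
        assert out.total_contacts <= dense.sum()

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            aggregate_surrogate([raw_map(np.eye(3)), raw_map(np.eye(4))], 2, seed=0)


class TestStitch:
    def test_single_window_identity(self):
        n, w = 10, 4
        mat = np.triu(np.arange(100, dtype=float).reshape(10, 10))
        mat = (mat + mat.T) / 2
        out = stitch_predictions([(0, mat)], "c", n * 200, w * 200)
        dense = out.to_dense()
        for i in range(n):
            for j in range(i, min(n, i + w + 1)):
                assert dense[i, j] == pytest.approx(mat[i, j])

    def test_mean_of_two_overlapping(self):
        n, w = 6, 3
        a = np.full((n, n), 2.0)
        b = np.full((n, n), 4.0)
        out = stitch_predictions([(0, a), (400, b)], "c", 8 * 200, w * 200)
        dense = out.to_dense()
        assert dense[0, 1] == pytest.approx(2.0)        # only window a
        assert dense[3, 4] == pytest.approx(3.0)        # overlap -> mean
        assert dense[6, 7] == pytest.approx(4.0)        # only window b

    def test_band_limit(self):
        n, w = 10, 2
        out = stitch_predictions([(0, np.ones((n, n)))], "c", n * 200, w * 200)
        assert out.get(0, 3) == 0.0 and out.get(0, 2) == 1.0


def test_window_tiling_covers_band():
    # every diagonal pixel within the band is covered by >= 1 window
    L, window, step, band = 1_000_000, 250_000, 50_000, 200_000
    wins = extract_windows(L, window, step)
    nb, w = L // 200, band // 200
    covered = np.zeros(nb, dtype=bool)
    for s, e in wins:
        covered[s // 200 : e // 200] = True
    assert covered.all()
    for i in range(0, nb - w, 997):
        j = i + w
        assert any(s <= i * 200 and j * 200 < e for s, e in wins)
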