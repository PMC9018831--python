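import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats
from scipy.ndimage import uniform_filter

from microcast.core_data import ContactMap
from microcast.evaluation import (
    annotate_fragments,
    call_compartments,
    distance_stratified_pearson,
    eqtl_pileup,
    filter_eqtl_pairs,
    fragment_spearman,
    group_test,
    scc,
)


def oe_map(dense, res=200, chrom="chr1"):
    return ContactMap(chrom, res, sp.coo_matrix(np.triu(dense)), state="oe",
                      n_bins=dense.shape[0])


def random_band_map(n, w, seed, res=200):
    rng = np.random.default_rng(seed)
    idx = np.arange(n)
    d = np.abs(idx[:, None] - idx[None, :])
    dense = np.triu(rng.random((n, n)) * (d <= w))
    return oe_map(dense, res=res)


# -- independent brute-force oracles ----------------------------------------


def scc_bruteforce(a, b, h, dmax):
    """Loop-over-diagonals reference implementation of the SCC."""
    A = uniform_filter(a, size=2 * h + 1, mode="constant", cval=0.0)
    B = uniform_filter(b, size=2 * h + 1, mode="constant", cval=0.0)
    num = den = 0.0
    for d in range(dmax + 1):
        xa = np.array([A[i, i + d] for i in range(len(A) - d)])
        xb = np.array([B[i, i + d] for i in range(len(B) - d)])
        if len(xa) < 2 or xa.var() == 0 or xb.var() == 0:
            continue
        r = np.corrcoef(xa, xb)[0, 1]
        w = len(xa) * np.sqrt(xa.var() * xb.var())
        num += w * r
        den += w
    return num / den


def pearson_by_stratum_bruteforce(a, b, dmax):
    out = {}
    for d in range(1, dmax + 1):
        xa = np.array([a[i, i + d] for i in range(len(a) - d)])
        xb = np.array([b[i, i + d] for i in range(len(b) - d)])
        if len(xa) >= 2 and xa.var() > 0 and xb.var() > 0:
            out[d] = np.corrcoef(xa, xb)[0, 1]
    return out


class TestSCC:
    def test_self_correlation_is_one(self):
        m = random_band_map(80, 30, seed=0)
        assert scc(m, m, max_distance_bp=30 * 200).scc == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = random_band_map(80, 30, seed=1)
        b = random_band_map(80, 30, seed=2)
        r1 = scc(a, b, max_distance_bp=6000).scc
        a5 = oe_map(a.to_dense() * 5.0)
        b3 = oe_map(b.to_dense() * 3.0)
        r2 = scc(a5, b3, max_distance_bp=6000).scc
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_symmetric_in_arguments(self):
        a = random_band_map(60, 25, seed=3)
        b = random_band_map(60, 25, seed=4)
        assert scc(a, b, max_distance_bp=5000).scc == pytest.approx(
            scc(b, a, max_distance_bp=5000).scc, abs=1e-12
        )

    def test_matches_bruteforce_oracle(self):
        a = random_band_map(100, 40, seed=5)
        b = random_band_map(100, 40, seed=6)
        rep = scc(a, b, h=5, max_distance_bp=40 * 200)
        expected = scc_bruteforce(a.to_dense(), b.to_dense(), h=5, dmax=40)
        assert rep.scc == pytest.approx(expected, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scc(random_band_map(50, 10, 0), random_band_map(60, 10, 0))


class TestStratifiedPearson:
    def test_identical_maps_all_ones(self):
        m = random_band_map(70, 20, seed=7)
        r = distance_stratified_pearson(m, m, max_distance_bp=4000)
        defined = r[1:][~np.isnan(r[1:])]
        np.testing.assert_allclose(defined, 1.0)

    def test_anticorrelation(self):
        a = random_band_map(70, 20, seed=8)
        b = oe_map(-a.to_dense())
        b.state = "log_oe"
        r = distance_stratified_pearson(a, b, max_distance_bp=4000)
        defined = r[1:][~np.isnan(r[1:])]
        np.testing.assert_allclose(defined, -1.0, atol=1e-12)

    def test_matches_bruteforce(self):
        a = random_band_map(90, 35, seed=9)
        b = random_band_map(90, 35, seed=10)
        r = distance_stratified_pearson(a, b, max_distance_bp=35 * 200)
        oracle = pearson_by_stratum_bruteforce(a.to_dense(), b.to_dense(), 35)
        for d, val in oracle.items():
            assert r[d] == pytest.approx(val, abs=1e-12)


class TestFragmentSpearman:
    def test_identical_maps_rho_one(self):
        m = random_band_map(60, 25, seed=11)
        df = fragment_spearman(m, m, fragment_bp=4000)
        np.testing.assert_allclose(df["rho"].dropna(), 1.0, atol=1e-12)

    def test_monotone_transform_invariance(self):
        # rank invariance of Spearman on the compared values; smoothing off
        # because a uniform filter does not commute with a cube transform
        a = random_band_map(60, 25, seed=12)
        b = oe_map(a.to_dense() ** 3)
        df = fragment_spearman(a, b, fragment_bp=4000, smooth_h=0)
        np.testing.assert_allclose(df["rho"].dropna(), 1.0, atol=1e-12)

    def test_matches_rank_then_pearson(self):
        a = random_band_map(40, 39, seed=13)
        b = random_band_map(40, 39, seed=14)
        df = fragment_spearman(a, b, fragment_bp=40 * 200, smooth_h=2)
        sa = uniform_filter(a.to_dense(), 5, mode="constant", cval=0.0)
        sb = uniform_filter(b.to_dense(), 5, mode="constant", cval=0.0)
        ii, jj = np.triu_indices(40)
        ra = stats.rankdata(sa[ii, jj])
        rb = stats.rankdata(sb[ii, jj])
        expected = np.corrcoef(ra, rb)[0, 1]
        assert df["rho"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_fragment_flagged_undefined(self):
        a = oe_map(np.zeros((20, 20)))
        b = random_band_map(20, 19, seed=15)
        df = fragment_spearman(a, b, fragment_bp=20 * 200)
        assert not df["defined"].iloc[0]
        assert np.isnan(df["rho"].iloc[0])

    def test_bad_fragment_size_rejected(self):
        m = random_band_map(20, 10, seed=16)
        with pytest.raises(ValueError):
            fragment_spearman(m, m, fragment_bp=4100)


class TestAnnotateFragments:
    def test_ten_fragments_one_in_top_tier(self):
        scores = pd.DataFrame({"fragment": range(10), "rho": np.linspace(0, 1, 10)})
        out = annotate_fragments(scores, phastcons=np.arange(10, dtype=float))
        assert (out["conservation"] == "top10").sum() == 1
        assert out.loc[9, "conservation"] == "top10"
        assert (out["conservation"] == "top10_50").sum() == 4

    def test_repliseq_zero_is_late(self):
        scores = pd.DataFrame({"fragment": range(3), "rho": [0.1, 0.2, 0.3]})
        out = annotate_fragments(scores, repliseq=np.array([1.0, 0.0, -2.0]))
        assert list(out["timing"]) == ["early", "late", "late"]

    def test_all_positive_repliseq_all_early(self):
        scores = pd.DataFrame({"fragment": range(4), "rho": [0.1] * 4})
        out = annotate_fragments(scores, repliseq=np.full(4, 0.5))
        assert (out["timing"] == "early").all()


class TestCompartments:
    def checkerboard(self, n=20, within=2.0, between=0.5):
        half = n // 2
        block = np.full((n, n), between)
        block[:half, :half] = within
        block[half:, half:] = within
        return block

    def test_two_block_pattern_recovered(self):
        dense = self.checkerboard()
        # independent eigen-decomposition oracle on the explicit matrix
        vals, vecs = np.linalg.eigh(dense - 1.0)
        lead = vecs[:, np.argmax(np.abs(vals))]
        assert len(set(np.sign(lead[:10]))) == 1 != len(set(np.sign(lead)))
        h3 = np.concatenate([np.full(10, 5.0), np.full(10, 1.0)])
        labels = call_compartments(oe_map(dense, res=250_000), h3)
        assert list(labels[:10]) == ["A"] * 10
        assert list(labels[10:]) == ["B"] * 10

    def test_sign_flip_invariance(self):
        dense = self.checkerboard()
        h3 = np.concatenate([np.full(10, 5.0), np.full(10, 1.0)])
        a = call_compartments(oe_map(dense, res=250_000), h3)
        # permuting block order flips the eigenvector sign pattern but the
        # H3K27ac rule keeps labels attached to the same bins
        perm = np.concatenate([np.arange(10, 20), np.arange(10)])
        b = call_compartments(oe_map(dense[np.ix_(perm, perm)], res=250_000), h3[perm])
        assert list(a[perm]) == list(b)

    def test_h3k27ac_decides_a_label(self):
        dense = self.checkerboard()
        h3_rev = np.concatenate([np.full(10, 1.0), np.full(10, 5.0)])
        labels = call_compartments(oe_map(dense, res=250_000), h3_rev)
        assert list(labels[:10]) == ["B"] * 10

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            call_compartments(oe_map(np.ones((6, 6)), res=250_000), np.ones(6))


class TestGroupTest:
    def frame(self, a, b):
        return pd.DataFrame({
            "rho": np.concatenate([a, b]),
            "compartment": ["A"] * len(a) + ["B"] * len(b),
        })

    def test_identical_groups_half_p(self):
        vals = np.array([0.1, 0.4, 0.5, 0.9])
        t, p = group_test(self.frame(vals, vals), "compartment", "A", "B")
        assert p == pytest.approx(0.5)

    def test_strong_difference_tiny_p(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.9, 0.01, 50)
        b = rng.normal(0.5, 0.01, 50)
        t, p = group_test(self.frame(a, b), "compartment", "A", "B")
        # cross-checked against the t distribution itself
        assert p < 1e-10
        df_w = 98  # equal n, near-equal variance
        assert p == pytest.approx(stats.t.sf(t, df_w), rel=0.2)

    def test_reversal_flips_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.6, 0.05, 30)
        b = rng.normal(0.5, 0.05, 30)
        _, p_fwd = group_test(self.frame(a, b), "compartment", "A", "B")
        _, p_rev = group_test(self.frame(a, b), "compartment", "B", "A")
        assert p_fwd + p_rev == pytest.approx(1.0, abs=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            group_test(self.frame([0.5], [0.1, 0.2]), "compartment", "A", "B")


class TestEqtlFilter:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "variant_pos", "tss_pos", "gene", "tissue"])

    def test_distance_filter(self):
        t = self.table([
            ("chr1", 10_000, 195_000, "G1", "lung"),    # 185 kb apart -> dropped
            ("chr1", 10_000, 110_000, "G2", "lung"),    # 100 kb apart -> kept
            ("chr1", 10_000, 190_000, "G3", "lung"),    # exactly 180 kb -> dropped
        ])
        kept = filter_eqtl_pairs(t)
        assert len(kept) == 1
        assert kept[0].variant_bin == 50 and kept[0].tss_bin == 550
        assert kept[0].distance_bp == 100_000

    def test_multi_tissue_pairs_dropped(self):
        t = self.table([
            ("chr1", 10_000, 50_000, "G1", "lung"),
            ("chr1", 10_050, 50_050, "G1", "pancreas"),  # same 200-bp bin pair
            ("chr1", 80_000, 120_000, "G2", "lung"),
        ])
        kept = filter_eqtl_pairs(t)
        assert len(kept) == 1 and kept[0].variant_bin == 400

    def test_empty_table(self):
        assert filter_eqtl_pairs(self.table([])) == []

    def test_malformed_rows_rejected_and_logged(self, caplog):
        t = self.table([
            ("chr1", "oops", 50_000, "G1", "lung"),
            ("chr1", 10_000, 50_000, "G2", "lung"),
        ])
        with caplog.at_level("WARNING"):
            kept = filter_eqtl_pairs(t)
        assert len(kept) == 1
        assert "malformed" in caplog.text


class TestEqtlPileup:
    def test_single_pair_is_submatrix(self):
        rng = np.random.default_rng(2)
        dense = np.triu(rng.random((250, 250)))
        cm = oe_map(dense)
        pairs = filter_eqtl_pairs(pd.DataFrame({
            "chrom": ["chr1"], "variant_pos": [24_000], "tss_pos": [30_000],
            "gene": ["G"], "tissue": ["lung"],
        }))
        res = eqtl_pileup(cm, pairs, side=21)
        np.testing.assert_array_equal(
            res.matrix, cm.to_dense()[110:131, 140:161]
        )

    def test_even_side_rejected(self):
        cm = oe_map(np.ones((50, 50)))
        pairs = filter_eqtl_pairs(pd.DataFrame({
            "chrom": ["chr1"], "variant_pos": [4000], "tss_pos": [6000],
            "gene": ["G"], "tissue": ["lung"],
        }))
        with pytest.raises(ValueError):
            eqtl_pileup(cm, pairs, side=100)

    def test_planted_contacts_enriched(self):
        rng = np.random.default_rng(3)
        n = 300
        dense = np.triu(rng.random((n, n)) * 0.2)
        centers = [(60, 100), (150, 210)]
        for i, j in centers:
            dense[i - 1 : i + 2, j - 1 : j + 2] += 3.0
        cm = oe_map(dense)
        rows = [{"chrom": "chr1", "variant_pos": i * 200 + 100, "tss_pos": j * 200 + 100,
                 "gene": "G", "tissue": f"t{k}"} for k, (i, j) in enumerate(centers)]
        pairs = filter_eqtl_pairs(pd.DataFrame(rows))
        res = eqtl_pileup(cm, pairs, side=41)
        off = res.matrix[:10, :10].mean()
        assert res.center_score > off
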