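import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wacekit.wace as wace
from wacekit.wace import (
    ICNVRegion,
    NullDistribution,
    ScoreTrack,
    call_regions,
    expression_scores,
    gaussian_smooth,
    ns_fdr,
    order_tracks,
    permutation_null,
    wavelet_smooth,
)
from conftest import make_study
from oracles import convolve_reflect, equivalent_smoothing_kernel


def make_track(values, chrom="chr1", fdr=None):
    n = len(values)
    return ScoreTrack(
        chromosome=chrom,
        gene_ids=[f"g{i:03d}" for i in range(n)],
        positions=np.arange(1, n + 1) * 100_000,
        values=np.asarray(values, dtype=float),
        fdr=fdr,
    )


class TestExpressionScores:
    def test_hand_computed_pooled_t(self):
        study = make_study(n_genes=1, n_per_group=3)
        study.matrix.iloc[0] = [4.0, 5.0, 6.0, 1.0, 2.0, 3.0]  # cases then controls
        es = expression_scores(study)
        assert es.iloc[0] == pytest.approx(3.674, abs=1e-3)

    def test_matches_scipy_on_random_data(self):
        study = make_study(n_genes=30, n_per_group=8, seed=21)
        es = expression_scores(study)
        g1 = study.matrix.iloc[:, :8]
        g0 = study.matrix.iloc[:, 8:]
        expected = stats.ttest_ind(g1, g0, axis=1).statistic
        np.testing.assert_allclose(es.to_numpy(), expected, atol=1e-10)
        welch = expression_scores(study, equal_var=False)
        expected_w = stats.ttest_ind(g1, g0, axis=1, equal_var=False).statistic
        np.testing.assert_allclose(welch.to_numpy(), expected_w, atol=1e-10)

    def test_identical_groups_score_zero(self):
        study = make_study(n_genes=2, n_per_group=3)
        study.matrix.iloc[0] = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        assert expression_scores(study).iloc[0] == 0.0

    def test_zero_variance_gene_flagged(self):
        study = make_study(n_genes=2, n_per_group=3)
        study.matrix.iloc[1] = 7.0
        es = expression_scores(study)
        assert es.iloc[1] == 0.0
        assert study.matrix.index[1] in es.attrs["zero_variance"]

    def test_small_group_raises(self):
        study = make_study(n_genes=3, n_per_group=2)
        study.phenotype.iloc[0] = 0  # leaves one case
        with pytest.raises(ValueError, match="at least 2"):
            expression_scores(study)


class TestOrderTracks:
    def test_sorted_by_position_per_chromosome(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(10)]
        ann = pd.DataFrame(
            {
                "chrom": ["chr2", "chr1"] * 5,
                "position_bp": rng.permutation(10) * 1000 + 1000,
            },
            index=genes,
        )
        es = pd.Series(rng.standard_normal(10), index=genes)
        tracks = order_tracks(es, ann)
        assert [t.chromosome for t in tracks] == ["chr1", "chr2"]
        for t in tracks:
            assert (np.diff(t.positions) >= 0).all()
            np.testing.assert_array_equal(t.values, es.loc[t.gene_ids].to_numpy())

    def test_position_tie_broken_by_gene_id(self):
        ann = pd.DataFrame(
            {"chrom": ["chr1"] * 3, "position_bp": [500, 500, 100]},
            index=["gB", "gA", "gC"],
        )
        es = pd.Series([1.0, 2.0, 3.0], index=["gB", "gA", "gC"])
        (track,) = order_tracks(es, ann)
        assert track.gene_ids == ["gC", "gA", "gB"]

    def test_unplaced_gene_excluded(self):
        ann = pd.DataFrame(
            {"chrom": ["chr1", "chr1", None], "position_bp": [100, 200, None]},
            index=["gA", "gB", "gC"],
        )
        es = pd.Series([1.0, 2.0, 3.0], index=["gA", "gB", "gC"])
        (track,) = order_tracks(es, ann)
        assert "gC" not in track.gene_ids

    def test_short_chromosome_skipped(self):
        ann = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr2"], "position_bp": [100, 200, 300]},
            index=["gA", "gB", "gC"],
        )
        es = pd.Series([1.0, 2.0, 3.0], index=ann.index)
        tracks = order_tracks(es, ann)
        assert [t.chromosome for t in tracks] == ["chr1"]


class TestWaveletSmooth:
    def test_constant_track_preserved(self):
        for level in (1, 2, 3, 4):
            track = make_track(np.full(40, 3.7))
            ns = wavelet_smooth(track, level=level)
            np.testing.assert_allclose(ns.values, 3.7, atol=1e-10)

    def test_unit_spike_matches_equivalent_kernel_and_sums_to_one(self):
        x = np.zeros(64)
        x[32] = 1.0
        ns = wavelet_smooth(make_track(x), "haar", level=3)
        kernel = equivalent_smoothing_kernel("haar", 3)
        expected = convolve_reflect(x, kernel)
        np.testing.assert_allclose(ns.values, expected, atol=1e-10)
        assert ns.values.sum() == pytest.approx(1.0, abs=1e-10)

    def test_level_zero_is_identity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(30)
        ns = wavelet_smooth(make_track(x), level=0)
        np.testing.assert_array_equal(ns.values, x)

    @pytest.mark.parametrize("filter_name", ["haar", "db2"])
    @pytest.mark.parametrize("n", [8, 17, 33, 64])
    def test_random_tracks_match_direct_convolution_oracle(self, filter_name, n):
        rng = np.random.default_rng(n)
        x = rng.standard_normal(n)
        for level in (1, 2, 3):
            ns = wavelet_smooth(make_track(x), filter_name, level=level)
            kernel = equivalent_smoothing_kernel(filter_name, level)
            expected = convolve_reflect(x, kernel)
            np.testing.assert_allclose(ns.values, expected, atol=1e-8)

    def test_variance_monotone_in_level(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(128)
        variances = [
            wavelet_smooth(make_track(x), level=s).values.var() for s in (1, 2, 3, 4)
        ]
        assert all(a >= b for a, b in zip(variances, variances[1:]))

    def test_track_length_preserved(self):
        for n in (5, 12, 100):
            track = make_track(np.random.default_rng(n).standard_normal(n))
            assert len(wavelet_smooth(track, level=3)) == n

    def test_too_short_track_raises(self):
        with pytest.raises(ValueError):
            wavelet_smooth(make_track([1.0]), level=3)


class TestGaussianSmooth:
    def test_constant_preserved(self):
        ns = gaussian_smooth(make_track(np.full(30, -2.5)), bandwidth=3.0)
        np.testing.assert_allclose(ns.values, -2.5, atol=1e-8)

    def test_spike_matches_closed_form_kernel(self):
        x = np.zeros(101)
        x[50] = 1.0
        sigma = 2.0
        ns = gaussian_smooth(make_track(x), bandwidth=sigma)
        # center far from boundary: sampled Gaussian, truncated at 4 sigma
        # (matching the smoother's finite support) and renormalized
        idx = np.arange(101) - 50
        radius = int(4 * sigma + 0.5)
        kernel = np.where(np.abs(idx) <= radius,
                          np.exp(-(idx**2) / (2 * sigma**2)), 0.0)
        kernel /= kernel.sum()
        np.testing.assert_allclose(ns.values, kernel, atol=1e-6)
        assert ns.values.sum() == pytest.approx(1.0, abs=1e-8)

    def test_bandwidth_zero_is_identity(self):
        x = np.random.default_rng(3).standard_normal(20)
        ns = gaussian_smooth(make_track(x), bandwidth=0.0)
        np.testing.assert_array_equal(ns.values, x)


class TestPermutationNull:
    def test_fixed_seed_reproducible(self):
        study = make_study(n_genes=20, n_per_group=6, seed=31)
        a = permutation_null(study, B=10, seed=5)
        b = permutation_null(study, B=10, seed=5)
        np.testing.assert_array_equal(a["chr1"].values, b["chr1"].values)

    def test_permutation_stream_prefix_stable(self):
        # growing B keeps earlier permutations' draws identical
        study = make_study(n_genes=20, n_per_group=6, seed=32)
        small = permutation_null(study, B=5, seed=7)
        large = permutation_null(study, B=10, seed=7)
        L = len(small["chr1"].values)
        np.testing.assert_array_equal(large["chr1"].values[:L], small["chr1"].values)

    def test_permuted_scores_match_direct_recomputation(self):
        study = make_study(n_genes=15, n_per_group=6, seed=33)
        X = study.matrix.to_numpy()
        B = 4
        got = wace._permuted_scores(X, study.phenotype.to_numpy(), B, seed=9)
        n = study.n_samples
        n1 = int(study.phenotype.sum())
        for b in range(B):
            rng = np.random.default_rng(np.random.SeedSequence(entropy=[9, b]))
            perm = rng.permutation(n)
            mask1 = np.zeros(n, bool)
            mask1[perm[:n1]] = True
            expected = stats.ttest_ind(X[:, mask1], X[:, ~mask1], axis=1).statistic
            np.testing.assert_allclose(got[b], expected, atol=1e-8)

    def test_pure_noise_null_centered(self):
        study = make_study(n_genes=100, n_per_group=20, seed=34)
        null = permutation_null(study, B=200, seed=11)["chr1"]
        vals = null.values
        se = vals.std() / np.sqrt(len(vals) / 15)  # ~15-gene smoothing correlation
        assert abs(vals.mean()) < 3 * max(se, 1e-3)


class TestNsFdr:
    def _null(self, values, B=1, chrom="chr1"):
        return NullDistribution(chromosome=chrom, values=np.asarray(values, float),
                                B=B, scaling_level=3)

    def test_counting_oracle_on_fixed_null(self):
        rng = np.random.default_rng(4)
        null_vals = rng.standard_normal(1000)
        null = self._null(null_vals, B=10)
        obs = np.array([0.5, -0.3, 2.0, -2.5, 0.0])
        out = ns_fdr(make_track(obs), null)
        for v, f in zip(obs, out.fdr):
            if v > 0:
                assert f == (null_vals >= v).sum() / 1000
            elif v < 0:
                assert f == (null_vals <= v).sum() / 1000
            else:
                assert f == 1.0

    def test_observed_above_all_null_gives_zero(self):
        null = self._null(np.linspace(-1, 1, 100))
        out = ns_fdr(make_track([5.0]), null)
        assert out.fdr[0] == 0.0

    def test_null_median_gives_half(self):
        null_vals = np.linspace(0.001, 1, 1000)  # positive-shifted fixture null
        med = float(np.median(null_vals))
        out = ns_fdr(make_track([med]), self._null(null_vals))
        assert out.fdr[0] == pytest.approx(0.5, abs=0.01)

    def test_zero_ns_gets_fdr_one(self):
        out = ns_fdr(make_track([0.0]), self._null(np.linspace(-1, 1, 100)))
        assert out.fdr[0] == 1.0

    def test_pseudocount_avoids_exact_zero(self):
        out = ns_fdr(make_track([5.0]), self._null(np.linspace(-1, 1, 100)),
                     pseudocount=True)
        assert 0 < out.fdr[0] <= 1 / 101 + 1e-12

    def test_chromosome_mismatch_raises(self):
        with pytest.raises(ValueError, match="chromosome"):
            ns_fdr(make_track([1.0], chrom="chr2"), self._null([0.0]))

    def test_empty_null_raises(self):
        null = self._null([1.0])
        null.values = np.array([])
        null._sorted = np.array([])
        with pytest.raises(ValueError, match="empty"):
            ns_fdr(make_track([1.0]), null)

    def test_excess_method_near_one_under_matched_null(self):
        # observed drawn from the same distribution as the null: the excess
        # estimator should report no signal (values close to 1)
        rng = np.random.default_rng(6)
        null = self._null(rng.standard_normal(20000), B=100)
        obs = rng.standard_normal(200)
        out = ns_fdr(make_track(obs), null, method="excess")
        assert np.median(out.fdr) > 0.5


class TestCallRegions:
    def _sig_track(self, signs, fdrs):
        values = np.asarray(signs, float) * 3.0
        return make_track(values, fdr=np.asarray(fdrs))

    def test_long_run_called_with_length(self):
        track = self._sig_track([1] * 12, [0.001] * 12)
        (region,) = call_regions(track, n=10, alpha=0.01)
        assert region.sign == "gain"
        assert region.n_significant == 12
        assert region.start_bp == track.positions[0]
        assert region.end_bp == track.positions[-1]

    def test_run_below_n_not_called(self):
        track = self._sig_track([1] * 9, [0.001] * 9)
        assert call_regions(track, n=10, alpha=0.01) == []

    def test_sign_break_yields_two_regions(self):
        track = self._sig_track([1] * 6 + [-1] * 6, [0.001] * 12)
        regions = call_regions(track, n=5, alpha=0.01)
        assert [r.sign for r in regions] == ["gain", "loss"]
        assert [r.n_significant for r in regions] == [6, 6]

    def test_fdr_threshold_is_strict(self):
        track = self._sig_track([1] * 6, [0.01] * 6)
        assert call_regions(track, n=5, alpha=0.01) == []

    def test_insignificant_gap_splits_runs(self):
        fdrs = [0.001] * 5 + [0.5] + [0.001] * 5
        track = self._sig_track([1] * 11, fdrs)
        regions = call_regions(track, n=5, alpha=0.01)
        assert len(regions) == 2
        assert all(r.n_significant == 5 for r in regions)

    def test_region_members_share_sign(self):
        rng = np.random.default_rng(8)
        values = rng.standard_normal(50)
        track = make_track(values, fdr=rng.uniform(0, 0.02, 50))
        for region in call_regions(track, n=3, alpha=0.01):
            idx = [track.gene_ids.index(g) for g in region.gene_ids]
            signs = np.sign(values[idx])
            assert len(set(signs)) == 1

    def test_requires_fdr(self):
        with pytest.raises(ValueError, match="fdr"):
            call_regions(make_track([1.0, 2.0]), n=1)


class TestNsTrackInvariants:
    def test_ns_length_equals_es_length_any_smoother(self):
        study = make_study(n_genes=37, n_per_group=5, seed=41)
        es = expression_scores(study)
        (track,) = order_tracks(es, study.annotation)
        assert len(wavelet_smooth(track, level=3)) == len(track)
        assert len(gaussian_smooth(track, bandwidth=2.0)) == len(track)

    def test_region_invariants_on_pipeline_output(self):
        from wacekit.simdata import SimConfig, simulate_study
        from wacekit.wace import infer_icnv_regions

        cfg = SimConfig(n_genes=600, n_samples_per_group=25, n_chromosomes=3,
                        segments=[("chr2", (50, 89), "gain", 1.2)], seed=51)
        study, _ = simulate_study(cfg)
        regions, tracks = infer_icnv_regions(study, B=50, seed=5)
        assert any(r.chromosome == "chr2" and r.sign == "gain" for r in regions)
        for r in regions:
            assert r.n_significant >= 5
            assert r.start_bp <= r.end_bp
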