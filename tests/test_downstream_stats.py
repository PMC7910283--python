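"""Permutation statistics, mixture model, k-mer utilities and metrics."""

import itertools

import numpy as np
import pytest

from chromavice.downstream_stats import (
    cie_asymmetry,
    concordance_binomial,
    decile_symmetry_test,
    f1_score,
    fit_fvice_mixture,
    hamming_neighbor_range,
    kmer_canonical_set,
    label_truth_by_containment,
    pr_auc,
    quantile_matched_downsample,
    rank_sum_enrichment,
    revcomp,
    tss_direction_bias,
)
from chromavice.io import FeatureInterval
from chromavice.synthetic import PhasingModel, simulate_asymmetric_features
from chromavice.vplot import build_window_grid


class TestCieAsymmetry:
    model = PhasingModel(theta=0.6, max_size=200)

    def test_left_biased_fragments_detected(self, default_grid):
        frags = simulate_asymmetric_features(40, 100, bias=0.6, model=self.model, rng=1)
        res = cie_asymmetry(frags, default_grid, n_permutations=200, max_size=200, rng=2)
        assert res.defined
        assert res.log2_ratio > 0  # left enrichment is positive by convention
        assert res.p < 0.01
        assert res.z == pytest.approx(
            (res.log2_ratio - res.null_mean) / res.null_sd
        )

    def test_strand_flip_negates_ratio(self, default_grid):
        frags = simulate_asymmetric_features(40, 100, bias=0.5, model=self.model, rng=3)
        flipped = [np.column_stack([-a[:, 0], a[:, 1]]) for a in frags]
        r1 = cie_asymmetry(frags, default_grid, n_permutations=30, max_size=200, rng=4)
        r2 = cie_asymmetry(flipped, default_grid, n_permutations=30, max_size=200, rng=4)
        # the ratio flips in sign (magnitudes carry Monte-Carlo noise from
        # the expected-information permutation, so only the sign is exact)
        assert np.sign(r1.log2_ratio) == -np.sign(r2.log2_ratio)
        assert r1.p < 0.05 and r2.p < 0.05

    def test_one_sided_profile_flagged_undefined(self):
        grid = build_window_grid(100, 10, 10)
        frags = [np.column_stack([np.full(30, -50), np.arange(41, 71)])]
        res = cie_asymmetry(frags, grid, n_permutations=5, max_size=200, rng=0)
        assert not res.defined and np.isnan(res.p)


class TestTssDirectionBias:
    motifs = [FeatureInterval("chr1", 995, 1005, "m", 0, "+")]

    def test_balanced_tss_give_zero(self):
        motifs = [
            FeatureInterval("chr1", c - 5, c + 5, f"m{i}", 0, "+")
            for i, c in enumerate((1000, 5000))
        ]
        tss = [("chr1", 900), ("chr1", 5100)]
        assert tss_direction_bias(motifs, tss) == pytest.approx(0.0)

    def test_all_right_is_negative_and_flips_with_strand(self):
        tss = [("chr1", 1200)]
        with pytest.warns(UserWarning, match="pseudocount"):
            right = tss_direction_bias(self.motifs, tss)
        assert right < 0
        minus = [FeatureInterval("chr1", 995, 1005, "m", 0, "-")]
        with pytest.warns(UserWarning, match="pseudocount"):
            flipped = tss_direction_bias(minus, tss)
        assert flipped == pytest.approx(-right)

    def test_empty_tss_rejected(self):
        with pytest.raises(ValueError):
            tss_direction_bias(self.motifs, [])


class TestConcordanceBinomial:
    def test_null_center_is_maximal(self):
        assert concordance_binomial(75, 150) == pytest.approx(1.0)

    def test_published_value(self):
        assert concordance_binomial(111, 150) == pytest.approx(3.38e-9, rel=5e-3)

    def test_extreme_tail_closed_form(self):
        assert concordance_binomial(150, 150) == pytest.approx(2 * 0.5**150, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            concordance_binomial(1, 0)
        with pytest.raises(ValueError):
            concordance_binomial(5, 3)


class TestFviceMixture:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(4)
        n = 500
        hi = rng.random(n) < 0.15
        x = np.where(hi, rng.normal(0.8, 0.1, n), rng.normal(0.2, 0.05, n))
        fit = fit_fvice_mixture(x, seed=0)
        assert fit.means[0] == pytest.approx(0.2, abs=0.05)
        assert fit.means[1] == pytest.approx(0.8, abs=0.05)
        assert fit.high_fraction == pytest.approx(0.15, abs=0.05)
        assert fit.bic_mixture < fit.bic_single  # mixture preferred

    def test_single_gaussian_data_prefers_single_model(self):
        rng = np.random.default_rng(5)
        wins = 0
        for rep in range(20):
            x = rng.normal(0.5, 0.1, 400)
            fit = fit_fvice_mixture(x, seed=rep)
            wins += fit.bic_single < fit.bic_mixture
        assert wins >= 18

    def test_lowest_decile_filter_applied(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0.5, 0.1, 100)
        bound = np.arange(100)
        fit = fit_fvice_mixture(x, bound_counts=bound, seed=0)
        # ~10% dropped
        assert len(fit.posteriors_high) <= 91

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            fit_fvice_mixture(np.full(50, 0.3))

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        x = np.concatenate([rng.normal(0, 1, 100), rng.normal(5, 1, 100)])
        f1 = fit_fvice_mixture(x, seed=0)
        f2 = fit_fvice_mixture(x[rng.permutation(len(x))], seed=0)
        np.testing.assert_allclose(np.sort(f1.means), np.sort(f2.means), atol=1e-6)
        assert f1.high_fraction == pytest.approx(f2.high_fraction, abs=0.01)


class TestRankSumEnrichment:
    def test_top_group_is_maximal_with_minimal_p(self):
        n = 30
        fv = {f"m{i}": float(i) for i in range(n)}
        gmap = {f"m{i}": "top" for i in range(n - 5, n)}
        (res,) = rank_sum_enrichment(fv, gmap, n_perm=999, rng=0)
        assert res.observed_rank_sum == sum(range(n - 4, n + 1))
        assert res.empirical_p == pytest.approx(2 / 1000)
        assert res.log2_enrichment > 0

    def test_matches_exhaustive_oracle_on_toy(self):
        # 8 motifs, group of 3: exact null over all C(8,3) member subsets
        rng = np.random.default_rng(8)
        values = rng.normal(size=8)
        ranks = np.argsort(np.argsort(values)) + 1.0
        members = [2, 5, 6]
        obs = ranks[members].sum()
        null = np.array([
            ranks[list(c)].sum() for c in itertools.combinations(range(8), 3)
        ])
        exact_med = np.median(null)
        exact_dir = (null >= obs).mean() if obs >= exact_med else (null <= obs).mean()
        exact_p = min(1.0, 2 * exact_dir)
        fv = {f"m{i}": float(values[i]) for i in range(8)}
        gmap = {f"m{i}": "G" for i in members}
        (res,) = rank_sum_enrichment(fv, gmap, min_group=3, n_perm=50_000, rng=1)
        assert res.observed_rank_sum == obs
        assert res.null_median == pytest.approx(exact_med, rel=0.05)
        assert res.empirical_p == pytest.approx(exact_p, abs=0.02)

    def test_small_groups_dropped_with_warning(self):
        fv = {f"m{i}": float(i) for i in range(10)}
        gmap = {"m0": "tiny", "m1": "tiny"}
        with pytest.warns(UserWarning, match="dropped"):
            assert rank_sum_enrichment(fv, gmap, n_perm=99, rng=0) == []

    def test_null_groups_are_calibrated(self):
        rng = np.random.default_rng(3)
        rej = 0
        n_rep = 200
        for _ in range(n_rep):
            fv = {f"m{i}": float(v) for i, v in enumerate(rng.normal(size=50))}
            members = rng.choice(50, 10, replace=False)
            gmap = {f"m{i}": "G" for i in members}
            (res,) = rank_sum_enrichment(fv, gmap, n_perm=999, rng=rng)
            rej += res.empirical_p < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rej / n_rep <= 0.05 + 3 * se


class TestQuantileMatchedDownsample:
    def test_identical_sets_unchanged(self, rng):
        x = rng.normal(size=200)
        ia, ib = quantile_matched_downsample(x, x.copy(), rng=0)
        assert len(ia) == len(ib) == 200

    def test_outputs_have_equal_size_and_matched_bins(self, rng):
        a = rng.normal(0, 1, 400)
        b = rng.normal(0.5, 1, 250)
        ia, ib = quantile_matched_downsample(a, b, n_quantiles=10, rng=1)
        assert len(ia) == len(ib)
        assert len(ia) <= min(len(a), len(b))

    def test_shifted_covariate_means_converge(self, rng):
        a = rng.normal(0, 1, 1000)
        b = rng.normal(0.8, 1, 1000)
        ia, ib = quantile_matched_downsample(a, b, rng=2)
        before = abs(a.mean() - b.mean())
        after = abs(a[ia].mean() - b[ib].mean())
        assert after < before / 3


class TestDecileSymmetry:
    def test_symmetric_matrix_gives_t_zero(self, rng):
        c = rng.integers(0, 50, size=(10, 10))
        sym = c + c.T
        X, T, p = decile_symmetry_test(sym, sym * 3, n_perm=999, rng=0)
        assert T == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_planted_up_bias_detected(self, rng):
        base = rng.integers(20, 40, size=(10, 10))
        sel = base.copy()
        iu, ju = np.triu_indices(10, k=1)
        sel[iu, ju] += 40  # transitions toward higher deciles inflated
        X, T, p = decile_symmetry_test(sel, base, n_perm=9_999, rng=1)
        assert T > 0
        assert p < 0.01

    def test_transposing_inputs_negates_t(self, rng):
        sel = rng.integers(0, 60, size=(10, 10))
        all_ = rng.integers(0, 60, size=(10, 10))
        _, T1, _ = decile_symmetry_test(sel, all_, n_perm=99, rng=0)
        _, T2, _ = decile_symmetry_test(sel.T, all_.T, n_perm=99, rng=0)
        assert T2 == pytest.approx(-T1)

    def test_matches_exhaustive_sign_oracle_on_4x4(self, rng):
        sel = rng.integers(0, 30, size=(4, 4))
        all_ = rng.integers(0, 30, size=(4, 4))
        X, T, p = decile_symmetry_test(sel, all_, n_perm=40_000, rng=2)
        iu, ju = np.triu_indices(4, k=1)
        diffs = X[iu, ju] - X[ju, iu]
        exact = np.mean([
            abs(np.dot(signs, diffs)) >= abs(T)
            for signs in itertools.product((-1, 1), repeat=len(diffs))
        ])
        assert p == pytest.approx(exact, abs=0.02)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            decile_symmetry_test(np.zeros((3, 4)), np.zeros((3, 4)), n_perm=9, rng=0)


class TestKmerTools:
    def test_canonical_6mer_count_is_2016(self):
        kmers = kmer_canonical_set(6)
        assert len(kmers) == 2016

    def test_k1_is_a_and_c(self):
        assert kmer_canonical_set(1) == ["A", "C"]

    def test_no_palindromes_and_no_rc_duplicates(self):
        kmers = kmer_canonical_set(4)
        as_set = set(kmers)
        for k in kmers:
            assert k != revcomp(k)
            assert revcomp(k) not in as_set

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            kmer_canonical_set(0)

    def test_hamming_neighbors_full_and_range(self):
        table = {k: float(i) for i, k in enumerate(kmer_canonical_set(6))}
        # range equals the spread between extreme neighbors, i.e. the
        # difference of the two deltas relative to the focal k-mer
        mx, mn, rng_ = hamming_neighbor_range("AAAAAA", table)
        assert rng_ == pytest.approx(mx - mn)
        # constant table: range 0
        const = {k: 1.0 for k in kmer_canonical_set(6)}
        assert hamming_neighbor_range("AAAAAA", const)[2] == 0.0

    def test_range_matches_enumeration_on_toy(self):
        table = {k: float(hash(k) % 97) for k in kmer_canonical_set(4)}
        kmer = "AACG"
        vals = []
        for pos in range(4):
            for b in "ACGT":
                if b == kmer[pos]:
                    continue
                nb = kmer[:pos] + b + kmer[pos + 1 :]
                canon = min(nb, revcomp(nb))
                if canon in table:
                    vals.append(table[canon])
        expected = max(vals) - min(vals)
        assert hamming_neighbor_range(kmer, table)[2] == pytest.approx(expected)


class TestEvaluationMetrics:
    def test_perfect_predictions(self):
        y = np.array([1, 0, 1, 1, 0], dtype=bool)
        assert f1_score(y, y) == 1.0

    def test_eq3_arithmetic(self):
        # precision 0.5, recall 0.5 -> F1 = 0.5
        pred = np.array([1, 1, 0, 0], dtype=bool)
        truth = np.array([1, 0, 1, 0], dtype=bool)
        assert f1_score(pred, truth) == pytest.approx(0.5)
        # precision 1, recall 0.5 -> F1 = 2/3
        pred = np.array([1, 0, 0, 0], dtype=bool)
        truth = np.array([1, 1, 0, 0], dtype=bool)
        assert f1_score(pred, truth) == pytest.approx(2 / 3)

    def test_no_positives_flagged_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(f1_score(np.array([True]), np.array([False])))

    def test_pr_auc_ranks_separable_scores_near_one(self, rng):
        y = rng.random(500) < 0.3
        scores = y + rng.normal(0, 0.05, 500)
        assert pr_auc(scores, y) > 0.99

    def test_truth_requires_full_containment(self):
        peaks = [FeatureInterval("chr1", 100, 200, "p")]
        inside = FeatureInterval("chr1", 120, 140, "a")
        straddle = FeatureInterval("chr1", 90, 140, "b")
        labels = label_truth_by_containment([inside, straddle], peaks)
        assert labels.tolist() == [True, False]
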