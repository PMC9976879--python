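"""Feature construction, GLM fitting, recurrence P-value and cross-validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import regdriver.background as bg
from regdriver.genome import Genome, SteppedTrack, TRINUCLEOTIDES_32, collapse_trinucleotide
from regdriver.intervals import GenomicInterval, RegulatorySpace


def flat_track(value=0.0, length=10_000, chrom="chr1"):
    return SteppedTrack.from_records([(chrom, 0, length, value)])


def make_space(start, end, activity=1.0, chrom="chr1"):
    return RegulatorySpace("G", "t", [GenomicInterval(chrom, start, end)], activity)


class TestGeneFeatures:
    def test_all_c_sequence_gc_one(self):
        genome = Genome.from_sequences({"chr1": "C" * 50})
        feats = bg.compute_gene_features(
            make_space(10, 40), [], genome, flat_track(length=50),
            pd.DataFrame({"chrom": [], "pos": []}), k=10, tissue_median_local_freq=0.0,
        )
        assert feats.gc_content == 1.0
        assert feats.trinuc_freq[TRINUCLEOTIDES_32.index("CCC")] == 1.0

    def test_single_position_context(self):
        genome = Genome.from_sequences({"chr1": "AACAA"})
        feats = bg.compute_gene_features(
            make_space(2, 3), [], genome, flat_track(length=5),
            pd.DataFrame({"chrom": [], "pos": []}), k=10, tissue_median_local_freq=0.0,
        )
        expected = np.zeros(32)
        expected[TRINUCLEOTIDES_32.index("ACA")] = 1.0
        np.testing.assert_allclose(feats.trinuc_freq, expected)

    def test_random_fixture_matches_brute_force(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 2_000))
        genome = Genome.from_sequences({"chr1": seq})
        space = make_space(100, 1_900)
        muts = pd.DataFrame(
            {"chrom": "chr1", "pos": rng.integers(0, 2_000, 60), "sample_id": "S1"}
        )
        flanks = [GenomicInterval("chr1", 0, 100), GenomicInterval("chr1", 1_900, 2_000)]
        feats = bg.compute_gene_features(
            space, flanks, genome, flat_track(length=2_000), muts, k=20,
        )
        # brute-force context tally
        tally = {t: 0 for t in TRINUCLEOTIDES_32}
        for pos in range(100, 1_900):
            tally[collapse_trinucleotide(seq[pos - 1:pos + 2])] += 1
        total = sum(tally.values())
        np.testing.assert_allclose(
            feats.trinuc_freq, [tally[t] / total for t in TRINUCLEOTIDES_32], atol=1e-12
        )
        assert abs(feats.trinuc_freq.sum() - 1.0) < 1e-9
        gc = sum(1 for b in seq[100:1900] if b in "GC") / 1_800
        assert feats.gc_content == pytest.approx(gc)
        in_flanks = sum(1 for p in muts["pos"] if p < 100 or p >= 1_900)
        assert feats.local_mut_freq == pytest.approx(in_flanks / (200 * 20))
        assert feats.n_positions == 1_800

    def test_empty_flanks_imputes_tissue_median(self):
        genome = Genome.from_sequences({"chr1": "ACGT" * 25})
        feats = bg.compute_gene_features(
            make_space(10, 20), [], genome, flat_track(length=100),
            pd.DataFrame({"chrom": [], "pos": []}), k=10, tissue_median_local_freq=0.123,
        )
        assert feats.flank_imputed and feats.local_mut_freq == 0.123


class TestUnivariableScreen:
    def test_noise_excluded_signal_included(self, rng):
        n = 500
        x_signal = rng.normal(size=n)
        x_noise = rng.normal(size=n)
        f = np.exp(-8 + 0.5 * x_signal)
        y = rng.poisson(f * 1e4) / 1e4  # frequency-scale response with Poisson noise
        X = pd.DataFrame({"signal": x_signal, "noise": x_noise})
        selected = bg.univariable_screen(X, y)
        assert "signal" in selected
        assert "noise" not in selected

    def test_constant_feature_skipped_intercept_only_allowed(self, rng):
        X = pd.DataFrame({"const_feat": np.ones(100)})
        y = rng.poisson(2.0, 100).astype(float)
        assert bg.univariable_screen(X, y) == []

    def test_requires_minimum_genes(self):
        X = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError):
            bg.univariable_screen(X, np.ones(10))


class TestFitBackground:
    def test_intercept_only_closed_form(self):
        y = np.full(200, 0.004)
        X = pd.DataFrame(index=range(200))
        fit = bg.fit_background(X, y, selected_features=[])
        assert fit.coefficients["const"] == pytest.approx(np.log(0.004), abs=1e-6)

    def test_recovers_simulated_coefficients_within_3se(self, rng):
        n, s, k = 500, 50, 200
        x = rng.normal(size=n)
        f = np.exp(-8 + 0.5 * x)
        n_mut = rng.binomial(k, 1 - (1 - f) ** s)
        y = n_mut / (s * k)
        X = pd.DataFrame({"x": x})
        fit = bg.fit_background(X, y, selected_features=["x"])
        se = fit.train_meta["coef_se"]
        # coefficients are on the z-scored scale; true slope is 0.5 * sd(x)
        assert abs(fit.coefficients["x"] - 0.5 * x.std()) < 3 * se["x"]
        true_intercept = -8 + 0.5 * x.mean()
        assert abs(fit.coefficients["const"] - true_intercept) < 3 * se["const"]

    def test_zero_response_rejected(self):
        X = pd.DataFrame({"x": np.arange(50.0)})
        with pytest.raises(ValueError):
            bg.fit_background(X, np.zeros(50))


class TestPredictF:
    def test_intercept_only_constant(self):
        fit = bg.BackgroundFit([], {"const": np.log(0.001)}, 1.0, {}, {})
        np.testing.assert_allclose(bg.predict_f(fit, pd.DataFrame(index=range(5))), 0.001)

    def test_matches_matrix_product_oracle(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20), "b": rng.normal(size=20)})
        means = {c: float(X[c].mean()) for c in X}
        sds = {c: float(X[c].std()) for c in X}
        coef = {"const": -9.0, "a": 0.4, "b": -0.2}
        fit = bg.BackgroundFit(["a", "b"], coef, 1.0, means, sds)
        Z = (X - pd.Series(means)) / pd.Series(sds)
        expected = np.exp(-9.0 + 0.4 * Z["a"] + (-0.2) * Z["b"])
        np.testing.assert_allclose(bg.predict_f(fit, X), expected)

    def test_positive_predictor_clamped(self):
        fit = bg.BackgroundFit([], {"const": 2.0}, 1.0, {}, {})
        assert bg.predict_f(fit, pd.DataFrame(index=[0]))[0] == pytest.approx(1 - 1e-12)

    def test_missing_feature_is_error(self):
        fit = bg.BackgroundFit(["a"], {"const": 0.0, "a": 1.0}, 1.0, {"a": 0.0}, {"a": 1.0})
        with pytest.raises(ValueError):
            bg.predict_f(fit, pd.DataFrame({"b": [1.0]}))


def binomial_tail_oracle(n, k, p):
    """Exact right-tail sum via math.comb."""
    from math import comb

    return sum(comb(k, x) * p**x * (1 - p) ** (k - x) for x in range(n, k + 1))


class TestMutationPvalue:
    def test_zero_observed_gives_one(self):
        assert bg.mutation_pvalue(0, 10, 0.01, 5)[1] == 1.0

    def test_all_samples_closed_form(self):
        p_sample, p_m = bg.mutation_pvalue(4, 4, 0.3, 2)
        assert p_m == pytest.approx(p_sample**4)

    def test_worked_example_exact_sum(self):
        p_sample, p_m = bg.mutation_pvalue(2, 5, 0.01, 10)
        expected_p = 1 - 0.99**10
        assert p_sample == pytest.approx(expected_p)
        assert p_m == pytest.approx(binomial_tail_oracle(2, 5, expected_p), rel=1e-12)

    def test_monotone_in_n_and_f(self):
        grid_f, s, k = [0.001, 0.01, 0.05], 20, 50
        for f in grid_f:
            pvals = [bg.mutation_pvalue(n, k, f, s)[1] for n in range(0, k + 1)]
            assert all(a >= b for a, b in zip(pvals, pvals[1:]))  # non-increasing in n
        for n in (1, 5, 10):
            pvals = [bg.mutation_pvalue(n, k, f, s)[1] for f in grid_f]
            assert all(a <= b for a, b in zip(pvals, pvals[1:]))  # non-decreasing in f

    def test_inconsistent_inputs(self):
        with pytest.raises(ValueError):
            bg.mutation_pvalue(1, 10, 0.01, 0)
        with pytest.raises(ValueError):
            bg.mutation_pvalue(0, 0, 0.01, 5)


class TestCrossValidation:
    def test_human_fold_grouping(self):
        chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX"]
        folds = bg.assign_folds(chroms)
        assert folds == bg.HUMAN_AUTOSOME_FOLDS
        assert {"chr12", "chr16"} <= set(folds[4])

    def test_toy_genome_one_fold_per_chromosome(self):
        folds = bg.assign_folds(["c1", "c2", "c3"])
        assert folds == [frozenset({c}) for c in ("c1", "c2", "c3")]

    def test_null_simulation_r2_near_zero(self, rng):
        n, k = 1_000, 100
        s = np.full(n, 50)
        X = pd.DataFrame({"x": rng.normal(size=n)})  # unrelated covariate
        counts = rng.poisson(2.0, n).astype(float)
        freq = counts / (s * k)
        chroms = np.repeat([f"c{i}" for i in range(4)], n // 4)
        table = bg.crossvalidate(X, freq, counts, s, k, chroms, p_cut=0.5)
        assert np.nanmean(table["explained_variance"]) < 0.02

    def test_informative_covariate_gives_high_r2(self, rng):
        n, k = 800, 200
        s = np.full(n, 80)
        x = rng.normal(size=n)
        f = np.exp(-8 + 0.8 * x)
        counts = rng.binomial(k, 1 - (1 - f) ** s[0]).astype(float)
        freq = counts / (s * k)
        chroms = np.repeat([f"c{i}" for i in range(4)], n // 4)
        table = bg.crossvalidate(pd.DataFrame({"x": x}), freq, counts, s, k, chroms)
        assert np.nanmedian(table["explained_variance"]) > 0.5

    def test_sex_chromosomes_and_top_percentile_excluded(self, rng):
        n = 200
        X = pd.DataFrame({"x": rng.normal(size=n)})
        counts = rng.poisson(3.0, n).astype(float)
        counts[:2] = 500.0  # extreme elements, top-1%
        s = np.full(n, 50)
        freq = counts / (s * 100)
        chroms = np.array(["chrX"] * 10 + ["c1"] * 95 + ["c2"] * 95, dtype=object)
        table = bg.crossvalidate(X, freq, counts, s, 100, chroms, p_cut=0.5)
        assert set(table["fold"]) == {"c1", "c2"}
        assert table["n_test"].sum() <= 190 - 2 + 1  # hypermutated elements dropped
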