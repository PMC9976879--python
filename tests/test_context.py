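"""Enrichment statistics, mutational profiles, TFBS/distance/essentiality summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from regdriver.context import (
    cdg_enrichment,
    cosine_similarity,
    distance_summary,
    dlbcl_top_hits,
    essentiality_summary,
    mutation_gene_pairs,
    mutational_profile,
    oncogene_tsg_enrichment,
    region_trinucleotide_frequency,
    tfbs_enrichment,
)
from regdriver.genome import Genome, SBS_CHANNELS_96
from regdriver.intervals import GeneAnnotation, GenomicInterval


def fisher_oracle(table):
    """Two-tailed Fisher probability by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    obs = stats.hypergeom.pmf(a, n, col1, row1)
    total = 0.0
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = stats.hypergeom.pmf(x, n, col1, row1)
        if p <= obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestCdgEnrichment:
    def test_worked_arithmetic(self):
        universe = [f"G{i}" for i in range(1_000)]
        cdg = universe[:50]
        candidates = universe[:4] + universe[100:106]  # R=10, O=4
        res = cdg_enrichment(candidates, cdg, universe)
        assert (res.observed, res.n_candidates, res.n_annotated, res.n_universe) == (4, 10, 50, 1_000)
        assert res.expected == pytest.approx(0.5)
        assert res.log2_fc == pytest.approx(3.0)
        assert res.fisher_p == pytest.approx(
            fisher_oracle([[4, 6], [46, 944]]), rel=1e-6
        )

    def test_observed_equals_expected_zero_log2(self):
        universe = [f"G{i}" for i in range(100)]
        res = cdg_enrichment(universe[:10], universe[:10] + universe[50:90], universe)
        # O = 10, E = 10 * 50 / 100 = 5 -> log2 = 1; construct O == E instead
        res = cdg_enrichment(universe[:10], universe[5:10] + universe[50:95], universe)
        assert res.expected == pytest.approx(res.observed)
        assert res.log2_fc == pytest.approx(0.0)

    def test_zero_observed_sentinel(self):
        universe = [f"G{i}" for i in range(100)]
        res = cdg_enrichment(universe[:5], universe[50:60], universe)
        assert res.log2_fc == float("-inf") and 0 <= res.fisher_p <= 1

    def test_candidates_equal_universe_degenerate(self):
        universe = [f"G{i}" for i in range(20)]
        res = cdg_enrichment(universe, universe[:5], universe)
        assert res.observed == 5 and res.fisher_p == pytest.approx(1.0)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            cdg_enrichment([], [], [])


class TestOncogeneTsg:
    def test_matches_hypergeometric_oracle(self):
        up = [f"U{i}" for i in range(48)]
        non_cand = [f"N{i}" for i in range(5_000)]
        onco = up[:6] + non_cand[:30]
        out = oncogene_tsg_enrichment(up, [], non_cand, onco, [], set(up[6:]) | set(non_cand[30:]))
        a, b = 6, 42
        c, d = 30, 4_970
        assert out["oncogene_up"]["fisher_p"] == pytest.approx(
            fisher_oracle([[a, b], [c, d]]), rel=1e-6
        )

    def test_zero_annotated_gives_p_one(self):
        out = oncogene_tsg_enrichment(["A"], ["B"], ["C"], [], [], ["A", "B", "C"])
        assert out["oncogene_up"]["fisher_p"] == 1.0

    def test_extreme_enrichment_significant(self):
        up = [f"U{i}" for i in range(20)]
        non_cand = [f"N{i}" for i in range(2_000)]
        out = oncogene_tsg_enrichment(up, [], non_cand, up, [], non_cand)
        assert out["oncogene_up"]["fisher_p"] < 1e-6


class TestMutationalProfile:
    def _genome(self):
        return Genome.from_sequences({"chr1": "AACAGACTGTTAACAG" * 10})

    def test_single_mutation_unit_mass(self):
        genome = Genome.from_sequences({"chr1": "AACAA"})
        freq = region_trinucleotide_frequency(genome, [GenomicInterval("chr1", 1, 4)])
        muts = pd.DataFrame({"chrom": ["chr1"], "pos": [2], "ref": ["C"], "alt": ["T"]})
        profile = mutational_profile(muts, genome, freq)
        assert profile["A[C>T]A"] == pytest.approx(1.0)
        assert profile.sum() == pytest.approx(1.0)

    def test_scale_invariance(self):
        genome = self._genome()
        regions = [GenomicInterval("chr1", 1, 150)]
        freq = region_trinucleotide_frequency(genome, regions)
        muts = pd.DataFrame(
            {"chrom": "chr1", "pos": [2, 6, 18, 22], "ref": list("CCCC"), "alt": list("TTGA")}
        )
        single = mutational_profile(muts, genome, freq)
        double = mutational_profile(pd.concat([muts, muts]), genome, freq)
        np.testing.assert_allclose(single.to_numpy(), double.to_numpy(), atol=1e-12)

    def test_counts_proportional_to_region_frequency_flatten(self, rng):
        genome = self._genome()
        regions = [GenomicInterval("chr1", 1, 159)]
        freq = region_trinucleotide_frequency(genome, regions)
        # one mutation per position with a fixed substitution type: counts of each
        # context are proportional to the regional frequency, so the normalised
        # profile is flat across the represented C>T / T>C channels per context count
        rows = []
        for pos in range(1, 159):
            base = genome.base("chr1", pos)
            alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[base]
            rows.append(("chr1", pos, base, alt))
        muts = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
        profile = mutational_profile(muts, genome, freq)
        represented = profile[profile > 0]
        np.testing.assert_allclose(represented, represented.iloc[0], rtol=1e-9)

    def test_inconsistent_context_errors(self):
        genome = Genome.from_sequences({"chr1": "AACAA"})
        freq = pd.Series(0.0, index=[t for t in region_trinucleotide_frequency(
            genome, [GenomicInterval("chr1", 1, 4)]).index])
        freq["CCC"] = 1.0
        muts = pd.DataFrame({"chrom": ["chr1"], "pos": [2], "ref": ["C"], "alt": ["T"]})
        with pytest.raises(ValueError):
            mutational_profile(muts, genome, freq)


class TestCosine:
    def test_identical_and_disjoint(self):
        a = np.array([1.0, 2.0, 0.0])
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert cosine_similarity(np.array([1.0, 0, 0]), np.array([0, 1.0, 0])) == 0.0

    def test_hand_computed(self):
        a = np.zeros(96)
        b = np.zeros(96)
        a[:2] = [3, 4]
        b[:2] = [4, 3]
        assert cosine_similarity(a, b) == pytest.approx(24 / 25)

    def test_symmetry_and_scale_invariance(self, rng):
        a, b = rng.uniform(size=96), rng.uniform(size=96)
        assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a))
        assert cosine_similarity(3 * a, b) == pytest.approx(cosine_similarity(a, b))

    def test_zero_vector_errors(self):
        with pytest.raises(ValueError):
            cosine_similarity(np.zeros(3), np.ones(3))


def events_frame(n_any, n_gain, prefix):
    rows = []
    for i in range(n_any):
        event = "gain" if i < n_gain else "break"
        rows.append((f"chr1", 1_000 + i, "A", event, "TF1", f"{prefix}{i}"))
    return pd.DataFrame(rows, columns=["chrom", "pos", "alt", "event", "tf_name", "key"])


class TestTfbsEnrichment:
    def test_worked_ratio_and_oracle_p(self):
        table = tfbs_enrichment(events_frame(34, 10, "d"), 100, events_frame(155, 40, "c"), 1_000)
        assert table.loc["any", "ratio"] == pytest.approx((34 / 100) / (155 / 1_000))
        assert table.loc["any", "fisher_p"] == pytest.approx(
            fisher_oracle([[34, 66], [155, 845]]), rel=1e-6
        )

    def test_identical_fractions_ratio_one(self):
        table = tfbs_enrichment(events_frame(20, 5, "d"), 100, events_frame(20, 5, "c"), 100)
        assert table.loc["any", "ratio"] == pytest.approx(1.0)
        assert table.loc["any", "fisher_p"] == pytest.approx(1.0)

    def test_zero_control_events_infinite_ratio(self):
        table = tfbs_enrichment(events_frame(5, 2, "d"), 50, events_frame(0, 0, "c"), 50)
        assert np.isinf(table.loc["any", "ratio"])
        assert 0 < table.loc["any", "fisher_p"] <= 1

    def test_no_events_anywhere_errors(self):
        with pytest.raises(ValueError):
            tfbs_enrichment(events_frame(0, 0, "d"), 10, events_frame(0, 0, "c"), 10)


def toy_genes():
    return {
        "T": GeneAnnotation("T", "protein_coding", "+", "chr1", 10_000, []),
        "NEAR": GeneAnnotation("NEAR", "lncRNA", "+", "chr1", 10_100, []),
        "FAR": GeneAnnotation("FAR", "protein_coding", "+", "chr1", 90_000, []),
    }


class TestDistance:
    def test_mutation_at_tss(self):
        pairs = mutation_gene_pairs(
            pd.DataFrame({"chrom": ["chr1"], "pos": [10_000]}), "T", toy_genes()
        )
        summary = distance_summary(pairs)
        assert summary["frac_promoter_250bp"] == 1.0
        assert pairs["gene_is_closest"].all()

    def test_all_pairs_distal(self):
        muts = pd.DataFrame({"chrom": "chr1", "pos": [40_000, 41_000]})
        summary = distance_summary(mutation_gene_pairs(muts, "T", toy_genes()))
        assert summary["frac_distal_20kb"] == 1.0
        assert summary["median_distance_bp"] == pytest.approx(30_500)

    def test_closest_flags_match_exhaustive_scan(self, rng):
        genes = {
            f"G{i}": GeneAnnotation(
                f"G{i}",
                "protein_coding" if i % 2 == 0 else "lncRNA",
                "+",
                "chr1",
                int(rng.integers(0, 100_000)),
                [],
            )
            for i in range(12)
        }
        muts = pd.DataFrame({"chrom": "chr1", "pos": rng.integers(0, 100_000, 20)})
        target = "G0"
        pairs = mutation_gene_pairs(muts, target, genes)
        for _, row in pairs.iterrows():
            dists = {g: abs(row["pos"] - a.tss) for g, a in genes.items()}
            assert row["gene_is_closest"] == (dists[target] <= min(dists.values()))
            coding = {g: d for g, d in dists.items() if genes[g].gene_type == "protein_coding"}
            assert row["gene_is_closest_coding"] == (dists[target] <= min(coding.values()))

    def test_empty_pairs_error(self):
        with pytest.raises(ValueError):
            distance_summary(pd.DataFrame(columns=["distance_bp"]))


class TestEssentiality:
    def _matrices(self, scores):
        dep = pd.DataFrame(scores, index=["g1", "g2", "g3"], columns=["c1", "c2", "c3"])
        expr = pd.DataFrame(10.0, index=dep.index, columns=dep.columns)
        return dep, expr

    def test_all_zero_scores(self):
        dep, expr = self._matrices(np.zeros((3, 3)))
        out = essentiality_summary(dep, expr, ["g1", "g2"], ["g3"], pd.Series(), rng=np.random.default_rng(0))
        assert out["mean_dependency"] == 0.0 and out["pct_dependent"] == 0.0

    def test_hand_tally(self):
        dep, expr = self._matrices([[0.9, 0.4, 0.6]] * 3)
        out = essentiality_summary(dep, expr, ["g1"], ["g2"], pd.Series(), rng=np.random.default_rng(0))
        assert out["mean_dependency"] == pytest.approx(np.mean([0.9, 0.4, 0.6]))
        assert out["pct_dependent"] == pytest.approx(100 * 2 / 3)

    def test_expression_gating_excludes_silent_lines(self):
        dep, expr = self._matrices([[0.9, 0.9, 0.9]] * 3)
        expr.loc["g1", "c1"] = 0.5  # below the TPM-like threshold
        out = essentiality_summary(dep, expr, ["g1"], ["g2"], pd.Series(), rng=np.random.default_rng(0))
        assert out["mean_dependency"] == pytest.approx(0.9)
        assert out["pct_dependent"] == pytest.approx(100.0)

    def test_resampling_null_calibrated_when_exchangeable(self):
        rng_data = np.random.default_rng(99)
        n_lines = 24
        dep = pd.DataFrame(
            rng_data.uniform(0, 1, (6, n_lines)),
            index=[f"g{i}" for i in range(6)],
            columns=[f"c{i}" for i in range(n_lines)],
        )
        expr = pd.DataFrame(10.0, index=dep.index, columns=dep.columns)
        tissues = pd.Series(
            ["match"] * 4 + ["other"] * (n_lines - 4), index=dep.columns
        )
        hits = 0
        n_rep = 120
        for seed in range(n_rep):
            out = essentiality_summary(
                dep, expr, list(dep.index[:3]), list(dep.index[3:]), tissues,
                tissue="match", n_iter=400, rng=np.random.default_rng(seed),
            )
            hits += out["resampling_p"] < 0.05
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert hits / n_rep < 0.05 + 4 * se

    def test_no_matched_lines_drops_tissue_outputs(self):
        dep, expr = self._matrices(np.full((3, 3), 0.7))
        out = essentiality_summary(
            dep, expr, ["g1"], ["g2"], pd.Series("other", index=dep.columns),
            tissue="match", rng=np.random.default_rng(0),
        )
        assert "resampling_p" not in out


class TestTopHits:
    def _inputs(self, n_patients=3, event="break", tf="REP", fold=6.0, cadd=20.0):
        muts = pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n_patients)],
                "chrom": "chr1",
                "pos": 500,
                "ref": "C",
                "alt": "T",
                "cadd_phred": cadd,
            }
        )
        tfbs = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [500], "alt": ["T"], "event": [event], "tf_name": [tf]}
        )
        classes = {"REP": "negative", "ACT": "positive"}
        samples = [f"S{i}" for i in range(10)]
        expr = pd.DataFrame(
            [[100.0] * 10], index=["G"], columns=samples
        )
        expr.loc["G", [f"S{i}" for i in range(n_patients)]] = 100.0 * fold
        return muts, tfbs, classes, expr, {("chr1", 500): "G"}

    def test_qualifying_break_hit(self):
        hits = dlbcl_top_hits(*self._inputs())
        assert len(hits) == 1 and hits.iloc[0]["gene_id"] == "G"

    def test_break_in_two_patients_excluded(self):
        assert len(dlbcl_top_hits(*self._inputs(n_patients=2))) == 0

    def test_gain_in_two_patients_qualifies(self):
        muts, tfbs, classes, expr, mg = self._inputs(n_patients=2, event="gain", tf="ACT")
        assert len(dlbcl_top_hits(muts, tfbs, classes, expr, mg)) == 1

    def test_low_fold_change_excluded(self):
        assert len(dlbcl_top_hits(*self._inputs(fold=2.5))) == 0

    def test_low_cadd_excluded(self):
        assert len(dlbcl_top_hits(*self._inputs(cadd=5.0))) == 0

    def test_wrong_regulator_class_excluded(self):
        muts, tfbs, classes, expr, mg = self._inputs(tf="ACT")  # break of a positive regulator
        assert len(dlbcl_top_hits(muts, tfbs, classes, expr, mg)) == 0
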