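"""Monte-Carlo cross-validation orchestration, aggregation and gene importance."""

import numpy as np
import pandas as pd
import pytest

from gxrx import (
    GAConfig,
    GARunResult,
    Chromosome,
    aggregate_predictions,
    chance_frequency,
    classify_predictable,
    correlations,
    flag_correlated_genes,
    gene_drug_response_correlation,
    generate,
    make_partitions,
    run_drug,
    selection_frequencies,
    SyntheticConfig,
)


class TestMakePartitions:
    def test_forced_single_test_sample(self):
        plan = make_partitions(10, 5, 0.1, seed=0)
        for train, test in plan.partitions:
            assert len(test) == 1 and len(train) == 9
            assert sorted(np.concatenate([train, test])) == list(range(10))

    def test_expected_test_membership(self):
        plan = make_partitions(500, 100, 0.1, seed=1)
        counts = np.zeros(500)
        for _, test in plan.partitions:
            counts[test] += 1
        # exactly 50 test slots per partition -> mean membership exactly 10
        assert counts.mean() == pytest.approx(10.0)
        assert counts.min() > 0  # at N=500, R=100 every sample shows up

    def test_seed_determinism(self):
        a = make_partitions(40, 10, 0.1, seed=5)
        b = make_partitions(40, 10, 0.1, seed=5)
        for (ta, sa), (tb, sb) in zip(a.partitions, b.partitions):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)

    def test_too_small_cohort(self):
        with pytest.raises(ValueError):
            make_partitions(2, 5, 0.1)


class TestAggregatePredictions:
    @pytest.mark.parametrize(
        "runs,want",
        [
            ([{0: 1.0}, {0: 2.0}], 1.5),
            ([{0: 0.7}], 0.7),
            ([{0: 0.5}, {0: 1.0}, {0: 1.5}], 1.0),
        ],
    )
    def test_mean_over_contributing_runs(self, runs, want):
        out = aggregate_predictions(runs, 2)
        assert out[0] == pytest.approx(want)

    def test_absent_sample_is_nan_not_fabricated(self):
        out = aggregate_predictions([{0: 1.0}], 3)
        assert np.isnan(out[1]) and np.isnan(out[2])


class TestCorrelations:
    def test_identity_and_antitone(self):
        y = np.array([0.3, 1.2, 2.0, 5.0])
        assert correlations(y, y) == (pytest.approx(1.0), pytest.approx(1.0))
        rp, rs = correlations(y, -y)
        assert rp == pytest.approx(-1.0) and rs == pytest.approx(-1.0)

    def test_spearman_hand_case(self):
        # ranks differ by d = (0,1,1,0): rho_s = 1 - 6*2/(4*15) = 0.8
        _, rs = correlations(np.array([1.0, 2, 3, 4]), np.array([1.0, 3, 2, 4]))
        assert rs == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlations(np.array([1.0, 1, 1]), np.array([1.0, 2, 3]))


class TestClassifyPredictable:
    @pytest.mark.parametrize(
        "rp,rs,want",
        [(0.40, 0.40, True), (0.55, 0.39, False), (-0.2, 0.9, False), (0.9, 0.9, True)],
    )
    def test_threshold_both_sided_inclusive(self, rp, rs, want):
        assert classify_predictable(rp, rs) is want


def run_result(genes, seed=0):
    return GARunResult(best_chromosome=Chromosome(tuple(genes)), best_loss=0.0, seed=seed)


class TestSelectionFrequencies:
    def test_counting_and_conservation(self):
        results = [run_result((0, 1, 2)), run_result((0, 3, 4))]
        freq = selection_frequencies(results, G=6)
        assert freq.tolist() == [2, 1, 1, 1, 1, 0]
        assert freq.sum() == 2 * 3

    def test_gene_in_all_runs(self):
        results = [run_result((5, i, 10 + i)) for i in range(4)]
        freq = selection_frequencies(results, G=20)
        assert freq[5] == 4


class TestChanceFrequency:
    def test_transcriptome_scale_expectation(self):
        # 30-gene sets over a 19163-gene transcriptome, 100 repeats
        assert chance_frequency(100, 30, 19163) == pytest.approx(0.1566, abs=5e-4)

    @pytest.mark.parametrize("R,d,G,want", [(100, 30, 3000, 1.0), (1, 7, 7, 1.0)])
    def test_exact_arithmetic(self, R, d, G, want):
        assert chance_frequency(R, d, G) == pytest.approx(want)


class TestGeneResponseCorrelation:
    def test_monotone_and_antimonotone(self):
        y = np.array([0.1, 0.5, 1.2, 3.0, 4.4])
        assert gene_drug_response_correlation(np.sort(np.random.default_rng(0).normal(size=5)), y) == pytest.approx(1.0)
        assert gene_drug_response_correlation(-y, y) == pytest.approx(-1.0)

    def test_flagging_at_default_cutoff(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=30)
        X = np.vstack([y + rng.normal(0, 0.2, 30), rng.normal(size=30)])
        out = flag_correlated_genes(X, y, ["corr", "noise"])
        assert bool(out.loc[out.gene == "corr", "flagged"].iloc[0]) is True


@pytest.fixture(scope="module")
def tiny_run():
    sd = generate(SyntheticConfig(G=60, n_cell_lines=60, samples_per_type=4, seed=3))
    ds = sd.pipeline_dataset()
    cfg = GAConfig(d=8, k=3, population_size=24, max_generations=20,
                   stall_generations=6, seed=5)
    plan = make_partitions(ds.n_cell_lines, 6, 0.1, seed=9)
    return sd, ds, cfg, plan, run_drug(ds, cfg, plan)


class TestRunDrug:

    def test_selection_frequency_conservation(self, tiny_run):
        _, ds, cfg, plan, res = tiny_run
        assert res.selection_frequency.sum() == plan.R * cfg.d

    def test_train_predictions_bounded_by_observed(self, tiny_run):
        _, ds, *_rest, res = tiny_run
        y = ds.y.to_numpy()
        seen = ~np.isnan(res.aggregated_train_prediction)
        assert res.aggregated_train_prediction[seen].min() >= y.min() - 1e-12
        assert res.aggregated_train_prediction[seen].max() <= y.max() + 1e-12

    def test_end_to_end_determinism(self, tiny_run):
        sd, ds, cfg, plan, res = tiny_run
        res2 = run_drug(ds, cfg, plan)
        assert res2.rho_pearson_test == res.rho_pearson_test
        np.testing.assert_array_equal(
            np.nan_to_num(res2.aggregated_test_prediction),
            np.nan_to_num(res.aggregated_test_prediction),
        )
        pd.testing.assert_series_equal(res2.selection_frequency, res.selection_frequency)

    def test_single_run_single_test_sample(self):
        sd = generate(SyntheticConfig(G=40, n_cell_lines=20, samples_per_type=2, seed=4))
        ds = sd.pipeline_dataset()
        cfg = GAConfig(d=5, k=3, population_size=12, max_generations=8,
                       stall_generations=4, seed=2)
        plan = make_partitions(ds.n_cell_lines, 1, 0.1, seed=1)
        res = run_drug(ds, cfg, plan)
        (train, test) = plan.partitions[0]
        for i in test:
            assert res.aggregated_test_prediction[i] == res.per_run_test_predictions[0][i]
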