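"""Transfer prediction to tissues and the specificity statistics."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from gxrx import (
    ExternalPredictionTable,
    GAConfig,
    SyntheticConfig,
    fold_change_from_log_units,
    generate,
    make_partitions,
    mutation_association,
    mutation_indicators_from_maf,
    predict_external,
    rank_sum_test,
    run_drug,
    subtype_differential,
    tumor_to_normal,
    tumor_type_specificity,
)


def table(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "source_class", "tissue_type",
                                     "subtype", "predicted_ln_ic50"])
    df["runs_contributing"] = 1
    return ExternalPredictionTable(rows=df)


def spread(tissue, source, center, n, subtype=None):
    # symmetric values around `center` so the median is exactly `center`
    offsets = np.linspace(-0.2, 0.2, n)
    return [(f"{tissue}-{source}-{i}", source, tissue, subtype, center + o)
            for i, o in enumerate(offsets)]


class TestTumorTypeSpecificity:
    def test_low_median_type_flagged(self):
        rows = spread("A", "tumor", 0.0, 5) + spread("B", "tumor", 0.0, 5) + spread("C", "tumor", -2.0, 5)
        rep = tumor_type_specificity(table(rows))
        assert rep.median_of_medians == pytest.approx(0.0)
        assert rep.specific_types == ["C"]

    def test_identical_types_not_flagged(self):
        rows = spread("A", "tumor", 1.0, 5) + spread("B", "tumor", 1.0, 5)
        assert tumor_type_specificity(table(rows)).specific_types == []

    def test_log_unit_is_e_fold(self):
        assert fold_change_from_log_units(1.0) == pytest.approx(2.718, abs=1e-3)
        assert fold_change_from_log_units(0.5) == pytest.approx(1.6487, abs=1e-4)
        assert fold_change_from_log_units(0.0) == 1.0


class TestTumorToNormal:
    def test_large_gap_flagged(self):
        rows = spread("A", "tumor", -1.5, 10) + spread("A", "normal", 0.0, 25)
        out = tumor_to_normal(table(rows))
        row = out[out.tissue_type == "A"].iloc[0]
        assert row.eligible and row.flagged

    def test_exactly_min_normals_is_skipped(self):
        rows = spread("A", "tumor", -3.0, 10) + spread("A", "normal", 0.0, 20)
        out = tumor_to_normal(table(rows), min_normals=20)
        row = out[out.tissue_type == "A"].iloc[0]
        assert not row.eligible and not row.flagged

    def test_identical_distributions_never_flagged(self):
        rows = spread("A", "tumor", 0.5, 30) + spread("A", "normal", 0.5, 30)
        out = tumor_to_normal(table(rows))
        assert not out["flagged"].any()


class TestSubtypeDifferential:
    def test_minimum_median_subtype_reported(self):
        rows = []
        for name, med in [("basal", -3.6), ("her2", -3.4), ("lumA", -2.8),
                          ("lumB", -3.0), ("normal-like", -3.0)]:
            rows += spread("BRCA", "tumor", med, 5, subtype=name)
        out = subtype_differential(table(rows))
        assert out.loc[out.most_sensitive, "subtype"].tolist() == ["basal"]

    def test_gap_beyond_half_log_unit_flagged(self):
        rows = []
        for name, med in [("a", 0.0), ("b", 0.0), ("c", 0.0), ("d", 0.0), ("e", -0.6)]:
            rows += spread("BRCA", "tumor", med, 5, subtype=name)
        out = subtype_differential(table(rows))
        assert out.loc[out.flagged, "subtype"].tolist() == ["e"]

    def test_equal_subtypes_unflagged(self):
        rows = spread("T", "tumor", 1.0, 4, "x") + spread("T", "tumor", 1.0, 4, "y")
        assert not subtype_differential(table(rows))["flagged"].any()

    def test_single_subtype_rejected(self):
        rows = spread("T", "tumor", 1.0, 4, "x")
        with pytest.raises(ValueError):
            subtype_differential(table(rows))


def exact_rank_sum_p(a, b):
    """Enumeration oracle: two-sided rank-sum p over all C(n+m, n) splits."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    n = len(a)
    observed = ranks[:n].sum()
    center = n * (len(pooled) + 1) / 2
    stat = abs(observed - center)
    hits = 0
    total = 0
    for idx in combinations(range(len(pooled)), n):
        total += 1
        if abs(ranks[list(idx)].sum() - center) >= stat - 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    def test_complete_separation_at_five_vs_five(self):
        p = rank_sum_test(np.arange(1.0, 6.0), np.arange(6.0, 11.0))
        assert p == pytest.approx(2 / comb(10, 5), rel=1e-9)  # 2/252

    def test_identical_groups_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert rank_sum_test(a, a) == pytest.approx(1.0)

    def test_matches_enumeration_for_all_small_sizes(self):
        rng = np.random.default_rng(123)
        for n in range(2, 7):
            for m in range(n, 7):
                a = rng.normal(size=n)
                b = rng.normal(size=m)
                assert rank_sum_test(a, b) == pytest.approx(exact_rank_sum_p(a, b), rel=1e-9)


class TestMutationAssociation:
    def build(self, n_mut, n_wt, delta):
        rows = [(f"m{i}", "tumor", "T", None, delta + 0.01 * i) for i in range(n_mut)]
        rows += [(f"w{i}", "tumor", "T", None, 0.0 + 0.01 * i) for i in range(n_wt)]
        muts = pd.DataFrame({"sample_id": [f"m{i}" for i in range(n_mut)],
                             "gene": "KRAS", "mutated": True})
        return table(rows), muts

    def test_eligible_pair_tested_with_direction(self):
        preds, muts = self.build(6, 10, -2.0)
        out = mutation_association(preds, muts)
        row = out.iloc[0]
        assert row.tested and row.n_mutated == 6
        assert row.direction == -1
        assert row.rank_sum_p < 0.01

    def test_below_min_mutated_skipped(self):
        preds, muts = self.build(4, 10, -2.0)
        out = mutation_association(preds, muts)
        assert not out.iloc[0].tested
        assert math.isnan(out.iloc[0].rank_sum_p)

    def test_indicator_construction_filters_variant_classes(self):
        maf = pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s1"],
                "gene": ["KRAS", "KRAS", "KRAS", "TP53"],
                "variant_class": ["Missense_Mutation", "Silent", "Splice_Site_Mutation", "3'UTR"],
            }
        )
        out = mutation_indicators_from_maf(maf)
        assert set(map(tuple, out[["sample_id", "gene"]].to_numpy())) == {("s1", "KRAS"), ("s3", "KRAS")}


@pytest.fixture(scope="module")
def trained():
    sd = generate(SyntheticConfig(G=80, n_cell_lines=50, n_tumor_types=2,
                                  samples_per_type=6, seed=21))
    ds = sd.pipeline_dataset()
    cfg = GAConfig(d=6, k=3, population_size=20, max_generations=12,
                   stall_generations=5, seed=3)
    plan = make_partitions(ds.n_cell_lines, 4, 0.1, seed=8)
    res = run_drug(ds, cfg, plan)
    return sd, ds, cfg, plan, res


class TestPredictExternal:

    def test_all_runs_contribute(self, trained):
        sd, ds, cfg, plan, res = trained
        out = predict_external(ds, res.run_results, plan, k=cfg.k)
        assert (out.rows["runs_contributing"] == plan.R).all()
        assert len(out.rows) == ds.external.n_samples

    def test_predictions_within_observed_range(self, trained):
        sd, ds, cfg, plan, res = trained
        out = predict_external(ds, res.run_results, plan, k=cfg.k)
        y = ds.y.to_numpy()
        assert out.rows["predicted_ln_ic50"].min() >= y.min() - 1e-12
        assert out.rows["predicted_ln_ic50"].max() <= y.max() + 1e-12

    def test_zero_distance_duplicate_recovers_observed_value(self):
        sd = generate(SyntheticConfig(G=60, n_cell_lines=40, n_tumor_types=2,
                                      samples_per_type=4, seed=13))
        ds = sd.pipeline_dataset()
        dup = sd.truth["duplicate_control"]
        cfg = GAConfig(d=5, k=1, population_size=16, max_generations=8,
                       stall_generations=4, seed=1)
        # pick a partition whose training set contains the duplicated cell line
        for seed in range(20):
            plan = make_partitions(ds.n_cell_lines, 1, 0.1, seed=seed)
            train = plan.partitions[0][0]
            pos = ds.X.sample_ids.index(dup["cell_line_id"])
            if pos in train:
                break
        res = run_drug(ds, cfg, plan)
        out = predict_external(ds, res.run_results, plan, k=1)
        got = out.rows.set_index("sample_id").loc[dup["external_id"], "predicted_ln_ic50"]
        assert got == pytest.approx(float(ds.y.iloc[pos]), abs=1e-9)
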