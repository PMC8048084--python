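"""Per-drug Monte-Carlo cross-validation, prediction aggregation and
gene-importance scoring.

For each drug the cell-line cohort is split R times (default 100) into a
90% training / 10% testing partition.  Each run evolves a d-gene set
minimizing leave-one-out kNN loss on the training set, then predicts the
held-out samples with the training cell lines as the only neighbor pool.
A sample's final prediction is the average over the runs in which it was
held out (resp. trained on).  A drug is "predictable" when the Pearson
and Spearman correlations between observed and aggregated test-set
predictions are both >= 0.4.  Gene importance is the selection frequency:
the number of the R best gene sets that contain the gene, to be compared
against the chance expectation R*d/G.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .ga import GAConfig, GARunResult, evolve
from .knn import knn_predict_pool, loo_predictions
from .matrix import DrugDataset

__all__ = [
    "PartitionPlan",
    "DrugModelResult",
    "make_partitions",
    "run_drug",
    "aggregate_predictions",
    "correlations",
    "classify_predictable",
    "selection_frequencies",
    "chance_frequency",
    "gene_drug_response_correlation",
    "flag_correlated_genes",
]


@dataclass
class PartitionPlan:
    """R independent train/test partitions over N samples."""

    partitions: list[tuple[np.ndarray, np.ndarray]]
    N: int
    test_fraction: float
    seed: int

    @property
    def R(self) -> int:
        return len(self.partitions)


@dataclass
class DrugModelResult:
    """Everything the Monte-Carlo CV produces for one drug.

    Aggregated prediction vectors hold NaN for samples that never appeared
    in the corresponding set (possible though rare); correlations are
    computed over the defined entries only.
    """

    drug_id: str
    run_results: list[GARunResult]
    per_run_test_predictions: list[dict[int, float]]
    per_run_train_predictions: list[dict[int, float]]
    aggregated_test_prediction: np.ndarray
    aggregated_train_prediction: np.ndarray
    rho_pearson_test: float
    rho_spearman_test: float
    predictable: bool
    selection_frequency: pd.Series
    sample_ids: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "drug_id": [self.drug_id],
                "rho_pearson_test": [self.rho_pearson_test],
                "rho_spearman_test": [self.rho_spearman_test],
                "predictable": [self.predictable],
            }
        )


def make_partitions(N: int, R: int, test_fraction: float = 0.1, seed: int = 0) -> PartitionPlan:
    """R independent uniform train/test partitions.

    Test size is round(test_fraction * N) with a floor of 1; every sample is
    expected to be held out about R * test_fraction times.
    """
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = max(1, round(test_fraction * N))
    if N - n_test < 2:
        raise ValueError(f"N={N} too small for a nonempty train/test split")
    rng = np.random.default_rng(seed)
    partitions = []
    for _ in range(R):
        perm = rng.permutation(N)
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
        partitions.append((train, test))
    return PartitionPlan(partitions=partitions, N=N, test_fraction=test_fraction, seed=seed)


def aggregate_predictions(per_run: list[dict[int, float]], N: int) -> np.ndarray:
    """Per-sample mean over the runs containing the sample; NaN when absent."""
    sums = np.zeros(N)
    counts = np.zeros(N)
    for run in per_run:
        for idx, val in run.items():
            sums[idx] += val
            counts[idx] += 1
    out = np.full(N, np.nan)
    seen = counts > 0
    out[seen] = sums[seen] / counts[seen]
    return out


def correlations(obs: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    """Pearson and Spearman correlation between observed and predicted values.

    Spearman uses mid-ranks for ties.  Requires >= 3 pairs and non-constant
    vectors.
    """
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("length mismatch")
    if obs.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho_p = float(stats.pearsonr(obs, pred).statistic)
    rho_s = float(stats.spearmanr(obs, pred).statistic)
    return rho_p, rho_s


def classify_predictable(rho_p: float, rho_s: float, threshold: float = 0.4) -> bool:
    """True iff both correlations reach the threshold (boundary inclusive)."""
    if not (np.isfinite(rho_p) and np.isfinite(rho_s)):
        raise ValueError("correlations must be finite")
    return bool(rho_p >= threshold and rho_s >= threshold)


def selection_frequencies(run_results: list[GARunResult], G: int) -> pd.Series:
    """Per-gene count of best gene sets containing it (length-G series)."""
    counts = np.zeros(G, dtype=int)
    for res in run_results:
        for g in res.best_chromosome.genes:
            if g >= G:
                raise IndexError(f"gene index {g} outside universe of size {G}")
            counts[g] += 1
    return pd.Series(counts, name="selection_frequency")


def chance_frequency(R: int, d: int, G: int) -> float:
    """Expected selection count of one gene under uniformly random d-sets: R*d/G."""
    if not (G >= d >= 1 and R >= 1):
        raise ValueError("require G >= d >= 1 and R >= 1")
    return R * d / G


def gene_drug_response_correlation(expr_row: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation between one gene's expression and ln(IC50)."""
    expr_row = np.asarray(expr_row, dtype=float)
    y = np.asarray(y, dtype=float)
    if expr_row.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(expr_row) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.spearmanr(expr_row, y).statistic)


def flag_correlated_genes(X: np.ndarray, y: np.ndarray, gene_ids: list[str],
                          cutoff: float = 0.3) -> pd.DataFrame:
    """Screen every gene for |Spearman rho| >= cutoff against ln(IC50)."""
    rhos = np.array([gene_drug_response_correlation(row, y) for row in np.asarray(X, dtype=float)])
    df = pd.DataFrame({"gene": gene_ids, "rho_spearman": rhos})
    df["flagged"] = np.abs(df["rho_spearman"]) >= cutoff
    return df


def run_drug(ds: DrugDataset, cfg: GAConfig, plan: PartitionPlan,
             progress: Optional[callable] = None) -> DrugModelResult:
    """Full Monte-Carlo CV for one drug.

    Run r evolves on partition r's training columns with seed
    ``cfg.seed + r``, predicts the held-out samples from the training pool,
    and leave-one-out-predicts the training samples.  Aggregation,
    correlations, the predictability flag and selection frequencies are
    populated on the result.
    """
    X = np.ascontiguousarray(ds.X.values.to_numpy(), dtype=float)
    y = ds.y.to_numpy(dtype=float)
    N = X.shape[1]
    if plan.N != N:
        raise ValueError(f"partition plan covers {plan.N} samples, dataset has {N}")

    run_results: list[GARunResult] = []
    test_preds: list[dict[int, float]] = []
    train_preds: list[dict[int, float]] = []
    for r, (train, test) in enumerate(plan.partitions):
        run_cfg = GAConfig(
            d=cfg.d, k=cfg.k, population_size=cfg.population_size,
            max_generations=cfg.max_generations, mutation_rate=cfg.mutation_rate,
            tournament_size=cfg.tournament_size, elite_count=cfg.elite_count,
            stall_generations=cfg.stall_generations, seed=cfg.seed + r,
        )
        res = evolve(run_cfg, X[:, train], y[train])
        run_results.append(res)
        genes = list(res.best_chromosome.genes)
        pool = X[np.ix_(genes, train)]
        test_vals = knn_predict_pool(pool, y[train], X[np.ix_(genes, test)], cfg.k)
        test_preds.append({int(i): float(v) for i, v in zip(test, test_vals)})
        train_vals = loo_predictions(pool, y[train], cfg.k)
        train_preds.append({int(i): float(v) for i, v in zip(train, train_vals)})
        if progress is not None:
            progress(r, res)

    agg_test = aggregate_predictions(test_preds, N)
    agg_train = aggregate_predictions(train_preds, N)
    seen = ~np.isnan(agg_test)
    # correlations need >= 3 non-constant pairs; with very few runs the
    # held-out coverage can be too thin to score
    try:
        rho_p, rho_s = correlations(y[seen], agg_test[seen])
        predictable = classify_predictable(rho_p, rho_s)
    except ValueError:
        rho_p = rho_s = float("nan")
        predictable = False
    return DrugModelResult(
        drug_id=ds.drug_id,
        run_results=run_results,
        per_run_test_predictions=test_preds,
        per_run_train_predictions=train_preds,
        aggregated_test_prediction=agg_test,
        aggregated_train_prediction=agg_train,
        rho_pearson_test=rho_p,
        rho_spearman_test=rho_s,
        predictable=predictable,
        selection_frequency=selection_frequencies(run_results, X.shape[0]),
        sample_ids=ds.X.sample_ids,
    )
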