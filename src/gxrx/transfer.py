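"""Transfer prediction of drug sensitivity to external tissue samples and
the downstream specificity statistics.

Each of the R Monte-Carlo runs contributes a prediction for every external
(tumor or normal) sample, using that run's best gene set and that run's
training cell lines as the only neighbor pool; the final imputed ln(IC50)
is the mean over the R runs.  The specificity statistics then work on
per-group medians:

* tumor-type specificity — a tumor type is flagged for a drug when its
  median predicted ln(IC50) is at least one logarithmic unit (~2.7-fold)
  below the median of the per-type medians;
* tumor-to-normal — for tissue types with more than ``min_normals`` normal
  samples, flag when the tumor median is more than one log unit below the
  normal median;
* subtype differential — flag subtypes whose median is more than half a
  log unit (~1.65-fold) below the median of subtype medians;
* mutation association — two-sided Wilcoxon rank-sum comparison of
  predicted ln(IC50) between mutated and wild-type samples, computed only
  where at least ``min_mutated`` samples carry the mutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .cv import PartitionPlan
from .ga import GARunResult
from .knn import knn_predict_pool
from .matrix import DrugDataset

__all__ = [
    "ExternalPredictionTable",
    "SpecificityReport",
    "predict_external",
    "tumor_type_specificity",
    "tumor_to_normal",
    "subtype_differential",
    "mutation_association",
    "mutation_indicators_from_maf",
    "rank_sum_test",
    "fold_change_from_log_units",
    "QUALIFYING_VARIANT_CLASSES",
]

# variant classes that qualify a sample as mutated in a gene; anything else
# (silent, UTR, intronic, ...) is ignored
QUALIFYING_VARIANT_CLASSES = frozenset(
    {
        "nonsense mutation",
        "missense mutation",
        "frame shift deletion",
        "frame shift insertion",
        "in frame deletion",
        "splice site mutation",
    }
)


@dataclass
class ExternalPredictionTable:
    """Imputed ln(IC50) per external sample, averaged over all R runs."""

    rows: pd.DataFrame  # sample_id, source_class, tissue_type, subtype, predicted_ln_ic50, runs_contributing

    def tumors(self) -> pd.DataFrame:
        return self.rows[self.rows["source_class"] == "tumor"]

    def normals(self) -> pd.DataFrame:
        return self.rows[self.rows["source_class"] == "normal"]


@dataclass
class SpecificityReport:
    """Bundle of the per-drug specificity fragments."""

    drug_id: str
    tissue_medians: pd.Series = field(default_factory=pd.Series)
    median_of_medians: float = math.nan
    specific_types: list[str] = field(default_factory=list)
    tumor_to_normal: Optional[pd.DataFrame] = None
    subtype_diff: Optional[pd.DataFrame] = None


def predict_external(ds: DrugDataset, run_results: list[GARunResult], plan: PartitionPlan,
                     k: int = 3) -> ExternalPredictionTable:
    """Impute ln(IC50) for every external sample from cell-line neighbors.

    For run r the neighbor pool is restricted to that run's training cell
    lines and the coordinates to that run's best gene set; predictions are
    averaged over all R runs, so ``runs_contributing`` equals R everywhere.
    """
    if ds.external is None:
        raise ValueError("dataset has no external expression matrix attached")
    if len(run_results) != plan.R:
        raise ValueError("run_results and partition plan have different lengths")
    X = ds.X.values.to_numpy(dtype=float)
    y = ds.y.to_numpy(dtype=float)
    E = ds.external.values.to_numpy(dtype=float)
    M = E.shape[1]
    total = np.zeros(M)
    for res, (train, _test) in zip(run_results, plan.partitions):
        genes = list(res.best_chromosome.genes)
        total += knn_predict_pool(X[np.ix_(genes, train)], y[train], E[genes, :], k)
    preds = total / plan.R

    meta = ds.external.meta
    if meta is None:
        raise ValueError("external matrix has no per-sample metadata")
    meta = meta.reindex(ds.external.sample_ids)
    rows = pd.DataFrame(
        {
            "sample_id": ds.external.sample_ids,
            "source_class": meta["source_class"].to_numpy(),
            "tissue_type": meta["tissue_type"].to_numpy(),
            "subtype": meta["subtype"].to_numpy() if "subtype" in meta.columns else pd.NA,
            "predicted_ln_ic50": preds,
            "runs_contributing": plan.R,
        }
    )
    return ExternalPredictionTable(rows=rows)


def tumor_type_specificity(preds: ExternalPredictionTable, threshold_log_units: float = 1.0,
                           drug_id: str = "") -> SpecificityReport:
    """Flag tumor types whose median sits >= threshold below the median of medians."""
    tumors = preds.tumors()
    medians = tumors.groupby("tissue_type")["predicted_ln_ic50"].median().sort_index()
    if len(medians) < 2:
        raise ValueError("need at least 2 tumor types for tumor-type specificity")
    mom = float(np.median(medians.to_numpy()))
    specific = [t for t, m in medians.items() if m <= mom - threshold_log_units]
    return SpecificityReport(
        drug_id=drug_id, tissue_medians=medians, median_of_medians=mom, specific_types=specific
    )


def tumor_to_normal(preds: ExternalPredictionTable, min_normals: int = 20,
                    threshold_log_units: float = 1.0) -> pd.DataFrame:
    """Tumor vs normal median comparison per tissue type.

    Only tissue types with strictly more than ``min_normals`` normal samples
    are eligible; the rest are reported with ``eligible = False``.  A type is
    flagged when the tumor median is more than ``threshold_log_units`` below
    the normal median.
    """
    tumors = preds.tumors()
    normals = preds.normals()
    types = sorted(set(tumors["tissue_type"]) & set(normals["tissue_type"]))
    out = []
    for t in types:
        tvals = tumors.loc[tumors["tissue_type"] == t, "predicted_ln_ic50"]
        nvals = normals.loc[normals["tissue_type"] == t, "predicted_ln_ic50"]
        eligible = len(nvals) > min_normals
        med_t = float(tvals.median())
        med_n = float(nvals.median())
        out.append(
            {
                "tissue_type": t,
                "n_tumor": len(tvals),
                "n_normal": len(nvals),
                "median_tumor": med_t,
                "median_normal": med_n,
                "eligible": eligible,
                "flagged": bool(eligible and med_t < med_n - threshold_log_units),
            }
        )
    return pd.DataFrame(out)


def subtype_differential(preds: ExternalPredictionTable, threshold_log_units: float = 0.5,
                         tissue_type: Optional[str] = None) -> pd.DataFrame:
    """Per-subtype medians vs the median of subtype medians.

    A subtype is flagged when its median is more than ``threshold_log_units``
    below the median of the subtype medians; the subtype with the minimum
    median is marked ``most_sensitive``.
    """
    tumors = preds.tumors()
    if tissue_type is not None:
        tumors = tumors[tumors["tissue_type"] == tissue_type]
    tumors = tumors[tumors["subtype"].notna()]
    medians = tumors.groupby("subtype")["predicted_ln_ic50"].median().sort_index()
    if len(medians) < 2:
        raise ValueError("need at least 2 subtypes for a subtype differential")
    mom = float(np.median(medians.to_numpy()))
    df = pd.DataFrame(
        {
            "subtype": medians.index,
            "n": tumors.groupby("subtype").size().reindex(medians.index).to_numpy(),
            "median": medians.to_numpy(),
            "median_of_medians": mom,
        }
    )
    df["flagged"] = (mom - df["median"]) > threshold_log_units
    df["most_sensitive"] = df["median"] == df["median"].min()
    return df


def rank_sum_test(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null enumeration when the smaller group has <= 8 observations and
    there are no ties; normal approximation with tie correction otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def mutation_indicators_from_maf(maf: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long-format variant table to per-(sample, gene) indicators.

    ``maf`` needs columns sample_id, gene, variant_class.  A sample counts as
    mutated in a gene when any qualifying variant class occurs; other classes
    are ignored.
    """
    norm = maf["variant_class"].str.strip().str.lower().str.replace("_", " ")
    hits = maf[norm.isin(QUALIFYING_VARIANT_CLASSES)]
    out = hits[["sample_id", "gene"]].drop_duplicates().reset_index(drop=True)
    out["mutated"] = True
    return out


def mutation_association(preds: ExternalPredictionTable, mutations: pd.DataFrame,
                         min_mutated: int = 5) -> pd.DataFrame:
    """Wilcoxon rank-sum association of mutation status with predicted ln(IC50).

    ``mutations`` holds per-(sample_id, gene) indicator rows (see
    :func:`mutation_indicators_from_maf`).  For every (gene, tissue type)
    with at least ``min_mutated`` mutated tumor samples and at least one
    wild-type sample, reports the two-sided p-value and the direction
    (sign of median(mutated) - median(wild-type)).  Ineligible pairs are
    returned with ``tested = False``.
    """
    tumors = preds.tumors()
    out = []
    for gene, sub in mutations.groupby("gene"):
        carriers = set(sub["sample_id"])
        for tissue, tsub in tumors.groupby("tissue_type"):
            is_mut = tsub["sample_id"].isin(carriers).to_numpy()
            mut = tsub.loc[is_mut, "predicted_ln_ic50"].to_numpy()
            wt = tsub.loc[~is_mut, "predicted_ln_ic50"].to_numpy()
            row = {
                "gene": gene,
                "tissue_type": tissue,
                "n_mutated": int(mut.size),
                "n_wildtype": int(wt.size),
            }
            if mut.size >= min_mutated and wt.size >= 1:
                p = rank_sum_test(mut, wt)
                row.update(
                    tested=True,
                    rank_sum_p=p,
                    direction=int(np.sign(np.median(mut) - np.median(wt))),
                )
            else:
                row.update(tested=False, rank_sum_p=math.nan, direction=0)
            out.append(row)
    return pd.DataFrame(out)


def fold_change_from_log_units(delta: float) -> float:
    """Fold change implied by a difference on the ln(IC50) scale: exp(delta)."""
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    return float(math.exp(delta))
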