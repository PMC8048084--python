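"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates the three data roles the analysis consumes:

* a cell-line cohort whose ln(IC50) is a noisy linear function of a small
  planted subset of genes, the "signal genes", acting on the pipeline's
  z-scored expression scale;
* tissue-labeled external tumor/normal samples drawn from the same
  generative model, with per-tissue mean shifts applied along the signal
  genes (so a "sensitive" tissue really is shifted on the scale the model
  predicts);
* per-sample mutation indicators whose carriers are shifted along the same
  signal axis, so mutation status is genuinely associated with response.

Raw expression is exponentiated Gaussian (TPM-like, heavy-tailed,
nonnegative).  The response is constructed from the z-scores the package's
own transform chain produces, so the planted relationship is exactly what
the GA/kNN model can recover.  Every draw is a deterministic function of
the seed, and the ``truth`` record suffices to recompute every planted
effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import (
    DrugDataset,
    DrugResponseTable,
    ExpressionMatrix,
    attach_external,
    build_drug_dataset,
    log2p1_transform,
    standardize,
    write_expression,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "null_generate", "export"]

DRUG_ID = "D1"


@dataclass
class SyntheticConfig:
    """Generator settings.

    By default three signal genes with effects (1.0, 0.8, 0.6) drive the
    response; the noise standard deviation is derived so the linear signal
    explains ~75% of the response variance (set ``noise_sd`` to override).
    Tissue 0 is planted as the sensitive tissue with a -1.5 log-unit shift;
    the other tissues are unshifted.  Mutation carriers are shifted
    +1.0 log unit (more resistant).
    """

    G: int = 500
    n_cell_lines: int = 200
    n_signal_genes: int = 3
    effect_sizes: tuple[float, ...] = (1.0, 0.8, 0.6)
    noise_sd: Optional[float] = None
    explained_variance: float = 0.75
    n_tumor_types: int = 4
    samples_per_type: int = 50
    tissue_shifts: Optional[tuple[float, ...]] = None  # default: (-1.5, 0, ..., 0)
    normal_fraction: float = 0.5
    subtype_count: int = 0
    subtype_shifts: tuple[float, ...] = ()
    mutation_genes: int = 2
    mutation_rate: float = 0.3
    mutation_effect: float = 1.0
    include_duplicate_control: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_genes > self.G:
            raise ValueError("more signal genes than genes")
        if len(self.effect_sizes) != self.n_signal_genes:
            raise ValueError("effect_sizes length must equal n_signal_genes")
        if self.noise_sd is not None and self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 < self.explained_variance < 1):
            raise ValueError("explained_variance must be in (0, 1)")
        if self.tissue_shifts is None:
            self.tissue_shifts = tuple(
                [-1.5] + [0.0] * (self.n_tumor_types - 1)
            ) if self.n_tumor_types >= 1 else ()
        if len(self.tissue_shifts) != self.n_tumor_types:
            raise ValueError("tissue_shifts length must equal n_tumor_types")
        if self.subtype_count and len(self.subtype_shifts) != self.subtype_count:
            raise ValueError("subtype_shifts length must equal subtype_count")
        if min(self.G, self.n_cell_lines, self.n_tumor_types, self.samples_per_type) < 1:
            raise ValueError("all counts must be >= 1")


@dataclass
class SyntheticDataset:
    """Generated cohort plus the truth record of every planted quantity."""

    expression: ExpressionMatrix            # raw TPM-like, cell lines
    responses: DrugResponseTable
    external: ExpressionMatrix              # raw TPM-like, tumor/normal samples
    mutations: pd.DataFrame                 # sample_id, gene, mutated
    truth: dict = field(default_factory=dict)

    def pipeline_dataset(self) -> DrugDataset:
        """Run the package's own transform chain and return the aligned dataset."""
        z_cells = standardize(self.expression)
        z_ext = standardize(self.external)
        ds = build_drug_dataset(z_cells, self.responses, DRUG_ID)
        return attach_external(ds, z_ext)


def _gene_ids(G: int) -> list[str]:
    return [f"G{i:04d}" for i in range(G)]


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw a full synthetic cohort (cell lines, external tissues, mutations)."""
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.G)
    signal_idx = np.arange(cfg.n_signal_genes)  # fixed, recorded in truth
    effects = np.asarray(cfg.effect_sizes, dtype=float)

    # per-gene baseline on the log2 scale; within-gene spread 1
    mu = rng.normal(3.0, 1.0, size=cfg.G)

    cell_ids = [f"CL{i:03d}" for i in range(cfg.n_cell_lines)]
    L_cells = mu[:, None] + rng.normal(0.0, 1.0, size=(cfg.G, cfg.n_cell_lines))
    raw_cells = np.exp2(L_cells)
    cell_meta = pd.DataFrame(
        {"source_class": "cell_line", "tissue_type": "cell_line", "subtype": pd.NA},
        index=pd.Index(cell_ids, name="sample_id"),
    )
    expression = ExpressionMatrix(
        values=pd.DataFrame(raw_cells, index=genes, columns=cell_ids),
        transform_state="raw",
        meta=cell_meta,
    )

    # response built from the pipeline's own z-scores so the planted
    # relationship is exactly on the scale the model sees
    Z = standardize(expression).values.to_numpy()
    signal = effects @ Z[signal_idx, :]
    var_signal = float(np.var(signal, ddof=1))
    if cfg.noise_sd is not None:
        noise_sd = float(cfg.noise_sd)
    else:
        noise_sd = float(np.sqrt(var_signal * (1.0 - cfg.explained_variance) / cfg.explained_variance))
    y = signal + rng.normal(0.0, noise_sd, size=cfg.n_cell_lines)

    responses = DrugResponseTable(
        records=pd.DataFrame(
            {
                "drug_id": DRUG_ID,
                "drug_name": "synthetic-drug",
                "putative_target": "planted-signal",
                "cell_line_id": cell_ids,
                "ln_ic50": y,
                "release": "GDSC2",
            }
        )
    )

    # scale factor translating a desired z-score shift into a log2-space shift
    s_ref = float(log2p1_transform(expression).values.to_numpy().std(axis=0, ddof=1).mean())
    # a shift of delta is applied to every signal gene on the z scale, so the
    # implied shift of the linear response signal is delta * sum(|effects|)
    sum_abs_effects = float(np.abs(effects).sum())

    tissue_names = [f"TT{t}" for t in range(cfg.n_tumor_types)]
    n_normal = int(round(cfg.normal_fraction * cfg.samples_per_type))
    n_tumor = cfg.samples_per_type - n_normal

    cols, meta_rows = [], []
    L_ext_list = []
    subtype_cycle = [f"S{i}" for i in range(cfg.subtype_count)] if cfg.subtype_count else []
    tumor_ids_by_type: dict[str, list[str]] = {t: [] for t in tissue_names}
    idx = 0
    for t, tname in enumerate(tissue_names):
        for j in range(cfg.samples_per_type):
            sid = f"EX{idx:04d}"
            idx += 1
            is_tumor = j < n_tumor
            L = mu + rng.normal(0.0, 1.0, size=cfg.G)
            subtype = pd.NA
            if is_tumor:
                L[signal_idx] += cfg.tissue_shifts[t] * s_ref
                if cfg.subtype_count and t == 0:
                    s = len(tumor_ids_by_type[tname]) % cfg.subtype_count
                    subtype = subtype_cycle[s]
                    L[signal_idx] += cfg.subtype_shifts[s] * s_ref
                tumor_ids_by_type[tname].append(sid)
            cols.append(sid)
            meta_rows.append(
                {
                    "sample_id": sid,
                    "source_class": "tumor" if is_tumor else "normal",
                    "tissue_type": tname,
                    "subtype": subtype,
                }
            )
            L_ext_list.append(L)

    L_ext = np.column_stack(L_ext_list)
    raw_ext = np.exp2(L_ext)

    # mutation carriers among tumor samples, shifted along the signal axis
    mutation_gene_names = [f"MUT{i}" for i in range(cfg.mutation_genes)]
    all_tumor_ids = [m["sample_id"] for m in meta_rows if m["source_class"] == "tumor"]
    col_of = {sid: i for i, sid in enumerate(cols)}
    mut_rows = []
    for mg in mutation_gene_names:
        carrier = rng.random(len(all_tumor_ids)) < cfg.mutation_rate
        for sid, is_carrier in zip(all_tumor_ids, carrier):
            if is_carrier:
                raw_ext[signal_idx, col_of[sid]] = np.exp2(
                    np.log2(raw_ext[signal_idx, col_of[sid]]) + cfg.mutation_effect * s_ref
                )
                mut_rows.append({"sample_id": sid, "gene": mg, "mutated": True})
    mutations = pd.DataFrame(mut_rows, columns=["sample_id", "gene", "mutated"])

    dup_control_id = None
    if cfg.include_duplicate_control:
        dup_control_id = "EXDUP"
        raw_ext = np.column_stack([raw_ext, raw_cells[:, 0]])
        cols.append(dup_control_id)
        meta_rows.append(
            {
                "sample_id": dup_control_id,
                "source_class": "tumor",
                "tissue_type": tissue_names[-1],
                "subtype": pd.NA,
            }
        )

    ext_meta = pd.DataFrame(meta_rows).set_index("sample_id")
    external = ExpressionMatrix(
        values=pd.DataFrame(raw_ext, index=genes, columns=cols),
        transform_state="raw",
        meta=ext_meta,
    )

    truth = {
        "drug_id": DRUG_ID,
        "signal_genes": [genes[i] for i in signal_idx],
        "signal_gene_indices": signal_idx.tolist(),
        "effect_sizes": effects.tolist(),
        "noise_sd": noise_sd,
        "signal_variance": var_signal,
        "explained_variance": var_signal / (var_signal + noise_sd**2),
        "tissue_types": tissue_names,
        "tissue_shifts": list(cfg.tissue_shifts),
        "response_scale_tissue_shifts": [s * sum_abs_effects for s in cfg.tissue_shifts],
        "subtype_shifts": list(cfg.subtype_shifts),
        "sum_abs_effects": sum_abs_effects,
        "s_ref": s_ref,
        "mutation_genes": mutation_gene_names,
        "mutation_effect": cfg.mutation_effect,
        "duplicate_control": (
            {"external_id": dup_control_id, "cell_line_id": cell_ids[0]}
            if dup_control_id
            else None
        ),
        "null": False,
        "seed": cfg.seed,
    }
    return SyntheticDataset(
        expression=expression, responses=responses, external=external,
        mutations=mutations, truth=truth,
    )


def null_generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Same marginals, but ln(IC50) is permuted so it is independent of expression."""
    ds = generate(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6E756C6C]))
    perm = rng.permutation(len(ds.responses.records))
    rec = ds.responses.records.copy()
    rec["ln_ic50"] = rec["ln_ic50"].to_numpy()[perm]
    ds.responses = DrugResponseTable(records=rec)
    ds.truth["null"] = True
    return ds


def export(ds: SyntheticDataset, outdir) -> None:
    """Write the cohort as plain-text TSV/JSON (byte-deterministic given the seed)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(ds.expression, outdir / "expression.tsv")
    write_expression(ds.external, outdir / "external.tsv")
    ds.responses.records.to_csv(outdir / "responses.tsv", sep="\t", index=False, float_format="%.12g")
    meta = pd.concat([ds.expression.meta, ds.external.meta])
    meta.to_csv(outdir / "metadata.tsv", sep="\t")
    ds.mutations.to_csv(outdir / "mutations.tsv", sep="\t", index=False)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(ds.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
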