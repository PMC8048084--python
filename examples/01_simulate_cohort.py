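"""Generate a synthetic drug-sensitivity cohort and inspect its planted truth.

The generator emulates the three data roles the pipeline consumes: a
cell-line cohort whose ln(IC50) is a noisy function of three planted
signal genes, tissue-labeled tumor/normal samples sharing that signal
(tissue 0 is shifted -1.5 log units = planted sensitive), and mutation
indicators correlated with the signal.
"""

from gxrx import SyntheticConfig, export, generate

cfg = SyntheticConfig(G=200, n_cell_lines=120, samples_per_type=20, seed=42)
cohort = generate(cfg)

print(f"cell lines: {cohort.expression.n_samples}, genes: {cohort.expression.n_genes}")
print(f"external samples: {cohort.external.n_samples} "
      f"({(cohort.external.meta['source_class'] == 'tumor').sum()} tumor, "
      f"{(cohort.external.meta['source_class'] == 'normal').sum()} normal)")
print(f"planted signal genes: {cohort.truth['signal_genes']}")
print(f"effect sizes: {cohort.truth['effect_sizes']}")
print(f"noise sd: {cohort.truth['noise_sd']:.3f} "
      f"-> signal explains {cohort.truth['explained_variance']:.0%} of response variance")
print(f"tissue shifts (log units): {dict(zip(cohort.truth['tissue_types'], cohort.truth['tissue_shifts']))}")

export(cohort, "scratch/example_cohort")
print("cohort exported to scratch/example_cohort/ "
      "(expression.tsv, responses.tsv, external.tsv, metadata.tsv, mutations.tsv, truth.json)")
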