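"""Cross-model differential expression: shared signal across many lines.

Eight lines each get a per-line log2 fold change table (drug vs vehicle);
a geneset down-shifted in every line's treated survivors is detected by the
mean difference z aggregation even though each single line is noisy.
"""

import pandas as pd

from mosaicpool import diffexp, simdata

set_genes = [f"GENE{i + 1:05d}" for i in range(100, 140)]
lines = [f"L{i + 1}" for i in range(8)]
log2fc = {}
for li, line in enumerate(lines):
    cfg = simdata.SimConfig(
        lines=[simdata.LineSpec(line)],
        conditions=[
            simdata.ConditionSpec("DMSO", 0.0, 1),
            simdata.ConditionSpec("drug", 1.0, 1),
        ],
        n_genes=800,
        pool_size=250,
        programs=[simdata.ProgramSpec("shared", set_genes, -0.06)],
        seed=10 + li,
    )
    exp, _ = simdata.simulate_pool(cfg)
    de = diffexp.per_line_log2fc(exp, line, "drug", "DMSO", compute_pvalues=False)
    log2fc[line] = de.set_index("gene")["log2fc"]
fc = pd.DataFrame(log2fc)

agg = diffexp.cross_model_aggregate(fc, n_boot=10_000, seed=1)
res = diffexp.geneset_shift_test(agg.mean_z, set(set_genes))
print(f"planted geneset mean Δz: {agg.mean_z.loc[set_genes].mean():+.2f}")
print(f"geneset shift test: Mann–Whitney p = {res['mw_p']:.2e}, direction {res['direction']:+.0f}")

summary, _ = diffexp.downsample_models(
    fc, ks=[2, 4, 6, 8], n_draws=10, genesets={"shared": set(set_genes)},
    n_random_sets=5, n_boot=1000, seed=2,
)
tgt = summary[summary["set"] == "shared"].sort_values("k")
print("\nsignificance vs number of lines used (model downsampling):")
for _, row in tgt.iterrows():
    print(f"  k = {row['k']}: median geneset p = {row['median_p']:.2e}")
print("a −0.06 log2 shift is weak in any one line but compounds across models:")
print("the geneset p drops by orders of magnitude as more lines enter the analysis.")
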