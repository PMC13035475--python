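"""Demultiplex a pooled experiment: hashes, genotypes, doublets.

Simulates a 4-line pool with 5% doublets, generates hashtag and SNP allele
evidence, and recovers each cell's sample and line of origin.
"""

import numpy as np

from mosaicpool import demux, simdata

lines = [simdata.LineSpec(f"L{i + 1}") for i in range(4)]
cfg = simdata.SimConfig(
    lines=lines,
    conditions=[
        simdata.ConditionSpec("DMSO", 0.0, 1),
        simdata.ConditionSpec("drug", 1.0, 1),
    ],
    n_genes=100,
    pool_size=1000,
    doublet_rate=0.05,
    seed=1,
)
exp, truth = simdata.simulate_pool(cfg)
reference = simdata.random_genotype_reference([l.line_id for l in lines], 150, seed=2)
alleles = simdata.simulate_allele_counts(exp, truth, reference, depth=50, seed=3)
hashes = simdata.simulate_hash_counts(exp, truth, seed=4)

hash_calls = demux.assign_hash(hashes)
calls = demux.assign_genotype(alleles, reference, hash_calls=hash_calls)

singlets = calls["call_type"] == "singlet"
acc = (
    calls.loc[singlets, "genotype_call"].to_numpy()
    == truth.cell_line[singlets.to_numpy()]
).mean()
recall = (
    (calls["call_type"] == "doublet").to_numpy() & truth.is_doublet
).sum() / truth.is_doublet.sum()
hash_acc = (hash_calls.to_numpy()[~truth.is_doublet] == truth.cell_hash[~truth.is_doublet]).mean()

print(f"cells: {exp.n_cells}, true doublets: {truth.is_doublet.sum()}")
print(f"singlet line accuracy:  {acc:.3f}")
print(f"doublet recall:         {recall:.3f}")
print(f"hash call accuracy:     {hash_acc:.3f}")
print("accuracy ≈ 1 means allele evidence at ~50 reads/cell pins down the line;")
print("doublets are caught because their reads fit a 50:50 two-line mixture better.")
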