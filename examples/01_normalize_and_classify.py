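"""Normalize a count matrix and classify temporal responses.

Generates a small synthetic time-course panel, TMM-normalizes it,
computes per-genotype log2 fold changes against the 0-h control, and
counts up/down/constant genes per genotype.
"""

from transgressnet import (
    GeneratorConfig,
    classify_all,
    fold_change_tensor,
    generate,
    normalize,
    tmm_factors,
)
from transgressnet.classify import summarize_calls

config = GeneratorConfig(seed=1, n_per_class=50, n_background=50)
dataset = generate(config)
print(f"counts: {len(dataset.mrna.gene_ids)} genes x {len(dataset.mrna.samples)} samples")

factors = tmm_factors(dataset.mrna)
print("TMM factors (first genotype's controls):")
print(factors.head(2).to_string())

norm = normalize(dataset.mrna, factors)
tensor = fold_change_tensor(norm)
calls = classify_all(tensor, threshold=2.0)
print("\nresponse counts per genotype (strict |log2FC| > 2 at any time):")
print(summarize_calls(calls).pivot(index="genotype", columns="category",
                                   values="n_genes").fillna(0).astype(int).to_string())
# 'constant' genes never leave the +/-2 log2 band; 'up_only'/'down_only'
# cross it in one direction at one or more stress times; 'mixed' cross both.
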