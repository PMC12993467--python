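"""Rarefaction, Shannon diversity and composition summaries on simulated counts.

Counts are rarefied to the shallowest sample, alpha diversity computed per
sample, and the community summarised as per-group mean proportions of the
top taxa - the standard descriptive sweep before any trend fitting.
"""

import numpy as np

from rumengrad import (
    alpha_diversity,
    default_config,
    gen_abundance,
    gen_diets,
    rarefy,
    to_relative,
    top_n_summary,
)

cfg = default_config(seed=17)
counts = gen_abundance(gen_diets(cfg), cfg)
even = rarefy(counts, depth="min", seed=17)

div = alpha_diversity(even)
shannon_by_group = {}
for d in div:
    g = even.metadata.loc[d.sample_id, "group_label"]
    shannon_by_group.setdefault(g, []).append(d.shannon)
print("Shannon index (mean over 3 animals) per diet group:")
for g, vals in shannon_by_group.items():
    print(f"  {g:>5s}: {np.mean(vals):.3f}")

summary = top_n_summary(to_relative(even), n=3)
print("\ntop-3 taxa, per-group mean proportions (rest pooled as Other):")
print(summary.round(4).to_string())
print(
    "\nIn this 6-taxon synthetic community the Shannon index rises toward "
    "high concentrate as the\ntwo dominant phyla approach parity near "
    "their alternation point - evenness, not richness,\ndrives H here. "
    "Each group column sums to 1 by compositional closure."
)
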