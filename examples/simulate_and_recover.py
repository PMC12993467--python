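"""Generate a synthetic feeding trial and recover its generating parameters.

The generator emulates the study design: 5 diets (concentrate fractions
0.20-0.80) x 3 animals, fermentation responses following the reference
gradient equations plus noise, and Dirichlet-multinomial taxon counts
whose expected proportions are log-linear in the gradient. The analysis
pipeline then re-estimates what the generator put in.
"""

from rumengrad import (
    alternation_report,
    default_config,
    fit_linear,
    fit_taxon_trends,
    gen_abundance,
    gen_diets,
    gen_fermentation,
    to_relative,
)
from rumengrad.reference import NH3N_CP_LINE
from rumengrad.simulate import analytic_crossing

cfg = default_config(seed=42)
diets = gen_diets(cfg)
ferm = gen_fermentation(diets, cfg)
counts = gen_abundance(diets, cfg)

cp = {d.group_label: d.profile.cp for d in diets}
m = fit_linear([cp[f.group_label] for f in ferm], [f.nh3n for f in ferm])
print(
    f"NH3-N vs CP: fitted slope {m.params['slope']:.4f} "
    f"(truth {NH3N_CP_LINE[0]}), intercept {m.params['intercept']:.4f} "
    f"(truth {NH3N_CP_LINE[1]}), R^2 {m.r2:.3f}"
)

trends = fit_taxon_trends(to_relative(counts), family="exponential")
report = alternation_report(
    trends, (0.20, 0.80), focus_pairs=[("p_Bacteroidetes", "p_Firmicutes")]
)
est = report["crossovers"][0].x_star
truth = analytic_crossing(cfg, "p_Bacteroidetes", "p_Firmicutes")
print(
    f"core-phylum crossover: estimated {est:.4f}, analytic truth {truth:.4f}, "
    f"error {abs(est - truth):.4f}"
)
print(
    "\nWith 15 samples at sequencing depth "
    f"{cfg.depth}, the pipeline localises the alternation point to within "
    "a few percent of concentrate inclusion."
)
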