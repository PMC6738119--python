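"""Generate a synthetic missed-cancer cohort and rank the model grid.

The generator draws screening volumes, intervals and true power-law
(alpha = 1/2) growth rates, back-computes mammogram dimensions, and
attaches a step-hazard survival outcome. rank_models then evaluates all
3 shapes x 4 laws x {continuous, dichotomised} prognostically and ranks
them by Cox AIC on 10-year breast cancer-specific survival.
"""

import warnings

from invigor import GeneratorConfig, calibration_report, generate_cohort, rank_models

warnings.filterwarnings("ignore")

cohort, truth = generate_cohort(GeneratorConfig(n=400, seed=1))
print(calibration_report(cohort).to_string(index=False))

grid = rank_models(cohort)
print("\ntop of the AIC-ranked model grid:")
cols = ["shape", "law", "form", "aic", "cutpoint", "hazard_ratio", "p_value"]
print(grid.table.head(6)[cols].to_string(index=False))
print(
    f"\nwinner: {grid.best['shape']} x {grid.best['law']} ({grid.best['form']});"
    f" the generating combination was sphere x power_0.5 with cutpoint 0.045."
    "\nLower AIC = better prognostic fit; the dichotomised winner's cutpoint"
    " estimates the generative fast/slow threshold."
)
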