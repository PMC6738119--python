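"""Log-rank-optimised cutpoint, stratified survival and adjusted Cox fit.

The fast/slow threshold is the candidate midpoint maximising the
two-group log-rank chi-square; patients above it form the fast-growing
group, whose survival is then compared with and without adjustment for
grade, age and ER status.
"""

import warnings

from invigor import (
    GeneratorConfig,
    cohort_rates,
    compute_sm_invigor,
    generate_cohort,
    multivariate_adjustment,
    optimise_cutpoint,
    power_law,
)
from invigor.survival import administrative_censor

warnings.filterwarnings("ignore")

cohort, _ = generate_cohort(GeneratorConfig(n=400, seed=3))
rates = cohort_rates(cohort, "sphere", power_law(0.5))
ok = rates["valid"].to_numpy()
t, e = administrative_censor(cohort.df.loc[ok, "bcss_months"], cohort.df.loc[ok, "event"], 120.0)

cut = optimise_cutpoint(rates.loc[ok, "rate"], t, e, min_group_frac=0.10)
print(
    f"optimal cutpoint {cut.threshold:.4f} mm^3/day "
    f"(chi2 = {cut.chi_square:.1f}, raw p = {cut.p_value:.2e}; "
    f"{cut.n_slow} slow vs {cut.n_fast} fast)"
)

out = compute_sm_invigor(cohort, "sphere", power_law(0.5), cut.threshold, horizon_months=120.0)
surv = out["report"]["survival"]
print(
    f"10-year BCSS: slow {100 * surv['km_slow']['survival_at_120m']:.1f}% vs "
    f"fast {100 * surv['km_fast']['survival_at_120m']:.1f}% "
    f"(log-rank p = {surv['logrank']['p_value']:.2e})"
)

fit = multivariate_adjustment(cohort, out["rates"]["label"].to_numpy())
print("\nCox fit adjusted for grade, age and ER status:")
print(fit.summary().to_string())
print(
    "\nThe 'fast' hazard ratio is the excess breast-cancer-specific mortality"
    " of fast-growing tumours after adjustment; the generator's true value is ~3.9."
)
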