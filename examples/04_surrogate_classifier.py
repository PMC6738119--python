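"""Train the KNN surrogate (Surr-INVIGOR) and validate it on a fresh cohort.

Candidate clinicopathological features are screened by Welch t-test
between fast- and slow-growing tumours, forward-selected in screening
rank order under repeated stratified cross-validation, and the winning
KNN is frozen. Applying it to an independent cohort stratifies survival
without needing a second mammogram.
"""

import warnings

from invigor import (
    GeneratorConfig,
    apply_surrogate,
    build_feature_matrix,
    compute_sm_invigor,
    generate_cohort,
    power_law,
    screen_features,
    sequential_select,
)

warnings.filterwarnings("ignore")

# discovery cohort: label by the growth index, then learn a surrogate
discovery, _ = generate_cohort(GeneratorConfig(n=92, seed=7))
labels = compute_sm_invigor(discovery, "sphere", power_law(0.5), 0.045)["rates"]["label"]
X, y, _ = build_feature_matrix(discovery, labels=labels.to_numpy())

screening = screen_features(X, y, threshold_p=0.2)
print("feature screening (Welch t-test, admitted if p < 0.2):")
print(screening.table.to_string(index=False))

artifact, trace = sequential_select(X, y, seed=17)
print(
    f"\nfrozen surrogate: features={artifact.selected_features}, k={artifact.k}, "
    f"CV accuracy={artifact.cv_accuracy:.3f} "
    f"(concordance with the growth-index label under 5-fold CV)"
)

# independent validation cohort
validation, _ = generate_cohort(GeneratorConfig(n=1241, seed=11))
result = apply_surrogate(artifact, validation)
surv = result["report"]
print(
    f"\nvalidation (n=1241): {surv['km_fast']['n']} predicted fast vs "
    f"{surv['km_slow']['n']} slow; 10-year BCSS "
    f"{100 * surv['km_fast']['survival_at_120m']:.1f}% vs "
    f"{100 * surv['km_slow']['survival_at_120m']:.1f}% "
    f"(log-rank p = {surv['logrank']['p_value']:.2e})"
)
print(
    "The surrogate separates survival in a cohort it never saw, using only"
    " routine features measured at diagnosis."
)
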