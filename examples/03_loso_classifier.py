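"""Leave-one-subject-out classification of the three group pairs.

Each subject's probability of belonging to the more-affected group comes
from a ridge-stabilized logistic regression fitted on every other subject
(features z-scored inside the fold).  AUC is the probability that a randomly
chosen diseased subject outranks a healthy one; sensitivity/specificity are
read at the 0.5 operating point.  Feature importance = |coefficient| of the
all-data fit on z-scored features.
"""

from speechling import CohortSpec, classify_pair, extract_feature_table, generate_cohort

cohort = generate_cohort(CohortSpec(n_per_group=39, seed=21))
features, _ = extract_feature_table(cohort.automated, cohort.tracks)

for pair in (("PD", "MSA"), ("HC", "MSA"), ("HC", "PD")):
    res = classify_pair(features, cohort.records, pair=pair)
    print(f"{pair[0]} vs {pair[1]} (positive = {res.positive}): "
          f"AUC {res.auc:.3f}, sens {res.sensitivity:.2f}, spec {res.specificity:.2f}")
    top = ", ".join(f"{k}={v:.2f}" for k, v in res.importance.head(3).items())
    print(f"  top features: {top}")
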