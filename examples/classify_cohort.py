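"""Evaluate case/control separation with the repeated undersampled protocol.

Generates a 118-subject feature-level cohort (90 cases, 28 controls) with
the planted group structure — cases lower-pitched, louder and more variable
— and compares the L1 linear SVM against the random-assignment (chance)
classifier under 100 iterations of 28-vs-28 undersampled five-fold CV.
"""

from hmvoice import CohortSpec, ProtocolConfig, balanced_repeated_cv, synth_cohort

table, labels = synth_cohort(CohortSpec(seed=1))
print(f"cohort: {int(labels.sum())} cases vs {int((1 - labels).sum())} controls, "
      f"{table.shape[1]} features")

config = ProtocolConfig(n_iterations=100, n_folds=5, seed=0)
for model in ("svm", "chance"):
    s = balanced_repeated_cv(table.to_numpy(), labels, config, model=model)
    lo, hi = s.auc_ci_95
    print(
        f"{model:>6}: AUC {s.auc_pct:5.2f}% ({lo:.2f}%, {hi:.2f}%)  "
        f"sens {s.sensitivity_pct:5.2f}%  spec {s.specificity_pct:5.2f}%  "
        f"acc {s.accuracy_pct:5.2f}%"
    )
# The SVM separates the groups well above the chance floor (~50% AUC); the
# CI is over the 100 undersampling iterations, so it reflects the sampling
# variability of the balanced subsets, not parametric assumptions.
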