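"""Simulate the default synthetic cohort and cross-validate the classifier.

Conditions: 60 Active vs 600 Inactive samples, 40 true abnormal-junction
features with a threefold Active-class enrichment of the abnormal fraction,
20 decoy junctions with no class effect, two cancer-type cohorts.
"""

import sjactiv as sj

cohort = sj.simulate_cohort(sj.SimConfig(seed=17))
print("Label counts:", cohort.labels["label"].value_counts().to_dict())

cv = sj.cross_validate(
    cohort.junctions, cohort.counts, cohort.labels, cohort.cohort_map, seed=17
)
c = cv.confusion
print(f"Confusion at threshold 10: TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}")
print("Metrics:", sj.compute_metrics(c))

points, auc = sj.pr_curve(cv.scores["nrf2_score"], cv.scores["label"])
print(f"PR-AUC: {auc:.4f}")
print(
    "\nEach fold reselects features on its training half (no leakage) and "
    "fits per-feature beta-binomial models; held-out samples are scored by "
    "the clipped log-likelihood ratio. With a threefold effect the classes "
    "separate completely."
)
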