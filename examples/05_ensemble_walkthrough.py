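"""Follow one test object through the staged ensemble.

Builds a 12-class ensemble whose schedule (12 -> 6 -> 3 with a minimum
stage size of 3) has three stages and therefore six subclassifiers, then
prints every subclassifier's vote for a single test object and the
max-wins combination.
"""

from lcnc import (BinarySpec, equal_quotas, es_schedule, fit_system,
                  generate_dataset, small_spec, split_dataset)
from lcnc.multiclass import predict_sample

print("schedule for the 37-class survey:",
      es_schedule(37, min_classes=10).stage_counts,
      "->", es_schedule(37).n_subclassifiers, "subclassifiers\n")

table = generate_dataset(small_spec(k=12, n_per_class=9, n_features=8,
                                    within_class_sd_fraction=0.5, seed=23))
train, test = split_dataset(table, equal_quotas(table, 6))
spec = BinarySpec(classifier="plsda", max_lv=3, n_splits=12, seed=1)
system = fit_system(train, "es", spec, min_classes=3)
print("demo schedule:", system.inner.schedule.stage_counts)

x, true = test.values[0], test.labels[0]
pred = predict_sample(system, x)
print(f"\ntest object from class {true}:")
for cid, vote in pred.votes.items():
    kind = "OVO" if int(cid[1:]) % 2 else "OVR(top-3)"
    print(f"  {cid} ({kind:>10}) votes for class {vote}")
print(f"max-wins decision: class {pred.predicted_class} "
      f"(tie break used: {pred.tie_broken})")
# Odd subclassifiers are OVO over progressively fewer candidate classes
# (ranked by the first OVO's votes); even ones are OVR over the top 3.
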