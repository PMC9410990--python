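"""Compare the six strategy x classifier systems on one small survey.

Trains OVR, OVO and the staged ensemble (ES), each with PLSDA and
LS-SVM cores, on a DUPLEX-split synthetic survey and prints test-set
accuracies.  With moderate class overlap the ranking typically follows
the large-class-number argument: pairwise strategies beat one-vs-rest,
and the staged ensemble is at least as good as plain OVO.
"""

from lcnc import (BinarySpec, accuracy, confusion_matrix, equal_quotas,
                  fit_system, generate_dataset, predict_table, small_spec,
                  split_dataset)

table = generate_dataset(small_spec(k=8, n_per_class=12, n_features=8,
                                    within_class_sd_fraction=0.45, seed=19))
train, test = split_dataset(table, equal_quotas(table, 8))
print(f"{len(train.classes())} classes, train {train.n_samples}, "
      f"test {test.n_samples}\n")

for classifier in ("plsda", "lssvm"):
    for strategy in ("ovr", "ovo", "es"):
        spec = BinarySpec(classifier=classifier, max_lv=4, n_splits=20,
                          folds=5, seed=7)
        system = fit_system(train, strategy, spec, min_classes=4)
        cm = confusion_matrix(test.labels, predict_table(system, test),
                              classes=system.classes)
        print(f"{strategy.upper():>3}-{classifier.upper():<6} "
              f"test accuracy {accuracy(cm):.3f}")
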