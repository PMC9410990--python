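"""Outlier diagnosis and representative train/test splitting.

Scores every sample within its class by Stahel-Donoho outlyingness
(500 random projections, median/MAD standardization), removes the single
planted gross outlier detected in each of classes 20, 27 and 37, and
splits every class 20/10 (20/9 where an outlier was removed) with the
deterministic DUPLEX algorithm.
"""

import numpy as np

from lcnc import (default_spec, detect_outliers_by_class, drop_nondetected,
                  equal_quotas, generate_dataset, split_dataset)

table = drop_nondetected(generate_dataset(default_spec(seed=1)))
report = detect_outliers_by_class(table, n_projections=500, seed=1)

removed = []
for c in (20, 27, 37):
    idx = table.rows_for_class(c)
    worst = idx[np.argmax(report.scores[idx])]
    print(f"class {c}: worst sample {table.sample_ids[worst]} "
          f"score {report.scores[worst]:.1f} (cutoff 3)")
    removed.append(worst)

clean = table.take_rows(np.setdiff1d(np.arange(table.n_samples), removed))
train, test = split_dataset(clean, equal_quotas(clean, 20))
print(f"\nafter removal: {clean.n_samples} objects")
print(f"DUPLEX split: train {train.n_samples}, test {test.n_samples}")
# 1110 objects minus 3 outliers -> 740 training + 367 test objects
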