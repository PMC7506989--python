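"""Compute staging metrics from a published confusion matrix.

The package ships four reference confusion matrices from a published
single-channel EEG staging evaluation.  This example recomputes overall
accuracy, Cohen's kappa and per-class sensitivity from the raw counts of
the five-class matrix scored on ISRUC subgroup-3 recordings.
"""

import imbef
from imbef.datasets import ISRUC3_AASM5

cm = ISRUC3_AASM5
acc = imbef.accuracy_from_confusion(cm)
kappa = imbef.kappa_from_confusion(cm)
sens = imbef.sensitivity_per_class(cm)

print(f"epochs scored     : {cm.total}")
print(f"overall accuracy  : {acc * 100:.2f}%   (diagonal / total)")
print(f"Cohen's kappa     : {kappa:.4f}  (chance-corrected agreement)")
for name, s in zip(cm.class_names, sens):
    print(f"sensitivity {name:4s}  : {s * 100:.2f}%")

# The N1 row illustrates why light sleep is the hard class: most N1
# misclassifications land in REM and N2, whose EEG rhythms overlap N1's.
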