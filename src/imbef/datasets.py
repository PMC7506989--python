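"""Reference confusion matrices from published sleep-staging evaluations.

These four matrices were reported, in full, by a published single-channel
EEG staging study evaluated on three public polysomnography collections
(Sleep-EDF, DREAMS Subjects and the third ISRUC subgroup).  They serve as an
exact oracle for the confusion-matrix metrics: accuracy, Cohen's kappa and
per-class sensitivities recomputed from the raw counts must agree with the
values printed alongside them.
"""

from __future__ import annotations

import numpy as np

from .classify import ConfusionMatrix

_RK6 = ("Awa", "REM", "S1", "S2", "S3", "S4")
_AASM5 = ("Awa", "REM", "N1", "N2", "N3")

#: six-class scoring, DREAMS Subjects recordings (R&K manual)
DRMS_RK6 = ConfusionMatrix(np.array([
    [5247, 96, 85, 155, 3, 15],
    [203, 3697, 86, 566, 1, 2],
    [418, 784, 257, 328, 1, 0],
    [262, 731, 62, 11852, 248, 119],
    [20, 0, 0, 1022, 543, 527],
    [174, 0, 0, 231, 271, 2395],
]), _RK6)

#: five-class scoring, DREAMS Subjects recordings (AASM manual)
DRMS_AASM5 = ConfusionMatrix(np.array([
    [3306, 53, 68, 111, 21],
    [131, 2452, 93, 330, 13],
    [341, 480, 260, 389, 10],
    [229, 499, 50, 7056, 417],
    [77, 1, 0, 761, 3117],
]), _AASM5)

#: six-class scoring, Sleep-EDF recordings (R&K manual)
SEDF_RK6 = ConfusionMatrix(np.array([
    [73165, 483, 46, 141, 0, 0],
    [876, 4819, 61, 988, 0, 0],
    [578, 1174, 583, 682, 0, 0],
    [375, 863, 76, 15631, 254, 50],
    [71, 0, 0, 1003, 1055, 159],
    [23, 0, 0, 171, 256, 1060],
]), _RK6)

#: five-class scoring, ISRUC subgroup-3 recordings (AASM manual)
ISRUC3_AASM5 = ConfusionMatrix(np.array([
    [1537, 13, 84, 53, 15],
    [36, 1032, 89, 68, 13],
    [91, 135, 648, 242, 7],
    [68, 85, 128, 2312, 257],
    [15, 1, 2, 229, 1729],
]), _AASM5)


def reference_confusion_matrices() -> dict:
    """All four published matrices keyed by dataset/scheme."""
    return {
        "drms_rk6": DRMS_RK6,
        "drms_aasm5": DRMS_AASM5,
        "sedf_rk6": SEDF_RK6,
        "isruc3_aasm5": ISRUC3_AASM5,
    }
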