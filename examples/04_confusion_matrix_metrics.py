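"""Confusion-matrix metrics: ACC, PRE, REC, SPF, F1, one-vs-rest per class.

The binary worked example here (TP=50, TN=40, FP=5, FN=5) gives
ACC=0.9000, PRE=REC=F1=0.9091, SPF=0.8889.
"""

import numpy as np

from dmflsim import compute_metrics, confusion_matrix

true_labels = np.repeat([0, 0, 1, 1], [50, 5, 5, 40])
predicted = np.repeat([0, 1, 0, 1], [50, 5, 5, 40])

cm = confusion_matrix(true_labels, predicted, 2, class_names=("disease", "healthy"))
print("confusion matrix (rows = true, cols = predicted):")
print(cm.counts)

report = compute_metrics(cm)
print(f"overall accuracy (trace/total): {report.accuracy:.4f}")
for cls, m in report.per_class.items():
    print(
        f"  {cls:8s} ACC={m['accuracy']:.4f} PRE={m['precision']:.4f} "
        f"REC={m['recall']:.4f} SPF={m['specificity']:.4f} F1={m['f1']:.4f}"
    )
print(f"macro: PRE={report.precision:.4f} REC={report.recall:.4f} F1={report.f1:.4f}")
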