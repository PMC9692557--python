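"""Subject-grouped cross-validated gesture recognition on a small cohort.

Generates a 6-subject cohort, extracts ASF-14NP features from the
non-paretic side, and evaluates an SVM over one 4-gesture model using
repeated subject-grouped hold-out (held-out subjects never contribute
training segments).
"""

import numpy as np

from asfemg.classify import CVSpec, GestureModel, cross_validate
from asfemg.evaluate import accuracy, macro_f1
from asfemg.pipeline import cohort_features
from asfemg.synth import generate_cohort

cohort = generate_cohort(n_subjects=6, seed=5, reps=8)
X, y, groups, _ = cohort_features(cohort, "non-paretic", "ASF14NP")
print(f"features: {X.shape[0]} segments x {X.shape[1]} values from {len(set(groups))} subjects")

model = GestureModel(labels=("rest", "fist", "wrist_extension", "wrist_flexion"))
cv = CVSpec(folds=2, iterations=5, test_subjects=1, seed=6)
mats = cross_validate(X, y, groups, model, "svm", cv)
accs = [accuracy(m) for m in mats]
f1s = [macro_f1(m) for m in mats]
print(f"model {model.labels}")
print(f"mean accuracy {np.mean(accs):.3f} +/- {np.std(accs):.3f} over {len(mats)} partitions")
print(f"mean macro-F1 {np.mean(f1s):.3f}")
print("accuracy > 0.70 clears the usability bar for myoelectric interfaces")
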