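"""Principal-component sweep: accuracy/F1 as a function of retained PCs.

Sweeps a reduced grid of component counts (the full protocol sweeps
1-50), refitting the standardizer and PCA inside each training fold, and
reports the best count by mean macro-F1.
"""

from asfemg.classify import CVSpec, GestureModel
from asfemg.pipeline import cohort_features
from asfemg.reduction import best_k, sweep_components
from asfemg.synth import generate_cohort

cohort = generate_cohort(n_subjects=5, seed=9, reps=6)
X, y, groups, _ = cohort_features(cohort, "paretic", "ASF24P")

model = GestureModel(labels=("rest", "pinch", "wrist_extension", "wrist_flexion"))
cv = CVSpec(folds=2, iterations=2, test_subjects=1, seed=10)
sweep = sweep_components(X, y, groups, model, "svm", cv, ks=[1, 2, 4, 8, 16, 32])
print(sweep.to_string(index=False))
print(f"best component count by mean F1: {best_k(sweep)}")
print("(ties resolve to the smallest k: cheaper vectors are preferred)")
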