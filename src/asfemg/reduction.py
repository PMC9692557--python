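"""PCA dimensional reduction and the principal-component sweep.

Feature matrices are standardized (zero mean, unit variance, statistics
from training data only) before projection. The sweep re-runs the full
grouped cross-validation at each component count k, refitting the
standardizer and the PCA inside every training fold, and selects the
best k by mean macro-F1 (smallest k on ties).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler


@dataclass
class PCAProjection:
    scaler: StandardScaler
    pca: PCA

    @property
    def n_components(self) -> int:
        return self.pca.n_components_


def _fix_signs(pca: PCA) -> PCA:
    # make each component's largest-magnitude loading positive
    comp = pca.components_
    flip = np.sign(comp[np.arange(comp.shape[0]), np.abs(comp).argmax(axis=1)])
    flip[flip == 0] = 1.0
    pca.components_ = comp * flip[:, None]
    return pca


def fit_pca(train_matrix: np.ndarray, n_components: int | None = None) -> PCAProjection:
    """Standardize and fit PCA on the training matrix only.

    Deterministic up to component sign, which is fixed by making each
    component's largest-magnitude loading positive.
    """
    X = np.asarray(train_matrix, float)
    scaler = StandardScaler().fit(X)
    k = n_components or min(X.shape)
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds rank bound {min(X.shape)}")
    pca = PCA(n_components=k, svd_solver="full").fit(scaler.transform(X))
    return PCAProjection(scaler=scaler, pca=_fix_signs(pca))


def apply_pca(proj: PCAProjection, matrix: np.ndarray, k: int | None = None) -> np.ndarray:
    """Project onto the top-k components of a fitted projection."""
    k = k or proj.n_components
    if k > proj.n_components:
        raise ValueError(f"k={k} exceeds fitted components {proj.n_components}")
    Z = proj.pca.transform(proj.scaler.transform(np.asarray(matrix, float)))
    return Z[:, :k]


def sweep_components(
    features: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray,
    model,
    classifier_spec,
    cv,
    ks,
) -> pd.DataFrame:
    """Mean accuracy / macro-F1 per component count k.

    Returns a DataFrame with columns k, mean_acc, mean_f1; PCA and
    standardization are refit inside each training fold by the CV engine.
    """
    from .classify import cross_validate
    from .evaluate import accuracy, macro_f1

    rows = []
    for k in sorted(int(k) for k in ks):
        mats = cross_validate(
            features, labels, groups, model, classifier_spec, cv, n_components=k
        )
        accs = [accuracy(m) for m in mats]
        f1s = [macro_f1(m) for m in mats]
        rows.append({"k": k, "mean_acc": float(np.mean(accs)), "mean_f1": float(np.mean(f1s))})
    return pd.DataFrame(rows)


def best_k(sweep: pd.DataFrame) -> int:
    """Component count maximising mean F1; smallest k wins ties."""
    s = sweep.sort_values("k", kind="stable")
    return int(s.loc[s["mean_f1"].idxmax(), "k"])
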