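"""Class-separation diagnostics: ED, SD and the RES index.

For two clouds of feature vectors, ED is the root-mean-square difference
between the class centroids, SD the pooled within-class dispersion
(per-dimension pooled variances averaged in quadrature), and RES their
ratio. RES grows as centroids move apart and shrinks as within-class
scatter grows; it is invariant to a common rotation of both classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class SeparationIndex:
    ed: float
    sd: float
    res: float


def res_index(class_a: np.ndarray, class_b: np.ndarray) -> SeparationIndex:
    """Euclidean-distance-to-SD separation ratio between two classes.

    Both arguments are (n_samples, n_features) with at least two samples
    each and equal feature dimension.
    """
    a = np.atleast_2d(np.asarray(class_a, float))
    b = np.atleast_2d(np.asarray(class_b, float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each class needs at least 2 vectors")
    if a.shape[1] != b.shape[1]:
        raise ValueError("feature dimensions differ")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    ed = float(np.sqrt(np.mean((ca - cb) ** 2)))
    na, nb = a.shape[0], b.shape[0]
    pooled_var = ((na - 1) * a.var(axis=0, ddof=1) + (nb - 1) * b.var(axis=0, ddof=1)) / (
        na + nb - 2
    )
    sd = float(np.sqrt(np.mean(pooled_var)))
    if sd == 0:
        raise ValueError("zero pooled standard deviation; RES undefined")
    return SeparationIndex(ed=ed, sd=sd, res=ed / sd)


def pairwise_res(features: np.ndarray, labels: np.ndarray):
    """RES for every unordered label pair, as a list of records."""
    labels = np.asarray(labels)
    uniq = sorted(set(labels.tolist()))
    out = []
    for i, la in enumerate(uniq):
        for lb in uniq[i + 1 :]:
            idx = res_index(features[labels == la], features[labels == lb])
            out.append(
                {"class_a": la, "class_b": lb, "ED": idx.ed, "SD": idx.sd, "RES": idx.res}
            )
    return out
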