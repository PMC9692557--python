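"""End-to-end orchestration: synthesize -> preprocess -> segment -> extract
-> classify -> summarize.

The stages mirror an offline analysis session: each limb recording is
calibrated (when starting from ADC counts), band-pass filtered and
Hampel-cleaned, segmented via envelope peak detection inside the
per-gesture blocks (the automated counterpart of manually selecting the
active region for each gesture), z-score normalized, and cut into 90 ms
labelled segments from which one of the three feature sets is extracted.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, evaluate, preprocess, segment, synth
from .calibration import Recording
from .features import sets


@dataclass
class RunConfig:
    n_subjects: int = 19
    reps: int = 10
    master_seed: int = 1
    feature_set_nonparetic: str = "ASF14NP"
    feature_set_paretic: str = "ASF24P"
    classifier: str = "svm"
    gl: int = 4
    cv_folds: int = 10
    cv_iterations: int = 10
    test_subjects: int = 3
    rest_segments_per_recording: int = 8
    out_dir: str = "run"


def recording_to_segments(
    rec: Recording,
    seg_cfg: segment.SegmentationConfig | None = None,
    pre_cfg: preprocess.PreprocessConfig | None = None,
    rest_cap: int = 8,
) -> list[segment.Segment]:
    """Preprocess and segment one recording using its block annotations.

    Peak detection runs independently within each gesture block (the
    semi-automatic protocol's manually selected active region); rest
    segments are cut from idle intervals, at most ``rest_cap`` per
    recording. Segments are taken from the cleaned, per-channel z-scored
    signal.
    """
    seg_cfg = seg_cfg or segment.SegmentationConfig()
    pre_cfg = pre_cfg or preprocess.PreprocessConfig()
    truth = rec.meta.get("truth")
    if truth is None:
        raise ValueError("recording lacks block annotations (meta['truth'])")
    cleaned = preprocess.clean(rec, pre_cfg)
    env = preprocess.rms_envelope(cleaned, pre_cfg)
    normed = preprocess.normalize(cleaned, pre_cfg.normalization)
    fs = rec.fs_hz

    segments: list[segment.Segment] = []
    margin = 0.25
    for block in truth["blocks"]:
        t0 = max(block["t_start"] - margin, 0.0)
        t1 = min(block["t_end"] + margin, rec.duration_s)
        i0, i1 = int(t0 * fs), int(t1 * fs)
        env_block = Recording(
            mv=env.mv[:, i0:i1],
            fs_hz=fs,
            channel_names=rec.channel_names,
            side=rec.side,
            subject_id=rec.subject_id,
        )
        peaks = [t0 + t for t in segment.detect_peaks(env_block, seg_cfg)]
        segments.extend(segment.extract_segments(normed, peaks, block["gesture"], seg_cfg))

    rest_intervals = []
    for idle in truth["idle"]:
        # keep clear of block edges
        a, b = idle["t_start"] + 0.4, idle["t_end"] - 0.4
        if b - a >= 0.2:
            rest_intervals.append((a, b))
        if len(rest_intervals) >= rest_cap:
            break
    segments.extend(segment.label_rest(normed, rest_intervals, seg_cfg))
    return segments


def cohort_features(
    cohort,
    side: str,
    feature_set: str,
    seg_cfg: segment.SegmentationConfig | None = None,
    pre_cfg: preprocess.PreprocessConfig | None = None,
):
    """Segment and extract features for one side of a generated cohort.

    Returns (X, y, groups, names).
    """
    mats, labels, groups = [], [], []
    names: list[str] = []
    for profile, rec_p, rec_np in cohort:
        rec = rec_p if side == "paretic" else rec_np
        segs = recording_to_segments(rec, seg_cfg, pre_cfg)
        X, y, names = sets.extract_matrix(segs, feature_set)
        mats.append(X)
        labels.append(y)
        groups.extend([profile.subject_id] * len(y))
    return np.vstack(mats), np.concatenate(labels), np.asarray(groups), names


def evaluate_side(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    side: str,
    classifier: str,
    gl: int,
    cv: classify.CVSpec,
    n_components: int | None = None,
) -> pd.DataFrame:
    """Run grouped CV over every gesture model of size ``gl``.

    Returns one row per (model, partition) with accuracy and macro-F1.
    """
    rows = []
    for model in classify.enumerate_models(gl):
        mats = classify.cross_validate(X, y, groups, model, classifier, cv, n_components)
        for it, m in enumerate(mats):
            rows.append(
                {
                    "side": side,
                    "classifier": classifier,
                    "gl": gl,
                    "pca": n_components is not None,
                    "model": "+".join(l for l in model.labels if l != "rest"),
                    "iteration": it,
                    "acc": evaluate.accuracy(m),
                    "f1": evaluate.macro_f1(m),
                }
            )
    return pd.DataFrame(rows)


def gl4_grand_mean_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    classifier: str,
    cv: classify.CVSpec,
) -> float:
    """Mean CV accuracy averaged over all 20 four-gesture models."""
    accs = []
    for model in classify.enumerate_models(4):
        mats = classify.cross_validate(X, y, groups, model, classifier, cv)
        accs.append(np.mean([evaluate.accuracy(m) for m in mats]))
    return float(np.mean(accs))


def practicality_benchmark(
    seed: int,
    n_subjects: int = 19,
    reps: int = 10,
    folds: int = 10,
    iterations: int = 10,
    test_subjects: int = 3,
) -> dict[str, dict[str, float | int]]:
    """Grand-mean GL4 SVM accuracy on a full synthetic cohort, per side.

    The non-paretic side uses ASF-14NP features, the paretic side ASF-24P;
    the CV protocol is subject-grouped repeated hold-out with
    ``folds x iterations`` random partitions of 3 held-out subjects.
    """
    cohort = synth.generate_cohort(n_subjects, seed, reps=reps)
    cv = classify.CVSpec(
        folds=folds, iterations=iterations, test_subjects=test_subjects, seed=seed + 1
    )
    out: dict[str, dict[str, float | int]] = {}
    for side, fset in (("non-paretic", "ASF14NP"), ("paretic", "ASF24P")):
        X, y, groups, _ = cohort_features(cohort, side, fset)
        acc = gl4_grand_mean_accuracy(X, y, groups, "svm", cv)
        out[side] = {"mean_accuracy": acc, "n_segments": int(len(y))}
    return out


def run_pipeline(cfg: RunConfig) -> Path:
    """Full synthetic-cohort run; writes results and a manifest to out_dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = synth.generate_cohort(cfg.n_subjects, cfg.master_seed, reps=cfg.reps)
    cv = classify.CVSpec(
        folds=cfg.cv_folds,
        iterations=cfg.cv_iterations,
        test_subjects=cfg.test_subjects,
        seed=cfg.master_seed + 1,
    )
    frames = []
    for side, fset in (
        ("non-paretic", cfg.feature_set_nonparetic),
        ("paretic", cfg.feature_set_paretic),
    ):
        X, y, groups, names = cohort_features(cohort, side, fset)
        pd.DataFrame(X, columns=names).assign(label=y, subject=groups).to_csv(
            out / f"features_{side}.csv", index=False
        )
        frames.append(
            evaluate_side(X, y, groups, side, cfg.classifier, cfg.gl, cv)
        )
    results = pd.concat(frames, ignore_index=True)
    results.to_csv(out / "results.csv", index=False)
    grid = evaluate.summarize(results.to_dict("records"))
    grid.to_csv(out / "summary.csv", index=False)
    manifest = {
        "config": asdict(cfg),
        "cohort_distributions": synth.COHORT_DISTRIBUTIONS,
        "n_result_rows": int(len(results)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
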