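"""Abnormal-gait detection evaluation.

Runs the full pipeline (reprojection -> surface normals -> region
accumulation) per sequence, scores every sequence under each processing
flow, and measures separation of normal vs abnormal gaits as ROC AUC, with
abnormal as the positive class and higher score = more asymmetric.

Two evaluation schemes:

* all-subjects — every sequence's raw score pooled into one ROC;
* leave-one-out — an AUC per held-out subject from that subject's own
  sequences (1 normal vs 8 abnormal: high-variance by construction),
  averaged across subjects.  Any trained quantity (the variance-based
  combination weights) is fitted only on the *other* subjects' normal
  sequences, so the held-out subject never influences training.

The 12 basic processing flows are {frame, segment} x {transverse,
sagittal, coronal} x {full, lower body}; combined flows (segment-based)
cover every nonempty subset of the three planes via zero weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .depth_io import CameraIntrinsics, reproject
from .errors import EvaluationError, InsufficientDataError
from .features import PLANES, split_regions
from .normals import DEFAULT_RADIUS, estimate_normals
from .symmetry import (
    PlaneWeights,
    SequenceFeatures,
    combined_index,
    fit_weights,
    frame_index,
    segment_index,
)

#: Plane subsets of the combined index, keyed by short names
#: (t = transverse, s = sagittal, c = coronal).
COMBOS = ("t", "s", "c", "ts", "sc", "tc", "tsc")


@dataclass
class SequenceInfo:
    """Lightweight stand-in for a LabelledSequence once frames are dropped."""

    label: str
    subject_id: int
    kind: str = "none"
    asymmetry_magnitude: float = 0.0


@dataclass
class EvalResult:
    """AUCs of one processing flow."""

    variant: tuple  # (scheme, plane-or-combo, body)
    auc_all: float
    auc_loo: float
    per_subject: list  # [(subject_id, auc), ...]

    def __post_init__(self):
        for a in (self.auc_all, self.auc_loo):
            if not (0.0 <= a <= 1.0):
                raise EvaluationError("AUC out of [0, 1]")


def roc_auc(scores_normal, scores_abnormal) -> float:
    """ROC AUC with abnormal positive; equals the Mann-Whitney statistic
    (ties counted as half) by the standard midrank construction."""
    a = np.asarray(scores_abnormal, dtype=float)
    n = np.asarray(scores_normal, dtype=float)
    if len(a) == 0 or len(n) == 0:
        raise InsufficientDataError("both score lists must be non-empty")
    y = np.concatenate([np.zeros(len(n)), np.ones(len(a))])
    return float(roc_auc_score(y, np.concatenate([n, a])))


def extract_sequence_features(
    seq, intrinsics: CameraIntrinsics | None = None,
    radius: float = DEFAULT_RADIUS,
) -> SequenceFeatures:
    """Run depth frames through the geometric pipeline.

    ``seq`` is a LabelledSequence or any object with ``frames`` (masked
    DepthFrames); intrinsics default to the sequence's own camera.
    """
    if intrinsics is None:
        intrinsics = seq.config.camera
    region_vectors = []
    for frame in seq.frames:
        cloud = reproject(frame, intrinsics)
        nrm = estimate_normals(cloud, radius=radius)
        region_vectors.append(split_regions(cloud, nrm))
    return SequenceFeatures(frames=region_vectors)


def run_benchmark(n_subjects: int, seed: int, *,
                  radius: float = DEFAULT_RADIUS, **benchmark_kwargs):
    """Simulate the labelled benchmark and run the geometric pipeline,
    one sequence at a time so depth frames never accumulate in memory.

    Returns ``(infos, features)``: parallel lists of SequenceInfo and
    SequenceFeatures, ready for :func:`evaluate_all`.
    """
    from .synthetic import benchmark_configs, simulate_walk

    infos, feats = [], []
    for subj, cfg in benchmark_configs(n_subjects, seed, **benchmark_kwargs):
        seq = simulate_walk(cfg)
        seq.subject_id = subj
        feats.append(extract_sequence_features(seq, radius=radius))
        infos.append(SequenceInfo(label=seq.label, subject_id=subj,
                                  kind=seq.kind,
                                  asymmetry_magnitude=seq.asymmetry_magnitude))
    return infos, feats


def _masked_weights(w: PlaneWeights, combo: str) -> PlaneWeights:
    """Zero out the planes absent from ``combo`` (e.g. 'ts')."""
    return PlaneWeights(
        wt=w.wt if "t" in combo else 0.0,
        ws=w.ws if "s" in combo else 0.0,
        wc=w.wc if "c" in combo else 0.0,
    )


def _check_structure(sequences) -> list:
    subjects = sorted({s.subject_id for s in sequences})
    if len(subjects) < 2:
        raise EvaluationError("need at least 2 subjects")
    for subj in subjects:
        own = [s for s in sequences if s.subject_id == subj]
        if not any(s.label == "normal" for s in own):
            raise EvaluationError(f"subject {subj} has no normal sequence")
        if not any(s.label == "abnormal" for s in own):
            raise EvaluationError(f"subject {subj} has no abnormal sequence")
    return subjects


def _auc_pair(sequences, scores, subjects):
    """Pooled AUC plus per-subject (1-vs-rest) AUCs from a score array."""
    labels = np.array([s.label == "abnormal" for s in sequences])
    auc_all = roc_auc(scores[~labels], scores[labels])
    per_subject = []
    for subj in subjects:
        sel = np.array([s.subject_id == subj for s in sequences])
        per_subject.append(
            (subj, roc_auc(scores[sel & ~labels], scores[sel & labels])))
    auc_loo = float(np.mean([a for _, a in per_subject]))
    return auc_all, auc_loo, per_subject


def evaluate_all(sequences, radius: float = DEFAULT_RADIUS,
                 features: list | None = None) -> list:
    """Evaluate every processing flow on a labelled benchmark.

    Returns EvalResults for the 12 basic flows plus the segment-based
    combined flows (single, pairwise, triple planes) on full and lower
    body.  ``features`` may carry precomputed per-sequence
    SequenceFeatures (parallel to ``sequences``) to skip the pipeline.
    """
    subjects = _check_structure(sequences)
    if features is None:
        features = [extract_sequence_features(s, radius=radius)
                    for s in sequences]
    if len(features) != len(sequences):
        raise EvaluationError("features must be parallel to sequences")

    results = []
    index_fn = {"frame": frame_index, "segment": segment_index}
    for scheme in ("frame", "segment"):
        for plane in PLANES:
            for body, lower in (("full", False), ("lower", True)):
                scores = np.array([
                    index_fn[scheme](f, plane, lower_only=lower).value
                    for f in features])
                auc_all, auc_loo, per_subject = _auc_pair(
                    sequences, scores, subjects)
                results.append(EvalResult(
                    variant=(scheme, plane, body),
                    auc_all=auc_all, auc_loo=auc_loo,
                    per_subject=per_subject))

    # Combined flows: weights from normal-gait training sequences only.
    normal_idx = [i for i, s in enumerate(sequences) if s.label == "normal"]
    for body, lower in (("full", False), ("lower", True)):
        w_all = fit_weights([features[i] for i in normal_idx],
                            scheme="segment", lower_only=lower)
        w_held = {}
        for subj in subjects:
            train = [features[i] for i in normal_idx
                     if sequences[i].subject_id != subj]
            w_held[subj] = fit_weights(train, scheme="segment",
                                       lower_only=lower)
        for combo in COMBOS:
            scores_all = np.array([
                combined_index(f, _masked_weights(w_all, combo),
                               scheme="segment", lower_only=lower).value
                for f in features])
            labels = np.array([s.label == "abnormal" for s in sequences])
            auc_all = roc_auc(scores_all[~labels], scores_all[labels])

            per_subject = []
            for subj in subjects:
                sel = [i for i, s in enumerate(sequences)
                       if s.subject_id == subj]
                w = _masked_weights(w_held[subj], combo)
                sc = np.array([
                    combined_index(features[i], w, scheme="segment",
                                   lower_only=lower).value for i in sel])
                lab = labels[sel]
                per_subject.append((subj, roc_auc(sc[~lab], sc[lab])))
            auc_loo = float(np.mean([a for _, a in per_subject]))
            results.append(EvalResult(
                variant=("segment", f"combined:{combo}", body),
                auc_all=auc_all, auc_loo=auc_loo, per_subject=per_subject))
    return results


def results_to_dataframe(results) -> pd.DataFrame:
    """Tabulate EvalResults (columns: scheme, plane, body, auc_all, auc_loo)."""
    rows = [
        {"scheme": r.variant[0], "plane": r.variant[1], "body": r.variant[2],
         "auc_all": r.auc_all, "auc_loo": r.auc_loo}
        for r in results
    ]
    return pd.DataFrame(rows)
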