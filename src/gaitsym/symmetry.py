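"""Sequence-level gait symmetry indices.

Two temporal schemes aggregate the per-frame region vectors of a walking
sequence into one scalar per anatomical plane (larger = more asymmetric):

* frame-based: the basic index is computed per frame, then averaged —
  If = (1/n) sum_i I(v_i).
* segment-based: the four region vectors are averaged over frames first and
  the basic index applied once to the mean posture — Is = I((1/n) sum_i v_i).
  This is the angle of the average posture over one or more gait cycles and
  is near zero for any symmetric gait, however asymmetric each individual
  stride snapshot looks.

A weighted combination sums the three per-plane indices with weights fitted
as the population variance of each plane's index over *normal* training
sequences (variance as an information measure; abnormal gaits are excluded
so the combination does not specialize to particular pathologies).  Weights
are used unnormalized: ROC analysis is invariant to positive rescaling of
scores.

No gait-cycle detection is performed; a sequence is whatever frame window
is supplied (two seconds or more recommended so the mean covers at least
one full stride).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateFeatureError,
    DegenerateWeightsError,
    EmptyInputError,
    InsufficientDataError,
    ParameterError,
)
from .features import PLANES, RegionVectors, basic_index

logger = logging.getLogger(__name__)


@dataclass
class SequenceFeatures:
    """Ordered per-frame region vectors of one walking sequence."""

    frames: list  # list[RegionVectors]

    def __post_init__(self):
        if len(self.frames) < 1:
            raise EmptyInputError("a sequence needs at least one frame")

    @property
    def n(self) -> int:
        return len(self.frames)

    def mean_vectors(self) -> RegionVectors:
        """Component-wise mean of the four region vectors over frames."""
        stack = {
            name: np.mean([getattr(f, name) for f in self.frames], axis=0)
            for name in ("vTL", "vTR", "vBL", "vBR")
        }
        return RegionVectors(**stack)


@dataclass(frozen=True)
class PlaneWeights:
    """Non-negative combination weights (transverse, sagittal, coronal)."""

    wt: float
    ws: float
    wc: float

    def __post_init__(self):
        w = (self.wt, self.ws, self.wc)
        if any(x < 0 or not np.isfinite(x) for x in w):
            raise ParameterError("weights must be finite and non-negative")
        if not any(x > 0 for x in w):
            raise DegenerateWeightsError("at least one weight must be positive")


@dataclass(frozen=True)
class GaitScore:
    """Scalar symmetry index of one sequence under one processing flow."""

    value: float
    scheme: str  # frame | segment | combined
    plane: str   # transverse | sagittal | coronal | combined
    body: str    # full | lower

    def __post_init__(self):
        if not (np.isfinite(self.value) and self.value >= 0):
            raise ParameterError("score must be finite and non-negative")


def frame_index(seq: SequenceFeatures, plane: str,
                lower_only: bool = False) -> GaitScore:
    """Frame-based index: mean of per-frame basic indices.

    Frames whose angle feature is degenerate are dropped with a warning;
    if every frame is degenerate the sequence is rejected.
    """
    values = []
    for i, v in enumerate(seq.frames):
        try:
            values.append(basic_index(v, plane, lower_only=lower_only))
        except DegenerateFeatureError:
            logger.warning("dropping frame %d: degenerate %s feature", i, plane)
    if not values:
        raise EmptyInputError(f"all frames degenerate for the {plane} plane")
    return GaitScore(value=float(np.mean(values)), scheme="frame",
                     plane=plane, body="lower" if lower_only else "full")


def segment_index(seq: SequenceFeatures, plane: str,
                  lower_only: bool = False) -> GaitScore:
    """Segment-based index: basic index of the mean posture."""
    value = basic_index(seq.mean_vectors(), plane, lower_only=lower_only)
    return GaitScore(value=float(value), scheme="segment",
                     plane=plane, body="lower" if lower_only else "full")


_INDEX_FN = {"frame": frame_index, "segment": segment_index}


def weights_to_json(weights: "PlaneWeights", scheme: str = "segment",
                    trained_on=None) -> dict:
    """Serializable record of fitted combination weights."""
    return {"wt": weights.wt, "ws": weights.ws, "wc": weights.wc,
            "scheme": scheme, "trained_on": list(trained_on or [])}


def fit_weights(training: Sequence[SequenceFeatures], scheme: str = "segment",
                lower_only: bool = False) -> PlaneWeights:
    """Fit combination weights from normal-gait training sequences.

    The weight of each plane is the population variance of that plane's
    chosen-scheme index over the training set.  Supply normal gaits only.
    """
    if len(training) < 2:
        raise InsufficientDataError("need at least 2 training sequences")
    fn = _INDEX_FN[scheme]
    var = {}
    for plane in PLANES:
        vals = [fn(s, plane, lower_only=lower_only).value for s in training]
        var[plane] = float(np.var(vals))  # population variance (ddof=0)
    if all(v == 0 for v in var.values()):
        raise DegenerateWeightsError(
            "all plane indices constant over training; weights undefined")
    return PlaneWeights(wt=var["transverse"], ws=var["sagittal"],
                        wc=var["coronal"])


def combined_index(seq: SequenceFeatures, weights: PlaneWeights,
                   scheme: str = "segment",
                   lower_only: bool = False) -> GaitScore:
    """Weighted sum of the three per-plane indices under one scheme.

    Pairwise or single-plane combinations are expressed by zero weights.
    """
    fn = _INDEX_FN[scheme]
    w = {"transverse": weights.wt, "sagittal": weights.ws,
         "coronal": weights.wc}
    total = 0.0
    for plane in PLANES:
        if w[plane] == 0:
            continue  # a zero weight must not force evaluation of its plane
        total += w[plane] * fn(seq, plane, lower_only=lower_only).value
    return GaitScore(value=float(total), scheme="combined", plane="combined",
                     body="lower" if lower_only else "full")
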