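"""Region accumulation and anatomical-plane angle features.

The body silhouette of a frame is split by the midlines of its tight pixel
bounding box into a 2x2 grid (top-left, top-right, bottom-left,
bottom-right in *image* coordinates).  All valid unit normals falling in a
cell are summed into one accumulated vector per region, giving the
quadruple {vTL, vTR, vBL, vBR}.  Left/right then mean image-left vs
image-right throughout; since both sides use the same convention the
symmetry indices do not depend on which anatomical side "left" denotes.

Three scalar features compare the left and right accumulated vectors after
projecting them onto an anatomical plane:

* transverse (alpha): project to (x, 0, z); reflect the right vector about
  the +z axis, then take the angle — zero for a left/right mirror pair.
* sagittal (beta): project to (0, y, z); plain angle, no reflection needed
  because both sides live in the same plane.
* coronal (gamma): project to (x, y, 0); reflect the right vector about the
  +y axis, then take the angle.

The basic symmetry index per plane is the sum of the top-pair and
bottom-pair angles (each in [0, pi], so the index is in [0, 2*pi]);
``lower_only`` keeps the bottom term alone for lower-body experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .depth_io import FramePoints
from .errors import DegenerateFeatureError, EmptyInputError
from .normals import NormalCloud

logger = logging.getLogger(__name__)

#: Projected vectors shorter than this are degenerate (angle undefined).
DEGENERATE_NORM = 1e-12

PLANES = ("transverse", "sagittal", "coronal")


@dataclass
class RegionVectors:
    """Accumulated normal vectors of the four silhouette grid cells."""

    vTL: np.ndarray
    vTR: np.ndarray
    vBL: np.ndarray
    vBR: np.ndarray

    def __post_init__(self):
        for name in ("vTL", "vTR", "vBL", "vBR"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be finite")
            setattr(self, name, v)

    def total(self) -> np.ndarray:
        """Sum over regions; equals the frame's total valid-normal sum."""
        return self.vTL + self.vTR + self.vBL + self.vBR


@dataclass
class AngleTriple:
    """Per-frame (or per-segment) plane angles, split into top and bottom."""

    alpha_top: float
    alpha_bottom: float
    beta_top: float
    beta_bottom: float
    gamma_top: float
    gamma_bottom: float


def split_regions(cloud: FramePoints, normals: NormalCloud) -> RegionVectors:
    """Accumulate valid normals into the 2x2 silhouette grid.

    The grid is the tight bounding box of *all* body pixels, split at its
    arithmetic midlines; cells are half-open with the midline belonging to
    the left/top cell.  Invalid normals are skipped, not zero-filled.
    """
    if len(cloud) != len(normals.valid):
        raise ValueError("cloud and normals must be parallel")
    if not np.any(normals.valid):
        raise EmptyInputError("no valid normals to accumulate")

    rows = cloud.pixels[:, 0]
    cols = cloud.pixels[:, 1]
    rmid = (rows.min() + rows.max()) / 2.0
    cmid = (cols.min() + cols.max()) / 2.0
    top = rows <= rmid
    left = cols <= cmid

    v = normals.valid
    nrm = normals.normals

    def acc(sel):
        sel = sel & v
        return nrm[sel].sum(axis=0) if np.any(sel) else np.zeros(3)

    return RegionVectors(
        vTL=acc(top & left),
        vTR=acc(top & ~left),
        vBL=acc(~top & left),
        vBR=acc(~top & ~left),
    )


def _angle(a: np.ndarray, b: np.ndarray, plane: str) -> float:
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na < DEGENERATE_NORM or nb < DEGENERATE_NORM:
        raise DegenerateFeatureError(
            f"zero projection onto the {plane} plane")
    c = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.arccos(c))


def angle_transverse(uL, uR) -> float:
    """Transverse-plane angle between left and reflected right vectors."""
    uL = np.asarray(uL, float)
    uR = np.asarray(uR, float)
    pL = np.array([uL[0], 0.0, uL[2]])
    pR = np.array([uR[0], 0.0, uR[2]])
    # reflection about +z: 2(z.u)z - u = (-x, 0, z)
    pR_ref = np.array([-pR[0], 0.0, pR[2]])
    return _angle(pL, pR_ref, "transverse")


def angle_sagittal(uL, uR) -> float:
    """Sagittal-plane angle between left and right vectors (no reflection)."""
    uL = np.asarray(uL, float)
    uR = np.asarray(uR, float)
    pL = np.array([0.0, uL[1], uL[2]])
    pR = np.array([0.0, uR[1], uR[2]])
    return _angle(pL, pR, "sagittal")


def angle_coronal(uL, uR) -> float:
    """Coronal-plane angle between left and reflected right vectors."""
    uL = np.asarray(uL, float)
    uR = np.asarray(uR, float)
    pL = np.array([uL[0], uL[1], 0.0])
    pR = np.array([uR[0], uR[1], 0.0])
    # reflection about +y: 2(y.u)y - u = (-x, y, 0)
    pR_ref = np.array([-pR[0], pR[1], 0.0])
    return _angle(pL, pR_ref, "coronal")


_ANGLE_FN = {
    "transverse": angle_transverse,
    "sagittal": angle_sagittal,
    "coronal": angle_coronal,
}


def features_to_dataframe(region_vectors_by_frame):
    """Tabulate per-frame features: six angle columns plus the twelve
    accumulated-vector components.  Frames with a degenerate plane get NaN
    angles (they are dropped from sequence aggregation, not zeroed)."""
    import pandas as pd

    rows = []
    for i, v in enumerate(region_vectors_by_frame):
        row = {"frame_index": i}
        for plane, prefix in (("transverse", "alpha"), ("sagittal", "beta"),
                              ("coronal", "gamma")):
            fn = _ANGLE_FN[plane]
            for part, (a, b) in (("top", (v.vTL, v.vTR)),
                                 ("bottom", (v.vBL, v.vBR))):
                try:
                    row[f"{prefix}_{part}"] = fn(a, b)
                except DegenerateFeatureError:
                    row[f"{prefix}_{part}"] = float("nan")
        for name in ("vTL", "vTR", "vBL", "vBR"):
            vec = getattr(v, name)
            for axis, val in zip("xyz", vec):
                row[f"{name}_{axis}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def angle_triple(v: RegionVectors) -> AngleTriple:
    """All six angle components (three planes x top/bottom pairs)."""
    return AngleTriple(
        alpha_top=angle_transverse(v.vTL, v.vTR),
        alpha_bottom=angle_transverse(v.vBL, v.vBR),
        beta_top=angle_sagittal(v.vTL, v.vTR),
        beta_bottom=angle_sagittal(v.vBL, v.vBR),
        gamma_top=angle_coronal(v.vTL, v.vTR),
        gamma_bottom=angle_coronal(v.vBL, v.vBR),
    )


def basic_index(v: RegionVectors, plane: str, lower_only: bool = False) -> float:
    """Per-frame symmetry index for one anatomical plane.

    Sum of the top-pair and bottom-pair angles (bottom alone when
    ``lower_only``).  Degenerate projections raise, tagged with the
    offending region pair.
    """
    fn = _ANGLE_FN[plane]
    try:
        bottom = fn(v.vBL, v.vBR)
    except DegenerateFeatureError as exc:
        raise DegenerateFeatureError(str(exc), region_pair="bottom") from exc
    if lower_only:
        return bottom
    try:
        top = fn(v.vTL, v.vTR)
    except DegenerateFeatureError as exc:
        raise DegenerateFeatureError(str(exc), region_pair="top") from exc
    return top + bottom
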