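"""Surface-normal estimation from body point clouds.

Each point's normal is the eigenvector with the smallest eigenvalue of the
covariance matrix of its metric neighborhood (closed ball, the point itself
included), found with a KD-tree.  Normals are then oriented toward the
camera: any normal with a positive z-component is flipped, so every valid
normal satisfies z <= 0.  The default 3 cm radius keeps the estimate local;
noise robustness comes from the downstream region accumulation rather than
from a large neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .depth_io import FramePoints
from .errors import EmptyInputError, ParameterError

#: Neighborhood radius in metres.
DEFAULT_RADIUS = 0.03

#: Relative gap between the two smallest eigenvalues below which the normal
#: direction is not identifiable and the point is marked invalid.
EIG_TIE_RTOL = 1e-9

#: Minimum neighbors (including the point itself) for a defined covariance.
MIN_NEIGHBORS = 3


@dataclass
class NormalCloud:
    """Unit normals parallel to a FramePoints' points.

    ``valid`` is False where estimation was degenerate (too few neighbors or
    an ambiguous smallest eigenvalue); invalid entries are zero vectors and
    must be skipped downstream.
    """

    normals: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        self.valid = np.asarray(self.valid, dtype=bool).reshape(-1)
        if len(self.normals) != len(self.valid):
            raise ParameterError("normals and valid must be parallel")


def _orient_toward_camera(normals: np.ndarray) -> np.ndarray:
    """Flip normals so z <= 0; resolve z == 0 by a fixed sign convention."""
    flip = normals[:, 2] > 0
    # z == 0: pick the sign making the first nonzero of (x, y) positive,
    # purely for determinism (the angle features are even in this choice
    # only through the orientation rule, so it must be reproducible).
    on_plane = normals[:, 2] == 0
    if np.any(on_plane):
        x, y = normals[:, 0], normals[:, 1]
        neg = on_plane & ((x < 0) | ((x == 0) & (y < 0)))
        flip = flip | neg
    out = normals.copy()
    out[flip] *= -1.0
    return out


def estimate_normals(cloud: FramePoints, radius: float = DEFAULT_RADIUS) -> NormalCloud:
    """Estimate camera-facing unit normals for every point of a frame.

    Parameters
    ----------
    cloud : FramePoints
        Non-empty body point cloud.
    radius : float
        Neighborhood radius in metres (closed ball).

    Returns
    -------
    NormalCloud
        Unit normals with z <= 0 where valid.
    """
    if radius <= 0:
        raise ParameterError("radius must be positive")
    pts = cloud.points
    n = len(pts)
    if n == 0:
        raise EmptyInputError("cannot estimate normals of an empty cloud")

    # Pairwise neighbor accumulation: for point i the neighborhood first and
    # second moments are sums over neighbors j (closed ball, self included),
    # gathered once from the KD-tree pair list and scattered with bincount.
    tree = cKDTree(pts)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs):
        idx = np.concatenate([pairs[:, 0], pairs[:, 1]])
        src = np.concatenate([pairs[:, 1], pairs[:, 0]])
    else:
        idx = np.empty(0, dtype=int)
        src = idx

    count = np.bincount(idx, minlength=n).astype(float) + 1.0  # + self
    s1 = pts.copy()
    for k in range(3):
        s1[:, k] += np.bincount(idx, weights=pts[src, k], minlength=n)

    # Second moments: 6 unique entries of the symmetric outer product.
    iu = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]
    s2 = np.empty((n, 6))
    for m, (a, b) in enumerate(iu):
        own = pts[:, a] * pts[:, b]
        s2[:, m] = own + np.bincount(
            idx, weights=pts[src, a] * pts[src, b], minlength=n)

    mu = s1 / count[:, None]
    cov = np.empty((n, 3, 3))
    for m, (a, b) in enumerate(iu):
        c = s2[:, m] / count - mu[:, a] * mu[:, b]
        cov[:, a, b] = c
        cov[:, b, a] = c

    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending eigenvalues
    normals = eigvecs[:, :, 0]

    scale = np.maximum(eigvals[:, 2], np.finfo(float).tiny)
    gap_ok = (eigvals[:, 1] - eigvals[:, 0]) > EIG_TIE_RTOL * scale
    valid = (count >= MIN_NEIGHBORS) & gap_ok & (eigvals[:, 2] > 0)

    normals = _orient_toward_camera(normals)
    normals[~valid] = 0.0
    return NormalCloud(normals=normals, valid=valid)
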