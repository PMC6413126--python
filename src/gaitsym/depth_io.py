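"""Depth-frame I/O, body segmentation and 3D reprojection.

A frontal depth camera observes a person walking on a treadmill.  Frames are
stored as 16-bit single-channel PNGs holding depth in millimetres (0 = no
return); internally all depth is carried in metres because the downstream
normal-estimation radius is metric.

Camera coordinate convention
----------------------------
Pixel coordinates are ``(u, v) = (column, row)`` with ``v`` growing downward
in the stored raster.  The pinhole back-projection of a pixel with depth
``d`` is

    x = (u - cx) * d / fx,    y = -(v - cy) * d / fy,    z = d

i.e. the raw pinhole ``y`` term is negated so that the resulting camera
frame has ``y`` pointing up and ``z`` pointing from the camera to the
subject.  Every left/right comparison downstream happens within this single
convention, so the sign of ``x`` (image-right positive) carries no
anatomical meaning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import EmptyInputError, FormatError, ParameterError

#: PNG integer unit -> metres (millimetre storage).
DEFAULT_UNIT_SCALE = 0.001


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole parameters mapping pixels + depth to 3D camera space.

    Attributes
    ----------
    fx, fy : float
        Focal lengths in pixels (must be positive).
    cx, cy : float
        Principal point (column, row) in pixels.
    """

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self):
        if not (self.fx > 0 and self.fy > 0):
            raise ParameterError("focal lengths must be positive")
        if not (np.isfinite(self.cx) and np.isfinite(self.cy)):
            raise ParameterError("principal point must be finite")


#: Kinect-2-like defaults: 512x424 depth image.
KINECT2_INTRINSICS = CameraIntrinsics(fx=365.0, fy=365.0, cx=256.0, cy=212.0)
KINECT2_IMAGE_SIZE = (424, 512)  # (rows, cols)


@dataclass
class DepthFrame:
    """One depth frame: metric depth grid plus optional body mask.

    ``depth`` is a 2D float array in metres with 0 marking invalid pixels
    (no camera return).  ``mask`` marks body pixels; it is filled either by
    :func:`segment_body` or supplied externally.
    """

    depth: np.ndarray
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 2:
            raise FormatError("depth must be a 2D grid")
        if np.any(self.depth < 0):
            raise FormatError("depth values must be non-negative")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.depth.shape:
                raise FormatError("mask shape must equal depth shape")


@dataclass
class FramePoints:
    """Body point cloud of one frame with back-pointers to source pixels.

    ``points`` is an (n, 3) array of camera-space coordinates in metres with
    every z > 0; ``pixels`` is the parallel (n, 2) integer array of
    (row, col) source pixel coordinates.
    """

    points: np.ndarray
    pixels: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.pixels = np.asarray(self.pixels, dtype=int).reshape(-1, 2)
        if len(self.points) != len(self.pixels):
            raise ParameterError("points and pixels must be parallel")

    def __len__(self) -> int:
        return len(self.points)


def read_depth_png(path, unit_scale: float = DEFAULT_UNIT_SCALE) -> DepthFrame:
    """Read a 16-bit single-channel depth PNG into a metric DepthFrame.

    Stored integers are multiplied by ``unit_scale`` (default 0.001:
    millimetres to metres); zeros stay zero and remain flagged invalid.
    """
    try:
        img = Image.open(path)
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read depth PNG {path!r}: {exc}") from exc
    if img.mode not in ("I;16", "I;16B", "I;16L", "I"):
        raise FormatError(
            f"{path!r}: expected 16-bit single-channel PNG, got mode {img.mode!r}"
        )
    raw = np.asarray(img, dtype=np.float64)
    if raw.ndim != 2:
        raise FormatError(f"{path!r}: expected single-channel image")
    return DepthFrame(depth=raw * unit_scale)


def write_depth_png(path, frame: DepthFrame,
                    unit_scale: float = DEFAULT_UNIT_SCALE) -> None:
    """Write a DepthFrame as 16-bit PNG (depth / unit_scale, rounded)."""
    raw = np.round(frame.depth / unit_scale)
    if np.any(raw > 65535):
        raise FormatError("depth exceeds 16-bit range at this unit_scale")
    Image.fromarray(raw.astype(np.uint16)).save(path)


def read_mask_png(path) -> np.ndarray:
    """Read an 8-bit mask PNG; nonzero pixels are body."""
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise FormatError(f"{path!r}: mask must be single-channel")
    return arr != 0


def write_mask_png(path, mask: np.ndarray) -> None:
    Image.fromarray((np.asarray(mask, bool) * np.uint8(255))).save(path)


def _backproject_grid(frame: DepthFrame, intr: CameraIntrinsics):
    """Vectorised Eq.-style back-projection of the whole grid (y negated)."""
    rows, cols = np.indices(frame.depth.shape)
    d = frame.depth
    x = (cols - intr.cx) * d / intr.fx
    y = -(rows - intr.cy) * d / intr.fy
    return x, y, d


def segment_body(frame: DepthFrame, box, intrinsics: CameraIntrinsics) -> DepthFrame:
    """Fill the body mask from a 3D bounding box above the treadmill.

    ``box`` is ``(min_xyz, max_xyz)`` in metres, camera space.  A pixel is
    marked iff its back-projected 3D point lies inside the half-open box
    ``[min, max)``; invalid (zero-depth) pixels are never marked.
    Returns a new DepthFrame sharing the depth grid.
    """
    lo = np.asarray(box[0], dtype=float)
    hi = np.asarray(box[1], dtype=float)
    if lo.shape != (3,) or hi.shape != (3,):
        raise ParameterError("box must be (min_xyz, max_xyz)")
    if np.any(lo >= hi):
        raise ParameterError("degenerate box: min must be < max on each axis")
    x, y, z = _backproject_grid(frame, intrinsics)
    valid = frame.depth > 0
    inside = (
        (x >= lo[0]) & (x < hi[0])
        & (y >= lo[1]) & (y < hi[1])
        & (z >= lo[2]) & (z < hi[2])
    )
    return DepthFrame(depth=frame.depth, mask=inside & valid)


def reproject(frame: DepthFrame, intrinsics: CameraIntrinsics) -> FramePoints:
    """Back-project every masked valid pixel to a 3D camera-space point.

    Requires a mask (a frame is rejected rather than guessing the body
    region).  Raises EmptyInputError when no masked pixel has valid depth.
    """
    if frame.mask is None:
        raise EmptyInputError(
            "frame has no body mask; run segment_body or supply one")
    sel = frame.mask & (frame.depth > 0)
    if not np.any(sel):
        raise EmptyInputError("no masked pixel with valid depth")
    rows, cols = np.nonzero(sel)
    d = frame.depth[rows, cols]
    x = (cols - intrinsics.cx) * d / intrinsics.fx
    y = -(rows - intrinsics.cy) * d / intrinsics.fy
    points = np.column_stack([x, y, d])
    pixels = np.column_stack([rows, cols])
    return FramePoints(points=points, pixels=pixels)


def project(points: np.ndarray, intrinsics: CameraIntrinsics):
    """Forward pinhole projection; the exact inverse of :func:`reproject`.

    Returns ``(u, v, d)`` float arrays with u = column, v = row.
    """
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    d = p[:, 2]
    u = intrinsics.cx + p[:, 0] * intrinsics.fx / d
    v = intrinsics.cy - p[:, 1] * intrinsics.fy / d
    return u, v, d


def write_ply(path, points: np.ndarray, normals: np.ndarray | None = None) -> None:
    """Export a point cloud as ASCII PLY (x y z [nx ny nz] per vertex)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    cols = [pts]
    props = ["property float x", "property float y", "property float z"]
    if normals is not None:
        nrm = np.asarray(normals, dtype=float).reshape(-1, 3)
        if len(nrm) != len(pts):
            raise ParameterError("normals must be parallel to points")
        cols.append(nrm)
        props += ["property float nx", "property float ny", "property float nz"]
    data = np.hstack(cols)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(pts)}\n")
        fh.write("\n".join(props) + "\nend_header\n")
        np.savetxt(fh, data, fmt="%.6f")


@dataclass
class SceneConfig:
    """Intrinsics + optional segmentation box, loadable from JSON."""

    intrinsics: CameraIntrinsics
    unit_scale: float = DEFAULT_UNIT_SCALE
    box: tuple | None = None  # (min_xyz, max_xyz) in metres

    @classmethod
    def from_json(cls, path) -> "SceneConfig":
        cfg = json.loads(Path(path).read_text())
        intr = CameraIntrinsics(
            fx=cfg["fx"], fy=cfg["fy"], cx=cfg["cx"], cy=cfg["cy"])
        box = None
        if "box" in cfg:
            box = (tuple(cfg["box"]["min"]), tuple(cfg["box"]["max"]))
        return cls(intrinsics=intr,
                   unit_scale=cfg.get("unit_scale", DEFAULT_UNIT_SCALE),
                   box=box)
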