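"""Synthetic frontal-view walking-depth sequences.

Emulates a treadmill gait lab: a depth camera 1.7 m above the ground faces
a subject walking 2.3 m away, recording 13 fps depth maps.  The subject is
an articulated body of simple primitives — torso ellipsoid, head sphere,
cylinder arms and legs — whose limbs swing sinusoidally at the stride
cadence with contralateral arm/leg pairs in antiphase (when the left leg
swings forward the left arm swings back).

Two asymmetric-gait families mirror the usual induced-pathology protocols:

* ``tilt_deg`` — a lateral roll of the whole body about the depth axis,
  as produced by padding a sole under one foot; the sign picks the side.
* ``leg_asym`` — unequal left/right leg motion, as produced by strapping a
  weight to one ankle: the affected leg's swing amplitude is scaled by
  ``1 - |leg_asym|`` and its phase lags by ``|leg_asym| * pi/8``; the sign
  picks the leg.

Rendering samples each primitive's surface on a deterministic parametric
grid, projects the samples through the pinhole model, and z-buffers them
per pixel (nearest wins, ties to the first-rendered primitive, torso
first).  i.i.d. Gaussian depth noise (default sd 5 mm, time-of-flight
like) is then added to rendered pixels; the body mask is exactly the set
of rendered pixels, so segmentation is perfect by construction — the
method under study starts after segmentation.  No treadmill or background
surfaces are rendered.

Everything is deterministic given the seed; noise is the only random
element within a sequence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .depth_io import (
    KINECT2_IMAGE_SIZE,
    KINECT2_INTRINSICS,
    CameraIntrinsics,
    DepthFrame,
    read_depth_png,
    read_mask_png,
    write_depth_png,
    write_mask_png,
)
from .errors import ConfigurationError, ParameterError

#: Benchmark camera: half Kinect-2 resolution, same field of view.  Keeps
#: the 81-sequence benchmark at desk scale while preserving geometry.
BENCHMARK_INTRINSICS = CameraIntrinsics(fx=182.5, fy=182.5, cx=128.0, cy=106.0)
BENCHMARK_IMAGE_SIZE = (212, 256)

#: Lateral-tilt levels (degrees) and leg-asymmetry levels used for the
#: benchmark's small/large abnormal gaits.
TILT_LEVELS = (4.0, 8.0)
LEG_ASYM_LEVELS = (0.15, 0.30)

#: Peak limb swing amplitudes (radians) of the symmetric gait.
LEG_SWING_AMPLITUDE = np.deg2rad(20.0)
ARM_SWING_AMPLITUDE = np.deg2rad(15.0)

#: Constant forward flexion of both legs (stance lean toward the camera).
#: Gives the lower-body surface a stable net vertical normal component, as
#: real flexed knees/shins do.
LEG_FORWARD_FLEX = np.deg2rad(8.0)

#: Mean swing offset (radians per unit |leg_asym|) of the weighted leg:
#: the loaded leg trails, so its average position shifts backward — the
#: displacement inequality of an ankle-weight gait, on top of its reduced
#: amplitude and phase lag.
LEG_ASYM_OFFSET = 0.35


@dataclass(frozen=True)
class BodyShape:
    """Primitive dimensions (metres) of the articulated body.

    Defaults describe a ~1.7 m adult; ``scaled`` derives other statures.
    """

    hip_height: float = 0.90
    shoulder_height: float = 1.40
    hip_halfwidth: float = 0.16
    shoulder_halfwidth: float = 0.22
    leg_length: float = 0.85
    leg_radius: float = 0.06
    arm_length: float = 0.55
    arm_radius: float = 0.04
    torso_semi: tuple = (0.18, 0.28, 0.11)  # (x, y, z) semi-axes
    head_radius: float = 0.11
    neck_gap: float = 0.06
    foot_semi: tuple = (0.045, 0.035, 0.12)  # (x, y, z) semi-axes
    foot_forward: float = 0.06  # toe offset toward the camera

    def scaled(self, height_scale: float, width_scale: float = 1.0) -> "BodyShape":
        return BodyShape(
            hip_height=self.hip_height * height_scale,
            shoulder_height=self.shoulder_height * height_scale,
            hip_halfwidth=self.hip_halfwidth * width_scale,
            shoulder_halfwidth=self.shoulder_halfwidth * width_scale,
            leg_length=self.leg_length * height_scale,
            leg_radius=self.leg_radius * width_scale,
            arm_length=self.arm_length * height_scale,
            arm_radius=self.arm_radius * width_scale,
            torso_semi=(self.torso_semi[0] * width_scale,
                        self.torso_semi[1] * height_scale,
                        self.torso_semi[2] * width_scale),
            head_radius=self.head_radius * (height_scale + width_scale) / 2,
            neck_gap=self.neck_gap * height_scale,
            foot_semi=(self.foot_semi[0] * width_scale,
                       self.foot_semi[1] * height_scale,
                       self.foot_semi[2] * height_scale),
            foot_forward=self.foot_forward * height_scale,
        )


@dataclass
class WalkConfig:
    """Full description of one simulated walking sequence."""

    n_frames: int = 26
    fps: float = 13.0
    cadence: float = 1.0  # strides per second
    camera: CameraIntrinsics = KINECT2_INTRINSICS
    image_size: tuple = KINECT2_IMAGE_SIZE  # (rows, cols)
    camera_height: float = 1.7
    subject_distance: float = 2.3
    body: BodyShape = field(default_factory=BodyShape)
    tilt_deg: float = 0.0
    leg_asym: float = 0.0
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.fps <= 0 or self.cadence <= 0:
            raise ParameterError("fps and cadence must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if abs(self.tilt_deg) >= 30:
            raise ParameterError("|tilt_deg| must be < 30")
        if abs(self.leg_asym) >= 1:
            raise ParameterError("|leg_asym| must be < 1")

    @property
    def is_normal(self) -> bool:
        return self.tilt_deg == 0.0 and self.leg_asym == 0.0


@dataclass
class LabelledSequence:
    """A simulated sequence with its ground-truth label."""

    frames: list  # list[DepthFrame]
    label: str    # "normal" | "abnormal"
    asymmetry_magnitude: float
    config: WalkConfig
    subject_id: int = 0
    kind: str = "none"  # "none" | "tilt" | "leg"

    def __post_init__(self):
        want = "normal" if self.config.is_normal else "abnormal"
        if self.label != want:
            raise ParameterError(
                "label must be normal iff tilt_deg == 0 and leg_asym == 0")


# ---------------------------------------------------------------------------
# Primitive surface sampling.  Angular grids use even counts so every
# cross-section point set is closed under x -> -x, which makes the
# symmetric configuration mirror-symmetric up to rasterization.

def _cylinder_points(length: float, radius: float, spacing: float) -> np.ndarray:
    """Axis-aligned cylinder surface, axis along -y from the origin,
    plus the far end cap.  Returned in the local frame of its pivot."""
    n_ax = max(int(np.ceil(length / spacing)) + 1, 2)
    n_ang = max(2 * int(np.ceil(np.pi * radius / spacing)), 8)
    s = np.linspace(0.0, length, n_ax)
    ang = 2 * np.pi * np.arange(n_ang) / n_ang
    ss, aa = np.meshgrid(s, ang, indexing="ij")
    side = np.column_stack([
        radius * np.cos(aa.ravel()),
        -ss.ravel(),
        radius * np.sin(aa.ravel()),
    ])
    # end cap (foot / hand)
    n_r = max(int(np.ceil(radius / spacing)), 1)
    cap = [np.array([[0.0, -length, 0.0]])]
    for r in np.linspace(radius / n_r, radius, n_r):
        m = max(2 * int(np.ceil(np.pi * r / spacing)), 4)
        a = 2 * np.pi * np.arange(m) / m
        cap.append(np.column_stack([
            r * np.cos(a), np.full(m, -length), r * np.sin(a)]))
    return np.vstack([side] + cap)


def _ellipsoid_points(semi, spacing: float) -> np.ndarray:
    """Ellipsoid surface centred at the origin (latitude/longitude grid)."""
    a, b, c = semi
    mean_r = (a + b + c) / 3.0
    n_lat = max(int(np.ceil(np.pi * mean_r / spacing)), 4)
    n_lon = max(2 * int(np.ceil(np.pi * mean_r / spacing)), 8)
    lat = np.linspace(-np.pi / 2, np.pi / 2, n_lat)
    lon = 2 * np.pi * np.arange(n_lon) / n_lon
    tt, pp = np.meshgrid(lat, lon, indexing="ij")
    return np.column_stack([
        a * np.cos(tt.ravel()) * np.cos(pp.ravel()),
        b * np.sin(tt.ravel()),
        c * np.cos(tt.ravel()) * np.sin(pp.ravel()),
    ])


def _rot_x(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_z(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def _limb_angles(config: WalkConfig, phase: float):
    """Swing angles (radians) of legs and arms at one stride phase.

    Positive angle swings the limb toward the camera.  Contralateral
    arm/leg pairs are in antiphase; ``leg_asym`` perturbs one leg.
    """
    a_leg_l = a_leg_r = LEG_SWING_AMPLITUDE
    ph_l = ph_r = 0.0
    off_l = off_r = 0.0
    s = config.leg_asym
    if s > 0:
        a_leg_l *= (1.0 - abs(s))
        ph_l = abs(s) * np.pi / 8
        off_l = -abs(s) * LEG_ASYM_OFFSET
    elif s < 0:
        a_leg_r *= (1.0 - abs(s))
        ph_r = abs(s) * np.pi / 8
        off_r = -abs(s) * LEG_ASYM_OFFSET
    leg_l = LEG_FORWARD_FLEX + off_l + a_leg_l * np.sin(phase - ph_l)
    leg_r = LEG_FORWARD_FLEX + off_r + a_leg_r * np.sin(phase + np.pi - ph_r)
    arm_l = ARM_SWING_AMPLITUDE * np.sin(phase + np.pi)
    arm_r = ARM_SWING_AMPLITUDE * np.sin(phase)
    return leg_l, leg_r, arm_l, arm_r


def _body_points(config: WalkConfig, frame_idx: int):
    """All surface samples of one frame in camera space, with the render
    order of their source primitive (torso first)."""
    b = config.body
    z0 = config.subject_distance
    ground = -config.camera_height  # camera at y = 0
    spacing = 0.7 * z0 / config.camera.fx  # ~0.7 pixel footprint

    # reduce to [0, 1) strides first so whole-cycle frames repeat exactly
    phase = 2 * np.pi * ((config.cadence * frame_idx / config.fps) % 1.0)
    leg_l, leg_r, arm_l, arm_r = _limb_angles(config, phase)

    hip_y = ground + b.hip_height
    sho_y = ground + b.shoulder_height
    torso_c = np.array([0.0, (hip_y + sho_y) / 2, z0])
    head_c = np.array([0.0, sho_y + b.neck_gap + b.head_radius, z0])

    leg_local = _cylinder_points(b.leg_length, b.leg_radius, spacing)
    arm_local = _cylinder_points(b.arm_length, b.arm_radius, spacing)

    def limb(local, angle, attach):
        return local @ _rot_x(angle).T + attach

    foot_local = _ellipsoid_points(b.foot_semi, spacing)

    def foot(angle, hip_attach):
        # the foot rides on the ankle but stays level (treadmill contact)
        ankle = hip_attach + _rot_x(angle) @ np.array([0.0, -b.leg_length, 0.0])
        centre = ankle + np.array([0.0, -b.foot_semi[1] / 2, -b.foot_forward])
        return foot_local + centre

    hip_l = np.array([-b.hip_halfwidth, hip_y, z0])
    hip_r = np.array([b.hip_halfwidth, hip_y, z0])
    parts = [
        _ellipsoid_points(b.torso_semi, spacing) + torso_c,
        _ellipsoid_points((b.head_radius,) * 3, spacing) + head_c,
        limb(leg_local, leg_l, hip_l),
        limb(leg_local, leg_r, hip_r),
        foot(leg_l, hip_l),
        foot(leg_r, hip_r),
        limb(arm_local, arm_l, np.array([-b.shoulder_halfwidth, sho_y, z0])),
        limb(arm_local, arm_r, np.array([b.shoulder_halfwidth, sho_y, z0])),
    ]
    pts = np.vstack(parts)
    order = np.repeat(np.arange(len(parts)), [len(p) for p in parts])

    if config.tilt_deg != 0.0:
        pivot = np.array([0.0, hip_y, z0])
        rot = _rot_z(np.deg2rad(config.tilt_deg))
        pts = (pts - pivot) @ rot.T + pivot
    return pts, order


def _render(points: np.ndarray, order: np.ndarray,
            camera: CameraIntrinsics, image_size) -> DepthFrame:
    """Pinhole projection + per-pixel z-buffer (nearest wins; depth ties go
    to the first-rendered primitive)."""
    if np.any(points[:, 2] <= 0.05):
        raise ConfigurationError("body primitives behind the camera")
    rows_n, cols_n = image_size
    z = points[:, 2]
    u = camera.cx + points[:, 0] * camera.fx / z
    v = camera.cy - points[:, 1] * camera.fy / z
    col = np.floor(u + 0.5).astype(int)
    row = np.floor(v + 0.5).astype(int)
    ok = (col >= 0) & (col < cols_n) & (row >= 0) & (row < rows_n)
    col, row, z, order = col[ok], row[ok], z[ok], order[ok]

    pix = row * cols_n + col
    # descending z, then descending order: the last write per pixel is the
    # nearest sample, ties resolved to the lowest primitive order.
    perm = np.lexsort((-order, -z))
    depth = np.zeros(rows_n * cols_n)
    depth[pix[perm]] = z[perm]
    depth = depth.reshape(rows_n, cols_n)
    return DepthFrame(depth=depth, mask=depth > 0)


def simulate_walk(config: WalkConfig) -> LabelledSequence:
    """Render a full labelled walking sequence from a WalkConfig."""
    rng = np.random.default_rng(config.seed)
    frames = []
    for i in range(config.n_frames):
        pts, order = _body_points(config, i)
        frame = _render(pts, order, config.camera, config.image_size)
        if config.noise_sd > 0:
            noisy = frame.depth.copy()
            sel = frame.mask
            noise = rng.normal(0.0, config.noise_sd, size=int(sel.sum()))
            noisy[sel] = np.maximum(noisy[sel] + noise, 1e-6)
            frame = DepthFrame(depth=noisy, mask=sel)
        frames.append(frame)
    mag = config.tilt_deg if config.tilt_deg != 0 else config.leg_asym
    kind = "tilt" if config.tilt_deg != 0 else ("leg" if config.leg_asym else "none")
    return LabelledSequence(
        frames=frames,
        label="normal" if config.is_normal else "abnormal",
        asymmetry_magnitude=float(mag),
        config=config,
        kind=kind,
    )


def benchmark_configs(n_subjects: int, seed: int, *,
                      n_frames: int = 200,
                      camera: CameraIntrinsics = BENCHMARK_INTRINSICS,
                      image_size=BENCHMARK_IMAGE_SIZE,
                      noise_sd: float = 0.005) -> list:
    """Configs of the labelled benchmark: per pseudo-subject, 1 normal walk
    plus 8 abnormal ones (lateral tilt and leg asymmetry, two levels, two
    sides), mirroring a 9-gaits-per-subject acquisition protocol.

    Body proportions and cadence vary per subject (drawn from ``seed``);
    the label structure is identical across seeds.  Returns
    ``[(subject_id, WalkConfig), ...]``.
    """
    if n_subjects < 2:
        raise ParameterError("need at least 2 subjects")
    master = np.random.default_rng(seed)
    base = BodyShape()
    configs = []
    for subj in range(n_subjects):
        height = master.uniform(1.54, 1.86)
        width_scale = master.uniform(0.9, 1.1)
        cadence = master.uniform(0.9, 1.1)
        body = base.scaled(height_scale=height / 1.72, width_scale=width_scale)

        gaits = [(0.0, 0.0)]
        gaits += [(sgn * t, 0.0) for t in TILT_LEVELS for sgn in (+1, -1)]
        gaits += [(0.0, sgn * a) for a in LEG_ASYM_LEVELS for sgn in (+1, -1)]
        for tilt, asym in gaits:
            configs.append((subj, WalkConfig(
                n_frames=n_frames, camera=camera, image_size=image_size,
                body=body, cadence=cadence, tilt_deg=tilt, leg_asym=asym,
                noise_sd=noise_sd,
                seed=int(master.integers(0, 2**31 - 1)),
            )))
    return configs


def make_benchmark(n_subjects: int, seed: int, **kwargs) -> list:
    """Materialise the full benchmark as LabelledSequences.

    Convenient for small runs; at full scale (81 sequences x 200 frames)
    prefer :func:`gaitsym.evaluate.run_benchmark`, which streams frames
    instead of holding every depth map in memory.
    """
    sequences = []
    for subj, cfg in benchmark_configs(n_subjects, seed, **kwargs):
        seq = simulate_walk(cfg)
        seq.subject_id = subj
        sequences.append(seq)
    return sequences


# ---------------------------------------------------------------------------
# On-disk interchange: PNG16 depth + PNG8 mask per frame + manifest JSON.

def write_sequence(seq: LabelledSequence, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        write_depth_png(out / f"depth_{i:05d}.png", frame)
        write_mask_png(out / f"mask_{i:05d}.png", frame.mask)
    cam = seq.config.camera
    manifest = {
        "label": seq.label,
        "subject_id": seq.subject_id,
        "kind": seq.kind,
        "asymmetry_magnitude": seq.asymmetry_magnitude,
        "n_frames": len(seq.frames),
        "fps": seq.config.fps,
        "cadence": seq.config.cadence,
        "tilt_deg": seq.config.tilt_deg,
        "leg_asym": seq.config.leg_asym,
        "noise_sd": seq.config.noise_sd,
        "seed": seq.config.seed,
        "camera": {"fx": cam.fx, "fy": cam.fy, "cx": cam.cx, "cy": cam.cy},
        "image_size": list(seq.config.image_size),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_sequence(in_dir) -> LabelledSequence:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    cam = CameraIntrinsics(**manifest["camera"])
    cfg = WalkConfig(
        n_frames=manifest["n_frames"], fps=manifest["fps"],
        cadence=manifest["cadence"], camera=cam,
        image_size=tuple(manifest["image_size"]),
        tilt_deg=manifest["tilt_deg"], leg_asym=manifest["leg_asym"],
        noise_sd=manifest["noise_sd"], seed=manifest["seed"],
    )
    frames = []
    for i in range(manifest["n_frames"]):
        frame = read_depth_png(src / f"depth_{i:05d}.png")
        mask = read_mask_png(src / f"mask_{i:05d}.png")
        frames.append(DepthFrame(depth=frame.depth, mask=mask))
    return LabelledSequence(
        frames=frames, label=manifest["label"],
        asymmetry_magnitude=manifest["asymmetry_magnitude"],
        config=cfg, subject_id=manifest["subject_id"], kind=manifest["kind"])
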