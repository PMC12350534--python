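"""Synthetic tracked scene: parametric phantom head, optical-tracking jitter,
checkerboard calibration sessions and depth-camera captures.

Everything downstream (calibration, co-registration, surface registration,
FRE/TRE) can be exercised against known ground truth. The phantom is
parametric — a superellipsoid cranium with a nose wedge and a neck — built
so the standard facial anthropometrics (bigonial width 118 mm, nose length
50 mm, alar base 35 mm) hold by construction and can be re-measured from the
sampled cloud. Per-camera noise presets abstract the depth technologies
(stereo IR with/without texture projector, RGB stereo with/without neural
refinement, structured light); their magnitudes are this package's own
estimates, kept as config data rather than code constants.

Phantom frame: origin at head center, x right, y anterior (out of the
face), z superior. Camera optical frame: x right, y down, z forward.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .camera import CameraIntrinsics, Checkerboard, CornerObservation, estimate_board_pose, project
from .coregistration import TrackedCapture
from .exceptions import ConfigError, DataError, PlacementError, VisibilityError
from .geometry import RigidTransform, apply, compose, invert

__all__ = [
    "PhantomScene",
    "CameraNoisePreset",
    "TrackingNoise",
    "generate_phantom_head",
    "scene_from_files",
    "measure_anthropometrics",
    "simulate_tracked_pose",
    "simulate_calibration_session",
    "simulate_intrinsics_views",
    "simulate_depth_capture",
    "builtin_presets",
    "get_preset",
    "load_presets",
    "save_presets",
    "default_intrinsics",
    "default_board",
    "look_at",
    "face_viewpoints",
    "craniotomy_viewpoints",
]

REGION_LABELS = ("face", "scalp", "craniotomy", "other")

# cranium superellipsoid shape (mm); a is solved so the jaw width at the
# gonion plane equals the 118 mm bigonial target
_EXP = 2.2
_GONION_Z = -55.0
_C_LOWER = 95.0
_C_UPPER = 105.0
_B_DEPTH = 90.0
_A_WIDTH = 59.0 / (1.0 - (abs(_GONION_Z) / _C_LOWER) ** _EXP) ** (1.0 / _EXP)

# nose wedge (mm)
_NOSE_TOP_Z = 5.0
_NOSE_LEN = 50.0
_NOSE_BOT_Z = _NOSE_TOP_Z - _NOSE_LEN
_ALAR_HALF = 17.5


@dataclass(frozen=True)
class PhantomScene:
    """Sampled phantom head with per-point region labels and fiducials."""

    surface_points: np.ndarray  # (N, 3) mm
    normals: np.ndarray  # (N, 3) unit
    region_labels: np.ndarray  # (N,) str in REGION_LABELS
    fiducials: np.ndarray  # (8, 3) mm
    craniotomy_box: np.ndarray  # (2, 3) mm: [min_corner, max_corner]

    def points_in_region(self, label: str) -> np.ndarray:
        return self.surface_points[self.region_labels == label]


@dataclass(frozen=True)
class CameraNoisePreset:
    """Depth-sensor noise model; all lengths mm, dropout a fraction."""

    name: str
    axial_sigma_mm: float
    lateral_sigma_mm: float
    dropout_rate: float
    quantization_mm: float
    range_min_mm: float
    range_max_mm: float

    def __post_init__(self):
        vals = (
            self.axial_sigma_mm,
            self.lateral_sigma_mm,
            self.dropout_rate,
            self.quantization_mm,
            self.range_min_mm,
            self.range_max_mm,
        )
        if any(v < 0 for v in vals):
            raise ConfigError("noise preset fields must be non-negative")
        if not self.range_min_mm < self.range_max_mm:
            raise ConfigError("range_min_mm must be < range_max_mm")


@dataclass(frozen=True)
class TrackingNoise:
    """Optical-tracker rigid-body jitter."""

    rot_sigma_deg: float = 0.0
    trans_sigma_mm: float = 0.0

    def __post_init__(self):
        if self.rot_sigma_deg < 0 or self.trans_sigma_mm < 0:
            raise ConfigError("tracking noise must be non-negative")


# ---------------------------------------------------------------------------
# phantom head
# ---------------------------------------------------------------------------


def _c_of_z(z):
    return np.where(z < 0, _C_LOWER, _C_UPPER)


def _implicit(pts):
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    c = _c_of_z(z)
    return (
        np.abs(x / _A_WIDTH) ** _EXP
        + np.abs(y / _B_DEPTH) ** _EXP
        + np.abs(z / c) ** _EXP
    )


def _surface_normal(pts):
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    c = _c_of_z(z)
    g = np.column_stack(
        [
            np.sign(x) * np.abs(x / _A_WIDTH) ** (_EXP - 1) / _A_WIDTH,
            np.sign(y) * np.abs(y / _B_DEPTH) ** (_EXP - 1) / _B_DEPTH,
            np.sign(z) * np.abs(z / c) ** (_EXP - 1) / c,
        ]
    )
    n = np.linalg.norm(g, axis=1, keepdims=True)
    return g / np.maximum(n, 1e-12)


def _superellipsoid_area() -> float:
    # Thomsen-style approximation on the mean ellipsoid; only used to size
    # the sample count so that halving the spacing quadruples the points
    a, b, c = _A_WIDTH, _B_DEPTH, 0.5 * (_C_LOWER + _C_UPPER)
    p = 1.6075
    return float(4 * np.pi * (((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3) ** (1 / p))


def _fibonacci_directions(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _nose_half_width(z):
    frac = np.clip((_NOSE_TOP_Z - z) / _NOSE_LEN, 0.0, 1.0)
    # never fully vanishes at the nasion so the tip row carries points
    return _ALAR_HALF * (0.02 + 0.98 * frac) ** 0.8


def _nose_height(x, z):
    base = 4.0 + 18.0 * (_NOSE_TOP_Z - z) / _NOSE_LEN
    w = _nose_half_width(z)
    r = np.abs(x) / np.maximum(w, 1e-9)
    # quartic falloff with a 10% residual rim so the alar edge is measurable
    return np.where(r <= 1.0, base * (1.0 - 0.9 * r**4), 0.0)


def _front_y(x, z):
    """y > 0 surface height of the cranium at (x, z); nan outside."""
    c = _c_of_z(np.asarray(z, float))
    rest = 1.0 - np.abs(x / _A_WIDTH) ** _EXP - np.abs(z / c) ** _EXP
    return np.where(rest > 0, _B_DEPTH * np.maximum(rest, 0) ** (1.0 / _EXP), np.nan)


def _face_features(x, z):
    """Forward (+y) relief of the facial features other than the nose (mm):
    brow ridge, eye-socket depressions, lip ridge and chin boss. These break
    the tangential sliding symmetry of the bare cranium dome, as the
    features of a real face do."""
    brow = 5.0 * np.exp(-(((z - 38.0) / 8.0) ** 2)) * np.exp(-((x / 30.0) ** 4))
    eyes = -7.0 * (
        np.exp(-(((x - 26.0) / 10.0) ** 2) - (((z - 22.0) / 8.0) ** 2))
        + np.exp(-(((x + 26.0) / 10.0) ** 2) - (((z - 22.0) / 8.0) ** 2))
    )
    cheeks = 3.5 * (
        np.exp(-(((x - 42.0) / 12.0) ** 2) - ((z - 2.0) / 12.0) ** 2)
        + np.exp(-(((x + 42.0) / 12.0) ** 2) - ((z - 2.0) / 12.0) ** 2)
    )
    lips = 4.0 * np.exp(-(((z + 66.0) / 6.0) ** 2)) * np.exp(-((x / 22.0) ** 4))
    chin = 6.0 * np.exp(-(((z + 80.0) / 10.0) ** 2) - ((x / 16.0) ** 2))
    return brow + eyes + cheeks + lips + chin


_CRANIOTOMY_DIR = np.array([0.35, -0.45, 0.82]) / np.linalg.norm([0.35, -0.45, 0.82])

_FIDUCIAL_DIRS = np.array(
    [
        [0.9, 0.3, 0.3],
        [-0.9, 0.3, 0.3],
        [0.6, 0.6, -0.5],
        [-0.6, 0.6, -0.5],
        [0.8, -0.4, 0.45],
        [-0.8, -0.4, 0.45],
        [0.15, 0.55, 0.82],
        [0.0, -0.95, 0.1],
    ]
)


def _project_to_surface(directions: np.ndarray) -> np.ndarray:
    d = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    scale = _implicit(d) ** (-1.0 / _EXP)
    return d * scale[:, None]


def generate_phantom_head(
    seed: int = 0,
    point_spacing_mm: float = 1.5,
    craniotomy_diameter_mm: float = 70.0,
) -> PhantomScene:
    """Build the phantom head cloud.

    Deterministic for a given seed. The cranium is sampled via a Fibonacci
    sphere projected onto the superellipsoid at a density of one point per
    ``point_spacing_mm``-square; the nose wedge and neck are grid-sampled at
    the same spacing. Anthropometric targets (bigonial width 118 mm, nose
    length 50 mm, alar base 35 mm) hold to within the sampling step and are
    re-measurable with :func:`measure_anthropometrics`.
    """
    if not (0.2 < point_spacing_mm < 5.0):
        raise DataError(f"point_spacing_mm must be in (0.2, 5), got {point_spacing_mm}")
    # shape parameters and sampling jitter use independent streams so the
    # same seed yields the same head geometry at every sampling density
    rng_shape = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    s = float(point_spacing_mm)

    n_cranium = int(_superellipsoid_area() / s**2)
    dirs = _fibonacci_directions(n_cranium)
    # tiny deterministic jitter so regular-grid artefacts do not alias with
    # the virtual depth-pixel grid
    dirs = dirs + rng.normal(scale=1e-3, size=dirs.shape)
    cranium = _project_to_surface(dirs)
    cran_normals = _surface_normal(cranium)

    # facial relief (brow/eyes/lips/chin) on the front of the cranium
    y0 = _front_y(cranium[:, 0], cranium[:, 2])
    frontal = np.isfinite(y0) & (cranium[:, 1] > 0.5 * np.nan_to_num(y0))
    dy = _face_features(cranium[:, 0], cranium[:, 2])
    # seeded aperiodic relief: real faces are asymmetric and non-repeating,
    # which is what gives surface registration a single deep optimum; a
    # smooth window suppresses it around the nose and the anthropometric
    # measurement zones so those stay exact
    xb = rng_shape.uniform(-55.0, 55.0, size=12)
    zb = rng_shape.uniform(-85.0, 55.0, size=12)
    amp = rng_shape.uniform(-3.5, 3.5, size=12)
    sig = rng_shape.uniform(12.0, 22.0, size=12)
    x, z = cranium[:, 0], cranium[:, 2]
    bumps = np.zeros(len(cranium))
    for k in range(12):
        bumps += amp[k] * np.exp(
            -(((x - xb[k]) ** 2) + ((z - zb[k]) ** 2)) / sig[k] ** 2
        )
    suppress = np.exp(-((x / 26.0) ** 6)) * np.exp(-(((z + 20.0) / 34.0) ** 6))
    dy = dy + bumps * (1.0 - suppress)
    cranium[frontal, 1] += dy[frontal]

    # carve out the nose footprint on the cranium front so the wedge replaces it
    in_nose_window = (
        (cranium[:, 1] > 0)
        & (cranium[:, 2] > _NOSE_BOT_Z)
        & (cranium[:, 2] < _NOSE_TOP_Z)
        & (np.abs(cranium[:, 0]) < _nose_half_width(cranium[:, 2]))
    )
    cranium = cranium[~in_nose_window]
    cran_normals = cran_normals[~in_nose_window]

    # nose wedge: forward (+y) offset above the cranium surface
    nz = np.linspace(_NOSE_BOT_Z, _NOSE_TOP_Z, max(2, int(round(_NOSE_LEN / s)) + 1))
    nose_pts = []
    for z in nz:
        w = float(_nose_half_width(z))
        nx = np.linspace(-w, w, max(3, int(round(2 * w / s)) + 1))
        h = _nose_height(nx, np.full_like(nx, z))
        keep = h > 0.2
        if not np.any(keep):
            continue
        y0 = _front_y(nx[keep], np.full(keep.sum(), z))
        nose_pts.append(np.column_stack([nx[keep], y0 + h[keep], np.full(keep.sum(), z)]))
    nose = np.concatenate(nose_pts, axis=0)
    nose_normals = np.tile([0.0, 1.0, 0.0], (len(nose), 1))

    # neck cylinder, labeled "other"
    neck_z = np.arange(-140.0, -88.0, s)
    neck_th = np.arange(0.0, 2 * np.pi, s / 45.0)
    tt, zz = np.meshgrid(neck_th, neck_z)
    neck = np.column_stack(
        [45.0 * np.cos(tt.ravel()), 45.0 * np.sin(tt.ravel()) - 20.0, zz.ravel()]
    )
    neck_normals = np.column_stack(
        [np.cos(tt.ravel()), np.sin(tt.ravel()), np.zeros(tt.size)]
    )

    pts = np.concatenate([cranium, nose, neck], axis=0)
    normals = np.concatenate([cran_normals, nose_normals, neck_normals], axis=0)

    labels = np.full(len(pts), "scalp", dtype=object)
    labels[len(cranium) : len(cranium) + len(nose)] = "face"
    labels[len(cranium) + len(nose) :] = "other"
    is_cran = np.arange(len(pts)) < len(cranium)
    face_mask = is_cran & (pts[:, 1] > 25.0) & (pts[:, 2] > -95.0) & (pts[:, 2] < 60.0)
    labels[face_mask] = "face"

    cran_center = _project_to_surface(_CRANIOTOMY_DIR[None, :])[0]
    crani_mask = is_cran & (
        np.linalg.norm(pts - cran_center, axis=1) < craniotomy_diameter_mm / 2.0
    )
    labels[crani_mask] = "craniotomy"
    crani_pts = pts[crani_mask]
    box = np.stack([crani_pts.min(axis=0), crani_pts.max(axis=0)])

    fiducials = _project_to_surface(_FIDUCIAL_DIRS)

    labels = labels.astype("U10")
    for arr in (pts, normals, labels, fiducials, box):
        arr.setflags(write=False)
    return PhantomScene(
        surface_points=pts,
        normals=normals,
        region_labels=labels,
        fiducials=fiducials,
        craniotomy_box=box,
    )


def scene_from_files(ply_path, fiducials_csv, craniotomy_box_json) -> PhantomScene:
    """Assemble a :class:`PhantomScene` from exported files (or a real scan).

    ``ply_path`` must carry normals and a label channel; ``fiducials_csv``
    has columns x_mm,y_mm,z_mm; ``craniotomy_box_json`` has keys
    ``min_mm`` / ``max_mm``.
    """
    import json as _json

    from .ply import read_ply

    pts, normals, labels = read_ply(ply_path)
    if normals is None or labels is None:
        raise DataError(f"{ply_path}: scene PLY needs normals and a label channel")
    fid = np.loadtxt(fiducials_csv, delimiter=",", skiprows=1).reshape(-1, 3)
    with open(craniotomy_box_json) as fh:
        d = _json.load(fh)
    box = np.stack([np.asarray(d["min_mm"], float), np.asarray(d["max_mm"], float)])
    return PhantomScene(
        surface_points=pts,
        normals=normals,
        region_labels=np.asarray(labels, dtype="U10"),
        fiducials=fid,
        craniotomy_box=box,
    )


def measure_anthropometrics(scene: PhantomScene) -> dict:
    """Re-measure the facial anthropometrics from the sampled cloud (mm).

    * bigonial width: x-extent of the head in a 3 mm band at the gonion plane;
    * nose length: z-extent of points protruding > 1 mm forward of the
      cranium front surface;
    * alar base: x-extent of those protruding points in the 2.5 mm band at
      the nose base.
    """
    pts = scene.surface_points
    band = np.abs(pts[:, 2] - _GONION_Z) < 1.5
    bigonial = float(pts[band, 0].max() - pts[band, 0].min())

    window = (
        (pts[:, 1] > 0)
        & (pts[:, 2] > _NOSE_BOT_Z - 3)
        & (pts[:, 2] < _NOSE_TOP_Z + 3)
        & (np.abs(pts[:, 0]) < _ALAR_HALF + 3)
    )
    sub = pts[window]
    y0 = _front_y(sub[:, 0], sub[:, 2])
    protrusion = sub[:, 1] - y0
    nose = sub[np.nan_to_num(protrusion, nan=-1.0) > 1.0]
    nose_length = float(nose[:, 2].max() - nose[:, 2].min())
    base_band = nose[nose[:, 2] < _NOSE_BOT_Z + 2.5]
    alar = float(base_band[:, 0].max() - base_band[:, 0].min())
    return {"bigonial_mm": bigonial, "nose_length_mm": nose_length, "alar_base_mm": alar}


# ---------------------------------------------------------------------------
# tracking jitter
# ---------------------------------------------------------------------------


def simulate_tracked_pose(true_pose: RigidTransform, noise: TrackingNoise, seed) -> RigidTransform:
    """Perturb a pose with tracker jitter.

    Rotation: random axis, angle |N(0, rot_sigma_deg)|, applied in the body
    frame (the tracker errs about the rigid body itself, not about the
    tracking-volume origin). Translation: isotropic N(0, trans_sigma_mm).
    Zero noise returns the input exactly. ``seed`` may be an int or a
    Generator.
    """
    if noise.rot_sigma_deg == 0.0 and noise.trans_sigma_mm == 0.0:
        return true_pose
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = abs(rng.normal(scale=np.radians(noise.rot_sigma_deg)))
    dt = rng.normal(scale=noise.trans_sigma_mm, size=3)
    jittered = compose(true_pose, RigidTransform.from_rotvec(axis * ang))
    return RigidTransform(jittered.rotation, true_pose.translation + dt)


# ---------------------------------------------------------------------------
# intrinsic-calibration views and co-registration sessions
# ---------------------------------------------------------------------------


def default_intrinsics() -> CameraIntrinsics:
    """A 1280x720 camera with fx = fy = 800 px, centered principal point."""
    return CameraIntrinsics(fx=800.0, fy=800.0, cx=640.0, cy=360.0, width=1280, height=720)


def default_board() -> Checkerboard:
    """10x7 inner corners, 25 mm squares (config-visible default)."""
    return Checkerboard(inner_rows=7, inner_cols=10, square_mm=25.0)


def _board_in_frustum(intr, board, pose) -> bool:
    try:
        uv = project(intr, pose, board).image_points
    except Exception:
        return False
    return bool(
        np.all(uv[:, 0] >= 1)
        and np.all(uv[:, 0] <= intr.width - 2)
        and np.all(uv[:, 1] >= 1)
        and np.all(uv[:, 1] <= intr.height - 2)
    )


def _centered_board_pose(
    board, tilt_axis, tilt_deg, depth_mm, offset=(0.0, 0.0), roll_deg=0.0
) -> RigidTransform:
    """Board -> camera pose with the pattern centered at the given depth.

    ``roll_deg`` spins the pattern about its own normal (in-plane)."""
    center = np.array(
        [
            (board.inner_cols - 1) * board.square_mm / 2.0,
            (board.inner_rows - 1) * board.square_mm / 2.0,
            0.0,
        ]
    )
    tilt = Rotation.from_rotvec(np.asarray(tilt_axis, float) * np.radians(tilt_deg)).as_matrix()
    roll = Rotation.from_rotvec([0.0, 0.0, np.radians(roll_deg)]).as_matrix()
    r = tilt @ roll
    t = np.array([offset[0], offset[1], depth_mm]) - r @ center
    return RigidTransform(r, t)


def simulate_intrinsics_views(
    intr: CameraIntrinsics,
    board: Checkerboard,
    corner_noise_px: float = 0.0,
    seed: int = 0,
    depths_mm=(420.0, 620.0),
    tilt_deg: float = 22.0,
):
    """Eight synthetic calibration views: four board tilts at each of two
    depth planes, the protocol used for intrinsic characterization.

    Returns ``(observations, true_poses)`` with poses board -> camera.
    """
    rng = np.random.default_rng(seed)
    axes = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)]
    offsets = [(-40, -30), (40, 30), (-40, 30), (40, -30)]
    observations, poses = [], []
    for depth in depths_mm:
        for axis, off in zip(axes, offsets):
            pose = _centered_board_pose(board, axis, tilt_deg, depth, off)
            if not _board_in_frustum(intr, board, pose):
                raise PlacementError("calibration view outside frustum; adjust depths")
            obs = project(intr, pose, board, capture_id=f"view_{len(poses):02d}")
            uv = obs.image_points
            if corner_noise_px > 0:
                uv = uv + rng.normal(scale=corner_noise_px, size=uv.shape)
            observations.append(CornerObservation(uv, capture_id=obs.capture_id))
            poses.append(pose)
    return observations, poses


def simulate_calibration_session(
    e_true: RigidTransform,
    g_true: RigidTransform,
    intr: CameraIntrinsics,
    board: Checkerboard,
    n_captures: int = 15,
    tracking_noise: TrackingNoise = TrackingNoise(),
    corner_noise_px: float = 0.0,
    seed: int = 0,
):
    """Simulate a tracked co-registration session with known ground truth.

    For each capture a board pose ``V`` is sampled inside the camera frustum
    and a board rigid-body pose is sampled in the tracking volume; the
    camera rigid-body pose then follows from the closure
    ``M = G^{-1} V^{-1} E^{-1}``. Tracker jitter is applied to the two
    tracked poses and pixel noise to the projected corners; with pixel noise
    the stored ``V`` is re-estimated from the noisy corners, as it would be
    on real data.
    """
    if n_captures < 3:
        raise DataError("n_captures must be >= 3")
    rng = np.random.default_rng(seed)
    captures = []
    for k in range(n_captures):
        for attempt in range(60):
            tilt_axis = rng.normal(size=3)
            tilt_axis[2] *= 0.3
            tilt_axis /= np.linalg.norm(tilt_axis)
            tilt = rng.uniform(12.0, 45.0)
            roll = rng.uniform(-180.0, 180.0)
            depth = rng.uniform(350.0, 550.0)
            off = rng.uniform(-60.0, 60.0, size=2)
            v = _centered_board_pose(board, tilt_axis, tilt, depth, off, roll_deg=roll)
            if _board_in_frustum(intr, board, v):
                break
        else:
            raise PlacementError("could not place board in frustum after 60 tries")

        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        m_board_true = RigidTransform(
            Rotation.from_quat(q).as_matrix(), rng.uniform(-500.0, 500.0, size=3)
        )
        m_rel = compose(invert(g_true), compose(invert(v), invert(e_true)))
        m_camera_true = compose(m_board_true, m_rel)

        obs = project(intr, v, board, capture_id=f"cap_{k:02d}")
        if corner_noise_px > 0:
            uv = obs.image_points + rng.normal(scale=corner_noise_px, size=obs.image_points.shape)
            obs = CornerObservation(uv, capture_id=obs.capture_id)
            v_store = estimate_board_pose(intr, board, obs)
        else:
            v_store = v
        captures.append(
            TrackedCapture(
                m_camera=simulate_tracked_pose(m_camera_true, tracking_noise, rng),
                m_board=simulate_tracked_pose(m_board_true, tracking_noise, rng),
                v=v_store,
                corners=obs,
                capture_id=f"cap_{k:02d}",
            )
        )
    return captures


# ---------------------------------------------------------------------------
# depth capture
# ---------------------------------------------------------------------------

# virtual depth sensor used for visibility (z-buffer) culling
_VGRID_W, _VGRID_H, _VGRID_F = 400, 300, 600.0


def simulate_depth_capture(
    scene: PhantomScene,
    camera_pose: RigidTransform,
    preset: CameraNoisePreset,
    seed: int = 0,
    return_indices: bool = False,
):
    """Render a noisy depth capture of the scene.

    ``camera_pose`` is the optical-frame pose in the phantom frame (optical
    -> phantom). Visibility combines back-face culling with a z-buffer over
    a virtual pixel grid; surviving points get axial noise along the viewing
    ray, lateral in-plane jitter, i.i.d. dropout, optional depth
    quantization, and removal outside the preset working range.

    Returns the camera-frame cloud (mm), plus the surviving scene indices
    when ``return_indices`` is set (the simulator's stand-in for an image
    segmentation of the capture).
    """
    rng = np.random.default_rng(seed)
    world_to_cam = invert(camera_pose)
    pts = apply(world_to_cam, scene.surface_points)
    nrm = scene.normals @ world_to_cam.rotation.T
    idx = np.arange(len(pts))

    infront = pts[:, 2] > 1.0
    pts, nrm, idx = pts[infront], nrm[infront], idx[infront]
    if len(pts) == 0:
        raise VisibilityError("no scene point in front of the camera")

    rays = pts / np.linalg.norm(pts, axis=1, keepdims=True)
    facing = np.einsum("ij,ij->i", nrm, rays) < -0.05
    pts, idx = pts[facing], idx[facing]
    rays = rays[facing]
    if len(pts) == 0:
        raise VisibilityError("no front-facing surface visible")

    # z-buffer on the virtual grid: keep the nearest point per pixel and
    # drop points occluded by a meaningfully nearer surface in their pixel
    u = np.clip((_VGRID_F * pts[:, 0] / pts[:, 2] + _VGRID_W / 2).astype(int), 0, _VGRID_W - 1)
    v = np.clip((_VGRID_F * pts[:, 1] / pts[:, 2] + _VGRID_H / 2).astype(int), 0, _VGRID_H - 1)
    pix = u * _VGRID_H + v
    order = np.lexsort((pts[:, 2], pix))
    pix_sorted = pix[order]
    first = np.r_[True, pix_sorted[1:] != pix_sorted[:-1]]
    nearest_z = np.repeat(pts[order][first, 2], np.diff(np.r_[np.nonzero(first)[0], len(pix)]))
    visible_sorted = pts[order][:, 2] <= nearest_z + 3.0  # occlusion margin, mm
    keep = order[visible_sorted]
    pts, idx, rays = pts[keep], idx[keep], rays[keep]

    in_range = (pts[:, 2] >= preset.range_min_mm) & (pts[:, 2] <= preset.range_max_mm)
    pts, idx, rays = pts[in_range], idx[in_range], rays[in_range]
    if len(pts) == 0:
        raise VisibilityError(
            f"no visible point within the {preset.name} working range "
            f"[{preset.range_min_mm:.0f}, {preset.range_max_mm:.0f}] mm"
        )

    if preset.dropout_rate > 0:
        keep = rng.random(len(pts)) >= preset.dropout_rate
        pts, idx, rays = pts[keep], idx[keep], rays[keep]
        if len(pts) == 0:
            raise VisibilityError("dropout removed every visible point")

    if preset.axial_sigma_mm > 0:
        pts = pts + rays * rng.normal(scale=preset.axial_sigma_mm, size=(len(pts), 1))
    if preset.lateral_sigma_mm > 0:
        ortho1 = np.cross(rays, [0.0, 0.0, 1.0])
        ortho1 /= np.maximum(np.linalg.norm(ortho1, axis=1, keepdims=True), 1e-9)
        ortho2 = np.cross(rays, ortho1)
        pts = pts + ortho1 * rng.normal(scale=preset.lateral_sigma_mm, size=(len(pts), 1))
        pts = pts + ortho2 * rng.normal(scale=preset.lateral_sigma_mm, size=(len(pts), 1))
    if preset.quantization_mm > 0:
        pts[:, 2] = np.round(pts[:, 2] / preset.quantization_mm) * preset.quantization_mm

    final = (pts[:, 2] >= preset.range_min_mm) & (pts[:, 2] <= preset.range_max_mm)
    pts, idx = pts[final], idx[final]
    if len(pts) == 0:
        raise VisibilityError("noise pushed every point outside the working range")
    if return_indices:
        return pts, idx
    return pts


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

_BUILTIN = [
    # working ranges follow the published sensor specs; noise magnitudes are
    # this package's own estimates chosen to separate the technology classes
    CameraNoisePreset("d405", 0.30, 0.10, 0.02, 0.0, 70.0, 500.0),
    CameraNoisePreset("d435f", 0.80, 0.20, 0.05, 0.0, 300.0, 3000.0),
    CameraNoisePreset("d435f-no-projector", 4.00, 1.00, 0.45, 0.0, 300.0, 3000.0),
    CameraNoisePreset("zed-m", 3.00, 0.80, 0.35, 0.0, 100.0, 9000.0),
    CameraNoisePreset("zed-m-plus", 0.60, 0.20, 0.03, 0.0, 100.0, 9000.0),
    CameraNoisePreset("oak-d", 5.00, 1.50, 0.50, 0.0, 300.0, 1000.0),
    CameraNoisePreset("photoneo-s", 0.25, 0.08, 0.01, 0.10, 330.0, 550.0),
]


def builtin_presets():
    """The seven built-in camera configurations (five cameras; the stereo-IR
    camera with its projector disabled and the RGB-stereo camera with neural
    refinement count as extra configurations)."""
    return list(_BUILTIN)


def get_preset(name: str) -> CameraNoisePreset:
    """Look up a built-in preset; the special name "null" returns an ideal
    noise-free sensor (not part of the seven built-ins) for closure tests."""
    if name == "null":
        return CameraNoisePreset("null", 0.0, 0.0, 0.0, 0.0, 70.0, 2000.0)
    for p in _BUILTIN:
        if p.name == name:
            return p
    raise ConfigError(f"unknown preset {name!r}; known: {[p.name for p in _BUILTIN]}")


def save_presets(path, presets) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({p.name: {k: v for k, v in asdict(p).items() if k != "name"} for p in presets}, fh)


def load_presets(path):
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return [CameraNoisePreset(name=k, **v) for k, v in d.items()]


# ---------------------------------------------------------------------------
# camera placement helpers
# ---------------------------------------------------------------------------


def look_at(eye, target, up=(0.0, 0.0, 1.0)) -> RigidTransform:
    """Optical-frame pose (optical -> world): z toward ``target``, y down."""
    eye = np.asarray(eye, float)
    fwd = np.asarray(target, float) - eye
    fwd /= np.linalg.norm(fwd)
    right = np.cross(fwd, np.asarray(up, float))
    n = np.linalg.norm(right)
    if n < 1e-9:
        right = np.cross(fwd, [0.0, 1.0, 0.0])
        n = np.linalg.norm(right)
    right /= n
    down = np.cross(fwd, right)
    return RigidTransform(np.column_stack([right, down, fwd]), eye)


_FACE_TARGET = np.array([0.0, 55.0, -25.0])


def face_viewpoints(n: int, seed: int, standoff_mm: float = 442.0):
    """Optical poses facing the phantom face (phantom frame), jittered in
    azimuth/elevation/distance around the nominal standoff."""
    rng = np.random.default_rng(seed)
    poses = []
    for _ in range(n):
        az = np.radians(rng.uniform(-22.0, 22.0))
        el = np.radians(rng.uniform(-8.0, 18.0))
        dist = standoff_mm + rng.uniform(-35.0, 35.0)
        d = np.array([np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)])
        poses.append(look_at(_FACE_TARGET + d * dist, _FACE_TARGET))
    return poses


def craniotomy_viewpoints(scene: PhantomScene, n: int, seed: int, standoff_mm: float = 454.0):
    """Optical poses looking down onto the craniotomy region."""
    rng = np.random.default_rng(seed)
    center = 0.5 * (scene.craniotomy_box[0] + scene.craniotomy_box[1])
    normal = _CRANIOTOMY_DIR
    poses = []
    for _ in range(n):
        wiggle = rng.normal(scale=0.12, size=3)
        d = normal + wiggle
        d /= np.linalg.norm(d)
        dist = standoff_mm + rng.uniform(-40.0, 40.0)
        poses.append(look_at(center + d * dist, center, up=(0.0, 1.0, 0.0)))
    return poses
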