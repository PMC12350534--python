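"""Pinhole camera model, checkerboard geometry and Zhang-style calibration.

Image coordinates: origin at the top-left pixel center, x right, y down,
units px. Distortion is the Brown–Conrady model with radial (k1, k2, k3)
and tangential (p1, p2) terms; all-zero coefficients give an ideal pinhole.

Board poses throughout this module map board-frame coordinates into the
camera optical frame (the raw perspective-n-point direction); this is the
transform called V in the co-registration chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import least_squares

from .exceptions import (
    ConfigError,
    DataError,
    DegenerateConfigurationError,
    IllConditionedError,
    PoseEstimationError,
    ProjectionDomainError,
)
from .geometry import RigidTransform

__all__ = [
    "CameraIntrinsics",
    "Checkerboard",
    "CornerObservation",
    "project",
    "project_points",
    "estimate_homography",
    "zhang_calibrate",
    "estimate_board_pose",
    "reprojection_error_px",
    "read_intrinsics",
    "write_intrinsics",
    "read_corners_csv",
    "write_corners_csv",
]


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics (px) plus Brown–Conrady distortion coefficients."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    p1: float = 0.0
    p2: float = 0.0

    def __post_init__(self):
        if not (self.fx > 0 and self.fy > 0):
            raise ConfigError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ConfigError("principal point must lie inside the sensor")

    @property
    def k_matrix(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    @property
    def distortion(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.p1, self.p2])


@dataclass(frozen=True)
class Checkerboard:
    """Planar checkerboard described by its inner-corner grid.

    ``inner_rows != inner_cols`` so the board orientation is unambiguous.
    Corners lie on the z = 0 plane of the board frame, row-major from the
    board origin, spaced ``square_mm`` apart.
    """

    inner_rows: int
    inner_cols: int
    square_mm: float

    def __post_init__(self):
        if self.inner_rows == self.inner_cols:
            raise ConfigError("inner_rows must differ from inner_cols (orientation)")
        if self.inner_rows < 3 or self.inner_cols < 3:
            raise ConfigError("need at least a 3x3 inner-corner grid")
        if self.square_mm <= 0:
            raise ConfigError("square_mm must be positive")

    @property
    def n_corners(self) -> int:
        return self.inner_rows * self.inner_cols

    @property
    def corner_points(self) -> np.ndarray:
        """(rows*cols, 3) corner coordinates (mm) in the board frame, z = 0."""
        r, c = np.mgrid[0 : self.inner_rows, 0 : self.inner_cols]
        pts = np.column_stack(
            [c.ravel() * self.square_mm, r.ravel() * self.square_mm, np.zeros(self.n_corners)]
        )
        return pts


@dataclass(frozen=True)
class CornerObservation:
    """Detected 2-D corners (px) for one capture, board-corner order."""

    image_points: np.ndarray
    capture_id: str = ""

    def __post_init__(self):
        pts = np.asarray(self.image_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise DataError(f"image_points must be (N, 2), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise DataError("non-finite corner coordinates")
        pts = pts.copy()
        pts.setflags(write=False)
        object.__setattr__(self, "image_points", pts)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def _distort_normalized(xy: np.ndarray, dist: np.ndarray) -> np.ndarray:
    k1, k2, k3, p1, p2 = dist
    x, y = xy[:, 0], xy[:, 1]
    r2 = x * x + y * y
    radial = 1.0 + k1 * r2 + k2 * r2**2 + k3 * r2**3
    xd = x * radial + 2.0 * p1 * x * y + p2 * (r2 + 2.0 * x * x)
    yd = y * radial + p1 * (r2 + 2.0 * y * y) + 2.0 * p2 * x * y
    return np.column_stack([xd, yd])


def _undistort_normalized(xy: np.ndarray, dist: np.ndarray, iters: int = 25) -> np.ndarray:
    """Invert the Brown–Conrady map by fixed-point iteration."""
    und = xy.copy()
    for _ in range(iters):
        d = _distort_normalized(und, dist) - und
        und = xy - d
    return und


def project_points(intr: CameraIntrinsics, points_cam: np.ndarray) -> np.ndarray:
    """Project camera-frame points (mm) to pixel coordinates.

    Raises :class:`ProjectionDomainError` if any point has z <= 0.
    """
    p = np.asarray(points_cam, dtype=float)
    if np.any(p[:, 2] <= 0):
        raise ProjectionDomainError("point behind camera (z <= 0)")
    norm = p[:, :2] / p[:, 2:3]
    dist = _distort_normalized(norm, intr.distortion)
    uv = dist * np.array([intr.fx, intr.fy]) + np.array([intr.cx, intr.cy])
    return uv


def project(
    intr: CameraIntrinsics, pose: RigidTransform, board: Checkerboard, capture_id: str = ""
) -> CornerObservation:
    """Project the board corners through a board->camera pose."""
    from .geometry import apply

    pts_cam = apply(pose, board.corner_points)
    return CornerObservation(project_points(intr, pts_cam), capture_id=capture_id)


def reprojection_error_px(
    intr: CameraIntrinsics,
    pose: RigidTransform,
    board: Checkerboard,
    obs: CornerObservation,
):
    """Mean and std of per-corner Euclidean reprojection distances (px)."""
    pred = project(intr, pose, board).image_points
    d = np.linalg.norm(pred - obs.image_points, axis=1)
    return float(d.mean()), float(d.std())


# ---------------------------------------------------------------------------
# homography estimation (normalized DLT)
# ---------------------------------------------------------------------------


def _normalizing_similarity(pts: np.ndarray) -> np.ndarray:
    c = pts.mean(axis=0)
    s = np.sqrt(2.0) / max(np.mean(np.linalg.norm(pts - c, axis=1)), 1e-12)
    return np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1.0]])


def estimate_homography(board_xy, image_points) -> np.ndarray:
    """Normalized-DLT homography mapping board plane (mm) to image (px).

    Returned scaled so that H[2, 2] = 1.
    """
    src = np.asarray(board_xy, dtype=float)
    dst = np.asarray(image_points, dtype=float)
    if src.shape[0] < 4 or src.shape != dst.shape:
        raise DegenerateConfigurationError("need >= 4 matched points")
    ts = _normalizing_similarity(src)
    td = _normalizing_similarity(dst)
    sh = np.column_stack([src, np.ones(len(src))]) @ ts.T
    dh = np.column_stack([dst, np.ones(len(dst))]) @ td.T
    a = []
    for (x, y, _), (u, v, _) in zip(sh, dh):
        a.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        a.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    a = np.asarray(a)
    _, s, vt = np.linalg.svd(a)
    if s[-2] < 1e-9 * s[0]:
        raise DegenerateConfigurationError("degenerate point configuration for homography")
    h = vt[-1].reshape(3, 3)
    h = np.linalg.inv(td) @ h @ ts
    if abs(h[2, 2]) < 1e-12:
        raise DegenerateConfigurationError("homography has vanishing scale")
    return h / h[2, 2]


# ---------------------------------------------------------------------------
# Zhang closed form + joint refinement
# ---------------------------------------------------------------------------


def _zhang_vij(h: np.ndarray, i: int, j: int) -> np.ndarray:
    return np.array(
        [
            h[0, i] * h[0, j],
            h[0, i] * h[1, j] + h[1, i] * h[0, j],
            h[1, i] * h[1, j],
            h[2, i] * h[0, j] + h[0, i] * h[2, j],
            h[2, i] * h[1, j] + h[1, i] * h[2, j],
            h[2, i] * h[2, j],
        ]
    )


def _intrinsics_from_homographies(hs, width, height) -> CameraIntrinsics:
    v = []
    for h in hs:
        v.append(_zhang_vij(h, 0, 1))
        v.append(_zhang_vij(h, 0, 0) - _zhang_vij(h, 1, 1))
    v = np.asarray(v)
    _, s, vt = np.linalg.svd(v)
    if s[0] / max(s[-2], 1e-300) > 1e12:
        raise IllConditionedError(
            f"near-coplanar view set (singular-value ratio {s[0] / s[-2]:.3g})"
        )
    b = vt[-1]
    b11, b12, b22, b13, b23, b33 = b
    den = b11 * b22 - b12**2
    if abs(den) < 1e-300 or b11 == 0:
        raise IllConditionedError("degenerate intrinsic constraint matrix")
    v0 = (b12 * b13 - b11 * b23) / den
    lam = b33 - (b13**2 + v0 * (b12 * b13 - b11 * b23)) / b11
    if lam / b11 <= 0:
        # the homogeneous solution is defined up to sign
        b = -b
        b11, b12, b22, b13, b23, b33 = b
        den = b11 * b22 - b12**2
        v0 = (b12 * b13 - b11 * b23) / den
        lam = b33 - (b13**2 + v0 * (b12 * b13 - b11 * b23)) / b11
    if lam / b11 <= 0 or lam * b11 / den <= 0:
        raise IllConditionedError("intrinsic constraints not positive definite")
    alpha = float(np.sqrt(lam / b11))
    beta = float(np.sqrt(lam * b11 / den))
    gamma = -b12 * alpha**2 * beta / lam  # skew; dropped from the model
    u0 = gamma * v0 / beta - b13 * alpha**2 / lam
    u0 = float(np.clip(u0, 0.0, width - 1))
    v0 = float(np.clip(v0, 0.0, height - 1))
    return CameraIntrinsics(fx=alpha, fy=beta, cx=u0, cy=v0, width=width, height=height)


def _pose_from_homography(k: np.ndarray, h: np.ndarray) -> RigidTransform:
    kin = np.linalg.inv(k)
    h1, h2, h3 = (kin @ h[:, i] for i in range(3))
    lam = 1.0 / max(np.linalg.norm(h1), 1e-300)
    if (lam * h3)[2] < 0:  # board must be in front of the camera
        lam = -lam
    r1 = lam * h1
    r2 = lam * h2
    r3 = np.cross(r1, r2)
    r = np.column_stack([r1, r2, r3])
    u, _, vt = np.linalg.svd(r)
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, 1.0, d]) @ vt
    return RigidTransform(r, lam * h3)


def _pack_params(intr: CameraIntrinsics, poses) -> np.ndarray:
    p = [intr.fx, intr.fy, intr.cx, intr.cy, intr.k1, intr.k2, intr.k3, intr.p1, intr.p2]
    for pose in poses:
        p.extend(pose.rotvec())
        p.extend(pose.translation)
    return np.asarray(p, dtype=float)


def _unpack_params(x: np.ndarray, width: int, height: int, n_views: int):
    fx, fy, cx, cy, k1, k2, k3, p1, p2 = x[:9]
    intr = CameraIntrinsics(
        fx=fx,
        fy=fy,
        cx=float(np.clip(cx, 0, width - 1e-6)),
        cy=float(np.clip(cy, 0, height - 1e-6)),
        width=width,
        height=height,
        k1=k1,
        k2=k2,
        k3=k3,
        p1=p1,
        p2=p2,
    )
    poses = []
    for i in range(n_views):
        seg = x[9 + 6 * i : 15 + 6 * i]
        poses.append(RigidTransform.from_rotvec(seg[:3], seg[3:]))
    return intr, poses


def zhang_calibrate(observations, board: Checkerboard, width: int = 1280, height: int = 720):
    """Recover intrinsics + distortion + per-view board poses from corner
    observations of a planar checkerboard.

    Closed-form intrinsics from the homography constraints, followed by a
    joint Levenberg–Marquardt-style least-squares refinement of intrinsics,
    distortion and per-view board->camera poses minimizing total squared
    reprojection error.

    Returns ``(CameraIntrinsics, [RigidTransform board->camera])``.
    """
    observations = list(observations)
    if len(observations) < 3:
        raise IllConditionedError(f"need >= 3 views, got {len(observations)}")
    xy = board.corner_points[:, :2]
    hs = [estimate_homography(xy, obs.image_points) for obs in observations]
    intr0 = _intrinsics_from_homographies(hs, width, height)
    poses0 = [_pose_from_homography(intr0.k_matrix, h) for h in hs]

    obs_stack = np.concatenate([o.image_points for o in observations], axis=0)

    def residuals(x):
        intr, poses = _unpack_params(x, width, height, len(observations))
        preds = []
        for pose in poses:
            pts = board.corner_points @ pose.rotation.T + pose.translation
            z = np.maximum(pts[:, 2], 1e-6)
            norm = pts[:, :2] / z[:, None]
            duv = _distort_normalized(norm, intr.distortion)
            preds.append(duv * np.array([intr.fx, intr.fy]) + np.array([intr.cx, intr.cy]))
        return (np.concatenate(preds, axis=0) - obs_stack).ravel()

    x0 = _pack_params(intr0, poses0)
    sol = least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                        max_nfev=200 * len(x0))
    intr, poses = _unpack_params(sol.x, width, height, len(observations))
    return intr, poses


# ---------------------------------------------------------------------------
# single-view board pose (perspective-n-point on the board plane)
# ---------------------------------------------------------------------------


def estimate_board_pose(
    intr: CameraIntrinsics, board: Checkerboard, obs: CornerObservation
) -> RigidTransform:
    """Board pose in the camera optical frame (board -> camera; the V of the
    co-registration chain).

    Pipeline: undistort corners, planar-homography decomposition for an
    initial pose, then iterative reprojection-error minimization with the
    full distortion model.
    """
    if obs.image_points.shape[0] != board.n_corners:
        raise DataError(
            f"observation has {obs.image_points.shape[0]} corners, board has {board.n_corners}"
        )
    norm = (obs.image_points - np.array([intr.cx, intr.cy])) / np.array([intr.fx, intr.fy])
    und = _undistort_normalized(norm, intr.distortion)
    h = estimate_homography(board.corner_points[:, :2], und)
    pose0 = _pose_from_homography(np.eye(3), h)

    def residuals(x):
        pose = RigidTransform.from_rotvec(x[:3], x[3:])
        pts = board.corner_points @ pose.rotation.T + pose.translation
        z = np.maximum(pts[:, 2], 1e-6)
        duv = _distort_normalized(pts[:, :2] / z[:, None], intr.distortion)
        pred = duv * np.array([intr.fx, intr.fy]) + np.array([intr.cx, intr.cy])
        return (pred - obs.image_points).ravel()

    x0 = np.concatenate([pose0.rotvec(), pose0.translation])
    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not np.all(np.isfinite(sol.x)):
        raise PoseEstimationError("board pose refinement diverged")
    pose = RigidTransform.from_rotvec(sol.x[:3], sol.x[3:])
    # board normal vs viewing direction: nearly edge-on boards are unstable
    tilt = np.degrees(np.arccos(np.clip(abs(pose.rotation[2, 2]), 0.0, 1.0)))
    if tilt > 85.0:
        warnings.warn(f"board nearly edge-on (tilt {tilt:.1f} deg); pose may be unstable")
    if pose.translation[2] <= 0:
        raise PoseEstimationError("estimated board lies behind the camera")
    return pose


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

_INTR_KEYS = ["fx", "fy", "cx", "cy", "k1", "k2", "k3", "p1", "p2", "width", "height"]


def write_intrinsics(path, intr: CameraIntrinsics) -> None:
    d = {k: getattr(intr, k) for k in _INTR_KEYS}
    d = {k: (int(v) if k in ("width", "height") else float(v)) for k, v in d.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_intrinsics(path) -> CameraIntrinsics:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    missing = [k for k in _INTR_KEYS if k not in d]
    if missing:
        raise ConfigError(f"intrinsics file {path} missing keys {missing}")
    unknown = [k for k in d if k not in _INTR_KEYS]
    if unknown:
        raise ConfigError(f"intrinsics file {path} has unknown keys {unknown}")
    return CameraIntrinsics(**d)


def write_board(path, board: Checkerboard) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "inner_rows": board.inner_rows,
                "inner_cols": board.inner_cols,
                "square_mm": float(board.square_mm),
            },
            fh,
            sort_keys=False,
        )


def read_board(path) -> Checkerboard:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    try:
        return Checkerboard(**d)
    except TypeError as exc:
        raise ConfigError(f"board file {path}: {exc}") from exc


def write_corners_csv(path, observations) -> None:
    rows = []
    for obs in observations:
        for idx, (u, v) in enumerate(obs.image_points):
            rows.append((obs.capture_id, idx, u, v))
    pd.DataFrame(rows, columns=["capture_id", "corner_index", "u_px", "v_px"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_corners_csv(path):
    df = pd.read_csv(path, float_precision="round_trip")
    need = ["capture_id", "corner_index", "u_px", "v_px"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ConfigError(f"corners file {path} missing columns {missing}")
    out = []
    for cid, grp in df.groupby("capture_id", sort=False):
        grp = grp.sort_values("corner_index")
        out.append(CornerObservation(grp[["u_px", "v_px"]].to_numpy(), capture_id=str(cid)))
    return out
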