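"""Rigid-body (SE(3)) primitives used by every frame chain in the pipeline.

Conventions (stated once, used everywhere):

* Column-vector, point-mapping transforms: ``p' = R @ p + t``.
* A transform documented as "A -> B" re-expresses coordinates given in frame A
  in frame B.
* All translations and point coordinates are in millimetres.

Rotations are stored as 3x3 matrices; unit quaternions are used internally
only for averaging (:func:`mean_transform`) and for the pose-table file
format.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .exceptions import (
    AmbiguousMeanError,
    DataError,
    DegenerateConfigurationError,
    FormatError,
    InvalidTransformError,
)

__all__ = [
    "RigidTransform",
    "compose",
    "invert",
    "apply",
    "rigid_fit",
    "mean_transform",
    "rotation_geodesic_deg",
    "random_transform",
    "read_pose_csv",
    "write_pose_csv",
    "read_pose_json",
    "write_pose_json",
]

_ORTHO_TOL = 1e-9
_DRIFT_TOL = 1e-12


def _orthonormalize(r: np.ndarray) -> np.ndarray:
    """Project a near-rotation matrix onto SO(3) via SVD."""
    u, _, vt = np.linalg.svd(r)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


@dataclass(frozen=True)
class RigidTransform:
    """An element of SE(3): proper rotation plus translation (mm).

    Invariants (checked at construction): ``R.T @ R == I`` to 1e-9 and
    ``det(R) == +1``.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(-1)
        if r.shape != (3, 3) or t.shape != (3,):
            raise InvalidTransformError(
                f"expected 3x3 rotation and 3-vector translation, got {r.shape} / {t.shape}"
            )
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(t))):
            raise InvalidTransformError("non-finite entries in transform")
        err = np.linalg.norm(r.T @ r - np.eye(3))
        if err > _ORTHO_TOL:
            raise InvalidTransformError(f"rotation not orthonormal (|R'R - I| = {err:.3g})")
        if np.linalg.det(r) < 0:
            raise InvalidTransformError("rotation has det -1 (reflection)")
        r = r.copy()
        t = t.copy()
        r.setflags(write=False)
        t.setflags(write=False)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    # -- constructors ---------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Axis-angle 3-vector (radians) plus translation (mm)."""
        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(), translation)

    @classmethod
    def from_quat_wxyz(cls, qw, qx, qy, qz, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        q = np.array([qx, qy, qz, qw], dtype=float)
        n = np.linalg.norm(q)
        if n == 0 or not np.isfinite(n):
            raise InvalidTransformError("zero or non-finite quaternion")
        qu = q / n
        t = cls(Rotation.from_quat(qu).as_matrix(), translation)
        # cache the source quaternion so quaternion-form serialization
        # round-trips bit-exactly (matrix<->quaternion conversion and even
        # renormalization wobble in the last ulp)
        qs = q if abs(n - 1.0) < 1e-9 else qu
        qc = np.array([qs[3], qs[0], qs[1], qs[2]])
        if qc[0] < 0:
            qc = -qc
        object.__setattr__(t, "_quat_cache", qc)
        return t

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise InvalidTransformError(f"expected 4x4 matrix, got {m.shape}")
        return cls(m[:3, :3], m[:3, 3])

    # -- views ----------------------------------------------------------
    def as_quat_wxyz(self) -> np.ndarray:
        """Unit quaternion (qw, qx, qy, qz), canonicalized to qw >= 0."""
        cached = getattr(self, "_quat_cache", None)
        if cached is not None:
            return cached.copy()
        x, y, z, w = Rotation.from_matrix(self.rotation).as_quat()
        q = np.array([w, x, y, z])
        if q[0] < 0:
            q = -q
        return q

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def rotvec(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_rotvec()

    def __repr__(self):  # short, log-friendly
        ang = np.degrees(np.linalg.norm(self.rotvec()))
        return f"RigidTransform(angle={ang:.3f} deg, t={np.round(self.translation, 3)} mm)"


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Composition a∘b: maps a point p as a(b(p)).

    Re-orthonormalizes the rotation product if numerical drift exceeds 1e-12.
    """
    r = a.rotation @ b.rotation
    if np.linalg.norm(r.T @ r - np.eye(3)) > _DRIFT_TOL:
        r = _orthonormalize(r)
    t = a.rotation @ b.translation + a.translation
    return RigidTransform(r, t)


def invert(t: RigidTransform) -> RigidTransform:
    """Inverse transform: compose(t, invert(t)) is the identity."""
    rt = t.rotation.T
    return RigidTransform(rt, -rt @ t.translation)


def apply(t: RigidTransform, points) -> np.ndarray:
    """Map an (N, 3) array of points (mm) through the transform.

    A single 3-vector is accepted and returned as a 3-vector.
    """
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if p.shape[1] != 3:
        raise DataError(f"points must be (N, 3), got {p.shape}")
    if not np.all(np.isfinite(p)):
        raise DataError("non-finite point coordinates")
    out = p @ t.rotation.T + t.translation
    return out[0] if single else out


def rigid_fit(source, target) -> RigidTransform:
    """Least-squares rigid alignment of index-paired point sets (Kabsch).

    Returns the proper-rotation minimizer of sum ||T(s_i) - t_i||^2; the
    reflection branch of the SVD solution is rejected by sign correction.
    Raises :class:`DegenerateConfigurationError` for N < 3 or collinear
    sources.
    """
    s = np.asarray(source, dtype=float)
    t = np.asarray(target, dtype=float)
    if s.shape != t.shape or s.ndim != 2 or s.shape[1] != 3:
        raise DataError(f"source/target must be matching (N, 3) arrays, got {s.shape}/{t.shape}")
    n = s.shape[0]
    if n < 3:
        raise DegenerateConfigurationError(f"need at least 3 correspondences, got {n}")
    cs = s.mean(axis=0)
    ct = t.mean(axis=0)
    s0 = s - cs
    t0 = t - ct
    sv = np.linalg.svd(s0, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise DegenerateConfigurationError("source points are collinear")
    h = s0.T @ t0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, ct - r @ cs)


def mean_transform(transforms) -> RigidTransform:
    """Average of rigid transforms: arithmetic mean translation, chordal
    mean rotation.

    The rotation mean is the unit-quaternion chordal mean (largest
    eigenvector of the sum of outer products, after hemisphere alignment to
    the first element). The inputs must lie on a single averaging branch;
    near-antipodal sets raise :class:`AmbiguousMeanError`.

    The choice of the chordal mean over an iterative Karcher mean is a
    design decision: for the small jitter between repeat captures at one
    position the two agree to well below 0.01 degrees.
    """
    transforms = list(transforms)
    if not transforms:
        raise DataError("mean_transform of empty list")
    if len(transforms) == 1:
        return transforms[0]
    for a in transforms[1:]:
        if rotation_geodesic_deg(transforms[0], a) > 120.0:
            raise AmbiguousMeanError("rotations span more than one averaging branch")
    quats = np.array([t.as_quat_wxyz() for t in transforms])
    # hemisphere (sign) alignment to the first quaternion
    signs = np.sign(quats @ quats[0])
    signs[signs == 0] = 1.0
    quats = quats * signs[:, None]
    m = quats.T @ quats
    w, v = np.linalg.eigh(m)
    q = v[:, -1]
    q /= np.linalg.norm(q)
    rot = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    t = np.mean([tr.translation for tr in transforms], axis=0)
    return RigidTransform(_orthonormalize(rot), t)


def rotation_geodesic_deg(a: RigidTransform, b: RigidTransform) -> float:
    """Geodesic rotation distance (the angle of Ra' Rb) in degrees, in
    [0, 180].

    Computed through the rotation-vector magnitude rather than
    arccos((trace - 1)/2); the two agree analytically but the arccos form
    loses ~half the floating-point digits near zero."""
    rel = Rotation.from_matrix(_orthonormalize(a.rotation.T @ b.rotation))
    return float(np.degrees(np.linalg.norm(rel.as_rotvec())))


def random_transform(rng, max_angle_deg=180.0, max_translation_mm=100.0) -> RigidTransform:
    """Random rigid transform: uniform random axis, angle U(0, max), uniform
    translation in a cube. Deterministic for a given generator state."""
    rng = np.random.default_rng(rng)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(0.0, max_angle_deg))
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform.from_rotvec(axis * ang, t)


# ---------------------------------------------------------------------------
# pose table files
# ---------------------------------------------------------------------------

POSE_CSV_COLUMNS = ["frame_id", "body_id", "qw", "qx", "qy", "qz", "tx_mm", "ty_mm", "tz_mm"]


def write_pose_csv(path, entries) -> None:
    """Write a pose table.

    ``entries``: iterable of ``(frame_id, body_id, RigidTransform)``.
    Quaternions are written canonicalized (qw >= 0) at full float precision,
    so a read/write cycle is a fixed point of the file contents.
    """
    rows = []
    for frame_id, body_id, tr in entries:
        qw, qx, qy, qz = tr.as_quat_wxyz()
        tx, ty, tz = tr.translation
        rows.append((frame_id, body_id, qw, qx, qy, qz, tx, ty, tz))
    df = pd.DataFrame(rows, columns=POSE_CSV_COLUMNS)
    df.to_csv(path, index=False, float_format="%.17g")


def read_pose_csv(path):
    """Read a pose table; returns a list of ``(frame_id, body_id, RigidTransform)``."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in POSE_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"pose table {path} missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        tr = RigidTransform.from_quat_wxyz(
            row.qw, row.qx, row.qy, row.qz, (row.tx_mm, row.ty_mm, row.tz_mm)
        )
        out.append((int(row.frame_id), str(row.body_id), tr))
    return out


def write_pose_json(path, transform: RigidTransform) -> None:
    """Write a single transform as a row-major 4x4 matrix JSON object."""
    with open(path, "w") as fh:
        json.dump({"matrix_4x4_row_major": transform.matrix().tolist()}, fh, indent=2)


def read_pose_json(path) -> RigidTransform:
    with open(path) as fh:
        obj = json.load(fh)
    return RigidTransform.from_matrix(np.asarray(obj["matrix_4x4_row_major"], dtype=float))
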