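"""Co-registration of a tracked camera with the tracking volume.

A depth camera carries a tracked rigid body; a checkerboard carries another.
For each capture the tracking system reports both rigid-body poses
(``m_camera``, ``m_board``, both rigid-body -> tracking frame), and the
board pose in the camera optical frame (``V``, board -> optical) comes from
:func:`depthreg.camera.estimate_board_pose`.

Two fixed mounting transforms are unknown and estimated jointly:

* ``E``  — optical center -> camera rigid body (the hand-eye transform);
* ``G``  — defined by the closure relation ``G = (M . E . V)^{-1}`` with
  ``M = invert(m_board) . m_camera`` (camera rigid body -> board rigid
  body); ``M . E . V`` maps board-pattern coordinates into the board
  rigid-body frame and is capture-independent for the true ``E``.

The estimator minimizes the spatial spread of the board corners pooled in
the board-rigid-body frame across captures (for a static board this is the
same as pooling in the tracking frame). Only the 6 d.o.f. of ``E`` are
searched; ``G`` is a deterministic function of ``E`` given the captures and
is recovered post hoc as the averaged closure transform. A 12-d.o.f. joint
mode is available for comparison. Optimization uses scipy's L-BFGS-B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .camera import (
    CameraIntrinsics,
    Checkerboard,
    CornerObservation,
    project_points,
)
from .exceptions import ConvergenceError, DataError, UnderdeterminedError
from .geometry import (
    RigidTransform,
    apply,
    compose,
    invert,
    mean_transform,
    rotation_geodesic_deg,
)

__all__ = [
    "TrackedCapture",
    "CoRegistrationResult",
    "relative_m",
    "spread_objective",
    "solve_eg",
    "coreg_projection_error_px",
]


@dataclass(frozen=True)
class TrackedCapture:
    """One calibration observation.

    ``m_camera`` / ``m_board``: tracked rigid-body poses (rigid body ->
    tracking frame), both expressed in the same tracking frame.
    ``v``: board -> optical-frame pose from the checkerboard image.
    ``corners``: the detected 2-D corners (optional; needed only for the
    reprojection validation).
    """

    m_camera: RigidTransform
    m_board: RigidTransform
    v: RigidTransform
    corners: CornerObservation | None = None
    capture_id: str = ""


@dataclass(frozen=True)
class CoRegistrationResult:
    e: RigidTransform
    g: RigidTransform
    objective_value: float  # mm; residual board-corner spread at the solution
    per_capture_residual_mm: tuple
    n_captures: int


def relative_m(capture: TrackedCapture) -> RigidTransform:
    """Relative tracked transform M = invert(m_board) . m_camera
    (camera rigid body -> board rigid body)."""
    return compose(invert(capture.m_board), capture.m_camera)


def _chain(capture: TrackedCapture, e: RigidTransform) -> RigidTransform:
    """M . E . V: board pattern -> board rigid body for a candidate E."""
    return compose(relative_m(capture), compose(e, capture.v))


def _corner_stack(captures, board: Checkerboard, e: RigidTransform) -> np.ndarray:
    """(n_captures, n_corners, 3) board corners pooled in the board
    rigid-body frame."""
    pts = board.corner_points
    return np.stack([apply(_chain(c, e), pts) for c in captures])


def spread_objective(
    e_candidate: RigidTransform, captures, board: Checkerboard, reducer: str = "mean"
) -> float:
    """Per-corner 3-D standard deviation (mm) of the pooled board corners
    across captures, reduced over corners.

    The per-corner 3-D std is the root of the summed coordinate variances;
    ``reducer`` chooses how the per-corner values are combined ("mean",
    "max" or "rms"). Zero exactly for perfectly consistent noise-free
    captures at the true E.
    """
    captures = list(captures)
    if len(captures) < 2:
        raise UnderdeterminedError("need >= 2 captures for a spread")
    reducers = {"mean": np.mean, "max": np.max, "rms": lambda v: np.sqrt(np.mean(v**2))}
    if reducer not in reducers:
        raise DataError(f"unknown reducer {reducer!r}; choose from {sorted(reducers)}")
    stack = _corner_stack(captures, board, e_candidate)
    var = stack.var(axis=0).sum(axis=1)  # (n_corners,)
    return float(reducers[reducer](np.sqrt(var)))


def _rotvec_to_matrix(r: np.ndarray) -> np.ndarray:
    """Rodrigues formula (avoids object construction in the hot loop)."""
    ang = np.linalg.norm(r)
    if ang < 1e-12:
        return np.eye(3)
    k = r / ang
    kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(ang) * kx + (1 - np.cos(ang)) * (kx @ kx)


def _mean_variance(e_params: np.ndarray, rm, tm, rv, tv, pts) -> float:
    """Smooth internal objective: mean per-corner variance (mm^2).

    Same minimizer as the mm spread, but quadratic (not |.|-like) at a
    perfect solution, which quasi-Newton methods need to converge tightly.
    ``rm/tm`` and ``rv/tv`` are the stacked rotations/translations of the
    per-capture M and V transforms.
    """
    re = _rotvec_to_matrix(e_params[:3])
    te = e_params[3:]
    r_ev = np.einsum("ij,njk->nik", re, rv)  # (n,3,3)
    t_ev = tv @ re.T + te  # (n,3)
    r_chain = np.einsum("nij,njk->nik", rm, r_ev)
    t_chain = np.einsum("nij,nj->ni", rm, t_ev) + tm
    stack = np.einsum("nij,kj->nki", r_chain, pts) + t_chain[:, None, :]
    return float(stack.var(axis=0).sum(axis=1).mean())


def _handeye_init(ms, vs) -> RigidTransform:
    """Closed-form initialization from capture pairs.

    The closure ``M_i E V_i = const`` gives, for any pair (i, j),
    ``A E = E B`` with ``A = M_j^{-1} M_i`` and ``B = V_j V_i^{-1}`` — the
    classic hand-eye relation. The rotation comes from aligning the
    rotation-axis vectors of B to those of A (Park–Martin style), the
    translation from the stacked linear system ``(R_A - I) t = R_E t_B - t_A``.
    """
    alphas, betas, lin_a, lin_b = [], [], [], []
    n = len(ms)
    pairs = [(i, (i + 1) % n) for i in range(n - 1)] + [(i, (i + 2) % n) for i in range(n - 2)]
    mats = []
    for i, j in pairs:
        a = compose(invert(ms[j]), ms[i])
        b = compose(vs[j], invert(vs[i]))
        alpha = RigidTransform(a.rotation, np.zeros(3)).rotvec()
        beta = RigidTransform(b.rotation, np.zeros(3)).rotvec()
        if np.linalg.norm(alpha) < 1e-6 or np.linalg.norm(beta) < 1e-6:
            continue
        alphas.append(alpha)
        betas.append(beta)
        mats.append((a, b))
    if len(alphas) < 2:
        return RigidTransform.identity()
    alphas = np.asarray(alphas)
    betas = np.asarray(betas)
    # rotation: orthogonal Procrustes on the axis vectors (no centering; the
    # relation is linear through the origin)
    h = betas.T @ alphas
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r_e = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    rows, rhs = [], []
    for a, b in mats:
        rows.append(a.rotation - np.eye(3))
        rhs.append(r_e @ b.translation - a.translation)
    t_e, *_ = np.linalg.lstsq(np.vstack(rows), np.concatenate(rhs), rcond=None)
    try:
        return RigidTransform(r_e, t_e)
    except Exception:
        return RigidTransform.identity()


def solve_eg(
    captures,
    board: Checkerboard,
    init: RigidTransform | None = None,
    joint: bool = False,
    max_iter: int = 500,
) -> CoRegistrationResult:
    """Estimate the hand-eye transform E and board-mount transform G.

    ``init`` overrides the closed-form hand-eye initialization. ``joint=True``
    searches the full 12 d.o.f. of (E, G) instead of eliminating G
    analytically; the two modes agree at the optimum.
    """
    captures = list(captures)
    if len(captures) < 3:
        raise UnderdeterminedError(f"need >= 3 captures, got {len(captures)}")
    ms = [relative_m(c) for c in captures]
    vs = [c.v for c in captures]
    pts = board.corner_points

    div = max(
        rotation_geodesic_deg(ms[i], ms[j])
        for i in range(len(ms))
        for j in range(i + 1, len(ms))
    )
    if div < 10.0:
        warnings.warn(
            f"camera-pose rotation diversity only {div:.1f} deg; E is weakly constrained"
        )

    e0 = init if init is not None else _handeye_init(ms, vs)
    x0 = np.concatenate([e0.rotvec(), e0.translation])

    rm = np.stack([m.rotation for m in ms])
    tm = np.stack([m.translation for m in ms])
    rv = np.stack([v.rotation for v in vs])
    tv = np.stack([v.translation for v in vs])

    if not joint:
        fun = lambda x: _mean_variance(x, rm, tm, rv, tv, pts)
    else:
        # 12-d.o.f. comparison mode: E plus an explicit mount C = G^{-1};
        # objective is the mean squared distance of each capture's implied
        # corners to the C-implied corners.
        chains0 = [compose(m, compose(e0, v)) for m, v in zip(ms, vs)]
        c0 = mean_transform(chains0)
        x0 = np.concatenate([x0, c0.rotvec(), c0.translation])

        def fun(x):
            e = RigidTransform.from_rotvec(x[:3], x[3:6])
            c = RigidTransform.from_rotvec(x[6:9], x[9:12])
            ref = pts @ c.rotation.T + c.translation
            acc = 0.0
            for m, v in zip(ms, vs):
                t = compose(m, compose(e, v))
                acc += float(((pts @ t.rotation.T + t.translation - ref) ** 2).sum(1).mean())
            return acc / len(ms)

    res = minimize(
        fun,
        x0,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-18, "gtol": 1e-14, "maxfun": 100000},
    )
    if not res.success and res.nit >= max_iter:
        raise ConvergenceError(
            f"L-BFGS-B did not converge in {max_iter} iterations", last_objective=float(res.fun)
        )
    # guard the descent property against pathological line-search exits
    x = res.x if fun(res.x) <= fun(x0) else x0
    e = RigidTransform.from_rotvec(x[:3], x[3:6])

    chains = [compose(m, compose(e, v)) for m, v in zip(ms, vs)]
    g = mean_transform([invert(c) for c in chains])
    stack = np.stack([pts @ c.rotation.T + c.translation for c in chains])
    mean_pts = stack.mean(axis=0)
    residuals = tuple(
        float(np.linalg.norm(stack[i] - mean_pts, axis=1).mean()) for i in range(len(chains))
    )
    objective = float(np.sqrt(stack.var(axis=0).sum(axis=1)).mean())
    return CoRegistrationResult(
        e=e,
        g=g,
        objective_value=objective,
        per_capture_residual_mm=residuals,
        n_captures=len(captures),
    )


def coreg_projection_error_px(
    result: CoRegistrationResult,
    captures,
    intr: CameraIntrinsics,
    board: Checkerboard,
):
    """Validation metric: project the virtual board through the estimated
    chain and compare with the observed corners.

    For each capture the board corners are carried board -> board rigid body
    (via ``G^{-1}``) -> camera rigid body (via ``M^{-1}``) -> optical frame
    (via ``E^{-1}``), projected with the intrinsics, and compared with the
    detected corners. Returns (mean, std) of the per-corner Euclidean
    distances in px over all captures.
    """
    dists = []
    for cap in captures:
        if cap.corners is None:
            raise DataError(f"capture {cap.capture_id!r} has no corner observation")
        m = relative_m(cap)
        v_implied = compose(invert(result.e), compose(invert(m), invert(result.g)))
        pts_cam = apply(v_implied, board.corner_points)
        pred = project_points(intr, pts_cam)
        dists.append(np.linalg.norm(pred - cap.corners.image_points, axis=1))
    d = np.concatenate(dists)
    return float(d.mean()), float(d.std())
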