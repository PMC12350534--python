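"""Surface registration: nearest neighbors, RANSAC global initialization and
point-to-point ICP, plus the frame chain carrying a camera-frame
registration into the tracking frame.

The global initializer uses triplet pairwise-distance compatibility (a
rotation-invariant descriptor) rather than learned or histogram features —
simple, dependency-free and sufficient at phantom scale. Learned
registration backends (e.g. deep global registration) plug in through the
:data:`BACKENDS` registry: any callable ``(source, target, seed) ->
RegistrationResult``; no network is implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import (
    DataError,
    DivergenceError,
    InitializationFailureError,
)
from .geometry import RigidTransform, apply, compose, invert, rigid_fit

__all__ = [
    "RegistrationResult",
    "nearest_neighbors",
    "voxel_downsample",
    "ransac_global_init",
    "icp_point_to_point",
    "register_face",
    "chain_to_tracking",
    "BACKENDS",
]


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of a surface registration (source -> target transform)."""

    transform: RigidTransform
    overlap_fraction: float
    inlier_rmse_mm: float
    n_iterations: int
    converged: bool
    #: (corr_tol_mm, inlier_rmse_mm) per accepted iteration; within one
    #: tolerance epoch the RMSE is non-increasing
    rmse_history: tuple = ()

    def __post_init__(self):
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise DataError("overlap_fraction outside [0, 1]")
        if self.inlier_rmse_mm < 0:
            raise DataError("inlier_rmse_mm must be >= 0")


def nearest_neighbors(query, reference):
    """Index and distance of the closest reference point for each query point.

    Backed by a k-d tree; agrees exactly with exhaustive search.
    """
    q = np.asarray(query, dtype=float)
    r = np.asarray(reference, dtype=float)
    if r.size == 0:
        raise DataError("reference cloud is empty")
    dist, idx = cKDTree(r).query(q)
    return idx, dist


def voxel_downsample(points, voxel_mm: float) -> np.ndarray:
    """Centroid-per-voxel downsampling on a regular grid."""
    p = np.asarray(points, dtype=float)
    if voxel_mm <= 0:
        return p.copy()
    keys = np.floor(p / voxel_mm).astype(np.int64)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    sums = np.zeros((len(counts), 3))
    np.add.at(sums, inverse, p)
    return sums / counts[:, None]


def _well_spread_triplet(rng, points, min_sep):
    for _ in range(30):
        i, j, k = rng.choice(len(points), size=3, replace=False)
        ab = points[j] - points[i]
        ac = points[k] - points[i]
        bc = points[k] - points[j]
        d = (np.linalg.norm(ab), np.linalg.norm(ac), np.linalg.norm(bc))
        if min(d) <= min_sep:
            continue
        # reject thin triangles: their fits are rotationally unstable
        altitude = 2.0 * np.linalg.norm(np.cross(ab, ac)) / max(d)
        if altitude > 0.5 * min_sep:
            return np.array([i, j, k])
    return None


def _ransac_candidates(src, tgt, rng, inlier_tol_mm, max_trials, k_best=6):
    """Congruent-triplet candidate search on the downsampled clouds.

    For each sampled well-spread source triplet (a, b, c) the pairwise
    distances (the rotation-invariant descriptor) are matched against the
    target: candidate (ta, tb) anchor pairs are drawn from the target
    distance matrix at |d - dab| <= tol, and tc must lie on the intersection
    of the two remaining distance rings. Each congruent triplet yields a
    rigid fit scored by inlier fraction on a source subsample. Returns up to
    ``k_best`` mutually distinct candidates, best score first; the caller
    disambiguates the surviving basins at full resolution.
    """
    if len(tgt) > 1800:
        tgt = tgt[rng.choice(len(tgt), size=1800, replace=False)]
    dt = np.linalg.norm(tgt[:, None, :] - tgt[None, :, :], axis=2)
    pair_tol = max(0.6 * inlier_tol_mm, 2.5)
    score_tol = max(0.6 * inlier_tol_mm, 2.5)
    tree = cKDTree(tgt)
    extent = np.linalg.norm(src.max(0) - src.min(0))
    min_sep = 0.35 * extent
    score_n = min(len(src), 150)
    score_pts = src[rng.choice(len(src), size=score_n, replace=False)]

    n_triplets = 8
    pairs_per_triplet = max(100, max_trials)
    cands = []  # (score, transform)
    for _ in range(n_triplets):
        if cands and max(sc for sc, _ in cands) >= 0.92:
            break
        trip = _well_spread_triplet(rng, src, min_sep)
        if trip is None:
            min_sep *= 0.7
            continue
        a, b, c = src[trip]
        dab = np.linalg.norm(a - b)
        dac = np.linalg.norm(a - c)
        dbc = np.linalg.norm(b - c)
        pair_err = np.abs(dt - dab)
        ia_all, ib_all = np.nonzero(pair_err <= pair_tol)
        if len(ia_all) == 0:
            continue
        # prioritize the tightest distance matches (most likely to be the
        # true correspondence), plus a random sample for diversity
        order = np.argsort(pair_err[ia_all, ib_all])
        n_tight = min(len(order), pairs_per_triplet // 2)
        chosen = list(order[:n_tight])
        if len(order) > n_tight:
            chosen += list(
                rng.choice(order[n_tight:], size=min(len(order) - n_tight, pairs_per_triplet // 2),
                           replace=False)
            )
        for m in chosen:
            ia, ib = ia_all[m], ib_all[m]
            # tc must lie on both remaining distance rings; take the best match
            err_c = np.abs(dt[ia] - dac) + np.abs(dt[ib] - dbc)
            ok = (np.abs(dt[ia] - dac) <= pair_tol) & (np.abs(dt[ib] - dbc) <= pair_tol)
            if not np.any(ok):
                continue
            err_c[~ok] = np.inf
            ic = int(np.argmin(err_c))
            try:
                t = rigid_fit(np.array([a, b, c]), np.array([tgt[ia], tgt[ib], tgt[ic]]))
            except Exception:
                continue
            d = tree.query(apply(t, score_pts))[0]
            cands.append((float(np.mean(d <= score_tol)), t))
    if not cands:
        return []
    cands.sort(key=lambda sc: -sc[0])
    kept = []
    for score, t in cands:
        if score <= 0.5 * cands[0][0]:
            break
        distinct = all(
            np.linalg.norm(t.translation - u.translation) > 3.0 * inlier_tol_mm
            or _rot_angle_deg(t, u) > 6.0
            for _, u in kept
        )
        if distinct:
            kept.append((score, t))
        if len(kept) >= k_best:
            break
    return kept


def _rot_angle_deg(a, b):
    from .geometry import rotation_geodesic_deg

    return rotation_geodesic_deg(a, b)


def _local_relief(points, k=12):
    """Distance of each point from the best-fit plane of its k neighbors —
    a cheap curvature proxy that flags geometrically distinctive points."""
    pts = np.asarray(points, float)
    kk = min(k + 1, len(pts))
    _, idx = cKDTree(pts).query(pts, k=kk)
    nb = pts[idx]  # (n, k+1, 3)
    ctr = nb.mean(axis=1, keepdims=True)
    d = nb - ctr
    cov = np.einsum("nki,nkj->nij", d, d) / kk
    w, v = np.linalg.eigh(cov)
    normal = v[:, :, 0]
    return np.abs(np.einsum("ni,ni->n", pts - ctr[:, 0, :], normal))


def _feature_points(points, quantile=0.7):
    """High-relief subset of a cloud (see :func:`_local_relief`)."""
    pts = np.asarray(points, float)
    r = _local_relief(pts)
    return pts[r >= np.quantile(r, quantile)]


def _feature_polish(t, src_feat, tgt_tree, tgt_feat, start_tol, floor_tol, iters, shrink=0.9):
    """Pull a coarse candidate toward its basin by ICP restricted to the
    high-relief points of BOTH clouds.

    Smooth regions admit tangential sliding; the distinctive points do not,
    and restricting the target side as well forces feature-to-feature
    correspondence, which widens the capture range enormously."""
    tol = start_tol
    for _ in range(iters):
        dist, idx = tgt_tree.query(apply(t, src_feat))
        inl = dist <= tol
        if np.sum(inl) < 3:
            return t
        try:
            t = rigid_fit(src_feat[inl], tgt_feat[idx[inl]])
        except Exception:
            return t
        tol = max(shrink * tol, floor_tol)
    return t


def ransac_global_init(
    source,
    target,
    seed: int = 0,
    n_samples: int = 3,
    max_trials: int = 400,
    inlier_tol_mm: float = 5.0,
) -> RigidTransform:
    """Coarse global alignment by triplet distance-compatibility RANSAC.

    Each trial samples a well-spread source triplet, finds target triplets
    whose pairwise distances are compatible (the rotation-invariant
    descriptor), fits a rigid transform to the candidate correspondence and
    scores it by inlier count at ``inlier_tol_mm`` on a subsample.
    Deterministic for a given seed. Raises
    :class:`InitializationFailureError` when no candidate reaches 3 inliers;
    callers may fall back to centroid + principal-axes alignment.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if len(src) < 3 or len(tgt) < 3:
        raise DataError("both clouds need at least 3 points")
    if n_samples != 3:
        raise DataError("triplet sampler supports n_samples=3 only")
    rng = np.random.default_rng(seed)
    cands = _ransac_candidates(src, tgt, rng, inlier_tol_mm, max_trials)
    if not cands:
        raise InitializationFailureError("no RANSAC candidate reached 3 inliers")
    # refine the shortlisted basins on the given clouds and keep the one
    # with the most inliers at the requested tolerance
    tree = cKDTree(tgt)
    score_pts = src[rng.choice(len(src), size=min(len(src), 600), replace=False)]
    best_t, best_inl = None, 2
    for _, t in cands:
        tol = 3.0 * inlier_tol_mm
        for it in range(20):
            dist, idx = tree.query(apply(t, score_pts))
            inl = dist <= tol
            if np.sum(inl) < 3:
                break
            try:
                t = rigid_fit(score_pts[inl], tgt[idx[inl]])
            except Exception:
                break
            tol = max(0.75 * tol, 0.05 * inlier_tol_mm)
        d = tree.query(apply(t, score_pts))[0]
        n_inl = int(np.sum(d <= inlier_tol_mm))
        if n_inl > best_inl:
            best_t, best_inl = t, n_inl
    if best_t is None:
        raise InitializationFailureError("no RANSAC candidate reached 3 inliers")
    return best_t


def _principal_axes_init(source, target) -> RigidTransform:
    """Fallback: centroid + principal-axes alignment, sign-disambiguated by
    nearest-neighbor score."""
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    cs, ct = src.mean(0), tgt.mean(0)
    us = np.linalg.svd(src - cs, full_matrices=False)[2].T
    ut = np.linalg.svd(tgt - ct, full_matrices=False)[2].T
    tree = cKDTree(tgt)
    best, best_cost = None, np.inf
    for sx in (1, -1):
        for sy in (1, -1):
            flip = np.diag([sx, sy, sx * sy])  # keep det +1
            r = ut @ flip @ us.T
            if np.linalg.det(r) < 0:
                continue
            t = RigidTransform(r, ct - r @ cs)
            cost = float(tree.query(apply(t, src[:: max(1, len(src) // 300)]))[0].mean())
            if cost < best_cost:
                best, best_cost = t, cost
    return best


def icp_point_to_point(
    source,
    target,
    init: RigidTransform | None = None,
    max_iter: int = 50,
    corr_tol_mm: float = 10.0,
    conv_tol: float = 1e-10,
    anneal: bool = True,
    overlap_tol_mm: float = 5.0,
) -> RegistrationResult:
    """Point-to-point ICP with distance-based correspondence rejection.

    Iterates nearest-neighbor correspondence (rejecting pairs beyond the
    current ``corr_tol_mm``) and a rigid least-squares fit. With
    ``anneal=True`` the rejection threshold halves every 10 iterations down
    to a floor of 2 mm. The inlier RMSE is non-increasing across accepted
    iterations within a threshold epoch; an iteration that would increase it
    terminates the loop instead. Stops when the RMSE improvement falls below
    ``conv_tol`` (absolute, mm) or after ``max_iter`` iterations.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if len(src) == 0 or len(tgt) == 0:
        raise DataError("empty cloud")
    t = init if init is not None else RigidTransform.identity()
    tree = cKDTree(tgt)
    tol = corr_tol_mm
    prev_rmse = np.inf
    n_it = 0
    converged = False
    history = []
    for n_it in range(1, max_iter + 1):
        cur = apply(t, src)
        dist, idx = tree.query(cur)
        inliers = dist <= tol
        if not np.any(inliers):
            raise DivergenceError(
                f"all correspondences rejected at iteration {n_it}", iteration=n_it
            )
        rmse = float(np.sqrt(np.mean(dist[inliers] ** 2)))
        if rmse > prev_rmse + 1e-12:
            converged = True  # threshold-change artefact; keep the previous state
            break
        history.append((tol, rmse))
        if rmse == 0.0:
            converged = True
            break
        improvement = prev_rmse - rmse
        prev_rmse = rmse
        if improvement < conv_tol:
            if anneal and tol > 2.0:
                tol = max(tol * 0.5, 2.0)
                prev_rmse = np.inf
                continue
            converged = True
            break
        try:
            step = rigid_fit(src[inliers], tgt[idx[inliers]])
        except Exception:
            converged = False
            break
        t = step
        if anneal and n_it % 10 == 0 and tol > 2.0:
            tol = max(tol * 0.5, 2.0)
            prev_rmse = np.inf

    cur = apply(t, src)
    dist, _ = tree.query(cur)
    inliers = dist <= tol
    rmse = float(np.sqrt(np.mean(dist[inliers] ** 2))) if np.any(inliers) else float("inf")
    overlap = float(np.mean(dist <= overlap_tol_mm))
    return RegistrationResult(
        transform=t,
        overlap_fraction=overlap,
        inlier_rmse_mm=rmse,
        n_iterations=n_it,
        converged=converged,
        rmse_history=tuple(history),
    )


def register_face(
    face_cloud,
    mr_face,
    seed: int = 0,
    voxel_mm: float = 5.0,
    inlier_tol_mm: float = 5.0,
    max_iter: int = 50,
) -> RegistrationResult:
    """Register a captured face cloud (camera optical frame) to the
    MR-derived face cloud (patient frame).

    Both clouds are voxel-downsampled (default 5 mm) for the RANSAC global
    initialization; the final ICP runs at full resolution. Returns the
    camera -> patient transform with overlap/RMSE diagnostics.
    """
    src = np.asarray(face_cloud, dtype=float)
    tgt = np.asarray(mr_face, dtype=float)
    if len(src) < 100 or len(tgt) < 100:
        raise DataError("need >= 100 points in each cloud after face cropping")
    src_ds = voxel_downsample(src, voxel_mm)
    tgt_ds = voxel_downsample(tgt, voxel_mm)
    rng = np.random.default_rng(seed)
    inits = [t for _, t in _ransac_candidates(src_ds, tgt_ds, rng, voxel_mm, max_trials=400)]
    if not inits:
        inits = [_principal_axes_init(src_ds, tgt_ds)]
    # pull every shortlisted candidate toward its basin by feature-to-
    # feature ICP (high-relief points of both clouds) — first on the
    # downsampled clouds with a wide capture range, then at full
    # resolution; the surviving basins are ranked by full-resolution
    # truncated RMSE and the best refined with ordinary ICP
    sf_ds = _feature_points(src_ds)
    tf_ds = _feature_points(tgt_ds)
    # the fine feature stage runs on lightly voxel-averaged clouds: the
    # averaging suppresses sensor noise that would otherwise swamp the
    # local-relief signal, while keeping enough resolution to localize
    src_sub = voxel_downsample(src, 0.5 * voxel_mm)
    tgt_sub = voxel_downsample(tgt, 0.5 * voxel_mm)
    sf = _feature_points(src_sub)
    tf = _feature_points(tgt_sub)
    tree_f_ds = cKDTree(tf_ds)
    tree_f = cKDTree(tf)
    tgt_tree = cKDTree(tgt)
    probe = src[rng.choice(len(src), size=min(len(src), 1500), replace=False)]
    ranked = []
    for init in inits:
        t1 = _feature_polish(init, sf_ds, tree_f_ds, tf_ds, 5.0 * voxel_mm, 0.6 * voxel_mm, 20, 0.85)
        t2 = _feature_polish(t1, sf, tree_f, tf, 3.0 * voxel_mm, 0.12 * voxel_mm, 40, 0.9)
        d = tgt_tree.query(apply(t2, probe))[0]
        ranked.append((float(np.sqrt(np.mean(np.minimum(d, 2.0 * voxel_mm) ** 2))), t2))
    ranked.sort(key=lambda rt: rt[0])
    best = None
    for _, t2 in ranked[:3]:
        try:
            fine = icp_point_to_point(
                src,
                tgt,
                init=t2,
                max_iter=max_iter,
                corr_tol_mm=2.0 * voxel_mm,
                anneal=True,
                overlap_tol_mm=inlier_tol_mm,
            )
        except DepthRegError:
            continue
        if best is None or fine.inlier_rmse_mm < best.inlier_rmse_mm:
            best = fine
    if best is None:
        raise InitializationFailureError("no candidate basin survived refinement")
    return best


def chain_to_tracking(reg, m_camera: RigidTransform, e: RigidTransform) -> RigidTransform:
    """Patient -> tracking transform implied by a face registration.

    ``reg`` is a :class:`RegistrationResult` (or a bare camera -> patient
    transform), ``m_camera`` the tracked camera rigid-body pose and ``e``
    the optical -> camera-rigid-body hand-eye transform. The optical-frame
    pose in the tracking frame is ``m_camera . e``; composing with the
    inverse registration yields patient -> tracking.
    """
    t = reg.transform if isinstance(reg, RegistrationResult) else reg
    return compose(m_camera, compose(e, invert(t)))


def _icp_backend(source, target, seed: int) -> RegistrationResult:
    return register_face(source, target, seed=seed)


#: registration backend registry: name -> callable(source, target, seed)
BACKENDS = {"icp": _icp_backend}
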