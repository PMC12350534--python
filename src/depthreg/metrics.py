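"""Registration-quality metrics and the benchmark protocol.

FRE (fiducial registration error) and TRE (target registration error) are
both surface RMSEs over overlapping points: FRE on the face clouds used to
compute the alignment, TRE on the held-out craniotomy region. Positions
whose overlap fraction falls below the exclusion threshold (default 95%) do
not contribute to the summary statistics — failed registrations are flagged,
not averaged in.
"""

from __future__ import annotations

from dataclasses import dataclass

import json

import numpy as np
import pandas as pd

from .config import BenchmarkConfig
from .exceptions import (
    DataError,
    DepthRegError,
    EmptyRoiError,
    NoOverlapError,
)
from .geometry import (
    RigidTransform,
    apply,
    compose,
    invert,
    mean_transform,
    rigid_fit,
)
from .registration import BACKENDS, chain_to_tracking, nearest_neighbors
from . import simulator as sim

__all__ = [
    "EvaluationReport",
    "overlap_fraction",
    "surface_rmse_mm",
    "crop_roi",
    "landmark_register",
    "run_benchmark",
    "markdown_table",
]


def overlap_fraction(source, target, dist_tol_mm: float) -> float:
    """Fraction of source points whose nearest target neighbor is within
    ``dist_tol_mm``."""
    s = np.asarray(source, float)
    t = np.asarray(target, float)
    if len(s) == 0 or len(t) == 0:
        raise DataError("empty cloud")
    if dist_tol_mm <= 0:
        raise DataError("dist_tol_mm must be positive")
    _, dist = nearest_neighbors(s, t)
    return float(np.mean(dist <= dist_tol_mm))


def surface_rmse_mm(source, target, dist_tol_mm: float) -> float:
    """RMS nearest-neighbor distance over the overlapping source points
    (those within ``dist_tol_mm`` of the target); backs both FRE and TRE."""
    s = np.asarray(source, float)
    t = np.asarray(target, float)
    if len(s) == 0 or len(t) == 0:
        raise DataError("empty cloud")
    _, dist = nearest_neighbors(s, t)
    inl = dist <= dist_tol_mm
    if not np.any(inl):
        raise NoOverlapError("no source point within the distance tolerance")
    return float(np.sqrt(np.mean(dist[inl] ** 2)))


def crop_roi(cloud, box, margin_mm: float = 0.0) -> np.ndarray:
    """Points inside an axis-aligned box expanded by ``margin_mm`` per face.

    The box is closed: points exactly on a face are included.
    """
    c = np.asarray(cloud, float)
    b = np.asarray(box, float).reshape(2, 3)
    lo = b[0] - margin_mm
    hi = b[1] + margin_mm
    mask = np.all((c >= lo) & (c <= hi), axis=1)
    out = c[mask]
    if len(out) == 0:
        raise EmptyRoiError("no point inside the region of interest")
    return out


def landmark_register(fiducials_measured, fiducials_mr, use_for_registration=None):
    """Manual fiducial-marker registration baseline.

    Fits a rigid transform (measured -> MR frame) on the registration subset
    of markers (default: the first half of the 8), then reports FRE as the
    RMSE of the fitted subset and TRE as the RMSE of the held-out subset
    under the same transform. Returns ``(transform, fre_mm, tre_mm)``.
    """
    meas = np.asarray(fiducials_measured, float)
    mr = np.asarray(fiducials_mr, float)
    if meas.shape != mr.shape or meas.ndim != 2 or meas.shape[1] != 3:
        raise DataError("fiducial sets must be matching (K, 3) arrays")
    k = len(meas)
    if use_for_registration is None:
        use_for_registration = range(k // 2)
    reg_idx = np.array(sorted(set(int(i) for i in use_for_registration)))
    if len(reg_idx) < 3:
        raise DataError("registration subset must contain >= 3 markers")
    if reg_idx.min() < 0 or reg_idx.max() >= k:
        raise DataError("registration index out of range")
    eval_idx = np.array([i for i in range(k) if i not in set(reg_idx.tolist())])
    if len(eval_idx) == 0:
        raise DataError("registration and evaluation subsets must be disjoint and non-empty")
    t = rigid_fit(meas[reg_idx], mr[reg_idx])
    res_reg = apply(t, meas[reg_idx]) - mr[reg_idx]
    fre = float(np.sqrt(np.mean(np.sum(res_reg**2, axis=1))))
    res_eval = apply(t, meas[eval_idx]) - mr[eval_idx]
    tre = float(np.sqrt(np.mean(np.sum(res_eval**2, axis=1))))
    return t, fre, tre


# ---------------------------------------------------------------------------
# benchmark protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvaluationReport:
    """Per-position rows and aggregate FRE/TRE for one camera configuration.

    ``per_position`` rows carry ``phase`` ("registration" or "testing"),
    the metric (fre_mm / tre_mm, None when unavailable), the overlap
    fraction and the exclusion flag. Summary statistics are computed only
    over non-excluded positions.
    """

    per_position: tuple
    summary: dict
    provenance: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "provenance": self.provenance,
                    "summary": self.summary,
                    "per_position": list(self.per_position),
                },
                fh,
                indent=2,
            )

    def to_csv(self, path) -> None:
        pd.DataFrame(list(self.per_position)).to_csv(path, index=False)

    @staticmethod
    def from_json(path) -> "EvaluationReport":
        with open(path) as fh:
            d = json.load(fh)
        return EvaluationReport(
            per_position=tuple(d["per_position"]),
            summary=d["summary"],
            provenance=d["provenance"],
        )


def _summarize(rows, key):
    vals = [r[key] for r in rows if not r["excluded"] and r[key] is not None]
    if not vals:
        return None, None
    return float(np.mean(vals)), float(np.std(vals))


def _default_mount() -> RigidTransform:
    """Plausible camera-mount hand-eye transform (optical -> rigid body)."""
    return RigidTransform.from_rotvec(
        np.radians(15.0) * np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0), (30.0, -40.0, 25.0)
    )


def run_benchmark(config: BenchmarkConfig) -> EvaluationReport:
    """Execute the two-phase evaluation protocol on the simulator.

    Registration phase: ``n_positions`` camera placements facing the
    phantom face, ``n_captures`` captures each; every capture is registered
    to the MR-derived face cloud and carried into the tracking frame; the
    per-position mean transform gives that position's FRE and overlap.

    Testing phase: ``n_positions`` placements over the craniotomy; captures
    are mapped into the patient frame through the pooled registration and
    scored (TRE) on the cropped craniotomy region against the MR cloud.

    The 95% overlap gate excludes unreliable positions from the summary;
    an all-excluded configuration yields a report (not an exception) whose
    summary metrics are None.
    """
    preset = sim.get_preset(config.preset)
    if config.axial_sigma_override_mm is not None:
        from dataclasses import replace

        preset = replace(preset, axial_sigma_mm=float(config.axial_sigma_override_mm))
    if config.algorithm not in BACKENDS:
        raise DataError(f"unknown algorithm {config.algorithm!r}; known: {list(BACKENDS)}")
    backend = BACKENDS[config.algorithm]
    rng = np.random.default_rng(config.seed)

    scene = sim.generate_phantom_head(
        seed=config.seed, point_spacing_mm=config.phantom_spacing_mm
    )
    mr_face = scene.points_in_region("face")
    mr_crani = scene.points_in_region("craniotomy")
    labels = scene.region_labels

    # ground-truth scene placement and camera mount
    p_true = RigidTransform.from_rotvec(
        rng.uniform(-0.4, 0.4, size=3), rng.uniform(-300.0, 300.0, size=3)
    )
    e_true = _default_mount()
    if config.coregister:
        from .coregistration import solve_eg

        session = sim.simulate_calibration_session(
            e_true,
            sim.RigidTransform.from_rotvec((0.0, 0.0, 0.1), (5.0, 5.0, 2.0)),
            sim.default_intrinsics(),
            sim.default_board(),
            n_captures=15,
            tracking_noise=config.tracking_noise,
            corner_noise_px=0.3,
            seed=int(rng.integers(2**31)),
        )
        e_est = solve_eg(session, sim.default_board()).e
    else:
        e_est = e_true

    noise = config.tracking_noise
    rows = []

    # -- registration phase ---------------------------------------------
    viewpoints = sim.face_viewpoints(
        config.n_positions, seed=int(rng.integers(2**31)), standoff_mm=config.registration_standoff_mm
    )
    position_transforms = []
    for j, base_pose in enumerate(viewpoints):
        cap_transforms = []
        cap_clouds_track = []
        for k in range(config.n_captures):
            cap_seed = int(rng.integers(2**31))
            wiggle = RigidTransform.from_rotvec(
                rng.normal(scale=0.01, size=3), rng.normal(scale=2.0, size=3)
            )
            opt_pose = compose(wiggle, base_pose)  # optical -> phantom
            opt_in_track = compose(p_true, opt_pose)
            m_cam_true = compose(opt_in_track, invert(e_true))
            m_cam = sim.simulate_tracked_pose(m_cam_true, noise, rng)
            try:
                cloud, idx = sim.simulate_depth_capture(
                    scene, opt_pose, preset, seed=cap_seed, return_indices=True
                )
                face_cap = cloud[labels[idx] == "face"]
                reg = backend(face_cap, mr_face, cap_seed)
            except DepthRegError:
                continue
            cap_transforms.append(chain_to_tracking(reg, m_cam, e_est))
            cap_clouds_track.append(apply(compose(m_cam, e_est), face_cap))
        row = {
            "phase": "registration",
            "position_id": j,
            "n_captures": len(cap_transforms),
            "fre_mm": None,
            "tre_mm": None,
            "overlap_fraction": 0.0,
            "excluded": True,
        }
        if cap_transforms:
            try:
                # failed registrations can disagree by arbitrary rotations,
                # which has no meaningful average — treat as excluded
                t_pos = mean_transform(cap_transforms)
            except DepthRegError:
                rows.append(row)
                continue
            source = np.concatenate(cap_clouds_track, axis=0)
            target = apply(t_pos, mr_face)
            ov = overlap_fraction(source, target, config.dist_tol_mm)
            row["overlap_fraction"] = ov
            row["excluded"] = bool(ov < config.overlap_threshold)
            try:
                row["fre_mm"] = surface_rmse_mm(source, target, config.dist_tol_mm)
            except NoOverlapError:
                row["excluded"] = True
            if not row["excluded"]:
                position_transforms.append(t_pos)
        rows.append(row)

    try:
        patient_reg = mean_transform(position_transforms) if position_transforms else None
    except DepthRegError:
        patient_reg = None

    # -- testing phase ---------------------------------------------------
    test_viewpoints = sim.craniotomy_viewpoints(
        scene,
        config.n_positions,
        seed=int(rng.integers(2**31)),
        standoff_mm=config.testing_standoff_mm,
    )
    for j, base_pose in enumerate(test_viewpoints):
        row = {
            "phase": "testing",
            "position_id": j,
            "n_captures": 0,
            "fre_mm": None,
            "tre_mm": None,
            "overlap_fraction": 0.0,
            "excluded": True,
        }
        clouds_patient = []
        n_caps = 0
        for k in range(config.n_captures):
            cap_seed = int(rng.integers(2**31))
            wiggle = RigidTransform.from_rotvec(
                rng.normal(scale=0.01, size=3), rng.normal(scale=2.0, size=3)
            )
            opt_pose = compose(wiggle, base_pose)
            opt_in_track = compose(p_true, opt_pose)
            m_cam_true = compose(opt_in_track, invert(e_true))
            m_cam = sim.simulate_tracked_pose(m_cam_true, noise, rng)
            if patient_reg is None:
                continue
            try:
                cloud, idx = sim.simulate_depth_capture(
                    scene, opt_pose, preset, seed=cap_seed, return_indices=True
                )
                roi_cap = cloud[labels[idx] == "craniotomy"]
                if len(roi_cap) == 0:
                    continue
                in_track = apply(compose(m_cam, e_est), roi_cap)
                in_patient = apply(invert(patient_reg), in_track)
                in_patient = crop_roi(
                    in_patient, scene.craniotomy_box, margin_mm=config.roi_margin_mm
                )
            except DepthRegError:
                continue
            clouds_patient.append(in_patient)
            n_caps += 1
        row["n_captures"] = n_caps
        if clouds_patient:
            source = np.concatenate(clouds_patient, axis=0)
            ov = overlap_fraction(source, mr_crani, config.dist_tol_mm)
            row["overlap_fraction"] = ov
            row["excluded"] = bool(ov < config.overlap_threshold)
            try:
                row["tre_mm"] = surface_rmse_mm(source, mr_crani, config.dist_tol_mm)
            except NoOverlapError:
                row["excluded"] = True
        rows.append(row)

    fre_mean, fre_std = _summarize([r for r in rows if r["phase"] == "registration"], "fre_mm")
    tre_mean, tre_std = _summarize([r for r in rows if r["phase"] == "testing"], "tre_mm")
    summary = {
        "fre_mean_mm": fre_mean,
        "fre_std_mm": fre_std,
        "tre_mean_mm": tre_mean,
        "tre_std_mm": tre_std,
        "n_excluded": int(sum(r["excluded"] for r in rows)),
        "overlap_threshold": config.overlap_threshold,
        "dist_tol_mm": config.dist_tol_mm,
    }
    provenance = {
        "camera_preset": preset.name,
        "algorithm": config.algorithm,
        "seed": config.seed,
    }
    return EvaluationReport(per_position=tuple(rows), summary=summary, provenance=provenance)


# ---------------------------------------------------------------------------
# report formatting
# ---------------------------------------------------------------------------


def _fmt_cell(mean, std, excluded_all):
    if excluded_all or mean is None:
        return "Overlay < 95%"
    return f"{mean:.2f} ± {std:.2f}"


def markdown_table(reports) -> str:
    """Merge evaluation reports into one markdown table (one row per camera
    preset, FRE/TRE columns per algorithm; fully excluded configurations
    show "Overlay < 95%")."""
    algos = sorted({r.provenance["algorithm"] for r in reports})
    presets = []
    for r in reports:
        name = r.provenance["camera_preset"]
        if name not in presets:
            presets.append(name)
    header = (
        "| Camera | "
        + " | ".join(f"FRE {a}" for a in algos)
        + " | "
        + " | ".join(f"TRE {a}" for a in algos)
        + " |"
    )
    sep = "|" + "---|" * (1 + 2 * len(algos))
    lines = [header, sep]
    for p in presets:
        cells = []
        for metric in ("fre", "tre"):
            for a in algos:
                match = [
                    r
                    for r in reports
                    if r.provenance["camera_preset"] == p and r.provenance["algorithm"] == a
                ]
                if not match:
                    cells.append("-")
                    continue
                r = match[0]
                phase = "registration" if metric == "fre" else "testing"
                rows = [x for x in r.per_position if x["phase"] == phase]
                excluded_all = all(x["excluded"] for x in rows) if rows else True
                cells.append(
                    _fmt_cell(
                        r.summary[f"{metric}_mean_mm"], r.summary[f"{metric}_std_mm"], excluded_all
                    )
                )
        lines.append("| " + p + " | " + " | ".join(cells) + " |")
    return "\n".join(lines)
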