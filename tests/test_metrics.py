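import numpy as np
import pytest

from depthreg.config import BenchmarkConfig
from depthreg.exceptions import DataError, EmptyRoiError, NoOverlapError
from depthreg.geometry import apply, random_transform, rigid_fit
from depthreg.metrics import (
    EvaluationReport,
    crop_roi,
    landmark_register,
    markdown_table,
    overlap_fraction,
    run_benchmark,
    surface_rmse_mm,
)


@pytest.fixture()
def cloud():
    return np.random.default_rng(0).normal(size=(300, 3)) * 50


class TestOverlapFraction:
    def test_identical_clouds(self, cloud):
        assert overlap_fraction(cloud, cloud, 1.0) == 1.0

    def test_far_shifted_cloud(self, cloud):
        far = cloud + 10.0 * 1.0 * 400  # 10x tolerance beyond the extent
        assert overlap_fraction(far, cloud, 1.0) == 0.0

    def test_fraction_counts_points_within_tolerance(self):
        tgt = np.zeros((1, 3))
        src = np.array([[0.5, 0, 0], [2.0, 0, 0], [0.2, 0, 0], [5.0, 0, 0]])
        assert overlap_fraction(src, tgt, 1.0) == 0.5

    def test_validation(self, cloud):
        with pytest.raises(DataError):
            overlap_fraction(np.zeros((0, 3)), cloud, 1.0)
        with pytest.raises(DataError):
            overlap_fraction(cloud, cloud, 0.0)


class TestSurfaceRmse:
    def test_aligned_clouds_zero(self, cloud):
        assert surface_rmse_mm(cloud, cloud, 5.0) == 0.0

    def test_uniform_plane_lift(self):
        rng = np.random.default_rng(1)
        plane = np.column_stack([rng.uniform(0, 100, 500), rng.uniform(0, 100, 500), np.zeros(500)])
        lifted = plane + [0.0, 0.0, 2.0]
        assert np.isclose(surface_rmse_mm(lifted, plane, 5.0), 2.0)

    def test_matches_per_point_loop(self, cloud):
        rng = np.random.default_rng(2)
        src = cloud + rng.normal(scale=1.0, size=cloud.shape)
        got = surface_rmse_mm(src, cloud, 5.0)
        dists = []
        for p in src:
            d = np.min(np.linalg.norm(cloud - p, axis=1))
            if d <= 5.0:
                dists.append(d)
        assert abs(got - np.sqrt(np.mean(np.array(dists) ** 2))) < 1e-12

    def test_no_overlap_raises(self, cloud):
        with pytest.raises(NoOverlapError):
            surface_rmse_mm(cloud + 1e5, cloud, 5.0)

    def test_invariant_to_common_rebasing(self, cloud):
        src = cloud + np.random.default_rng(3).normal(scale=0.5, size=cloud.shape)
        w = random_transform(np.random.default_rng(4), 40, 200)
        a = surface_rmse_mm(src, cloud, 5.0)
        b = surface_rmse_mm(apply(w, src), apply(w, cloud), 5.0)
        assert abs(a - b) < 1e-9


class TestCropRoi:
    def test_box_covering_everything(self, cloud):
        box = np.stack([cloud.min(0) - 1, cloud.max(0) + 1])
        assert np.array_equal(crop_roi(cloud, box), cloud)

    def test_closed_boundary_convention(self):
        box = np.array([[0.0, 0, 0], [1.0, 1, 1]])
        pts = np.array([[0.0, 0.5, 0.5], [1.0, 1.0, 1.0], [1.0001, 0.5, 0.5]])
        out = crop_roi(pts, box, margin_mm=0.0)
        assert len(out) == 2

    def test_margin_and_brute_force_count(self, cloud):
        box = np.array([[-20.0, -20, -20], [20.0, 20, 20]])
        for margin in (0.0, 5.0):
            out = crop_roi(cloud, box, margin)
            lo, hi = box[0] - margin, box[1] + margin
            expected = np.sum(np.all((cloud >= lo) & (cloud <= hi), axis=1))
            assert len(out) == expected

    def test_empty_roi_raises(self, cloud):
        with pytest.raises(EmptyRoiError):
            crop_roi(cloud, np.array([[1e5, 1e5, 1e5], [1e5 + 1, 1e5 + 1, 1e5 + 1]]))


class TestLandmarkRegister:
    def _fiducials(self, seed=0):
        return np.random.default_rng(seed).uniform(-80, 80, size=(8, 3))

    def test_noise_free_fre_tre_zero(self):
        mr = self._fiducials()
        t_true = random_transform(np.random.default_rng(1), 30, 200)
        measured = apply(t_true, mr)
        t, fre, tre = landmark_register(measured, mr)
        assert fre < 1e-9 and tre < 1e-9

    def test_default_split_is_half_half(self):
        mr = self._fiducials()
        t, fre, tre = landmark_register(mr, mr)
        # with the 4 + 4 split the fitted transform is identity here
        assert fre < 1e-9 and tre < 1e-9
        assert np.allclose(t.matrix(), np.eye(4), atol=1e-9)

    def test_tre_dominates_fre_statistically(self):
        """Held-out error exceeds fitted error on average over noisy trials
        (verified against the Monte-Carlo expectation that the fit absorbs
        part of the noise in the registration subset)."""
        mr = self._fiducials(2)
        rng = np.random.default_rng(3)
        fres, tres = [], []
        for _ in range(500):
            measured = mr + rng.normal(scale=0.3, size=mr.shape)
            _, fre, tre = landmark_register(measured, mr)
            fres.append(fre)
            tres.append(tre)
        assert np.mean(tres) >= np.mean(fres)

    def test_overlapping_subsets_rejected(self):
        mr = self._fiducials()
        with pytest.raises(DataError):
            landmark_register(mr, mr, use_for_registration=range(8))
        with pytest.raises(DataError):
            landmark_register(mr, mr, use_for_registration=[0, 1])


class TestBenchmark:
    @pytest.fixture(scope="class")
    def small_zero_noise_report(self):
        cfg = BenchmarkConfig(
            preset="null",
            seed=0,
            n_positions=2,
            n_captures=2,
            phantom_spacing_mm=2.5,
            tracking_rot_sigma_deg=0.0,
            tracking_trans_sigma_mm=0.0,
        )
        return run_benchmark(cfg)

    def test_zero_noise_closure(self, small_zero_noise_report):
        s = small_zero_noise_report.summary
        assert s["fre_mean_mm"] < 1e-6
        assert s["tre_mean_mm"] < 1e-6
        assert s["n_excluded"] == 0

    def test_protocol_counts(self, small_zero_noise_report):
        rows = small_zero_noise_report.per_position
        reg = [r for r in rows if r["phase"] == "registration"]
        tst = [r for r in rows if r["phase"] == "testing"]
        assert len(reg) == 2 and len(tst) == 2
        assert all(r["n_captures"] == 2 for r in reg)

    def test_summary_matches_row_recomputation(self, small_zero_noise_report):
        rows = small_zero_noise_report.per_position
        s = small_zero_noise_report.summary
        fres = [r["fre_mm"] for r in rows if r["phase"] == "registration" and not r["excluded"]]
        assert np.isclose(s["fre_mean_mm"], np.mean(fres))
        assert np.isclose(s["fre_std_mm"], np.std(fres))

    def test_report_json_round_trip(self, small_zero_noise_report, tmp_path):
        small_zero_noise_report.to_json(tmp_path / "r.json")
        back = EvaluationReport.from_json(tmp_path / "r.json")
        assert back.summary == small_zero_noise_report.summary
        assert list(back.per_position) == list(small_zero_noise_report.per_position)

    def test_markdown_table_formats_exclusions(self):
        rep = EvaluationReport(
            per_position=(
                {"phase": "registration", "position_id": 0, "n_captures": 5,
                 "fre_mm": None, "tre_mm": None, "overlap_fraction": 0.8, "excluded": True},
                {"phase": "testing", "position_id": 0, "n_captures": 5,
                 "fre_mm": None, "tre_mm": 2.0, "overlap_fraction": 0.99, "excluded": False},
            ),
            summary={"fre_mean_mm": None, "fre_std_mm": None,
                     "tre_mean_mm": 2.0, "tre_std_mm": 0.0,
                     "n_excluded": 1, "overlap_threshold": 0.95, "dist_tol_mm": 5.0},
            provenance={"camera_preset": "x", "algorithm": "icp", "seed": 0},
        )
        table = markdown_table([rep])
        assert "Overlay < 95%" in table
        assert "2.00 ± 0.00" in table

    def test_exclusion_gate_near_threshold(self):
        """A position at 94% overlap is excluded at the 95% threshold."""
        rep = EvaluationReport(
            per_position=(
                {"phase": "registration", "position_id": 0, "n_captures": 5,
                 "fre_mm": 1.0, "tre_mm": None, "overlap_fraction": 0.94, "excluded": True},
            ),
            summary={"fre_mean_mm": None, "fre_std_mm": None, "tre_mean_mm": None,
                     "tre_std_mm": None, "n_excluded": 1,
                     "overlap_threshold": 0.95, "dist_tol_mm": 5.0},
            provenance={"camera_preset": "x", "algorithm": "icp", "seed": 0},
        )
        # invariant: excluded rows never contribute to the summary
        assert rep.summary["fre_mean_mm"] is None
        assert rep.per_position[0]["excluded"] is (0.94 < 0.95)
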