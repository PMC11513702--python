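"""Per-tooth metrics: landmark geometry, coverage percentages, thickness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gingimetry import ArchParams, generate_arch_pair, register
from gingimetry.measurement import (
    CEJUnavailable,
    MeasurementConfig,
    ToothMeasurementRecord,
    assess_case,
    complete_root_coverage,
    deepest_recession_point,
    mean_root_coverage,
    recession_depth,
    recession_reduction,
    thickness_profile,
)
from gingimetry.registration import RegistrationResult, apply_transform, make_transform
from gingimetry.synthetic import _grid_mesh
from scipy.spatial.transform import Rotation

Z = np.array([0.0, 0.0, 1.0])


def _record(tooth_id="T", pre=2.0, post=1.0, **kw):
    base = dict(
        tooth_id=tooth_id,
        recession_depth_pre=pre,
        recession_depth_post=post,
        recession_reduction=pre - post if pre is not None else 0.0,
        mrc_percent=None,
        complete_coverage=None if post is None else post <= 0,
        thickness_gain=0.0,
        thickness_samples=[],
        measurement_mode="full_profile",
    )
    base.update(kw)
    return ToothMeasurementRecord(**base)


class TestDeepestPoint:
    def test_returns_most_apical_point(self):
        margin = np.array([(0, 0, 2), (0, 0, 1), (0, 0, 3)], dtype=float)
        assert np.array_equal(deepest_recession_point(margin, Z), [0, 0, 1])

    def test_ties_broken_by_lowest_index(self):
        margin = np.array([(1, 0, 5), (2, 0, 5), (3, 0, 5)], dtype=float)
        assert np.array_equal(deepest_recession_point(margin, Z), [1, 0, 5])

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_result_minimises_axial_coordinate(self, seed):
        rng = np.random.default_rng(seed)
        margin = rng.normal(size=(12, 3))
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        p = deepest_recession_point(margin, axis)
        assert np.array_equal(p, margin[np.argmin(margin @ axis)])


class TestRecessionDepth:
    def test_margin_apical_of_cej(self):
        cej = np.array([(0, 0, 0), (1, 0, 0)], dtype=float)
        assert recession_depth(np.array([0, 0, -1.5]), cej, Z) == pytest.approx(1.5)

    def test_margin_on_cej_is_zero(self):
        cej = np.array([(0, 0, 0)], dtype=float)
        assert recession_depth(np.array([0.0, 0, 0]), cej, Z) == 0.0

    def test_margin_beyond_cej_is_negative(self):
        cej = np.array([(0, 0, 0)], dtype=float)
        assert recession_depth(np.array([0, 0, 0.3]), cej, Z) == pytest.approx(-0.3)

    def test_nearest_cej_point_chosen_in_orthogonal_plane(self):
        # the contralateral CEJ arm (far in xy) must not be paired
        cej = np.array([(0, 0, -5), (8, 0, 0)], dtype=float)
        assert recession_depth(np.array([0, 0, -1.0]), cej, Z) == pytest.approx(-4.0)

    def test_missing_cej_flags_metric_unavailable(self):
        with pytest.raises(CEJUnavailable):
            recession_depth(np.zeros(3), None, Z)


class TestRecessionReduction:
    def test_identical_points_zero(self):
        p = np.array([1.0, 2.0, 3.0])
        assert recession_reduction(p, p, Z) == 0.0

    def test_pure_axial_displacement_is_exact(self):
        p = np.array([5.0, 1.0, -2.0])
        assert recession_reduction(p, p + 1.0 * Z, Z) == pytest.approx(1.0)
        assert recession_reduction(p, p - 0.7 * Z, Z) == pytest.approx(-0.7)

    def test_euclidean_vs_axial_modes(self):
        p = np.zeros(3)
        q = np.array([0.3, 0.0, 0.4])
        assert recession_reduction(p, q, Z, mode="euclidean") == pytest.approx(0.5)
        assert recession_reduction(p, q, Z, mode="axial") == pytest.approx(0.4)

    def test_invariant_under_common_rigid_transform(self):
        rng = np.random.default_rng(4)
        p, q = rng.normal(size=(2, 3))
        T = make_transform(
            Rotation.from_rotvec(rng.normal(size=3)).as_matrix(), rng.normal(size=3)
        )
        axis_t = T[:3, :3] @ Z
        before = recession_reduction(p, q, Z)
        after = recession_reduction(
            apply_transform(p, T), apply_transform(q, T), axis_t
        )
        assert after == pytest.approx(before, abs=1e-9)

    def test_never_consults_cej(self, quiet_pair):
        """The CEJ-free metric stays computable with cej stripped."""
        pre, post, anns, truth = quiet_pair
        ann = anns[0]
        ann_nocej = type(ann)(
            **{
                **ann.__dict__,
                "cej": None,
            }
        )
        apex_pre = deepest_recession_point(ann_nocej.margin_pre, ann.coronal_axis)
        apex_post = deepest_recession_point(ann_nocej.margin_post, ann.coronal_axis)
        r = recession_reduction(apex_pre, apex_post, ann.coronal_axis)
        assert r == pytest.approx(truth.by_id(ann.tooth_id).true_reduction, abs=1e-6)


class TestCoveragePercentages:
    def test_mrc_reference_cases(self):
        recs = [
            _record("A", 2.0, 0.0),
            _record("B", 2.0, 1.0),
            _record("C", 2.0, -0.2),
        ]
        summary = mean_root_coverage(recs)
        per = dict(summary.per_tooth)
        assert per["A"] == pytest.approx(100.0)
        assert per["B"] == pytest.approx(50.0)
        assert per["C"] == pytest.approx(110.0)

    def test_zero_pre_depth_excluded_with_warning(self):
        recs = [_record("A", 2.0, 1.0), _record("B", 0.0, 0.0)]
        with pytest.warns(UserWarning):
            summary = mean_root_coverage(recs)
        assert summary.n_excluded == 1
        assert len(summary.per_tooth) == 1

    def test_crc_21_of_82(self):
        recs = [_record(f"T{i}", 2.0, 0.0 if i < 21 else 1.0) for i in range(82)]
        assert complete_root_coverage(recs) == 25.61

    def test_crc_limits(self):
        none_covered = [_record(f"T{i}", 2.0, 1.0) for i in range(7)]
        all_covered = [_record(f"T{i}", 2.0, -0.1) for i in range(7)]
        assert complete_root_coverage(none_covered) == 0.0
        assert complete_root_coverage(all_covered) == 100.0
        with pytest.raises(ValueError):
            complete_root_coverage([])

    def test_mrc_100_iff_post_depth_zero(self):
        rec = _record("A", 1.7, 0.0)
        summary = mean_root_coverage([rec])
        assert dict(summary.per_tooth)["A"] == pytest.approx(100.0)
        assert rec.complete_coverage
        beyond = _record("B", 1.7, -0.3)
        assert dict(mean_root_coverage([beyond]).per_tooth)["B"] > 100.0
        assert beyond.complete_coverage


def _cylinder_band(radius, d_theta=0.24, n_theta=60, z_lo=-8.0, z_hi=2.0, n_z=50):
    theta = np.linspace(-d_theta, d_theta, n_theta)
    z = np.linspace(z_lo, z_hi, n_z)
    return _grid_mesh(theta, z, np.full((n_theta, n_z), radius))


class TestThicknessProfile:
    def test_identical_meshes_zero_gain_full_profile(self):
        mesh = _cylinder_band(25.0)
        apex = np.array([25.0, 0.0, -2.0])
        samples, gain, mode = thickness_profile(
            mesh, mesh, apex, Z, np.array([1.0, 0.0, 0.0])
        )
        assert mode == "full_profile"
        assert gain == pytest.approx(0.0, abs=1e-9)
        assert all(abs(d) < 1e-9 for _, d in samples)

    def test_uniform_inflation_recovered(self):
        """A 0.33 mm outward offset over the whole band reads back as a
        0.33 mm gain (within surface-discretisation error)."""
        pre = _cylinder_band(25.0)
        post = _cylinder_band(25.33)
        apex = np.array([25.0, 0.0, -2.0])
        samples, gain, mode = thickness_profile(
            pre, post, apex, Z, np.array([1.0, 0.0, 0.0])
        )
        assert mode == "full_profile"
        assert gain == pytest.approx(0.33, abs=0.02)

    def test_apex_only_when_grid_sample_missing(self):
        pre = _cylinder_band(25.0)
        post = _cylinder_band(25.1, z_lo=-4.5)  # apical samples fall off the sheet
        apex = np.array([25.0, 0.0, -2.0])
        samples, gain, mode = thickness_profile(
            pre, post, apex, Z, np.array([1.0, 0.0, 0.0])
        )
        assert mode == "apex_only"
        assert gain == pytest.approx(0.1, abs=0.02)

    def test_six_point_grid_without_apex_sample(self):
        pre = _cylinder_band(25.0)
        cfg = MeasurementConfig(include_apex=False)
        samples, _, mode = thickness_profile(
            pre, pre, np.array([25.0, 0.0, -2.0]), Z, np.array([1.0, 0, 0]), cfg
        )
        assert len(samples) == 6
        assert all(abs(off) > 0 for off, _ in samples)
        assert mode == "full_profile"


class TestAssessCase:
    def test_noise_free_case_recovers_ground_truth(self, registered_quiet):
        pre, post, anns, truth, reg = registered_quiet
        records = assess_case(pre, post, anns, reg)
        assert len(records) == len(anns)
        for r in records:
            t = truth.by_id(r.tooth_id)
            assert r.recession_depth_pre == pytest.approx(
                t.true_recession_depth_pre, abs=1e-3
            )
            assert r.recession_reduction == pytest.approx(t.true_reduction, abs=1e-3)
            assert r.complete_coverage == t.complete_coverage
            assert r.thickness_gain == pytest.approx(t.true_thickness_gain, abs=0.02)
            assert r.measurement_mode == "full_profile"

    def test_identical_casts_measure_no_change(self):
        params = ArchParams(
            n_teeth=3,
            seed=9,
            coverage_fraction_distribution=(0.0, 0.0),
            thickness_gain_distribution=(0.0, 0.0),
            noise_sd=0.0,
            max_rotation_deg=0.0,
            max_translation_mm=0.0,
            artifact_probability=0.0,
            mesh_edge_length=0.4,
        )
        pre, post, anns, _ = generate_arch_pair(params)
        reg = RegistrationResult(np.eye(4), 0.0, 3, True, 0)
        for r in assess_case(pre, post, anns, reg):
            assert r.recession_reduction == pytest.approx(0.0, abs=1e-12)
            assert r.thickness_gain == pytest.approx(0.0, abs=1e-9)

    def test_artifact_fraction_propagates_to_apex_only_mode(self):
        params = ArchParams(
            n_teeth=10,
            seed=31,
            artifact_probability=0.5,
            noise_sd=0.0,
            max_rotation_deg=0.0,
            max_translation_mm=0.0,
            mesh_edge_length=0.35,
        )
        pre, post, anns, truth = generate_arch_pair(params)
        reg = register(post, pre, anns)
        records = assess_case(pre, post, anns, reg)
        flagged = {t.tooth_id for t in truth.teeth if t.artifact}
        assert flagged  # seed chosen stochastically flags some teeth
        for r in records:
            expected = "apex_only" if r.tooth_id in flagged else "full_profile"
            assert r.measurement_mode == expected

    def test_replicates_and_raters_multiply_records(self, registered_quiet):
        pre, post, anns, _, reg = registered_quiet
        records = assess_case(
            pre, post, anns, reg, raters=("r1", "r2"), n_replicates=3, landmark_sd=0.02
        )
        assert len(records) == len(anns) * 2 * 3
        # jitter-free re-run is deterministic
        again = assess_case(
            pre, post, anns, reg, raters=("r1", "r2"), n_replicates=3, landmark_sd=0.02
        )
        assert [r.recession_reduction for r in records] == [
            r.recession_reduction for r in again
        ]

    def test_missing_cej_flags_record_not_failure(self, registered_quiet):
        pre, post, anns, truth, reg = registered_quiet
        stripped = []
        for ann in anns:
            clone = type(ann)(**{**ann.__dict__, "cej": None})
            stripped.append(clone)
        records = assess_case(pre, post, stripped, reg)
        for r in records:
            assert not r.cej_available
            assert r.recession_depth_pre is None and r.mrc_percent is None
            t = truth.by_id(r.tooth_id)
            assert r.recession_reduction == pytest.approx(t.true_reduction, abs=1e-3)
        with pytest.raises(ValueError):
            complete_root_coverage(records)
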