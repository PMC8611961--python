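"""Render -> quantify round trip and the summed 28-joint score."""

import numpy as np
import pytest

from scintira.atlas import JointAtlas
from scintira.cohort import PatientTruth, sample_cohort
from scintira.config import RenderConfig
from scintira.errors import LocalizationError, MeasurementError
from scintira.phantom import PlanarScan, ScanSet, render_scanset
from scintira.quantify import (
    JointMeasurement,
    PatientUptakeProfile,
    ReferenceMeasurement,
    compute_joint_ratio,
    locate_joint_rois,
    measure_reference_uptake,
    quantify_scanset,
    summed_uptake_28,
)

NOISE_OFF = RenderConfig(poisson_noise=False)


def make_patient(atlas, ratios=None, default_ratio=1.0, index=0):
    """Truth patient with prescribed per-joint ratios (non-affected status)."""
    true_ratios = {j.joint_id: default_ratio for j in atlas.joints}
    if ratios:
        true_ratios.update(ratios)
    return PatientTruth(
        patient_id=f"T-{index:03d}",
        index=index,
        disease="RA",
        severity_class="only",
        statuses={j.joint_id: "non_affected" for j in atlas.joints},
        true_ratios=true_ratios,
    )


class TestRoundTrip:
    def test_noise_free_recovery_within_2_percent(self, atlas, study_config):
        patient = sample_cohort(study_config.ra_cohort, atlas, seed=5)[0]
        profile = quantify_scanset(render_scanset(patient, atlas, NOISE_OFF), atlas)
        for jid, true in patient.true_ratios.items():
            assert abs(profile.ratio_of(jid) - true) / true < 0.02

    def test_unit_ratio_matches_reference_mean(self, atlas):
        patient = make_patient(atlas, default_ratio=1.0)
        ss = render_scanset(patient, atlas, NOISE_OFF)
        profile = quantify_scanset(ss, atlas)
        ref = profile.reference.mean_reference_counts
        assert ref == pytest.approx(NOISE_OFF.bone_count_level)
        for m in profile.measurements.values():
            assert m.mean_joint_counts == pytest.approx(ref, rel=1e-2)

    def test_noisy_recovery_mean_absolute_error_below_5_percent(
        self, atlas, study_config
    ):
        rc = RenderConfig(poisson_noise=True, seed=21)
        errors = []
        for patient in sample_cohort(study_config.ra_cohort, atlas, seed=6)[:4]:
            profile = quantify_scanset(render_scanset(patient, atlas, rc), atlas)
            errors.extend(
                abs(profile.ratio_of(jid) - true) / true
                for jid, true in patient.true_ratios.items()
            )
        assert len(errors) >= 100
        assert np.mean(errors) < 0.05

    def test_scale_invariance(self, atlas):
        patient = make_patient(atlas, ratios={"wrist_left": 2.3, "mcp2_right": 0.6})
        ss = render_scanset(patient, atlas, NOISE_OFF)
        before = quantify_scanset(ss, atlas)
        scaled = ScanSet(
            patient_id=ss.patient_id,
            scans={
                v: PlanarScan(
                    counts=(s.counts.astype(np.int64) * 3),
                    view=s.view,
                    pixel_size_mm=s.pixel_size_mm,
                )
                for v, s in ss.scans.items()
            },
        )
        after = quantify_scanset(scaled, atlas)
        for jid in before.measurements:
            assert after.ratio_of(jid) == pytest.approx(before.ratio_of(jid))

    def test_single_joint_monotonicity(self, atlas):
        base = make_patient(atlas)
        bumped = make_patient(atlas, ratios={"knee_left": 2.5}, index=1)
        p0 = quantify_scanset(render_scanset(base, atlas, NOISE_OFF), atlas)
        p1 = quantify_scanset(render_scanset(bumped, atlas, NOISE_OFF), atlas)
        assert p1.ratio_of("knee_left") > p0.ratio_of("knee_left")
        assert p1.summed_28 > p0.summed_28
        for jid in p0.measurements:
            if jid != "knee_left":
                assert p1.ratio_of(jid) == pytest.approx(p0.ratio_of(jid), abs=1e-6)


class TestLocalization:
    def test_centered_hotspot_refines_to_landmark(self, atlas):
        patient = make_patient(atlas, default_ratio=1.5)
        ss = render_scanset(patient, atlas, NOISE_OFF)
        for roi in locate_joint_rois(ss, atlas):
            j = atlas[roi.joint_id]
            assert roi.center[0] == pytest.approx(j.row, abs=1e-6)
            assert roi.center[1] == pytest.approx(j.col, abs=1e-6)

    def test_offset_hotspot_recovered_within_1_px(self, atlas):
        """Hotspot rendered 3 px away from the atlas landmark (inside the
        search radius) is re-centered by the centroid refinement."""
        df = atlas.to_frame()
        df.loc[df.joint_id == "mcp3_left", "row"] += 3
        shifted = JointAtlas.from_frame(df, aux_landmarks=atlas.aux_landmarks)
        patient = make_patient(atlas, default_ratio=1.5)
        ss = render_scanset(patient, shifted, NOISE_OFF)
        rois = {r.joint_id: r for r in locate_joint_rois(ss, atlas)}
        true_center = (atlas["mcp3_left"].row + 3, atlas["mcp3_left"].col)
        got = rois["mcp3_left"].center
        assert np.hypot(got[0] - true_center[0], got[1] - true_center[1]) < 1.0

    def test_landmark_outside_image_raises(self, atlas):
        df = atlas.to_frame()
        df.loc[df.joint_id == "mcp3_left", "row"] = 500
        broken = JointAtlas.from_frame(df, aux_landmarks=atlas.aux_landmarks)
        ss = render_scanset(make_patient(atlas), atlas, NOISE_OFF)
        with pytest.raises(LocalizationError, match="mcp3_left"):
            locate_joint_rois(ss, broken)


class TestReference:
    def test_uniform_image_gives_constant_reference(self, atlas):
        ss = ScanSet(
            patient_id="U",
            scans={
                "wholebody_anterior": PlanarScan(
                    counts=np.full((220, 80), 37, dtype=np.uint16),
                    view="wholebody_anterior",
                    pixel_size_mm=6.0,
                )
            },
        )
        ref = measure_reference_uptake(ss, atlas)
        assert ref.mean_reference_counts == pytest.approx(37.0)

    def test_phantom_reference_equals_bone_level(self, atlas):
        rc = RenderConfig(poisson_noise=False, background_count_level=10,
                          bone_count_level=100)
        ss = render_scanset(make_patient(atlas), atlas, rc)
        ref = measure_reference_uptake(ss, atlas)
        assert ref.mean_reference_counts == pytest.approx(100.0)

    def test_missing_wholebody_view_raises(self, atlas):
        ss = render_scanset(make_patient(atlas), atlas, NOISE_OFF)
        del ss.scans["wholebody_anterior"]
        with pytest.raises(MeasurementError):
            measure_reference_uptake(ss, atlas)

    def test_ratio_definition_and_zero_reference(self):
        ref = ReferenceMeasurement(50.0, "wholebody_anterior", [])
        assert compute_joint_ratio(50.0, ref) == 1.0
        with pytest.raises(MeasurementError):
            ReferenceMeasurement(0.0, "wholebody_anterior", [])


def _profile(atlas, ratios: dict, excluded=()):
    ref = ReferenceMeasurement(100.0, "wholebody_anterior", [])
    measurements = {
        jid: JointMeasurement(jid, 100.0 * r, 29, (0.0, 0.0), r)
        for jid, r in ratios.items()
    }
    return PatientUptakeProfile(
        patient_id="P", measurements=measurements, reference=ref,
        excluded=set(excluded),
    )


class TestSummed28:
    def test_all_ones_sums_to_28(self, atlas, das28_ids):
        prof = _profile(atlas, {j: 1.0 for j in das28_ids})
        assert summed_uptake_28(prof, atlas) == pytest.approx(28.0)

    def test_contralateral_imputation(self, atlas, das28_ids):
        ratios = {j: 1.0 for j in das28_ids if j != "knee_right"}
        ratios["knee_left"] = 1.5
        prof = _profile(atlas, ratios, excluded={"knee_right"})
        # 26 joints at 1.0 + measured knee 1.5 + imputed knee 1.5
        assert summed_uptake_28(prof, atlas) == pytest.approx(29.0)

    def test_both_partners_excluded_use_patient_mean(self, atlas, das28_ids):
        ratios = {j: 2.0 for j in das28_ids if not j.startswith("knee")}
        prof = _profile(atlas, ratios, excluded={"knee_left", "knee_right"})
        assert summed_uptake_28(prof, atlas) == pytest.approx(28 * 2.0)

    def test_fewer_than_14_measurable_joints_rejected(self, atlas, das28_ids):
        prof = _profile(atlas, {j: 1.0 for j in das28_ids[:10]})
        with pytest.raises(MeasurementError):
            summed_uptake_28(prof, atlas)
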