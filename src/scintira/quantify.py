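"""Joint ROI quantification: uptake ratios and the summed 28-joint score.

For each joint the atlas landmark seeds a local search: the ROI center is
refined to the count-weighted centroid of the neighbourhood (search
radius twice the ROI radius), falling back to the landmark when the
neighbourhood is empty.  The joint uptake ratio is the mean count inside
the circular ROI divided by the mean count of the reference bone region
(two rectangular mid-femoral-shaft ROIs on the anterior whole-body view).

The summed 28-joint score adds the ratios of the DAS28 joints; an
excluded (arthroplasty) joint contributes its contralateral partner's
ratio, and if both partners are excluded it contributes the patient's
mean over the remaining DAS28 joints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import JointAtlas
from .errors import LocalizationError, MeasurementError
from .phantom import ScanSet, disk_mask

#: Half-extent (rows, cols) of each rectangular femoral reference ROI.
REFERENCE_HALF_EXTENT = (7, 1)


@dataclass
class JointROI:
    joint_id: str
    view: str
    center: tuple[float, float]  # refined (row, col)
    radius: int


@dataclass
class JointMeasurement:
    joint_id: str
    mean_joint_counts: float
    n_pixels: int
    refined_center: tuple[float, float]
    ratio: float

    def __post_init__(self):
        if self.n_pixels < 1:
            raise MeasurementError(f"{self.joint_id}: empty ROI")
        if self.ratio < 0:
            raise MeasurementError(f"{self.joint_id}: negative ratio")


@dataclass
class ReferenceMeasurement:
    mean_reference_counts: float
    view: str
    rois: list[tuple[int, int, int, int]]  # (r0, r1, c0, c1) inclusive corners

    def __post_init__(self):
        if self.mean_reference_counts <= 0:
            raise MeasurementError("reference region mean must be > 0")


@dataclass
class PatientUptakeProfile:
    patient_id: str
    measurements: dict[str, JointMeasurement]
    reference: ReferenceMeasurement
    excluded: set[str] = field(default_factory=set)
    summed_28: float | None = None

    def ratio_of(self, joint_id: str) -> float:
        return self.measurements[joint_id].ratio


def _refine_center(counts: np.ndarray, landmark: tuple[int, int],
                   radius: int) -> tuple[float, float]:
    """Count-weighted centroid within the search disk (radius 2x ROI).

    The centroid is snapped to the pixel grid: sub-pixel jitter of the
    centroid under counting noise is far below half a pixel, and measuring
    the ROI at a noise-driven fractional center would otherwise select
    upward-fluctuated pixels and bias the ROI mean high.  Genuine landmark
    offsets (whole pixels) are still recovered.
    """
    rr, cc = disk_mask(counts.shape, landmark, 2 * radius)
    w = counts[rr, cc].astype(float)
    total = w.sum()
    if total <= 0:
        return float(landmark[0]), float(landmark[1])
    return (
        float(np.rint((rr * w).sum() / total)),
        float(np.rint((cc * w).sum() / total)),
    )


def locate_joint_rois(scanset: ScanSet, atlas: JointAtlas,
                      joints=None) -> list[JointROI]:
    """Refined circular ROI placements for the requested joints (default all)."""
    wanted = set(joints) if joints is not None else None
    placements = []
    for j in atlas.joints:
        if wanted is not None and j.joint_id not in wanted:
            continue
        if j.view not in scanset:
            raise LocalizationError(
                f"view {j.view} missing for joint {j.joint_id}"
            )
        counts = scanset[j.view].counts
        if not (0 <= j.row < counts.shape[0] and 0 <= j.col < counts.shape[1]):
            raise LocalizationError(
                f"landmark of joint {j.joint_id} outside view {j.view}"
            )
        center = _refine_center(counts, (j.row, j.col), j.roi_radius)
        placements.append(JointROI(j.joint_id, j.view, center, j.roi_radius))
    return placements


def measure_reference_uptake(scanset: ScanSet, atlas: JointAtlas) -> ReferenceMeasurement:
    """Mean counts over the bilateral mid-femoral-shaft reference ROIs.

    Each rectangle is centered at the midpoint of the hip and knee
    landmarks of its side; the two ROI means are averaged.
    """
    view = "wholebody_anterior"
    if view not in scanset:
        raise MeasurementError("whole-body anterior view required for reference uptake")
    counts = scanset[view].counts
    hh, hw = REFERENCE_HALF_EXTENT
    means, rois = [], []
    for side in ("right", "left"):
        hip = atlas.aux_landmarks[f"hip_{side}"]
        knee = atlas[f"knee_{side}"]
        mid_r = (hip[1] + knee.row) // 2
        mid_c = (hip[2] + knee.col) // 2
        r0, r1 = mid_r - hh, mid_r + hh
        c0, c1 = mid_c - hw, mid_c + hw
        if r0 < 0 or c0 < 0 or r1 >= counts.shape[0] or c1 >= counts.shape[1]:
            raise MeasurementError(f"reference ROI ({side}) outside whole-body view")
        means.append(float(counts[r0 : r1 + 1, c0 : c1 + 1].mean()))
        rois.append((r0, r1, c0, c1))
    mean_ref = float(np.mean(means))
    if mean_ref <= 0:
        raise MeasurementError("reference region mean is non-positive")
    return ReferenceMeasurement(mean_reference_counts=mean_ref, view=view, rois=rois)


def compute_joint_ratio(mean_joint: float, reference: ReferenceMeasurement) -> float:
    """Joint-to-bone uptake ratio: mean joint counts / mean reference counts."""
    if reference.mean_reference_counts <= 0:
        raise MeasurementError("cannot form ratio: non-positive reference mean")
    return mean_joint / reference.mean_reference_counts


def quantify_scanset(scanset: ScanSet, atlas: JointAtlas,
                     excluded: set[str] | None = None,
                     joints=None) -> PatientUptakeProfile:
    """Measure every (non-excluded) joint and the summed 28-joint score."""
    excluded = set(excluded or ())
    reference = measure_reference_uptake(scanset, atlas)
    wanted = [
        j.joint_id
        for j in atlas.joints
        if j.joint_id not in excluded and (joints is None or j.joint_id in set(joints))
    ]
    measurements: dict[str, JointMeasurement] = {}
    for roi in locate_joint_rois(scanset, atlas, joints=wanted):
        counts = scanset[roi.view].counts
        rr, cc = disk_mask(counts.shape, roi.center, roi.radius)
        mean_joint = float(counts[rr, cc].mean())
        measurements[roi.joint_id] = JointMeasurement(
            joint_id=roi.joint_id,
            mean_joint_counts=mean_joint,
            n_pixels=int(rr.size),
            refined_center=roi.center,
            ratio=compute_joint_ratio(mean_joint, reference),
        )
    profile = PatientUptakeProfile(
        patient_id=scanset.patient_id,
        measurements=measurements,
        reference=reference,
        excluded=excluded,
    )
    das28_ids = {j.joint_id for j in atlas.das28_joints()}
    if das28_ids <= (set(measurements) | excluded):
        profile.summed_28 = summed_uptake_28(profile, atlas)
    return profile


def summed_uptake_28(profile: PatientUptakeProfile, atlas: JointAtlas) -> float:
    """Summed joint uptake ratio over the 28 DAS28 joints with imputation."""
    das28 = atlas.das28_joints()
    measured = {
        j.joint_id: profile.measurements[j.joint_id].ratio
        for j in das28
        if j.joint_id in profile.measurements and j.joint_id not in profile.excluded
    }
    if len(measured) < 14:
        raise MeasurementError(
            f"profile unusable: only {len(measured)} measurable DAS28 joints"
        )
    mean_remaining = float(np.mean(list(measured.values())))
    total = 0.0
    for j in das28:
        if j.joint_id in measured:
            total += measured[j.joint_id]
            continue
        partner = atlas.partner_of(j.joint_id)
        if partner is not None and partner in measured:
            total += measured[partner]
        else:
            total += mean_remaining
    return total


# ------------------------------------------------------------------ tables


def measurements_table(profiles: list[PatientUptakeProfile]) -> pd.DataFrame:
    """Per-joint measurement table (one row per patient-joint)."""
    rows = []
    for p in profiles:
        for m in p.measurements.values():
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "joint_id": m.joint_id,
                    "mean_joint": m.mean_joint_counts,
                    "mean_reference": p.reference.mean_reference_counts,
                    "ratio": m.ratio,
                }
            )
    return pd.DataFrame(rows)


def summed_table(profiles: list[PatientUptakeProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in profiles],
            "summed_28": [p.summed_28 for p in profiles],
        }
    )
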