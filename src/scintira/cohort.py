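"""Synthetic patient cohorts: joint statuses, true uptake ratios, clinical data.

The generative model, per patient:

1. A latent severity class is drawn from ``activity_mixture`` (its
   proportions mirror the observed low/moderate/high disease-activity
   split).  Each class carries shift parameters that scale the per-joint
   probability of clinical involvement and shift the status-conditional
   uptake-ratio means.
2. Every joint independently receives a status in {non-affected, tender,
   swollen, both} and a true joint-to-bone uptake ratio drawn from the
   status-conditional truncated normal (floor ``ratio_floor``, sampled by
   rejection).  A patient-level offset (SD ``patient_effect_sd``) shifts
   all of a patient's ratio means, modelling global tracer-uptake
   variability between patients.
3. The latent joint burden z (standardized count of active DAS28 joints
   plus their mean uptake ratio) drives ESR on the log scale and the
   patient global assessment linearly, with class-specific intercept
   shifts.
4. DAS28-ESR is computed from the drawn TJC/SJC/ESR/GH and the recorded
   disease stratum is the thresholded category -- patients are *classified*,
   not assigned, exactly as in a clinical study.

Identical (config, seed) pairs give bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical
from .atlas import JointAtlas
from .config import ACTIVE_STATUSES, CohortConfig
from .errors import AnalysisError, ConfigurationError


def truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                     floor: float, size: int = 1) -> np.ndarray:
    """Draw from N(mean, sd) conditioned on x >= floor, by rejection."""
    out = np.empty(size)
    remaining = np.arange(size)
    while remaining.size:
        draws = rng.normal(mean, sd, size=remaining.size)
        good = draws >= floor
        out[remaining[good]] = draws[good]
        remaining = remaining[~good]
    return out


@dataclass
class PatientTruth:
    """Ground truth for one synthetic patient."""

    patient_id: str
    index: int
    disease: str
    severity_class: str  # latent generator class (sampled)
    statuses: dict[str, str]  # joint_id -> status
    true_ratios: dict[str, float]  # joint_id -> ratio (excluded joints absent)
    excluded_joints: set[str] = field(default_factory=set)
    esr: float = 10.0
    global_assessment: float = 40.0
    das28_esr: float | None = None
    disease_stratum: str | None = None  # classified from DAS28-ESR (RA only)

    def clinical_statuses(self, atlas: JointAtlas) -> list[clinical.JointClinicalStatus]:
        """Tender/swollen flags for the 28 DAS28 joints."""
        out = []
        for j in atlas.das28_joints():
            s = self.statuses[j.joint_id]
            out.append(
                clinical.JointClinicalStatus(
                    joint_id=j.joint_id,
                    tender=s in ("tender", "both"),
                    swollen=s in ("swollen", "both"),
                )
            )
        return out

    def n_active_das28(self, atlas: JointAtlas) -> int:
        return sum(
            1 for j in atlas.das28_joints() if self.statuses[j.joint_id] != "non_affected"
        )


def _sample_patient(cfg: CohortConfig, atlas: JointAtlas, index: int,
                    rng: np.random.Generator) -> PatientTruth:
    strata = list(cfg.activity_mixture.items())
    probs = np.array([s.proportion for _, s in strata])
    class_name, params = strata[rng.choice(len(strata), p=probs / probs.sum())]

    u = rng.normal(0.0, cfg.patient_effect_sd) if cfg.patient_effect_sd > 0 else 0.0

    statuses: dict[str, str] = {}
    ratios: dict[str, float] = {}
    for j in atlas.joints:
        base = cfg.base_prevalence(j.area)
        p_active = {s: min(1.0, base[s] * params.prevalence_scale) for s in ACTIVE_STATUSES}
        total = sum(p_active.values())
        if total > 1.0:
            p_active = {s: p / total for s, p in p_active.items()}
            total = 1.0
        r = rng.random()
        acc = 0.0
        status = "non_affected"
        for s in ACTIVE_STATUSES:
            acc += p_active[s]
            if r < acc:
                status = s
                break
        dist = cfg.ratio_distribution(status)
        shift = (
            params.ratio_shift_nonaffected
            if status == "non_affected"
            else params.ratio_shift_active
        )
        statuses[j.joint_id] = status
        ratios[j.joint_id] = float(
            truncated_normal(rng, dist.mean + shift + u, dist.sd, cfg.ratio_floor)[0]
        )

    das28_joints = [j.joint_id for j in atlas.das28_joints()]
    active = [jid for jid in das28_joints if statuses[jid] != "non_affected"]
    burden = len(active) + (
        float(np.mean([ratios[jid] for jid in active])) if active else 0.0
    )
    z = (burden - cfg.burden_standardization.mean) / cfg.burden_standardization.sd

    ec, gc = cfg.esr_coupling, cfg.gh_coupling
    esr = float(
        np.clip(
            math.exp(ec.log_intercept + params.esr_log_shift + ec.z_coef * z
                     + rng.normal(0.0, ec.sigma)),
            ec.floor,
            ec.ceiling,
        )
    )
    gh = float(
        np.clip(
            gc.intercept + params.gh_shift + gc.z_coef * z + rng.normal(0.0, gc.sigma),
            gc.floor,
            gc.ceiling,
        )
    )

    prefix = "RA" if cfg.disease == "RA" else "OA"
    patient = PatientTruth(
        patient_id=f"{prefix}-{index:03d}",
        index=index,
        disease=cfg.disease,
        severity_class=class_name,
        statuses=statuses,
        true_ratios=ratios,
        esr=esr,
        global_assessment=gh,
    )
    if cfg.disease == "RA":
        tjc, sjc, _ = clinical.count_joints(patient.clinical_statuses(atlas))
        patient.das28_esr = clinical.das28_esr(tjc, sjc, esr, gh)
        patient.disease_stratum = clinical.classify_activity(patient.das28_esr)
    return patient


def sample_cohort(cfg: CohortConfig, atlas: JointAtlas,
                  seed: int | None = None) -> list[PatientTruth]:
    """Generate a cohort of :class:`PatientTruth`; deterministic given seed.

    ``seed`` overrides ``cfg.seed`` when given.  Each patient draws from an
    independently spawned child stream, so cohorts of different sizes share
    their leading patients.
    """
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    children = root.spawn(cfg.n_patients)
    return [
        _sample_patient(cfg, atlas, i, np.random.default_rng(children[i]))
        for i in range(cfg.n_patients)
    ]


#: Large-joint areas eligible for arthroplasty exclusion.
EXCLUDABLE_AREAS = ("knee", "elbow", "shoulder", "wrist")


def sample_exclusions(cohort: list[PatientTruth], n_excluded: int,
                      seed: int = 0, areas=None) -> list[PatientTruth]:
    """Flag ``n_excluded`` large joints (distinct patients) as arthroplasties.

    ``areas`` may be a multiset of area names of length ``n_excluded``
    (e.g. ``("knee", "knee", "elbow")``) to pin the anatomical composition;
    by default areas are drawn uniformly from knee/elbow.  Excluded joints
    lose their true ratio (nothing is rendered or measured there).
    """
    if n_excluded == 0:
        return cohort
    if n_excluded > len(cohort):
        raise AnalysisError(
            f"cannot place {n_excluded} exclusions across {len(cohort)} patients"
        )
    if areas is None:
        areas_list = None
    else:
        areas_list = list(areas)
        if len(areas_list) != n_excluded:
            raise ConfigurationError("exclusions: areas length must equal n_excluded")
        for a in areas_list:
            if a not in EXCLUDABLE_AREAS:
                raise ConfigurationError(f"exclusions: area {a!r} is not a large joint")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xE8C]))
    patient_idx = rng.choice(len(cohort), size=n_excluded, replace=False)
    for k, pi in enumerate(patient_idx):
        patient = cohort[pi]
        area = areas_list[k] if areas_list else str(rng.choice(("knee", "elbow")))
        side = str(rng.choice(("left", "right")))
        joint_id = f"{area}_{side}"
        if joint_id not in patient.statuses:
            raise AnalysisError(f"no joint {joint_id} available for exclusion")
        patient.excluded_joints.add(joint_id)
        patient.true_ratios.pop(joint_id, None)
    return cohort


def count_analyzable_das28_joints(cohort: list[PatientTruth], atlas: JointAtlas) -> int:
    """Number of DAS28 joints with a measurable ratio across the cohort."""
    das28 = {j.joint_id for j in atlas.das28_joints()}
    return sum(
        len(das28 - p.excluded_joints) for p in cohort
    )


# ------------------------------------------------------------------ tables


def joint_truth_table(cohort: list[PatientTruth], atlas: JointAtlas) -> pd.DataFrame:
    """One row per patient-joint: status flags, exclusion, true ratio."""
    rows = []
    for p in cohort:
        for j in atlas.joints:
            s = p.statuses[j.joint_id]
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "joint_id": j.joint_id,
                    "area": j.area,
                    "side": j.side,
                    "das28_member": j.das28_member,
                    "tender": s in ("tender", "both"),
                    "swollen": s in ("swollen", "both"),
                    "excluded": j.joint_id in p.excluded_joints,
                    "true_ratio": p.true_ratios.get(j.joint_id, float("nan")),
                }
            )
    return pd.DataFrame(rows)


def patient_truth_table(cohort: list[PatientTruth]) -> pd.DataFrame:
    """One row per patient: ESR, global assessment, DAS28-ESR, stratum."""
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort],
            "disease": [p.disease for p in cohort],
            "esr": [p.esr for p in cohort],
            "global_assessment": [p.global_assessment for p in cohort],
            "das28_esr": [p.das28_esr for p in cohort],
            "stratum": [p.disease_stratum for p in cohort],
        }
    )


def write_cohort_tables(cohort: list[PatientTruth], atlas: JointAtlas,
                        out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "joints": out / "cohort_joints.csv",
        "patients": out / "cohort_patients.csv",
    }
    joint_truth_table(cohort, atlas).to_csv(paths["joints"], index=False)
    patient_truth_table(cohort).to_csv(paths["patients"], index=False)
    return paths
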