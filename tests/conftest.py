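"""Shared fixtures: atlas, calibrated config, and a session-scoped
full-pipeline sweep (generate -> render -> quantify -> score) over many
seeds that several calibration-property tests share."""

from __future__ import annotations

import numpy as np
import pytest

from scintira.atlas import default_atlas
from scintira.clinical import PatientClinical
from scintira.cohort import sample_cohort, sample_exclusions
from scintira.config import RenderConfig, default_study_config
from scintira.diagnostics import pearson_correlation
from scintira.phantom import render_scanset
from scintira.quantify import quantify_scanset

N_PIPELINE_SEEDS = 100


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def study_config():
    return default_study_config()


@pytest.fixture(scope="session")
def das28_ids(atlas):
    return [j.joint_id for j in atlas.das28_joints()]


@pytest.fixture(scope="session")
def pipeline_seed_stats(atlas, study_config, das28_ids):
    """Per-seed full-pipeline statistics for the default RA study conditions.

    For each seed: sample the 65-patient cohort with 3 arthroplasty
    exclusions, render the phantom scan sets with Poisson noise, quantify
    the 28 DAS28 joints, score DAS28-ESR, and record
    - Pearson r between the measured summed 28-joint score and DAS28-ESR,
    - the measured summed-score mean of the classified high-activity stratum,
    - the clinically-active fraction among analyzable joints.
    """
    cfg = study_config
    r_values, high_means, active_fracs = [], [], []
    for seed in range(N_PIPELINE_SEEDS):
        cohort = sample_cohort(cfg.ra_cohort, atlas, seed=seed)
        cohort = sample_exclusions(
            cohort, cfg.exclusions.n_excluded, seed=seed, areas=cfg.exclusions.areas
        )
        rc = RenderConfig(poisson_noise=True, seed=9000 + seed)
        summed, das28, strata = [], [], []
        n_active = n_joints = 0
        for p in cohort:
            ss = render_scanset(p, atlas, rc)
            prof = quantify_scanset(ss, atlas, excluded=p.excluded_joints,
                                    joints=das28_ids)
            clin = PatientClinical(
                patient_id=p.patient_id,
                statuses=p.clinical_statuses(atlas),
                esr=p.esr,
                global_assessment=p.global_assessment,
            )
            summed.append(prof.summed_28)
            das28.append(clin.das28_esr)
            strata.append(clin.activity)
            for jid in das28_ids:
                if jid in p.excluded_joints:
                    continue
                n_joints += 1
                n_active += p.statuses[jid] != "non_affected"
        summed = np.array(summed)
        strata = np.array(strata)
        r_values.append(pearson_correlation(summed, das28).r)
        if (strata == "high").any():
            high_means.append(float(summed[strata == "high"].mean()))
        active_fracs.append(n_active / n_joints)
    return {
        "r": np.array(r_values),
        "high_means": np.array(high_means),
        "active_frac": np.array(active_fracs),
    }
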