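"""End-to-end study orchestration: simulate -> render -> quantify -> score ->
evaluate, with report tables mirroring a clinical imaging-biomarker study.

The report layout follows the conventional three-table structure of a
diagnostic bone-scintigraphy study: a baseline cohort summary (medians and
ranges), joint-level detection performance per joint area and overall
(AUC, Youden cut-off, sensitivity/specificity/PPV/NPV with CIs), and
disease-activity stratum comparisons plus correlations of the summed
28-joint uptake score with DAS28-ESR, ESR and the patient global
assessment.  The joint-level analysis is restricted to the 28 DAS28
joints minus arthroplasty exclusions; the six reporting areas are
shoulder, elbow, wrist, MCP, hand IP (thumb IP pooled with proximal IP)
and knee.

Everything is deterministic given the study seed; the report carries the
config hash and seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical, cohort, diagnostics, phantom, quantify
from .atlas import REPORT_AREAS, JointAtlas, default_atlas
from .config import StudyConfig, config_hash, to_dict
from .errors import StageError

log = logging.getLogger("scintira")


def round1(x: float) -> float:
    """Round to 1 decimal place, half away from zero (report style)."""
    sign = 1.0 if x >= 0 else -1.0
    return float(sign * np.floor(abs(float(x)) * 10.0 + 0.5) / 10.0)


def percent(num: int, den: int) -> float:
    """Percentage rounded to 1 decimal place, half away from zero."""
    return round1(100.0 * num / den)


def _median_range(values) -> dict:
    v = np.asarray(values, dtype=float)
    return {
        "median": float(np.median(v)),
        "min": float(v.min()),
        "max": float(v.max()),
        "n": int(v.size),
    }


def summarize_cohort(clinical_df: pd.DataFrame, joint_ratios,
                     summed_scores) -> dict:
    """Baseline-characteristics summary (medians/ranges, activity split)."""
    if len(clinical_df) == 0:
        raise StageError("summarize", "empty cohort")
    n = len(clinical_df)
    counts = {
        level: int((clinical_df["activity"] == level).sum())
        for level in clinical.ACTIVITY_LEVELS
    }
    return {
        "n_patients": n,
        "tender_joint_count": _median_range(clinical_df["tjc28"]),
        "swollen_joint_count": _median_range(clinical_df["sjc28"]),
        "esr": _median_range(clinical_df["esr"]),
        "global_assessment": _median_range(clinical_df["global_assessment"]),
        "das28_esr": _median_range(clinical_df["das28_esr"]),
        "joint_uptake_ratio": _median_range(joint_ratios),
        "summed_uptake_28": _median_range(summed_scores),
        "activity_counts": counts,
        "activity_percent": {k: percent(v, n) for k, v in counts.items()},
    }


def _summary_to_dict(s: diagnostics.DiagnosticSummary, n: int) -> dict:
    def prop(p: diagnostics.ProportionWithCI):
        if p.value is None:
            return {"percent": None, "ci_percent": None}
        return {
            "percent": round1(100.0 * p.value),
            "ci_percent": [round1(100.0 * p.ci[0]), round1(100.0 * p.ci[1])],
        }

    return {
        "n": n,
        "cutoff": s.cutoff,
        "auc": s.auc,
        "auc_ci": list(s.auc_ci) if s.auc_ci else None,
        "tp": s.tp,
        "fp": s.fp,
        "fn": s.fn,
        "tn": s.tn,
        "sensitivity": prop(s.sensitivity),
        "specificity": prop(s.specificity),
        "ppv": prop(s.ppv),
        "npv": prop(s.npv),
    }


def _comparison_to_dict(c: diagnostics.GroupComparisonResult | None) -> dict | None:
    if c is None:
        return None
    return {
        "test_used": c.test_used,
        "levene_p": c.levene_p,
        "global_p": c.global_p,
        "pairwise": {f"{a}|{b}": p for (a, b), p in c.pairwise.items()},
    }


def _correlation_to_dict(c: diagnostics.CorrelationResult) -> dict:
    return {"r": c.r, "ci": list(c.ci), "p": c.p, "n": c.n}


def _safe_compare(groups: dict, alpha: float):
    usable = {k: v for k, v in groups.items() if len(v) >= 3}
    if len(usable) < 2:
        return None
    return diagnostics.compare_groups(usable, alpha_levene=alpha)


def run_study(config: StudyConfig, out_dir: str | Path | None = None,
              write_images: bool = False, atlas: JointAtlas | None = None) -> dict:
    """Execute the full pipeline and return the study report dict.

    If ``out_dir`` is given the report and its CSV tables are exported
    there (plus rendered TIFF scan sets when ``write_images`` is set).
    Any stage failure raises :class:`StageError` naming the stage, and no
    partial outputs are left behind.
    """
    atlas = atlas or default_atlas()
    chash = config_hash(config)
    dx = config.diagnostics

    log.info("stage=simulate config=%s seed=%d", chash, config.seed)
    try:
        ra = cohort.sample_cohort(config.ra_cohort, atlas)
        ra = cohort.sample_exclusions(
            ra, config.exclusions.n_excluded, seed=config.seed,
            areas=config.exclusions.areas,
        )
        oa = cohort.sample_cohort(config.oa_cohort, atlas)
    except Exception as e:  # noqa: BLE001
        raise StageError("simulate", str(e)) from e

    log.info("stage=render_quantify n_ra=%d n_oa=%d", len(ra), len(oa))
    try:
        scans = {}
        profiles: dict[str, quantify.PatientUptakeProfile] = {}
        for i, p in enumerate(ra + oa):
            # distinct render sub-seed per cohort keeps the two independent
            offset = 0 if p.disease == "RA" else 100000
            ss = phantom.render_scanset(p, atlas, config.render,
                                        seed=config.render.seed + offset)
            profiles[p.patient_id] = quantify.quantify_scanset(
                ss, atlas, excluded=p.excluded_joints
            )
            if write_images and out_dir is not None:
                scans[p.patient_id] = ss
    except Exception as e:  # noqa: BLE001
        raise StageError("render_quantify", str(e)) from e

    log.info("stage=score")
    try:
        ra_clinical = [
            clinical.PatientClinical(
                patient_id=p.patient_id,
                statuses=p.clinical_statuses(atlas),
                esr=p.esr,
                global_assessment=p.global_assessment,
            )
            for p in ra
        ]
        clin_df = clinical.clinical_table(ra_clinical)
    except Exception as e:  # noqa: BLE001
        raise StageError("score", str(e)) from e

    log.info("stage=evaluate")
    try:
        das28_ids = [j.joint_id for j in atlas.das28_joints()]
        rows = []
        for p in ra:
            prof = profiles[p.patient_id]
            for jid in das28_ids:
                if jid in p.excluded_joints:
                    continue
                rows.append(
                    {
                        "patient_id": p.patient_id,
                        "joint_id": jid,
                        "area": atlas.report_area_of(jid),
                        "ratio": prof.ratio_of(jid),
                        "active": p.statuses[jid] != "non_affected",
                        "stratum": p.disease_stratum,
                    }
                )
        joint_df = pd.DataFrame(rows)
        n_analyzed = len(joint_df)
        n_active = int(joint_df["active"].sum())

        joint_diag = {}
        total = diagnostics.evaluate_marker(
            joint_df["ratio"], joint_df["active"],
            B=dx.bootstrap_samples, alpha=dx.ci_alpha, seed=config.seed + 10,
        )
        joint_diag["total"] = _summary_to_dict(total, n_analyzed)
        for area in REPORT_AREAS:
            sub = joint_df[joint_df["area"] == area]
            if sub["active"].nunique() < 2:
                joint_diag[area] = {"n": len(sub),
                                    "note": "single-class area, ROC undefined"}
                continue
            s = diagnostics.evaluate_marker(
                sub["ratio"], sub["active"],
                B=dx.bootstrap_samples, alpha=dx.ci_alpha, seed=config.seed + 11,
            )
            joint_diag[area] = _summary_to_dict(s, len(sub))

        summed = {p.patient_id: profiles[p.patient_id].summed_28 for p in ra}
        summed_arr = np.array([summed[p.patient_id] for p in ra])
        high = np.array([p.disease_stratum == "high" for p in ra])
        if high.any() and (~high).any():
            patient_diag = _summary_to_dict(
                diagnostics.evaluate_marker(
                    summed_arr, high, B=dx.bootstrap_samples,
                    alpha=dx.ci_alpha, seed=config.seed + 12,
                ),
                len(ra),
            )
        else:
            patient_diag = {"n": len(ra), "note": "single-class cohort, ROC undefined"}

        strata = {
            level: summed_arr[[p.disease_stratum == level for p in ra]]
            for level in clinical.ACTIVITY_LEVELS
        }
        oa_summed = np.array([profiles[p.patient_id].summed_28 for p in oa])
        stratum_stats = {
            level: {
                "n": int(v.size),
                "summed_mean": float(v.mean()) if v.size else None,
                "summed_sd": float(v.std(ddof=1)) if v.size > 1 else None,
            }
            for level, v in {**strata, "oa_comparison": oa_summed}.items()
        }
        comparisons = {
            "summed_by_stratum": _comparison_to_dict(
                _safe_compare(strata, dx.levene_alpha)
            ),
            "summed_by_stratum_with_oa": _comparison_to_dict(
                _safe_compare({**strata, "oa_comparison": oa_summed}, dx.levene_alpha)
            ),
            "active_ratio_by_stratum": _comparison_to_dict(
                _safe_compare(
                    {
                        level: joint_df.query("active and stratum == @level")["ratio"].values
                        for level in clinical.ACTIVITY_LEVELS
                    },
                    dx.levene_alpha,
                )
            ),
            "nonaffected_ratio_by_stratum": _comparison_to_dict(
                _safe_compare(
                    {
                        level: joint_df.query("not active and stratum == @level")["ratio"].values
                        for level in clinical.ACTIVITY_LEVELS
                    },
                    dx.levene_alpha,
                )
            ),
            "ratio_by_status": _comparison_to_dict(
                _safe_compare(
                    {
                        status: np.array(
                            [
                                profiles[p.patient_id].ratio_of(jid)
                                for p in ra
                                for jid in das28_ids
                                if jid not in p.excluded_joints
                                and p.statuses[jid] == status
                            ]
                        )
                        for status in ("non_affected", "tender", "swollen", "both")
                    },
                    dx.levene_alpha,
                )
            ),
        }

        clin_by_id = clin_df.set_index("patient_id")
        ordered = [p.patient_id for p in ra]
        correlations = {
            "summed_vs_das28": _correlation_to_dict(
                diagnostics.pearson_correlation(
                    summed_arr, clin_by_id.loc[ordered, "das28_esr"].values
                )
            ),
            "summed_vs_esr": _correlation_to_dict(
                diagnostics.pearson_correlation(
                    summed_arr, clin_by_id.loc[ordered, "esr"].values
                )
            ),
            "summed_vs_gh": _correlation_to_dict(
                diagnostics.pearson_correlation(
                    summed_arr, clin_by_id.loc[ordered, "global_assessment"].values
                )
            ),
        }

        cohort_summary = summarize_cohort(
            clin_df, joint_df["ratio"].values, summed_arr
        )

        oa_joint_count = cohort.count_analyzable_das28_joints(oa, atlas)
        report = {
            "provenance": {
                "config_hash": chash,
                "seed": int(config.seed),
                "version": _package_version(),
            },
            "cohort_summary": cohort_summary,
            "joint_diagnostics": joint_diag,
            "patient_diagnostics": patient_diag,
            "stratum_stats": stratum_stats,
            "comparisons": comparisons,
            "correlations": correlations,
            "audit": {
                "n_ra_patients": len(ra),
                "n_oa_patients": len(oa),
                "n_analyzed_joints": n_analyzed,
                "n_active_joints": n_active,
                "n_nonaffected_joints": n_analyzed - n_active,
                "active_percent": percent(n_active, n_analyzed),
                "n_oa_joints": oa_joint_count,
                "n_excluded_joints": int(sum(len(p.excluded_joints) for p in ra)),
            },
        }
        assert (
            report["audit"]["n_active_joints"]
            + report["audit"]["n_nonaffected_joints"]
            == report["audit"]["n_analyzed_joints"]
        )
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("evaluate", str(e)) from e

    if out_dir is not None:
        try:
            export_report(report, out_dir)
            cohort.write_cohort_tables(ra + oa, atlas, out_dir)
            quantify.measurements_table(list(profiles.values())).to_csv(
                Path(out_dir) / "measurements.csv", index=False
            )
            quantify.summed_table(list(profiles.values())).to_csv(
                Path(out_dir) / "summed_scores.csv", index=False
            )
            clin_df.to_csv(Path(out_dir) / "clinical.csv", index=False)
            if write_images:
                for ss in scans.values():
                    phantom.write_scanset(ss, Path(out_dir) / "scans")
        except StageError:
            raise
        except Exception as e:  # noqa: BLE001
            raise StageError("export", str(e)) from e
    return report


def _package_version() -> str:
    from . import __version__

    return __version__


def report_json(report: dict) -> str:
    """Canonical JSON serialization (stable key order, lossless floats)."""
    return json.dumps(report, sort_keys=True, indent=1, allow_nan=False)


def report_hash(report: dict) -> str:
    return hashlib.sha256(report_json(report).encode()).hexdigest()[:16]


# CSV schemas for the exported tables
TABLE1_COLUMNS = ["characteristic", "median", "min", "max", "n"]
TABLE2_COLUMNS = [
    "area", "n", "auc", "auc_ci_low", "auc_ci_high", "cutoff",
    "sensitivity_pct", "specificity_pct", "ppv_pct", "npv_pct",
]
TABLE3_COLUMNS = ["group", "n", "summed_mean", "summed_sd"]


def export_report(report: dict, out_dir: str | Path,
                  formats=("json", "csv")) -> dict[str, Path]:
    """Write the consolidated JSON report plus one CSV per report table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    try:
        if "json" in formats:
            path = out / "report.json"
            path.write_text(report_json(report))
            written["json"] = path
        if "csv" in formats:
            cs = report["cohort_summary"]
            rows1 = [
                {"characteristic": k, **v}
                for k, v in cs.items()
                if isinstance(v, dict) and "median" in v
            ]
            t1 = out / "table1_cohort.csv"
            pd.DataFrame(rows1, columns=TABLE1_COLUMNS).to_csv(t1, index=False)
            written["table1"] = t1

            rows2 = []
            for area, d in report["joint_diagnostics"].items():
                if "auc" not in d:
                    continue
                rows2.append(
                    {
                        "area": area,
                        "n": d["n"],
                        "auc": d["auc"],
                        "auc_ci_low": d["auc_ci"][0],
                        "auc_ci_high": d["auc_ci"][1],
                        "cutoff": d["cutoff"],
                        "sensitivity_pct": d["sensitivity"]["percent"],
                        "specificity_pct": d["specificity"]["percent"],
                        "ppv_pct": d["ppv"]["percent"],
                        "npv_pct": d["npv"]["percent"],
                    }
                )
            t2 = out / "table2_joint_detection.csv"
            pd.DataFrame(rows2, columns=TABLE2_COLUMNS).to_csv(t2, index=False)
            written["table2"] = t2

            rows3 = [
                {"group": g, "n": d["n"], "summed_mean": d["summed_mean"],
                 "summed_sd": d["summed_sd"]}
                for g, d in report["stratum_stats"].items()
            ]
            t3 = out / "table3_strata.csv"
            pd.DataFrame(rows3, columns=TABLE3_COLUMNS).to_csv(t3, index=False)
            written["table3"] = t3

            rows4 = [
                {"pair": k, "r": d["r"], "ci_low": d["ci"][0],
                 "ci_high": d["ci"][1], "p": d["p"], "n": d["n"]}
                for k, d in report["correlations"].items()
            ]
            t4 = out / "correlations.csv"
            pd.DataFrame(rows4).to_csv(t4, index=False)
            written["correlations"] = t4
    except Exception:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise
    return written


def import_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
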