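"""Configuration objects for cohort simulation, rendering and the study run.

All configs are plain dataclasses with ``to_dict``/``from_dict`` and YAML
round-tripping.  The packaged default (``data/default_config.yaml``) holds
the calibrated study conditions: a 65-patient rheumatoid-arthritis cohort
with three arthroplasty exclusions plus a 15-patient osteoarthritis
comparison cohort, with status-conditional uptake-ratio distributions and
ESR / global-assessment coupling constants derived from the published
group moments (see :mod:`scintira.calibration`).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError

STATUSES = ("non_affected", "tender", "swollen", "both")
ACTIVE_STATUSES = ("tender", "swollen", "both")


@dataclass
class RatioDistribution:
    """(mean, sd) of the true joint uptake ratio for one clinical status."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigurationError(f"ratio_distributions: sd must be > 0, got {self.sd}")


@dataclass
class StratumParams:
    """Per-severity-class mixture weight and shift parameters.

    ``prevalence_scale`` multiplies the base per-joint status probabilities;
    ``ratio_shift_active`` / ``ratio_shift_nonaffected`` are added to the
    status-conditional ratio means; ``esr_log_shift`` / ``gh_shift`` are
    added to the ESR (log scale) and global-assessment coupling intercepts.
    """

    proportion: float
    prevalence_scale: float = 1.0
    ratio_shift_active: float = 0.0
    ratio_shift_nonaffected: float = 0.0
    esr_log_shift: float = 0.0
    gh_shift: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.proportion <= 1.0:
            raise ConfigurationError(
                f"activity_mixture: proportion must be in [0,1], got {self.proportion}"
            )
        if self.prevalence_scale < 0:
            raise ConfigurationError("activity_mixture: prevalence_scale must be >= 0")


@dataclass
class EsrCoupling:
    """Log-linear link from latent joint burden to ESR (mm/h).

    ESR = clip(exp(intercept + shift + z_coef * z + eps), floor, ceiling)
    with z the patient's standardized latent burden and
    eps ~ N(0, sigma).
    """

    log_intercept: float = 2.54
    z_coef: float = 0.25
    sigma: float = 0.22
    floor: float = 2.0
    ceiling: float = 120.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ConfigurationError("esr_coupling: sigma must be >= 0")
        if self.floor < 1.0:
            raise ConfigurationError("esr_coupling: floor must be >= 1 (log-defined)")


@dataclass
class GhCoupling:
    """Linear link from latent burden to patient global assessment (0-100)."""

    intercept: float = 43.0
    z_coef: float = 6.0
    sigma: float = 7.0
    floor: float = 0.0
    ceiling: float = 100.0

    def __post_init__(self):
        if self.sigma < 0:
            raise ConfigurationError("gh_coupling: sigma must be >= 0")


@dataclass
class BurdenStandardization:
    """Population mean/SD used to standardize the latent joint burden."""

    mean: float = 8.0
    sd: float = 3.2

    def __post_init__(self):
        if self.sd <= 0:
            raise ConfigurationError("burden_standardization: sd must be > 0")


@dataclass
class CohortConfig:
    """Truth-level generative model for one patient cohort."""

    n_patients: int
    disease: str  # "RA" | "OA"
    status_prevalence: dict  # {"default" | area: {tender, swollen, both}}
    ratio_distributions: dict  # status -> RatioDistribution
    activity_mixture: dict  # stratum name -> StratumParams
    esr_coupling: EsrCoupling = field(default_factory=EsrCoupling)
    gh_coupling: GhCoupling = field(default_factory=GhCoupling)
    burden_standardization: BurdenStandardization = field(
        default_factory=BurdenStandardization
    )
    patient_effect_sd: float = 0.0
    ratio_floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.disease not in ("RA", "OA"):
            raise ConfigurationError(f"disease must be 'RA' or 'OA', got {self.disease!r}")
        if self.ratio_floor <= 0:
            raise ConfigurationError(f"ratio_floor must be > 0, got {self.ratio_floor}")
        if self.patient_effect_sd < 0:
            raise ConfigurationError("patient_effect_sd must be >= 0")
        for key, probs in self.status_prevalence.items():
            for status, p in probs.items():
                if status not in ACTIVE_STATUSES:
                    raise ConfigurationError(
                        f"status_prevalence[{key}]: unknown status {status!r}"
                    )
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"status_prevalence[{key}][{status}] must be in [0,1], got {p}"
                    )
            if sum(probs.values()) > 1.0 + 1e-9:
                raise ConfigurationError(
                    f"status_prevalence[{key}]: probabilities sum to more than 1"
                )
        self.ratio_distributions = {
            k: (v if isinstance(v, RatioDistribution) else RatioDistribution(**v))
            for k, v in self.ratio_distributions.items()
        }
        for status in ("non_affected",):
            if status not in self.ratio_distributions:
                raise ConfigurationError(
                    f"ratio_distributions must include {status!r}"
                )
        self.activity_mixture = {
            k: (v if isinstance(v, StratumParams) else StratumParams(**v))
            for k, v in self.activity_mixture.items()
        }
        total = sum(s.proportion for s in self.activity_mixture.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(
                f"activity_mixture: proportions must sum to 1, got {total}"
            )
        for conv, name in (
            (EsrCoupling, "esr_coupling"),
            (GhCoupling, "gh_coupling"),
            (BurdenStandardization, "burden_standardization"),
        ):
            val = getattr(self, name)
            if isinstance(val, dict):
                setattr(self, name, conv(**val))

    def base_prevalence(self, area: str) -> dict:
        probs = self.status_prevalence.get(area, self.status_prevalence["default"])
        return {s: probs.get(s, 0.0) for s in ACTIVE_STATUSES}

    def ratio_distribution(self, status: str) -> RatioDistribution:
        try:
            return self.ratio_distributions[status]
        except KeyError:
            raise ConfigurationError(f"ratio_distributions: no entry for {status!r}")


@dataclass
class RenderConfig:
    """Gamma-camera phantom rendering parameters.

    Only *relative* count levels matter for uptake ratios; the defaults
    put soft tissue at 10 and skeleton / reference bone at 100 mean counts
    per pixel, which gives roughly 1-2% Poisson noise on an ROI-mean ratio.
    """

    view_shapes: dict = field(default_factory=lambda: dict(_default_view_shapes()))
    pixel_size_mm: dict = field(default_factory=lambda: dict(_default_pixel_mm()))
    background_count_level: float = 10.0
    bone_count_level: float = 100.0
    hotspot_kernel_sigma: float = 1.8
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.background_count_level <= 0:
            raise ConfigurationError("background_count_level must be > 0")
        if self.bone_count_level <= 0:
            raise ConfigurationError("bone_count_level must be > 0")
        if self.hotspot_kernel_sigma <= 0:
            raise ConfigurationError("hotspot_kernel_sigma must be > 0")
        self.view_shapes = {k: tuple(v) for k, v in self.view_shapes.items()}


def _default_view_shapes():
    from .atlas import VIEW_SHAPES

    return VIEW_SHAPES


def _default_pixel_mm():
    from .atlas import VIEW_PIXEL_MM

    return VIEW_PIXEL_MM


@dataclass
class DiagnosticsConfig:
    """Options for the statistical evaluation stage."""

    bootstrap_samples: int = 2000
    bootstrap_alpha: float = 0.05
    levene_alpha: float = 0.05
    ci_alpha: float = 0.05

    def __post_init__(self):
        if self.bootstrap_samples < 100:
            raise ConfigurationError("bootstrap_samples must be >= 100")


@dataclass
class ExclusionConfig:
    """Arthroplasty exclusions applied to the RA cohort."""

    n_excluded: int = 3
    areas: list | None = field(default_factory=lambda: ["knee", "knee", "elbow"])

    def __post_init__(self):
        if self.n_excluded < 0:
            raise ConfigurationError("n_excluded must be >= 0")
        if self.areas is not None and len(self.areas) != self.n_excluded:
            raise ConfigurationError(
                "exclusions: areas list length must equal n_excluded"
            )


@dataclass
class StudyConfig:
    """Everything needed for one full simulate-render-quantify-score run."""

    ra_cohort: CohortConfig
    oa_cohort: CohortConfig
    render: RenderConfig = field(default_factory=RenderConfig)
    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)
    diagnostics: DiagnosticsConfig = field(default_factory=DiagnosticsConfig)
    seed: int = 0

    def __post_init__(self):
        for name, conv in (
            ("ra_cohort", CohortConfig),
            ("oa_cohort", CohortConfig),
            ("render", RenderConfig),
            ("exclusions", ExclusionConfig),
            ("diagnostics", DiagnosticsConfig),
        ):
            val = getattr(self, name)
            if isinstance(val, dict):
                setattr(self, name, conv(**val))

    def reseeded(self, seed: int) -> "StudyConfig":
        """Copy of the config with `seed` propagated to every stage."""
        d = to_dict(self)
        d["seed"] = seed
        d["ra_cohort"]["seed"] = seed
        d["oa_cohort"]["seed"] = seed + 1
        d["render"]["seed"] = seed + 2
        return StudyConfig(**d)


# --------------------------------------------------------------------- IO


def to_dict(cfg) -> dict:
    """Dataclass tree -> plain dict (tuples become lists)."""
    return json.loads(json.dumps(asdict(cfg)))


def config_hash(cfg) -> str:
    """Stable short hash of a config for provenance stamps."""
    payload = json.dumps(to_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def dump_yaml(cfg, path: str | Path | None = None) -> str:
    text = yaml.safe_dump(to_dict(cfg), sort_keys=True)
    if path is not None:
        Path(path).write_text(text)
    return text


def load_study_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        return StudyConfig(**yaml.safe_load(fh))


def default_study_config() -> StudyConfig:
    """The packaged calibrated default study configuration."""
    ref = resources.files("scintira.data").joinpath("default_config.yaml")
    return StudyConfig(**yaml.safe_load(ref.read_text()))
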