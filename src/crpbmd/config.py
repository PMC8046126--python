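"""Configuration for the synthetic longitudinal cohort generator.

Defaults emulate a multi-wave midlife women's cohort followed across the
menopause transition: ~annual visits over 17 waves, women aged 42-52 and
almost all premenopausal or early perimenopausal at entry, between-woman
log2 CRP distributed around 0.53 +/- 2.07 log2 mg/L, lumbar-spine (LS) and
femoral-neck (FN) BMD around 1.07 +/- 0.14 and 0.84 +/- 0.13 g/cm2, and
stage-specific annualized BMD decline rates of (-0.61, -1.61, -0.65) %/y at
the LS and (-0.45, -1.28, -0.95) %/y at the FN for combined MT stages 1-3.
The CRP -> decline effects (``beta_per_doubling_*``, %/y per log2 unit)
default to (0, 0, -0.10) at the LS and (-0.09, 0, -0.09) at the FN.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["CohortConfig", "BINARY_COVARIATES"]

#: binary time-varying covariates: name -> (baseline prob, per-visit onset hazard,
#: per-visit cessation hazard)
BINARY_COVARIATES = {
    "smoking": (0.141, 0.005, 0.030),
    "diabetes": (0.057, 0.010, 0.005),
    "bone_beneficial": (0.001, 0.005, 0.020),
    "bone_adverse": (0.029, 0.010, 0.050),
    "corticosteroids": (0.019, 0.010, 0.300),
    "nsaids": (0.219, 0.070, 0.150),
    "aspirin": (0.073, 0.030, 0.100),
    "calcium": (0.463, 0.070, 0.080),
    "vitd": (0.380, 0.070, 0.080),
}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    Probabilities are per woman-visit unless noted.  Stage-indexed tuples are
    (stage 1, stage 2, stage 3) of the combined MT staging.
    """

    n_women: int = 1431
    n_waves: int = 17
    visit_spacing_years: float = 1.0
    visit_time_jitter_sd: float = 0.08
    missing_visit_prob: float = 0.10

    # MT timeline: years from baseline to late-perimenopause onset (may be
    # negative: already past that point at enrolment), and duration of the
    # late-peri / amenorrhea run-in to the final menstrual period.
    stage2_entry_mean: float = 5.5
    stage2_entry_sd: float = 3.0
    late_peri_dur_mean: float = 1.5
    late_peri_dur_sd: float = 0.75
    early_post_span: int = 2

    # CRP (log2 mg/L): between-woman level, chronic within-woman AR(1)
    # deviation sampled at assay occasions, per-wave drift by stage, and
    # multiplicative acute spikes.
    crp_level_mean: float = 0.53
    crp_level_sd: float = 2.07
    crp_within_sd: float = 0.93
    crp_ar1: float = 0.3
    crp_assay_interval: int = 2
    crp_drift_per_stage: tuple = (0.02, 0.02, 0.0)
    acute_spike_prob: float = 0.03
    acute_spike_factor_range: tuple = (6.0, 40.0)

    # BMD (g/cm2): baseline distribution, stage-specific annualized decline
    # (%/y), CRP effect (%/y per log2 unit) and multiplicative measurement
    # noise (log-normal, sd = cv).
    bmd_baseline_mean_ls: float = 1.07
    bmd_baseline_sd_ls: float = 0.14
    bmd_baseline_mean_fn: float = 0.84
    bmd_baseline_sd_fn: float = 0.13
    stage_decline_ls: tuple = (-0.61, -1.61, -0.65)
    stage_decline_fn: tuple = (-0.45, -1.28, -0.95)
    beta_per_doubling_ls: tuple = (0.0, 0.0, -0.10)
    beta_per_doubling_fn: tuple = (-0.09, 0.0, -0.09)
    bmd_measurement_cv_ls: float = 0.014
    bmd_measurement_cv_fn: float = 0.022
    bmd_missing_prob: float = 0.02

    # Hormone therapy and covariate dynamics.
    ht_baseline_prob: float = 0.0
    ht_initiation_hazard: float = 0.02
    bmi_baseline_mean: float = 27.4
    bmi_baseline_sd: float = 6.8
    bmi_drift_mean: float = 0.16
    bmi_drift_sd: float = 0.60
    alcohol_baseline_probs: tuple = (0.550, 0.219, 0.183, 0.048)
    alcohol_switch_prob: float = 0.08
    binary_covariates: dict = field(default_factory=lambda: dict(BINARY_COVARIATES))
    covariate_missing_prob: float = 0.01

    seed: int = 0

    _PROBS = (
        "missing_visit_prob",
        "acute_spike_prob",
        "bmd_missing_prob",
        "ht_baseline_prob",
        "ht_initiation_hazard",
        "alcohol_switch_prob",
        "covariate_missing_prob",
    )
    _POSITIVE = (
        "visit_spacing_years",
        "stage2_entry_sd",
        "late_peri_dur_sd",
        "crp_level_sd",
        "bmd_baseline_sd_ls",
        "bmd_baseline_sd_fn",
        "bmi_baseline_sd",
    )

    def __post_init__(self):
        self.validate()

    def validate(self) -> "CohortConfig":
        """Check invariants; raise ValueError naming the offending field."""
        if self.n_women < 0:
            raise ValueError(f"n_women must be >= 0, got {self.n_women}")
        if self.n_waves < 2:
            raise ValueError(f"n_waves must be >= 2, got {self.n_waves}")
        for name in self._PROBS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name in self._POSITIVE:
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name in ("crp_within_sd", "visit_time_jitter_sd", "bmi_drift_sd",
                     "bmd_measurement_cv_ls", "bmd_measurement_cv_fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not -1.0 < self.crp_ar1 < 1.0:
            raise ValueError(f"crp_ar1 must lie in (-1, 1), got {self.crp_ar1}")
        if self.crp_assay_interval < 1:
            raise ValueError(f"crp_assay_interval must be >= 1, got {self.crp_assay_interval}")
        if self.early_post_span not in (2, 3):
            raise ValueError(f"early_post_span must be 2 or 3, got {self.early_post_span}")
        lo, hi = self.acute_spike_factor_range
        if not (1.0 < lo <= hi):
            raise ValueError(
                f"acute_spike_factor_range must satisfy 1 < lo <= hi, got {(lo, hi)}"
            )
        for name in ("crp_drift_per_stage", "stage_decline_ls", "stage_decline_fn",
                     "beta_per_doubling_ls", "beta_per_doubling_fn"):
            if len(getattr(self, name)) != 3:
                raise ValueError(f"{name} must have one entry per combined stage (3)")
        if len(self.alcohol_baseline_probs) != 4 or abs(sum(self.alcohol_baseline_probs) - 1) > 1e-9:
            raise ValueError("alcohol_baseline_probs must be 4 probabilities summing to 1")
        for name, spec in self.binary_covariates.items():
            if len(spec) != 3 or not all(0 <= p <= 1 for p in spec):
                raise ValueError(
                    f"binary_covariates[{name!r}] must be (baseline, on, off) probabilities"
                )
        if not isinstance(self.seed, int):
            raise ValueError(f"seed must be an integer, got {self.seed!r}")
        return self

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        clean = {
            k: tuple(v) if isinstance(v, list) and k != "binary_covariates" else v
            for k, v in d.items()
        }
        if "binary_covariates" in clean:
            clean["binary_covariates"] = {
                name: tuple(spec) for name, spec in clean["binary_covariates"].items()
            }
        return cls(**clean)

    @classmethod
    def from_file(cls, path) -> "CohortConfig":
        """Load from a YAML or JSON file mirroring the field names."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
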