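"""Run configuration.

Every analysis constant — the 2 mg/L systemic-inflammation threshold, the
20 mg/L active-infection cap, the eligibility/lookback windows in days, the
renal thresholds, the study window and data cutoff — lives here with its
study default, so each can be audited and varied in tests.  Configuration is
a pydantic model; a YAML file with matching sections overrides defaults.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
import yaml
from pydantic import BaseModel, Field, model_validator

from .codes import DEFAULT_CODE_LISTS
from .model import CodeList


class Thresholds(BaseModel):
    """Clinical decision thresholds."""

    crp_si: float = 2.0              # mg/L, systemic inflammation (inclusive)
    crp_infection_max: float = 20.0  # mg/L, active-infection cap (strict >)
    egfr_ckd: float = 60.0           # mL/min/1.73m2, CKD (strict <)
    egfr_stage4: float = 30.0        # stage 4 upper bound (strict <)
    egfr_stage5: float = 15.0        # stage 5 upper bound (strict <)
    uacr_ckd: float = 30.0           # mg/g, albuminuria (inclusive >=)


class Windows(BaseModel):
    """Temporal windows, in whole days.

    Calendar-unit windows from the study protocol are fixed-day
    approximations: 2 months = 60 d, 3 months = 90 d, 12 months = 365 d,
    18 months = 548 d, 3 years = 1095 d.
    """

    infection_after_rx: int = 60     # CRP within 2 months after antibiotic rx
    infection_before_rx: int = 7     # CRP within 7 days before antibiotic rx
    immunosuppressant: int = 90      # CRP < 3 months after immunosuppressant rx
    cancer: int = 1095               # CRP < 3 years after malignancy diagnosis
    crp_grouping: int = 90           # geometric-mean grouping span
    lab_lookback: int = 548          # baseline labs/vitals before index
    drug_window: int = 365           # drug exposure before/after index
    point_lookback: int = 548        # eligible CRP recency at the cutoff date
    cancer_comorbidity: int = 1095   # "cancer" comorbidity: dx > 3 y before index


class Switches(BaseModel):
    """Documented alternative semantics, off by default."""

    #: CKD if ANY historical eGFR < 60 (default: most recent prior only).
    egfr_any_historical: bool = False
    #: point-prevalence numerator: any in-window grouped CRP >= threshold
    #: (default: most recent in-window grouped CRP only).
    point_any_in_window: bool = False
    #: run the inflammatory/rheumatoid-disease sensitivity analysis.
    sensitivity_analysis: bool = True


class GeneratorConfig(BaseModel):
    """Synthetic-cohort generator parameters.

    Defaults emulate the marginals of the study population: age about
    71 ± 12 years, 57% male, roughly a third of patients with CKD, log-normal
    CRP with stratum-specific medians whose mixture median is near 2.4 mg/L
    (IQR about 1.2–4.8), sparse irregular CRP sampling, infection episodes
    that couple antibiotic prescriptions with CRP spikes above 20 mg/L, and
    an annual mortality process.
    """

    n_patients: int = Field(default=1000, gt=0)
    seed: int = 0
    p_ckd: float = Field(default=0.32, ge=0, le=1)
    #: median baseline CRP (mg/L) by stratum
    crp_median_ckd: float = 2.9
    crp_median_nonckd: float = 2.2
    #: sigma of log CRP; ln(4.8/1.2) / (2 * 0.6745) from the observed IQR
    crp_log_sigma: float = 1.03
    #: sd of the per-patient log-scale random intercept; CRP tracks a
    #: patient's chronic inflammatory state, so most of the marginal
    #: log-sigma is between-patient
    crp_patient_log_sd: float = 0.7
    #: sparse testing: CRP is not routine in primary care
    crp_tests_per_year: float = Field(default=0.25, ge=0)
    p_pre_ascvd_crp: float = Field(default=0.15, ge=0, le=1)
    infection_episodes_per_year: float = Field(default=0.15, ge=0)
    p_crp_test_in_episode: float = Field(default=0.5, ge=0, le=1)
    p_immunosuppressant_user: float = Field(default=0.02, ge=0, le=1)
    p_cancer: float = Field(default=0.05, ge=0, le=1)
    p_nmsc: float = Field(default=0.02, ge=0, le=1)
    p_chronic_infection: float = Field(default=0.01, ge=0, le=1)
    annual_mortality: float = Field(default=0.04, ge=0, le=1)
    #: fraction with no creatinine/UACR/CKD-diagnosis data at all → CKD
    #: status unknown downstream
    p_renal_data_missing: float = Field(default=0.06, ge=0, le=1)
    p_ckd_diagnosis_coded: float = Field(default=0.5, ge=0, le=1)
    #: CKD-stratum stage mix (stage3, stage4, stage5, stage1/2)
    stage_mix: tuple[float, float, float, float] = (0.711, 0.098, 0.011, 0.18)
    age_mean: float = 71.0
    age_sd: float = 12.0
    p_male: float = Field(default=0.57, ge=0, le=1)
    #: per-concept comorbidity prevalences
    comorbidity_prevalence: dict[str, float] = Field(default_factory=lambda: {
        "diabetes": 0.34, "hypertension": 0.66, "copd": 0.30, "dementia": 0.05,
        "heart_failure": 0.10, "atrial_fibrillation": 0.13, "ibd": 0.008,
        "rheumatoid_disease": 0.18, "cns_inflammatory_disease": 0.002,
        "liver_disease": 0.05,
    })
    #: per-class drug-exposure prevalences (pre-index 12 months)
    drug_prevalence: dict[str, float] = Field(default_factory=lambda: {
        "corticosteroids": 0.06, "statins": 0.68, "aspirin": 0.54,
        "antiplatelet": 0.10, "anticoagulants": 0.14, "nsaids": 0.31,
        "acei_arb": 0.60, "mra": 0.05, "beta_blockers": 0.42,
        "diuretics": 0.25, "calcium_channel_blockers": 0.20,
        "glucose_lowering": 0.29, "sglt2_inhibitors": 0.04,
        "glp1_receptor_agonists": 0.016, "ezetimibe": 0.03,
        "pcsk9_inhibitors": 0.003, "omega3": 0.002,
        "fibrates_resins_nicotinic": 0.05, "other_bp_medications": 0.04,
        "colchicine": 0.017,
    })
    lab_panels_per_year: float = Field(default=0.7, ge=0)
    vital_sets_per_year: float = Field(default=0.6, ge=0)
    p_uacr_measured: float = Field(default=0.5, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        if abs(sum(self.stage_mix) - 1.0) > 1e-9:
            raise ValueError("stage_mix must sum to 1")
        return self


class RunConfig(BaseModel):
    """Top-level configuration for a pipeline run."""

    study_start: dt.date = dt.date(2014, 1, 1)
    study_end: dt.date = dt.date(2023, 7, 31)
    cutoff_date: dt.date = dt.date(2023, 7, 31)
    thresholds: Thresholds = Field(default_factory=Thresholds)
    windows: Windows = Field(default_factory=Windows)
    switches: Switches = Field(default_factory=Switches)
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    #: concept name -> {system, prefixes}; merged over the built-in defaults
    code_lists: dict[str, dict] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        return self

    def resolved_code_lists(self) -> dict[str, CodeList]:
        """Built-in default concepts, overlaid with any configured overrides."""
        lists = dict(DEFAULT_CODE_LISTS)
        for name, spec in self.code_lists.items():
            lists[name] = CodeList(
                name=name, system=spec["system"], prefixes=tuple(spec["prefixes"])
            )
        return lists


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a RunConfig from YAML; with no path, return study defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def dump_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=False)
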