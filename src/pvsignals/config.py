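"""Configuration models for the synthetic-report generator and the pipeline.

All configuration is plain JSON-serialisable data validated with pydantic;
invariant violations raise :class:`~pvsignals.errors.ConfigurationError`
naming the offending key, so CLI users see which setting to fix.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .errors import ConfigurationError
from .tables import AGE_GROUPS, GROUPS, REPORTER_TYPES, SEXES, WEIGHT_GROUPS

STUDY_DRUG_A = "BEVACIZUMAB"  # anti-VEGF monoclonal antibody
STUDY_DRUG_B = "TEMOZOLOMIDE"  # alkylating chemotherapy

#: Background per-report reporting probabilities for a catalogue of
#: immune-related preferred terms. Frequencies are graded the way SRS data
#: grade them: common GI/haematological terms near 1-2%, rare opportunistic
#: infections a few per thousand.
DEFAULT_EVENT_CATALOG: Dict[str, float] = {
    "Diarrhoea": 0.020,
    "Thrombocytopenia": 0.015,
    "Neutropenia": 0.012,
    "Lymphocyte count decreased": 0.010,
    "Pancytopenia": 0.008,
    "Arthralgia": 0.010,
    "Pruritus": 0.010,
    "Sepsis": 0.008,
    "Febrile neutropenia": 0.006,
    "Lymphopenia": 0.006,
    "Aspartate aminotransferase increased": 0.006,
    "Hepatitis": 0.004,
    "Pleural effusion": 0.004,
    "Aplastic anaemia": 0.003,
    "Toxic epidermal necrolysis": 0.003,
    "Eosinophilia": 0.003,
    "Haemophagocytic lymphohistiocytosis": 0.002,
    "Strongyloidiasis": 0.002,
    "Epstein-Barr virus infection": 0.002,
    "Pneumonia cytomegaloviral": 0.002,
    "Nephrotic syndrome": 0.002,
    "Enterocolitis": 0.002,
    "Optic neuritis": 0.002,
    "Cholangitis": 0.002,
}

#: Demographic mixes loosely matching large oncology SRS cohorts: mostly
#: adults, heavy weight missingness, physicians the modal reporter.
DEFAULT_DEMOGRAPHICS: Dict[str, Dict[str, float]] = {
    "sex": {"male": 0.55, "female": 0.45},
    "age_group": {
        "<2": 0.001,
        "2-11": 0.009,
        "12-17": 0.01,
        "18-64": 0.62,
        "65-85": 0.35,
        ">85": 0.01,
    },
    "weight_group": {"<50kg": 0.05, "50-100kg": 0.80, ">100kg": 0.15},
    "reporter_type": {"MD": 0.45, "HP": 0.22, "CN": 0.14, "OT": 0.14, "PH": 0.05},
}

DEFAULT_INDICATION_LABELS: Dict[str, Dict[str, float]] = {
    group: {
        "Glioblastoma multiforme": 0.55,
        "Glioblastoma": 0.25,
        "Malignant glioma, recurrent": 0.10,
        "Breast cancer": 0.05,  # decoys exercise the indication-exclusion path
        "Colorectal cancer": 0.05,
    }
    for group in GROUPS
}

#: Field-level missingness probabilities. Dates and weight are the fields
#: spontaneous reports most often leave blank.
DEFAULT_MISSINGNESS: Dict[str, float] = {
    "start_date": 0.45,
    "onset_date": 0.25,
    "sex": 0.15,
    "age_group": 0.25,
    "weight_group": 0.60,
    "reporter_type": 0.03,
}

_MISSINGNESS_FIELDS = set(DEFAULT_MISSINGNESS)
_DEMOGRAPHIC_LEVELS = {
    "sex": set(SEXES) - {"unknown"},
    "age_group": set(AGE_GROUPS) - {"unknown"},
    "weight_group": set(WEIGHT_GROUPS) - {"unknown"},
    "reporter_type": set(REPORTER_TYPES) - {"unknown"},
}


class SimulationConfig(BaseModel):
    """Generator settings; the defaults describe a null cohort (no injected
    signals) of realistic size and missingness.

    ``signal_multipliers`` multiply a group's baseline reporting probability
    for a term. The COMBO group's effective multiplier is

        mult(COMBO, t) x mult(BEV_MONO, t) x mult(TMZ_MONO, t) x interaction(t)

    so monotherapy signals propagate multiplicatively to the combination
    (a multiplicative null), and ``interaction_multipliers`` inject
    more-than-multiplicative reporting on top.
    """

    model_config = ConfigDict(extra="forbid")

    group_sizes: Dict[str, int] = {
        "COMBO": 1000,
        "BEV_MONO": 2000,
        "TMZ_MONO": 3000,
        "BACKGROUND": 10000,
    }
    event_catalog: Dict[str, float] = dict(DEFAULT_EVENT_CATALOG)
    signal_multipliers: Dict[str, Dict[str, float]] = {}
    interaction_multipliers: Dict[str, float] = {}
    #: (shape beta, scale eta in days) per group per term
    tto_models: Dict[str, Dict[str, Tuple[float, float]]] = {}
    default_tto: Tuple[float, float] = (1.0, 60.0)
    missingness: Dict[str, float] = dict(DEFAULT_MISSINGNESS)
    duplicate_rate: float = 0.05
    partial_date_rate: float = 0.0
    demographics: Dict[str, Dict[str, float]] = {
        k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()
    }
    indication_labels: Dict[str, Dict[str, float]] = {
        g: dict(v) for g, v in DEFAULT_INDICATION_LABELS.items()
    }
    database_tag: str = "FAERS"
    seed: int = 0

    @model_validator(mode="after")
    def _check_invariants(self) -> "SimulationConfig":
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigurationError(f"group_sizes.{g}", f"unknown group (allowed: {GROUPS})")
            if n < 0:
                raise ConfigurationError(f"group_sizes.{g}", "group size must be >= 0")
        for term, p in self.event_catalog.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"event_catalog.{term}", "probability must be in [0, 1]")
        for g, terms in self.signal_multipliers.items():
            if g not in GROUPS:
                raise ConfigurationError(f"signal_multipliers.{g}", "unknown group")
            for term, m in terms.items():
                if m < 0:
                    raise ConfigurationError(
                        f"signal_multipliers.{g}.{term}", "multiplier must be >= 0"
                    )
        for term, m in self.interaction_multipliers.items():
            if m < 0:
                raise ConfigurationError(
                    f"interaction_multipliers.{term}", "multiplier must be >= 0"
                )
        for g, models in self.tto_models.items():
            for term, (shape, scale) in models.items():
                if shape <= 0 or scale <= 0:
                    raise ConfigurationError(
                        f"tto_models.{g}.{term}", "Weibull shape and scale must be > 0"
                    )
        if self.default_tto[0] <= 0 or self.default_tto[1] <= 0:
            raise ConfigurationError("default_tto", "Weibull shape and scale must be > 0")
        for f, p in self.missingness.items():
            if f not in _MISSINGNESS_FIELDS:
                raise ConfigurationError(
                    f"missingness.{f}", f"unknown field (allowed: {sorted(_MISSINGNESS_FIELDS)})"
                )
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"missingness.{f}", "probability must be in [0, 1]")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ConfigurationError("duplicate_rate", "probability must be in [0, 1]")
        if not 0.0 <= self.partial_date_rate <= 1.0:
            raise ConfigurationError("partial_date_rate", "probability must be in [0, 1]")
        for field, dist in self.demographics.items():
            if field not in _DEMOGRAPHIC_LEVELS:
                raise ConfigurationError(f"demographics.{field}", "unknown demographic field")
            bad = set(dist) - _DEMOGRAPHIC_LEVELS[field]
            if bad:
                raise ConfigurationError(f"demographics.{field}", f"unknown categories {sorted(bad)}")
            total = sum(dist.values())
            if any(p < 0 for p in dist.values()) or abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"demographics.{field}", f"distribution must sum to 1 (got {total})"
                )
        for g, dist in self.indication_labels.items():
            if g not in GROUPS:
                raise ConfigurationError(f"indication_labels.{g}", "unknown group")
            total = sum(dist.values())
            if any(p < 0 for p in dist.values()) or abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"indication_labels.{g}", f"distribution must sum to 1 (got {total})"
                )
        return self

    def effective_multiplier(self, group: str, term: str) -> float:
        m = self.signal_multipliers.get(group, {}).get(term, 1.0)
        if group == "COMBO":
            m *= self.signal_multipliers.get("BEV_MONO", {}).get(term, 1.0)
            m *= self.signal_multipliers.get("TMZ_MONO", {}).get(term, 1.0)
            m *= self.interaction_multipliers.get(term, 1.0)
        return m

    def tto_model_for(self, group: str, term: str) -> Tuple[float, float]:
        return tuple(self.tto_models.get(group, {}).get(term, self.default_tto))


def demo_simulation_config(seed: int = 0) -> SimulationConfig:
    """A small simulated study with injected ground truth: monotherapy
    haematological signals, combination-specific opportunistic-infection
    interaction signals, and group-specific onset-time shapes."""
    return SimulationConfig(
        group_sizes={"COMBO": 800, "BEV_MONO": 1500, "TMZ_MONO": 2000, "BACKGROUND": 8000},
        signal_multipliers={
            "BEV_MONO": {"Lymphocyte count decreased": 4.0, "Arthralgia": 3.0, "Optic neuritis": 5.0},
            "TMZ_MONO": {"Thrombocytopenia": 5.0, "Neutropenia": 4.0, "Pancytopenia": 4.0},
        },
        interaction_multipliers={
            "Haemophagocytic lymphohistiocytosis": 6.0,
            "Pneumonia cytomegaloviral": 6.0,
            "Strongyloidiasis": 5.0,
            "Enterocolitis": 5.0,
        },
        tto_models={
            "TMZ_MONO": {"Thrombocytopenia": (1.0, 50.0), "Neutropenia": (1.0, 55.0)},
            "BEV_MONO": {"Lymphocyte count decreased": (1.5, 36.0)},
            "COMBO": {"Lymphocyte count decreased": (0.7, 45.0)},
        },
        duplicate_rate=0.04,
        seed=seed,
    )


class PipelineConfig(BaseModel):
    """Declarative end-to-end pipeline configuration.

    Exactly one of ``simulate`` or (``faers_dir`` / ``cvard_path``) selects
    the input source; the remaining blocks tune each stage.
    """

    model_config = ConfigDict(extra="forbid")

    simulate: Optional[SimulationConfig] = None
    faers_dir: Optional[str] = None
    cvard_path: Optional[str] = None

    dictionary_path: Optional[str] = None  # two-column CSV (term, tier); default GBM dictionary if absent
    term_map_path: Optional[str] = None
    exposure_mode: str = "primary"
    both_ps_policy: str = "exclude"

    min_n: int = 3
    comparator_mode: str = "rest_of_database"
    bh_adjust: bool = False

    interaction_min_n: int = 3
    tto_fit_min_n: int = 10
    irae_terms: Optional[List[str]] = None
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PipelineConfig":
        has_files = self.faers_dir is not None or self.cvard_path is not None
        if self.simulate is not None and has_files:
            raise ConfigurationError(
                "simulate", "provide either a simulate block or input paths, not both"
            )
        if self.simulate is None and not has_files:
            raise ConfigurationError("simulate", "one of simulate / faers_dir / cvard_path required")
        if self.exposure_mode not in {"primary", "any_role"}:
            raise ConfigurationError("exposure_mode", "must be 'primary' or 'any_role'")
        if self.both_ps_policy not in {"exclude", "combo"}:
            raise ConfigurationError("both_ps_policy", "must be 'exclude' or 'combo'")
        if self.comparator_mode not in {"rest_of_database", "other_cohort_groups"}:
            raise ConfigurationError(
                "comparator_mode", "must be 'rest_of_database' or 'other_cohort_groups'"
            )
        if self.min_n < 0 or self.interaction_min_n < 0 or self.tto_fit_min_n < 0:
            raise ConfigurationError("min_n", "count thresholds must be >= 0")
        return self


__all__ = [
    "SimulationConfig",
    "PipelineConfig",
    "demo_simulation_config",
    "DEFAULT_EVENT_CATALOG",
    "STUDY_DRUG_A",
    "STUDY_DRUG_B",
    "ValidationError",
]
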