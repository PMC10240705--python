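"""Input parameter set for one payer perspective.

Every model input — plan demographics, COPD prevalence, GOLD ABCD
distribution, annual healthcare resource use (HCRU) rates, unit costs,
inhaler medication parameters, the remote-monitoring fee schedule, the
intervention effect sizes and the uptake schedule — is carried in a single
validated :class:`PayerInputs` object, loaded from a YAML config.

Two configurations ship per payer:

``*_derived``
    every per-patient baseline is computed purely from the published input
    table (rates × unit costs, WAC price averaging, PDC weighting).
``*_replication``
    the per-patient hospitalization, ED and SABA baselines are overridden
    with the published per-patient dollar values (their exact upstream
    derivation is not recoverable from the inputs alone), and an explicit
    reconciliation line is carried on the monitored arm so that category
    sums match the published totals.

Validation is strict: unknown keys are rejected, every failed invariant is
reported (not just the first), and any distribution (age shares, GOLD
shares, controller mix) must sum to 1 within 1e-6.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    field_validator,
    model_validator,
)

GOLD_GROUPS = ("A", "B", "C", "D")
CONTROLLER_CATEGORIES = ("LAMA", "LABA", "LABA_ICS", "LABA_LAMA", "LABA_LAMA_ICS")

#: tolerance for "shares sum to one" checks
DISTRIBUTION_TOL = 1e-6

BUILTIN_CONFIGS = (
    "commercial_derived",
    "commercial_replication",
    "medicare_derived",
    "medicare_replication",
)


class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigFormatError(ConfigError):
    """The document does not parse as YAML/JSON (message names the location)."""


class ConfigValidationError(ConfigError):
    """The document parsed but violates one or more invariants.

    ``errors`` holds every violation found, not just the first.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.errors))


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


def _check_simplex(name: str, values: dict[str, float]) -> None:
    for key, v in values.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} {key}={v} outside [0, 1]")
    total = math.fsum(values.values())
    if abs(total - 1.0) > DISTRIBUTION_TOL:
        raise ValueError(f"{name} sum {total:g} ≠ 1")


class PerGold(_Strict):
    """One real value per GOLD 2017 ABCD group."""

    A: float
    B: float
    C: float
    D: float

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.A, self.B, self.C, self.D)

    def as_dict(self) -> dict[str, float]:
        return {g: getattr(self, g) for g in GOLD_GROUPS}


class AgeShares(_Strict):
    """Fractions of plan members in the <40, 40-64 and >=65 bands."""

    under_40: float = Field(ge=0, le=1)
    age_40_64: float = Field(ge=0, le=1)
    age_65_plus: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _sums_to_one(self) -> "AgeShares":
        total = math.fsum([self.under_40, self.age_40_64, self.age_65_plus])
        if abs(total - 1.0) > DISTRIBUTION_TOL:
            raise ValueError(f"age shares sum {total:g} ≠ 1")
        return self


class PayerPopulation(_Strict):
    plan_size: float = Field(gt=0, description="plan member count")
    age_shares: AgeShares


class PrevalenceByAge(_Strict):
    """COPD prevalence by age band; the <40 band is structurally excluded."""

    age_40_64: float = Field(ge=0, le=1)
    age_65_plus: float = Field(ge=0, le=1)


class GoldDistribution(PerGold):
    @model_validator(mode="after")
    def _is_distribution(self) -> "GoldDistribution":
        _check_simplex("GOLD shares", self.as_dict())
        return self


class HcruProfile(_Strict):
    """Annual per-patient event counts by GOLD group."""

    outpatient_visits: PerGold
    ed_visits: PerGold
    hospitalizations: PerGold
    readmissions: PerGold

    @model_validator(mode="after")
    def _nonnegative_and_nested(self) -> "HcruProfile":
        problems = []
        for field in ("outpatient_visits", "ed_visits", "hospitalizations", "readmissions"):
            for g, v in getattr(self, field).as_dict().items():
                if v < 0:
                    problems.append(f"hcru {field} {g}={v} < 0")
        for g in GOLD_GROUPS:
            r = getattr(self.readmissions, g)
            h = getattr(self.hospitalizations, g)
            if r > h:
                problems.append(f"readmissions {g}={r} exceed hospitalizations {h}")
        if problems:
            raise ValueError("; ".join(problems))
        return self


class UnitCostSet(_Strict):
    """2020 USD per event."""

    office_outpatient_visit: float = Field(ge=0)
    ed_visit: float = Field(ge=0)
    hospitalization: float = Field(ge=0)


class PaymentRatios(_Strict):
    """Commercial-to-Medicare payment ratios by setting."""

    hospital_outpatient_ed: float = Field(gt=0)
    physician_office: float = Field(gt=0)
    inpatient: float = Field(gt=0)


class WacPrice(_Strict):
    label: str
    price: float = Field(ge=0, description="WAC per canister, USD")


class SabaInputs(_Strict):
    weekly_puffs: PerGold
    wac_prices: list[WacPrice] = Field(default_factory=list)
    actuations_per_canister: int = Field(gt=0, default=200)
    annual_cost_override: Optional[float] = Field(default=None, ge=0)

    @field_validator("weekly_puffs")
    @classmethod
    def _puffs_nonnegative(cls, v: PerGold) -> PerGold:
        bad = [g for g, x in v.as_dict().items() if x < 0]
        if bad:
            raise ValueError(f"weekly SABA puffs negative for group(s) {bad}")
        return v


class ControllerDailyCosts(_Strict):
    LAMA: float = Field(ge=0)
    LABA: float = Field(ge=0)
    LABA_ICS: float = Field(ge=0)
    LABA_LAMA: float = Field(ge=0)
    LABA_LAMA_ICS: float = Field(ge=0)

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in CONTROLLER_CATEGORIES}


class ControllerMix(_Strict):
    """Fraction of a GOLD group on each controller regimen (sums to 1)."""

    LAMA: float = Field(ge=0, le=1, default=0.0)
    LABA: float = Field(ge=0, le=1, default=0.0)
    LABA_ICS: float = Field(ge=0, le=1, default=0.0)
    LABA_LAMA: float = Field(ge=0, le=1, default=0.0)
    LABA_LAMA_ICS: float = Field(ge=0, le=1, default=0.0)

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in CONTROLLER_CATEGORIES}

    @model_validator(mode="after")
    def _is_distribution(self) -> "ControllerMix":
        _check_simplex("controller mix", self.as_dict())
        return self


class ControllerMixByGold(_Strict):
    A: ControllerMix
    B: ControllerMix
    C: ControllerMix
    D: ControllerMix

    def for_group(self, g: str) -> ControllerMix:
        return getattr(self, g)


class ControllerInputs(_Strict):
    daily_costs: ControllerDailyCosts
    mix: ControllerMixByGold
    pdc: PerGold

    @field_validator("pdc")
    @classmethod
    def _pdc_in_unit_interval(cls, v: PerGold) -> PerGold:
        bad = {g: x for g, x in v.as_dict().items() if not 0 <= x <= 1}
        if bad:
            raise ValueError(f"PDC outside [0, 1] for {bad}")
        return v


class RtmEntry(_Strict):
    """One remote-therapeutic-monitoring billing code."""

    code: str
    annual_frequency: int = Field(ge=0, description="billings per patient-year")
    fee: float = Field(ge=0, description="USD per billing")


class InterventionEffects(_Strict):
    hosp_reduction: float = Field(ge=0, le=1)
    ed_reduction: float = Field(ge=0, le=1)
    saba_reduction: float = Field(ge=0, le=1)
    subscription_cost: float = Field(ge=0, description="USD per patient-year")
    bill_rtm_for_all_enrolled: bool = True


class BaselineCostOverrides(_Strict):
    """Published per-patient annual dollar baselines substituted for the
    rate-times-unit-cost derivation (replication configs only)."""

    hospitalizations: Optional[float] = Field(default=None, ge=0)
    ed_visits: Optional[float] = Field(default=None, ge=0)


class ModelSettings(_Strict):
    days_per_year: float = 365.25
    reconciliation_line: float = Field(
        default=0.0,
        ge=0,
        description="USD per patient-year added to the monitored arm so "
        "category sums match the published enrolled totals",
    )

    @field_validator("days_per_year")
    @classmethod
    def _days_supported(cls, v: float) -> float:
        if v not in (365.0, 365.25):
            raise ValueError(f"days_per_year must be 365 or 365.25, got {v}")
        return v

    @property
    def weeks_per_year(self) -> float:
        return self.days_per_year / 7.0


class PayerInputs(_Strict):
    """The complete, validated input set for one payer perspective."""

    payer: Literal["commercial", "medicare"]
    population: PayerPopulation
    prevalence: PrevalenceByAge
    gold_distribution: GoldDistribution
    hcru: HcruProfile
    unit_costs: Optional[UnitCostSet] = None
    commercial_unit_costs: Optional[UnitCostSet] = None
    payment_ratios: Optional[PaymentRatios] = None
    saba: SabaInputs
    controller: ControllerInputs
    rtm: list[RtmEntry]
    effects: InterventionEffects
    uptake: list[float]
    settings: ModelSettings = ModelSettings()
    baseline_cost_overrides: BaselineCostOverrides = BaselineCostOverrides()

    @field_validator("uptake")
    @classmethod
    def _uptake_fractions(cls, v: list[float]) -> list[float]:
        if len(v) < 1:
            raise ValueError("uptake schedule needs at least one year")
        bad = [x for x in v if not 0 <= x <= 1]
        if bad:
            raise ValueError(f"uptake fractions outside [0, 1]: {bad}")
        return v

    @model_validator(mode="after")
    def _resolve_unit_costs(self) -> "PayerInputs":
        if self.unit_costs is None:
            if self.commercial_unit_costs is None or self.payment_ratios is None:
                raise ValueError(
                    "provide unit_costs, or commercial_unit_costs together "
                    "with payment_ratios to derive them"
                )
            derived = derive_medicare_unit_costs(
                self.commercial_unit_costs, self.payment_ratios
            )
            object.__setattr__(self, "unit_costs", derived)
        elif self.commercial_unit_costs is not None and self.payment_ratios is not None:
            derived = derive_medicare_unit_costs(
                self.commercial_unit_costs, self.payment_ratios
            )
            for f in ("office_outpatient_visit", "ed_visit", "hospitalization"):
                a, b = getattr(self.unit_costs, f), getattr(derived, f)
                if abs(a - b) > 1e-6:
                    raise ValueError(
                        f"unit_costs.{f}={a} inconsistent with value {b} derived "
                        "from commercial_unit_costs and payment_ratios"
                    )
        return self

    @property
    def plan_size(self) -> float:
        return self.population.plan_size

    @property
    def horizon(self) -> int:
        return len(self.uptake)


def derive_medicare_unit_costs(
    commercial: UnitCostSet, ratios: PaymentRatios
) -> UnitCostSet:
    """Convert commercial unit costs to Medicare payments.

    ED visits use the hospital-outpatient/ED ratio, office visits the
    physician-office ratio, hospitalizations the inpatient ratio. Values are
    left unrounded; rounding to whole dollars happens at the reporting layer.
    """
    return UnitCostSet(
        office_outpatient_visit=commercial.office_outpatient_visit
        / ratios.physician_office,
        ed_visit=commercial.ed_visit / ratios.hospital_outpatient_ed,
        hospitalization=commercial.hospitalization / ratios.inpatient,
    )


def _format_pydantic_errors(exc: ValidationError) -> list[str]:
    out = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        out.append(f"{loc}: {err['msg']}")
    return out


def load_inputs(source: str | Path) -> PayerInputs:
    """Load and validate a payer configuration.

    ``source`` may be a path to a YAML/JSON file, a YAML document string, or
    the name of a shipped configuration (see :data:`BUILTIN_CONFIGS`).

    Raises :class:`ConfigFormatError` on parse failure (naming the location)
    and :class:`ConfigValidationError` listing every violated invariant.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif source in BUILTIN_CONFIGS:
        text = (
            resources.files("copd_bia").joinpath(f"configs/{source}.yaml").read_text()
        )
    elif "\n" not in source and Path(source).exists():
        text = Path(source).read_text()
    else:
        text = source
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ConfigFormatError(f"config does not parse{where}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigFormatError("config document must be a mapping of parameter names")
    try:
        return PayerInputs.model_validate(data)
    except ValidationError as exc:
        raise ConfigValidationError(_format_pydantic_errors(exc)) from exc


def load_builtin(name: str) -> PayerInputs:
    """Load one of the shipped configurations by name."""
    if name not in BUILTIN_CONFIGS:
        raise KeyError(f"unknown builtin config {name!r}; choose from {BUILTIN_CONFIGS}")
    return load_inputs(name)


def builtin_config_path(name: str) -> Path:
    if name not in BUILTIN_CONFIGS:
        raise KeyError(f"unknown builtin config {name!r}; choose from {BUILTIN_CONFIGS}")
    return Path(str(resources.files("copd_bia").joinpath(f"configs/{name}.yaml")))


def serialize(inputs: PayerInputs) -> str:
    """Serialize to YAML such that ``load_inputs(serialize(x)) == x``."""
    data = inputs.model_dump(exclude_none=True)
    return yaml.safe_dump(data, sort_keys=True)


def config_json_schema() -> dict:
    """JSON Schema for the config document (machine-checkable)."""
    return PayerInputs.model_json_schema()
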