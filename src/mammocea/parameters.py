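"""Typed parameter containers, validation, configuration I/O, and the
fee-substitution derivation of per-scan mammography costs.

A full scenario is one :class:`ParameterBundle`, serialisable to a single
YAML document (see :func:`save_config` / :func:`load_config`).  All money
is in 2023 Singapore dollars (SGD) and kept at full float precision;
rounding happens only at report time.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

SCHEMA_VERSION = 1

#: canonical strategy names expected by the reference configuration
CANONICAL_STRATEGIES = ("conventional", "companion", "standalone")


class ConfigSchemaError(ValueError):
    """A configuration document does not match the documented schema."""


class ParameterValidationError(ValueError):
    """A parameter value violates a type invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class StrategyProfile:
    """A reading strategy's test characteristics and per-scan price.

    ``sensitivity``/``specificity`` are per-attendance probabilities of a
    positive read given preclinical cancer / a negative read given no
    cancer; ``cost_per_scan`` is the all-in price of one screening
    mammogram under this reading workflow (SGD).
    """

    name: str
    sensitivity: float
    specificity: float
    cost_per_scan: float

    def validate(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ParameterValidationError(
                f"StrategyProfile '{self.name}': sensitivity must lie in [0, 1]"
            )
        if not 0.0 <= self.specificity <= 1.0:
            raise ParameterValidationError(
                f"StrategyProfile '{self.name}': specificity must lie in [0, 1]"
            )
        if self.cost_per_scan < 0:
            raise ParameterValidationError(
                f"StrategyProfile '{self.name}': cost_per_scan must be >= 0"
            )


@dataclass
class ScreeningPolicy:
    """National screening policy and simulation frame.

    Biennial screening between ``start_age`` and ``stop_age`` inclusive;
    the cohort enters at ``start_age`` and is followed for ``horizon``
    annual cycles.  ``compliance`` is the per-round attendance
    probability.  With ``fixed_attenders`` the compliant fraction is a
    fixed subgroup that attends every round instead of an independent
    per-round draw.  ``half_cycle_correction`` applies half weights to
    the first and last cycle's state-occupancy terms at accumulation
    time (off by default).
    """

    start_age: int = 50
    stop_age: int = 69
    interval: int = 2
    compliance: float = 0.4
    horizon: int = 50
    cohort_size: float = 10_000.0
    fixed_attenders: bool = False
    half_cycle_correction: bool = False

    def validate(self) -> None:
        if self.start_age > self.stop_age:
            raise ParameterValidationError(
                "ScreeningPolicy: start_age must not exceed stop_age"
            )
        if self.interval < 1:
            raise ParameterValidationError("ScreeningPolicy: interval must be >= 1")
        if not 0.0 <= self.compliance <= 1.0:
            raise ParameterValidationError(
                "ScreeningPolicy: compliance must lie in [0, 1]"
            )
        if self.horizon < self.stop_age - self.start_age:
            raise ParameterValidationError(
                "ScreeningPolicy: horizon must cover at least stop_age - start_age"
            )
        if self.cohort_size <= 0:
            raise ParameterValidationError("ScreeningPolicy: cohort_size must be > 0")


@dataclass
class EconomicSettings:
    discount_rate: float = 0.03
    wtp_threshold: float = 50_000.0
    currency_year: int = 2023

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ParameterValidationError(
                "EconomicSettings: discount_rate must be >= 0"
            )
        if self.wtp_threshold <= 0:
            raise ParameterValidationError(
                "EconomicSettings: wtp_threshold must be > 0"
            )


@dataclass
class NaturalHistoryParams:
    """Age- and stage-specific annual event probabilities.

    ``onset_rate`` and ``other_cause_mortality`` are keyed by integer age;
    the stage-indexed lists run over stages 0–IV.  ``stage_progression``
    is the annual probability an undiagnosed cancer advances one stage
    (stage IV cannot advance, so its entry must be 0).
    ``clinical_detection`` is the annual probability an undiagnosed
    cancer surfaces symptomatically (an interval cancer when it happens
    between screens); it must be non-decreasing in stage.
    """

    onset_rate: dict[int, float]
    stage_progression: list[float]
    clinical_detection: list[float]
    recurrence_rate: list[float]
    bc_mortality_by_stage: list[float]
    bc_mortality_recurrence: float
    other_cause_mortality: dict[int, float]

    def validate(self) -> None:
        for label, vec in (
            ("stage_progression", self.stage_progression),
            ("clinical_detection", self.clinical_detection),
            ("recurrence_rate", self.recurrence_rate),
            ("bc_mortality_by_stage", self.bc_mortality_by_stage),
        ):
            if len(vec) != 5:
                raise ParameterValidationError(
                    f"NaturalHistoryParams: {label} must have one entry per stage 0-IV"
                )
            for s, p in enumerate(vec):
                if not 0.0 <= p <= 1.0:
                    raise ParameterValidationError(
                        f"NaturalHistoryParams: {label}[{s}] must lie in [0, 1]"
                    )
        if self.stage_progression[4] != 0.0:
            raise ParameterValidationError(
                "NaturalHistoryParams: stage_progression for stage IV must be 0"
            )
        if any(
            b > a
            for a, b in zip(self.clinical_detection[1:], self.clinical_detection[:-1])
        ):
            raise ParameterValidationError(
                "NaturalHistoryParams: clinical_detection must be non-decreasing in stage"
            )
        if not 0.0 <= self.bc_mortality_recurrence <= 1.0:
            raise ParameterValidationError(
                "NaturalHistoryParams: bc_mortality_recurrence must lie in [0, 1]"
            )
        for label, table in (
            ("onset_rate", self.onset_rate),
            ("other_cause_mortality", self.other_cause_mortality),
        ):
            for age, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ParameterValidationError(
                        f"NaturalHistoryParams: {label} at age {age} must lie in [0, 1]"
                    )
        ages = sorted(self.other_cause_mortality)
        vals = [self.other_cause_mortality[a] for a in ages]
        if any(b < a for a, b in zip(vals, vals[1:])):
            raise ParameterValidationError(
                "NaturalHistoryParams: other_cause_mortality must be non-decreasing in age"
            )


@dataclass
class CostSet:
    """Unit costs (SGD, 2023).

    ``treatment_cost`` is the one-off cost of the treatment year by stage
    at diagnosis.  Remission surveillance costs
    ``remission_fraction × treatment_cost(stage)`` per year; recurrence
    management costs ``recurrence_cost`` per year regardless of stage.
    Recall work-up prices one ultrasound per recall plus a biopsy for
    ``biopsy_fraction_of_recalls`` of recalls.  The three per-scan prices
    derive from ``mammogram_base_cost``, ``radiologist_read_fee`` and
    ``ai_fee`` via :func:`derive_scan_costs`.
    """

    treatment_cost: list[float]
    remission_fraction: float
    recurrence_cost: float
    ultrasound_cost: float
    biopsy_cost: float
    biopsy_fraction_of_recalls: float
    mammogram_base_cost: float = 110.0
    radiologist_read_fee: float = 17.5
    ai_fee: float = 5.0

    def validate(self) -> None:
        if len(self.treatment_cost) != 5:
            raise ParameterValidationError(
                "CostSet: treatment_cost must have one entry per stage 0-IV"
            )
        money = {
            "remission_fraction": self.remission_fraction,
            "recurrence_cost": self.recurrence_cost,
            "ultrasound_cost": self.ultrasound_cost,
            "biopsy_cost": self.biopsy_cost,
            "mammogram_base_cost": self.mammogram_base_cost,
            "radiologist_read_fee": self.radiologist_read_fee,
            "ai_fee": self.ai_fee,
        }
        for s, c in enumerate(self.treatment_cost):
            money[f"treatment_cost[{s}]"] = c
        for label, v in money.items():
            if v < 0:
                raise ParameterValidationError(f"CostSet: {label} must be >= 0")
        if not 0.0 <= self.biopsy_fraction_of_recalls <= 1.0:
            raise ParameterValidationError(
                "CostSet: biopsy_fraction_of_recalls must lie in [0, 1]"
            )


@dataclass
class UtilitySet:
    """Health-state utility weights in [0, 1] (0 = death, 1 = full health)."""

    healthy: float
    undiagnosed: float
    by_stage: list[float]
    remission: float
    recurrence: float

    def validate(self) -> None:
        if len(self.by_stage) != 5:
            raise ParameterValidationError(
                "UtilitySet: by_stage must have one entry per stage 0-IV"
            )
        weights = {
            "healthy": self.healthy,
            "undiagnosed": self.undiagnosed,
            "remission": self.remission,
            "recurrence": self.recurrence,
        }
        for s, u in enumerate(self.by_stage):
            weights[f"by_stage[{s}]"] = u
        for label, u in weights.items():
            if not 0.0 <= u <= 1.0:
                raise ParameterValidationError(
                    f"UtilitySet: {label} must lie in [0, 1]"
                )
        if not self.healthy >= self.remission >= self.recurrence:
            raise ParameterValidationError(
                "UtilitySet: require healthy >= remission >= recurrence"
            )
        if any(b > a for a, b in zip(self.by_stage, self.by_stage[1:])):
            raise ParameterValidationError(
                "UtilitySet: by_stage must be non-increasing in stage"
            )


@dataclass
class UncertaintySettings:
    """Dispersion used by probabilistic sensitivity analysis.

    Costs are sampled from Gamma distributions with coefficient of
    variation ``cost_cv``; utilities from Beta distributions with
    absolute standard deviation ``utility_sd``.
    """

    cost_cv: float = 0.05
    utility_sd: float = 0.05

    def validate(self) -> None:
        if self.cost_cv < 0:
            raise ParameterValidationError("UncertaintySettings: cost_cv must be >= 0")
        if self.utility_sd < 0:
            raise ParameterValidationError(
                "UncertaintySettings: utility_sd must be >= 0"
            )


@dataclass
class ParameterBundle:
    """One complete, validated scenario."""

    strategies: dict[str, StrategyProfile]
    policy: ScreeningPolicy
    economics: EconomicSettings
    natural_history: NaturalHistoryParams
    costs: CostSet
    utilities: UtilitySet
    uncertainty: UncertaintySettings = field(default_factory=UncertaintySettings)
    schema_version: int = SCHEMA_VERSION

    def validate(self) -> None:
        if not self.strategies:
            raise ParameterValidationError(
                "ParameterBundle: at least one strategy is required"
            )
        for name, s in self.strategies.items():
            if s.name != name:
                raise ParameterValidationError(
                    f"ParameterBundle: strategy key '{name}' does not match profile name '{s.name}'"
                )
            s.validate()
        self.policy.validate()
        self.economics.validate()
        self.natural_history.validate()
        self.costs.validate()
        self.utilities.validate()
        self.uncertainty.validate()
        # every age the cohort engine will touch must be covered
        ages = range(self.policy.start_age - 1, self.policy.start_age + self.policy.horizon)
        for label, table in (
            ("onset_rate", self.natural_history.onset_rate),
            ("other_cause_mortality", self.natural_history.other_cause_mortality),
        ):
            missing = [a for a in ages if a not in table]
            if missing:
                raise ParameterValidationError(
                    f"NaturalHistoryParams: {label} missing ages {missing[:5]}..."
                    if len(missing) > 5
                    else f"NaturalHistoryParams: {label} missing ages {missing}"
                )


# ---------------------------------------------------------------------------
# fee substitution
# ---------------------------------------------------------------------------


def derive_scan_costs(
    base: float, read_fee: float, ai_fee: float
) -> tuple[float, float, float]:
    """Per-scan prices under the three reading workflows.

    The double-read price ``base`` includes two radiologist reading fees.
    The AI-companion workflow replaces one radiologist's fee with the AI
    service fee; the AI-standalone workflow replaces both.

    Returns ``(conventional, companion, standalone)``.
    """
    if min(base, read_fee, ai_fee) < 0:
        raise ValueError("derive_scan_costs: all inputs must be >= 0")
    if base < 2 * read_fee:
        raise ValueError(
            "derive_scan_costs: interpretation fees exceed scan price "
            f"(base {base} < 2 x read_fee {read_fee})"
        )
    conventional = base
    companion = base - read_fee + ai_fee
    standalone = base - 2 * read_fee + ai_fee
    return conventional, companion, standalone


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

_SECTIONS = (
    "schema_version",
    "strategies",
    "policy",
    "economics",
    "natural_history",
    "costs",
    "utilities",
    "uncertainty",
)


#: config fields that may be omitted (model options with documented defaults)
_OPTIONAL_FIELDS: dict[type, set[str]] = {
    ScreeningPolicy: {"fixed_attenders", "half_cycle_correction"},
    UncertaintySettings: {"cost_cv", "utility_sd"},
}


def _build(cls: type, mapping: Any, section: str, **extra: Any):
    """Instantiate a dataclass from a mapping, rejecting unknown keys and
    requiring every non-optional field to be stated explicitly."""
    if not isinstance(mapping, dict):
        raise ConfigSchemaError(f"{section}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(mapping) - set(fields) - set(extra)
    if unknown:
        raise ConfigSchemaError(f"{section}: unknown key '{sorted(unknown)[0]}'")
    kwargs = dict(extra)
    kwargs.update(mapping)
    optional = _OPTIONAL_FIELDS.get(cls, set())
    for name in fields:
        if name not in kwargs and name not in optional:
            raise ConfigSchemaError(f"{section}: missing field '{name}'")
    return cls(**kwargs)


def _age_table(raw: Any, section: str) -> dict[int, float]:
    if not isinstance(raw, dict):
        raise ConfigSchemaError(f"{section}: expected a mapping of age to probability")
    return {int(a): float(p) for a, p in raw.items()}


def bundle_from_dict(raw: Any) -> ParameterBundle:
    """Build and validate a :class:`ParameterBundle` from plain data."""
    if not isinstance(raw, dict):
        raise ConfigSchemaError("config: expected a mapping at top level")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ConfigSchemaError(f"config: unknown section '{sorted(unknown)[0]}'")
    for required in ("strategies", "policy", "economics", "natural_history", "costs", "utilities"):
        if required not in raw:
            raise ConfigSchemaError(f"config: missing section '{required}'")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigSchemaError(
            f"config: unsupported schema_version {version} (expected {SCHEMA_VERSION})"
        )
    if not isinstance(raw["strategies"], dict):
        raise ConfigSchemaError("strategies: expected a mapping of name to profile")
    strategies = {
        name: _build(StrategyProfile, prof, f"strategies.{name}", name=name)
        for name, prof in raw["strategies"].items()
    }
    # canonical display order is independent of YAML key sorting
    ordered = {
        name: strategies.pop(name)
        for name in CANONICAL_STRATEGIES
        if name in strategies
    }
    ordered.update(strategies)
    strategies = ordered
    nh_raw = dict(raw["natural_history"]) if isinstance(raw["natural_history"], dict) else None
    if nh_raw is None:
        raise ConfigSchemaError("natural_history: expected a mapping")
    for key in ("onset_rate", "other_cause_mortality"):
        if key in nh_raw:
            nh_raw[key] = _age_table(nh_raw[key], f"natural_history.{key}")
    bundle = ParameterBundle(
        strategies=strategies,
        policy=_build(ScreeningPolicy, raw["policy"], "policy"),
        economics=_build(EconomicSettings, raw["economics"], "economics"),
        natural_history=_build(NaturalHistoryParams, nh_raw, "natural_history"),
        costs=_build(CostSet, raw["costs"], "costs"),
        utilities=_build(UtilitySet, raw["utilities"], "utilities"),
        uncertainty=_build(
            UncertaintySettings, raw.get("uncertainty", {}), "uncertainty"
        ),
        schema_version=version,
    )
    bundle.validate()
    return bundle


def bundle_to_dict(bundle: ParameterBundle) -> dict[str, Any]:
    """Plain-data representation, round-trippable via :func:`bundle_from_dict`."""
    out: dict[str, Any] = {"schema_version": bundle.schema_version}
    out["strategies"] = {
        name: {
            "sensitivity": s.sensitivity,
            "specificity": s.specificity,
            "cost_per_scan": s.cost_per_scan,
        }
        for name, s in bundle.strategies.items()
    }
    out["policy"] = dataclasses.asdict(bundle.policy)
    out["economics"] = dataclasses.asdict(bundle.economics)
    out["natural_history"] = dataclasses.asdict(bundle.natural_history)
    out["costs"] = dataclasses.asdict(bundle.costs)
    out["utilities"] = dataclasses.asdict(bundle.utilities)
    out["uncertainty"] = dataclasses.asdict(bundle.uncertainty)
    return out


def load_config(path: str | Path) -> ParameterBundle:
    """Read and validate a scenario from a YAML document."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return bundle_from_dict(raw)


def save_config(bundle: ParameterBundle, path: str | Path) -> None:
    """Write a scenario as a YAML document (round-trips via :func:`load_config`)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(bundle_to_dict(bundle), fh, sort_keys=True)
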