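"""Rule-based diagnosis calculator for acute rheumatic fever (ARF).

ARF has no single diagnostic test: diagnosis applies the Australian
revision of the Jones criteria, which stratify major and minor
manifestations by population risk and require fixed counts of each,
together with evidence of a preceding group A streptococcal infection.
This module implements the whole pipeline in the order a case flows
through it:

1.  configuration / reference tables — every numeric threshold and the
    age-banded upper limits of normal (ULN) the engine consults;
2.  patient record schema — one suspected-ARF presentation;
3.  criteria engine — risk-group assignment, manifestation resolution,
    streptococcal-evidence assessment, and the ordered diagnosis
    (Not ARF < Possible < Probable < Definite);
4.  agreement statistics — the 4x4 gold-vs-calculator cross-tabulation,
    Cohen's kappa, and one-vs-rest sensitivity / specificity, for
    validating the calculator against an expert-panel gold standard;
5.  synthetic cohort generator and named clinical fixtures;
6.  JSON / CSV input-output used by the command-line tool.
"""

from __future__ import annotations

import enum
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.stats import norm

logger = logging.getLogger("arfdx")

__all__ = [
    "ArfdxError",
    "ConfigurationError",
    "InputError",
    "RiskIndeterminateError",
    "UndefinedKappaError",
    "RiskThresholds",
    "AgeBandedULN",
    "UlnTables",
    "CalculatorConfig",
    "default_thresholds",
    "default_config",
    "lookup_uln",
    "load_config",
    "save_config",
    "Category",
    "CATEGORY_LABELS",
    "CATEGORY_ORDER",
    "JointFinding",
    "JOINT_RANK",
    "CarditisStatus",
    "PriorHistory",
    "Judgement",
    "RiskLevel",
    "RiskBasis",
    "RiskGroup",
    "PatientPresentation",
    "ManifestationProfile",
    "StrepEvidence",
    "DiagnosisResult",
    "ADVISORY_DIFFERENTIAL",
    "ADVISORY_SPECIALIST",
    "ADVISORY_ECHO_PENDING",
    "ADVISORY_HISTORY_UNVERIFIED",
    "assign_risk_group",
    "classify_manifestations",
    "assess_strep_evidence",
    "assign_diagnosis",
    "diagnose",
    "ConfusionTable",
    "KappaResult",
    "CategoryMetrics",
    "OverallMetrics",
    "AgreementReport",
    "build_confusion",
    "cohen_kappa",
    "per_category_metrics",
    "overall_metrics",
    "agreement_report",
    "panel_validation_table",
    "CohortSpec",
    "LabDistribution",
    "DiscordanceModel",
    "generate_cohort",
    "load_fixtures",
    "patient_record_schema",
    "cohort_spec_schema",
    "read_presentations",
    "presentation_to_record",
    "write_presentations",
    "result_to_record",
    "write_results",
    "read_label_pairs",
    "read_confusion_json",
    "write_confusion_json",
]


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class ArfdxError(Exception):
    """Base class for calculator errors."""


class ConfigurationError(ArfdxError):
    """Malformed configuration (thresholds, ULN bands, cohort spec)."""


class InputError(ArfdxError):
    """Malformed patient record or label input."""


class RiskIndeterminateError(ArfdxError):
    """No risk input was supplied; the caller must provide an override."""


class UndefinedKappaError(ArfdxError):
    """Kappa is undefined (chance agreement is 1 but observed is not)."""


# ---------------------------------------------------------------------------
# Section 1 — reference tables (configuration)
#
# Thresholds printed in the criteria table are compared inclusively (>=);
# the epidemiological cutoffs that assign the risk group are strict (>),
# and "elevated above the ULN" (serology, PR interval) is strict (>).
# ---------------------------------------------------------------------------

CONFIG_SCHEMA_VERSION = 1


class RiskThresholds(BaseModel):
    """Numeric criteria thresholds, stratified by population risk.

    The low-risk criteria are stricter: fever and ESR cut-offs are at
    least as high as the high-risk ones, CRP is shared.  Units: fever
    degC, ESR mm/h, CRP mg/L, incidence per 100,000/year in 5-14-year-
    olds, RHD prevalence per 1,000 all ages.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    fever_min_high: float = Field(gt=0)
    fever_min_low: float = Field(gt=0)
    esr_min_high: float = Field(gt=0)
    esr_min_low: float = Field(gt=0)
    crp_min: float = Field(gt=0)
    incidence_cutoff: float = Field(gt=0)
    rhd_prevalence_cutoff: float = Field(gt=0)

    @model_validator(mode="after")
    def _low_risk_is_stricter(self) -> "RiskThresholds":
        if self.fever_min_low < self.fever_min_high:
            raise ValueError("low-risk fever threshold must be >= high-risk")
        if self.esr_min_low < self.esr_min_high:
            raise ValueError("low-risk ESR threshold must be >= high-risk")
        return self


def default_thresholds() -> RiskThresholds:
    """Thresholds of the current Australian criteria.

    Fever >= 38.0 degC (high-risk) / >= 38.5 degC (low-risk); ESR >= 30
    mm/h (high) / >= 60 mm/h (low); CRP >= 30 mg/L in both groups.
    High-risk setting: ARF incidence > 30/100,000/year in 5-14-year-olds
    or all-age RHD prevalence > 2/1,000.
    """
    return RiskThresholds(
        fever_min_high=38.0,
        fever_min_low=38.5,
        esr_min_high=30.0,
        esr_min_low=60.0,
        crp_min=30.0,
        incidence_cutoff=30.0,
        rhd_prevalence_cutoff=2.0,
    )


class AgeBandedULN(BaseModel):
    """Age-banded upper limits of normal for one measurement.

    Bands are half-open ``[low, high)`` intervals in years, contiguous
    from 0 with an open-ended (``inf``) top band, so every non-negative
    age falls in exactly one band.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    measurement_kind: str
    bands: tuple[tuple[float, float, float], ...]

    @model_validator(mode="after")
    def _bands_cover_all_ages(self) -> "AgeBandedULN":
        if not self.bands:
            raise ValueError("at least one band is required")
        if self.bands[0][0] != 0:
            raise ValueError("bands must start at age 0")
        if not math.isinf(self.bands[-1][1]):
            raise ValueError("top band must be open-ended")
        for (lo, hi, _), (nlo, _, _) in zip(self.bands, self.bands[1:]):
            if hi != nlo:
                raise ValueError("bands must be contiguous and ordered")
        for lo, hi, limit in self.bands:
            if not lo < hi:
                raise ValueError("band bounds must satisfy low < high")
            if limit <= 0:
                raise ValueError("ULN values must be positive")
        return self


def lookup_uln(table: AgeBandedULN, age: float) -> float:
    """Upper limit of normal for ``age`` (years).

    A boundary age resolves to the band whose inclusive lower bound it
    equals.  Negative ages are a domain error.
    """
    if age < 0:
        raise InputError(f"age must be non-negative, got {age}")
    for lo, hi, limit in table.bands:
        if lo <= age < hi:
            return limit
    raise ConfigurationError(f"no band contains age {age}")  # pragma: no cover


class UlnTables(BaseModel):
    """The three ULN tables the engine consults."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    pr_interval: AgeBandedULN
    aso_titre: AgeBandedULN
    adb_titre: AgeBandedULN


class CalculatorConfig(BaseModel):
    """Complete engine configuration: thresholds plus the ULN tables.

    A ``schema_version`` guards the on-disk format; unknown fields are
    rejected so a typo cannot silently alter a clinical threshold.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    schema_version: int = CONFIG_SCHEMA_VERSION
    thresholds: RiskThresholds
    uln: UlnTables

    @model_validator(mode="after")
    def _check_version(self) -> "CalculatorConfig":
        if self.schema_version != CONFIG_SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self.schema_version}"
            )
        return self


# Default ULN tables.  The published criteria table does not print these
# values; the defaults below are the age bands of the Australian ARF/RHD
# guideline the calculator implements (PR interval in ms; serology ULNs
# from Northern Territory reference data, IU/mL).  They are configuration,
# not code: override them via a config file for other settings.
_DEFAULT_PR_ULN = AgeBandedULN(
    measurement_kind="PR interval ms",
    bands=(
        (0.0, 3.0, 140.0),
        (3.0, 12.0, 160.0),
        (12.0, 17.0, 180.0),
        (17.0, math.inf, 200.0),
    ),
)
_DEFAULT_ASO_ULN = AgeBandedULN(
    measurement_kind="ASO titre IU/mL",
    bands=(
        (0.0, 5.0, 170.0),
        (5.0, 15.0, 276.0),
        (15.0, 25.0, 238.0),
        (25.0, 35.0, 177.0),
        (35.0, math.inf, 127.0),
    ),
)
_DEFAULT_ADB_ULN = AgeBandedULN(
    measurement_kind="anti-DNase B titre IU/mL",
    bands=(
        (0.0, 5.0, 366.0),
        (5.0, 15.0, 499.0),
        (15.0, 25.0, 473.0),
        (25.0, 35.0, 390.0),
        (35.0, math.inf, 265.0),
    ),
)


def default_config() -> CalculatorConfig:
    """Shipped default configuration (thresholds + ULN tables)."""
    return CalculatorConfig(
        thresholds=default_thresholds(),
        uln=UlnTables(
            pr_interval=_DEFAULT_PR_ULN,
            aso_titre=_DEFAULT_ASO_ULN,
            adb_titre=_DEFAULT_ADB_ULN,
        ),
    )


def _config_to_plain(config: CalculatorConfig) -> dict:
    data = config.model_dump(mode="json")
    # YAML cannot round-trip float("inf") portably; spell it out.
    for table in data["uln"].values():
        table["bands"] = [
            [lo, "inf" if math.isinf(hi) else hi, limit]
            for lo, hi, limit in table["bands"]
        ]
    return data


def _config_from_plain(data: object) -> CalculatorConfig:
    if not isinstance(data, dict):
        raise ConfigurationError("configuration root must be a mapping")
    data = json.loads(json.dumps(data))  # deep copy, normalise types
    try:
        for table in data.get("uln", {}).values():
            if isinstance(table, dict) and isinstance(table.get("bands"), list):
                table["bands"] = [
                    [lo, math.inf if hi == "inf" else hi, limit]
                    for lo, hi, limit in table["bands"]
                ]
        return CalculatorConfig.model_validate(data)
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(str(exc)) from exc


def save_config(config: CalculatorConfig, path: str | Path) -> None:
    """Write the configuration as YAML (deterministic key order)."""
    Path(path).write_text(
        yaml.safe_dump(_config_to_plain(config), sort_keys=True)
    )


def load_config(path: str | Path) -> CalculatorConfig:
    """Load and validate a YAML or JSON configuration file."""
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    config = _config_from_plain(data)
    logger.info(
        "loaded configuration schema_version=%d thresholds=%s",
        config.schema_version,
        config.thresholds.model_dump(),
    )
    return config


# ---------------------------------------------------------------------------
# Section 2 — patient record schema and result types
# ---------------------------------------------------------------------------

class Category(enum.IntEnum):
    """Ordered diagnostic certainty: Not ARF < Possible < Probable < Definite."""

    NOT_ARF = 0
    POSSIBLE = 1
    PROBABLE = 2
    DEFINITE = 3

    @property
    def label(self) -> str:
        return CATEGORY_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "Category":
        try:
            return _LABEL_TO_CATEGORY[label]
        except KeyError:
            raise InputError(f"unknown category label: {label!r}") from None


CATEGORY_LABELS: dict[Category, str] = {
    Category.NOT_ARF: "not-arf",
    Category.POSSIBLE: "possible",
    Category.PROBABLE: "probable",
    Category.DEFINITE: "definite",
}
_LABEL_TO_CATEGORY = {v: k for k, v in CATEGORY_LABELS.items()}
CATEGORY_ORDER: tuple[str, ...] = tuple(CATEGORY_LABELS.values())


class JointFinding(str, enum.Enum):
    """Single highest-ranking joint finding of the presentation."""

    NONE = "none"
    MONOARTHRALGIA = "monoarthralgia"
    POLYARTHRALGIA = "polyarthralgia"
    ASEPTIC_MONOARTHRITIS = "aseptic-monoarthritis"
    POLYARTHRITIS = "polyarthritis"


#: Clinical severity ranking used by the joint-upgrade monotonicity property.
JOINT_RANK: dict[JointFinding, int] = {
    JointFinding.NONE: 0,
    JointFinding.MONOARTHRALGIA: 1,
    JointFinding.POLYARTHRALGIA: 2,
    JointFinding.ASEPTIC_MONOARTHRITIS: 3,
    JointFinding.POLYARTHRITIS: 4,
}


class CarditisStatus(str, enum.Enum):
    ABSENT = "absent"
    PRESENT = "present-clinical-or-subclinical"
    ECHO_PENDING = "echo-pending"


class PriorHistory(str, enum.Enum):
    CONFIRMED_NONE = "confirmed-none"
    DOCUMENTED_HISTORY = "documented-history"
    UNKNOWN = "unknown"


class Judgement(str, enum.Enum):
    """Clinician's answer to "Is ARF considered the most likely diagnosis?"."""

    YES = "yes"
    UNCERTAIN = "uncertain"
    NO = "no"


class RiskLevel(str, enum.Enum):
    HIGH = "high"
    LOW = "low"


class RiskBasis(str, enum.Enum):
    EPIDEMIOLOGY = "epidemiology"
    INDIGENOUS_RURAL_REMOTE = "indigenous-rural-remote"
    EXPLICIT_OVERRIDE = "explicit-override"


class RiskGroup(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)

    value: RiskLevel
    basis: RiskBasis


class PatientPresentation(BaseModel):
    """One suspected-ARF case.

    Absent optional fields mean "not measured / result unavailable" and
    contribute nothing to the diagnosis; in the CSV projection an empty
    cell maps to absent.  Multiple joint findings must be pre-ranked by
    the caller into the single highest-ranking ``joint_finding``.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    age: float = Field(ge=0, description="age in years")
    community_incidence: float | None = Field(
        default=None, ge=0,
        description="ARF incidence per 100,000/year in 5-14-year-olds",
    )
    community_rhd_prevalence: float | None = Field(
        default=None, ge=0, description="all-age RHD prevalence per 1,000"
    )
    indigenous_rural_remote: bool | None = None
    risk_group_override: RiskLevel | None = None
    prior_arf_rhd: PriorHistory = PriorHistory.UNKNOWN
    joint_finding: JointFinding = JointFinding.NONE
    carditis: CarditisStatus = CarditisStatus.ABSENT
    chorea: bool | None = None
    erythema_marginatum: bool | None = None
    subcutaneous_nodules: bool | None = None
    max_temperature: float | None = Field(default=None, ge=0, description="degC")
    esr: float | None = Field(default=None, ge=0, description="mm/h")
    crp: float | None = Field(default=None, ge=0, description="mg/L")
    pr_interval: float | None = Field(default=None, ge=0, description="ms")
    aso_titre: float | None = Field(default=None, ge=0, description="IU/mL")
    adb_titre: float | None = Field(default=None, ge=0, description="IU/mL")
    rising_titres: bool | None = None
    positive_throat_culture_or_rapid_test: bool | None = None
    clinician_judgement: Judgement | None = None


#: Joint-derived manifestation identifiers (at most one may appear in a
#: profile, in either column).
_JOINT_IDS = frozenset(
    j.value for j in JointFinding if j is not JointFinding.NONE
)


@dataclass(frozen=True)
class ManifestationProfile:
    """Resolved major/minor manifestation sets for one presentation."""

    majors: frozenset[str]
    minors: frozenset[str]
    notes: tuple[str, ...] = ()

    @property
    def n_major(self) -> int:
        return len(self.majors)

    @property
    def n_minor(self) -> int:
        return len(self.minors)

    def __post_init__(self) -> None:
        if self.majors & self.minors:
            raise ValueError("a manifestation cannot be both major and minor")
        if len((self.majors | self.minors) & _JOINT_IDS) > 1:
            raise ValueError("at most one joint-derived manifestation allowed")


@dataclass(frozen=True)
class StrepEvidence:
    """Evidence of a preceding group A streptococcal infection."""

    status: str  # "evidence" | "no-evidence-or-unmeasured"
    basis: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.status == "evidence") != bool(self.basis):
            raise ValueError("status must be 'evidence' iff basis is non-empty")

    @property
    def has_evidence(self) -> bool:
        return self.status == "evidence"


# Advisory wording of the revised calculator, stored once as versioned
# constants so text changes are tracked like code.
ADVISORY_DIFFERENTIAL = (
    "The Jones Criteria and the diagnosis provided by this calculator "
    "assume differential diagnoses have been considered, tested for and "
    "excluded. Clinical signs also found in septic arthritis, bacteraemia, "
    "lupus and numerous other conditions when entered into the app can "
    "result in a diagnosis of possible, probable or even definite ARF "
    "being displayed."
)
ADVISORY_SPECIALIST = (
    "In complicated or early cases, or those with incomplete "
    "investigations, seek specialist advice."
)
ADVISORY_ECHO_PENDING = (
    "If echocardiogram is pending, base decision on clinical assessment "
    "until echocardiogram result is available."
)
ADVISORY_HISTORY_UNVERIFIED = (
    "Prior ARF/RHD history was not confirmed; the presentation was "
    "assessed as an initial episode. Verify the history before finalising "
    "the diagnosis."
)


@dataclass(frozen=True)
class DiagnosisResult:
    """Ordered diagnosis category with its audit trail."""

    category: Category
    episode_type: str  # "initial" | "recurrent"
    pathway: tuple[int, int] | None  # (majors required, minors required)
    strep: str  # StrepEvidence.status
    advisories: tuple[str, ...]
    asked_clinician_question: bool

    def __post_init__(self) -> None:
        if self.category is Category.DEFINITE and self.strep != "evidence":
            raise ValueError("a definite diagnosis requires strep evidence")
        if (
            self.category in (Category.POSSIBLE, Category.PROBABLE)
            and not self.asked_clinician_question
        ):
            raise ValueError(
                "possible/probable require the clinician question"
            )
        if ADVISORY_DIFFERENTIAL not in self.advisories:
            raise ValueError("differential-diagnosis advisory missing")
        if ADVISORY_SPECIALIST not in self.advisories:
            raise ValueError("specialist-advice advisory missing")


# ---------------------------------------------------------------------------
# Section 3 — criteria engine
# ---------------------------------------------------------------------------

def assign_risk_group(
    p: PatientPresentation, t: RiskThresholds
) -> RiskGroup:
    """Assign the population risk group.

    Precedence: an explicit override wins; otherwise Aboriginal and/or
    Torres Strait Islander patients in rural/remote settings are
    high-risk; otherwise the community epidemiology decides (incidence
    strictly above the cutoff in 5-14-year-olds, or all-age RHD
    prevalence strictly above its cutoff).  With no risk input at all
    the group is indeterminate and the caller must supply an override.
    """
    if p.risk_group_override is not None:
        return RiskGroup(
            value=p.risk_group_override, basis=RiskBasis.EXPLICIT_OVERRIDE
        )
    if p.indigenous_rural_remote:
        return RiskGroup(
            value=RiskLevel.HIGH, basis=RiskBasis.INDIGENOUS_RURAL_REMOTE
        )
    if p.community_incidence is not None and p.community_incidence > t.incidence_cutoff:
        return RiskGroup(value=RiskLevel.HIGH, basis=RiskBasis.EPIDEMIOLOGY)
    if (
        p.community_rhd_prevalence is not None
        and p.community_rhd_prevalence > t.rhd_prevalence_cutoff
    ):
        return RiskGroup(value=RiskLevel.HIGH, basis=RiskBasis.EPIDEMIOLOGY)
    if p.community_incidence is not None or p.community_rhd_prevalence is not None:
        return RiskGroup(value=RiskLevel.LOW, basis=RiskBasis.EPIDEMIOLOGY)
    if p.indigenous_rural_remote is not None:
        return RiskGroup(
            value=RiskLevel.LOW, basis=RiskBasis.INDIGENOUS_RURAL_REMOTE
        )
    raise RiskIndeterminateError(
        "no risk input present; supply community incidence / RHD prevalence, "
        "the Indigenous rural/remote flag, or an explicit risk_group_override"
    )


# Joint-finding placement per risk group: value is "major", "minor" or None.
_JOINT_PLACEMENT: dict[RiskLevel, dict[JointFinding, str | None]] = {
    RiskLevel.HIGH: {
        JointFinding.POLYARTHRITIS: "major",
        JointFinding.ASEPTIC_MONOARTHRITIS: "major",
        JointFinding.POLYARTHRALGIA: "major",
        JointFinding.MONOARTHRALGIA: "minor",
        JointFinding.NONE: None,
    },
    RiskLevel.LOW: {
        JointFinding.POLYARTHRITIS: "major",
        JointFinding.ASEPTIC_MONOARTHRITIS: "minor",
        JointFinding.POLYARTHRALGIA: "minor",
        JointFinding.MONOARTHRALGIA: None,
        JointFinding.NONE: None,
    },
}


def classify_manifestations(
    p: PatientPresentation,
    g: RiskGroup,
    t: RiskThresholds,
    uln: UlnTables,
) -> ManifestationProfile:
    """Resolve the presentation into major and minor manifestation sets.

    Carditis (clinical or subclinical), Sydenham chorea, erythema
    marginatum and subcutaneous nodules are major in both risk groups.
    The single joint finding is placed per risk group: in high-risk
    settings polyarthritis, aseptic monoarthritis and polyarthralgia are
    major and monoarthralgia minor; in low-risk settings only
    polyarthritis is major, polyarthralgia and aseptic monoarthritis are
    minor, and monoarthralgia counts for nothing.  Fever and the
    inflammatory-marker minor use the group's thresholds (inclusive).
    A prolonged PR interval (strictly above the age ULN) is a minor
    manifestation unless carditis already counts as a major.  Absent or
    pending measurements contribute nothing.
    """
    majors: set[str] = set()
    minors: set[str] = set()
    notes: list[str] = []

    if p.carditis == CarditisStatus.PRESENT:
        majors.add("carditis")
    elif p.carditis == CarditisStatus.ECHO_PENDING:
        notes.append("echocardiogram pending: carditis not counted")
    if p.chorea:
        majors.add("sydenham-chorea")
    if p.erythema_marginatum:
        majors.add("erythema-marginatum")
    if p.subcutaneous_nodules:
        majors.add("subcutaneous-nodules")

    placement = _JOINT_PLACEMENT[g.value][p.joint_finding]
    if placement == "major":
        majors.add(p.joint_finding.value)
        notes.append(f"{p.joint_finding.value}: major ({g.value.value}-risk)")
    elif placement == "minor":
        minors.add(p.joint_finding.value)
        notes.append(f"{p.joint_finding.value}: minor ({g.value.value}-risk)")
    elif p.joint_finding != JointFinding.NONE:
        notes.append(
            f"{p.joint_finding.value}: not a manifestation in "
            f"{g.value.value}-risk settings"
        )

    fever_min = (
        t.fever_min_high if g.value == RiskLevel.HIGH else t.fever_min_low
    )
    if p.max_temperature is not None and p.max_temperature >= fever_min:
        minors.add("fever")

    esr_min = t.esr_min_high if g.value == RiskLevel.HIGH else t.esr_min_low
    if (p.esr is not None and p.esr >= esr_min) or (
        p.crp is not None and p.crp >= t.crp_min
    ):
        minors.add("elevated-inflammatory-markers")

    if p.pr_interval is not None:
        limit = lookup_uln(uln.pr_interval, p.age)
        if p.pr_interval > limit:
            if "carditis" in majors:
                notes.append(
                    "prolonged PR interval suppressed: carditis already "
                    "counted as a major manifestation"
                )
            else:
                minors.add("prolonged-pr-interval")

    return ManifestationProfile(
        majors=frozenset(majors), minors=frozenset(minors), notes=tuple(notes)
    )


def assess_strep_evidence(
    p: PatientPresentation, uln: UlnTables
) -> StrepEvidence:
    """Assess evidence of a preceding group A streptococcal infection.

    Evidence: an ASO or anti-DNase B titre strictly above the age ULN,
    documented rising titres, or a positive throat culture / rapid
    antigen test.  Titres within normal limits or not measured give
    no evidence.
    """
    basis: list[str] = []
    if p.aso_titre is not None and p.aso_titre > lookup_uln(
        uln.aso_titre, p.age
    ):
        basis.append("elevated-aso-titre")
    if p.adb_titre is not None and p.adb_titre > lookup_uln(
        uln.adb_titre, p.age
    ):
        basis.append("elevated-adb-titre")
    if p.rising_titres:
        basis.append("rising-titres")
    if p.positive_throat_culture_or_rapid_test:
        basis.append("positive-culture-or-rapid-test")
    if basis:
        return StrepEvidence(status="evidence", basis=tuple(basis))
    return StrepEvidence(status="no-evidence-or-unmeasured")


#: Diagnostic pathways as (majors required, minors required) pairs.
#: A recurrence in a patient with documented ARF/RHD history adds the
#: three-minor pathway.
PATHWAYS_INITIAL: tuple[tuple[int, int], ...] = ((2, 0), (1, 2))
PATHWAYS_RECURRENT: tuple[tuple[int, int], ...] = ((2, 0), (1, 2), (0, 3))


def _meets(n_major: int, n_minor: int, a: int, b: int) -> bool:
    return n_major >= a and n_minor >= b


def _one_manifestation_short(
    n_major: int, n_minor: int, a: int, b: int
) -> bool:
    """One major or one minor short of the (a, b) pathway."""
    return _meets(n_major, n_minor, a - 1, b) or _meets(
        n_major, n_minor, a, max(b - 1, 0)
    )


def assign_diagnosis(
    m: ManifestationProfile,
    s: StrepEvidence,
    prior: PriorHistory,
    judgement: Judgement | None = None,
) -> DiagnosisResult:
    """Assign the ordered diagnosis category from a resolved profile.

    Definite ARF requires a full pathway (2 major, or 1 major + 2 minor,
    or — for a documented recurrence — 3 minor) together with evidence
    of preceding streptococcal infection.  A presentation that falls
    short by exactly one element — one manifestation short of a pathway
    with strep evidence, or a complete pathway without strep evidence —
    triggers the clinician question "Is ARF considered the most likely
    diagnosis?": yes gives Probable, uncertain (the default) Possible,
    no gives Not ARF.  Anything further short is Not ARF without asking.

    An unknown prior history is assessed as an initial episode with an
    advisory; only a documented history opens the recurrence pathway.
    """
    recurrent = prior == PriorHistory.DOCUMENTED_HISTORY
    pathways = PATHWAYS_RECURRENT if recurrent else PATHWAYS_INITIAL
    nmaj, nmin = m.n_major, m.n_minor

    advisories = [ADVISORY_DIFFERENTIAL, ADVISORY_SPECIALIST]
    if prior == PriorHistory.UNKNOWN:
        advisories.append(ADVISORY_HISTORY_UNVERIFIED)
    episode = "recurrent" if recurrent else "initial"

    satisfied = next(
        ((a, b) for a, b in pathways if _meets(nmaj, nmin, a, b)), None
    )
    if s.has_evidence and satisfied is not None:
        return DiagnosisResult(
            category=Category.DEFINITE,
            episode_type=episode,
            pathway=satisfied,
            strep=s.status,
            advisories=tuple(advisories),
            asked_clinician_question=False,
        )

    if s.has_evidence:
        near = next(
            (
                (a, b)
                for a, b in pathways
                if _one_manifestation_short(nmaj, nmin, a, b)
            ),
            None,
        )
        shortfall = near is not None and nmaj + nmin >= 1
    else:
        near = satisfied
        shortfall = satisfied is not None

    if shortfall:
        answer = judgement if judgement is not None else Judgement.UNCERTAIN
        category = {
            Judgement.YES: Category.PROBABLE,
            Judgement.UNCERTAIN: Category.POSSIBLE,
            Judgement.NO: Category.NOT_ARF,
        }[answer]
        return DiagnosisResult(
            category=category,
            episode_type=episode,
            pathway=near,
            strep=s.status,
            advisories=tuple(advisories),
            asked_clinician_question=True,
        )

    return DiagnosisResult(
        category=Category.NOT_ARF,
        episode_type=episode,
        pathway=None,
        strep=s.status,
        advisories=tuple(advisories),
        asked_clinician_question=False,
    )


def diagnose(
    p: PatientPresentation, config: CalculatorConfig | None = None
) -> DiagnosisResult:
    """Run the full calculator on one presentation.

    Composes risk-group assignment, manifestation resolution,
    streptococcal-evidence assessment and category assignment.  An
    absent clinician judgement defaults to "uncertain".  A pending
    echocardiogram contributes nothing to the profile and attaches its
    advisory to the result.
    """
    cfg = config if config is not None else default_config()
    group = assign_risk_group(p, cfg.thresholds)
    profile = classify_manifestations(p, group, cfg.thresholds, cfg.uln)
    strep = assess_strep_evidence(p, cfg.uln)
    result = assign_diagnosis(
        profile, strep, p.prior_arf_rhd, p.clinician_judgement
    )
    if p.carditis == CarditisStatus.ECHO_PENDING:
        result = DiagnosisResult(
            category=result.category,
            episode_type=result.episode_type,
            pathway=result.pathway,
            strep=result.strep,
            advisories=result.advisories + (ADVISORY_ECHO_PENDING,),
            asked_clinician_question=result.asked_clinician_question,
        )
    return result


# ---------------------------------------------------------------------------
# Section 4 — agreement statistics
#
# Rows are the gold-standard (expert-panel) labels, columns the
# calculator's: this orientation is fixed in every reader, writer and
# rendered header because transposition is the classic silent bug.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionTable:
    """k x k cross-tabulation; rows = gold standard, columns = calculator."""

    categories: tuple[str, ...]
    counts: np.ndarray  # shape (k, k), non-negative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.categories)
        if counts.shape != (k, k):
            raise InputError(
                f"counts must be {k}x{k}, got {counts.shape}"
            )
        if (counts < 0).any():
            raise InputError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def build_confusion(
    gold: Sequence[str],
    predicted: Sequence[str],
    categories: Sequence[str] = CATEGORY_ORDER,
) -> ConfusionTable:
    """Cross-tabulate paired gold and calculator labels."""
    if len(gold) != len(predicted):
        raise InputError(
            f"gold and predicted differ in length: {len(gold)} vs {len(predicted)}"
        )
    if len(gold) == 0:
        raise InputError("label sequences must be non-empty")
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)), dtype=np.int64)
    for g, p in zip(gold, predicted):
        if g not in index:
            raise InputError(f"unknown gold label: {g!r}")
        if p not in index:
            raise InputError(f"unknown predicted label: {p!r}")
        counts[index[g], index[p]] += 1
    return ConfusionTable(categories=tuple(categories), counts=counts)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci: tuple[float, float]
    observed_agreement: float
    expected_agreement: float


def cohen_kappa(t: ConfusionTable) -> KappaResult:
    """Cohen's chance-corrected agreement, kappa = (Po - Pe) / (1 - Pe).

    Po is the observed agreement (diagonal fraction), Pe the agreement
    expected from the marginals.  The standard error is the asymptotic
    formula se = sqrt(Po (1 - Po) / (n (1 - Pe)^2)) with a normal 95%
    interval clipped to [-1, 1].  A degenerate table where both raters
    use a single identical category gives kappa = 1; a single-category
    marginal with imperfect agreement leaves kappa undefined.
    """
    n = t.n
    if n < 1:
        raise InputError("confusion table is empty")
    po = float(np.trace(t.counts)) / n
    pe = float(t.row_sums @ t.col_sums) / (n * n)
    if pe == 1.0:
        if po == 1.0:
            return KappaResult(
                kappa=1.0, se=0.0, ci=(1.0, 1.0),
                observed_agreement=1.0, expected_agreement=1.0,
            )
        raise UndefinedKappaError(
            "chance agreement is 1 but observed agreement is not"
        )
    kappa = (po - pe) / (1.0 - pe)
    se = math.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    ci = (
        max(kappa - 1.96 * se, -1.0),
        min(kappa + 1.96 * se, 1.0),
    )
    return KappaResult(
        kappa=kappa, se=se, ci=ci,
        observed_agreement=po, expected_agreement=pe,
    )


@dataclass(frozen=True)
class CategoryMetrics:
    """One-vs-rest diagnostic accuracy for a single category.

    ``None`` marks a metric whose denominator is zero (no gold-positive
    or no gold-negative cases): explicitly not applicable, never 0 or 100.
    """

    sensitivity: float | None
    specificity: float | None

    @property
    def sensitivity_pct(self) -> int | None:
        return _pct(self.sensitivity)

    @property
    def specificity_pct(self) -> int | None:
        return _pct(self.specificity)


def _pct(x: float | None) -> int | None:
    """Nearest-integer percent (half away from zero, deterministic)."""
    if x is None:
        return None
    return int(math.floor(100.0 * x + 0.5))


def per_category_metrics(t: ConfusionTable) -> dict[str, CategoryMetrics]:
    """One-vs-rest sensitivity and specificity for each category.

    For category k: sensitivity = TP / gold positives (row sum) and
    specificity = TN / gold negatives, with TN = n - row_k - col_k + TP.
    """
    if t.n < 1:
        raise InputError("confusion table is empty")
    out: dict[str, CategoryMetrics] = {}
    n = t.n
    for k, cat in enumerate(t.categories):
        tp = int(t.counts[k, k])
        row = int(t.row_sums[k])
        col = int(t.col_sums[k])
        tn = n - row - col + tp
        sens = tp / row if row > 0 else None
        spec = tn / (n - row) if n - row > 0 else None
        out[cat] = CategoryMetrics(sensitivity=sens, specificity=spec)
    return out


@dataclass(frozen=True)
class OverallMetrics:
    sensitivity: float
    specificity: float
    agreement: float
    discordant: float

    @property
    def sensitivity_pct(self) -> int:
        return _pct(self.sensitivity)

    @property
    def specificity_pct(self) -> int:
        return _pct(self.specificity)

    @property
    def agreement_pct(self) -> int:
        return _pct(self.agreement)

    @property
    def discordant_pct(self) -> int:
        return _pct(self.discordant)


def overall_metrics(t: ConfusionTable) -> OverallMetrics:
    """Micro-averaged accuracy over the one-vs-rest collapses.

    Overall sensitivity pools true positives over all categories
    (which equals the raw agreement); overall specificity pools the
    true negatives of each collapse.
    """
    if t.n < 1:
        raise InputError("confusion table is empty")
    n = t.n
    tp_total = int(np.trace(t.counts))
    pos_total = int(t.row_sums.sum())
    tn_total = sum(
        n - int(t.row_sums[k]) - int(t.col_sums[k]) + int(t.counts[k, k])
        for k in range(len(t.categories))
    )
    neg_total = sum(n - int(t.row_sums[k]) for k in range(len(t.categories)))
    agreement = tp_total / n
    return OverallMetrics(
        sensitivity=tp_total / pos_total,
        specificity=tn_total / neg_total if neg_total > 0 else 1.0,
        agreement=agreement,
        discordant=1.0 - agreement,
    )


@dataclass(frozen=True)
class AgreementReport:
    """Full agreement summary for a gold-vs-calculator table."""

    table: ConfusionTable
    observed_agreement: float
    expected_agreement: float
    kappa: float
    kappa_se: float
    kappa_ci: tuple[float, float]
    per_category: dict[str, CategoryMetrics]
    overall: OverallMetrics

    def to_dict(self) -> dict:
        return {
            "orientation": "rows=gold-standard, columns=calculator",
            "categories": list(self.table.categories),
            "counts": self.table.counts.tolist(),
            "n": self.table.n,
            "observed_agreement": self.observed_agreement,
            "expected_agreement": self.expected_agreement,
            "kappa": self.kappa,
            "kappa_se": self.kappa_se,
            "kappa_ci95": list(self.kappa_ci),
            "per_category": {
                cat: {
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "sensitivity_pct": m.sensitivity_pct,
                    "specificity_pct": m.specificity_pct,
                }
                for cat, m in self.per_category.items()
            },
            "overall": {
                "sensitivity": self.overall.sensitivity,
                "specificity": self.overall.specificity,
                "sensitivity_pct": self.overall.sensitivity_pct,
                "specificity_pct": self.overall.specificity_pct,
                "agreement": self.overall.agreement,
                "agreement_pct": self.overall.agreement_pct,
                "discordant": self.overall.discordant,
                "discordant_pct": self.overall.discordant_pct,
            },
        }

    def render_text(self) -> str:
        """Human-readable report (rows = gold standard, columns = calculator)."""
        t = self.table
        width = max(len(c) for c in t.categories) + 2
        lines = [
            "Agreement report (rows = gold standard, columns = calculator)",
            "",
            " " * width
            + "".join(f"{c:>{width}}" for c in t.categories)
            + f"{'total':>{width}}",
        ]
        for i, cat in enumerate(t.categories):
            row = "".join(f"{int(v):>{width}}" for v in t.counts[i])
            lines.append(f"{cat:<{width}}{row}{int(t.row_sums[i]):>{width}}")
        lines.append(
            f"{'total':<{width}}"
            + "".join(f"{int(v):>{width}}" for v in t.col_sums)
            + f"{t.n:>{width}}"
        )
        lines += [
            "",
            f"observed agreement  Po = {self.observed_agreement:.4f}"
            f" ({self.overall.agreement_pct}%)",
            f"expected agreement  Pe = {self.expected_agreement:.4f}",
            f"Cohen's kappa          = {self.kappa:.3f}"
            f" (SE {self.kappa_se:.3f}, 95% CI"
            f" {self.kappa_ci[0]:.3f}-{self.kappa_ci[1]:.3f})",
            "",
            "per-category (one-vs-rest)   sensitivity  specificity",
        ]
        for cat, m in self.per_category.items():
            s = "n/a" if m.sensitivity_pct is None else f"{m.sensitivity_pct}%"
            p = "n/a" if m.specificity_pct is None else f"{m.specificity_pct}%"
            lines.append(f"  {cat:<25}  {s:>11}  {p:>11}")
        lines.append(
            f"  {'overall (micro-average)':<25}  "
            f"{str(self.overall.sensitivity_pct) + '%':>11}  "
            f"{str(self.overall.specificity_pct) + '%':>11}"
        )
        lines.append(
            f"discordant: {int(round(self.overall.discordant * t.n))}/{t.n}"
            f" ({self.overall.discordant_pct}%)"
        )
        return "\n".join(lines)


def agreement_report(t: ConfusionTable) -> AgreementReport:
    """Compute every agreement statistic for one confusion table."""
    kr = cohen_kappa(t)
    return AgreementReport(
        table=t,
        observed_agreement=kr.observed_agreement,
        expected_agreement=kr.expected_agreement,
        kappa=kr.kappa,
        kappa_se=kr.se,
        kappa_ci=kr.ci,
        per_category=per_category_metrics(t),
        overall=overall_metrics(t),
    )


def panel_validation_table() -> ConfusionTable:
    """Gold-vs-calculator table of the 35-patient validation cohort.

    Cross-tabulation of expert-panel consensus diagnoses against the
    calculator's for 35 consecutively enrolled suspected-ARF patients:
    gold marginals (4, 6, 2, 23), calculator marginals (4, 5, 1, 25) and
    diagonal (3, 4, 1, 23) in category order not-arf/possible/probable/
    definite.  The published marginals and diagonal determine every
    agreement statistic; the off-diagonal completion below is the
    consistent placement of the four discordant cases.
    """
    counts = np.array(
        [
            #  not  poss  prob  def   (calculator)
            [3, 0, 0, 1],  # gold not-arf
            [1, 4, 0, 1],  # gold possible
            [0, 1, 1, 0],  # gold probable
            [0, 0, 0, 23],  # gold definite
        ],
        dtype=np.int64,
    )
    return ConfusionTable(categories=CATEGORY_ORDER, counts=counts)


# ---------------------------------------------------------------------------
# Section 5 — synthetic cohort generator and clinical fixtures
# ---------------------------------------------------------------------------

class LabDistribution(BaseModel):
    """Lognormal lab-value model parameterised by threshold exceedance.

    ``exceedance`` is the probability that the drawn value lies at or
    above the clinically relevant threshold (the high-risk criteria
    threshold, or the age ULN); ``sigma`` is the lognormal shape on the
    natural-log scale.  The median is derived so the exceedance
    probability is the directly specified knob.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    exceedance: float = Field(ge=0.0, le=1.0)
    sigma: float = Field(gt=0.0)


class DiscordanceModel(BaseModel):
    """Gold-label perturbation mimicking expert-panel reclassification.

    With probability ``rate`` a case's gold label moves to an adjacent
    category in the Not ARF < Possible < Probable < Definite order —
    the near-miss pattern of real panel disagreements (for example a
    monoarthritis read down to monoarthralgia, or an excluded
    differential turning Possible into Not ARF).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    rate: float = Field(ge=0.0, le=1.0)


def _default_manifestation_prevalences() -> dict[str, float]:
    return {
        "polyarthritis": 0.35,
        "aseptic-monoarthritis": 0.25,
        "polyarthralgia": 0.12,
        "monoarthralgia": 0.10,
        "carditis": 0.35,
        "echo-pending": 0.05,
        "sydenham-chorea": 0.08,
        "erythema-marginatum": 0.02,
        "subcutaneous-nodules": 0.02,
        "rising-titres": 0.20,
        "positive-culture": 0.15,
    }


def _default_lab_distributions() -> dict[str, LabDistribution]:
    return {
        "max_temperature": LabDistribution(exceedance=0.70, sigma=0.012),
        "esr": LabDistribution(exceedance=0.60, sigma=0.8),
        "crp": LabDistribution(exceedance=0.60, sigma=0.9),
        "pr_interval": LabDistribution(exceedance=0.15, sigma=0.08),
        "aso_titre": LabDistribution(exceedance=0.60, sigma=0.7),
        "adb_titre": LabDistribution(exceedance=0.60, sigma=0.7),
    }


def _default_missingness() -> dict[str, float]:
    return {
        "max_temperature": 0.05,
        "esr": 0.10,
        "crp": 0.10,
        "pr_interval": 0.20,
        "aso_titre": 0.10,
        "adb_titre": 0.10,
    }


class CohortSpec(BaseModel):
    """Parameters of a simulated suspected-ARF cohort.

    The defaults emulate a ~35-patient tertiary-hospital cohort from a
    high-burden region: predominantly high-risk patients, a small
    documented-recurrence fraction, manifestation prevalences that make
    Definite the most common outcome, and a gold-label discordance rate
    of 4/35 matching observed panel-vs-calculator disagreement.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    n: int = Field(default=35, ge=1)
    seed: int = 0
    risk_mix: float = Field(default=0.9, ge=0.0, le=1.0)
    recurrence_fraction: float = Field(default=0.1, ge=0.0, le=1.0)
    manifestation_prevalences: dict[str, float] = Field(
        default_factory=_default_manifestation_prevalences
    )
    lab_distributions: dict[str, LabDistribution] = Field(
        default_factory=_default_lab_distributions
    )
    missingness_rates: dict[str, float] = Field(
        default_factory=_default_missingness
    )
    discordance_model: DiscordanceModel = Field(
        default_factory=lambda: DiscordanceModel(rate=4 / 35)
    )

    @model_validator(mode="after")
    def _rates_in_range(self) -> "CohortSpec":
        for name, p in {
            **self.manifestation_prevalences,
            **self.missingness_rates,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of range for {name!r}: {p}")
        joint_total = sum(
            self.manifestation_prevalences.get(j, 0.0)
            for j in (
                "polyarthritis",
                "aseptic-monoarthritis",
                "polyarthralgia",
                "monoarthralgia",
            )
        )
        if joint_total > 1.0:
            raise ValueError("joint-finding prevalences must sum to <= 1")
        return self


def _lognormal_above(
    rng: np.random.Generator, threshold: float, dist: LabDistribution
) -> float:
    """Draw a lognormal value whose exceedance of ``threshold`` is the knob."""
    # ln X ~ Normal(ln m, sigma^2) with ln m = ln T - sigma * z_(1-p)
    # gives P(X >= T) = p.
    if dist.exceedance <= 0.0:
        z = 8.0
    elif dist.exceedance >= 1.0:
        z = -8.0
    else:
        z = norm.ppf(1.0 - dist.exceedance)
    log_median = math.log(threshold) - dist.sigma * z
    return float(
        math.exp(rng.normal(loc=log_median, scale=dist.sigma))
    )


def _draw_presentation(
    spec: CohortSpec, idx: int, config: CalculatorConfig
) -> PatientPresentation:
    # counter-based substream: one patient's draws never depend on another's
    rng = np.random.default_rng([spec.seed, idx])
    prev = spec.manifestation_prevalences
    labs = spec.lab_distributions
    miss = spec.missingness_rates
    t = config.thresholds

    age = round(float(rng.uniform(3.0, 30.0)), 1)
    high = bool(rng.random() < spec.risk_mix)
    recurrent = bool(rng.random() < spec.recurrence_fraction)

    joint_order = (
        "polyarthritis",
        "aseptic-monoarthritis",
        "polyarthralgia",
        "monoarthralgia",
    )
    u = rng.random()
    joint = JointFinding.NONE
    cumulative = 0.0
    for name in joint_order:
        cumulative += prev.get(name, 0.0)
        if u < cumulative:
            joint = JointFinding(name)
            break

    v = rng.random()
    if v < prev.get("carditis", 0.0):
        carditis = CarditisStatus.PRESENT
    elif v < prev.get("carditis", 0.0) + prev.get("echo-pending", 0.0):
        carditis = CarditisStatus.ECHO_PENDING
    else:
        carditis = CarditisStatus.ABSENT

    def _lab(field_name: str, threshold: float) -> float | None:
        if rng.random() < miss.get(field_name, 0.0):
            return None
        return round(_lognormal_above(rng, threshold, labs[field_name]), 1)

    fields: dict[str, object] = {
        "age": age,
        "indigenous_rural_remote": high,
        # low-risk community epidemiology for the non-Indigenous-remote arm
        "community_incidence": None if high else round(float(rng.uniform(0, 10)), 1),
        "prior_arf_rhd": (
            PriorHistory.DOCUMENTED_HISTORY
            if recurrent
            else PriorHistory.CONFIRMED_NONE
        ),
        "joint_finding": joint,
        "carditis": carditis,
        "chorea": bool(rng.random() < prev.get("sydenham-chorea", 0.0)),
        "erythema_marginatum": bool(
            rng.random() < prev.get("erythema-marginatum", 0.0)
        ),
        "subcutaneous_nodules": bool(
            rng.random() < prev.get("subcutaneous-nodules", 0.0)
        ),
        "max_temperature": _lab("max_temperature", t.fever_min_high),
        "esr": _lab("esr", t.esr_min_high),
        "crp": _lab("crp", t.crp_min),
        "pr_interval": _lab(
            "pr_interval", lookup_uln(config.uln.pr_interval, age)
        ),
        "aso_titre": _lab("aso_titre", lookup_uln(config.uln.aso_titre, age)),
        "adb_titre": _lab("adb_titre", lookup_uln(config.uln.adb_titre, age)),
        "rising_titres": (
            True if rng.random() < prev.get("rising-titres", 0.0) else None
        ),
        "positive_throat_culture_or_rapid_test": (
            True if rng.random() < prev.get("positive-culture", 0.0) else None
        ),
        "clinician_judgement": None,
    }
    return PatientPresentation(**fields)


def generate_cohort(
    spec: CohortSpec, config: CalculatorConfig | None = None
) -> tuple[list[PatientPresentation], list[str]]:
    """Generate a cohort with known gold labels.

    Each patient is drawn from an independent counter-based substream of
    the seed, so insertion order does not cascade.  The gold label is
    the calculator's own diagnosis perturbed by the discordance model
    (adjacent-category relabelling at the configured rate), emulating an
    expert panel that mostly agrees but occasionally reclassifies a
    near-miss.  Identical ``(spec, seed)`` pairs give identical cohorts.
    """
    try:
        spec = CohortSpec.model_validate(spec)
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(str(exc)) from exc
    cfg = config if config is not None else default_config()
    presentations = [
        _draw_presentation(spec, i, cfg) for i in range(spec.n)
    ]
    gold: list[str] = []
    # dedicated perturbation substream, out of the per-patient index range
    perturb_rng = np.random.default_rng([spec.seed, spec.n, 1])
    rate = spec.discordance_model.rate
    for p in presentations:
        cat = diagnose(p, cfg).category
        if rate > 0 and perturb_rng.random() < rate:
            if cat is Category.NOT_ARF:
                cat = Category.POSSIBLE
            elif cat is Category.DEFINITE:
                cat = Category.PROBABLE
            else:
                step = 1 if perturb_rng.random() < 0.5 else -1
                cat = Category(int(cat) + step)
        gold.append(cat.label)
    return presentations, gold


def load_fixtures() -> dict[str, tuple[PatientPresentation, Category]]:
    """Named clinical presentations with their expected calculator category.

    These reconstruct archetypal suspected-ARF cases from a tertiary-
    hospital validation cohort: a high-risk culture-negative
    monoarthritis with fever, raised CRP and an elevated anti-DNase B
    titre (Definite); the same case with the joint finding read down to
    monoarthralgia (drops below Definite); a high-risk monoarthritis
    with fever and streptococcal evidence whose category turns on the
    clinician's judgement; and an empty low-risk presentation.
    """
    monoarthritis_definite = PatientPresentation(
        age=10,
        indigenous_rural_remote=True,
        prior_arf_rhd=PriorHistory.CONFIRMED_NONE,
        joint_finding=JointFinding.ASEPTIC_MONOARTHRITIS,
        carditis=CarditisStatus.ABSENT,
        max_temperature=38.6,
        crp=40.0,
        adb_titre=800.0,
    )
    monoarthralgia_downgrade = monoarthritis_definite.model_copy(
        update={
            "joint_finding": JointFinding.MONOARTHRALGIA,
            "clinician_judgement": Judgement.UNCERTAIN,
        }
    )
    judgement_case = PatientPresentation(
        age=12,
        indigenous_rural_remote=True,
        prior_arf_rhd=PriorHistory.CONFIRMED_NONE,
        joint_finding=JointFinding.ASEPTIC_MONOARTHRITIS,
        max_temperature=38.4,
        aso_titre=900.0,
    )
    empty_low_risk = PatientPresentation(
        age=9, risk_group_override=RiskLevel.LOW
    )
    return {
        "high-risk-monoarthritis-definite": (
            monoarthritis_definite,
            Category.DEFINITE,
        ),
        "monoarthralgia-downgrade": (
            monoarthralgia_downgrade,
            Category.POSSIBLE,
        ),
        "judgement-yes": (
            judgement_case.model_copy(
                update={"clinician_judgement": Judgement.YES}
            ),
            Category.PROBABLE,
        ),
        "judgement-uncertain": (
            judgement_case.model_copy(
                update={"clinician_judgement": Judgement.UNCERTAIN}
            ),
            Category.POSSIBLE,
        ),
        "judgement-no": (
            judgement_case.model_copy(
                update={"clinician_judgement": Judgement.NO}
            ),
            Category.NOT_ARF,
        ),
        "empty-low-risk": (empty_low_risk, Category.NOT_ARF),
    }


# ---------------------------------------------------------------------------
# Section 6 — input/output (JSON canonical, CSV projection)
# ---------------------------------------------------------------------------

#: Column order of the CSV projection of a patient record.
CSV_COLUMNS: tuple[str, ...] = tuple(PatientPresentation.model_fields)


def patient_record_schema() -> dict:
    """JSON Schema for a single patient record."""
    return PatientPresentation.model_json_schema()


def cohort_spec_schema() -> dict:
    """JSON Schema for a cohort-simulation spec."""
    return CohortSpec.model_json_schema()


def _record_from_csv_row(row: Mapping[str, object]) -> dict:
    record: dict = {}
    bool_fields = {
        "indigenous_rural_remote",
        "chorea",
        "erythema_marginatum",
        "subcutaneous_nodules",
        "rising_titres",
        "positive_throat_culture_or_rapid_test",
    }
    for key, value in row.items():
        if key == "gold_label":
            continue
        if value is None or (isinstance(value, float) and math.isnan(value)):
            continue
        text = str(value).strip()
        if text == "":
            continue
        if key in bool_fields:
            lowered = text.lower()
            if lowered not in {"true", "false"}:
                raise InputError(
                    f"field {key!r}: expected true/false, got {text!r}"
                )
            record[key] = lowered == "true"
        else:
            record[key] = text
    return record


def read_presentations(path: str | Path) -> list[PatientPresentation]:
    """Read patient records from JSON (object or array) or CSV.

    CSV cells left empty mean "not measured"; booleans are spelled
    true/false.  Validation errors carry the record index and field.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        records = [
            _record_from_csv_row(row) for row in frame.to_dict("records")
        ]
    else:
        data = json.loads(path.read_text())
        if isinstance(data, dict):
            data = [data]
        if not isinstance(data, list):
            raise InputError("JSON input must be an object or an array")
        records = [
            {k: v for k, v in rec.items() if k != "gold_label"}
            if isinstance(rec, dict)
            else rec
            for rec in data
        ]
    presentations: list[PatientPresentation] = []
    errors: list[str] = []
    for i, record in enumerate(records):
        try:
            presentations.append(PatientPresentation.model_validate(record))
        except (ValueError, TypeError) as exc:
            errors.append(f"record {i}: {exc}")
    if errors:
        raise InputError("\n".join(errors))
    return presentations


def presentation_to_record(p: PatientPresentation) -> dict:
    """JSON-ready dict with absent fields omitted."""
    return {
        k: v
        for k, v in p.model_dump(mode="json").items()
        if v is not None
    }


def write_presentations(
    presentations: Sequence[PatientPresentation],
    path: str | Path,
    fmt: str = "json",
    gold_labels: Sequence[str] | None = None,
) -> None:
    """Write a cohort as JSON (canonical) or the CSV projection."""
    path = Path(path)
    if fmt == "json":
        payload = [presentation_to_record(p) for p in presentations]
        if gold_labels is not None:
            for record, label in zip(payload, gold_labels):
                record["gold_label"] = label
        path.write_text(json.dumps(payload, indent=2) + "\n")
    elif fmt == "csv":
        rows = []
        for i, p in enumerate(presentations):
            dumped = p.model_dump(mode="json")
            row = {
                k: ("" if v is None else v) for k, v in dumped.items()
            }
            if gold_labels is not None:
                row["gold_label"] = gold_labels[i]
            rows.append(row)
        columns = list(CSV_COLUMNS) + (
            ["gold_label"] if gold_labels is not None else []
        )
        pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    else:
        raise InputError(f"unknown cohort format: {fmt!r}")


def result_to_record(r: DiagnosisResult) -> dict:
    return {
        "category": r.category.label,
        "episode_type": r.episode_type,
        "pathway": list(r.pathway) if r.pathway is not None else None,
        "strep": r.strep,
        "asked_clinician_question": r.asked_clinician_question,
        "advisories": list(r.advisories),
    }


def write_results(
    results: Sequence[DiagnosisResult], path: str | Path, fmt: str = "json"
) -> None:
    path = Path(path)
    records = [result_to_record(r) for r in results]
    if fmt == "json":
        path.write_text(json.dumps(records, indent=2) + "\n")
    elif fmt == "csv":
        rows = [
            {
                **rec,
                "pathway": (
                    "" if rec["pathway"] is None
                    else f"{rec['pathway'][0]}+{rec['pathway'][1]}"
                ),
                "advisories": " | ".join(rec["advisories"]),
            }
            for rec in records
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        raise InputError(f"unknown result format: {fmt!r}")


def read_label_pairs(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a two-column CSV of (gold, predicted) labels."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for column in ("gold", "predicted"):
        if column not in frame.columns:
            raise InputError(
                f"label CSV needs 'gold' and 'predicted' columns, "
                f"got {list(frame.columns)}"
            )
    return list(frame["gold"]), list(frame["predicted"])


def read_confusion_json(path: str | Path) -> ConfusionTable:
    """Read a confusion table from JSON.

    Expected shape: ``{"categories": [...], "counts": [[...], ...]}``
    with rows = gold standard, columns = calculator.
    """
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict) or "categories" not in data or "counts" not in data:
        raise InputError(
            "confusion JSON must contain 'categories' and 'counts'"
        )
    return ConfusionTable(
        categories=tuple(data["categories"]),
        counts=np.asarray(data["counts"], dtype=np.int64),
    )


def write_confusion_json(t: ConfusionTable, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "orientation": "rows=gold-standard, columns=calculator",
                "categories": list(t.categories),
                "counts": t.counts.tolist(),
            },
            indent=2,
        )
        + "\n"
    )
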