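"""Domain types, packaged reference tables, and record validation.

Every downstream stage (indices, risk, biomarkers, synthetic data) consumes
the types defined here.  Reference tables (regulatory maximum limits,
reference doses, consumption scenarios, consumer profiles) ship as a
packaged YAML file and can be overridden with a user file of the same
layout via :func:`load_reference_tables`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

import pandas as pd
import yaml

from .exceptions import ConfigurationError, ValidationError

__all__ = [
    "Tissue",
    "Authority",
    "RfdStatus",
    "TissueConcentration",
    "ConcentrationMeasurement",
    "BiometricRecord",
    "WaterConcentration",
    "RegulatoryLimit",
    "ReferenceDose",
    "ExposureScenario",
    "ConsumerProfile",
    "ReferenceTables",
    "load_reference_tables",
    "dump_reference_tables",
    "validate_records",
    "normalize_element",
    "load_survey_tissue_summary",
    "load_survey_biometrics",
    "load_survey_bcf",
    "load_survey_enzymes",
]

# All IUPAC element symbols; unknown symbols are rejected at parse time.
ELEMENT_SYMBOLS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co Ni "
    "Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb Te I "
    "Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re Os Ir Pt "
    "Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es Fm Md No Lr "
    "Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)


def normalize_element(symbol: str) -> str:
    """Case-normalize a chemical symbol; raise on unknown symbols."""
    s = str(symbol).strip()
    s = s[:1].upper() + s[1:].lower()
    if s not in ELEMENT_SYMBOLS:
        raise ValidationError(f"unknown element symbol: {symbol!r}")
    return s


class Tissue(str, enum.Enum):
    MUSCLE = "muscle"
    LIVER = "liver"

    @classmethod
    def parse(cls, value: "Tissue | str") -> "Tissue":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise ValidationError(f"unknown tissue: {value!r}") from None


class Authority(str, enum.Enum):
    """Regulatory authority issuing a maximum permissible limit."""

    BRAZIL = "Brazil"
    MERCOSUL = "MERCOSUL"
    CHILE = "Chile"
    FAO = "FAO"
    WHO_FAO_CODEX = "WHO/FAO (CODEX)"

    @classmethod
    def parse(cls, value: "Authority | str") -> "Authority":
        if isinstance(value, cls):
            return value
        key = str(value).strip().upper().replace("-", "_").replace("/", "_")
        key = key.replace(" ", "_").replace("(", "").replace(")", "")
        aliases = {
            "BRAZIL": cls.BRAZIL,
            "BRASIL": cls.BRAZIL,
            "MERCOSUL": cls.MERCOSUL,
            "MERCOSUR": cls.MERCOSUL,
            "CHILE": cls.CHILE,
            "FAO": cls.FAO,
            "WHO_FAO": cls.WHO_FAO_CODEX,
            "WHO_FAO_CODEX": cls.WHO_FAO_CODEX,
            "WHO_FAO__CODEX": cls.WHO_FAO_CODEX,
            "CODEX": cls.WHO_FAO_CODEX,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValidationError(f"unknown authority: {value!r}") from None


class RfdStatus(str, enum.Enum):
    ACTIVE = "active"
    REVOKED = "revoked"


def _positive(name: str, value: float) -> float:
    value = float(value)
    if not value > 0 or not math.isfinite(value):
        raise ValidationError(f"{name} must be strictly positive, got {value}")
    return value


def _non_negative(name: str, value: float) -> float:
    value = float(value)
    if value < 0 or not math.isfinite(value):
        raise ValidationError(f"{name} must be non-negative, got {value}")
    return value


@dataclass(frozen=True)
class TissueConcentration:
    """Summary of one element in one species/site/tissue group (mg/kg).

    Non-detects carry ``detected=False`` and no summary statistics; they are
    never coerced to zero.  Invariants that depend on several fields are
    checked by :meth:`violations` (report-based) rather than at construction,
    so that malformed input rows remain representable.
    """

    species: str
    site: str
    tissue: Tissue
    element: str
    mean: Optional[float] = None
    sd: Optional[float] = None
    min: Optional[float] = None
    max: Optional[float] = None
    detection_limit: float = 1e-6
    detected: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissue", Tissue.parse(self.tissue))
        object.__setattr__(self, "element", normalize_element(self.element))
        _positive("detection_limit", self.detection_limit)
        for name in ("mean", "sd", "min", "max"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, float(v))

    def violations(self) -> list[str]:
        """Return human-readable invariant violations (empty when clean)."""
        problems: list[str] = []
        if self.detected:
            if self.mean is None:
                problems.append("detected row has no mean")
            if self.mean is not None and self.mean < 0:
                problems.append("mean < 0")
            if self.sd is not None and self.sd < 0:
                problems.append("sd < 0")
            lo, mu, hi = self.min, self.mean, self.max
            if lo is not None and hi is not None and lo > hi:
                problems.append("min > max")
            if lo is not None and mu is not None and lo > mu:
                problems.append("min > mean")
            if hi is not None and mu is not None and mu > hi:
                problems.append("mean > max")
        else:
            for name in ("mean", "sd", "min", "max"):
                if getattr(self, name) is not None:
                    problems.append(f"non-detect row carries {name}")
        return problems


@dataclass(frozen=True)
class ConcentrationMeasurement:
    """A single acid-digest measurement: instrument reading, extract, mass."""

    instrument_reading: float  # mg/L
    extract_volume: float  # L
    sample_mass: float  # kg

    def __post_init__(self) -> None:
        _non_negative("instrument_reading", self.instrument_reading)
        _positive("extract_volume", self.extract_volume)
        _positive("sample_mass", self.sample_mass)


@dataclass(frozen=True)
class BiometricRecord:
    """Weight (g) and length (cm) of one fish, optionally sexed."""

    weight: float
    length: float
    sex: Optional[str] = None

    def __post_init__(self) -> None:
        _positive("weight", self.weight)
        _positive("length", self.length)


@dataclass(frozen=True)
class WaterConcentration:
    element: str
    site: str
    value: float  # mg/L
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "element", normalize_element(self.element))
        _non_negative("value", self.value)


@dataclass(frozen=True)
class RegulatoryLimit:
    element: str
    authority: Authority
    ml: float  # mg/kg

    def __post_init__(self) -> None:
        object.__setattr__(self, "element", normalize_element(self.element))
        object.__setattr__(self, "authority", Authority.parse(self.authority))
        _positive("ml", self.ml)


@dataclass(frozen=True)
class ReferenceDose:
    element: str
    rfd: float  # mg/kg-bw/day
    source: str = ""
    status: RfdStatus = RfdStatus.ACTIVE

    def __post_init__(self) -> None:
        object.__setattr__(self, "element", normalize_element(self.element))
        object.__setattr__(self, "status", RfdStatus(self.status))
        _positive("rfd", self.rfd)


@dataclass(frozen=True)
class ExposureScenario:
    name: str
    ingestion_rate: float  # g/day
    population: str = ""

    def __post_init__(self) -> None:
        _positive("ingestion_rate", self.ingestion_rate)


@dataclass(frozen=True)
class ConsumerProfile:
    label: str
    body_weight: float  # kg

    def __post_init__(self) -> None:
        _positive("body_weight", self.body_weight)


class ReferenceTables(NamedTuple):
    """Bundle of regulatory limits, RfDs, scenarios, and consumer profiles."""

    limits: tuple[RegulatoryLimit, ...]
    rfds: tuple[ReferenceDose, ...]
    scenarios: tuple[ExposureScenario, ...]
    profiles: tuple[ConsumerProfile, ...]

    def limits_for(self, element: str) -> tuple[RegulatoryLimit, ...]:
        element = normalize_element(element)
        return tuple(l for l in self.limits if l.element == element)

    def ml_for(
        self,
        element: str,
        authority: Optional[Authority | str] = None,
        strictest: bool = False,
    ) -> Optional[RegulatoryLimit]:
        """Select the limit used for RQ.

        Default precedence Brazil > MERCOSUL > Chile > FAO > WHO/FAO picks
        the national limit when one exists, otherwise the single authority
        that regulates the element.  ``strictest`` selects the lowest ML;
        ``authority`` restricts to one authority (returns None if absent).
        """
        candidates = self.limits_for(element)
        if not candidates:
            return None
        if authority is not None:
            authority = Authority.parse(authority)
            for lim in candidates:
                if lim.authority == authority:
                    return lim
            return None
        if strictest:
            return min(candidates, key=lambda l: l.ml)
        order = list(Authority)
        return min(candidates, key=lambda l: order.index(l.authority))

    def rfd_for(self, element: str) -> Optional[ReferenceDose]:
        element = normalize_element(element)
        for r in self.rfds:
            if r.element == element:
                return r
        return None


def _default_config_text() -> str:
    return resources.files("ecotox.data").joinpath("reference_tables.yaml").read_text()


def load_reference_tables(config: str | Path | dict | None = None) -> ReferenceTables:
    """Load reference tables from YAML (path or mapping); defaults when None.

    Raises :class:`ConfigurationError` on duplicate (element, authority)
    limit keys or duplicate RfD/scenario/profile keys, and
    :class:`ValidationError` on non-positive values.
    """
    if config is None:
        raw = yaml.safe_load(_default_config_text())
    elif isinstance(config, dict):
        raw = config
    else:
        text = Path(config).read_text()
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigurationError("reference-table config must be a mapping")

    limits = tuple(RegulatoryLimit(**row) for row in raw.get("limits", []))
    rfds = tuple(ReferenceDose(**row) for row in raw.get("rfds", []))
    scenarios = tuple(ExposureScenario(**row) for row in raw.get("scenarios", []))
    profiles = tuple(ConsumerProfile(**row) for row in raw.get("profiles", []))

    seen: set = set()
    for lim in limits:
        key = (lim.element, lim.authority)
        if key in seen:
            raise ConfigurationError(f"duplicate limit for {key[0]} / {key[1].value}")
        seen.add(key)
    for name, items in (
        ("rfd", [r.element for r in rfds]),
        ("scenario", [s.name for s in scenarios]),
        ("profile", [p.label for p in profiles]),
    ):
        dupes = {k for k in items if items.count(k) > 1}
        if dupes:
            raise ConfigurationError(f"duplicate {name} key(s): {sorted(dupes)}")
    return ReferenceTables(limits, rfds, scenarios, profiles)


def dump_reference_tables(tables: ReferenceTables, path: str | Path | None = None) -> str:
    """Serialize tables back to the YAML config layout (lossless round trip)."""
    doc = {
        "limits": [
            {"element": l.element, "authority": l.authority.value, "ml": l.ml}
            for l in tables.limits
        ],
        "rfds": [
            {"element": r.element, "rfd": r.rfd, "source": r.source, "status": r.status.value}
            for r in tables.rfds
        ],
        "scenarios": [
            {"name": s.name, "ingestion_rate": s.ingestion_rate, "population": s.population}
            for s in tables.scenarios
        ],
        "profiles": [
            {"label": p.label, "body_weight": p.body_weight} for p in tables.profiles
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass(frozen=True)
class ValidationIssue:
    index: int
    reason: str


def validate_records(
    rows: Iterable[TissueConcentration],
) -> tuple[list[TissueConcentration], list[ValidationIssue]]:
    """Split rows into clean records and an issue report.

    Rows violating an invariant are excluded from the clean list and
    reported with their position and reason; clean rows pass through
    unchanged.  Never raises.
    """
    clean: list[TissueConcentration] = []
    issues: list[ValidationIssue] = []
    for i, row in enumerate(rows):
        problems = row.violations()
        if problems:
            issues.extend(ValidationIssue(i, p) for p in problems)
        else:
            clean.append(row)
    return clean, issues


# ---------------------------------------------------------------------------
# Packaged survey summaries (two-site, two-species field dataset) used to
# calibrate the synthetic generator and as worked examples in the docs/tests.

def _data_path(name: str):
    return resources.files("ecotox.data").joinpath(name)


def load_survey_tissue_summary() -> pd.DataFrame:
    """Element summary (mg/kg) per species/site/tissue; blank stats = non-detect."""
    with resources.as_file(_data_path("survey_tissue_summary.csv")) as p:
        return pd.read_csv(p)


def load_survey_biometrics() -> pd.DataFrame:
    with resources.as_file(_data_path("survey_biometrics.csv")) as p:
        return pd.read_csv(p)


def load_survey_bcf() -> pd.DataFrame:
    """Published bioconcentration factors per element/site/tissue."""
    with resources.as_file(_data_path("survey_bcf.csv")) as p:
        return pd.read_csv(p)


def load_survey_enzymes() -> pd.DataFrame:
    """Enzyme activity summaries (U/L) per species/site/enzyme/tissue."""
    with resources.as_file(_data_path("survey_enzymes.csv")) as p:
        return pd.read_csv(p)
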