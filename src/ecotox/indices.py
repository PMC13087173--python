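"""Per-fish and per-element physical indices.

Digest concentration, Fulton condition factor with condition bands, and
bioconcentration factor with the US-EPA accumulation classes.
"""

from __future__ import annotations

import enum
import math

from .data_model import BiometricRecord, ConcentrationMeasurement
from .exceptions import UndefinedRatioError, ValidationError

__all__ = [
    "ConditionClass",
    "BcfClass",
    "digest_concentration",
    "fulton_q",
    "classify_condition",
    "bcf",
    "classify_bcf",
]


class ConditionClass(str, enum.Enum):
    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"


class BcfClass(str, enum.Enum):
    NON_BIOACCUMULATIVE = "non_bioaccumulative"
    BIOACCUMULATIVE = "bioaccumulative"
    HIGH = "high"


def digest_concentration(m: ConcentrationMeasurement) -> float:
    """Tissue concentration in mg/kg from an acid-digest measurement.

    reading (mg/L) x extract volume (L) / digested mass (kg).
    """
    return m.instrument_reading * m.extract_volume / m.sample_mass


def fulton_q(b: BiometricRecord) -> float:
    """Fulton condition factor Q = 100 * W / L^3 (W in g, L in cm).

    The caller supplies whichever length convention the survey recorded
    (total or standard length); Q values are only comparable within one
    convention.
    """
    return 100.0 * b.weight / b.length**3


def classify_condition(q: float) -> ConditionClass:
    """Condition band: poor (Q <= 1), moderate (1 < Q < 1.4), good (Q >= 1.4)."""
    if not math.isfinite(q) or q < 0:
        raise ValidationError(f"condition factor must be finite and >= 0, got {q}")
    if q <= 1.0:
        return ConditionClass.POOR
    if q >= 1.4:
        return ConditionClass.GOOD
    return ConditionClass.MODERATE


def bcf(c_org: float, c_water: float) -> float:
    """Bioconcentration factor: tissue (mg/kg) over water (mg/L).

    Raises :class:`UndefinedRatioError` when the water concentration is
    zero — the ratio is undefined, not infinite.
    """
    if c_org < 0:
        raise ValidationError(f"organism concentration must be >= 0, got {c_org}")
    if c_water <= 0:
        raise UndefinedRatioError(
            f"water concentration must be strictly positive, got {c_water}"
        )
    return c_org / c_water


def classify_bcf(v: float) -> BcfClass:
    """US-EPA accumulation classes; 1000 and 5000 belong to 'bioaccumulative'."""
    if not math.isfinite(v) or v < 0:
        raise ValidationError(f"BCF must be finite and >= 0, got {v}")
    if v < 1000.0:
        return BcfClass.NON_BIOACCUMULATIVE
    if v <= 5000.0:
        return BcfClass.BIOACCUMULATIVE
    return BcfClass.HIGH
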