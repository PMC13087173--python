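"""Site-contrast and association statistics.

Mann-Whitney U with an exact-vs-asymptotic policy (exact enumeration for
small untied samples, tie-corrected normal approximation with continuity
correction otherwise), product-moment correlation, and categorical
strength labels for |r|.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import UndefinedCorrelationError, ValidationError

__all__ = [
    "Alternative",
    "Strength",
    "MannWhitneyResult",
    "mann_whitney",
    "correlate",
    "classify_strength",
    "EXACT_MAX_N",
    "DEFAULT_ALPHA",
]

# Exact enumeration is used when the smaller sample has at most this many
# observations and there are no ties; cheap enough to brute-force verify.
EXACT_MAX_N = 8
DEFAULT_ALPHA = 0.05


class Alternative(str, enum.Enum):
    TWO_SIDED = "two-sided"
    LESS = "less"
    GREATER = "greater"


class Strength(str, enum.Enum):
    WEAK = "weak"
    MODERATE = "moderate"
    STRONG = "strong"


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of the first sample (midrank ties)
    p: float
    method: str  # "exact" or "asymptotic"
    alternative: Alternative

    def significant(self, alpha: float = DEFAULT_ALPHA) -> bool:
        return self.p < alpha


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: Alternative | str = Alternative.TWO_SIDED,
) -> MannWhitneyResult:
    """Mann-Whitney U test for two independent samples.

    Exact p by enumeration when min(n_x, n_y) <= EXACT_MAX_N and the pooled
    sample has no ties; otherwise the normal approximation with tie and
    continuity corrections.  U_x + U_y = n_x * n_y always holds.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    alternative = Alternative(alternative)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    exact_ok = min(x.size, y.size) <= EXACT_MAX_N and not has_ties
    method = "exact" if exact_ok else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative.value, method=method, use_continuity=True
    )
    p = float(min(res.pvalue, 1.0))
    return MannWhitneyResult(float(res.statistic), p, method, alternative)


def correlate(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation r in [-1, 1].

    Requires equal lengths >= 3 and non-zero variance in each sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("samples must have equal length")
    if x.size < 3:
        raise ValidationError("correlation requires at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    return max(-1.0, min(1.0, r))


def classify_strength(r: float) -> Strength:
    """Strength label for |r|: weak < 0.40 <= moderate < 0.70 <= strong.

    The published anchor bands leave gaps; this closes them downward so the
    three labels partition [0, 1].
    """
    a = abs(r)
    if a > 1.0:
        raise ValidationError(f"|r| must be <= 1, got {r}")
    if a < 0.40:
        return Strength.WEAK
    if a < 0.70:
        return Strength.MODERATE
    return Strength.STRONG
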