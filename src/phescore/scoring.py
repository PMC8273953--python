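"""PHES component scoring: deficit Z-scores, banded points, total and cut-off.

Each raw result is compared with its age/education-matched expectation and
expressed as a *deficit Z*: the number of residual standard deviations by
which performance is worse than expected (positive = worse, for every test,
after reversing the sign for the points-scored DST).  The deficit Z is banded
into component points:

    deficit_z <= 1          ->  0      (within +/- 1 SD of the norm)
    1 < deficit_z <= 2      -> -1
    2 < deficit_z <= 3      -> -2
    deficit_z > 3           -> -3
    deficit_z < -1          -> +1      (better than 1 SD above the norm)

Band boundaries belong to the less pathological band; the +1 bonus requires
performance strictly better than 1 SD.  PHES is the integer sum of the five
component points, bounded in [-15, +5]; scores below the population cut-off
(mean - 2 SD, floored to an integer) flag minimal hepatic encephalopathy.
"""

from __future__ import annotations

import math

from .models import (
    Direction,
    MheRule,
    NormativeModel,
    ComponentScore,
    PhesResult,
    RawBattery,
    ScoringError,
    Subject,
    Test,
    TestNorm,
)

__all__ = [
    "ltt_composite",
    "expected_value",
    "deficit_z",
    "band_points",
    "score_battery",
    "derive_cutoff",
    "classify_mhe",
    "PHES_MIN",
    "PHES_MAX",
]

PHES_MIN = -15
PHES_MAX = 5


def ltt_composite(ltt_time: float, ltt_errors: float) -> float:
    """Error-adjusted line-tracing score ``(1 + errors/100) * time`` (seconds)."""
    if not ltt_time > 0:
        raise ValueError(f"ltt_time must be > 0, got {ltt_time}")
    if ltt_errors < 0:
        raise ValueError(f"ltt_errors must be >= 0, got {ltt_errors}")
    return (1.0 + ltt_errors / 100.0) * ltt_time


def expected_value(norm: TestNorm, age: float, education: float) -> float:
    """Norm-predicted raw score: intercept + age_coef*age + edu_coef*education."""
    return norm.intercept + norm.age_coef * age + norm.edu_coef * education


def deficit_z(
    observed: float, expected: float, residual_sd: float, direction: Direction
) -> float:
    """Standardised distance from the norm; positive always means worse."""
    if not residual_sd > 0:
        raise ValueError(f"residual_sd must be > 0, got {residual_sd}")
    z = (observed - expected) / residual_sd
    return z if Direction(direction) is Direction.HIGHER_IS_WORSE else -z


def band_points(z: float) -> int:
    """Banded component points for a deficit Z (step function onto {-3..+1})."""
    if not math.isfinite(z):
        raise ValueError(f"deficit_z must be finite, got {z}")
    if z < -1:
        return 1
    if z <= 1:
        return 0
    if z <= 2:
        return -1
    if z <= 3:
        return -2
    return -3


def score_battery(
    subject: Subject,
    battery: RawBattery,
    model: NormativeModel,
    rule: MheRule = MheRule.STRICT_LESS,
) -> PhesResult:
    """Score a complete battery against ``model`` and classify MHE.

    Raises :class:`ScoringError` naming the test if any raw result is missing.
    """
    components = []
    for test in Test:
        observed = battery.result(test)
        if observed is None:
            raise ScoringError(f"subject {subject.id!r}: missing result for {test.value}")
        norm = model.norms[test]
        exp = expected_value(norm, subject.age, subject.education)
        z = deficit_z(observed, exp, norm.residual_sd, norm.direction)
        components.append(
            ComponentScore(test=test, observed=observed, expected=exp, deficit_z=z,
                           points=band_points(z))
        )
    phes = sum(c.points for c in components)
    return PhesResult(
        components=tuple(components),
        phes=phes,
        mhe=classify_mhe(phes, model.cutoff, rule),
        cutoff_used=model.cutoff,
    )


def derive_cutoff(phes_mean: float, phes_sd: float) -> int:
    """Population cut-off: mean - 2 SD, floored to the nearest integer.

    PHES is integer-valued, so the threshold is conservative: e.g.
    (-0.08, 1.28) -> floor(-2.64) = -3.
    """
    if not phes_sd > 0:
        raise ValueError(f"phes_sd must be > 0, got {phes_sd}")
    return math.floor(phes_mean - 2.0 * phes_sd)


def classify_mhe(phes: int, cutoff: int, rule: MheRule = MheRule.STRICT_LESS) -> bool:
    """MHE flag: PHES strictly below the cut-off (or at-or-below, if configured)."""
    rule = MheRule(rule)
    return phes < cutoff if rule is MheRule.STRICT_LESS else phes <= cutoff
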