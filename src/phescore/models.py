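"""Domain types for the PHES normative-scoring pipeline.

The battery comprises five paper-and-pencil psychometric tests: the number
connection tests A and B (NCT-A, NCT-B), the serial dotting test (SDT), the
line tracing test (LTT) and the digit symbol test (DST).  All but the DST are
timed (seconds; more time = worse performance); the DST is scored in points
within a fixed 90 s window (more points = better performance).  The LTT enters
scoring as the error-adjusted composite ``(1 + errors/100) * time``.

A :class:`NormativeModel` bundles one linear age/education norm per test
together with the population PHES mean/SD and the integer screening cut-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional


class PhesError(Exception):
    """Base class for all pipeline errors."""


class FitError(PhesError):
    """Normative regression could not be fitted (rank deficiency, small n)."""


class ValidationError(PhesError):
    """A model, file or configuration violated its schema."""


class ScoringError(PhesError):
    """A battery could not be scored (e.g. a missing test result)."""


class ParseError(PhesError):
    """A subject file row could not be parsed."""


class Test(str, Enum):
    """The five battery tests."""

    NCT_A = "NCT_A"
    NCT_B = "NCT_B"
    SDT = "SDT"
    LTT = "LTT"
    DST = "DST"


Test.__test__ = False  # not a pytest collection target

#: Tests whose raw result is a completion time in seconds.
TIMED_TESTS = (Test.NCT_A, Test.NCT_B, Test.SDT, Test.LTT)


class Direction(str, Enum):
    HIGHER_IS_WORSE = "higher_is_worse"
    HIGHER_IS_BETTER = "higher_is_better"


def expected_direction(test: Test) -> Direction:
    """Scoring direction implied by the test identity (DST is reversed)."""
    return Direction.HIGHER_IS_BETTER if test is Test.DST else Direction.HIGHER_IS_WORSE


class Group(str, Enum):
    VOLUNTEER = "volunteer"
    CIRRHOTIC = "cirrhotic"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class MheRule(str, Enum):
    """Classification rule at the cut-off: strictly below (default) or at-or-below."""

    STRICT_LESS = "strict_less"
    LESS_EQUAL = "less_equal"


#: Registered clinical covariates and their admissible values.
CLINICAL_COVARIATES: dict[str, frozenset[str]] = {
    "child_pugh": frozenset({"A", "B", "C"}),
    "ascites": frozenset({"yes", "no"}),
    "jaundice": frozenset({"yes", "no"}),
    "gi_bleed": frozenset({"yes", "no"}),
}


@dataclass
class Subject:
    """One participant: demographics, group label and optional clinical covariates."""

    id: str
    age: float
    education: float
    group: Group
    sex: Sex = Sex.UNKNOWN
    clinical: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        self.sex = Sex(self.sex)
        if not self.age > 0:
            raise ValidationError(f"subject {self.id!r}: age must be > 0, got {self.age}")
        if self.education < 0:
            raise ValidationError(
                f"subject {self.id!r}: education must be >= 0, got {self.education}"
            )
        for key, value in self.clinical.items():
            allowed = CLINICAL_COVARIATES.get(key)
            if allowed is None:
                raise ValidationError(f"subject {self.id!r}: unknown covariate {key!r}")
            if value not in allowed:
                raise ValidationError(
                    f"subject {self.id!r}: covariate {key}={value!r} not in {sorted(allowed)}"
                )


@dataclass
class RawBattery:
    """Raw test results for one subject.

    Times are in seconds; ``dst`` is a point count; ``ltt_errors`` is the LTT
    error score.  Any field may be ``None`` (missing); validation applies only
    to present values.
    """

    nct_a: Optional[float] = None
    nct_b: Optional[float] = None
    sdt: Optional[float] = None
    ltt_time: Optional[float] = None
    ltt_errors: Optional[float] = None
    dst: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("nct_a", "nct_b", "sdt", "ltt_time"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValidationError(f"{name} must be > 0, got {v}")
        if self.ltt_errors is not None and self.ltt_errors < 0:
            raise ValidationError(f"ltt_errors must be >= 0, got {self.ltt_errors}")
        if self.dst is not None and self.dst < 0:
            raise ValidationError(f"dst must be >= 0, got {self.dst}")

    def result(self, test: Test) -> Optional[float]:
        """Observed value entering the norm for ``test`` (LTT -> composite)."""
        if test is Test.LTT:
            if self.ltt_time is None or self.ltt_errors is None:
                return None
            from .scoring import ltt_composite

            return ltt_composite(self.ltt_time, self.ltt_errors)
        return {
            Test.NCT_A: self.nct_a,
            Test.NCT_B: self.nct_b,
            Test.SDT: self.sdt,
            Test.DST: self.dst,
        }[test]


@dataclass(frozen=True)
class TestNorm:
    """Linear age/education norm for one test: expected = intercept + a*age + e*edu."""

    test: Test
    intercept: float
    age_coef: float
    edu_coef: float
    residual_sd: float
    direction: Direction

    def __post_init__(self) -> None:
        object.__setattr__(self, "test", Test(self.test))
        object.__setattr__(self, "direction", Direction(self.direction))
        if not self.residual_sd > 0:
            raise ValidationError(
                f"{self.test.value}: residual_sd must be > 0, got {self.residual_sd}"
            )
        if self.direction is not expected_direction(self.test):
            raise ValidationError(
                f"{self.test.value}: direction {self.direction.value!r} inconsistent "
                f"with test identity (only DST is higher_is_better)"
            )


@dataclass
class NormativeModel:
    """A complete set of norms plus PHES population statistics and cut-off."""

    name: str
    norms: Mapping[Test, TestNorm]
    phes_mean: float
    phes_sd: float
    cutoff: int
    provenance: str = ""

    def __post_init__(self) -> None:
        self.norms = {Test(t): n for t, n in self.norms.items()}
        missing = [t.value for t in Test if t not in self.norms]
        if missing:
            raise ValidationError(f"model {self.name!r}: missing norms for {missing}")
        for t, norm in self.norms.items():
            if norm.test is not t:
                raise ValidationError(
                    f"model {self.name!r}: norm keyed {t.value} is for {norm.test.value}"
                )
        if not self.phes_sd > 0:
            raise ValidationError(f"model {self.name!r}: phes_sd must be > 0")
        if self.cutoff != int(self.cutoff) or self.cutoff > 0:
            raise ValidationError(
                f"model {self.name!r}: cutoff must be an integer <= 0, got {self.cutoff}"
            )
        self.cutoff = int(self.cutoff)


@dataclass(frozen=True)
class ComponentScore:
    """One test's contribution to PHES."""

    test: Test
    observed: float
    expected: float
    deficit_z: float
    points: int


@dataclass(frozen=True)
class PhesResult:
    """Scored battery: five components, total PHES and the MHE flag."""

    components: tuple[ComponentScore, ...]
    phes: int
    mhe: bool
    cutoff_used: int

    def component(self, test: Test) -> ComponentScore:
        for c in self.components:
            if c.test is test:
                return c
        raise KeyError(test)


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure x outcome contingency counts for odds-ratio analysis."""

    exposed_case: int
    exposed_noncase: int
    unexposed_case: int
    unexposed_noncase: int

    def __post_init__(self) -> None:
        for name in (
            "exposed_case",
            "exposed_noncase",
            "unexposed_case",
            "unexposed_noncase",
        ):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValidationError(f"{name} must be a non-negative count, got {v}")
        if self.total == 0:
            raise ValidationError("contingency table is empty")

    @property
    def total(self) -> int:
        return (
            self.exposed_case
            + self.exposed_noncase
            + self.unexposed_case
            + self.unexposed_noncase
        )

    @property
    def has_zero_cell(self) -> bool:
        return 0 in (
            self.exposed_case,
            self.exposed_noncase,
            self.unexposed_case,
            self.unexposed_noncase,
        )


class StatisticKind(str, Enum):
    MEAN_T = "mean_t"
    MEDIAN_MANNWHITNEY = "median_mannwhitney"
    PROPORTION_FISHER_CHI2 = "proportion_fisher_chi2"
    ODDS_RATIO = "odds_ratio"


@dataclass(frozen=True)
class GroupComparison:
    """One MHE vs no-MHE contrast with its complete-case denominators."""

    variable: str
    n_mhe: int
    n_nomhe: int
    statistic_kind: Optional[StatisticKind]
    estimate: object
    p_value: float
    computable: bool = True
    note: str = ""

    def __post_init__(self) -> None:
        if self.computable and not (0 <= self.p_value <= 1 or math.isnan(self.p_value)):
            raise ValidationError(f"{self.variable}: p value {self.p_value} outside [0, 1]")
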