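"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

Volunteers: age drawn from weighted bands (default: the standardisation
sample's band counts 29/31/19/17/6 over 20-72 years), education a truncated
Gaussian per band, and each test result generated as the normative linear
predictor plus Gaussian residual noise.  Cirrhotic patients are the same
measurement model shifted towards worse performance by a configurable number
of residual SDs per test, with clinical covariates (Child-Pugh class,
ascites, jaundice, prior GI haemorrhage) drawn at configurable prevalences
and missingness.

Determinism: identical (n, model, config, seed) always yields an identical
cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
from scipy import stats

from .models import (
    Group,
    NormativeModel,
    RawBattery,
    Sex,
    Subject,
    Test,
    ValidationError,
    Direction,
)

__all__ = [
    "AgeBand",
    "DemographyConfig",
    "CirrhosisConfig",
    "gen_volunteers",
    "gen_cirrhotics",
]

#: Floor for generated completion times (s); Gaussian tails cannot go below.
MIN_TIME_S = 10.0
#: Mean LTT error count used when decomposing the composite into (time, errors).
LTT_ERROR_MEAN = 5.0


@dataclass(frozen=True)
class AgeBand:
    """One age band with its sampling weight and education distribution."""

    low: float
    high: float
    weight: float
    edu_mean: float
    edu_sd: float
    edu_min: float
    edu_max: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValidationError(f"band [{self.low}, {self.high}) is empty")
        if self.weight < 0:
            raise ValidationError("band weight must be >= 0")
        if self.edu_min < 0 or self.edu_min > self.edu_max:
            raise ValidationError("education bounds must satisfy 0 <= min <= max")
        if not self.edu_sd > 0:
            raise ValidationError("education SD must be > 0")


# Default demography: the standardisation sample's age-band counts (n = 102)
# with each band's education mean +/- SD (range).
_DEFAULT_BANDS = (
    AgeBand(20, 30, 29 / 102, 12.0, 4.0, 7.0, 21.0),
    AgeBand(30, 40, 31 / 102, 13.0, 5.0, 4.0, 22.0),
    AgeBand(40, 50, 19 / 102, 11.0, 3.0, 5.0, 16.0),
    AgeBand(50, 60, 17 / 102, 10.0, 4.0, 4.0, 15.0),
    AgeBand(60, 72, 6 / 102, 6.0, 2.0, 4.0, 6.0),
)


@dataclass(frozen=True)
class DemographyConfig:
    """Age-band weights, per-band education distributions, sex ratio."""

    bands: tuple[AgeBand, ...] = _DEFAULT_BANDS
    sex_ratio_male: float = 54 / 102

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValidationError("at least one age band is required")
        total = sum(b.weight for b in self.bands)
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValidationError(f"band weights must sum to 1, got {total}")
        ordered = sorted(self.bands, key=lambda b: b.low)
        for left, right in zip(ordered, ordered[1:]):
            if right.low < left.high:
                raise ValidationError(
                    f"bands [{left.low},{left.high}) and [{right.low},{right.high}) overlap"
                )
        if not 0 <= self.sex_ratio_male <= 1:
            raise ValidationError("sex_ratio_male must be in [0, 1]")


# Default covariate prevalences: the cirrhotic cohort's marginals
# (ascites 34%, jaundice 18%, prior GI bleed 16%; Child-Pugh A/B/C
# 60.5/27.9/11.6% among the 43/50 with a recorded class).
_DEFAULT_PREVALENCES: Mapping[str, object] = {
    "ascites": 0.34,
    "jaundice": 0.18,
    "gi_bleed": 0.16,
    "child_pugh": {"A": 0.605, "B": 0.279, "C": 0.116},
}
_DEFAULT_MISSINGNESS: Mapping[str, float] = {
    "ascites": 0.0,
    "jaundice": 0.0,
    "gi_bleed": 0.0,
    "child_pugh": 0.14,  # 7 of 50 without a recorded class
}


@dataclass(frozen=True)
class CirrhosisConfig:
    """Disease model for the simulated cirrhotic arm.

    ``deficit_shift`` moves every test (or each test, if a map) towards worse
    performance by that many residual SDs; demography is the volunteer
    demography offset in age and education.
    """

    deficit_shift: Union[float, Mapping[Test, float]] = 2.0
    age_offset: float = 11.0
    education_offset: float = -2.0
    covariate_prevalences: Mapping[str, object] = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCES)
    )
    covariate_missingness: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MISSINGNESS)
    )

    def __post_init__(self) -> None:
        for t, s in self._shift_map().items():
            if s < 0:
                raise ValidationError(f"deficit_shift for {t.value} must be >= 0, got {s}")
        for name, p in self.covariate_prevalences.items():
            values = p.values() if isinstance(p, Mapping) else (p,)
            for v in values:
                if not 0 <= float(v) <= 1:
                    raise ValidationError(f"prevalence for {name!r} outside [0, 1]: {v}")
        for name, m in self.covariate_missingness.items():
            if not 0 <= float(m) <= 1:
                raise ValidationError(f"missingness for {name!r} outside [0, 1]: {m}")

    def _shift_map(self) -> dict[Test, float]:
        if isinstance(self.deficit_shift, Mapping):
            return {Test(t): float(s) for t, s in self.deficit_shift.items()}
        return {t: float(self.deficit_shift) for t in Test}


def _draw_demographics(
    n: int, demo: DemographyConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    weights = np.array([b.weight for b in demo.bands])
    weights = weights / weights.sum()
    band_idx = rng.choice(len(demo.bands), size=n, p=weights)
    ages = np.empty(n)
    edus = np.empty(n)
    for bi, b in enumerate(demo.bands):
        mask = band_idx == bi
        k = int(mask.sum())
        if k == 0:
            continue
        ages[mask] = rng.uniform(b.low, b.high, size=k)
        lo = (b.edu_min - b.edu_mean) / b.edu_sd
        hi = (b.edu_max - b.edu_mean) / b.edu_sd
        edus[mask] = stats.truncnorm.rvs(
            lo, hi, loc=b.edu_mean, scale=b.edu_sd, size=k, random_state=rng
        )
    male = rng.random(n) < demo.sex_ratio_male
    return ages, edus, male


def _draw_batteries(
    ages: np.ndarray,
    edus: np.ndarray,
    model: NormativeModel,
    shift: Mapping[Test, float],
    rng: np.random.Generator,
) -> list[RawBattery]:
    """Expected value + residual noise per test, shifted towards deficit."""
    n = len(ages)
    raw: dict[Test, np.ndarray] = {}
    for test in Test:
        norm = model.norms[test]
        worse = 1.0 if norm.direction is Direction.HIGHER_IS_WORSE else -1.0
        mu = (
            norm.intercept
            + norm.age_coef * ages
            + norm.edu_coef * edus
            + worse * shift[test] * norm.residual_sd
        )
        raw[test] = mu + rng.normal(0.0, norm.residual_sd, size=n)
    # Floors keep Gaussian tails physical: times >= MIN_TIME_S, DST >= 0 points.
    dst = np.maximum(0, np.rint(raw[Test.DST])).astype(int)
    composite = np.maximum(MIN_TIME_S, raw[Test.LTT])
    # Split the LTT composite into (time, errors): errors are a Poisson count,
    # time back-solved so the composite is exactly the drawn value.
    errors = rng.poisson(LTT_ERROR_MEAN, size=n)
    ltt_time = composite / (1.0 + errors / 100.0)
    nct_a = np.maximum(MIN_TIME_S, raw[Test.NCT_A])
    nct_b = np.maximum(MIN_TIME_S, raw[Test.NCT_B])
    sdt = np.maximum(MIN_TIME_S, raw[Test.SDT])
    return [
        RawBattery(
            nct_a=float(nct_a[i]),
            nct_b=float(nct_b[i]),
            sdt=float(sdt[i]),
            ltt_time=float(ltt_time[i]),
            ltt_errors=int(errors[i]),
            dst=int(dst[i]),
        )
        for i in range(n)
    ]


def _draw_covariates(
    cfg: CirrhosisConfig, rng: np.random.Generator
) -> dict[str, str]:
    clinical: dict[str, str] = {}
    for name, p in cfg.covariate_prevalences.items():
        if rng.random() < float(cfg.covariate_missingness.get(name, 0.0)):
            continue
        if isinstance(p, Mapping):
            levels = sorted(p)
            probs = np.array([float(p[k]) for k in levels])
            probs = probs / probs.sum()
            clinical[name] = str(rng.choice(levels, p=probs))
        else:
            clinical[name] = "yes" if rng.random() < float(p) else "no"
    return clinical


def gen_volunteers(
    n: int,
    model: Optional[NormativeModel] = None,
    demo: Optional[DemographyConfig] = None,
    seed: int = 0,
) -> list[tuple[Subject, RawBattery]]:
    """Generate ``n`` healthy volunteers under the normative measurement model."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    from .norms import builtin_cameroon_norms

    model = model or builtin_cameroon_norms()
    demo = demo or DemographyConfig()
    rng = np.random.default_rng(seed)
    ages, edus, male = _draw_demographics(n, demo, rng)
    batteries = _draw_batteries(ages, edus, model, {t: 0.0 for t in Test}, rng)
    return [
        (
            Subject(
                id=f"V{i:05d}",
                age=float(ages[i]),
                education=float(edus[i]),
                group=Group.VOLUNTEER,
                sex=Sex.MALE if male[i] else Sex.FEMALE,
            ),
            batteries[i],
        )
        for i in range(n)
    ]


def gen_cirrhotics(
    n: int,
    model: Optional[NormativeModel] = None,
    cfg: Optional[CirrhosisConfig] = None,
    demo: Optional[DemographyConfig] = None,
    seed: int = 0,
) -> list[tuple[Subject, RawBattery]]:
    """Generate ``n`` cirrhotic patients: shifted performance plus covariates."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    from .norms import builtin_cameroon_norms

    model = model or builtin_cameroon_norms()
    cfg = cfg or CirrhosisConfig()
    demo = demo or DemographyConfig()
    rng = np.random.default_rng(seed)
    ages, edus, male = _draw_demographics(n, demo, rng)
    ages = ages + cfg.age_offset
    edus = np.maximum(0.0, edus + cfg.education_offset)
    batteries = _draw_batteries(ages, edus, model, cfg._shift_map(), rng)
    return [
        (
            Subject(
                id=f"C{i:05d}",
                age=float(ages[i]),
                education=float(edus[i]),
                group=Group.CIRRHOTIC,
                sex=Sex.MALE if male[i] else Sex.FEMALE,
                clinical=_draw_covariates(cfg, rng),
            ),
            batteries[i],
        )
        for i in range(n)
    ]
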