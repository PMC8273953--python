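"""Normative regression models: fitting, built-in constants and JSON files.

Each test's expected raw score is a linear function of age and years of
education, estimated by ordinary least squares on a healthy-volunteer sample;
the residual standard deviation (unbiased, denominator n - 3) standardises
observed scores into deficit Z units.  The built-in ``cameroon-2021`` model
carries the published Cameroonian constants; alternate normative populations
load from JSON files with the same schema.
"""

from __future__ import annotations

import json
import math
import os
from typing import IO, Iterable, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .models import (
    Direction,
    FitError,
    Group,
    NormativeModel,
    PhesResult,
    RawBattery,
    Subject,
    Test,
    TestNorm,
    ValidationError,
    expected_direction,
)
from .scoring import derive_cutoff, score_battery

__all__ = [
    "fit_test_model",
    "fit_norms",
    "builtin_cameroon_norms",
    "correlate",
    "save_norms",
    "load_norms",
]

MIN_FIT_N = 10

# Published Cameroonian constants: per-test (intercept, age_coef, edu_coef,
# residual SD), volunteer PHES mean/SD and the screening cut-off.
_CAMEROON_TABLE = {
    Test.NCT_A: (125.62, 0.3, -4.47, 11.69),
    Test.NCT_B: (159.82, 1.39, -7.96, 24.65),
    Test.SDT: (78.89, 0.35, -1.6, 9.39),
    Test.LTT: (150.02, 0.11, -3.82, 15.10),
    Test.DST: (23.40, -0.20, 1.63, 3.24),
}
_CAMEROON_PHES_MEAN = -0.08
_CAMEROON_PHES_SD = 1.28
_CAMEROON_CUTOFF = -3


def builtin_cameroon_norms() -> NormativeModel:
    """The built-in Cameroonian normative model (ages 20-72, education >= 4 y)."""
    norms = {
        test: TestNorm(
            test=test,
            intercept=b0,
            age_coef=ba,
            edu_coef=be,
            residual_sd=sd,
            direction=expected_direction(test),
        )
        for test, (b0, ba, be, sd) in _CAMEROON_TABLE.items()
    }
    return NormativeModel(
        name="cameroon-2021",
        norms=norms,
        phes_mean=_CAMEROON_PHES_MEAN,
        phes_sd=_CAMEROON_PHES_SD,
        cutoff=_CAMEROON_CUTOFF,
        provenance="Cameroonian healthy-volunteer standardisation sample (n = 102)",
    )


def _volunteer_design(
    sample: Iterable[tuple[Subject, RawBattery]], test: Test
) -> tuple[np.ndarray, np.ndarray]:
    """Per-test complete-case design: volunteers with a non-missing result."""
    ages, edus, ys = [], [], []
    for subject, battery in sample:
        if subject.group is not Group.VOLUNTEER:
            continue
        y = battery.result(test)
        if y is None:
            continue
        ages.append(subject.age)
        edus.append(subject.education)
        ys.append(float(y))
    X = np.column_stack([np.asarray(ages, float), np.asarray(edus, float)]) \
        if ys else np.empty((0, 2))
    return X, np.asarray(ys, float)


def fit_test_model(sample: Iterable[tuple[Subject, RawBattery]], test: Test) -> TestNorm:
    """OLS fit of one test's raw result on (1, age, education).

    The LTT is fitted on its error-adjusted composite, not the raw time.
    Residual SD uses the unbiased denominator n - 3.  Raises
    :class:`FitError` for n < 10 or a rank-deficient design (naming the
    collinear predictor).
    """
    test = Test(test)
    X, y = _volunteer_design(sample, test)
    n = len(y)
    if n < MIN_FIT_N:
        raise FitError(
            f"{test.value}: need >= {MIN_FIT_N} volunteers with a result, got {n}"
        )
    for j, name in enumerate(("age", "education")):
        if np.ptp(X[:, j]) == 0:
            raise FitError(f"{test.value}: predictor {name!r} is constant (rank-deficient design)")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < 3:
        raise FitError(f"{test.value}: age and education are collinear (rank-deficient design)")
    fit = sm.OLS(y, design).fit()
    resid_sd = math.sqrt(float(fit.ssr) / (n - 3))
    if resid_sd == 0.0:
        resid_sd = float(np.finfo(float).tiny)  # exact data; keep the SD invariant positive
    return TestNorm(
        test=test,
        intercept=float(fit.params[0]),
        age_coef=float(fit.params[1]),
        edu_coef=float(fit.params[2]),
        residual_sd=resid_sd,
        direction=expected_direction(test),
    )


def fit_norms(
    sample: list[tuple[Subject, RawBattery]],
    name: str = "fitted",
    provenance: str = "",
) -> NormativeModel:
    """Fit all five test norms, then calibrate the PHES cut-off on the sample.

    The fitted norms are applied back to the fitting sample; the sample's
    mean and SD of PHES give the population statistics, and the cut-off is
    mean - 2 SD floored to an integer.
    """
    norms = {test: fit_test_model(sample, test) for test in Test}
    provisional = NormativeModel(
        name=name, norms=norms, phes_mean=0.0, phes_sd=1.0, cutoff=0,
        provenance=provenance,
    )
    phes = [
        score_battery(subj, batt, provisional).phes
        for subj, batt in sample
        if subj.group is Group.VOLUNTEER
        and all(batt.result(t) is not None for t in Test)
    ]
    if len(phes) < 2:
        raise FitError("need >= 2 complete volunteer batteries to calibrate the cut-off")
    mean = float(np.mean(phes))
    sd = float(np.std(phes, ddof=1))
    if sd == 0.0:
        raise FitError("zero variance in sample PHES; cannot calibrate the cut-off")
    return NormativeModel(
        name=name, norms=norms, phes_mean=mean, phes_sd=sd,
        cutoff=derive_cutoff(mean, sd), provenance=provenance,
    )


def _corr_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, bool]:
    """(pearson_r, pearson_p, spearman_r, spearman_p, defined)."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan, math.nan, math.nan, False
    pr, pp = stats.pearsonr(x, y)
    sr, sp = stats.spearmanr(x, y)
    return float(pr), float(pp), float(sr), float(sp), True


def correlate(
    sample: list[tuple[Subject, RawBattery, PhesResult]]
) -> pd.DataFrame:
    """Correlations of each raw test result, and PHES, with age and education.

    Returns a tidy frame with columns ``measure, predictor, n, pearson_r,
    pearson_p, spearman_r, spearman_p, defined``.  Signs follow the raw
    results (not deficit Z).  A zero-variance column yields ``defined=False``
    for its cells rather than an error.
    """
    complete = [
        (s, b, r)
        for s, b, r in sample
        if all(b.result(t) is not None for t in Test)
    ]
    if len(complete) < 3:
        raise ValueError(f"need >= 3 complete records, got {len(complete)}")
    age = np.array([s.age for s, _, _ in complete], float)
    edu = np.array([s.education for s, _, _ in complete], float)
    columns: dict[str, np.ndarray] = {
        t.value: np.array([b.result(t) for _, b, _ in complete], float) for t in Test
    }
    columns["PHES"] = np.array([r.phes for _, _, r in complete], float)
    rows = []
    for measure, values in columns.items():
        for pname, pred in (("age", age), ("education", edu)):
            pr, pp, sr, sp, ok = _corr_pair(pred, values)
            rows.append(
                dict(measure=measure, predictor=pname, n=len(values),
                     pearson_r=pr, pearson_p=pp, spearman_r=sr, spearman_p=sp,
                     defined=ok)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Normative-model JSON files

_NORM_FIELDS = ("intercept", "age_coef", "edu_coef", "residual_sd", "direction")


def _model_to_dict(model: NormativeModel) -> dict:
    return {
        "name": model.name,
        "provenance": model.provenance,
        "phes_mean": model.phes_mean,
        "phes_sd": model.phes_sd,
        "cutoff": model.cutoff,
        "norms": {
            t.value: {
                "intercept": norm.intercept,
                "age_coef": norm.age_coef,
                "edu_coef": norm.edu_coef,
                "residual_sd": norm.residual_sd,
                "direction": norm.direction.value,
            }
            for t, norm in model.norms.items()
        },
    }


def save_norms(model: NormativeModel, destination: Union[str, os.PathLike, IO[str]]) -> None:
    """Write a normative model to JSON (round-trips through :func:`load_norms`)."""
    payload = _model_to_dict(model)
    if hasattr(destination, "write"):
        json.dump(payload, destination, indent=2)
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def load_norms(source: Union[str, os.PathLike, IO[str]]) -> NormativeModel:
    """Read a normative model from JSON, validating the schema field by field."""
    if hasattr(source, "read"):
        data = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            data = json.load(fh)
    if not isinstance(data, dict):
        raise ValidationError("norms file: top level must be a JSON object")
    for key in ("name", "phes_mean", "phes_sd", "cutoff", "norms"):
        if key not in data:
            raise ValidationError(f"norms file: missing field {key!r}")
    raw_norms = data["norms"]
    if not isinstance(raw_norms, dict):
        raise ValidationError("norms file: 'norms' must be an object keyed by test")
    known = {t.value for t in Test}
    for key in raw_norms:
        if key not in known:
            raise ValidationError(f"norms file: unknown test name {key!r}")
    for t in Test:
        if t.value not in raw_norms:
            raise ValidationError(f"norms file: missing test entry {t.value!r}")
    norms = {}
    for t in Test:
        entry = raw_norms[t.value]
        for f in _NORM_FIELDS:
            if f not in entry:
                raise ValidationError(f"norms file: {t.value} entry missing {f!r}")
        if not float(entry["residual_sd"]) > 0:
            raise ValidationError(
                f"norms file: {t.value} residual_sd must be > 0, got {entry['residual_sd']}"
            )
        try:
            direction = Direction(entry["direction"])
        except ValueError as exc:
            raise ValidationError(
                f"norms file: {t.value} direction {entry['direction']!r} invalid"
            ) from exc
        norms[t] = TestNorm(
            test=t,
            intercept=float(entry["intercept"]),
            age_coef=float(entry["age_coef"]),
            edu_coef=float(entry["edu_coef"]),
            residual_sd=float(entry["residual_sd"]),
            direction=direction,
        )
    return NormativeModel(
        name=str(data["name"]),
        norms=norms,
        phes_mean=float(data["phes_mean"]),
        phes_sd=float(data["phes_sd"]),
        cutoff=int(data["cutoff"]),
        provenance=str(data.get("provenance", "")),
    )
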