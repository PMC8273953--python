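"""Cohort epidemiology: MHE prevalence, odds ratios and group contrasts.

Every contrast uses per-variable complete-case denominators: a subject
missing a covariate drops out of that variable's table only.  Odds ratios
are cross-product ratios with Woolf (log-normal) confidence intervals;
quantitative variables are compared by t-test or Mann-Whitney U depending on
Shapiro-Wilk normality and Levene variance homogeneity, categorical ones by
chi-square or Fisher's exact test when any expected cell is below 5.  All
tests are two-sided; no multiplicity correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .models import (
    GroupComparison,
    StatisticKind,
    TwoByTwo,
    ValidationError,
)

__all__ = [
    "Prevalence",
    "prevalence",
    "odds_ratio",
    "woolf_ci",
    "complete_case_counts",
    "compare_groups",
    "cohort_report",
    "render_or",
    "render_ci",
    "render_pct",
    "VARIABLES",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05
MIN_EXPECTED_FOR_CHI2 = 5.0


@dataclass(frozen=True)
class Prevalence:
    cases: int
    total: int

    @property
    def proportion(self) -> float:
        return self.cases / self.total

    @property
    def percent(self) -> float:
        return 100.0 * self.proportion


def prevalence(flags: list[bool]) -> Prevalence:
    """Proportion of true flags, with the raw numerator/denominator."""
    if len(flags) == 0:
        raise ValueError("prevalence of an empty cohort is undefined")
    return Prevalence(cases=int(sum(bool(f) for f in flags)), total=len(flags))


def odds_ratio(t: TwoByTwo, haldane: bool = False) -> float:
    """Cross-product odds ratio ``(a*d)/(b*c)`` at full precision.

    A zero cell makes the OR undefined and returns NaN, unless ``haldane``
    applies the Haldane-Anscombe 0.5 continuity correction to every cell.
    """
    a, b, c, d = (
        t.exposed_case,
        t.exposed_noncase,
        t.unexposed_case,
        t.unexposed_noncase,
    )
    if t.has_zero_cell:
        if not haldane:
            return math.nan
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def woolf_ci(t: TwoByTwo, level: float = 0.95, haldane: bool = False) -> tuple[float, float]:
    """Woolf log-OR interval: exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d))."""
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0, 1), got {level}")
    a, b, c, d = (
        t.exposed_case,
        t.exposed_noncase,
        t.unexposed_case,
        t.unexposed_noncase,
    )
    if t.has_zero_cell:
        if not haldane:
            return (math.nan, math.nan)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


# ---------------------------------------------------------------------------
# Cohort-frame contrasts.  A cohort is a DataFrame with one row per cirrhotic
# subject: boolean `mhe`, numeric `age`/`education`, and categorical columns
# (NaN = missing).  `exposure` names the level counted as exposed in 2x2s.

@dataclass(frozen=True)
class VariableSpec:
    name: str
    kind: str  # "quantitative" | "categorical"
    exposure: object = None
    levels: tuple = ()


VARIABLES: dict[str, VariableSpec] = {
    "age": VariableSpec("age", "quantitative"),
    "education": VariableSpec("education", "quantitative"),
    "sex": VariableSpec("sex", "categorical", exposure="male", levels=("male", "female")),
    "child_pugh": VariableSpec(
        "child_pugh", "categorical", exposure=("B", "C"), levels=("A", "B", "C")
    ),
    "ascites": VariableSpec("ascites", "categorical", exposure="yes", levels=("yes", "no")),
    "jaundice": VariableSpec("jaundice", "categorical", exposure="yes", levels=("yes", "no")),
    "gi_bleed": VariableSpec("gi_bleed", "categorical", exposure="yes", levels=("yes", "no")),
}


def _split(cohort: pd.DataFrame, variable: str) -> tuple[pd.Series, pd.Series]:
    if variable not in VARIABLES:
        raise KeyError(f"unknown variable {variable!r}; registered: {sorted(VARIABLES)}")
    if variable not in cohort.columns:
        raise KeyError(f"cohort frame has no column {variable!r}")
    col = cohort[variable]
    mhe_mask = cohort["mhe"].astype(bool)
    return col[mhe_mask].dropna(), col[~mhe_mask].dropna()


def complete_case_counts(cohort: pd.DataFrame, variable: str) -> dict[str, int]:
    """Non-missing record counts per MHE group for one variable."""
    g_mhe, g_no = _split(cohort, variable)
    counts = {"mhe": int(len(g_mhe)), "no_mhe": int(len(g_no))}
    if counts["mhe"] == 0 and counts["no_mhe"] == 0:
        logger.warning("variable %r has no recorded values; downstream tests skipped", variable)
    return counts


def two_by_two(cohort: pd.DataFrame, variable: str) -> TwoByTwo:
    """Exposure x MHE contingency table on complete cases."""
    spec = VARIABLES[variable]
    if spec.kind != "categorical":
        raise ValueError(f"{variable!r} is not categorical")
    g_mhe, g_no = _split(cohort, variable)
    exposure = spec.exposure if isinstance(spec.exposure, tuple) else (spec.exposure,)
    return TwoByTwo(
        exposed_case=int(g_mhe.isin(exposure).sum()),
        exposed_noncase=int(g_no.isin(exposure).sum()),
        unexposed_case=int((~g_mhe.isin(exposure)).sum()),
        unexposed_noncase=int((~g_no.isin(exposure)).sum()),
    )


def _quantitative_comparison(variable: str, g_mhe: pd.Series, g_no: pd.Series) -> GroupComparison:
    x = np.asarray(g_mhe, float)
    y = np.asarray(g_no, float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return GroupComparison(
            variable=variable, n_mhe=len(x), n_nomhe=len(y), statistic_kind=None,
            estimate=0.0, p_value=math.nan, computable=False,
            note="constant variable",
        )
    # Shapiro-Wilk per group and Levene gate the parametric choice.
    normal = True
    for arr in (x, y):
        if np.ptp(arr) == 0:
            normal = False
            break
        if stats.shapiro(arr).pvalue < ALPHA:
            normal = False
            break
    equal_var = False
    if normal:
        equal_var = stats.levene(x, y).pvalue >= ALPHA
    if normal and equal_var:
        res = stats.ttest_ind(x, y, equal_var=True)
        kind = StatisticKind.MEAN_T
        estimate = float(np.mean(x) - np.mean(y))
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided")
        kind = StatisticKind.MEDIAN_MANNWHITNEY
        estimate = float(np.median(x) - np.median(y))
    return GroupComparison(
        variable=variable, n_mhe=len(x), n_nomhe=len(y),
        statistic_kind=kind, estimate=estimate, p_value=float(res.pvalue),
    )


def _categorical_comparison(variable: str, cohort: pd.DataFrame) -> GroupComparison:
    t = two_by_two(cohort, variable)
    table = np.array(
        [[t.exposed_case, t.unexposed_case], [t.exposed_noncase, t.unexposed_noncase]]
    )
    n_mhe = t.exposed_case + t.unexposed_case
    n_no = t.exposed_noncase + t.unexposed_noncase
    if min(table.sum(axis=0)) == 0 or min(table.sum(axis=1)) == 0:
        return GroupComparison(
            variable=variable, n_mhe=n_mhe, n_nomhe=n_no, statistic_kind=None,
            estimate=t, p_value=math.nan, computable=False,
            note="degenerate margin",
        )
    expected = stats.contingency.expected_freq(table)
    if expected.min() < MIN_EXPECTED_FOR_CHI2:
        p = float(stats.fisher_exact(table)[1])
    else:
        p = float(stats.chi2_contingency(table, correction=False)[1])
    return GroupComparison(
        variable=variable, n_mhe=n_mhe, n_nomhe=n_no,
        statistic_kind=StatisticKind.PROPORTION_FISHER_CHI2,
        estimate=t, p_value=p,
    )


def compare_groups(cohort: pd.DataFrame, variable: str) -> GroupComparison:
    """MHE vs no-MHE contrast for one variable, complete cases only.

    Quantitative variables need >= 2 observations per group; otherwise the
    comparison is returned marked not-computable rather than raising.
    """
    spec = VARIABLES[variable]
    g_mhe, g_no = _split(cohort, variable)
    if spec.kind == "quantitative":
        if len(g_mhe) < 2 or len(g_no) < 2:
            return GroupComparison(
                variable=variable, n_mhe=len(g_mhe), n_nomhe=len(g_no),
                statistic_kind=None, estimate=math.nan, p_value=math.nan,
                computable=False, note="fewer than 2 observations in a group",
            )
        return _quantitative_comparison(variable, g_mhe, g_no)
    if len(g_mhe) + len(g_no) == 0:
        return GroupComparison(
            variable=variable, n_mhe=0, n_nomhe=0, statistic_kind=None,
            estimate=math.nan, p_value=math.nan, computable=False,
            note="no recorded values",
        )
    return _categorical_comparison(variable, cohort)


# ---------------------------------------------------------------------------
# Rendering (the reporting layer truncates ORs to two decimals and CI bounds
# to one, matching the printing convention of the source tables; percentages
# round half-up to one decimal).

def _truncate(x: float, decimals: int) -> float:
    scale = 10 ** decimals
    return math.floor(x * scale) / scale


def render_or(value: float) -> str:
    return "undefined" if math.isnan(value) else f"{_truncate(value, 2):.2f}"


def render_ci(ci: tuple[float, float]) -> str:
    lo, hi = ci
    if math.isnan(lo) or math.isnan(hi):
        return "undefined"
    return f"[{_truncate(lo, 1):.1f}-{_truncate(hi, 1):.1f}]"


def render_pct(x: float) -> str:
    q = Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{q}%"


def cohort_report(cohort: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Per-variable contrast table for a scored cirrhotic cohort.

    One row per variable: complete-case ns, estimate (mean/median difference
    or rendered OR with Woolf CI) and two-sided p value.
    """
    rows = []
    for name in variables or list(VARIABLES):
        cmp_ = compare_groups(cohort, name)
        row = dict(
            variable=name, n_mhe=cmp_.n_mhe, n_nomhe=cmp_.n_nomhe,
            kind=cmp_.statistic_kind.value if cmp_.statistic_kind else "not_computable",
            p_value=cmp_.p_value,
        )
        if isinstance(cmp_.estimate, TwoByTwo):
            t = cmp_.estimate
            or_ = odds_ratio(t)
            row["estimate"] = f"OR {render_or(or_)} {render_ci(woolf_ci(t))}"
            row["pct_mhe"] = render_pct(100.0 * t.exposed_case / cmp_.n_mhe) if cmp_.n_mhe else ""
            row["pct_nomhe"] = (
                render_pct(100.0 * t.exposed_noncase / cmp_.n_nomhe) if cmp_.n_nomhe else ""
            )
        else:
            row["estimate"] = (
                "" if not cmp_.computable else f"diff {cmp_.estimate:.2f}"
            )
            row["pct_mhe"] = row["pct_nomhe"] = ""
        rows.append(row)
    return pd.DataFrame(rows)
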