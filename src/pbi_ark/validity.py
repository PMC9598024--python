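"""Convergent-validity battery for PBI scores.

Eleven convergent variables are derived from visit-1 (treatment start) and
visit-2 (after the pollen season) clinical data:

* physician and patient global judgement of well-being versus the previous
  season (categorical; small response categories are excluded by a fixed
  per-population configuration: children keep much/somewhat better and
  unchanged, adolescents keep much/somewhat better only);
* change in rhinitis and conjunctivitis severity and in the frequency and
  duration of rhinitis symptoms, dichotomised as decreased vs. not
  (strict ordinal improvement from visit 1 to visit 2; ties count as no
  decrease);
* normalisation of impaired sleep, activities and performance, restricted
  to respondents impaired at visit 1 (normal at visit 2 -> normalised);
* change in average and peak impairment on the 0-10 VAS (visit 2 minus
  visit 1, continuous).

Each scale x variable cell uses pairwise deletion and the test matching
the variable's scale level: Pearson correlation for continuous change,
a t-test for dichotomies (pooled variance unless Levene's test at its 0.1
screening level indicates unequal variances, then Welch), and one-way
ANOVA with eta squared for categorical variables with more than two
levels.  Significance is flagged at p < 0.05, two-sided; effect sizes are
labelled with the conventional small/medium/strong cut-offs (d: 0.2 /
0.5 / 0.8; eta^2: 0.01 / 0.06 / 0.14; r: 0.1 / 0.3 / 0.5, inclusive at
each boundary on the absolute value).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .instrument import (
    Cohort,
    DURATION_LEVELS,
    FREQUENCY_LEVELS,
    IMPAIRMENT_LEVELS,
    JUDGEMENT_LEVELS,
    Population,
    SEVERITY_LEVELS,
    SubscaleMap,
)

__all__ = [
    "VariableKind",
    "ConvergentVariable",
    "ValidityResult",
    "ConvergentValidityBattery",
    "derive_convergent",
    "levene_equal_variance",
    "two_group_compare",
    "one_way_anova",
    "pearson_assoc",
    "effect_label",
    "validity_battery",
    "LEVENE_SCREEN_P",
]

#: Levene screening level below which the Welch t-test is used.
LEVENE_SCREEN_P = 0.1

EFFECT_THRESHOLDS = {
    "d": (0.2, 0.5, 0.8),
    "eta2": (0.01, 0.06, 0.14),
    "r": (0.1, 0.3, 0.5),
}


class VariableKind(enum.Enum):
    DICHOTOMOUS = "dichotomous"
    CATEGORICAL = "categorical"
    CONTINUOUS = "continuous"


@dataclass(frozen=True)
class ConvergentVariable:
    """One derived convergent variable with its derivation record.

    ``values`` holds one entry per respondent: a level string
    (dichotomous/categorical, ordered as in ``levels``), a float
    (continuous), or None (missing / excluded).  For dichotomies
    ``levels`` fixes the group order used for Cohen's d.
    """

    name: str
    kind: VariableKind
    values: tuple
    levels: Optional[tuple[str, ...]] = None
    derivation: str = ""


@dataclass(frozen=True)
class ValidityResult:
    scale: str
    variable: str
    test: Optional[str]              # "t_test" | "welch_t" | "anova" | "pearson"
    statistic: Optional[float]
    p: Optional[float]
    effect_size: Optional[float]
    effect_kind: Optional[str]       # "d" | "eta2" | "r"
    effect_label: Optional[str]
    n: int
    estimable: bool

    @property
    def significant(self) -> Optional[bool]:
        return None if self.p is None else bool(self.p < 0.05)


def _not_estimable(scale: str, variable: str, n: int = 0) -> ValidityResult:
    return ValidityResult(scale, variable, None, None, None, None, None, None, n, False)


# ---------------------------------------------------------------------------
# Variable derivation


def _ordinal_decrease(v1, v2, levels: Sequence[str]) -> Optional[str]:
    if v1 is None or v2 is None:
        return None
    i1, i2 = levels.index(v1), levels.index(v2)
    return "decreased" if i2 < i1 else "no_decrease"


def _normalised(v1, v2) -> Optional[str]:
    if v1 is None or v2 is None:
        return None
    if v1 != "impaired":
        return None  # no normalisation event to classify
    return "normalised" if v2 == "normal" else "not_normalised"


def _vas_change(v1, v2) -> Optional[float]:
    if v1 is None or v2 is None:
        return None
    return float(v2) - float(v1)


def _judgement(value, allowed: Sequence[str]) -> Optional[str]:
    if value is None or value not in allowed:
        return None
    return value


#: Global-judgement categories retained per population (small cells excluded
#: by configuration, keeping the battery deterministic).
JUDGEMENT_KEPT = {
    Population.CHILDREN: ("much_better", "somewhat_better", "unchanged"),
    Population.ADOLESCENTS: ("much_better", "somewhat_better"),
}

#: Worse-outcome-first group order for change/normalisation dichotomies, so a
#: benefit-sensitive scale yields a negative d.
_DICHOTOMY_ORDER = {
    "decrease": ("no_decrease", "decreased"),
    "normalise": ("not_normalised", "normalised"),
}


def derive_convergent(
    cohort: Cohort, population: Optional[Union[Population, str]] = None
) -> list[ConvergentVariable]:
    """Derive the eleven convergent variables from visit-1/visit-2 fields.

    ``population`` selects the global-judgement category configuration; by
    default it is inferred from the cohort (which must then be a single
    age group).  Missing visit values propagate as per-respondent missing
    (pairwise deletion downstream).
    """
    if population is None:
        groups = {r.age_group for r in cohort.respondents}
        if len(groups) != 1:
            raise ValueError("cohort mixes age groups; pass population explicitly")
        population = groups.pop()
    population = Population(population) if isinstance(population, str) else population
    kept = JUDGEMENT_KEPT[population]

    def col(name):
        return cohort.convergent_series(name)

    variables: list[ConvergentVariable] = []
    for who in ("physician", "patient"):
        vals = tuple(_judgement(v, kept) for v in col(f"v2_global_judgement_{who}"))
        kind = VariableKind.CATEGORICAL if len(kept) > 2 else VariableKind.DICHOTOMOUS
        variables.append(
            ConvergentVariable(
                name=f"global_judgement_{who}",
                kind=kind,
                values=vals,
                levels=kept,
                derivation=f"v2_global_judgement_{who}; kept levels {kept}",
            )
        )
    for name, field, levels in (
        ("rhinitis_severity_change", "rhinitis_severity", SEVERITY_LEVELS),
        ("conjunctivitis_severity_change", "conjunctivitis_severity", SEVERITY_LEVELS),
        ("rhinitis_frequency_change", "rhinitis_frequency", FREQUENCY_LEVELS),
        ("rhinitis_duration_change", "rhinitis_duration", DURATION_LEVELS),
    ):
        vals = tuple(
            _ordinal_decrease(v1, v2, levels)
            for v1, v2 in zip(col(f"v1_{field}"), col(f"v2_{field}"))
        )
        variables.append(
            ConvergentVariable(
                name=name,
                kind=VariableKind.DICHOTOMOUS,
                values=vals,
                levels=_DICHOTOMY_ORDER["decrease"],
                derivation=f"v2_{field} < v1_{field} (strict ordinal) -> decreased",
            )
        )
    for name, field in (
        ("sleep_normalised", "sleep"),
        ("activities_normalised", "activities"),
        ("performance_normalised", "performance"),
    ):
        vals = tuple(
            _normalised(v1, v2) for v1, v2 in zip(col(f"v1_{field}"), col(f"v2_{field}"))
        )
        variables.append(
            ConvergentVariable(
                name=name,
                kind=VariableKind.DICHOTOMOUS,
                values=vals,
                levels=_DICHOTOMY_ORDER["normalise"],
                derivation=f"impaired at v1_{field}; v2_{field} normal -> normalised",
            )
        )
    for name, field in (("vas_avg_change", "vas_avg"), ("vas_peak_change", "vas_peak")):
        vals = tuple(
            _vas_change(v1, v2) for v1, v2 in zip(col(f"v1_{field}"), col(f"v2_{field}"))
        )
        variables.append(
            ConvergentVariable(
                name=name,
                kind=VariableKind.CONTINUOUS,
                values=vals,
                derivation=f"v2_{field} - v1_{field}",
            )
        )
    return variables


# ---------------------------------------------------------------------------
# Tests


def levene_equal_variance(group1: Sequence[float], group2: Sequence[float]) -> float:
    """Levene's test p-value (mean-centred absolute deviations)."""
    g1, g2 = np.asarray(group1, float), np.asarray(group2, float)
    if g1.size < 1 or g2.size < 1:
        raise ValueError("both groups must be non-empty")
    if np.ptp(g1) == 0 and np.ptp(g2) == 0 and g1.mean() == g2.mean():
        return 1.0  # degenerate: identical constant samples
    with np.errstate(divide="ignore", invalid="ignore"):
        stat, p = stats.levene(g1, g2, center="mean")
    if math.isnan(p):
        return 1.0
    return float(p)


def _cohens_d(g1: np.ndarray, g2: np.ndarray) -> float:
    n1, n2 = g1.size, g2.size
    sp2 = ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        return 0.0 if g1.mean() == g2.mean() else math.copysign(math.inf, g1.mean() - g2.mean())
    return float((g1.mean() - g2.mean()) / math.sqrt(sp2))


def two_group_compare(
    scores: Sequence[float],
    groups: Sequence[Optional[str]],
    group_order: tuple[str, str],
    scale: str = "scale",
    variable: str = "variable",
) -> ValidityResult:
    """t-test of scores between two groups with Levene-gated variance pooling.

    ``group_order`` fixes (group 1, group 2) for the sign of Cohen's d,
    which uses the pooled SD regardless of which t branch ran.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(groups, dtype=object)
    ok = ~np.isnan(scores) & np.array([g is not None for g in labels])
    g1 = scores[ok & (labels == group_order[0])]
    g2 = scores[ok & (labels == group_order[1])]
    if g1.size < 2 or g2.size < 2:
        return _not_estimable(scale, variable, int(g1.size + g2.size))
    welch = levene_equal_variance(g1, g2) < LEVENE_SCREEN_P
    t, p = stats.ttest_ind(g1, g2, equal_var=not welch)
    d = _cohens_d(g1, g2)
    return ValidityResult(
        scale=scale,
        variable=variable,
        test="welch_t" if welch else "t_test",
        statistic=float(t),
        p=float(p),
        effect_size=d,
        effect_kind="d",
        effect_label=effect_label(d, "d"),
        n=int(g1.size + g2.size),
        estimable=True,
    )


def one_way_anova(
    scores: Sequence[float],
    groups: Sequence[Optional[str]],
    scale: str = "scale",
    variable: str = "variable",
) -> ValidityResult:
    """One-way ANOVA with eta squared = SS_between / SS_total."""
    scores = np.asarray(scores, float)
    labels = np.asarray(groups, dtype=object)
    ok = ~np.isnan(scores) & np.array([g is not None for g in labels])
    samples = []
    for level in pd.unique(labels[ok]):
        s = scores[ok & (labels == level)]
        if s.size >= 1:
            samples.append(s)
    allv = np.concatenate(samples) if samples else np.empty(0)
    if len(samples) < 2 or allv.size - len(samples) < 1:
        return _not_estimable(scale, variable, int(ok.sum()))
    grand = allv.mean()
    ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ss_total = ((allv - grand) ** 2).sum()
    if ss_total == 0:
        return _not_estimable(scale, variable, int(allv.size))
    f, p = stats.f_oneway(*samples)
    eta2 = float(ss_between / ss_total)
    return ValidityResult(
        scale=scale,
        variable=variable,
        test="anova",
        statistic=float(f),
        p=float(p),
        effect_size=eta2,
        effect_kind="eta2",
        effect_label=effect_label(eta2, "eta2"),
        n=int(allv.size),
        estimable=True,
    )


def pearson_assoc(
    scores: Sequence[float],
    change: Sequence[Optional[float]],
    scale: str = "scale",
    variable: str = "variable",
) -> ValidityResult:
    """Pearson correlation with two-sided p."""
    scores = np.asarray(scores, float)
    change = np.array([math.nan if v is None else float(v) for v in change])
    ok = ~np.isnan(scores) & ~np.isnan(change)
    x, y = scores[ok], change[ok]
    if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return _not_estimable(scale, variable, int(x.size))
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return ValidityResult(
        scale=scale,
        variable=variable,
        test="pearson",
        statistic=r,
        p=float(res.pvalue),
        effect_size=r,
        effect_kind="r",
        effect_label=effect_label(r, "r"),
        n=int(x.size),
        estimable=True,
    )


def effect_label(value: float, kind: str) -> str:
    """SMALL/MEDIUM/STRONG label, inclusive at each cut-off, |value| for d and r."""
    if kind not in EFFECT_THRESHOLDS:
        raise ValueError(f"kind must be one of {sorted(EFFECT_THRESHOLDS)}, got {kind!r}")
    if not math.isfinite(value):
        return "STRONG" if kind in ("d", "r") or value > 0 else "NEGLIGIBLE"
    small, medium, strong = EFFECT_THRESHOLDS[kind]
    v = abs(value)
    if v >= strong:
        return "STRONG"
    if v >= medium:
        return "MEDIUM"
    if v >= small:
        return "SMALL"
    return "NEGLIGIBLE"


# ---------------------------------------------------------------------------
# Battery


class ConvergentValidityBattery(BaseEstimator):
    """Full scales-by-variables convergent-validity matrix.

    ``fit(cohort, scores)`` derives the convergent variables and runs, per
    cell, the test matching the variable kind with pairwise deletion.
    Fitted attributes: ``results_`` (list of :class:`ValidityResult`),
    ``frame_`` (long-format DataFrame).
    """

    def __init__(self, subscale_map: Optional[SubscaleMap] = None):
        self.subscale_map = subscale_map

    def fit(self, cohort: Cohort, scores: pd.DataFrame) -> "ConvergentValidityBattery":
        subscale_map = self.subscale_map
        if subscale_map is None:
            groups = {r.age_group for r in cohort.respondents}
            if len(groups) != 1:
                raise ValueError("cohort mixes age groups; pass an explicit subscale_map")
            from .instrument import builtin_subscale_map

            subscale_map = builtin_subscale_map(groups.pop())
        self.subscale_map_ = subscale_map
        variables = derive_convergent(cohort, subscale_map.population)
        scale_names = ("global",) + subscale_map.names
        ordered = scores.set_index("id").reindex([r.id for r in cohort.respondents])
        results = []
        for var in variables:
            for scale in scale_names:
                s = ordered[scale].to_numpy(dtype=float)
                if var.kind is VariableKind.CONTINUOUS:
                    res = pearson_assoc(s, var.values, scale, var.name)
                elif var.kind is VariableKind.DICHOTOMOUS:
                    res = two_group_compare(s, var.values, var.levels[:2], scale, var.name)
                else:
                    res = one_way_anova(s, var.values, scale, var.name)
                results.append(res)
        self.variables_ = variables
        self.results_ = results
        self.frame_ = pd.DataFrame(
            [
                {
                    "variable": r.variable,
                    "scale": r.scale,
                    "test": r.test,
                    "statistic": r.statistic,
                    "p": r.p,
                    "effect_size": r.effect_size,
                    "effect_kind": r.effect_kind,
                    "effect_label": r.effect_label,
                    "N": r.n,
                    "significant": r.significant,
                    "estimable": r.estimable,
                }
                for r in results
            ]
        )
        return self


def validity_battery(
    cohort: Cohort, scores: pd.DataFrame, subscale_map: Optional[SubscaleMap] = None
) -> pd.DataFrame:
    """Thin wrapper returning the long-format battery DataFrame."""
    return ConvergentValidityBattery(subscale_map=subscale_map).fit(cohort, scores).frame_
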