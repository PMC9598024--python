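"""Needs-weighted benefit scoring for the PBI-AR-K.

The Patient Benefit Index combines pre-treatment importance ratings (PNQ)
with treatment-benefit ratings (PBQ) into a weighted score:

    PBI = sum_i( benefit_i * importance_i ) / sum_i( importance_i )

over the items i whose recoded importance and benefit are both observed.
The score lies in [0, 4]; scores >= 1 are conventionally read as an at
least minimally relevant benefit.

Two part-specific recodes precede scoring:

* PNQ: a "does not apply to me" answer is equated with importance 0
  (a goal that does not apply cannot be important).
* PBQ: a "did not apply to me" answer is treated as missing (no benefit
  can be rated for a goal that did not apply).

Items whose importance or benefit is missing after the recodes drop out of
both numerator and denominator (re-normalisation), which keeps the score in
[0, 4].  A score is reported as undefined when fewer than half of the item
set (rounded up) pair, or when the summed importance of the paired items
is zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .instrument import (
    MISSING,
    N_ITEMS,
    NOT_APPLY_CODE,
    Cohort,
    Population,
    ResponseValue,
    SubscaleMap,
    builtin_subscale_map,
    response_to_code,
)

__all__ = [
    "PbiScore",
    "PbiScorer",
    "recode_importance",
    "recode_benefit",
    "pbi_score",
    "score_cohort",
    "score_matrix",
    "relevant_benefit_rate",
    "item_descriptives",
    "need_profile",
]


def _to_codes(values: Sequence[ResponseValue], expected_len: int = N_ITEMS) -> np.ndarray:
    if len(values) != expected_len:
        raise ValueError(f"expected {expected_len} responses, got {len(values)}")
    return np.array([response_to_code(v) for v in values], dtype=float)


def recode_importance(pnq: Union[Sequence[ResponseValue], np.ndarray]) -> np.ndarray:
    """PNQ recode: not-apply -> importance 0; ordinals unchanged; missing kept.

    Accepts a vector of :class:`ResponseValue` or a raw float-coded array
    (NaN missing, -1 not-apply).  Returns a float array with NaN for missing.
    """
    raw = np.asarray(pnq, dtype=float) if not _is_response_seq(pnq) else _to_codes(pnq)
    return np.where(raw == NOT_APPLY_CODE, 0.0, raw)


def recode_benefit(pbq: Union[Sequence[ResponseValue], np.ndarray]) -> np.ndarray:
    """PBQ recode: not-apply -> missing; ordinals unchanged; missing kept."""
    raw = np.asarray(pbq, dtype=float) if not _is_response_seq(pbq) else _to_codes(pbq)
    return np.where(raw == NOT_APPLY_CODE, np.nan, raw)


def _is_response_seq(values) -> bool:
    return len(values) > 0 and isinstance(values[0], ResponseValue) or (
        len(values) == 0 and not isinstance(values, np.ndarray)
    )


@dataclass(frozen=True)
class PbiScore:
    """A weighted benefit score over one item set.

    ``value`` is None when the score is undefined (zero summed importance
    over the paired items, or too few paired items).  ``denominator`` is the
    summed importance of the contributing items, reported so the weighting
    can be reconstructed from the output.
    """

    value: Optional[float]
    n_items_used: int
    denominator: float

    @property
    def defined(self) -> bool:
        return self.value is not None


def min_items_required(n_items: int) -> int:
    """A score needs at least half of its item set (rounded up) to pair."""
    return math.ceil(n_items / 2)


def score_matrix(
    importance: np.ndarray,
    benefit: np.ndarray,
    items: Iterable[int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised PBI over an (n, 19) importance and benefit matrix pair.

    Returns ``(values, n_used, denominators)``; undefined scores are NaN in
    ``values``.  Used by both the per-respondent scorer and the bulk
    property checks.
    """
    item_list = sorted(set(items))
    if not item_list:
        raise ValueError("empty item set")
    if not set(item_list) <= set(range(1, N_ITEMS + 1)):
        raise ValueError(f"item ids outside 1..{N_ITEMS}: {item_list}")
    idx = np.asarray(item_list) - 1
    imp = np.atleast_2d(np.asarray(importance, dtype=float))[:, idx]
    ben = np.atleast_2d(np.asarray(benefit, dtype=float))[:, idx]
    paired = ~np.isnan(imp) & ~np.isnan(ben)
    denom = np.where(paired, imp, 0.0).sum(axis=1)
    numer = np.where(paired, imp * ben, 0.0).sum(axis=1)
    n_used = paired.sum(axis=1)
    defined = (n_used >= min_items_required(len(item_list))) & (denom > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(defined, numer / np.where(denom > 0, denom, np.nan), np.nan)
    return values, n_used, denom


def pbi_score(
    importance: Union[Sequence[ResponseValue], np.ndarray],
    benefit: Union[Sequence[ResponseValue], np.ndarray],
    items: Iterable[int] = range(1, N_ITEMS + 1),
) -> PbiScore:
    """Weighted benefit score of one respondent over ``items``.

    ``importance`` and ``benefit`` are the *recoded* vectors (float, NaN for
    missing) or raw :class:`ResponseValue` vectors, in which case the
    part-specific recodes are applied first.
    """
    imp = recode_importance(importance) if _is_response_seq(importance) else np.asarray(importance, float)
    ben = recode_benefit(benefit) if _is_response_seq(benefit) else np.asarray(benefit, float)
    values, n_used, denom = score_matrix(imp.reshape(1, -1), ben.reshape(1, -1), items)
    value = None if np.isnan(values[0]) else float(values[0])
    return PbiScore(value=value, n_items_used=int(n_used[0]), denominator=float(denom[0]))


class PbiScorer(BaseEstimator, TransformerMixin):
    """Transformer computing global and subscale PBI scores for a cohort.

    Parameters
    ----------
    subscale_map:
        The subscale partition to score.  Defaults to the bundled map for
        the population inferred at fit time (all respondents must then
        belong to one age group).

    After :meth:`fit`, ``subscale_map_`` holds the resolved map.
    :meth:`transform` returns a DataFrame with one row per respondent and
    columns ``id, age_group, global, <subscale...>, n_items_used_global,
    denominator_global`` plus ``undefined_<scale>`` flags.  Undefined
    scores are NaN, never imputed.
    """

    def __init__(self, subscale_map: Optional[SubscaleMap] = None):
        self.subscale_map = subscale_map

    def fit(self, cohort: Cohort, y=None) -> "PbiScorer":
        if self.subscale_map is not None:
            self.subscale_map_ = self.subscale_map
        else:
            groups = {r.age_group for r in cohort.respondents}
            if len(groups) != 1:
                raise ValueError(
                    "cohort mixes age groups; pass an explicit subscale_map "
                    "or subset the cohort first"
                )
            self.subscale_map_ = builtin_subscale_map(groups.pop())
        return self

    def transform(self, cohort: Cohort) -> pd.DataFrame:
        if not hasattr(self, "subscale_map_"):
            raise RuntimeError("PbiScorer is not fitted")
        imp = recode_importance(cohort.pnq_raw_matrix())
        ben = recode_benefit(cohort.pbq_raw_matrix())
        out = pd.DataFrame(
            {
                "id": [r.id for r in cohort.respondents],
                "age_group": [r.age_group.value for r in cohort.respondents],
            }
        )
        g_val, g_n, g_den = score_matrix(imp, ben, range(1, N_ITEMS + 1))
        out["global"] = g_val
        for name in self.subscale_map_.names:
            s_val, _, _ = score_matrix(imp, ben, self.subscale_map_.items_of(name))
            out[name] = s_val
        out["n_items_used_global"] = g_n
        out["denominator_global"] = g_den
        for scale in ("global",) + self.subscale_map_.names:
            out[f"undefined_{scale}"] = out[scale].isna()
        return out

    def fit_transform(self, cohort: Cohort, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(cohort).transform(cohort)


def score_cohort(cohort: Cohort, subscale_map: Optional[SubscaleMap] = None) -> pd.DataFrame:
    """Global + subscale PBI scores for every respondent (thin wrapper)."""
    return PbiScorer(subscale_map=subscale_map).fit_transform(cohort)


def relevant_benefit_rate(scores: Iterable[Union[PbiScore, float, None]]) -> dict:
    """Share of defined scores at or above the relevance threshold of 1.0.

    Returns ``{"rate": float|None, "n_defined": int, "n_undefined": int}``;
    the rate is None when no score is defined.
    """
    values = []
    n_undefined = 0
    for s in scores:
        v = s.value if isinstance(s, PbiScore) else s
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_undefined += 1
        else:
            values.append(float(v))
    rate = None if not values else sum(v >= 1.0 for v in values) / len(values)
    return {"rate": rate, "n_defined": len(values), "n_undefined": n_undefined}


def item_descriptives(cohort: Cohort, part: str) -> pd.DataFrame:
    """Per-item N, mean, SD and top-two-category share for one part.

    ``part`` is ``"pnq"`` or ``"pbq"``.  The percentage bases differ by
    part: for the PNQ the not-apply answers are counted as importance 0
    (the base includes them); for the PBQ they are excluded, and an extra
    ``pct_did_apply`` column reports the share of respondents answering the
    item for whom the goal applied at all.  SD uses the n-1 denominator.
    Items with no usable answers yield NaN statistics and ``undefined``
    True.
    """
    part = part.lower()
    if part == "pnq":
        mat = recode_importance(cohort.pnq_raw_matrix())
    elif part == "pbq":
        mat = recode_benefit(cohort.pbq_raw_matrix())
    else:
        raise ValueError(f"part must be 'pnq' or 'pbq', got {part!r}")

    rows = []
    raw = cohort.pbq_raw_matrix() if part == "pbq" else None
    for j, item in enumerate(cohort.instrument.items):
        col = mat[:, j]
        obs = col[~np.isnan(col)]
        n = obs.size
        rec: dict[str, object] = {"item_id": item.id, "N": n}
        if n == 0:
            rec.update(mean=np.nan, sd=np.nan, pct_quite_or_very=np.nan, undefined=True)
        else:
            rec.update(
                mean=float(obs.mean()),
                sd=float(obs.std(ddof=1)) if n > 1 else np.nan,
                pct_quite_or_very=float(100.0 * np.mean(obs >= 3)),
                undefined=False,
            )
        if part == "pbq":
            answered = raw[:, j][~np.isnan(raw[:, j])]  # ordinal or not-apply
            rec["pct_did_apply"] = (
                float(100.0 * np.mean(answered != NOT_APPLY_CODE)) if answered.size else np.nan
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def need_profile(cohort: Cohort, grouping: str) -> pd.DataFrame:
    """Per-group per-item mean importance (PNQ recode applied).

    ``grouping`` is ``"age_group"``, ``"sex"`` or ``"asthma"``.  Returns a
    DataFrame indexed by group label with one column per item id, suitable
    for spider-chart export.  Empty groups are omitted with a warning.
    """
    key_funcs = {
        "age_group": lambda r: r.age_group.value,
        "sex": lambda r: r.sex.value,
        "asthma": lambda r: "asthma" if r.asthma else "no_asthma",
    }
    if grouping not in key_funcs:
        raise ValueError(f"grouping must be one of {sorted(key_funcs)}, got {grouping!r}")
    key = key_funcs[grouping]
    imp = recode_importance(cohort.pnq_raw_matrix())
    labels = np.array([key(r) for r in cohort.respondents])
    expected = {
        "age_group": [p.value for p in Population],
        "sex": ["male", "female"],
        "asthma": ["asthma", "no_asthma"],
    }[grouping]
    rows = {}
    for label in expected:
        sel = imp[labels == label]
        if sel.shape[0] == 0:
            warnings.warn(f"group {label!r} is empty and was omitted", stacklevel=2)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            rows[label] = np.nanmean(sel, axis=0)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[it.id for it in cohort.instrument.items]
    )
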