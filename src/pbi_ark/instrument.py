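"""Instrument and cohort data model for the PBI-AR-K questionnaire.

The PBI-AR-K is a two-part patient-reported outcome instrument for allergic
rhinitis in children (5-12 years) and adolescents (13-17 years).  The Patient
Needs Questionnaire (PNQ) rates the pre-treatment importance of 19 treatment
goals; the Patient Benefit Questionnaire (PBQ) rates, during or after
treatment, how far each goal was achieved.  Both parts use a 5-point ordinal
scale (0 = "not at all" ... 4 = "very") with an additional "does/did not
apply to me" option.

This module defines the domain types (response values, items, instrument,
subscale maps, respondents, cohorts) and reads/writes the cohort CSV dialect
and the JSON instrument definition.  The two non-ordinal response states --
NOT_APPLICABLE and MISSING -- are kept distinct at ingestion because the
scoring rules treat them differently per questionnaire part (see
:mod:`pbi_ark.scoring`).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

N_ITEMS = 19

#: Sentinel float codes used in raw response matrices.
NOT_APPLY_CODE = -1.0

#: CSV token for the "does/did not apply to me" response.
NOT_APPLY_TOKEN = "NA"


class SchemaError(ValueError):
    """An instrument definition or cohort file violates its schema."""


class CohortParseError(SchemaError):
    """A cohort CSV cell could not be decoded; carries row/column address."""

    def __init__(self, message: str, row: Optional[int] = None, column: Optional[str] = None):
        self.row = row
        self.column = column
        if row is not None or column is not None:
            message = f"{message} (row {row}, column {column!r})"
        super().__init__(message)


class ResponseState(enum.Enum):
    ORDINAL = "ordinal"
    NOT_APPLICABLE = "not_applicable"
    MISSING = "missing"


@dataclass(frozen=True)
class ResponseValue:
    """One answer to one questionnaire item.

    Either an ordinal level 0-4, the explicit "does/did not apply to me"
    option, or a missing (unanswered) cell.  The level is present iff the
    state is ORDINAL.
    """

    state: ResponseState
    level: Optional[int] = None

    def __post_init__(self) -> None:
        if self.state is ResponseState.ORDINAL:
            if self.level not in (0, 1, 2, 3, 4):
                raise ValueError(f"ordinal level must be in 0..4, got {self.level!r}")
        elif self.level is not None:
            raise ValueError(f"{self.state.name} responses carry no level")

    @staticmethod
    def ordinal(level: int) -> "ResponseValue":
        return _ORDINALS[level]

    @property
    def is_ordinal(self) -> bool:
        return self.state is ResponseState.ORDINAL


NOT_APPLICABLE = ResponseValue(ResponseState.NOT_APPLICABLE)
MISSING = ResponseValue(ResponseState.MISSING)
_ORDINALS = tuple(ResponseValue(ResponseState.ORDINAL, lv) for lv in range(5))


def response_to_code(value: ResponseValue) -> float:
    """Encode a response as a float: level, -1.0 for not-apply, NaN for missing."""
    if value.state is ResponseState.ORDINAL:
        return float(value.level)
    if value.state is ResponseState.NOT_APPLICABLE:
        return NOT_APPLY_CODE
    return math.nan


def response_from_code(code: float) -> ResponseValue:
    if math.isnan(code):
        return MISSING
    if code == NOT_APPLY_CODE:
        return NOT_APPLICABLE
    return ResponseValue.ordinal(int(code))


@dataclass(frozen=True)
class Item:
    id: int
    need_text: str
    benefit_text: str

    def __post_init__(self) -> None:
        if not (1 <= self.id <= N_ITEMS):
            raise SchemaError(f"item id must be in 1..{N_ITEMS}, got {self.id}")


@dataclass(frozen=True)
class Instrument:
    """A two-part needs/benefit questionnaire definition."""

    name: str
    items: tuple[Item, ...]
    scale_labels: tuple[str, ...]
    not_apply_label: str

    def __post_init__(self) -> None:
        if len(self.scale_labels) != 5:
            raise SchemaError(f"exactly 5 scale labels required, got {len(self.scale_labels)}")
        ids = [it.id for it in self.items]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate item ids: {dup}")
        object.__setattr__(self, "items", tuple(sorted(self.items, key=lambda it: it.id)))

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def item_ids(self) -> tuple[int, ...]:
        return tuple(it.id for it in self.items)

    def item(self, item_id: int) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise KeyError(item_id)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "scale_labels": list(self.scale_labels),
            "not_apply_label": self.not_apply_label,
            "items": [
                {"id": it.id, "need_text": it.need_text, "benefit_text": it.benefit_text}
                for it in self.items
            ],
        }


class Population(enum.Enum):
    CHILDREN = "children"
    ADOLESCENTS = "adolescents"


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"


@dataclass(frozen=True)
class SubscaleMap:
    """Named partition of the 19 item ids into subscales."""

    population: Population
    subscales: Mapping[str, frozenset[int]]

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "subscales",
            {name: frozenset(ids) for name, ids in self.subscales.items()},
        )
        all_ids: list[int] = []
        for ids in self.subscales.values():
            all_ids.extend(ids)
        if len(all_ids) != len(set(all_ids)):
            raise SchemaError("subscales overlap")
        if set(all_ids) != set(range(1, N_ITEMS + 1)):
            raise SchemaError(
                f"subscales must partition 1..{N_ITEMS}; got {sorted(set(all_ids))}"
            )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.subscales.keys())

    def items_of(self, name: str) -> frozenset[int]:
        return self.subscales[name]


# Published subscale structure: four subscales in children, three in
# adolescents (the adolescent solution merges five retained factors into
# three content-defined subscales).
CHILDREN_SUBSCALES = SubscaleMap(
    Population.CHILDREN,
    {
        "treatment_burden": frozenset({6, 11, 17, 18, 19}),
        "fatigue_social_life": frozenset({1, 4, 10, 14, 15, 16}),
        "physical_symptoms": frozenset({2, 3, 9, 12}),
        "being_outdoors": frozenset({5, 7, 8, 13}),
    },
)

ADOLESCENT_SUBSCALES = SubscaleMap(
    Population.ADOLESCENTS,
    {
        "treatment_burden": frozenset({6, 11, 17, 18, 19}),
        "physical_symptoms": frozenset({1, 2, 3, 5, 7, 8, 9}),
        "psychosocial_burden": frozenset({4, 10, 12, 13, 14, 15, 16}),
    },
)


def builtin_subscale_map(population: Union[Population, str]) -> SubscaleMap:
    population = Population(population) if isinstance(population, str) else population
    return CHILDREN_SUBSCALES if population is Population.CHILDREN else ADOLESCENT_SUBSCALES


# Convergent-variable raw fields (visit 1 and visit 2) ----------------------

SEVERITY_LEVELS = ("none", "mild", "moderate", "strong")
FREQUENCY_LEVELS = ("lt4_days", "ge4_days")
DURATION_LEVELS = ("lt4_weeks", "ge4_weeks")
IMPAIRMENT_LEVELS = ("normal", "impaired")
JUDGEMENT_LEVELS = ("much_better", "somewhat_better", "unchanged", "worse")

_VISIT_FIELDS = {
    "rhinitis_severity": SEVERITY_LEVELS,
    "conjunctivitis_severity": SEVERITY_LEVELS,
    "rhinitis_frequency": FREQUENCY_LEVELS,
    "rhinitis_duration": DURATION_LEVELS,
    "sleep": IMPAIRMENT_LEVELS,
    "activities": IMPAIRMENT_LEVELS,
    "performance": IMPAIRMENT_LEVELS,
}
_VAS_FIELDS = ("vas_avg", "vas_peak")

CONVERGENT_COLUMNS: tuple[str, ...] = tuple(
    [f"v1_{f}" for f in _VISIT_FIELDS] + [f"v1_{f}" for f in _VAS_FIELDS]
    + [f"v2_{f}" for f in _VISIT_FIELDS] + [f"v2_{f}" for f in _VAS_FIELDS]
    + ["v2_global_judgement_physician", "v2_global_judgement_patient"]
)

PNQ_COLUMNS = tuple(f"pnq_{i:02d}" for i in range(1, N_ITEMS + 1))
PBQ_COLUMNS = tuple(f"pbq_{i:02d}" for i in range(1, N_ITEMS + 1))
COHORT_COLUMNS: tuple[str, ...] = (
    ("id", "age_years", "sex", "asthma") + PNQ_COLUMNS + PBQ_COLUMNS + CONVERGENT_COLUMNS
)


def _allowed_levels(column: str) -> Optional[tuple[str, ...]]:
    if column.startswith(("v1_", "v2_")):
        base = column[3:]
        if base in _VISIT_FIELDS:
            return _VISIT_FIELDS[base]
        if base.startswith("global_judgement"):
            return JUDGEMENT_LEVELS
    return None


def age_group_for(age_years: float) -> Population:
    """Age 5-12 -> children; 13-17 -> adolescents (12-year-olds are children)."""
    if 5 <= age_years < 13:
        return Population.CHILDREN
    if 13 <= age_years <= 17:
        return Population.ADOLESCENTS
    raise SchemaError(f"age {age_years} outside the instrument's 5-17 range")


@dataclass(frozen=True)
class Respondent:
    id: str
    age_years: float
    sex: Sex
    asthma: bool
    pnq: tuple[ResponseValue, ...]
    pbq: tuple[ResponseValue, ...]
    convergent: Mapping[str, Optional[object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pnq) != N_ITEMS or len(self.pbq) != N_ITEMS:
            raise SchemaError(
                f"respondent {self.id}: PNQ/PBQ must each have {N_ITEMS} entries"
            )
        self.age_group  # validates the range
        for col in ("v1_vas_avg", "v1_vas_peak", "v2_vas_avg", "v2_vas_peak"):
            v = self.convergent.get(col)
            if v is not None and not (0 <= v <= 10):
                raise SchemaError(f"respondent {self.id}: {col}={v} outside 0..10")

    @property
    def age_group(self) -> Population:
        return age_group_for(self.age_years)


@dataclass(frozen=True)
class Cohort:
    instrument: Instrument
    respondents: tuple[Respondent, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.respondents]
        if len(set(ids)) != len(ids):
            raise SchemaError("respondent ids are not unique")
        object.__setattr__(self, "respondents", tuple(self.respondents))

    def __len__(self) -> int:
        return len(self.respondents)

    def subset(self, population: Union[Population, str]) -> "Cohort":
        population = Population(population) if isinstance(population, str) else population
        return Cohort(
            self.instrument,
            tuple(r for r in self.respondents if r.age_group is population),
        )

    def pnq_raw_matrix(self) -> np.ndarray:
        """(n, 19) float matrix; NaN = missing, -1 = not-applicable, else 0-4."""
        return np.array(
            [[response_to_code(v) for v in r.pnq] for r in self.respondents], dtype=float
        ).reshape(len(self), N_ITEMS)

    def pbq_raw_matrix(self) -> np.ndarray:
        return np.array(
            [[response_to_code(v) for v in r.pbq] for r in self.respondents], dtype=float
        ).reshape(len(self), N_ITEMS)

    def convergent_series(self, column: str) -> list[Optional[object]]:
        return [r.convergent.get(column) for r in self.respondents]


# ---------------------------------------------------------------------------
# Instrument I/O


def builtin_instrument() -> Instrument:
    """The bundled 19-item PBI-AR-K with both wordings per item."""
    text = resources.files("pbi_ark.data").joinpath("pbi_ar_k.json").read_text("utf-8")
    return load_instrument(text)


def load_instrument(document: Union[str, Path]) -> Instrument:
    """Parse an instrument definition from JSON text or a file path."""
    if isinstance(document, Path):
        document = document.read_text("utf-8")
    try:
        raw = json.loads(document)
    except json.JSONDecodeError as exc:
        raise SchemaError(f"instrument definition is not valid JSON: {exc}") from exc
    for key in ("name", "scale_labels", "not_apply_label", "items"):
        if key not in raw:
            raise SchemaError(f"instrument definition missing field {key!r}")
    items = []
    for entry in raw["items"]:
        for key in ("id", "need_text", "benefit_text"):
            if key not in entry:
                raise SchemaError(f"item entry missing field {key!r}: {entry}")
        items.append(Item(int(entry["id"]), entry["need_text"], entry["benefit_text"]))
    return Instrument(
        name=raw["name"],
        items=tuple(items),
        scale_labels=tuple(raw["scale_labels"]),
        not_apply_label=raw["not_apply_label"],
    )


def save_instrument(instrument: Instrument, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(instrument.to_dict(), indent=2) + "\n", "utf-8")


# ---------------------------------------------------------------------------
# Cohort CSV I/O
#
# Dialect: one row per respondent; response cells hold "0".."4", the
# not-apply token "NA", or are empty (missing).  Categorical convergent
# cells hold the level tokens defined above; VAS cells hold integers 0-10.


def _decode_response(cell: str, row: int, column: str) -> ResponseValue:
    cell = cell.strip()
    if cell == "":
        return MISSING
    if cell == NOT_APPLY_TOKEN:
        return NOT_APPLICABLE
    try:
        level = int(cell)
    except ValueError:
        raise CohortParseError(f"unparseable response {cell!r}", row, column) from None
    if not 0 <= level <= 4:
        raise CohortParseError(f"response level {level} outside 0..4", row, column)
    return ResponseValue.ordinal(level)


def _decode_convergent(cell: str, row: int, column: str) -> Optional[object]:
    cell = cell.strip()
    if cell == "":
        return None
    if column.endswith(("vas_avg", "vas_peak")):
        try:
            value = int(cell)
        except ValueError:
            raise CohortParseError(f"unparseable VAS value {cell!r}", row, column) from None
        if not 0 <= value <= 10:
            raise CohortParseError(f"VAS value {value} outside 0..10", row, column)
        return value
    levels = _allowed_levels(column)
    if levels is not None and cell not in levels:
        raise CohortParseError(
            f"level {cell!r} not in {list(levels)}", row, column
        )
    return cell


def read_cohort(file: Union[str, Path], instrument: Optional[Instrument] = None) -> Cohort:
    """Read a cohort CSV; rejects out-of-range codes rather than coercing them."""
    instrument = instrument or builtin_instrument()
    df = pd.read_csv(file, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise SchemaError(f"unknown columns: {unknown}")
    required = [c for c in ("id", "age_years", "sex", "asthma") + PNQ_COLUMNS + PBQ_COLUMNS]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing columns: {missing_cols}")

    respondents = []
    for i, rec in enumerate(df.to_dict("records")):
        row = i + 2  # 1-based, after the header
        try:
            age = float(rec["age_years"])
        except ValueError:
            raise CohortParseError(
                f"unparseable age {rec['age_years']!r}", row, "age_years"
            ) from None
        try:
            sex = Sex(rec["sex"].strip().lower())
        except ValueError:
            raise CohortParseError(f"unknown sex {rec['sex']!r}", row, "sex") from None
        asthma_token = rec["asthma"].strip().lower()
        if asthma_token not in ("true", "false", "1", "0", "yes", "no"):
            raise CohortParseError(f"unparseable flag {rec['asthma']!r}", row, "asthma")
        asthma = asthma_token in ("true", "1", "yes")
        pnq = tuple(_decode_response(rec[c], row, c) for c in PNQ_COLUMNS)
        pbq = tuple(_decode_response(rec[c], row, c) for c in PBQ_COLUMNS)
        convergent = {
            c: _decode_convergent(rec[c], row, c) for c in CONVERGENT_COLUMNS if c in rec
        }
        try:
            respondents.append(
                Respondent(rec["id"], age, sex, asthma, pnq, pbq, convergent)
            )
        except SchemaError as exc:
            raise CohortParseError(str(exc), row, None) from exc
    return Cohort(instrument, tuple(respondents))


def _encode_response(value: ResponseValue) -> str:
    if value.state is ResponseState.ORDINAL:
        return str(value.level)
    if value.state is ResponseState.NOT_APPLICABLE:
        return NOT_APPLY_TOKEN
    return ""


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for r in cohort.respondents:
        rec: dict[str, object] = {
            "id": r.id,
            "age_years": f"{r.age_years:g}",
            "sex": r.sex.value,
            "asthma": "true" if r.asthma else "false",
        }
        for c, v in zip(PNQ_COLUMNS, r.pnq):
            rec[c] = _encode_response(v)
        for c, v in zip(PBQ_COLUMNS, r.pbq):
            rec[c] = _encode_response(v)
        for c in CONVERGENT_COLUMNS:
            v = r.convergent.get(c)
            rec[c] = "" if v is None else str(v)
        rows.append(rec)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(cohort: Cohort, file: Union[str, Path]) -> None:
    cohort_to_frame(cohort).to_csv(file, index=False)
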