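"""Subject-level lipid data model, derived quantities, file I/O and cohort
inclusion filtering.

All lipid concentrations are milligrams per decilitre (mg/dL). The model
stores the three measured panel values (total cholesterol, HDL cholesterol,
triglycerides) and derives non-HDL cholesterol, LDL cholesterol (Sampson
equation), the inverse of HDL cholesterol and the natural log of
triglycerides — the transformed features the downstream phenotyping and
risk-index machinery consumes.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import DomainError, SchemaError, UnitError

logger = logging.getLogger(__name__)

#: Canonical CSV column order for cohort files.
CANONICAL_COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "tc",
    "hdlc",
    "tg",
    "apob",
    "on_lipid_lowering",
    "event",
    "time",
)

#: Default inclusion window in years (bounds inclusive).
DEFAULT_MIN_AGE = 40.0
DEFAULT_MAX_AGE = 70.0


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


_SEX_ALIASES = {
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
    "m": Sex.MALE,
    "male": Sex.MALE,
}


def parse_sex(value: object) -> Sex | None:
    """Map F/M/female/male (case-insensitive) to :class:`Sex`.

    Returns ``None`` for missing values; raises :class:`DomainError` for an
    unrecognised non-missing value.
    """
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, Sex):
        return value
    key = str(value).strip().lower()
    if key in ("", "nan"):
        return None
    try:
        return _SEX_ALIASES[key]
    except KeyError:
        raise DomainError(f"unrecognised sex value: {value!r}") from None


class DerivedLipids(NamedTuple):
    nhdlc: float  # mg/dL
    ldlc: float  # mg/dL, Sampson estimate
    inv_h: float  # dL/mg
    ln_tg: float  # ln(mg/dL)


def sampson_ldl(tc: float, hdlc: float, tg: float) -> float:
    """Sampson-equation LDL cholesterol estimate (mg/dL).

    Valid at high triglyceride concentrations where Friedewald fails. A
    negative result is returned as-is with a logged warning (no clamping):
    it signals an out-of-range panel, and silently flooring it would hide
    that from the caller.
    """
    nhdlc = tc - hdlc
    ldlc = (
        tc / 0.948
        - hdlc / 0.971
        - (tg / 8.56 + tg * nhdlc / 2140.0 - tg * tg / 16100.0)
        - 9.44
    )
    if ldlc < 0:
        logger.warning(
            "Sampson LDL estimate negative (%.2f mg/dL) for tc=%.1f hdlc=%.1f tg=%.1f",
            ldlc, tc, hdlc, tg,
        )
    return ldlc


def derive_panel(tc: float, hdlc: float, tg: float) -> DerivedLipids:
    """Compute (nhdlc, ldlc, inv_h, ln_tg) from a measured panel.

    Preconditions: tc, hdlc, tg strictly positive and hdlc < tc.
    """
    if not (tc > 0 and hdlc > 0 and tg > 0):
        raise DomainError(
            f"lipid values must be strictly positive (tc={tc}, hdlc={hdlc}, tg={tg})"
        )
    if not hdlc < tc:
        raise DomainError(f"hdlc ({hdlc}) must be below tc ({tc})")
    return DerivedLipids(
        nhdlc=tc - hdlc,
        ldlc=sampson_ldl(tc, hdlc, tg),
        inv_h=1.0 / hdlc,
        ln_tg=math.log(tg),
    )


@dataclass(frozen=True)
class LipidPanel:
    """One subject's lipid panel, demographics and optional ASCVD outcome.

    Derived quantities are exposed as properties so they can never drift
    out of sync with the raw values.
    """

    subject_id: str
    tc: float
    hdlc: float
    tg: float
    age: float | None = None
    sex: Sex | None = None
    apob: float | None = None
    on_lipid_lowering: bool | None = None
    event: bool | None = None
    time: float | None = None

    def __post_init__(self) -> None:
        if not (self.tc > 0 and self.hdlc > 0 and self.tg > 0):
            raise DomainError(
                f"{self.subject_id}: lipids must be strictly positive"
            )
        if not self.hdlc < self.tc:
            raise DomainError(
                f"{self.subject_id}: hdlc ({self.hdlc}) must be below tc ({self.tc})"
            )
        if self.event is not None and self.time is None:
            raise DomainError(f"{self.subject_id}: event recorded without follow-up time")
        if self.time is not None and self.time < 0:
            raise DomainError(f"{self.subject_id}: negative follow-up time")

    @property
    def nhdlc(self) -> float:
        return self.tc - self.hdlc

    @property
    def ldlc(self) -> float:
        return sampson_ldl(self.tc, self.hdlc, self.tg)

    @property
    def inv_h(self) -> float:
        return 1.0 / self.hdlc

    @property
    def ln_tg(self) -> float:
        return math.log(self.tg)


# Rejection reason codes used by parse_cohort / apply_inclusion.
REASON_MISSING_LIPID = "missing_lipid"
REASON_NONPOSITIVE_LIPID = "nonpositive_lipid"
REASON_HDLC_NOT_BELOW_TC = "hdlc_not_below_tc"
REASON_EVENT_WITHOUT_TIME = "event_without_time"
REASON_NEGATIVE_TIME = "negative_time"
REASON_INVALID_SEX = "invalid_sex"
REASON_AGE_RANGE = "age_range"
REASON_MISSING_AGE = "missing_age"
REASON_MEDICATION = "medication"


@dataclass
class CohortTable:
    """Ordered collection of valid :class:`LipidPanel` records.

    ``n_rejected`` counts excluded rows by reason code and ``rejected``
    lists (subject_id, reason) pairs for the rejection report.
    """

    records: list[LipidPanel] = field(default_factory=list)
    source_label: str = ""
    n_rejected: Counter = field(default_factory=Counter)
    rejected: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = [i for i, c in Counter(ids).items() if c > 1]
            raise DomainError(f"duplicate subject_id values: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[LipidPanel]:
        return iter(self.records)

    def to_dataframe(self, derived: bool = False) -> pd.DataFrame:
        """Raw fields as a DataFrame; ``derived=True`` appends nhdlc, ldlc,
        inv_h, ln_tg columns."""
        rows = []
        for r in self.records:
            row = {
                "subject_id": r.subject_id,
                "age": r.age,
                "sex": r.sex.value if r.sex is not None else None,
                "tc": r.tc,
                "hdlc": r.hdlc,
                "tg": r.tg,
                "apob": r.apob,
                "on_lipid_lowering": r.on_lipid_lowering,
                "event": r.event,
                "time": r.time,
            }
            if derived:
                row.update(nhdlc=r.nhdlc, ldlc=r.ldlc, inv_h=r.inv_h, ln_tg=r.ln_tg)
            rows.append(row)
        cols = list(CANONICAL_COLUMNS) + (
            ["nhdlc", "ldlc", "inv_h", "ln_tg"] if derived else []
        )
        return pd.DataFrame(rows, columns=cols)

    def feature_array(self, names: Iterable[str]) -> np.ndarray:
        """Column-stacked array of the named panel attributes."""
        names = list(names)
        return np.array(
            [[getattr(r, n) for n in names] for r in self.records], dtype=float
        )


def _float_or_none(value: object) -> float | None:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n", "0.0", "1.0"}


def _bool_or_none(value: object) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("", "nan"):
        return None
    if s in _TRUTHY or s == "1.0":
        return True
    if s in {"0", "false", "f", "no", "n", "0.0"}:
        return False
    try:
        return bool(float(s))
    except ValueError:
        raise DomainError(f"unrecognised boolean value: {value!r}") from None


def parse_cohort(
    path: str,
    column_map: Mapping[str, str] | None = None,
    source_label: str | None = None,
    units: str = "mg/dL",
) -> CohortTable:
    """Read a cohort CSV into a :class:`CohortTable`.

    Parameters
    ----------
    path:
        CSV file with a header row. Canonical column names are
        ``subject_id, age, sex, tc, hdlc, tg, apob, on_lipid_lowering,
        event, time``; only ``tc, hdlc, tg`` are required.
    column_map:
        Optional mapping from canonical names to the file's actual header
        names for non-canonical files.
    units:
        Must be ``"mg/dL"``; anything else raises :class:`UnitError`
        (no automatic conversion is performed).

    Rows with missing or non-positive tc/hdlc/tg, hdlc >= tc, an event flag
    without a follow-up time, a negative time, or an unparseable sex value
    are excluded and counted by reason; row order is otherwise preserved.
    """
    if units != "mg/dL":
        raise UnitError(f"only mg/dL input is supported, got {units!r}")
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    column_map = dict(column_map or {})

    def col(name: str) -> str | None:
        actual = column_map.get(name, name)
        return actual if actual in df.columns else None

    for required in ("tc", "hdlc", "tg"):
        if col(required) is None:
            raise SchemaError(
                f"required column {required!r} not found in {path} "
                f"(header: {list(df.columns)})"
            )

    has_id = col("subject_id") is not None
    records: list[LipidPanel] = []
    n_rejected: Counter = Counter()
    rejected: list[tuple[str, str]] = []

    for i, row in df.iterrows():
        sid = str(row[col("subject_id")]) if has_id else f"row{i}"

        def get(name: str) -> object:
            c = col(name)
            return row[c] if c is not None else None

        tc = _float_or_none(get("tc"))
        hdlc = _float_or_none(get("hdlc"))
        tg = _float_or_none(get("tg"))
        if tc is None or hdlc is None or tg is None:
            n_rejected[REASON_MISSING_LIPID] += 1
            rejected.append((sid, REASON_MISSING_LIPID))
            continue
        if tc <= 0 or hdlc <= 0 or tg <= 0:
            n_rejected[REASON_NONPOSITIVE_LIPID] += 1
            rejected.append((sid, REASON_NONPOSITIVE_LIPID))
            continue
        if hdlc >= tc:
            n_rejected[REASON_HDLC_NOT_BELOW_TC] += 1
            rejected.append((sid, REASON_HDLC_NOT_BELOW_TC))
            continue
        try:
            sex = parse_sex(get("sex"))
        except DomainError:
            n_rejected[REASON_INVALID_SEX] += 1
            rejected.append((sid, REASON_INVALID_SEX))
            continue
        event = _bool_or_none(get("event"))
        time = _float_or_none(get("time"))
        if event is not None and time is None:
            n_rejected[REASON_EVENT_WITHOUT_TIME] += 1
            rejected.append((sid, REASON_EVENT_WITHOUT_TIME))
            continue
        if time is not None and time < 0:
            n_rejected[REASON_NEGATIVE_TIME] += 1
            rejected.append((sid, REASON_NEGATIVE_TIME))
            continue
        records.append(
            LipidPanel(
                subject_id=sid,
                tc=tc,
                hdlc=hdlc,
                tg=tg,
                age=_float_or_none(get("age")),
                sex=sex,
                apob=_float_or_none(get("apob")),
                on_lipid_lowering=_bool_or_none(get("on_lipid_lowering")),
                event=event,
                time=time,
            )
        )

    return CohortTable(
        records=records,
        source_label=source_label if source_label is not None else str(path),
        n_rejected=n_rejected,
        rejected=rejected,
    )


def write_cohort(cohort: CohortTable, path: str, derived: bool = False) -> None:
    """Write a cohort to CSV with canonical columns at fixed decimal
    precision (round-trips through :func:`parse_cohort`)."""
    df = cohort.to_dataframe(derived=derived)
    # booleans as 0/1 so the round-trip is unambiguous
    for c in ("on_lipid_lowering", "event"):
        df[c] = df[c].map(lambda v: None if v is None else int(v))
    df.to_csv(path, index=False, float_format="%.10g")


def write_rejections(cohort: CohortTable, path: str) -> None:
    """Write the rejection report as CSV ``subject_id,reason``."""
    pd.DataFrame(cohort.rejected, columns=["subject_id", "reason"]).to_csv(
        path, index=False
    )


def apply_inclusion(
    cohort: CohortTable,
    min_age: float = DEFAULT_MIN_AGE,
    max_age: float = DEFAULT_MAX_AGE,
) -> CohortTable:
    """Apply the study inclusion criteria.

    Retains records with ``min_age <= age <= max_age`` (bounds inclusive)
    that are not on lipid-lowering medication. A missing
    ``on_lipid_lowering`` flag is treated as False with a logged warning;
    a missing age excludes the record. Exclusions are counted by reason on
    top of the cohort's existing rejection counts, so the operation is
    idempotent on its own output.
    """
    records: list[LipidPanel] = []
    n_rejected = Counter(cohort.n_rejected)
    rejected = list(cohort.rejected)
    warned_missing_med = False
    for r in cohort.records:
        if r.age is None:
            n_rejected[REASON_MISSING_AGE] += 1
            rejected.append((r.subject_id, REASON_MISSING_AGE))
            continue
        if not (min_age <= r.age <= max_age):
            n_rejected[REASON_AGE_RANGE] += 1
            rejected.append((r.subject_id, REASON_AGE_RANGE))
            continue
        if r.on_lipid_lowering is None and not warned_missing_med:
            logger.warning(
                "on_lipid_lowering missing for some records; treating as False"
            )
            warned_missing_med = True
        if r.on_lipid_lowering is True:
            n_rejected[REASON_MEDICATION] += 1
            rejected.append((r.subject_id, REASON_MEDICATION))
            continue
        records.append(r)
    return CohortTable(
        records=records,
        source_label=cohort.source_label,
        n_rejected=n_rejected,
        rejected=rejected,
    )
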