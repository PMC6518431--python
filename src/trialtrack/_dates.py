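"""Calendar-date primitives: precision-flagged dates and month arithmetic.

Registries report many dates at month granularity ("2010-03").  Such dates
are stored as a concrete day plus a precision flag so that every computation
works on real ``datetime.date`` objects while the imputation stays auditable.
The imputation direction is a property of the field's role:

* ``first`` (start and registration dates): impute the first day of the
  month, biasing registration-delay classification toward *prospective*;
* ``last`` (completion, publication, summary dates): impute the last day of
  the month, biasing window checks toward *published in time*.

Both biases are deliberate benefit-of-the-doubt conventions.
"""

from __future__ import annotations

import calendar
import datetime as dt
import re
from enum import Enum
from typing import Literal, Optional

from pydantic import BaseModel

from .errors import SchemaError


class Precision(str, Enum):
    day = "day"
    month = "month"


class Actuality(str, Enum):
    actual = "actual"
    estimated = "estimated"


class ImpreciseDate(BaseModel, frozen=True):
    """A calendar date together with the precision it was reported at."""

    date: dt.date
    precision: Precision = Precision.day

    def isoformat(self) -> str:
        if self.precision is Precision.month:
            return f"{self.date.year:04d}-{self.date.month:02d}"
        return self.date.isoformat()

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")
_DAY_RE = re.compile(r"^(\d{4})-(\d{2})-(\d{2})$")

Impute = Literal["first", "last"]


def month_start(year: int, month: int) -> dt.date:
    return dt.date(year, month, 1)


def month_end(year: int, month: int) -> dt.date:
    return dt.date(year, month, calendar.monthrange(year, month)[1])


def parse_imprecise(text: Optional[str], impute: Impute) -> Optional[ImpreciseDate]:
    """Parse ``YYYY-MM-DD`` (day precision) or ``YYYY-MM`` (month precision).

    Empty/None input returns None.  Month-precision dates are imputed to the
    first or last day of the month according to ``impute``; day-precision
    dates are never altered.
    """
    if text is None:
        return None
    text = text.strip()
    if not text:
        return None
    m = _DAY_RE.match(text)
    if m:
        try:
            d = dt.date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
        except ValueError as exc:
            raise SchemaError(f"invalid date {text!r}: {exc}") from None
        return ImpreciseDate(date=d, precision=Precision.day)
    m = _MONTH_RE.match(text)
    if m:
        year, month = int(m.group(1)), int(m.group(2))
        if not 1 <= month <= 12:
            raise SchemaError(f"invalid date {text!r}: month out of range")
        d = month_start(year, month) if impute == "first" else month_end(year, month)
        return ImpreciseDate(date=d, precision=Precision.month)
    raise SchemaError(f"unparseable date {text!r} (expected YYYY-MM-DD or YYYY-MM)")


def add_months(d: dt.date, months: int) -> dt.date:
    """Calendar-month addition with end-of-month clamping.

    Jan 31 + 1 month -> Feb 28 (or 29 in a leap year).  This mirrors how
    registries and regulators phrase month-grained deadlines.
    """
    total = d.year * 12 + (d.month - 1) + months
    year, month0 = divmod(total, 12)
    month = month0 + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)
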