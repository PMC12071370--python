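"""Deidentification transforms: double-hashed patient IDs and epoch date recoding.

Two transforms protect indirect identifiers:

* Patient identifiers are hashed twice with SHA-256 — once with a salt
  held by the contributing site, once with a salt held by the central
  platform — so neither party alone can reverse the mapping.
* Calendar dates are never collected. Clinical durations arrive as time
  intervals (days, weeks or months) and, where a FHIR element demands
  actual dates, are recoded into a pseudo-period anchored at the Unix
  epoch date 1970-01-01 whose span preserves the collected interval.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from datetime import date

from dateutil.relativedelta import relativedelta

EPOCH = date(1970, 1, 1)

INTERVAL_UNITS = ("days", "weeks", "months")


@dataclass(frozen=True)
class TimeInterval:
    """A deidentified duration: non-negative value plus unit."""

    value: int
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in INTERVAL_UNITS:
            raise ValueError(f"unknown interval unit {self.unit!r}")
        if self.value < 0:
            raise ValueError("interval value must be non-negative")


@dataclass(frozen=True)
class PseudoPeriod:
    """A pseudo-date period standing in for a real calendar period.

    ``start`` is always the epoch anchor; the span realizes the source
    interval (weeks as exactly 7 days, months by calendar-month addition
    from day 1).
    """

    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start != EPOCH:
            raise ValueError("pseudo-periods must start at 1970-01-01")
        if self.end < self.start:
            raise ValueError("period end precedes start")


def hash_patient_id(local_id: str, site_salt: str, platform_salt: str) -> str:
    """Double-hash a local patient identifier into a platform identifier.

    Stage 1 (at the site): SHA-256 over ``site_salt + local_id``.
    Stage 2 (at the platform): SHA-256 over ``platform_salt + stage1``.
    Both digests are lowercase hex; the result is deterministic.
    """
    if not local_id:
        raise ValueError("local_id must be non-empty")
    stage1 = hashlib.sha256((site_salt + local_id).encode("utf-8")).hexdigest()
    stage2 = hashlib.sha256((platform_salt + stage1).encode("utf-8")).hexdigest()
    return stage2


def recode_interval(interval: TimeInterval) -> PseudoPeriod:
    """Recode a collected time interval into an epoch-anchored pseudo-period."""
    if interval.unit == "days":
        end = EPOCH + relativedelta(days=interval.value)
    elif interval.unit == "weeks":
        end = EPOCH + relativedelta(weeks=interval.value)
    else:  # months: calendar addition, never ambiguous from day 1
        end = EPOCH + relativedelta(months=interval.value)
    return PseudoPeriod(start=EPOCH, end=end)


def decode_period(period: PseudoPeriod, unit: str) -> TimeInterval:
    """Recover the interval a pseudo-period encodes, in the requested unit.

    Only exactly representable spans decode (e.g. a 10-day span is not a
    whole number of weeks); anything else raises ``ValueError``.
    """
    if unit not in INTERVAL_UNITS:
        raise ValueError(f"unknown interval unit {unit!r}")
    if period.start != EPOCH:
        raise ValueError("period does not start at the epoch anchor")
    days = (period.end - period.start).days
    if unit == "days":
        return TimeInterval(days, "days")
    if unit == "weeks":
        if days % 7:
            raise ValueError(f"{days}-day span is not a whole number of weeks")
        return TimeInterval(days // 7, "weeks")
    # months
    if period.end.day != 1:
        raise ValueError("span is not a whole number of calendar months")
    months = (period.end.year - EPOCH.year) * 12 + (period.end.month - EPOCH.month)
    return TimeInterval(months, "months")
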