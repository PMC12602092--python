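"""Otolith-derived ages and reader-precision statistics.

Integer age comes from counts of opaque zones in otolith thin sections read by
two independent readers. Fractional age adds the part of the year the fish was
alive past its assumed birth date (March 15, the median of the January-April
spawning peak), with all day counts divided by a fixed 365-day year.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._utils import logger

#: Assumed median birth date (month, day).
DEFAULT_BIRTH_MONTH_DAY: tuple[int, int] = (3, 15)


@dataclass
class FishRecord:
    """One fish: identity, capture metadata and otolith readings.

    ``integer_age`` is only set once both readers agree (see
    :func:`select_agreement_subset`); ``fractional_age`` is derived from the
    agreed zone count and the capture date.
    """

    fish_id: str
    water_body: str
    capture_date: _dt.date
    reader1_zones: int | None = None
    reader2_zones: int | None = None
    integer_age: int | None = None
    fractional_age: float | None = None
    total_length: float | None = None
    weight: float | None = None
    extra: dict = field(default_factory=dict)


def _most_recent_birthday(capture_date: _dt.date, birth_month_day: tuple[int, int]) -> _dt.date:
    month, day = birth_month_day
    candidate = _dt.date(capture_date.year, month, day)
    if candidate > capture_date:
        candidate = _dt.date(capture_date.year - 1, month, day)
    return candidate


def fractional_age(
    opaque_zones: int,
    capture_date: _dt.date,
    birth_month_day: tuple[int, int] = DEFAULT_BIRTH_MONTH_DAY,
) -> float:
    """Fractional age in years from an opaque-zone count and a capture date.

    Days alive among integer years = zones * 365; days alive in the last year
    = days elapsed since the most recent birth date on or before capture. The
    sum is divided by a fixed 365 (real calendar differences in the numerator,
    so a leap day passed since the birthday counts as one day).
    """
    if opaque_zones < 0:
        raise ValueError(f"opaque_zones must be >= 0, got {opaque_zones}")
    if not isinstance(capture_date, _dt.date):
        raise TypeError("capture_date must be a datetime.date")
    days_last_year = (capture_date - _most_recent_birthday(capture_date, birth_month_day)).days
    return (opaque_zones * 365 + days_last_year) / 365.0


def select_agreement_subset(records: Iterable[FishRecord]) -> list[FishRecord]:
    """Keep fish for which both readers agree on the zone count.

    Sets ``integer_age`` to the agreed count and fills ``fractional_age``.
    Records with a missing reader count are excluded with a logged warning.
    """
    kept: list[FishRecord] = []
    for rec in records:
        if rec.reader1_zones is None or rec.reader2_zones is None:
            logger.warning("fish %s excluded: missing reader count", rec.fish_id)
            continue
        if rec.reader1_zones != rec.reader2_zones:
            continue
        rec.integer_age = int(rec.reader1_zones)
        rec.fractional_age = fractional_age(rec.integer_age, rec.capture_date)
        kept.append(rec)
    return kept


def iape(zone_counts_by_reader: Sequence[Sequence[float]] | np.ndarray) -> float:
    """Index of average percent error (Beamish-Fournier), in percent.

    ``zone_counts_by_reader`` is fish x readers. For fish j read R times with
    mean x-bar_j, APE_j = (100 / R) * sum_i |x_ij - x-bar_j| / x-bar_j; the
    index is the mean of APE_j over fish. Fish with mean 0 are skipped.
    """
    counts = np.asarray(zone_counts_by_reader, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a fish x readers array with >= 2 readers")
    if counts.shape[0] < 1:
        raise ValueError("need at least one fish")
    means = counts.mean(axis=1)
    ok = means > 0
    if not ok.all():
        logger.warning("iape: skipping %d fish with zero mean count", int((~ok).sum()))
    if not ok.any():
        raise ValueError("all fish have zero mean zone count")
    r = counts.shape[1]
    ape = (100.0 / r) * (np.abs(counts[ok] - means[ok, None]) / means[ok, None]).sum(axis=1)
    return float(ape.mean())


def intra_observer_error(
    pairs_by_reader: Sequence[tuple[Sequence[int], Sequence[int]]],
) -> float:
    """Mean over readers of (disagreements between original and recount) / recounts."""
    if len(pairs_by_reader) == 0:
        raise ValueError("need at least one reader")
    rates = []
    for original, recount in pairs_by_reader:
        orig = np.asarray(original)
        rec = np.asarray(recount)
        if orig.shape != rec.shape:
            raise ValueError("original and recount vectors differ in length")
        if orig.size == 0:
            raise ValueError("empty recount vector")
        rates.append(float(np.mean(orig != rec)))
    return float(np.mean(rates))
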