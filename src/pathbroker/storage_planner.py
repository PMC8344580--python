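"""Capacity estimation and two-tier storage assignment.

A scanning operation producing roughly 1 GB per WSI at a million scans
a year needs about 1 PB of new storage annually.  Because most slides
are reviewed soon after scanning, a two-tier design keeps recently
scanned slides on fast (tier-1, flash) storage and migrates older ones
to economical tier-2 disk.  The tier-1 window is chosen from the
first-access histogram: the smallest number of months after scanning
within which a target fraction of the digitally reviewed slides was
first opened.

Months are calendar-agnostic 30.44-day bins; month 1 covers accesses
within (0, 1] month of scanning.  Never-accessed slides are excluded
from the access curve's denominator but still tier-assigned by scan
date.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .records import ImageRecord

DAYS_PER_MONTH = 30.44
GB_PER_PB = 1e6  # decimal convention: 10^6 GB = 1 PB


@dataclass(frozen=True)
class AccessLogEntry:
    image_id: str
    scan_date: datetime.date
    first_access_date: Optional[datetime.date] = None  # None = never opened

    def __post_init__(self):
        if (
            self.first_access_date is not None
            and self.first_access_date < self.scan_date
        ):
            raise ValueError(
                f"{self.image_id}: first access {self.first_access_date} "
                f"before scan {self.scan_date}"
            )


@dataclass(frozen=True)
class AccessCurve:
    """Cumulative fraction of accessed WSI first opened by month m."""

    points: tuple[tuple[int, float], ...]  # (month, cumulative fraction), sorted
    n_accessed: int
    n_total: int

    def fraction_at(self, month: int) -> float:
        out = 0.0
        for m, f in self.points:
            if m <= month:
                out = f
            else:
                break
        return out

    @property
    def max_fraction(self) -> float:
        return self.points[-1][1] if self.points else 0.0


def estimate_annual_storage(
    avg_size_gb_per_wsi: float, scans_per_year: float
) -> float:
    """Projected storage need in PB/year (bilinear in both inputs)."""
    if avg_size_gb_per_wsi <= 0 or scans_per_year <= 0:
        raise ValueError("average WSI size and scanning rate must be positive")
    return avg_size_gb_per_wsi * scans_per_year / GB_PER_PB


def month_after_scan(scan_date: datetime.date, access_date: datetime.date) -> int:
    """1-based 30.44-day month bin of an access (same-day access → month 1)."""
    days = (access_date - scan_date).days
    if days < 0:
        raise ValueError("access before scan")
    return max(1, math.ceil(days / DAYS_PER_MONTH))


def build_access_curve(log: Iterable[AccessLogEntry]) -> AccessCurve:
    """Cumulative first-access curve over the digitally reviewed WSI.

    Only accessed entries enter the denominator; an empty log or one
    with no accessed entry is an error.
    """
    entries = list(log)
    if not entries:
        raise ValueError("empty access log")
    months = [
        month_after_scan(e.scan_date, e.first_access_date)
        for e in entries
        if e.first_access_date is not None
    ]
    if not months:
        raise ValueError("no accessed entries in log")
    n = len(months)
    counts: dict[int, int] = {}
    for m in months:
        counts[m] = counts.get(m, 0) + 1
    cum, points = 0, []
    for m in sorted(counts):
        cum += counts[m]
        points.append((m, cum / n))
    return AccessCurve(points=tuple(points), n_accessed=n, n_total=len(entries))


def select_tier1_window(curve: AccessCurve, coverage_target: float) -> int:
    """Smallest month m with cumulative access fraction ≥ target."""
    if not 0 < coverage_target <= 1:
        raise ValueError("coverage_target must be in (0, 1]")
    for m, f in curve.points:
        if f >= coverage_target:
            return m
    raise ValueError(
        f"coverage target {coverage_target} unreachable; "
        f"maximum attainable fraction is {curve.max_fraction:.4f}"
    )


def assign_tiers(
    images: Sequence[ImageRecord],
    window_months: int,
    as_of_date: datetime.date,
) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Partition images: scanned within the window → tier-1, else tier-2."""
    cutoff_days = window_months * DAYS_PER_MONTH
    tier1, tier2 = [], []
    for img in images:
        if img.scan_date > as_of_date:
            raise ValueError(f"{img.image_id} scanned after as_of_date")
        age_days = (as_of_date - img.scan_date).days
        (tier1 if age_days <= cutoff_days else tier2).append(img)
    return tier1, tier2


def read_access_log(path: Union[str, Path]) -> list[AccessLogEntry]:
    """CSV columns: image_id, scan_date, first_access_date (blank = never)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            AccessLogEntry(
                image_id=row.image_id,
                scan_date=datetime.date.fromisoformat(row.scan_date),
                first_access_date=(
                    datetime.date.fromisoformat(row.first_access_date)
                    if row.first_access_date
                    else None
                ),
            )
        )
    return out
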