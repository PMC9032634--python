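"""Data model and I/O for personal exposure measurements.

A measurement is one worker-shift respirable-dust concentration (mg/m3,
8-hour time-weighted average) tagged with the homogeneous exposure group
(HEG) it belongs to, the calendar year, and whether it comes from the
current monitoring campaign or a past (historical) one.

Concentrations are modelled as lognormal, so all inference runs on the
natural logarithms of the measurements.  :class:`HEGStats` carries the
sufficient statistics of a group — the count ``n``, the mean ``ybar`` and
the sample standard deviation ``s_y`` (n−1 denominator) of the
log-concentrations — from which the geometric mean ``gm = exp(ybar)`` and
geometric standard deviation ``gsd = exp(s_y)`` follow.  Natural logs are
used throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ValidationError

CAMPAIGNS = ("current", "past")

#: Required columns of a measurement CSV, in write order.
CSV_COLUMNS = ("heg_id", "year", "concentration", "campaign")


@dataclass(frozen=True)
class ExposureRecord:
    """One worker-shift exposure measurement on the raw (mg/m3) scale."""

    heg_id: str
    year: int
    concentration: float
    campaign: str = "current"

    def __post_init__(self) -> None:
        if not self.heg_id:
            raise ValidationError("heg_id must be a non-empty string")
        if not self.concentration > 0:
            raise ValidationError(
                f"concentration must be positive (lognormal support), "
                f"got {self.concentration!r}"
            )
        if self.campaign not in CAMPAIGNS:
            raise ValidationError(
                f"campaign must be one of {CAMPAIGNS}, got {self.campaign!r}"
            )


@dataclass(frozen=True)
class HEGStats:
    """Sufficient statistics of one HEG's log-concentrations.

    ``ybar`` and ``s_y`` (sample SD, n−1 denominator) are the quantities the
    lognormal model consumes; ``am``/``sd`` are the raw-scale arithmetic
    summaries and may be absent when the stats were reconstructed from a
    printed GM/GSD pair.
    """

    n: int
    ybar: float
    s_y: float
    am: float | None = None
    sd: float | None = None
    heg_id: str | None = None
    campaign: str | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if self.s_y < 0:
            raise ValidationError(f"s_y must be >= 0, got {self.s_y}")

    @property
    def gm(self) -> float:
        """Geometric mean, exp(ybar), mg/m3."""
        return math.exp(self.ybar)

    @property
    def gsd(self) -> float:
        """Geometric standard deviation, exp(s_y), unitless (>= 1)."""
        return math.exp(self.s_y)


def read_measurements(path) -> list[ExposureRecord]:
    """Read a measurement CSV into a list of :class:`ExposureRecord`.

    The file must have a header row with columns ``heg_id``, ``year``,
    ``concentration`` and ``campaign`` (comma-separated, UTF-8, decimal
    point).  Rows with non-positive concentrations are rejected with a
    :class:`ValidationError` naming the offending row.
    """
    frame = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"measurement CSV {path} is missing column(s): {missing}")
    records = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        conc = float(row.concentration)
        if not conc > 0:
            raise ValidationError(
                f"row {idx}: concentration must be positive, got {conc!r}"
            )
        records.append(
            ExposureRecord(
                heg_id=str(row.heg_id),
                year=int(row.year),
                concentration=conc,
                campaign=str(row.campaign),
            )
        )
    return records


def write_measurements(records: Iterable[ExposureRecord], path) -> None:
    """Write records to the measurement CSV format (see :func:`read_measurements`)."""
    frame = pd.DataFrame(
        [(r.heg_id, r.year, r.concentration, r.campaign) for r in records],
        columns=list(CSV_COLUMNS),
    )
    frame.to_csv(path, index=False)


def summarize_heg(records: Sequence[ExposureRecord]) -> HEGStats:
    """Compute the log-scale sufficient statistics of one HEG campaign.

    All records must share ``heg_id`` and ``campaign`` and there must be at
    least two of them (the sample SD needs n >= 2).
    """
    records = list(records)
    n = len(records)
    if n < 2:
        raise InsufficientDataError(
            f"need at least 2 measurements to summarize a HEG, got {n}"
        )
    heg_ids = {r.heg_id for r in records}
    if len(heg_ids) != 1:
        raise ValidationError(f"records mix HEGs: {sorted(heg_ids)}")
    campaigns = {r.campaign for r in records}
    if len(campaigns) != 1:
        raise ValidationError(f"records mix campaigns: {sorted(campaigns)}")
    x = np.array([r.concentration for r in records], dtype=float)
    logs = np.log(x)
    return HEGStats(
        n=n,
        ybar=float(logs.mean()),
        s_y=float(logs.std(ddof=1)),
        am=float(x.mean()),
        sd=float(x.std(ddof=1)),
        heg_id=records[0].heg_id,
        campaign=records[0].campaign,
    )


def stats_from_table(
    n: int,
    gm: float,
    gsd: float,
    heg_id: str | None = None,
    campaign: str | None = None,
) -> HEGStats:
    """Reconstruct log-scale sufficient statistics from a printed GM/GSD pair.

    ``ybar = ln(gm)`` and ``s_y = ln(gsd)``; the arithmetic summaries are left
    unset because the lognormal model never needs them.
    """
    if n < 2:
        raise InsufficientDataError(f"n must be >= 2, got {n}")
    if not gm > 0:
        raise ValidationError(f"gm must be positive, got {gm}")
    if gsd < 1:
        raise ValidationError(f"gsd must be >= 1, got {gsd}")
    return HEGStats(
        n=n,
        ybar=math.log(gm),
        s_y=math.log(gsd),
        heg_id=heg_id,
        campaign=campaign,
    )
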