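"""SAMI Code of Practice comparator: P90 point estimate and exposure category.

The South African Mining Industry Code of Practice classifies a HEG by where
the 90th percentile (P90) of its current campaign falls relative to the
occupational exposure limit (OEL):

    category 1  P90 <  0.1 * OEL   very highly controlled
    category 2  P90 in [0.1, 0.5) * OEL   highly controlled
    category 3  P90 in [0.5, 1.0) * OEL   adequately controlled
    category 4  P90 >= OEL         poorly controlled

Lower bounds are inclusive.  The category drives the minimum sampling
frequency (annual / 6-monthly / 3-monthly for categories 2-4); that schedule
is informational here, not enforced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import DEFAULT_OEL, Z90
from .errors import InsufficientDataError, ValidationError
from .exposure_data import ExposureRecord, summarize_heg

METHODS = ("empirical", "normal", "lognormal")

#: Human-readable control-quality label per category.
CATEGORY_LABELS = {
    1: "very highly controlled",
    2: "highly controlled",
    3: "adequately controlled",
    4: "poorly controlled",
}


@dataclass(frozen=True)
class SAMIResult:
    p90: float
    category: int
    method: str


def sami_p90(records: Sequence[ExposureRecord], method: str = "empirical") -> float:
    """P90 point estimate of a HEG's measurements, mg/m3.

    ``empirical`` is the 90th sample percentile with numpy's default linear
    interpolation between order statistics.  ``normal`` assumes a normal
    exposure distribution, ``am + z90 * sd``; ``lognormal`` assumes lognormal,
    ``gm * gsd ** z90`` (z90 = 1.2816).
    """
    if method not in METHODS:
        raise ValidationError(f"unknown P90 method {method!r}; expected one of {METHODS}")
    if len(records) < 2:
        raise InsufficientDataError(f"need >= 2 measurements, got {len(records)}")
    if method == "empirical":
        x = np.array([r.concentration for r in records], dtype=float)
        return float(np.percentile(x, 90))
    stats = summarize_heg(records)
    if method == "normal":
        return stats.am + Z90 * stats.sd
    return stats.gm * stats.gsd**Z90


def sami_category(p90: float, oel: float = DEFAULT_OEL) -> int:
    """Map a P90 estimate to SAMI exposure category 1-4 (lower-inclusive bins)."""
    if p90 < 0:
        raise ValidationError(f"p90 must be >= 0, got {p90}")
    if not oel > 0:
        raise ValidationError(f"oel must be positive, got {oel}")
    if p90 < 0.1 * oel:
        return 1
    if p90 < 0.5 * oel:
        return 2
    if p90 < oel:
        return 3
    return 4


def sami_assess(
    records: Sequence[ExposureRecord],
    oel: float = DEFAULT_OEL,
    method: str = "empirical",
) -> SAMIResult:
    """Convenience wrapper: P90 estimate plus its exposure category."""
    p90 = sami_p90(records, method=method)
    return SAMIResult(p90=p90, category=sami_category(p90, oel), method=method)
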