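"""Synthetic lognormal exposure data, including moment-matched study fixtures.

The study this package implements analyses nine homogeneous exposure groups
(HEGs) of South African underground coal-mine workers, each with a current
monitoring campaign and a corresponding historical (past) campaign.  Only the
per-campaign summary statistics are public, so :data:`HEG_SUMMARIES` records
them and :func:`study_fixtures` regenerates synthetic raw measurements whose
log-scale sample moments match those summaries exactly.

Because the lognormal posterior depends on the data only through
``(n, ybar, s_y)``, moment-matched fixtures make every downstream result
independent of the synthetic seed: any seed yields the same posterior.
Moment matching is an affine map on the log scale (standardize the normal
draw, then rescale and shift to the target moments), so it preserves the
normality of the generating sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .exposure_data import ExposureRecord, HEGStats, stats_from_table, write_measurements


class CampaignSummary(NamedTuple):
    """Printed summary of one HEG campaign: year, count, arithmetic mean/SD,
    geometric mean/GSD (concentrations in mg/m3)."""

    year: int
    n: int
    am: float
    sd: float
    gm: float
    gsd: float


#: Study conditions: summary statistics of the nine HEGs' current and past
#: monitoring campaigns (243 current-campaign measurements in total).
HEG_SUMMARIES: dict[str, dict[str, CampaignSummary]] = {
    "HEG A": {
        "current": CampaignSummary(2018, 14, 2.20, 1.96, 1.52, 2.55),
        "past": CampaignSummary(2017, 20, 2.00, 1.35, 1.51, 2.30),
    },
    "HEG B": {
        "current": CampaignSummary(2019, 21, 2.36, 1.45, 1.58, 3.56),
        "past": CampaignSummary(2018, 21, 1.93, 2.52, 0.69, 5.96),
    },
    "HEG C": {
        "current": CampaignSummary(2018, 13, 2.42, 2.22, 1.91, 1.96),
        "past": CampaignSummary(2017, 19, 1.48, 0.95, 1.20, 2.03),
    },
    "HEG D": {
        "current": CampaignSummary(2017, 52, 0.71, 0.66, 0.42, 3.29),
        "past": CampaignSummary(2016, 53, 1.46, 1.69, 0.76, 3.59),
    },
    "HEG E": {
        "current": CampaignSummary(2018, 35, 1.32, 1.74, 0.62, 3.53),
        "past": CampaignSummary(2017, 50, 1.18, 1.01, 0.78, 2.78),
    },
    "HEG F": {
        "current": CampaignSummary(2018, 20, 1.24, 1.90, 0.60, 3.80),
        "past": CampaignSummary(2017, 32, 0.96, 0.82, 0.60, 3.05),
    },
    "HEG G": {
        "current": CampaignSummary(2019, 24, 2.42, 1.70, 1.93, 2.01),
        "past": CampaignSummary(2018, 40, 0.69, 0.91, 0.29, 4.63),
    },
    "HEG H": {
        "current": CampaignSummary(2018, 38, 1.43, 1.75, 0.74, 3.50),
        "past": CampaignSummary(2017, 45, 0.90, 0.82, 0.62, 2.44),
    },
    "HEG I": {
        "current": CampaignSummary(2019, 26, 2.04, 1.58, 1.29, 3.67),
        "past": CampaignSummary(2018, 39, 1.02, 0.91, 0.59, 3.27),
    },
}

#: Seed under which :func:`study_fixtures` is deterministic.
DEFAULT_FIXTURE_SEED = 20407


class FixturePair(NamedTuple):
    current: list[ExposureRecord]
    past: list[ExposureRecord]


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of one synthetic HEG campaign."""

    heg_id: str
    n: int
    gm: float
    gsd: float
    seed: int
    match_moments: bool = True

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError(f"n must be >= 2, got {self.n}")
        if not self.gm > 0:
            raise ValidationError(f"gm must be positive, got {self.gm}")
        if self.gsd < 1:
            raise ValidationError(f"gsd must be >= 1, got {self.gsd}")


def generate_heg(
    spec: SyntheticSpec, year: int = 2018, campaign: str = "current"
) -> list[ExposureRecord]:
    """Draw one synthetic HEG campaign.

    Log-concentrations are drawn Normal(ln gm, (ln gsd)^2).  With
    ``match_moments`` the draw is affinely standardized on the log scale so
    that the *sample* mean-log equals ``ln gm`` and the sample SD-log
    (n−1 denominator) equals ``ln gsd`` exactly.
    """
    rng = np.random.default_rng(spec.seed)
    mu, sigma = np.log(spec.gm), np.log(spec.gsd)
    logs = rng.normal(mu, sigma if sigma > 0 else 1.0, size=spec.n)
    if spec.match_moments:
        if sigma == 0.0:
            logs = np.full(spec.n, mu)
        else:
            sd = logs.std(ddof=1)
            z = (logs - logs.mean()) / sd
            logs = mu + sigma * z
    return [
        ExposureRecord(
            heg_id=spec.heg_id,
            year=year,
            concentration=float(c),
            campaign=campaign,
        )
        for c in np.exp(logs)
    ]


def study_fixtures(seed: int = DEFAULT_FIXTURE_SEED) -> dict[str, FixturePair]:
    """Moment-matched synthetic measurements for all nine HEGs, both campaigns.

    Deterministic given ``seed``; per-campaign child seeds are derived so the
    groups are mutually independent.
    """
    fixtures: dict[str, FixturePair] = {}
    for i, (heg_id, campaigns) in enumerate(sorted(HEG_SUMMARIES.items())):
        pair = {}
        for j, campaign in enumerate(("current", "past")):
            summ = campaigns[campaign]
            child_seed = (seed * 100003 + 7919 * i + 104729 * j) % 2**31
            spec = SyntheticSpec(
                heg_id=heg_id,
                n=summ.n,
                gm=summ.gm,
                gsd=summ.gsd,
                seed=child_seed,
                match_moments=True,
            )
            pair[campaign] = generate_heg(spec, year=summ.year, campaign=campaign)
        fixtures[heg_id] = FixturePair(pair["current"], pair["past"])
    return fixtures


def fixture_stats(heg_id: str, campaign: str = "current") -> HEGStats:
    """Sufficient statistics of one study HEG campaign, straight from the
    printed GM/GSD summary (no synthetic sampling involved)."""
    summ = HEG_SUMMARIES[heg_id][campaign]
    return stats_from_table(summ.n, summ.gm, summ.gsd, heg_id=heg_id, campaign=campaign)


def write_fixture_csv(path, seed: int = DEFAULT_FIXTURE_SEED) -> None:
    """Write all fixture measurements (both campaigns) to one measurement CSV."""
    records = []
    for pair in study_fixtures(seed).values():
        records.extend(pair.current)
        records.extend(pair.past)
    write_measurements(records, path)
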