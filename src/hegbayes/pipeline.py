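"""End-to-end study orchestration: fixtures or CSV in, compliance report out.

For every HEG with current-campaign data the pipeline computes the SAMI CoP
P90 comparator and fits the lognormal model twice — once under the
non-informative uniform prior and once under the informative prior elicited
from that HEG's historical campaign (skipped, with a logged warning, when no
historical data exist).  Results are collected into a
:class:`ComplianceReport` and written as CSV tables plus an optional P95
comparison figure.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .bayes import (
    MCMCConfig,
    P95Constraint,
    PosteriorDraws,
    UniformPrior,
    elicit_informative_prior,
    gibbs_sample,
)
from .constants import DEFAULT_OEL
from .errors import ValidationError
from .exposure_data import HEGStats, read_measurements, summarize_heg
from .posterior import (
    CategoryProbabilities,
    Diagnostics,
    PosteriorSummary,
    category_probabilities,
    compute_diagnostics,
    summarize_posterior,
)
from .sami_cop import SAMIResult, sami_assess
from .synthetic import study_fixtures

logger = logging.getLogger("hegbayes")

REGIMES = ("non_informative", "informative")

SUMMARY_COLUMNS = [
    "heg_id", "regime", "sami_p90", "sami_category",
    "gm_median", "gm_cri_lower", "gm_cri_upper",
    "gsd_median", "gsd_cri_lower", "gsd_cri_upper",
    "p95_median", "p95_cri_lower", "p95_cri_upper",
]
CATEGORY_COLUMNS = [
    "heg_id", "regime", "p95_median",
    "category1_pct", "category2_pct", "category3_pct", "category4_pct",
]
DIAGNOSTIC_COLUMNS = [
    "heg_id", "regime", "parameter", "rhat", "ess_bulk", "ess_tail", "flagged",
]


@dataclass
class StudyConfig:
    """Tunable knobs of a compliance study run."""

    oel: float = DEFAULT_OEL
    p95_cap_multiplier: float | None = None  # None disables the P95 bound
    n0: int = 5
    prior_mode: str = "moments"  # 'moments' or 'subsample'
    sami_method: str = "empirical"
    n_chains: int = 4
    n_iter: int = 20_000
    n_warmup: int = 2_000
    thin: int = 1
    seed: int = 20407

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def mcmc(self, seed: int) -> MCMCConfig:
        return MCMCConfig(
            n_iter=self.n_iter,
            n_warmup=self.n_warmup,
            n_chains=self.n_chains,
            seed=seed,
            thin=self.thin,
        )

    def constraint(self) -> P95Constraint:
        if self.p95_cap_multiplier is None:
            return P95Constraint(enabled=False, oel=self.oel)
        return P95Constraint(
            enabled=True, multiplier=self.p95_cap_multiplier, oel=self.oel
        )


@dataclass
class RegimeResult:
    regime: str
    prior_params: dict
    summary: PosteriorSummary
    categories: CategoryProbabilities
    diagnostics: Diagnostics
    truncated_mass: dict
    seed: int
    draws: PosteriorDraws | None = None


@dataclass
class HEGResult:
    heg_id: str
    stats: HEGStats
    sami: SAMIResult
    regimes: dict = field(default_factory=dict)


@dataclass
class ComplianceReport:
    hegs: dict
    oel: float
    config: StudyConfig
    config_hash: str
    warnings: list = field(default_factory=list)


def _fit_seed(config: StudyConfig, heg_index: int, regime: str) -> int:
    return (config.seed + 1_000_003 * heg_index + 613 * REGIMES.index(regime)) % 2**31


def _fit_regime(
    config: StudyConfig,
    stats: HEGStats,
    regime: str,
    seed: int,
    past_records=None,
    keep_draws: bool = False,
) -> RegimeResult:
    constraint = config.constraint()
    if regime == "non_informative":
        prior = UniformPrior()
        prior_params = {"type": "uniform", **asdict(prior)}
    else:
        cap = None
        if config.p95_cap_multiplier is not None:
            cap = config.p95_cap_multiplier * config.oel
        prior = elicit_informative_prior(
            past_records,
            n0=config.n0,
            seed=seed,
            mode=config.prior_mode,
            p95_cap=cap,
        )
        prior_params = {"type": "informative", **asdict(prior)}
    draws = gibbs_sample(stats, prior, constraint, config.mcmc(seed))
    result = RegimeResult(
        regime=regime,
        prior_params=prior_params,
        summary=summarize_posterior(draws),
        categories=category_probabilities(draws, config.oel),
        diagnostics=compute_diagnostics(draws),
        truncated_mass=draws.truncated_mass,
        seed=seed,
        draws=draws if keep_draws else None,
    )
    logger.info(
        "%s %s: n=%d ybar=%.4f s_y=%.4f gm_med=%.3f p95_med=%.3f "
        "truncated_mass mu=%.2e sigma2=%.2e",
        stats.heg_id, regime, stats.n, stats.ybar, stats.s_y,
        result.summary.gm.median, result.summary.p95.median,
        draws.truncated_mass["mu"], draws.truncated_mass["sigma2"],
    )
    return result


def _load_groups(source) -> dict:
    """Map heg_id -> {'current': records, 'past': records} from a source."""
    if source == "fixtures":
        return {
            heg: {"current": pair.current, "past": pair.past}
            for heg, pair in study_fixtures().items()
        }
    records = read_measurements(source)
    groups: dict = {}
    for r in records:
        groups.setdefault(r.heg_id, {}).setdefault(r.campaign, []).append(r)
    return groups


def run_study(
    config: StudyConfig | None = None,
    source="fixtures",
    keep_draws: bool = False,
) -> ComplianceReport:
    """Run the full compliance study and return the report.

    ``source`` is either the literal string ``"fixtures"`` (the built-in
    nine-HEG synthetic study) or a path to a measurement CSV.  Deterministic
    given the config seed.
    """
    config = config or StudyConfig()
    groups = _load_groups(source)
    report = ComplianceReport(
        hegs={}, oel=config.oel, config=config, config_hash=config.hash()
    )
    for idx, heg_id in enumerate(sorted(groups)):
        campaigns = groups[heg_id]
        if "current" not in campaigns:
            msg = f"{heg_id}: no current-campaign data; HEG skipped"
            logger.warning(msg)
            report.warnings.append(msg)
            continue
        current = campaigns["current"]
        stats = summarize_heg(current)
        heg_result = HEGResult(
            heg_id=heg_id,
            stats=stats,
            sami=sami_assess(current, oel=config.oel, method=config.sami_method),
        )
        heg_result.regimes["non_informative"] = _fit_regime(
            config, stats, "non_informative",
            _fit_seed(config, idx, "non_informative"), keep_draws=keep_draws,
        )
        past = campaigns.get("past")
        if past:
            heg_result.regimes["informative"] = _fit_regime(
                config, stats, "informative",
                _fit_seed(config, idx, "informative"),
                past_records=past if config.prior_mode == "subsample"
                else summarize_heg(past),
                keep_draws=keep_draws,
            )
        else:
            msg = f"{heg_id}: no historical data; informative fit skipped"
            logger.warning(msg)
            report.warnings.append(msg)
        report.hegs[heg_id] = heg_result
    return report


def _summary_frame(report: ComplianceReport) -> pd.DataFrame:
    rows = []
    for heg_id in sorted(report.hegs):
        h = report.hegs[heg_id]
        for regime in REGIMES:
            if regime not in h.regimes:
                continue
            s = h.regimes[regime].summary
            rows.append({
                "heg_id": heg_id, "regime": regime,
                "sami_p90": h.sami.p90, "sami_category": h.sami.category,
                "gm_median": s.gm.median, "gm_cri_lower": s.gm.cri_lower,
                "gm_cri_upper": s.gm.cri_upper,
                "gsd_median": s.gsd.median, "gsd_cri_lower": s.gsd.cri_lower,
                "gsd_cri_upper": s.gsd.cri_upper,
                "p95_median": s.p95.median, "p95_cri_lower": s.p95.cri_lower,
                "p95_cri_upper": s.p95.cri_upper,
            })
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def _category_frame(report: ComplianceReport) -> pd.DataFrame:
    rows = []
    for heg_id in sorted(report.hegs):
        h = report.hegs[heg_id]
        for regime in REGIMES:
            if regime not in h.regimes:
                continue
            r = h.regimes[regime]
            p1, p2, p3, p4 = r.categories.as_tuple()
            rows.append({
                "heg_id": heg_id, "regime": regime,
                "p95_median": r.summary.p95.median,
                "category1_pct": 100 * p1, "category2_pct": 100 * p2,
                "category3_pct": 100 * p3, "category4_pct": 100 * p4,
            })
    return pd.DataFrame(rows, columns=CATEGORY_COLUMNS)


def _diagnostic_frame(report: ComplianceReport) -> pd.DataFrame:
    rows = []
    n_chains = report.config.n_chains
    for heg_id in sorted(report.hegs):
        for regime in REGIMES:
            h = report.hegs[heg_id]
            if regime not in h.regimes:
                continue
            d = h.regimes[regime].diagnostics
            bad = d.flagged(n_chains)
            for param in ("mu", "sigma"):
                rows.append({
                    "heg_id": heg_id, "regime": regime, "parameter": param,
                    "rhat": d.rhat[param], "ess_bulk": d.ess_bulk[param],
                    "ess_tail": d.ess_tail[param], "flagged": param in bad,
                })
    return pd.DataFrame(rows, columns=DIAGNOSTIC_COLUMNS)


def write_report(report: ComplianceReport, outdir, persist_draws: bool = False) -> dict:
    """Write the report tables (and optionally the raw draws) under ``outdir``.

    Produces ``posterior_summaries.csv``, ``category_probabilities.csv``,
    ``diagnostics.csv`` and ``run.log``; with ``persist_draws``, one
    ``draws/<heg>_<regime>.csv`` per fit (requires the report to have been
    run with ``keep_draws=True``).  Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "summaries": outdir / "posterior_summaries.csv",
        "categories": outdir / "category_probabilities.csv",
        "diagnostics": outdir / "diagnostics.csv",
        "log": outdir / "run.log",
    }
    _summary_frame(report).to_csv(paths["summaries"], index=False)
    _category_frame(report).to_csv(paths["categories"], index=False)
    _diagnostic_frame(report).to_csv(paths["diagnostics"], index=False)

    lines = [
        f"config_hash: {report.config_hash}",
        f"config: {json.dumps(asdict(report.config), sort_keys=True)}",
        f"oel: {report.oel}",
    ]
    for heg_id in sorted(report.hegs):
        h = report.hegs[heg_id]
        lines.append(
            f"{heg_id}: n={h.stats.n} ybar={h.stats.ybar:.6f} s_y={h.stats.s_y:.6f} "
            f"sami_p90={h.sami.p90:.4f} sami_category={h.sami.category}"
        )
        for regime in REGIMES:
            if regime not in h.regimes:
                continue
            r = h.regimes[regime]
            flagged = r.diagnostics.flagged(report.config.n_chains)
            lines.append(
                f"  {regime}: seed={r.seed} "
                f"truncated_mass_mu={r.truncated_mass['mu']:.3e} "
                f"truncated_mass_sigma2={r.truncated_mass['sigma2']:.3e} "
                f"diagnostics_flagged={flagged or 'none'}"
            )
    for msg in report.warnings:
        lines.append(f"warning: {msg}")
    paths["log"].write_text("\n".join(lines) + "\n")

    if persist_draws:
        draws_dir = outdir / "draws"
        draws_dir.mkdir(exist_ok=True)
        for heg_id in sorted(report.hegs):
            for regime, r in report.hegs[heg_id].regimes.items():
                if r.draws is None:
                    continue
                d = r.draws
                n_chains, n_draws = d.mu.shape
                frame = pd.DataFrame({
                    "chain": [c for c in range(n_chains) for _ in range(n_draws)],
                    "mu": d.mu.ravel(),
                    "sigma": d.sigma.ravel(),
                })
                name = f"{heg_id.replace(' ', '_')}_{regime}.csv"
                frame.to_csv(draws_dir / name, index=False)
        paths["draws"] = draws_dir
    return paths


def plot_p95_comparison(report: ComplianceReport, path) -> None:
    """Median and 95% CrI of the posterior P95 per HEG and regime, with the
    OEL reference line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    hegs = sorted(report.hegs)
    fig, ax = plt.subplots(figsize=(9, 5))
    offsets = {"non_informative": -0.12, "informative": 0.12}
    colors = {"non_informative": "tab:blue", "informative": "tab:orange"}
    for regime in REGIMES:
        xs, meds, lo_err, hi_err = [], [], [], []
        for i, heg_id in enumerate(hegs):
            h = report.hegs[heg_id]
            if regime not in h.regimes:
                continue
            s = h.regimes[regime].summary.p95
            xs.append(i + offsets[regime])
            meds.append(s.median)
            lo_err.append(s.median - s.cri_lower)
            hi_err.append(s.cri_upper - s.median)
        if xs:
            ax.errorbar(
                xs, meds, yerr=[lo_err, hi_err], fmt="o", capsize=3,
                color=colors[regime], label=regime.replace("_", "-"),
            )
    ax.axhline(report.oel, color="red", linestyle="--", label=f"OEL = {report.oel} mg/m3")
    ax.set_xticks(range(len(hegs)))
    ax.set_xticklabels(hegs, rotation=45, ha="right")
    ax.set_ylabel("posterior P95 (mg/m3), median and 95% CrI")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
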