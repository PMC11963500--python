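"""Seeded generator of synthetic country panels.

The generator emulates the statistical structure of the multi-country
inputs the analysis consumes: 126 low- and middle-income countries across
six WHO regions and three income groups, each with

* a 2000-2020 annual MMR series following a piecewise log-linear trend
  (0-2 breakpoints, segment APCs between -8% and +3%) observed with
  log-normal noise,
* cause-of-death shares drawn from a Dirichlet over the six aggregate
  causes, with the hemorrhage share split 24/3/73 into its components,
* baseline (2024) coverage for each registered intervention,
* a 2020 standard error and the implied 80% uncertainty interval.

Trend magnitudes per income group mirror the strata of real MMR estimates
(low income 300-700, lower-middle 70-400, upper-middle 10-170 per 100,000
in 2020).  Every country draws from its own random substream keyed by
(seed, index), so generated records do not depend on generation order.
Adjacent trend segments differ by at least a configurable APC gap so that
breakpoints are identifiable — a generator convenience, not a claim about
real series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mmrproj.core_data import (
    CAUSES,
    CauseProfile,
    CountryRecord,
    INCOME_GROUPS,
    MMRSeries,
    ValidationError,
    WHO_REGIONS,
    decompose_hemorrhage,
)
from mmrproj.impact import ui_from_se

#: Allocation of the 126 countries over (region, income group); counts are
#: loosely modelled on the real distribution of LMICs across WHO regions.
DEFAULT_ALLOCATION: tuple[tuple[str, str, int], ...] = (
    ("AFR", "low", 18), ("AFR", "lower_middle", 19), ("AFR", "upper_middle", 8),
    ("AMR", "low", 1), ("AMR", "lower_middle", 4), ("AMR", "upper_middle", 17),
    ("SEAR", "low", 1), ("SEAR", "lower_middle", 7), ("SEAR", "upper_middle", 2),
    ("EUR", "low", 0), ("EUR", "lower_middle", 5), ("EUR", "upper_middle", 12),
    ("EMR", "low", 4), ("EMR", "lower_middle", 6), ("EMR", "upper_middle", 4),
    ("WPR", "low", 0), ("WPR", "lower_middle", 10), ("WPR", "upper_middle", 8),
)

#: 2020 MMR range (per 100,000 live births) by income group.
DEFAULT_MMR_RANGES: dict[str, tuple[float, float]] = {
    "low": (300.0, 700.0),
    "lower_middle": (70.0, 400.0),
    "upper_middle": (10.0, 170.0),
}

#: Dirichlet mean shares over the six aggregate causes (hemorrhage is the
#: aggregate of its three components before decomposition).
DEFAULT_CAUSE_MEANS: dict[str, float] = {
    "hemorrhage": 0.27,
    "hypertensive_disorders": 0.16,
    "sepsis": 0.10,
    "abortion": 0.08,
    "other_direct": 0.14,
    "indirect": 0.25,
}

_AGGREGATE_CAUSES = tuple(DEFAULT_CAUSE_MEANS)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic panel generator.

    All MMR magnitudes are per 100,000 live births; noise and APCs act on
    the natural-log scale of MMR (log-normal observation noise, conjugate
    to the log-linear joinpoint trend model).
    """

    n_countries: int = 126
    allocation: tuple[tuple[str, str, int], ...] = DEFAULT_ALLOCATION
    mmr_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MMR_RANGES)
    )
    start_year: int = 2000
    end_year: int = 2020
    max_breakpoints: int = 2
    min_segment_years: int = 6
    apc_range: tuple[float, float] = (-8.0, 3.0)  # percent per year
    min_apc_gap: float = 2.0  # pp between adjacent segments
    noise_sd: float = 0.01  # sd of log-MMR observation noise
    cause_concentration: float = 50.0
    coverage_range: tuple[float, float] = (0.2, 0.9)
    relative_se_2020: float = 0.08
    live_births_range: tuple[int, int] = (20_000, 3_000_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries < 1:
            raise ValidationError("n_countries must be >= 1")
        for name, (lo, hi) in (
            ("apc_range", self.apc_range),
            ("coverage_range", self.coverage_range),
            ("live_births_range", self.live_births_range),
        ):
            if lo >= hi:
                raise ValidationError(f"{name} must be well-ordered, got {lo}..{hi}")
        for grp, (lo, hi) in self.mmr_ranges.items():
            if not (0 < lo < hi):
                raise ValidationError(f"mmr_ranges[{grp}] must satisfy 0 < low < high")
        if self.start_year >= self.end_year:
            raise ValidationError("start_year must precede end_year")
        if self.noise_sd < 0 or self.relative_se_2020 < 0:
            raise ValidationError("noise parameters must be >= 0")
        for region, income, count in self.allocation:
            if region not in WHO_REGIONS or income not in INCOME_GROUPS or count < 0:
                raise ValidationError(f"bad allocation entry {(region, income, count)}")


@dataclass(frozen=True)
class GroundTruth:
    """The latent trend used to build one synthetic series."""

    iso3: str
    breakpoint_years: tuple[int, ...]
    segment_apcs: tuple[float, ...]


def _strata(config: GeneratorConfig) -> list[tuple[str, str]]:
    """Assign each country index a (region, income) stratum, cycling the
    allocation table proportionally when n_countries differs from its total."""
    cells = [(r, g) for r, g, count in config.allocation for _ in range(count)]
    if not cells:
        raise ValidationError("allocation table is empty")
    return [cells[i % len(cells)] for i in range(config.n_countries)]


def _rng_for(config: GeneratorConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(index,)))


def _draw_trend(
    rng: np.random.Generator, config: GeneratorConfig
) -> tuple[tuple[int, ...], tuple[float, ...]]:
    """Breakpoint years and per-segment APCs with identifiable slope changes."""
    years = config.end_year - config.start_year
    max_bp = min(config.max_breakpoints, years // config.min_segment_years - 1)
    n_bp = int(rng.integers(0, max(max_bp, 0) + 1))
    while True:
        offsets = np.sort(
            rng.choice(
                np.arange(config.min_segment_years, years - config.min_segment_years + 1),
                size=n_bp,
                replace=False,
            )
        )
        gaps = np.diff(np.concatenate(([0], offsets, [years])))
        if (gaps >= config.min_segment_years).all():
            break
    breakpoints = tuple(int(config.start_year + o) for o in offsets)

    lo, hi = config.apc_range
    apcs: list[float] = []
    for _ in range(n_bp + 1):
        while True:
            apc = float(rng.uniform(lo, hi))
            if not apcs or abs(apc - apcs[-1]) >= config.min_apc_gap:
                apcs.append(apc)
                break
    return breakpoints, tuple(apcs)


def generate_country(
    config: GeneratorConfig,
    index: int,
    intervention_ids: tuple[str, ...] = (),
) -> tuple[CountryRecord, GroundTruth]:
    """Generate one synthetic country and its latent ground truth.

    Deterministic for fixed ``(config.seed, index)`` regardless of how many
    other countries are generated.
    """
    rng = _rng_for(config, index)
    region, income = _strata(config)[index]
    iso3 = f"S{index:03d}"

    breakpoints, apcs = _draw_trend(rng, config)
    lo, hi = config.mmr_ranges[income]
    log_mmr_2020 = float(rng.uniform(math.log(lo), math.log(hi)))

    # build the latent log-linear path backwards from the 2020 anchor
    years = list(range(config.start_year, config.end_year + 1))
    slopes = [math.log(1.0 + a / 100.0) for a in apcs]
    edges = [config.start_year, *breakpoints, config.end_year]
    latent = {config.end_year: log_mmr_2020}
    for year in reversed(years[:-1]):
        seg = next(i for i in range(len(slopes)) if edges[i] <= year < edges[i + 1])
        latent[year] = latent[year + 1] - slopes[seg]

    noise = rng.normal(0.0, config.noise_sd, size=len(years)) if config.noise_sd > 0 else np.zeros(len(years))
    mmr = tuple(math.exp(latent[y] + e) for y, e in zip(years, noise))

    mmr_2020 = mmr[-1]
    se_2020 = config.relative_se_2020 * mmr_2020
    se = tuple(se_2020 if y == config.end_year else None for y in years)
    ui = ui_from_se(mmr_2020, se_2020)

    alpha = np.array(
        [DEFAULT_CAUSE_MEANS[c] for c in _AGGREGATE_CAUSES]
    ) * config.cause_concentration
    agg_shares = rng.dirichlet(alpha)
    shares = dict(zip(_AGGREGATE_CAUSES, agg_shares))
    hem = shares.pop("hemorrhage")
    ante, intra, post = decompose_hemorrhage(float(hem))
    profile = CauseProfile(
        {
            "antepartum_hemorrhage": ante,
            "intrapartum_hemorrhage": intra,
            "postpartum_hemorrhage": post,
            **{c: float(s) for c, s in shares.items()},
        }
    )

    c_lo, c_hi = config.coverage_range
    coverage = {iid: float(rng.uniform(c_lo, c_hi)) for iid in intervention_ids}

    b_lo, b_hi = config.live_births_range
    live_births = int(
        round(math.exp(rng.uniform(math.log(b_lo), math.log(b_hi))))
    )

    record = CountryRecord(
        iso3=iso3,
        region=region,
        income_group=income,
        live_births=live_births,
        series=MMRSeries(iso3=iso3, years=tuple(years), mmr=mmr, se=se),
        causes=profile,
        coverage=coverage,
        mmr_ui_2020=ui,
    )
    truth = GroundTruth(iso3=iso3, breakpoint_years=breakpoints, segment_apcs=apcs)
    return record, truth


def generate_panel(
    config: GeneratorConfig,
    intervention_ids: tuple[str, ...] = (),
) -> tuple[list[CountryRecord], list[GroundTruth]]:
    """Generate the full panel: ``n_countries`` records plus ground truth."""
    records, truths = [], []
    for index in range(config.n_countries):
        record, truth = generate_country(config, index, intervention_ids)
        records.append(record)
        truths.append(truth)
    return records, truths
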