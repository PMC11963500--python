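"""The cause-and-intervention impact model.

For a single intervention acting on a single cause, the model is the pair of
product formulas

    estimated MMR  = MMR * (1 - cause_share * coverage_change
                              * efficacy * affected_fraction)
    lives saved    = live_births * (MMR / 100,000) * cause_share
                              * coverage_change * efficacy * affected_fraction

Multiple interventions acting on the same cause combine multiplicatively on
the residual deaths (a LiST-style residual cascade): with per-intervention
effect e_i = coverage_change_i * efficacy_i * affected_fraction_i, residual
deaths for cause c are D_c * prod_i (1 - e_ic).  The cause's total deaths
averted are attributed to interventions in proportion to their independent
savings D_c * e_ic, rescaled so the attribution sums exactly to the total —
an order-independent rule that reduces to the printed single-intervention
formula when only one intervention targets the cause.

Background (non-intervention) mortality is held constant at the 2020 level
in scenario projections; only the sensitivity mode extrapolates the
2015-2020 trend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import norm

from mmrproj.core_data import (
    CAUSES,
    CountryRecord,
    Intervention,
    ValidationError,
    _check_fraction,
)
from mmrproj.scenarios import (
    BASELINE_YEAR,
    HORIZON_YEAR,
    Scenario,
    coverage_change,
    coverage_trajectory,
)

#: Standard-normal 90th percentile: half-width multiplier of an 80% interval.
Z_80 = float(norm.ppf(0.9))

#: Lower UI bounds are floored at this small positive MMR.
_MMR_EPS = 1e-9


@dataclass(frozen=True)
class ProjectionResult:
    """Projection for one country under one scenario in one year."""

    iso3: str
    scenario_id: int
    year: int
    mmr: float
    ui: tuple[float, float]
    residual_deaths: Mapping[str, float]  # by cause, deaths/yr
    lives_saved: Mapping[str, float]  # by intervention, deaths averted
    pct_reduction_vs_s0: float
    live_births: int

    @property
    def total_lives_saved(self) -> float:
        return sum(self.lives_saved.values())

    @property
    def total_residual_deaths(self) -> float:
        return sum(self.residual_deaths.values())


def _check_factors(cause_share, coverage_change_, efficacy, affected_fraction) -> None:
    _check_fraction("cause_share", cause_share)
    _check_fraction("coverage_change", coverage_change_)
    _check_fraction("efficacy", efficacy)
    _check_fraction("affected_fraction", affected_fraction)


def single_intervention_mmr(
    mmr: float,
    cause_share: float,
    coverage_change: float,
    efficacy: float,
    affected_fraction: float,
) -> float:
    """Estimated MMR after one intervention scales up against one cause."""
    if mmr <= 0:
        raise ValidationError("mmr must be > 0")
    _check_factors(cause_share, coverage_change, efficacy, affected_fraction)
    return mmr * (1.0 - cause_share * coverage_change * efficacy * affected_fraction)


def single_intervention_lives_saved(
    live_births: float,
    mmr: float,
    cause_share: float,
    coverage_change: float,
    efficacy: float,
    affected_fraction: float,
) -> float:
    """Additional maternal lives saved by one intervention in one year."""
    if live_births <= 0:
        raise ValidationError("live_births must be > 0")
    if mmr <= 0:
        raise ValidationError("mmr must be > 0")
    _check_factors(cause_share, coverage_change, efficacy, affected_fraction)
    return (
        live_births
        * (mmr / 100_000.0)
        * cause_share
        * coverage_change
        * efficacy
        * affected_fraction
    )


def apply_interventions(
    country: CountryRecord,
    registry: Sequence[Intervention],
    coverage_changes: Mapping[str, float],
) -> tuple[dict[str, float], dict[str, float]]:
    """Apply a set of interventions to a country's baseline deaths.

    Returns ``(residual_deaths_by_cause, lives_saved_by_intervention)``.
    ``coverage_changes`` maps intervention id to its coverage change (the
    scenario coverage in the projection year minus baseline coverage).
    """
    baseline_deaths = country.live_births * country.mmr_2020 / 100_000.0
    residual: dict[str, float] = {}
    independent: dict[str, dict[str, float]] = {c: {} for c in CAUSES}
    lives_saved: dict[str, float] = {iv.id: 0.0 for iv in registry}

    for cause in CAUSES:
        d_c = baseline_deaths * country.causes[cause]
        survive = 1.0
        for iv in registry:
            if cause not in iv.targets:
                continue
            efficacy, affected = iv.targets[cause]
            cc = coverage_changes.get(iv.id, 0.0)
            _check_fraction(f"coverage change for {iv.id}", cc)
            e = cc * efficacy * affected
            survive *= 1.0 - e
            independent[cause][iv.id] = d_c * e
        residual[cause] = d_c * survive
        averted = d_c - residual[cause]
        indep_total = sum(independent[cause].values())
        if indep_total > 0:
            scale = averted / indep_total
            for iid, saving in independent[cause].items():
                lives_saved[iid] += saving * scale
    return residual, lives_saved


def _scenario_coverage_changes(
    country: CountryRecord, scenario: Scenario, year: int
) -> dict[str, float]:
    changes = {}
    for iid, baseline in country.coverage.items():
        traj = coverage_trajectory(baseline, scenario, (scenario.baseline_year, year))
        changes[iid] = coverage_change(traj, year)
    return changes


def project(
    country: CountryRecord,
    scenario: Scenario,
    registry: Sequence[Intervention],
    year: int = HORIZON_YEAR,
    lives_saved_mode: str = "annual",
) -> ProjectionResult:
    """Project a country's MMR and lives saved under a scenario.

    ``lives_saved_mode`` is ``"annual"`` (deaths averted in the projection
    year, the default reporting convention) or ``"cumulative"`` (summed over
    every year from the first post-baseline year through ``year``).
    """
    if lives_saved_mode not in ("annual", "cumulative"):
        raise ValidationError(f"unknown lives_saved_mode {lives_saved_mode!r}")
    changes = _scenario_coverage_changes(country, scenario, year)
    residual, lives_saved = apply_interventions(country, registry, changes)

    if lives_saved_mode == "cumulative":
        lives_saved = {iid: 0.0 for iid in lives_saved}
        for y in range(scenario.baseline_year + 1, year + 1):
            _, annual = apply_interventions(
                country, registry, _scenario_coverage_changes(country, scenario, y)
            )
            for iid, v in annual.items():
                lives_saved[iid] += v

    est_mmr = sum(residual.values()) / country.live_births * 100_000.0
    ui = propagate_ui(country.mmr_2020, country.mmr_ui_2020, est_mmr)
    # scenario 0 never changes coverage, so its MMR is the baseline MMR
    pct_reduction = (country.mmr_2020 - est_mmr) / country.mmr_2020 * 100.0
    return ProjectionResult(
        iso3=country.iso3,
        scenario_id=scenario.id,
        year=year,
        mmr=est_mmr,
        ui=ui,
        residual_deaths=residual,
        lives_saved=lives_saved,
        pct_reduction_vs_s0=pct_reduction,
        live_births=country.live_births,
    )


def propagate_ui(
    baseline_mmr: float,
    baseline_ui: tuple[float, float],
    estimated_mmr: float,
) -> tuple[float, float]:
    """Propagate an 80% UI multiplicatively.

    Both bounds are scaled by the ratio of estimated to baseline MMR, so the
    relative width of the interval is preserved.
    """
    if baseline_mmr <= 0:
        raise ValidationError("baseline mmr must be > 0")
    low, high = baseline_ui
    if not low <= baseline_mmr <= high:
        raise ValidationError("baseline UI must bracket the baseline MMR")
    ratio = estimated_mmr / baseline_mmr
    return low * ratio, high * ratio


def ui_from_se(mmr: float, se: float) -> tuple[float, float]:
    """80% uncertainty interval (10th/90th percentiles) from a normal
    approximation: mmr ± z_0.9 * se, with the lower bound floored just
    above zero."""
    if se < 0:
        raise ValidationError("se must be >= 0")
    half = Z_80 * se
    return max(mmr - half, _MMR_EPS), mmr + half


def sensitivity_project(mmr_2020: float, apc_2015_2020: float, year: int) -> float:
    """Extrapolate MMR from 2020 by the 2015-2020 APC (sensitivity mode:
    coverage frozen, background trend continues)."""
    if year < 2020:
        raise ValidationError("sensitivity projection starts at 2020")
    if apc_2015_2020 <= -100.0:
        raise ValidationError("APC must be > -100%")
    return mmr_2020 * (1.0 + apc_2015_2020 / 100.0) ** (year - 2020)


def aggregate(
    results: Iterable[ProjectionResult],
    baseline: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Aggregate projections to a group (region, income group, or world).

    Group MMR is births-weighted: total residual deaths over total live
    births, times 100,000.  Lives saved are summed.  When ``baseline`` maps
    iso3 to baseline MMR, the group percent reduction is recomputed from the
    aggregated MMRs.
    """
    results = list(results)
    if not results:
        raise ValidationError("cannot aggregate an empty group")
    total_births = sum(r.live_births for r in results)
    total_deaths = sum(r.total_residual_deaths for r in results)
    group_mmr = total_deaths / total_births * 100_000.0
    out = {
        "mmr": group_mmr,
        "lives_saved": sum(r.total_lives_saved for r in results),
        "live_births": float(total_births),
        "n_countries": float(len(results)),
    }
    if baseline is not None:
        base_deaths = sum(baseline[r.iso3] * r.live_births / 100_000.0 for r in results)
        base_mmr = base_deaths / total_births * 100_000.0
        out["baseline_mmr"] = base_mmr
        out["pct_reduction_vs_s0"] = (base_mmr - group_mmr) / base_mmr * 100.0
    return out


def aggregate_records(records: Iterable[CountryRecord]) -> dict[str, float]:
    """Births-weighted 2020 MMR of a group of countries."""
    records = list(records)
    if not records:
        raise ValidationError("cannot aggregate an empty group")
    births = sum(r.live_births for r in records)
    deaths = sum(r.live_births * r.mmr_2020 / 100_000.0 for r in records)
    return {
        "mmr": deaths / births * 100_000.0,
        "live_births": float(births),
        "n_countries": float(len(records)),
    }
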