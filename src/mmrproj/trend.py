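"""Joinpoint regression on log-MMR: APC, AAPC, and trend classification.

The trend model is continuous piecewise-linear regression of ln(MMR) on
calendar year, with breakpoints ("joinpoints") restricted to observed years.
Within a segment the annual percent change is APC = (exp(slope) - 1) * 100;
over a multi-segment window the average annual percent change (AAPC) is the
segment-length-weighted geometric mean, AAPC = (exp(sum(w_s * slope_s) /
sum(w_s)) - 1) * 100.

Breakpoint count is selected by forward sequential nested-model F-tests:
the best k-breakpoint placement (by residual sum of squares) is accepted
over the best (k-1)-breakpoint fit only when the F-test for the two added
parameters is significant at a Bonferroni-corrected level — the correction
accounts for the number of admissible placements searched at that stage.
This uses the residual degrees of freedom directly, which keeps short noisy
annual series from sprouting spurious joinpoints where a fixed BIC penalty
would.  Candidate placements are enumerated exhaustively, which is cheap
for annual series (21 points admit at most three breakpoints with three
observations per segment).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import exp
from typing import Sequence

import numpy as np
from scipy.stats import f as f_dist

from mmrproj.core_data import MMRSeries

#: Residual floor per observation (log scale): perfect fits below this
#: precision are treated as exact ties so BIC parsimony decides.
_RSS_FLOOR_PER_OBS = 1e-18


class InsufficientDataError(ValueError):
    """Too few observations for the requested fit."""


@dataclass(frozen=True)
class Segment:
    """One linear piece of a joinpoint fit (years are inclusive)."""

    start_year: int
    end_year: int
    slope: float

    @property
    def apc(self) -> float:
        """Annual percent change implied by the log-scale slope."""
        return (exp(self.slope) - 1.0) * 100.0


@dataclass(frozen=True)
class JoinpointFit:
    """A fitted joinpoint model for one MMR series."""

    iso3: str
    years: tuple[int, ...]
    log_mmr: tuple[float, ...]
    breakpoints: tuple[int, ...]
    segments: tuple[Segment, ...]
    #: Per candidate breakpoint count: p-value of the F-test for accepting
    #: that count over one fewer (0.0 for the mandatory 0-breakpoint fit).
    scores: dict[int, float] = field(default_factory=dict)
    #: True when the series was too short to place any breakpoint.
    too_short: bool = False

    @property
    def start_year(self) -> int:
        return self.years[0]

    @property
    def end_year(self) -> int:
        return self.years[-1]


def _slope_ols(t: np.ndarray, y: np.ndarray) -> float:
    t = t - t.mean()
    return float(np.dot(t, y - y.mean()) / np.dot(t, t))


def fit_segment(
    series: MMRSeries, year_range: tuple[int, int] | None = None
) -> tuple[float, float]:
    """Least-squares fit of ln(MMR) on year over ``year_range`` (inclusive).

    Returns ``(slope, APC)`` where APC = (exp(slope) - 1) * 100.
    """
    years = np.asarray(series.years, dtype=float)
    logy = np.log(series.mmr)
    if year_range is not None:
        lo, hi = year_range
        mask = (years >= lo) & (years <= hi)
        years, logy = years[mask], logy[mask]
    if len(years) < 2:
        raise InsufficientDataError(
            f"{series.iso3}: need >= 2 observations in {year_range}, have {len(years)}"
        )
    slope = _slope_ols(years, logy)
    return slope, (exp(slope) - 1.0) * 100.0


def _hinge_design(t: np.ndarray, breakpoints: Sequence[float]) -> np.ndarray:
    cols = [np.ones_like(t), t - t[0]]
    cols.extend(np.maximum(0.0, t - b) for b in breakpoints)
    return np.column_stack(cols)


def _fit_placement(
    t: np.ndarray, y: np.ndarray, breakpoints: Sequence[float]
) -> tuple[float, np.ndarray]:
    """RSS and per-segment slopes of the continuous piecewise-linear fit."""
    X = _hinge_design(t, breakpoints)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    slopes = np.cumsum(beta[1:])  # slope of segment s = base slope + deltas
    return rss, slopes


def _admissible_placements(
    years: Sequence[int], max_breakpoints: int, min_obs_per_segment: int
) -> dict[int, list[tuple[int, ...]]]:
    """All breakpoint placements at observed years with enough observations
    per segment (a breakpoint year counts toward both adjacent segments)."""
    placements: dict[int, list[tuple[int, ...]]] = {0: [()]}
    interior = list(years[1:-1])
    index = {y: i for i, y in enumerate(years)}
    n = len(years)
    for k in range(1, max_breakpoints + 1):
        found = []
        for combo in itertools.combinations(interior, k):
            cuts = [0] + [index[b] for b in combo] + [n - 1]
            if all(b - a + 1 >= min_obs_per_segment for a, b in zip(cuts, cuts[1:])):
                found.append(combo)
        if not found:
            break
        placements[k] = found
    return placements


def fit_joinpoint(
    series: MMRSeries,
    max_breakpoints: int = 3,
    min_obs_per_segment: int = 3,
    alpha: float = 0.05,
) -> JoinpointFit:
    """Fit a joinpoint model to an annual MMR series.

    Exhaustively searches breakpoint placements at observed years, fits each
    by least squares (continuous in ln(MMR)), and grows the breakpoint count
    by forward sequential F-tests at level ``alpha`` (Bonferroni-corrected
    for the placements searched at each stage), so an extra joinpoint is
    kept only when it explains significantly more than noise.  A series too
    short to admit any breakpoint yields the single-segment fit flagged
    ``too_short``.
    """
    n = len(series)
    if n < 2:
        raise InsufficientDataError(f"{series.iso3}: need >= 2 observations, have {n}")
    t = np.asarray(series.years, dtype=float)
    y = np.log(series.mmr)

    placements = _admissible_placements(series.years, max_breakpoints, min_obs_per_segment)
    best_by_k: dict[int, tuple[float, tuple[int, ...], np.ndarray]] = {}
    for k, combos in placements.items():
        best = None
        for combo in combos:
            rss, slopes = _fit_placement(t, y, combo)
            if best is None or rss < best[0]:
                best = (rss, combo, slopes)
        best_by_k[k] = best

    # Select the largest breakpoint count whose best placement is
    # significant against the best placement with one fewer.  All counts are
    # evaluated (no early stopping): a single joinpoint can fail to improve
    # a down-up-down series even though two joinpoints fit it decisively.
    scores: dict[int, float] = {0: 0.0}
    chosen_k = 0
    for k in sorted(best_by_k):
        if k == 0:
            continue
        df_resid = n - (2 + 2 * k)
        if df_resid <= 0:
            break
        rss_prev = max(best_by_k[k - 1][0], n * _RSS_FLOOR_PER_OBS)
        rss_k = max(best_by_k[k][0], n * _RSS_FLOOR_PER_OBS)
        f_stat = ((rss_prev - rss_k) / 2.0) / (rss_k / df_resid)
        p_value = float(f_dist.sf(f_stat, 2, df_resid)) if f_stat > 0 else 1.0
        scores[k] = p_value
        if p_value < alpha / len(placements[k]):
            chosen_k = k
    _, breakpoints, slopes = best_by_k[chosen_k]

    edges = [series.years[0], *breakpoints, series.years[-1]]
    segments = tuple(
        Segment(start_year=a, end_year=b, slope=float(s))
        for a, b, s in zip(edges, edges[1:], slopes)
    )
    return JoinpointFit(
        iso3=series.iso3,
        years=series.years,
        log_mmr=tuple(float(v) for v in y),
        breakpoints=tuple(breakpoints),
        segments=segments,
        scores=scores,
        too_short=len(placements) == 1,
    )


def aapc(fit: JoinpointFit, year_range: tuple[int, int] | None = None) -> float:
    """Average annual percent change over ``year_range``.

    Length-weighted geometric average of the segment slopes:
    AAPC = (exp(sum(w_s * slope_s) / sum(w_s)) - 1) * 100, where ``w_s`` is
    the number of years of segment ``s`` inside the range.
    """
    lo, hi = year_range if year_range is not None else (fit.start_year, fit.end_year)
    total_w = 0.0
    acc = 0.0
    for seg in fit.segments:
        w = min(hi, seg.end_year) - max(lo, seg.start_year)
        if w > 0:
            total_w += w
            acc += w * seg.slope
    if total_w == 0:
        raise ValueError(f"year range {year_range} does not overlap fit {fit.iso3}")
    return (exp(acc / total_w) - 1.0) * 100.0


def classify_trend(
    fit: JoinpointFit, pivot_year: int = 2015, end_year: int = 2020
) -> str:
    """Classify a country's recent MMR trend against its earlier trend.

    Refits a single segment to the [pivot_year, end_year] window and
    compares with the AAPC over [start, pivot_year]:

    * ``"increasing"`` — the recent APC is positive;
    * ``"stalled"`` — the recent APC is non-positive but less negative than
      the earlier average decline (the reduction has slowed);
    * ``"declining"`` — otherwise.
    """
    window = MMRSeries(
        iso3=fit.iso3,
        years=fit.years,
        mmr=tuple(exp(v) for v in fit.log_mmr),
    )
    _, post_apc = fit_segment(window, (pivot_year, end_year))
    if post_apc > 0:
        return "increasing"
    pre_aapc = aapc(fit, (fit.start_year, pivot_year))
    if post_apc > pre_aapc:
        return "stalled"
    return "declining"
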