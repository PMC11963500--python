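"""Coverage scale-up scenarios and trajectory construction.

Four built-in scenarios span the policy space from no change to universal
coverage by 2030:

* S0 — no scale-up: coverage stays at its baseline (2024) value;
* S1 — modest scale-up: +2 percentage points per year, capped at 100%;
* S2 — substantial scale-up: +5 percentage points per year, capped at 100%;
* S3 — universal coverage: linear path to 95% coverage by 2030.

The annual increments are read as absolute percentage points, the usual
convention in coverage scale-up modelling; a relative (proportional growth)
reading is available via ``increment_is_relative=True``.  Endpoint-target
trajectories never reduce coverage already above the target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from mmrproj.core_data import ConfigError, ValidationError, _check_fraction

BASELINE_YEAR = 2024
HORIZON_YEAR = 2030

RULE_KINDS = ("constant", "annual_increment", "endpoint_target")


@dataclass(frozen=True)
class Scenario:
    """A coverage-trajectory rule applied uniformly to every intervention."""

    id: int
    kind: str
    name: str = ""
    increment: float = 0.0  # coverage fraction per year (0.02 = 2 pp/yr)
    cap: float = 1.0
    endpoint: float = 0.0
    endpoint_year: int = HORIZON_YEAR
    baseline_year: int = BASELINE_YEAR
    increment_is_relative: bool = False

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ValidationError(f"scenario {self.id}: unknown rule kind {self.kind!r}")
        if self.increment < 0:
            raise ValidationError(f"scenario {self.id}: increment must be >= 0")
        _check_fraction(f"scenario {self.id} cap", self.cap)
        _check_fraction(f"scenario {self.id} endpoint", self.endpoint)
        if self.baseline_year >= self.endpoint_year:
            raise ValidationError(
                f"scenario {self.id}: baseline year must precede endpoint year"
            )


def builtin_scenarios() -> tuple[Scenario, Scenario, Scenario, Scenario]:
    """The four built-in scenarios S0–S3."""
    return (
        Scenario(id=0, kind="constant", name="no scale-up"),
        Scenario(id=1, kind="annual_increment", name="modest scale-up", increment=0.02),
        Scenario(id=2, kind="annual_increment", name="substantial scale-up", increment=0.05),
        Scenario(id=3, kind="endpoint_target", name="universal coverage", endpoint=0.95),
    )


def coverage_trajectory(
    baseline_coverage: float,
    scenario: Scenario,
    years: tuple[int, int] = (BASELINE_YEAR, HORIZON_YEAR),
) -> dict[int, float]:
    """Coverage per year from baseline to horizon under a scenario.

    Trajectories are non-decreasing and bounded by the cap (and by 1).
    """
    _check_fraction("baseline coverage", baseline_coverage)
    start, end = years
    out: dict[int, float] = {}
    for year in range(start, end + 1):
        dt = year - scenario.baseline_year
        if scenario.kind == "constant" or dt <= 0:
            cov = baseline_coverage
        elif scenario.kind == "annual_increment":
            if scenario.increment_is_relative:
                cov = baseline_coverage * (1.0 + scenario.increment) ** dt
            else:
                cov = baseline_coverage + scenario.increment * dt
            cov = min(cov, scenario.cap)
        else:  # endpoint_target
            target = max(baseline_coverage, scenario.endpoint)
            span = scenario.endpoint_year - scenario.baseline_year
            frac = min(dt, span) / span
            cov = baseline_coverage + (target - baseline_coverage) * frac
        out[year] = min(max(cov, baseline_coverage), 1.0)
    return out


def coverage_change(trajectory: dict[int, float], year: int) -> float:
    """Coverage change: coverage in ``year`` minus coverage at baseline."""
    first = min(trajectory)
    if year not in trajectory:
        raise ValueError(f"year {year} outside trajectory range {first}-{max(trajectory)}")
    return trajectory[year] - trajectory[first]


def load_scenarios(path: str | Path) -> list[Scenario]:
    """Load scenario overrides from a JSON array of Scenario fields."""
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, list):
        raise ConfigError("scenario config must be a JSON array")
    out = []
    for i, entry in enumerate(raw):
        try:
            out.append(Scenario(**entry))
        except (TypeError, ValidationError) as exc:
            raise ConfigError(f"scenario config entry {i}: {exc}") from exc
    return out
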