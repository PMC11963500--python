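"""Domain types, the cause taxonomy, the intervention registry, and panel I/O.

The model works on a closed taxonomy of eight causes of maternal death.
Maternal hemorrhage is carried in disaggregated form (antepartum,
intrapartum, postpartum); sources that report a single aggregate hemorrhage
share are split with :func:`decompose_hemorrhage` using the fixed
24% / 3% / 73% partition from the systematic cause-of-death literature.

All shares, coverages, efficacies and affected fractions are stored as
fractions in [0, 1]; percent appears only at I/O boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: The closed cause-of-death taxonomy (order is canonical for I/O).
CAUSES: tuple[str, ...] = (
    "antepartum_hemorrhage",
    "intrapartum_hemorrhage",
    "postpartum_hemorrhage",
    "hypertensive_disorders",
    "sepsis",
    "abortion",
    "other_direct",
    "indirect",
)

#: Life-course periods an intervention can belong to.
PERIODS: tuple[str, ...] = ("periconceptual", "pregnancy", "childbirth")

#: Fixed split of aggregate maternal hemorrhage into its three components.
HEMORRHAGE_SPLIT: dict[str, float] = {
    "antepartum_hemorrhage": 0.24,
    "intrapartum_hemorrhage": 0.03,
    "postpartum_hemorrhage": 0.73,
}

#: The six WHO regions used for grouping.
WHO_REGIONS: tuple[str, ...] = ("AFR", "AMR", "SEAR", "EUR", "EMR", "WPR")

#: World Bank income groups in scope (high income is excluded by design).
INCOME_GROUPS: tuple[str, ...] = ("low", "lower_middle", "upper_middle")

_SHARE_TOL = 1e-9


class ValidationError(ValueError):
    """A domain invariant was violated."""


class ConfigError(ValueError):
    """An intervention or scenario configuration file is malformed."""


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValidationError(f"{name} must be in [0, 1], got {value!r}")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CauseProfile:
    """Shares of maternal deaths by cause; shares sum to one.

    Parameters
    ----------
    shares
        Mapping from every cause in :data:`CAUSES` to its fraction of
        maternal deaths.  Unknown causes are rejected, missing causes are
        rejected, and the shares must sum to 1 within 1e-9.
    """

    shares: Mapping[str, float]

    def __post_init__(self) -> None:
        shares = dict(self.shares)
        unknown = set(shares) - set(CAUSES)
        if unknown:
            raise ValidationError(f"unknown causes: {sorted(unknown)}")
        missing = set(CAUSES) - set(shares)
        if missing:
            raise ValidationError(f"missing causes: {sorted(missing)}")
        for cause, share in shares.items():
            _check_fraction(f"share[{cause}]", share)
        total = sum(shares.values())
        if abs(total - 1.0) > _SHARE_TOL:
            raise ValidationError(f"cause shares sum to {total!r}, expected 1")
        object.__setattr__(self, "shares", shares)

    def __getitem__(self, cause: str) -> float:
        return self.shares[cause]

    @classmethod
    def from_aggregate_hemorrhage(
        cls, hemorrhage: float, **other_shares: float
    ) -> "CauseProfile":
        """Build a profile from an aggregate hemorrhage share plus the
        five non-hemorrhage shares, applying the fixed decomposition."""
        ante, intra, post = decompose_hemorrhage(hemorrhage)
        return cls(
            {
                "antepartum_hemorrhage": ante,
                "intrapartum_hemorrhage": intra,
                "postpartum_hemorrhage": post,
                **other_shares,
            }
        )


@dataclass(frozen=True)
class Intervention:
    """One maternal health intervention.

    ``targets`` maps each target cause to an ``(efficacy, affected_fraction)``
    pair: efficacy is the proportional reduction in cause-specific mortality
    among those reached, affected fraction the share of the cause's deaths the
    intervention can act on.
    """

    id: str
    period: str
    targets: Mapping[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.period not in PERIODS:
            raise ValidationError(
                f"intervention {self.id!r}: period {self.period!r} not in {PERIODS}"
            )
        targets = {c: (float(e), float(a)) for c, (e, a) in dict(self.targets).items()}
        if not targets:
            raise ValidationError(f"intervention {self.id!r}: no target causes")
        for cause, (efficacy, affected) in targets.items():
            if cause not in CAUSES:
                raise ValidationError(
                    f"intervention {self.id!r}: unknown target cause {cause!r}"
                )
            _check_fraction(f"intervention {self.id!r} efficacy[{cause}]", efficacy)
            _check_fraction(f"intervention {self.id!r} affected_fraction[{cause}]", affected)
        object.__setattr__(self, "targets", targets)


@dataclass(frozen=True)
class MMRSeries:
    """An annual MMR time series for one country.

    MMR is maternal deaths per 100,000 live births.  ``se`` holds the
    standard error where known (``None`` entries where not)."""

    iso3: str
    years: tuple[int, ...]
    mmr: tuple[float, ...]
    se: tuple[float | None, ...] | None = None

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        mmr = tuple(float(v) for v in self.mmr)
        if len(years) != len(mmr):
            raise ValidationError(f"{self.iso3}: years and mmr length mismatch")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ValidationError(f"{self.iso3}: years must be strictly increasing")
        if any(v <= 0 for v in mmr):
            raise ValidationError(f"{self.iso3}: all MMR values must be > 0")
        se = self.se
        if se is not None:
            se = tuple(None if s is None else float(s) for s in se)
            if len(se) != len(years):
                raise ValidationError(f"{self.iso3}: se length mismatch")
            if any(s is not None and s < 0 for s in se):
                raise ValidationError(f"{self.iso3}: standard errors must be >= 0")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "mmr", mmr)
        object.__setattr__(self, "se", se)

    def __len__(self) -> int:
        return len(self.years)

    def value(self, year: int) -> float:
        try:
            return self.mmr[self.years.index(year)]
        except ValueError:
            raise KeyError(f"{self.iso3}: no observation for year {year}") from None


@dataclass(frozen=True)
class CountryRecord:
    """One country's full model input.

    ``coverage`` maps intervention id to baseline (2024) coverage.  The 80%
    uncertainty interval ``mmr_ui_2020`` brackets the 2020 MMR point estimate.
    """

    iso3: str
    region: str
    income_group: str
    live_births: int
    series: MMRSeries
    causes: CauseProfile
    coverage: Mapping[str, float]
    mmr_ui_2020: tuple[float, float]

    def __post_init__(self) -> None:
        if self.region not in WHO_REGIONS:
            raise ValidationError(f"{self.iso3}: unknown region {self.region!r}")
        if self.income_group not in INCOME_GROUPS:
            raise ValidationError(f"{self.iso3}: unknown income group {self.income_group!r}")
        if int(self.live_births) <= 0:
            raise ValidationError(f"{self.iso3}: live_births must be > 0")
        object.__setattr__(self, "live_births", int(self.live_births))
        coverage = {k: float(v) for k, v in dict(self.coverage).items()}
        for iid, cov in coverage.items():
            _check_fraction(f"{self.iso3} coverage[{iid}]", cov)
        object.__setattr__(self, "coverage", coverage)
        low, high = (float(b) for b in self.mmr_ui_2020)
        point = self.mmr_2020
        if not low <= point <= high:
            raise ValidationError(
                f"{self.iso3}: UI ({low}, {high}) does not bracket 2020 MMR {point}"
            )
        object.__setattr__(self, "mmr_ui_2020", (low, high))

    @property
    def mmr_2020(self) -> float:
        return self.series.value(2020)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def decompose_hemorrhage(aggregate_share: float) -> tuple[float, float, float]:
    """Split an aggregate hemorrhage share into (antepartum, intrapartum,
    postpartum) components using the fixed 24/3/73 partition.

    The components sum to the input exactly: the postpartum component is
    computed as the remainder so no rounding is lost.
    """
    _check_fraction("aggregate hemorrhage share", aggregate_share)
    ante = HEMORRHAGE_SPLIT["antepartum_hemorrhage"] * aggregate_share
    intra = HEMORRHAGE_SPLIT["intrapartum_hemorrhage"] * aggregate_share
    post = aggregate_share - ante - intra
    return ante, intra, post


_DEFAULT_CONFIG_RESOURCE = "default_interventions.json"


def _load_registry_config(source) -> list[dict]:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return json.load(fh)
    return json.load(source)


def default_intervention_registry(config_path: str | Path | None = None) -> list[Intervention]:
    """Load the intervention registry.

    With no argument, loads the packaged default: the fourteen maternal
    health interventions (one periconceptual, three pregnancy, ten
    childbirth) with *placeholder* efficacy and affected-fraction values —
    these are synthetic defaults for testing and demonstration, not
    published effectiveness estimates, and real analyses should supply a
    config file with sourced values.
    """
    if config_path is None:
        ref = resources.files("mmrproj.data").joinpath(_DEFAULT_CONFIG_RESOURCE)
        raw = json.loads(ref.read_text())
    else:
        raw = _load_registry_config(config_path)
    if not isinstance(raw, list):
        raise ConfigError("intervention config must be a JSON array")
    registry: list[Intervention] = []
    seen: set[str] = set()
    for i, entry in enumerate(raw):
        label = entry.get("id", f"<entry {i}>") if isinstance(entry, dict) else f"<entry {i}>"
        try:
            targets = {
                t["cause"]: (t["efficacy"], t["affected_fraction"])
                for t in entry["targets"]
            }
            iv = Intervention(id=entry["id"], period=entry["period"], targets=targets)
        except (KeyError, TypeError, ValidationError) as exc:
            raise ConfigError(f"intervention config entry {label!r}: {exc}") from exc
        if iv.id in seen:
            raise ConfigError(f"duplicate intervention id {iv.id!r}")
        seen.add(iv.id)
        registry.append(iv)
    return registry


def write_interventions(registry: Sequence[Intervention], path: str | Path) -> None:
    """Write a registry back to the JSON config format."""
    payload = [
        {
            "id": iv.id,
            "period": iv.period,
            "targets": [
                {"cause": c, "efficacy": e, "affected_fraction": a}
                for c, (e, a) in iv.targets.items()
            ],
        }
        for iv in registry
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Panel CSV I/O
# ---------------------------------------------------------------------------

_COUNTRY_COLS = ["iso3", "region", "income_group", "live_births", "mmr_ui_low_2020", "mmr_ui_high_2020"]
_SERIES_COLS = ["iso3", "year", "mmr", "se"]
_CAUSE_COLS = ["iso3", "cause", "share"]
_COVERAGE_COLS = ["iso3", "intervention_id", "coverage_2024"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{name}: missing columns {missing}")


def read_panel(directory: str | Path) -> list[CountryRecord]:
    """Read a country panel from ``countries.csv``, ``mmr_series.csv``,
    ``causes.csv`` and ``coverage.csv`` in ``directory``.

    Raises :class:`ValidationError` naming the offending file and rows on
    any schema or invariant violation.
    """
    directory = Path(directory)
    countries = pd.read_csv(directory / "countries.csv")
    series = pd.read_csv(directory / "mmr_series.csv")
    causes = pd.read_csv(directory / "causes.csv")
    coverage = pd.read_csv(directory / "coverage.csv")
    _require_columns(countries, _COUNTRY_COLS, "countries.csv")
    _require_columns(series, _SERIES_COLS, "mmr_series.csv")
    _require_columns(causes, _CAUSE_COLS, "causes.csv")
    _require_columns(coverage, _COVERAGE_COLS, "coverage.csv")

    bad = causes.groupby("iso3")["share"].sum()
    bad = bad[(bad - 1.0).abs() > 1e-6]
    if len(bad):
        rows = causes.index[causes["iso3"].isin(bad.index)].tolist()
        raise ValidationError(
            f"causes.csv: shares do not sum to 1 for {sorted(bad.index)} (rows {rows})"
        )

    records: list[CountryRecord] = []
    for row in countries.itertuples(index=True):
        iso3 = row.iso3
        sub = series[series["iso3"] == iso3].sort_values("year")
        if sub.empty:
            raise ValidationError(f"mmr_series.csv: no rows for {iso3}")
        se_col = [None if pd.isna(s) else float(s) for s in sub["se"]]
        try:
            mmr_series = MMRSeries(
                iso3=iso3,
                years=tuple(sub["year"]),
                mmr=tuple(sub["mmr"]),
                se=tuple(se_col),
            )
            cause_sub = causes[causes["iso3"] == iso3]
            profile = CauseProfile(dict(zip(cause_sub["cause"], cause_sub["share"])))
            cov_sub = coverage[coverage["iso3"] == iso3]
            record = CountryRecord(
                iso3=iso3,
                region=row.region,
                income_group=row.income_group,
                live_births=row.live_births,
                series=mmr_series,
                causes=profile,
                coverage=dict(zip(cov_sub["intervention_id"], cov_sub["coverage_2024"])),
                mmr_ui_2020=(row.mmr_ui_low_2020, row.mmr_ui_high_2020),
            )
        except ValidationError as exc:
            raise ValidationError(f"countries.csv row {row.Index} ({iso3}): {exc}") from exc
        records.append(record)
    return records


def write_panel(records: Iterable[CountryRecord], directory: str | Path) -> None:
    """Write a panel as the four CSVs that :func:`read_panel` reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = list(records)
    pd.DataFrame(
        [
            {
                "iso3": r.iso3,
                "region": r.region,
                "income_group": r.income_group,
                "live_births": r.live_births,
                "mmr_ui_low_2020": r.mmr_ui_2020[0],
                "mmr_ui_high_2020": r.mmr_ui_2020[1],
            }
            for r in records
        ],
        columns=_COUNTRY_COLS,
    ).to_csv(directory / "countries.csv", index=False)

    series_rows = []
    for r in records:
        se = r.series.se or (None,) * len(r.series)
        for year, mmr, s in zip(r.series.years, r.series.mmr, se):
            series_rows.append({"iso3": r.iso3, "year": year, "mmr": mmr, "se": s})
    pd.DataFrame(series_rows, columns=_SERIES_COLS).to_csv(
        directory / "mmr_series.csv", index=False
    )

    pd.DataFrame(
        [
            {"iso3": r.iso3, "cause": c, "share": r.causes[c]}
            for r in records
            for c in CAUSES
        ],
        columns=_CAUSE_COLS,
    ).to_csv(directory / "causes.csv", index=False)

    pd.DataFrame(
        [
            {"iso3": r.iso3, "intervention_id": iid, "coverage_2024": cov}
            for r in records
            for iid, cov in sorted(r.coverage.items())
        ],
        columns=_COVERAGE_COLS,
    ).to_csv(directory / "coverage.csv", index=False)
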