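"""Typed containers and readers for the model's input tables.

The decision model is driven by three inputs:

* an arm-level clinical event-count table per follow-up year
  (:class:`ArmYearEvents`), where the final observed year is recorded as
  ``"4+"`` and applies to every subsequent cycle;
* a unit-cost table per clinical event or service in US$
  (:class:`UnitCostTable`), priced from SUS (Brazilian public healthcare
  system) reimbursement values;
* a model configuration (:class:`ModelConfig`): horizon, discount rates,
  late-period probabilities, probabilistic-sensitivity-analysis settings.

Packaged fixtures (``graftcea/data``) ship the published event counts and
unit costs for the 466-vs-466 patient comparison of single-dose 3 mg/kg
r-ATG induction versus no induction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ARMS = ("no_induction", "r_atg")

#: Cost components always present in a complete :class:`UnitCostTable`.
COST_COMPONENTS = (
    "r_atg_induction",
    "immunosuppression_year",
    "follow_up_year",
    "cmv_episode",
    "ar_episode",
    "graft_loss_event",
    "dialysis_year",
    "retransplant_event",
)

#: Components that the published first-year cost table does not price and
#: which therefore fall back to config defaults when absent from a CSV.
OPTIONAL_COST_COMPONENTS = ("dialysis_year", "retransplant_event")

_EVENT_COUNT_FIELDS = (
    "n_at_risk",
    "cmv",
    "acute_rejection",
    "graft_loss_prior_ar",
    "graft_loss_no_prior_ar",
    "death_functioning",
    "death_after_graft_loss",
    "retransplant",
)


class ValidationError(ValueError):
    """An input table violates one of its declared invariants."""


class ParseError(ValueError):
    """An input file could not be parsed into the expected schema."""


@dataclass(frozen=True)
class ArmYearEvents:
    """Event counts for one treatment arm in one follow-up year.

    ``recurring=True`` marks the "year 4+" record whose counts apply to
    year 4 and, absent other information, to every later cycle.  Counts for
    death after graft loss and retransplantation are conditional on having
    lost the graft; their natural denominator is the arm's cumulative
    first-year graft losses (see :func:`year1_graft_losses`).
    """

    arm: str
    year: int
    n_at_risk: int
    cmv: int = 0
    acute_rejection: int = 0
    graft_loss_prior_ar: int = 0
    graft_loss_no_prior_ar: int = 0
    death_functioning: int = 0
    death_after_graft_loss: int = 0
    retransplant: int = 0
    recurring: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(
                f"unknown arm {self.arm!r}; expected one of {ARMS}"
            )
        if self.year < 1:
            raise ValidationError(f"year must be >= 1, got {self.year}")
        for name in _EVENT_COUNT_FIELDS:
            value = getattr(self, name)
            if value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")
        for name in (
            "cmv",
            "acute_rejection",
            "graft_loss_prior_ar",
            "graft_loss_no_prior_ar",
            "death_functioning",
        ):
            if getattr(self, name) > self.n_at_risk:
                raise ValidationError(
                    f"{name}={getattr(self, name)} exceeds n_at_risk="
                    f"{self.n_at_risk} ({self.arm}, year {self.year_label})"
                )
        terminal = (
            self.graft_loss_prior_ar
            + self.graft_loss_no_prior_ar
            + self.death_functioning
        )
        if terminal > self.n_at_risk:
            raise ValidationError(
                "graft losses plus deaths with functioning graft exceed "
                f"n_at_risk ({self.arm}, year {self.year_label})"
            )
        if self.year > 1 and (self.cmv or self.acute_rejection):
            raise ValidationError(
                "CMV and acute rejection are recorded only in year 1 "
                f"({self.arm}, year {self.year_label})"
            )

    @property
    def year_label(self) -> str:
        return f"{self.year}+" if self.recurring else str(self.year)

    @property
    def graft_losses(self) -> int:
        """Total graft losses in the year, irrespective of AR history."""
        return self.graft_loss_prior_ar + self.graft_loss_no_prior_ar


def _parse_year(raw: object) -> tuple[int, bool]:
    text = str(raw).strip()
    recurring = text.endswith("+")
    if recurring:
        text = text[:-1]
    try:
        year = int(text)
    except ValueError as exc:
        raise ParseError(f"unparseable year value {raw!r}") from exc
    return year, recurring


def load_event_table(path: str | Path) -> list[ArmYearEvents]:
    """Read a per-arm, per-year event-count CSV.

    The CSV must carry a header with the :class:`ArmYearEvents` field names;
    the ``year`` column accepts plain integers and the recurring marker
    (e.g. ``4+``).
    """
    try:
        frame = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"no records in {path}") from exc
    if frame.empty:
        raise ValidationError(f"no records in {path}")
    expected = {"arm", "year", *_EVENT_COUNT_FIELDS}
    missing = expected - set(frame.columns)
    if missing:
        raise ParseError(f"missing columns in {path}: {sorted(missing)}")

    records: list[ArmYearEvents] = []
    for idx, row in frame.iterrows():
        year, recurring = _parse_year(row["year"])
        counts = {}
        for name in _EVENT_COUNT_FIELDS:
            try:
                counts[name] = int(row[name])
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"row {idx}: column {name!r} is not an integer "
                    f"({row[name]!r})"
                ) from exc
        records.append(
            ArmYearEvents(
                arm=str(row["arm"]).strip(),
                year=year,
                recurring=recurring,
                **counts,
            )
        )
    return records


def write_event_table(records: list[ArmYearEvents], path: str | Path) -> None:
    """Write event records to CSV; inverse of :func:`load_event_table`."""
    rows = []
    for rec in records:
        row = {"arm": rec.arm, "year": rec.year_label}
        row.update({name: getattr(rec, name) for name in _EVENT_COUNT_FIELDS})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def events_for(
    records: list[ArmYearEvents], arm: str, year: int
) -> ArmYearEvents:
    """Record applying to ``year`` for ``arm`` (recurring rows cover later years)."""
    exact = [r for r in records if r.arm == arm and r.year == year]
    if exact:
        return exact[0]
    recurring = [
        r for r in records if r.arm == arm and r.recurring and r.year <= year
    ]
    if recurring:
        return max(recurring, key=lambda r: r.year)
    raise ValidationError(f"no event record for arm={arm!r}, year {year}")


def year1_graft_losses(records: list[ArmYearEvents], arm: str) -> int:
    """Cumulative first-year graft losses: the denominator for post-graft-loss events."""
    return events_for(records, arm, 1).graft_losses


@dataclass(frozen=True)
class UnitCostTable:
    """Unit cost in US$ per clinical event or per patient-year of a service.

    Death is an absorbing, cost-free state and has no entry here.
    """

    r_atg_induction: float
    immunosuppression_year: float
    follow_up_year: float
    cmv_episode: float
    ar_episode: float
    graft_loss_event: float
    dialysis_year: float
    retransplant_event: float

    def __post_init__(self) -> None:
        for name in COST_COMPONENTS:
            if getattr(self, name) < 0:
                raise ValidationError(
                    f"cost {name} must be >= 0, got {getattr(self, name)}"
                )

    def __getitem__(self, component: str) -> float:
        if component not in COST_COMPONENTS:
            raise KeyError(
                f"unknown cost component {component!r}; "
                f"valid: {COST_COMPONENTS}"
            )
        return getattr(self, component)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in COST_COMPONENTS}

    def scaled(self, factor: float) -> "UnitCostTable":
        return UnitCostTable(
            **{k: v * factor for k, v in self.as_dict().items()}
        )

    def replace(self, **updates: float) -> "UnitCostTable":
        return replace(self, **updates)


def load_cost_table(
    path: str | Path, config: "ModelConfig | None" = None
) -> UnitCostTable:
    """Read a ``component,unit_cost_usd`` CSV into a :class:`UnitCostTable`.

    ``dialysis_year`` and ``retransplant_event`` are not part of the
    published first-year cost table; when absent they are filled from the
    configuration defaults (with a logged warning).
    """
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"no records in {path}") from exc
    if not {"component", "unit_cost_usd"} <= set(frame.columns):
        raise ParseError(
            f"{path}: expected columns 'component' and 'unit_cost_usd'"
        )
    costs: dict[str, float] = {}
    for _, row in frame.iterrows():
        name = str(row["component"]).strip()
        if name not in COST_COMPONENTS:
            raise ValidationError(
                f"unknown cost component {name!r}; valid: {COST_COMPONENTS}"
            )
        value = float(row["unit_cost_usd"])
        if value < 0:
            raise ValidationError(f"cost {name} must be >= 0, got {value}")
        costs[name] = value

    cfg = config or default_config()
    fallbacks = {
        "dialysis_year": cfg.dialysis_year_usd,
        "retransplant_event": cfg.retransplant_event_usd,
    }
    for name in OPTIONAL_COST_COMPONENTS:
        if name not in costs:
            costs[name] = fallbacks[name]
            logger.warning(
                "cost table %s omits %r; using config default %.2f",
                path,
                name,
                fallbacks[name],
            )
    missing = [
        c
        for c in COST_COMPONENTS
        if c not in costs and c not in OPTIONAL_COST_COMPONENTS
    ]
    if missing:
        raise ValidationError(f"cost table {path} missing components {missing}")
    return UnitCostTable(**costs)


def write_cost_table(costs: UnitCostTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "component": list(COST_COMPONENTS),
            "unit_cost_usd": [costs[c] for c in COST_COMPONENTS],
        }
    ).to_csv(path, index=False)


@dataclass
class ModelConfig:
    """Run configuration: horizon, discounting, late-period inputs, PSA settings."""

    horizon_years: int = 10
    cycle_length_years: int = 1
    discount_rate_costs: float = 0.05
    discount_rate_effects: float = 0.05
    exchange_rate_brl_per_usd: float = 5.12
    dialysis_year_usd: float = 7800.0
    retransplant_event_usd: float = 5300.0
    maintenance_timing: str = "start"
    #: event -> annual probability applied identically to both arms from
    #: cycle 5 onward; None derives a pooled "year 4+" schedule from the
    #: observed counts.
    post_year4_probabilities: dict[str, float] | None = None
    wtp_grid_ar_episodes: dict = field(
        default_factory=lambda: {"start": 0, "stop": 2000, "step": 25}
    )
    wtp_grid_graft_years: dict = field(
        default_factory=lambda: {"start": 0, "stop": 20000, "step": 250}
    )
    psa_iterations: int = 10000
    psa_cost_cv: float = 0.10
    rng_seed: int = 20140617

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ValidationError("horizon_years must be >= 1")
        for name in ("discount_rate_costs", "discount_rate_effects"):
            rate = getattr(self, name)
            if not 0.0 <= rate < 1.0:
                raise ValidationError(f"{name} must be in [0, 1), got {rate}")
        if self.exchange_rate_brl_per_usd <= 0:
            raise ValidationError("exchange rate must be > 0")
        if self.maintenance_timing not in ("start", "end"):
            raise ValidationError(
                "maintenance_timing must be 'start' or 'end'"
            )
        if self.psa_iterations < 1:
            raise ValidationError("psa_iterations must be >= 1")
        if self.psa_cost_cv < 0:
            raise ValidationError("psa_cost_cv must be >= 0")

    def convert_brl(self, amount_brl: float) -> float:
        """Convert R$ to US$ at the configured exchange rate."""
        return amount_brl / self.exchange_rate_brl_per_usd

    def wtp_grid(self, outcome: str) -> list[float]:
        bounds = (
            self.wtp_grid_ar_episodes
            if outcome == "ar_episodes"
            else self.wtp_grid_graft_years
        )
        grid, value = [], float(bounds["start"])
        while value <= bounds["stop"]:
            grid.append(value)
            value += bounds["step"]
        return grid


_CONFIG_FIELDS = {f.name for f in fields(ModelConfig)}


def load_config(path: str | Path) -> ModelConfig:
    """Load a YAML (or JSON: YAML superset) configuration file."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ParseError(f"unknown config keys in {path}: {sorted(unknown)}")
    return ModelConfig(**raw)


def _packaged(name: str):
    return resources.files("graftcea.data").joinpath(name)


def default_config() -> ModelConfig:
    with resources.as_file(_packaged("default_config.yaml")) as path:
        return load_config(path)


def packaged_event_table() -> list[ArmYearEvents]:
    """The published per-arm, per-year event counts (466 patients per arm)."""
    with resources.as_file(_packaged("study_events.csv")) as path:
        return load_event_table(path)


def packaged_cost_table(config: ModelConfig | None = None) -> UnitCostTable:
    """The published first-year unit costs, completed with config defaults."""
    with resources.as_file(_packaged("unit_costs.csv")) as path:
        return load_cost_table(path, config=config)


def incidence_percent(events: int, n: int) -> float:
    """Percentage ``100 * events / n`` rounded half-up to one decimal."""
    if n <= 0:
        raise ValidationError("denominator must be > 0")
    if not 0 <= events <= n:
        raise ValidationError("events must satisfy 0 <= events <= n")
    pct = Decimal(100 * events) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
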