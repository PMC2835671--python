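"""Model parameter set: base case, validation and config-file I/O.

All probabilities are stored as proportions in [0, 1]; all money fields
are 2009 Australian dollars.  The base case bundles the pooled adverse
event rates for Australian/NZ colorectal cancer surgery, the colon/rectal
casemix split, the four AR-DRG episode costs (rectal/colon resection,
with and without complications), the self-audit administration costs,
and the analysis settings (effect-size scenario, caseload, Monte Carlo
draws, national incidence and surgical uptake).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .evidence import EVENT_TYPES

logger = logging.getLogger(__name__)

#: DRG cost cells, fixed model order.
DRG_CELLS: tuple[str, ...] = ("rectal_comp", "rectal_uncomp", "colon_comp", "colon_uncomp")


@dataclass(frozen=True)
class RateRange:
    """A base-case rate with its plausible (low, high) range."""

    mean: float
    low: float
    high: float


@dataclass(frozen=True)
class ShareRange:
    """Colon share of the colorectal casemix with its plausible range."""

    base: float
    low: float
    high: float


@dataclass(frozen=True)
class ParameterSet:
    """Complete input set for the two-arm decision model."""

    event_rates: dict[str, RateRange]
    death_attrib_fraction: float = 0.16
    apply_death_attribution: bool = False
    colon_share: ShareRange = ShareRange(base=0.687, low=0.687, high=0.759)
    drg_costs: dict[str, float] = field(
        default_factory=lambda: {
            "rectal_comp": 33_277.0,
            "rectal_uncomp": 18_094.0,
            "colon_comp": 30_899.0,
            "colon_uncomp": 14_283.0,
        }
    )
    cost_range_fraction: float = 0.30
    audit_software_cost_per_year: float = 250.0
    data_entry_cost_per_audit: float = 16.67
    annual_caseload: int = 20
    reduction_fraction: float = 0.50
    reduction_sd: float = 0.10
    n_draws: int = 2_000
    seed: int = 2010
    incidence: int = 13_076
    surgery_uptake: float = 0.95
    sample_colon_share: bool = True
    sample_admin_costs: bool = False

    def replace(self, **changes: Any) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def with_event_rate_mean(self, event: str, mean: float) -> "ParameterSet":
        """Copy with one event's base-case mean replaced (range kept)."""
        rates = dict(self.event_rates)
        r = rates[event]
        rates[event] = RateRange(mean=mean, low=min(r.low, mean), high=max(r.high, mean))
        return self.replace(event_rates=rates)


def default_parameters() -> ParameterSet:
    """The published base case.

    Event-rate means/ranges are the pooled values (see
    :mod:`audit_savings.evidence`); costs are AR-DRG national averages
    for rectal (G01A/G01B) and colon (G02A/G02B) episodes with/without
    complications, in 2009 AUD.
    """
    return ParameterSet(
        event_rates={
            "anastomotic_leak": RateRange(0.044, 0.005, 0.082),
            "wound_infection": RateRange(0.056, 0.021, 0.091),
            "dvt": RateRange(0.035, 0.003, 0.067),
            "return_to_theatre": RateRange(0.075, 0.027, 0.122),
            "respiratory": RateRange(0.055, 0.002, 0.107),
            "death_30d": RateRange(0.033, 0.002, 0.064),
        }
    )


def validate(params: ParameterSet) -> list[str]:
    """Check invariants; return human-readable findings (empty = valid)."""
    findings: list[str] = []

    def check_unit(name: str, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            findings.append(f"{name}: proportion {value} outside [0, 1]")

    for event in EVENT_TYPES:
        if event not in params.event_rates:
            findings.append(f"event_rates: missing event type {event!r}")
    for event, r in params.event_rates.items():
        for part in ("mean", "low", "high"):
            check_unit(f"event_rates[{event}].{part}", getattr(r, part))
        if not (r.low <= r.mean <= r.high):
            findings.append(f"event_rates[{event}]: requires low <= mean <= high, got {r}")

    total = sum(params.event_rates[e].mean for e in EVENT_TYPES if e in params.event_rates)
    if total >= 1.0:
        findings.append(f"event_rates: means sum to {total} >= 1; no-event branch impossible")

    check_unit("death_attrib_fraction", params.death_attrib_fraction)
    for part in ("base", "low", "high"):
        check_unit(f"colon_share.{part}", getattr(params.colon_share, part))
    if not (params.colon_share.low <= params.colon_share.base <= params.colon_share.high):
        findings.append("colon_share: requires low <= base <= high")

    for cell in DRG_CELLS:
        if cell not in params.drg_costs:
            findings.append(f"drg_costs: missing cell {cell!r}")
        elif params.drg_costs[cell] <= 0:
            findings.append(f"drg_costs[{cell}]: cost must be positive")
    for organ in ("rectal", "colon"):
        comp, uncomp = params.drg_costs.get(f"{organ}_comp"), params.drg_costs.get(f"{organ}_uncomp")
        if comp is not None and uncomp is not None and comp <= uncomp:
            findings.append(
                f"drg_costs: {organ} with-complications cost ({comp}) must exceed "
                f"no-complications cost ({uncomp})"
            )

    if params.cost_range_fraction < 0:
        findings.append("cost_range_fraction: must be non-negative")
    if params.audit_software_cost_per_year < 0:
        findings.append("audit_software_cost_per_year: must be non-negative")
    if params.data_entry_cost_per_audit < 0:
        findings.append("data_entry_cost_per_audit: must be non-negative")
    if params.annual_caseload < 1:
        findings.append("annual_caseload: must be >= 1")
    check_unit("reduction_fraction", params.reduction_fraction)
    if params.reduction_sd < 0:
        findings.append("reduction_sd: must be non-negative")
    if params.n_draws < 2:
        findings.append("n_draws: must be >= 2")
    if params.incidence < 0:
        findings.append("incidence: must be non-negative")
    check_unit("surgery_uptake", params.surgery_uptake)
    return findings


class ConfigError(ValueError):
    """A configuration file could not be interpreted."""


_SCALAR_FIELDS = {
    f.name: f.type
    for f in dataclasses.fields(ParameterSet)
    if f.name not in ("event_rates", "colon_share", "drg_costs")
}
_VALID_KEYS = set(_SCALAR_FIELDS) | {"event_rates", "colon_share", "drg_costs"}


def _to_dict(params: ParameterSet) -> dict[str, Any]:
    d = dataclasses.asdict(params)
    d["event_rates"] = {e: dataclasses.asdict(r) for e, r in params.event_rates.items()}
    d["colon_share"] = dataclasses.asdict(params.colon_share)
    return d


def params_to_dict(params: ParameterSet) -> dict[str, Any]:
    """Plain-dict snapshot of a parameter set (for manifests/JSON)."""
    return _to_dict(params)


def save_config(params: ParameterSet, path: str | Path) -> None:
    """Write a YAML config (flat keys mirroring field names; money in 2009 AUD)."""
    Path(path).write_text(yaml.safe_dump(_to_dict(params), sort_keys=False))


def params_from_dict(data: dict[str, Any]) -> ParameterSet:
    """Build a ParameterSet from a (possibly partial) plain dict.

    Unspecified fields fall back to the base case with a logged notice;
    unknown keys and type mismatches raise :class:`ConfigError`.
    """
    unknown = set(data) - _VALID_KEYS
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(_VALID_KEYS)}"
        )
    base = default_parameters()
    kwargs: dict[str, Any] = {}

    if "event_rates" in data:
        raw = data["event_rates"]
        if not isinstance(raw, dict):
            raise ConfigError("event_rates: expected a mapping of event -> {mean, low, high}")
        rates = dict(base.event_rates)
        for event, spec in raw.items():
            if event not in EVENT_TYPES:
                raise ConfigError(f"event_rates: unknown event {event!r}; valid: {EVENT_TYPES}")
            try:
                rates[event] = RateRange(float(spec["mean"]), float(spec["low"]), float(spec["high"]))
            except (KeyError, TypeError, ValueError) as exc:
                raise ConfigError(f"event_rates[{event}]: expected mean/low/high numbers") from exc
        kwargs["event_rates"] = rates
    if "colon_share" in data:
        spec = data["colon_share"]
        try:
            kwargs["colon_share"] = ShareRange(
                float(spec["base"]), float(spec["low"]), float(spec["high"])
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError("colon_share: expected base/low/high numbers") from exc
    if "drg_costs" in data:
        spec = data["drg_costs"]
        if not isinstance(spec, dict) or set(spec) - set(DRG_CELLS):
            raise ConfigError(f"drg_costs: expected mapping with keys among {DRG_CELLS}")
        costs = dict(base.drg_costs)
        for cell, value in spec.items():
            try:
                costs[cell] = float(value)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"drg_costs[{cell}]: expected a number") from exc
        kwargs["drg_costs"] = costs

    for name in _SCALAR_FIELDS:
        if name not in data:
            continue
        value = data[name]
        default = getattr(base, name)
        try:
            if isinstance(default, bool):
                if not isinstance(value, bool):
                    raise TypeError
                kwargs[name] = value
            elif isinstance(default, int):
                if isinstance(value, float) and not value.is_integer():
                    raise TypeError
                kwargs[name] = int(value)
            else:
                kwargs[name] = float(value)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{name}: type mismatch, got {value!r}") from exc

    missing = _VALID_KEYS - set(data)
    if missing:
        logger.info("config: fields %s not specified; using base-case defaults", sorted(missing))
    params = dataclasses.replace(base, **kwargs)
    findings = validate(params)
    if findings:
        raise ConfigError("invalid configuration: " + "; ".join(findings))
    return params


def load_config(path: str | Path) -> ParameterSet:
    """Read a YAML/JSON config file into a validated ParameterSet."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return params_from_dict(data)
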