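"""Uncertainty analysis: distribution elicitation, tornado, and PSA.

Elicitation is by moment matching.  A "plausible range" printed for a
probability parameter is read as a central 95% interval, so the target
standard deviation is ``(high - low) / 3.92``; a beta distribution is
then parameterized to hit the target mean and SD exactly.  Episode costs
are right-skewed in practice, so they get gamma distributions with a
coefficient of variation of ``cost_range_fraction / 1.96`` — the same
±30% band used by the one-way sensitivity analysis then doubles as the
95% sampling interval.

The probabilistic sensitivity analysis re-evaluates the decision tree on
each of ``n_draws`` independently sampled parameter sets (event rates and
colon share from betas, DRG costs from gammas, the audit effect size from
a beta with configurable SD) and summarizes the per-case saving by its
mean and 2.5/97.5 percentiles.  Parameters are sampled independently —
no correlation structure is imposed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np

from .evidence import EVENT_TYPES
from .model import expected_arm_cost, incremental_saving
from .parameters import DRG_CELLS, ParameterSet, ShareRange, validate

logger = logging.getLogger(__name__)


class ElicitationError(ValueError):
    """The requested moments admit no valid distribution."""


@dataclass(frozen=True)
class DistributionSpec:
    """A moment-matched beta or gamma distribution.

    For ``family='beta'`` the shape parameters are (alpha, beta); for
    ``family='gamma'`` they are (shape, scale).  The analytic mean and SD
    equal ``target_mean`` / ``target_sd`` by construction.
    """

    family: Literal["beta", "gamma"]
    shape_a: float
    shape_b: float
    target_mean: float
    target_sd: float

    @property
    def mean(self) -> float:
        if self.family == "beta":
            return self.shape_a / (self.shape_a + self.shape_b)
        return self.shape_a * self.shape_b

    @property
    def sd(self) -> float:
        if self.family == "beta":
            a, b = self.shape_a, self.shape_b
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        return math.sqrt(self.shape_a) * self.shape_b

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "beta":
            return rng.beta(self.shape_a, self.shape_b, size=size)
        return rng.gamma(self.shape_a, self.shape_b, size=size)


def beta_from_mean_sd(mean: float, sd: float) -> DistributionSpec:
    """Method-of-moments beta hitting a target mean and SD exactly."""
    if not (0.0 < mean < 1.0):
        raise ElicitationError(f"beta mean must be in (0, 1), got {mean}")
    if sd <= 0.0:
        raise ElicitationError(f"beta sd must be positive, got {sd}")
    nu = mean * (1.0 - mean) / sd**2 - 1.0  # alpha + beta
    if nu <= 0.0:
        raise ElicitationError(
            f"sd {sd} too large for a beta with mean {mean} "
            f"(implied shape <= 0); shrink the plausible range"
        )
    return DistributionSpec("beta", mean * nu, (1.0 - mean) * nu, mean, sd)


def beta_from_mean_interval(mean: float, low: float, high: float) -> DistributionSpec:
    """Beta elicited from a mean and a plausible range read as a 95% CI."""
    if not (0.0 <= low <= mean <= high <= 1.0):
        raise ElicitationError(f"require 0 <= low <= mean <= high <= 1, got ({mean}, {low}, {high})")
    return beta_from_mean_sd(mean, (high - low) / 3.92)


def gamma_from_mean_cv(mean: float, cv: float) -> DistributionSpec:
    """Gamma with given mean and coefficient of variation (shape=1/cv²)."""
    if mean <= 0.0 or cv <= 0.0:
        raise ElicitationError(f"gamma needs positive mean and cv, got ({mean}, {cv})")
    shape = 1.0 / cv**2
    scale = mean * cv**2
    return DistributionSpec("gamma", shape, scale, mean, mean * cv)


# ---------------------------------------------------------------------------
# One-way sensitivity analysis / tornado.
# ---------------------------------------------------------------------------

OutputKind = Literal["audit_cost", "saving"]


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    input_low: float
    input_high: float
    output_low: float
    output_high: float

    @property
    def swing(self) -> float:
        return abs(self.output_high - self.output_low)


def _set_event_rate(event: str) -> Callable[[ParameterSet, float], ParameterSet]:
    return lambda p, v: p.with_event_rate_mean(event, v)


def _set_colon_share(p: ParameterSet, v: float) -> ParameterSet:
    s = p.colon_share
    return p.replace(colon_share=ShareRange(base=v, low=min(s.low, v), high=max(s.high, v)))


def _set_cost(cell: str) -> Callable[[ParameterSet, float], ParameterSet]:
    return lambda p, v: p.replace(drg_costs={**p.drg_costs, cell: v})


def ranged_parameters(
    params: ParameterSet,
) -> dict[str, tuple[float, float, Callable[[ParameterSet, float], ParameterSet]]]:
    """All ranged cost and epidemiological parameters: name -> (low, high, setter).

    Event rates and colon share use their plausible ranges; the four DRG
    costs use symmetric ±``cost_range_fraction`` bands around base.
    """
    reg: dict[str, tuple[float, float, Callable]] = {}
    for event in EVENT_TYPES:
        r = params.event_rates[event]
        reg[event] = (r.low, r.high, _set_event_rate(event))
    reg["colon_share"] = (params.colon_share.low, params.colon_share.high, _set_colon_share)
    f = params.cost_range_fraction
    for cell in DRG_CELLS:
        base = params.drg_costs[cell]
        reg[cell] = (base * (1.0 - f), base * (1.0 + f), _set_cost(cell))
    return reg


def _evaluate(params: ParameterSet, output: OutputKind) -> float:
    if output == "audit_cost":
        return expected_arm_cost(params, "audit").expected_cost
    if output == "saving":
        return incremental_saving(params)
    raise ValueError(f"unknown output {output!r}; valid: ('audit_cost', 'saving')")


def one_way_sa(
    params: ParameterSet,
    parameter_name: str,
    low: float | None = None,
    high: float | None = None,
    output: OutputKind = "audit_cost",
) -> TornadoEntry:
    """Re-evaluate the deterministic model at one parameter's extremes."""
    reg = ranged_parameters(params)
    if parameter_name not in reg:
        raise ValueError(
            f"unknown ranged parameter {parameter_name!r}; valid: {sorted(reg)}"
        )
    reg_low, reg_high, setter = reg[parameter_name]
    lo = reg_low if low is None else low
    hi = reg_high if high is None else high
    return TornadoEntry(
        parameter=parameter_name,
        input_low=lo,
        input_high=hi,
        output_low=_evaluate(setter(params, lo), output),
        output_high=_evaluate(setter(params, hi), output),
    )


def tornado(params: ParameterSet, output: OutputKind = "audit_cost") -> list[TornadoEntry]:
    """One-way SA over every ranged parameter, sorted by swing (desc)."""
    entries = [one_way_sa(params, name, output=output) for name in ranged_parameters(params)]
    entries.sort(key=lambda e: e.swing, reverse=True)
    return entries


def tornado_figure(entries: Sequence[TornadoEntry], base_value: float, path) -> None:
    """Horizontal-bar tornado diagram written to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    entries = sorted(entries, key=lambda e: e.swing)  # widest bar on top
    labels = [e.parameter for e in entries]
    lows = [min(e.output_low, e.output_high) for e in entries]
    widths = [e.swing for e in entries]
    fig, ax = plt.subplots(figsize=(8, 0.45 * len(entries) + 1.5))
    ax.barh(labels, widths, left=lows, color="#4878a8")
    ax.axvline(base_value, color="black", lw=1, ls="--", label="base case")
    ax.set_xlabel("Expected cost / saving (2009 AUD)")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis.
# ---------------------------------------------------------------------------

#: Fixed sampling order; one RNG sub-stream per entry so adding a
#: parameter never reshuffles existing draws within a version.
PSA_PARAM_ORDER: tuple[str, ...] = EVENT_TYPES + (
    "colon_share",
    "rectal_comp",
    "rectal_uncomp",
    "colon_comp",
    "colon_uncomp",
    "reduction_fraction",
    "audit_software_cost_per_year",
    "data_entry_cost_per_audit",
)

_MAX_RETRIES_PER_DRAW = 100


@dataclass(frozen=True)
class PsaResult:
    """Monte Carlo draws of the per-case incremental saving."""

    draws: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    seed: int
    n_resampled: int = 0

    @property
    def n_draws(self) -> int:
        return len(self.draws)


def _psa_samplers(params: ParameterSet) -> dict[str, Callable[[np.random.Generator], float]]:
    """One scalar sampler per PSA parameter, honoring the sampling flags."""

    def const(v: float) -> Callable[[np.random.Generator], float]:
        return lambda rng: v

    def from_spec(spec: DistributionSpec) -> Callable[[np.random.Generator], float]:
        return lambda rng: float(spec.sample(rng))

    samplers: dict[str, Callable[[np.random.Generator], float]] = {}
    for event in EVENT_TYPES:
        r = params.event_rates[event]
        if r.high > r.low:
            samplers[event] = from_spec(beta_from_mean_interval(r.mean, r.low, r.high))
        else:
            samplers[event] = const(r.mean)
    cs = params.colon_share
    if params.sample_colon_share and cs.high > cs.low:
        samplers["colon_share"] = from_spec(
            beta_from_mean_sd(cs.base, (cs.high - cs.low) / 3.92)
        )
    else:
        samplers["colon_share"] = const(cs.base)
    cv = params.cost_range_fraction / 1.96
    for cell in DRG_CELLS:
        if cv > 0:
            samplers[cell] = from_spec(gamma_from_mean_cv(params.drg_costs[cell], cv))
        else:
            samplers[cell] = const(params.drg_costs[cell])
    if params.reduction_sd > 0:
        samplers["reduction_fraction"] = from_spec(
            beta_from_mean_sd(params.reduction_fraction, params.reduction_sd)
        )
    else:
        samplers["reduction_fraction"] = const(params.reduction_fraction)
    for name in ("audit_software_cost_per_year", "data_entry_cost_per_audit"):
        base = getattr(params, name)
        if params.sample_admin_costs and base > 0:
            samplers[name] = from_spec(gamma_from_mean_cv(base, cv))
        else:
            samplers[name] = const(base)
    return samplers


def _assemble(params: ParameterSet, sampled: dict[str, float]) -> ParameterSet:
    out = params
    for event in EVENT_TYPES:
        out = out.with_event_rate_mean(event, sampled[event])
    out = _set_colon_share(out, sampled["colon_share"])
    out = out.replace(
        drg_costs={cell: sampled[cell] for cell in DRG_CELLS},
        reduction_fraction=sampled["reduction_fraction"],
        audit_software_cost_per_year=sampled["audit_software_cost_per_year"],
        data_entry_cost_per_audit=sampled["data_entry_cost_per_audit"],
    )
    return out


def run_psa(
    params: ParameterSet,
    n_draws: int | None = None,
    seed: int | None = None,
) -> PsaResult:
    """Monte Carlo PSA of the per-case incremental saving.

    Per draw, every uncertain parameter is sampled from its elicited
    distribution (in ``PSA_PARAM_ORDER``, each from its own sub-stream of
    the seeded generator) and the decision tree is rolled back on the
    sampled set.  Draws whose parameter set fails validation (e.g. a
    gamma draw inverting a with/without-complications cost pair) are
    re-sampled, up to a capped retry count, and the tally is logged.
    Identical seeds give bitwise-identical results.
    """
    n = params.n_draws if n_draws is None else int(n_draws)
    if n < 2:
        raise ValueError(f"n_draws must be >= 2, got {n}")
    used_seed = params.seed if seed is None else int(seed)
    findings = validate(params)
    if findings:
        raise ValueError("invalid parameters: " + "; ".join(findings))

    samplers = _psa_samplers(params)
    streams = {
        name: np.random.Generator(np.random.PCG64(child))
        for name, child in zip(PSA_PARAM_ORDER, np.random.SeedSequence(used_seed).spawn(len(PSA_PARAM_ORDER)))
    }

    draws = np.empty(n, dtype=float)
    n_resampled = 0
    for i in range(n):
        for attempt in range(_MAX_RETRIES_PER_DRAW):
            sampled = {name: samplers[name](streams[name]) for name in PSA_PARAM_ORDER}
            candidate = _assemble(params, sampled)
            if not validate(candidate):
                break
            n_resampled += 1
        else:
            raise RuntimeError(
                f"draw {i}: no valid parameter set after {_MAX_RETRIES_PER_DRAW} retries"
            )
        draws[i] = incremental_saving(candidate)
    if n_resampled:
        logger.info("PSA: re-sampled %d invalid parameter sets", n_resampled)

    ci_low, ci_high = np.percentile(draws, [2.5, 97.5], method="linear")
    return PsaResult(
        draws=draws,
        mean=float(draws.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        seed=used_seed,
        n_resampled=n_resampled,
    )
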