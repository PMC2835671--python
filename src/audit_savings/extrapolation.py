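"""Scaling per-case savings to surgeon caseloads and the national level.

The per-case PSA mean and 95% interval for each effect-size scenario are
computed once (with audit administration amortized at the base caseload
of 20) and then multiplied by each caseload — every caseload row of the
scenario table is an exact multiple of its caseload-1 row, mirroring how
the published annual figures scale.  The national projection multiplies
the per-case saving by annual incidence and the surgical uptake fraction.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .parameters import ParameterSet
from .uncertainty import PsaResult, run_psa

#: Effect-size scenarios: 25% (small), 50% (base), 75% (large) reductions.
DEFAULT_REDUCTIONS: tuple[float, ...] = (0.25, 0.50, 0.75)
DEFAULT_CASELOADS: tuple[int, ...] = (1, 20, 40, 70)


def annual_savings(per_case: float, caseload: int) -> float:
    """Annual saving for one surgeon: per-case saving x caseload."""
    if caseload < 1:
        raise ValueError(f"caseload must be >= 1, got {caseload}")
    return per_case * caseload


def national_savings(per_case: float, incidence: float, uptake: float) -> float:
    """National annual saving: per-case x incidence x surgical uptake."""
    if incidence < 0:
        raise ValueError(f"incidence must be >= 0, got {incidence}")
    if not (0.0 <= uptake <= 1.0):
        raise ValueError(f"uptake must be in [0, 1], got {uptake}")
    return per_case * incidence * uptake


def _scenario_seed(seed: int, index: int) -> int:
    # one CLI/script seed drives every scenario deterministically
    return (seed * 1_000_003 + index) % 2**31


def scenario_table(
    params: ParameterSet,
    reductions: Sequence[float] = DEFAULT_REDUCTIONS,
    caseloads: Sequence[int] = DEFAULT_CASELOADS,
    n_draws: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Annual cost-savings by effect-size scenario and surgeon caseload.

    One PSA per reduction scenario (admin cost amortized at
    ``params.annual_caseload``, the base of 20), then the per-case mean
    and CI endpoints are scaled exactly by each caseload.  Columns:
    reduction_fraction, caseload, mean_saving, ci_low, ci_high.
    """
    base_seed = params.seed if seed is None else int(seed)
    rows = []
    for i, reduction in enumerate(reductions):
        psa: PsaResult = run_psa(
            params.replace(reduction_fraction=reduction),
            n_draws=n_draws,
            seed=_scenario_seed(base_seed, i),
        )
        for caseload in caseloads:
            rows.append(
                {
                    "reduction_fraction": reduction,
                    "caseload": int(caseload),
                    "mean_saving": annual_savings(psa.mean, caseload),
                    "ci_low": annual_savings(psa.ci_low, caseload),
                    "ci_high": annual_savings(psa.ci_high, caseload),
                }
            )
    return pd.DataFrame(rows)
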