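"""Elicitation moment-matching, tornado ranking, and PSA behaviour."""

import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from audit_savings.model import expected_arm_cost, incremental_saving
from audit_savings.parameters import RateRange, ShareRange
from audit_savings.uncertainty import (
    ElicitationError,
    beta_from_mean_interval,
    beta_from_mean_sd,
    gamma_from_mean_cv,
    one_way_sa,
    ranged_parameters,
    run_psa,
    tornado,
)

# --------------------------------------------------------------------------
# moment-matched elicitation
# --------------------------------------------------------------------------


def test_symmetric_interval_gives_symmetric_beta():
    spec = beta_from_mean_interval(0.5, 0.3, 0.7)
    assert spec.shape_a == pytest.approx(spec.shape_b, rel=1e-12)


def test_beta_for_leak_rate_matches_targets():
    spec = beta_from_mean_interval(0.044, 0.005, 0.082)
    assert spec.target_sd == pytest.approx((0.082 - 0.005) / 3.92, abs=1e-12)
    assert spec.mean == pytest.approx(0.044, abs=1e-9)
    assert spec.sd == pytest.approx(0.077 / 3.92, abs=1e-9)
    # cross-check the analytic moments against scipy's beta
    dist = scipy.stats.beta(spec.shape_a, spec.shape_b)
    assert dist.mean() == pytest.approx(spec.target_mean, abs=1e-9)
    assert dist.std() == pytest.approx(spec.target_sd, abs=1e-9)


def test_infeasible_beta_moments_raise():
    # an extreme mean with the full unit interval as its 95% range implies
    # sd > sqrt(mean(1-mean)), which no beta can realize
    with pytest.raises(ElicitationError, match="shrink"):
        beta_from_mean_interval(0.97, 0.0, 1.0)
    with pytest.raises(ElicitationError):
        beta_from_mean_sd(0.5, 0.6)
    with pytest.raises(ElicitationError):
        beta_from_mean_interval(0.5, 0.6, 0.7)  # mean outside [low, high]


def test_gamma_for_colon_cost_matches_targets():
    spec = gamma_from_mean_cv(14_283, 0.153)
    assert spec.mean == pytest.approx(14_283, abs=1e-9)
    assert spec.sd == pytest.approx(2_185.3, abs=1.0)
    dist = scipy.stats.gamma(spec.shape_a, scale=spec.shape_b)
    assert dist.mean() == pytest.approx(14_283, abs=1e-6)


def test_gamma_tiny_cv_concentrates_at_mean():
    spec = gamma_from_mean_cv(14_283, 1e-5)
    assert spec.sd < 1.0


def test_gamma_rejects_nonpositive_inputs():
    with pytest.raises(ElicitationError):
        gamma_from_mean_cv(-1.0, 0.1)
    with pytest.raises(ElicitationError):
        gamma_from_mean_cv(100.0, 0.0)


@settings(max_examples=100, derandomize=True)
@given(st.floats(0.01, 0.99), st.floats(0.2, 0.9))
def test_beta_moment_round_trip(mean, sd_frac):
    # keep sd inside the feasible region sd^2 < mean(1-mean)
    sd = sd_frac * math.sqrt(mean * (1 - mean)) * 0.9
    spec = beta_from_mean_sd(mean, sd)
    assert spec.mean == pytest.approx(mean, abs=1e-9)
    assert spec.sd == pytest.approx(sd, abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(st.floats(1.0, 1e6), st.floats(1e-3, 2.0))
def test_gamma_moment_round_trip(mean, cv):
    spec = gamma_from_mean_cv(mean, cv)
    assert spec.shape_a * spec.shape_b == pytest.approx(mean, rel=1e-12)
    assert spec.sd == pytest.approx(mean * cv, rel=1e-9)


# --------------------------------------------------------------------------
# one-way sensitivity analysis / tornado
# --------------------------------------------------------------------------


def test_colon_uncomp_half_width(params):
    entry = one_way_sa(params, "colon_uncomp", output="audit_cost")
    half_width = (entry.output_high - entry.output_low) / 2
    # 0.687 x 0.851 x 0.30 x 14,283
    assert half_width == pytest.approx(2_505.2, abs=5.0)


def test_rectal_uncomp_half_width(params):
    entry = one_way_sa(params, "rectal_uncomp", output="audit_cost")
    half_width = (entry.output_high - entry.output_low) / 2
    # 0.313 x 0.851 x 0.30 x 18,094
    assert half_width == pytest.approx(1_446.0, abs=5.0)


def test_point_range_gives_zero_swing(params):
    entry = one_way_sa(params, "dvt", low=0.035, high=0.035, output="audit_cost")
    assert entry.swing == 0.0


def test_unknown_parameter_lists_valid_names(params):
    with pytest.raises(ValueError, match="colon_uncomp"):
        one_way_sa(params, "not_a_parameter")


def test_tornado_ranks_uncomplicated_costs_first(params):
    entries = tornado(params, output="audit_cost")
    assert [e.parameter for e in entries[:2]] == ["colon_uncomp", "rectal_uncomp"]
    assert len(entries) == len(ranged_parameters(params))
    swings = [e.swing for e in entries]
    assert swings == sorted(swings, reverse=True)


def test_tornado_collapsed_ranges_all_zero(params):
    collapsed = params.replace(
        event_rates={e: RateRange(r.mean, r.mean, r.mean) for e, r in params.event_rates.items()},
        colon_share=ShareRange(0.687, 0.687, 0.687),
        cost_range_fraction=0.0,
    )
    assert all(e.swing == 0.0 for e in tornado(collapsed))


# --------------------------------------------------------------------------
# probabilistic sensitivity analysis
# --------------------------------------------------------------------------


def _near_degenerate(params):
    scale = 1e-4
    rates = {
        e: RateRange(r.mean, r.mean - scale * (r.mean - r.low), r.mean + scale * (r.high - r.mean))
        for e, r in params.event_rates.items()
    }
    return params.replace(
        event_rates=rates,
        colon_share=ShareRange(0.687, 0.687 - scale * 0.01, 0.687 + scale * 0.072),
        cost_range_fraction=params.cost_range_fraction * scale,
        reduction_sd=params.reduction_sd * scale,
    )


def test_psa_is_deterministic_given_seed(params):
    a = run_psa(params, n_draws=300, seed=7)
    b = run_psa(params, n_draws=300, seed=7)
    assert np.array_equal(a.draws, b.draws)
    assert (a.mean, a.ci_low, a.ci_high) == (b.mean, b.ci_low, b.ci_high)
    c = run_psa(params, n_draws=300, seed=8)
    assert not np.array_equal(a.draws, c.draws)


def test_psa_summary_orders(params):
    res = run_psa(params, n_draws=500, seed=3)
    assert res.ci_low <= res.mean <= res.ci_high
    assert res.n_draws == 500
    q = np.percentile(res.draws, [2.5, 97.5], method="linear")
    assert (res.ci_low, res.ci_high) == (q[0], q[1])


def test_psa_degenerate_variance_matches_deterministic(params):
    deterministic = incremental_saving(params)
    res = run_psa(_near_degenerate(params), n_draws=200, seed=11)
    assert res.mean == pytest.approx(deterministic, abs=1.0)
    assert res.ci_high - res.ci_low < 2.0


def test_psa_mean_close_to_deterministic_saving(params):
    """With mean-preserving input distributions the PSA mean sits near the
    deterministic roll-back (the model is close to linear in its inputs)."""
    res = run_psa(params, n_draws=2_000, seed=5)
    assert res.mean == pytest.approx(incremental_saving(params), rel=0.05)


def test_psa_estimator_consistency(params):
    """Across independent seeds the spread of PSA means is consistent with
    the Monte Carlo standard error sd(draws)/sqrt(n)."""
    n_draws, seeds = 2_000, range(20)
    results = [run_psa(params, n_draws=n_draws, seed=s) for s in seeds]
    means = np.array([r.mean for r in results])
    se_theory = np.mean([r.draws.std(ddof=1) for r in results]) / math.sqrt(n_draws)
    ratio = means.std(ddof=1) / se_theory
    assert 1 / 3 < ratio < 3


def test_psa_respects_colon_share_flag(params):
    fixed = params.replace(sample_colon_share=False)
    res = run_psa(fixed, n_draws=100, seed=2)
    assert len(res.draws) == 100
    # identical seeds, flag flipped: draws must differ
    res2 = run_psa(params, n_draws=100, seed=2)
    assert not np.array_equal(res.draws, res2.draws)


def test_psa_rejects_too_few_draws(params):
    with pytest.raises(ValueError):
        run_psa(params, n_draws=1, seed=0)
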