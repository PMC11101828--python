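"""Causal estimators: Wald ratio, IVW, weighted median/mode, MR-Egger."""

import numpy as np
import pytest
from scipy import stats

from mrkit.estimators import (cochran_q, ivw, mr_egger,
                              pvalue_consistency_check, ratio_estimates,
                              weighted_median, weighted_mode, _weighted_median)
from mrkit.harmonize import HarmonizedInstrument

from conftest import make_instruments, random_instruments


def ratios_from(beta, weight):
    """RatioEstimate list with given ratios and weights (se = w^-1/2)."""
    ins = make_instruments(np.ones(len(beta)), np.asarray(beta, dtype=float),
                           se_exp=1e-6, se_out=np.asarray(weight, dtype=float) ** -0.5)
    return ratio_estimates(ins)


# ---------------------------------------------------------------------------
# Wald ratios

def test_wald_ratio_matches_hand_arithmetic(ea_caffeine_instruments):
    (r,) = ratio_estimates(ea_caffeine_instruments)
    assert r.beta_ratio == pytest.approx(-0.0049 / 0.0686)      # -0.0714
    assert r.se_ratio == pytest.approx(0.0023 / 0.0686)         # 0.0335
    # the delta-method CI reproduces the published interval
    assert r.beta_ratio - 1.96 * r.se_ratio == pytest.approx(-0.137, abs=5e-4)
    assert r.beta_ratio + 1.96 * r.se_ratio == pytest.approx(-0.006, abs=5e-4)


def test_null_outcome_effect_gives_zero_ratio():
    (r,) = ratio_estimates(make_instruments([0.1], [0.0], se_out=0.02))
    assert r.beta_ratio == 0.0 and r.se_ratio == pytest.approx(0.2)


def test_ratio_invariant_to_joint_sign_flip():
    a = ratio_estimates(make_instruments([0.1], [0.03]))[0]
    b = ratio_estimates(make_instruments([-0.1], [-0.03]))[0]
    assert a.beta_ratio == b.beta_ratio and a.se_ratio == b.se_ratio


def test_zero_exposure_effect_is_an_error():
    with pytest.raises(ZeroDivisionError):
        ratio_estimates(make_instruments([0.0], [0.1]))


# ---------------------------------------------------------------------------
# IVW

def test_single_instrument_ivw_is_wald_ratio_bitwise(ea_caffeine_instruments):
    (r,) = ratio_estimates(ea_caffeine_instruments)
    res = ivw([r], model="fixed")
    assert res.method == "wald_ratio" and res.n_snps == 1
    assert res.beta == r.beta_ratio and res.se == r.se_ratio


def test_random_effects_with_one_instrument_falls_back_to_wald(ea_caffeine_instruments):
    res = ivw(ratio_estimates(ea_caffeine_instruments), model="multiplicative_random")
    assert res.method == "wald_ratio" and res.notes


def test_two_instrument_fixed_ivw_matches_published_european_estimate(
        eu_caffeine_instruments):
    res = ivw(ratio_estimates(eu_caffeine_instruments), model="fixed")
    assert round(res.beta, 3) == -0.048
    assert round(res.ci_low, 3) == -0.057 and round(res.ci_high, 3) == -0.040


def test_identical_ratios_collapse_both_models():
    gamma = np.array([0.1, 0.2, 0.5])
    ins = make_instruments(gamma, 0.7 * gamma)
    ratios = ratio_estimates(ins)
    fe = ivw(ratios, model="fixed")
    re = ivw(ratios, model="multiplicative_random")
    assert fe.beta == pytest.approx(0.7) == re.beta
    assert fe.se == re.se and fe.q == pytest.approx(0.0, abs=1e-20)


def test_ivw_equals_weighted_regression_through_origin(rng):
    """Algebraic identity: IVW(fixed) is WLS of Gamma on gamma, no intercept,
    weights 1/se_out^2 — checked against statsmodels on random instances."""
    import statsmodels.api as sm
    for _ in range(20):
        ins = random_instruments(rng, j=int(rng.integers(3, 12)))
        res = ivw(ratio_estimates(ins), model="fixed")
        x = np.array([i.beta_exp for i in ins])
        y = np.array([i.beta_out for i in ins])
        w = np.array([1 / i.se_out**2 for i in ins])
        fit = sm.WLS(y, x, weights=w).fit()
        assert res.beta == pytest.approx(fit.params[0], rel=1e-12)
        # statsmodels scales by the residual variance estimate; undo it
        se_unscaled = fit.bse[0] / np.sqrt(fit.scale)
        assert res.se == pytest.approx(se_unscaled, rel=1e-10)


def test_random_effects_se_never_below_fixed(rng):
    for _ in range(10):
        ins = random_instruments(rng, j=8, alpha=rng.normal(0, 0.02, 8))
        ratios = ratio_estimates(ins)
        assert ivw(ratios, "multiplicative_random").se >= ivw(ratios, "fixed").se


def test_q_permutation_invariance_and_zero_iff_equal(rng):
    ins = random_instruments(rng, j=9)
    ratios = ratio_estimates(ins)
    q1 = cochran_q(ratios)[0]
    perm = [ratios[i] for i in rng.permutation(9)]
    assert cochran_q(perm)[0] == pytest.approx(q1, rel=1e-12)
    assert q1 > 0  # noisy ratios are never exactly equal


def test_empty_input_is_an_error():
    with pytest.raises(ValueError):
        ivw([])


# ---------------------------------------------------------------------------
# weighted median

def test_weighted_median_equal_weights_is_simple_median():
    ratios = ratios_from([1.0, 2.0, 10.0], [1.0, 1.0, 1.0])
    res = weighted_median(ratios, n_boot=200, seed=1)
    assert res.beta == pytest.approx(2.0)


def test_weighted_median_three_point_interpolation_by_hand():
    # weights 10,1,1 on ratios 1,2,10: cumulative standardized weights are
    # (5/12, 10.5/12, 11.5/12); interpolating to 0.5 gives 1 + (1/12)/(5.5/12)
    ratios = ratios_from([1.0, 2.0, 10.0], [10.0, 1.0, 1.0])
    res = weighted_median(ratios, n_boot=200, seed=1)
    assert res.beta == pytest.approx(1.0 + 1.0 / 5.5, rel=1e-12)


def test_weighted_median_equal_weights_even_count_interpolates():
    ratios = ratios_from([1.0, 2.0, 3.0, 4.0], np.ones(4))
    assert weighted_median(ratios, n_boot=200, seed=1).beta == pytest.approx(2.5)


def test_weighted_median_resists_minority_invalid_instruments(rng):
    """7 valid instruments at ratio 0.5 plus 3 at 5.0: the median stays near
    0.5 while IVW is dragged upward."""
    beta = np.r_[rng.normal(0.5, 0.02, 7), rng.normal(5.0, 0.02, 3)]
    ratios = ratios_from(beta, np.ones(10))
    med = weighted_median(ratios, n_boot=500, seed=2).beta
    mean = ivw(ratios, "fixed").beta
    assert abs(med - 0.5) < 0.1
    assert abs(mean - 0.5) > 1.0


def test_weighted_median_seed_reproducible_and_needs_three():
    ratios = ratios_from([1.0, 2.0, 3.0], np.ones(3))
    a = weighted_median(ratios, n_boot=200, seed=7)
    b = weighted_median(ratios, n_boot=200, seed=7)
    assert a.se == b.se
    with pytest.raises(ValueError):
        weighted_median(ratios[:2], n_boot=200, seed=1)


def test_weighted_median_helper_handles_ties_stably():
    b = np.array([2.0, 2.0, 1.0])
    w = np.array([1.0, 1.0, 1.0])
    assert _weighted_median(b, w) == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# weighted mode

def test_mode_of_identical_ratios_is_the_common_value():
    gamma = np.array([0.1, 0.2, 0.4])
    ratios = ratio_estimates(make_instruments(gamma, 0.9 * gamma))
    res = weighted_mode(ratios, n_boot=100, seed=3)
    assert res.beta == pytest.approx(0.9)


def test_mode_finds_majority_cluster_against_grid_oracle(rng):
    beta = np.r_[rng.normal(0.5, 0.05, 8), np.array([5.0, 5.1])]
    ratios = ratios_from(beta, np.ones(10))
    res = weighted_mode(ratios, n_boot=100, seed=4)
    assert 0.3 < res.beta < 0.7
    # oracle: plain argmax of the weighted normal-pdf mixture on a fine grid
    h = 0.9 * min(beta.std(ddof=1), np.subtract(*np.percentile(beta, [75, 25])) / 1.34) \
        * len(beta) ** -0.2
    grid = np.linspace(beta.min() - 3 * h, beta.max() + 3 * h, 200_001)
    dens = stats.norm.pdf((grid[:, None] - beta[None, :]) / h).sum(axis=1)
    assert res.beta == pytest.approx(grid[np.argmax(dens)], abs=1e-3)


def test_mode_invariant_to_weight_rescaling(rng):
    beta = rng.normal(0.4, 0.1, 6)
    a = weighted_mode(ratios_from(beta, np.ones(6)), n_boot=100, seed=5)
    b = weighted_mode(ratios_from(beta, 2 * np.ones(6)), n_boot=100, seed=5)
    assert a.beta == pytest.approx(b.beta, rel=1e-9)


# ---------------------------------------------------------------------------
# MR-Egger

def test_egger_recovers_exact_linear_data():
    gamma = np.array([0.1, 0.2, 0.3, 0.5])
    a, b = 0.01, 0.7
    ins = make_instruments(gamma, a + b * gamma)
    res = mr_egger(ins)
    assert res.egger_intercept == pytest.approx(a, rel=1e-9)
    assert res.beta == pytest.approx(b, rel=1e-9)
    # exact fit: residual factor floored at 1, so SEs stay positive
    assert res.se > 0 and res.egger_intercept_se > 0


def test_egger_no_pleiotropy_limit():
    gamma = np.array([0.08, 0.15, 0.22, 0.4, 0.12])
    ins = make_instruments(gamma, 0.3 * gamma)
    res = mr_egger(ins)
    assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)
    assert res.beta == pytest.approx(0.3, rel=1e-9)


def test_egger_matches_normal_equations_oracle(rng):
    """Closed-form (X'WX)^-1 X'Wy on the gamma-oriented data."""
    ins = random_instruments(rng, j=10, alpha=rng.normal(0.01, 0.01, 10))
    res = mr_egger(ins)
    sign = np.sign([i.beta_exp for i in ins])
    x = sign * np.array([i.beta_exp for i in ins])
    y = sign * np.array([i.beta_out for i in ins])
    w = np.array([1 / i.se_out**2 for i in ins])
    X = np.column_stack([np.ones(10), x])
    coef = np.linalg.solve(X.T * w @ X, X.T @ (w * y))
    assert res.egger_intercept == pytest.approx(coef[0], rel=1e-10)
    assert res.beta == pytest.approx(coef[1], rel=1e-10)
    # and statsmodels WLS agrees
    import statsmodels.api as sm
    fit = sm.WLS(y, X, weights=w).fit()
    assert res.beta == pytest.approx(fit.params[1], rel=1e-10)


def test_egger_orientation_makes_result_allele_flip_invariant(rng):
    ins = random_instruments(rng, j=8, alpha=rng.normal(0.005, 0.01, 8))
    flipped = [HarmonizedInstrument(
        variant_id=i.variant_id, beta_exp=-i.beta_exp, se_exp=i.se_exp,
        beta_out=-i.beta_out, se_out=i.se_out, eaf_exp=1 - i.eaf_exp,
        eaf_out=1 - i.eaf_out) for i in ins[:4]] + list(ins[4:])
    a, b = mr_egger(ins), mr_egger(flipped)
    assert a.beta == pytest.approx(b.beta, rel=1e-12)
    assert a.egger_intercept == pytest.approx(b.egger_intercept, rel=1e-12)


def test_egger_requires_three_and_noncollinear():
    gamma = np.array([0.1, 0.2])
    with pytest.raises(ValueError):
        mr_egger(make_instruments(gamma, 0.3 * gamma))
    same = np.full(4, 0.2)
    with pytest.raises(ValueError, match="collinear"):
        mr_egger(make_instruments(same, 0.3 * same))


# ---------------------------------------------------------------------------
# cross-cutting properties

def test_scale_equivariance_of_all_estimators(rng):
    """Multiplying exposure effects by c scales every estimate by 1/c and
    leaves p-values unchanged."""
    ins = random_instruments(rng, j=8)
    c = 2.5
    scaled = [HarmonizedInstrument(
        variant_id=i.variant_id, beta_exp=c * i.beta_exp, se_exp=c * i.se_exp,
        beta_out=i.beta_out, se_out=i.se_out, eaf_exp=i.eaf_exp,
        eaf_out=i.eaf_out) for i in ins]
    r1, r2 = ratio_estimates(ins), ratio_estimates(scaled)
    for base, sc in [(ivw(r1, "fixed"), ivw(r2, "fixed")),
                     (weighted_median(r1, 300, seed=6), weighted_median(r2, 300, seed=6)),
                     (mr_egger(ins), mr_egger(scaled))]:
        assert sc.beta == pytest.approx(base.beta / c, rel=1e-9)
        assert sc.pvalue == pytest.approx(base.pvalue, rel=1e-6)


# ---------------------------------------------------------------------------
# p-value consistency

@pytest.mark.parametrize("beta,se,expected,rel", [
    (0.0686, 0.0187, 2.42e-4, 0.02),   # printed alongside the source table
    (1.96, 1.0, 0.05, 0.002),
])
def test_pvalue_recomputation(beta, se, expected, rel):
    assert pvalue_consistency_check(beta, se) == pytest.approx(expected, rel=rel)


def test_pvalue_null_beta_is_one():
    assert pvalue_consistency_check(0.0, 0.1) == 1.0
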