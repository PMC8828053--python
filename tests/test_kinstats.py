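"""Survival curves, censored MLE, counting statistics, G tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cosmofret.kinstats import (
    conditional_fraction,
    estimate_bleach_rate,
    expected_two_label_fraction,
    fit_exponential_mle,
    grouped_median,
    model_expected_proportions,
    offset_histogram,
    pattern_frequency_test,
    proportion_with_se,
    survival_curve,
    wilson_interval,
)


def test_survival_equals_ecdf_complement_without_censoring(rng):
    d = rng.exponential(20.0, 200)
    sc = survival_curve(d)
    d_sorted = np.sort(d)
    for i, t in enumerate(d_sorted):
        # S(t) right after the i-th event time equals 1 - (i+1)/n exactly
        assert sc.at(t) == pytest.approx(1.0 - (i + 1) / 200, abs=1e-12)
    assert sc.at(0.0) == 1.0


def test_survival_matches_lifelines_with_censoring(rng):
    """Dual-route check: product-limit estimates agree with lifelines'
    KaplanMeierFitter on a censored sample."""
    lifelines = pytest.importorskip("lifelines")
    d = rng.exponential(30.0, 150)
    c = rng.random(150) < 0.3
    d[c] = d[c] * rng.random(c.sum())  # censor at random earlier times
    sc = survival_curve(d, c)
    kmf = lifelines.KaplanMeierFitter()
    kmf.fit(d, event_observed=~c)
    for t in (5.0, 15.0, 40.0, 80.0):
        assert sc.at(t) == pytest.approx(
            float(kmf.predict(t)), abs=1e-9)


def test_survival_at_tau_close_to_inverse_e(rng):
    tau = 25.0
    d = rng.exponential(tau, 10_000)
    sc = survival_curve(d)
    lo, hi = sc.ci_at(tau)
    assert lo <= np.exp(-1.0) <= hi


def test_greenwood_interval_coverage(rng):
    """95% Greenwood band covers the true survival ~95% of the time
    (independent right-censoring, as the estimator assumes)."""
    tau, n, reps, t0 = 30.0, 200, 400, 25.0
    true_s = np.exp(-t0 / tau)
    cover = 0
    for _ in range(reps):
        d = rng.exponential(tau, n)
        censor_at = rng.exponential(90.0, n)
        cens = censor_at < d
        obs = np.minimum(d, censor_at)
        sc = survival_curve(obs, cens)
        lo, hi = sc.ci_at(t0)
        cover += lo <= true_s <= hi
    assert 0.91 <= cover / reps <= 0.985


@given(st.lists(st.floats(0.1, 100.0), min_size=3, max_size=40))
@settings(max_examples=40, deadline=None)
def test_survival_monotone_and_bracketed(durations):
    sc = survival_curve(durations)
    assert np.all(np.diff(sc.survival) <= 1e-12)
    assert np.all(sc.ci_lower <= sc.survival + 1e-12)
    assert np.all(sc.ci_upper >= sc.survival - 1e-12)


def test_survival_empty_input_raises():
    with pytest.raises(ValueError):
        survival_curve([])


def test_mle_uncensored_equals_arithmetic_mean(rng):
    d = rng.exponential(12.0, 50)
    fit = fit_exponential_mle(d, bootstrap_B=0)
    assert fit.mean_s == pytest.approx(d.mean())


def test_mle_censored_recovery(rng):
    tau, n = 30.0, 300
    d = rng.exponential(tau, n)
    cut = 35.0
    c = d > cut
    d = np.minimum(d, cut)
    fit = fit_exponential_mle(d, c, bootstrap_B=300, rng_seed=1)
    assert c.sum() > 50
    assert abs(fit.mean_s - tau) < 3 * fit.se_s


def test_mle_left_truncation_correction(rng):
    """Observations conditioned on exceeding a detection cutoff recover
    the untruncated mean when the cutoff is declared."""
    tau, cut = 30.0, 5.0
    d = rng.exponential(tau, 20_000)
    d = d[d > cut][:5000]
    fit = fit_exponential_mle(d, bootstrap_B=0, min_duration=cut)
    assert abs(fit.mean_s - tau) < 3 * tau / np.sqrt(5000)


def test_mle_bootstrap_se_matches_asymptotic(rng):
    tau, n = 30.0, 400
    d = rng.exponential(tau, n)
    fit = fit_exponential_mle(d, bootstrap_B=800, rng_seed=2)
    assert fit.se_s == pytest.approx(fit.mean_s / np.sqrt(n), rel=0.25)


def test_mle_all_censored_raises():
    with pytest.raises(ValueError):
        fit_exponential_mle([5.0, 6.0], [True, True])


def test_bleach_rate_decomposition_exact():
    """Noiseless observed rates at the two exposures invert the forward
    model k_obs = k_i + f * k_b exactly."""
    from cosmofret.kinstats import RateFit

    k_i, k_b = 0.01, 0.005
    f1 = RateFit(mean_s=1.0 / (k_i + 1.0 * k_b), se_s=0.0, n=10,
                 n_censored=0, log_likelihood=0.0)
    f2 = RateFit(mean_s=1.0 / (k_i + 2.4 * k_b), se_s=0.0, n=10,
                 n_censored=0, log_likelihood=0.0)
    (kb, _), (ki, _) = estimate_bleach_rate(f1, f2)
    assert kb == pytest.approx(k_b)
    assert ki == pytest.approx(k_i)


def test_bleach_rate_equal_rates_gives_zero_bleach():
    from cosmofret.kinstats import RateFit

    f = RateFit(100.0, 5.0, 10, 0, 0.0)
    (kb, _), (ki, _) = estimate_bleach_rate(f, f)
    assert kb == pytest.approx(0.0)
    assert ki == pytest.approx(0.01)


def test_bleach_rate_identical_exposures_singular():
    from cosmofret.kinstats import RateFit

    f = RateFit(100.0, 5.0, 10, 0, 0.0)
    with pytest.raises(ValueError):
        estimate_bleach_rate(f, f, 1.0, 1.0)


def test_two_label_fraction():
    assert expected_two_label_fraction(0.88) == pytest.approx(0.7744)
    assert expected_two_label_fraction(1.0) == 1.0
    assert expected_two_label_fraction(0.5) == 0.25
    with pytest.raises(ValueError):
        expected_two_label_fraction(1.2)


def test_proportions_match_printed_values():
    p, se = proportion_with_se(37, 82)
    assert round(p, 2) == 0.45 and round(se, 2) == 0.05
    p, se = proportion_with_se(22, 90)
    assert p == pytest.approx(0.2444, abs=1e-3)
    assert se == pytest.approx(0.0453, abs=1e-3)
    assert proportion_with_se(0, 50) == (0.0, 0.0)
    p, _ = proportion_with_se(22, 166)
    assert round(100 * p) == 13
    with pytest.raises(ValueError):
        proportion_with_se(1, 0)


def test_wilson_interval_contains_point_estimate():
    lo, hi = wilson_interval(37, 82)
    assert lo < 37 / 82 < hi


def test_conditional_fraction_printed_ratio():
    p1, s1 = 0.18, 0.02
    p2, s2 = 0.23, 0.02
    r, se = conditional_fraction(p1, s1, p2, s2)
    assert 0.78 <= r <= 0.79
    assert se > 0
    with pytest.raises(ValueError):
        conditional_fraction(0.1, 0.01, 0.0, 0.01)


def test_conditional_fraction_self_ratio_is_one():
    r, _ = conditional_fraction(0.3, 0.02, 0.3, 0.02)
    assert r == 1.0


def test_g_test_printed_profile_counts():
    """The observed profile counts are consistent with equal quarters
    (single-ORC flip) and structurally impossible under re-interaction."""
    obs = [25, 21, 22, 22]
    r = pattern_frequency_test(obs, model_expected_proportions("orc_flip"))
    assert r.p_value > 0.05 and not r.structural_zero_violated
    r2 = pattern_frequency_test(obs, model_expected_proportions("re_fret"))
    assert r2.p_value == 0.0 and r2.structural_zero_violated


def test_g_test_zero_at_expectation():
    r = pattern_frequency_test([25, 25, 25, 25], [0.25] * 4)
    assert r.g == 0.0 and r.p_value == pytest.approx(1.0, abs=1e-9)


def test_g_test_exact_p_matches_enumeration_oracle():
    """Exact small-n p equals a brute-force enumeration computed here."""
    import itertools
    import math

    obs = [6, 1, 3]
    props = np.array([0.5, 0.25, 0.25])
    n = sum(obs)
    exp = n * props

    def g_of(c):
        return 2 * sum(ci * math.log(ci / ei)
                       for ci, ei in zip(c, exp) if ci > 0)

    g_obs = g_of(obs)
    p_brute = 0.0
    for c1 in range(n + 1):
        for c2 in range(n + 1 - c1):
            c3 = n - c1 - c2
            c = (c1, c2, c3)
            if g_of(c) >= g_obs - 1e-9:
                pmf = (math.factorial(n)
                       / math.prod(math.factorial(x) for x in c)
                       * math.prod(p ** x for p, x in zip(props, c)))
                p_brute += pmf
    r = pattern_frequency_test(obs, props)
    assert r.exact
    assert r.p_value == pytest.approx(p_brute, rel=1e-6)


def test_g_test_type_i_error_near_alpha(rng):
    """Multinomial null at n=90: rejection rate at alpha=0.05 is ~5%
    (chi-square reference used for speed)."""
    reps, alpha = 400, 0.05
    rej = 0
    for _ in range(reps):
        obs = rng.multinomial(90, [0.25] * 4)
        r = pattern_frequency_test(obs, [0.25] * 4, exact_max_n=0)
        rej += r.p_value < alpha
    assert 0.02 <= rej / reps <= 0.09


def test_offset_histogram_centred():
    edges, counts, frac, se = offset_histogram([0.0] * 12)
    centre = np.argmax(counts)
    mid = 0.5 * (edges[centre] + edges[centre + 1])
    assert mid == pytest.approx(0.0)
    assert counts[centre] == 12 and frac[centre] == 1.0


def test_offset_histogram_shifted_exponential(rng):
    lags = rng.exponential(8.3, 400)
    edges, counts, frac, se = offset_histogram(lags)
    mean = np.average(0.5 * (edges[:-1] + edges[1:]), weights=counts)
    assert abs(mean - 8.3) < 3 * 8.3 / np.sqrt(400) + 1.2


def test_grouped_median_resolves_lattice(rng):
    """Frame-quantised exponential dwells: the interpolated median lands
    near the true median even though raw values sit on a 2.4-s grid."""
    true_median = 11.0
    tau = true_median / np.log(2.0)
    x = rng.exponential(tau, 4000)
    q = np.round((x - 1.2) / 2.4) * 2.4 + 1.2  # lattice at 1.2 + 2.4k
    med, se = grouped_median(q, 2.4, B=200, rng_seed=0)
    assert abs(med - true_median) < 0.8
    assert se > 0
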