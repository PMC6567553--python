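"""Rate estimation: exact Poisson CIs, standardization, pooling, prevalence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import als_epi as ae
from als_epi.bands import BAND_LABELS, SEXES


def poisson_ci_bisect(k: int, level: float = 0.95) -> tuple[float, float]:
    """Independent oracle: bisection on the cumulative Poisson tail sums.

    low solves P(X >= k | mu) = alpha/2 (upper tail, increasing in mu);
    high solves P(X <= k | mu) = alpha/2 (lower tail, decreasing in mu).
    """
    alpha = (1 - level) / 2

    def tail_sum(mu, lo_term, hi_term):
        ks = np.arange(lo_term, hi_term + 1)
        return float(stats.poisson.pmf(ks, mu).sum())

    def bisect(f, target, lo, hi, increasing):
        for _ in range(100):
            mid = (lo + hi) / 2
            val = f(mid)
            if (val < target) == increasing:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    big = int(10 * k + 200)
    low = 0.0 if k == 0 else bisect(
        lambda mu: tail_sum(mu, k, big), alpha, 1e-9, 3.0 * k + 10, increasing=True
    )
    high = bisect(
        lambda mu: tail_sum(mu, 0, k), alpha, 1e-9, 3.0 * k + 50, increasing=False
    )
    return low, high


def _uniform_table(value: float) -> ae.CountTable:
    t = ae.CountTable(study_years=14)
    for sex in SEXES:
        for band in BAND_LABELS:
            t.set(sex, band, value)
    return t


def _uniform_pop(value: float, label="r") -> ae.PopulationTable:
    frame = pd.DataFrame(value, index=list(BAND_LABELS), columns=list(SEXES))
    return ae.PopulationTable(frame, label=label)


# ---------------------------------------------------------------------------
# exact Poisson intervals


def test_poisson_ci_zero_events_has_zero_lower_bound():
    low, high = ae.poisson_exact_ci(0, 0.95)
    assert low == 0.0
    assert high == pytest.approx(3.688879, abs=1e-5)


def test_poisson_ci_k10_matches_frozen_oracle_values():
    # frozen from the tail-sum bisection oracle above
    low, high = ae.poisson_exact_ci(10, 0.95)
    assert low == pytest.approx(4.795389, rel=1e-6)
    assert high == pytest.approx(18.390356, rel=1e-6)


@pytest.mark.parametrize("k", [1, 2, 5, 17, 50])
def test_poisson_ci_agrees_with_bisection_oracle(k):
    low, high = ae.poisson_exact_ci(k, 0.95)
    olow, ohigh = poisson_ci_bisect(k)
    assert low == pytest.approx(olow, rel=1e-6)
    assert high == pytest.approx(ohigh, rel=1e-6)


def test_poisson_ci_rejects_negative_count():
    with pytest.raises(ValueError):
        ae.poisson_exact_ci(-1)


@given(st.floats(min_value=0.1, max_value=500), st.floats(min_value=0.5, max_value=0.999))
@settings(max_examples=100, deadline=None)
def test_poisson_ci_brackets_the_count(k, level):
    low, high = ae.poisson_exact_ci(k, level)
    assert 0 <= low <= k <= high


# ---------------------------------------------------------------------------
# crude and specific rates


def test_crude_rate_arithmetic_and_frozen_ci():
    est = ae.crude_rate(20, 1_000_000)
    assert est.rate == pytest.approx(2.0)
    est = ae.crude_rate(10, 500_000)
    assert est.rate == pytest.approx(2.0)
    assert est.ci_low == pytest.approx(0.959078, rel=1e-5)
    assert est.ci_high == pytest.approx(3.678071, rel=1e-5)
    zero = ae.crude_rate(0, 1000)
    assert zero.rate == 0 and zero.ci_low == 0


def test_crude_rate_requires_positive_person_years():
    with pytest.raises(ValueError):
        ae.crude_rate(1, 0)


def test_lsl_like_crude_rate_reproduces_printed_interval(lsl_bundle):
    """122.9 weighted cases over the fixture's person-years -> 1.29 (1.07-1.53)."""
    config, _frame, _truth, cases = lsl_bundle
    kept, _ = ae.apply_exclusions(cases, "incidence")
    overlaps = {
        r.sector_id: ae.SectorOverlap(r.sector_id, r.fraction_in_catchment)
        for r in ae.gen_sector_overlaps(config).itertuples()
    }
    counts = ae.bin_cases(ae.weight_by_sector(kept, overlaps), 14)
    est = ae.crude_rate(counts.total(), config.pop_15plus * 14)
    assert round(est.rate, 2) == 1.29
    assert round(est.ci_low, 2) == 1.07
    assert round(est.ci_high, 2) == 1.53


def test_specific_rates_cell_arithmetic():
    counts = _uniform_table(7.0)
    counts.set("male", "65-69", 7.0)
    pop = _uniform_pop(25_000)
    table = ae.specific_rates(counts, pop, 14)
    assert table.rate("male", "65-69") == pytest.approx(7 / (25_000 * 14) * 1e5)
    # homogeneity: counts proportional to population -> identical rates
    assert len({round(table.rate(s, b), 12) for s in SEXES for b in BAND_LABELS}) == 1


def test_specific_rates_rejects_zero_population_cell():
    pop_frame = pd.DataFrame(1000.0, index=list(BAND_LABELS), columns=list(SEXES))
    pop_frame.at["90+", "female"] = 0.0
    with pytest.raises(ValueError, match="90"):
        ae.specific_rates(_uniform_table(1.0), ae.PopulationTable(pop_frame), 14)


# ---------------------------------------------------------------------------
# direct standardization


def _rate_table(rates_by_cell: dict) -> ae.RateTable:
    ests = {}
    for sex in SEXES:
        for band in BAND_LABELS:
            r = rates_by_cell.get((sex, band), 1.0)
            ests[sex, band] = ae.RateEstimate(r, r, r, 0.95, "poisson_exact", 1, 1e5)
    return ae.RateTable(ests, 14)


def test_standardize_is_weighted_mean_of_band_rates():
    # two informative bands, rates 1 and 3, standard weights 25%/75% -> 2.5
    rates = _rate_table({("male", b): 0.0 for b in BAND_LABELS}
                        | {("female", b): 0.0 for b in BAND_LABELS}
                        | {("male", "60-64"): 1.0, ("male", "65-69"): 3.0})
    std_frame = pd.DataFrame(0.0, index=list(BAND_LABELS), columns=list(SEXES))
    std_frame.at["60-64", "male"] = 25_000
    std_frame.at["65-69", "male"] = 75_000
    std = ae.StandardPopulation(std_frame)
    est = ae.direct_standardize(rates, std, sex="male")
    assert est.rate == pytest.approx(2.5)


def test_self_standardization_recovers_crude_rate(canterbury_bundle):
    config, _frame, _truth, cases = canterbury_bundle
    kept, _ = ae.apply_exclusions(cases, "incidence")
    counts = ae.bin_cases([(c, 1.0) for c in kept], 14)
    counts = ae.substitute_zero_cells(counts)
    pop_frame = ae.gen_population(config).pivot_table(
        index="age_band", columns="sex", values="count"
    )
    pop = ae.PopulationTable(pop_frame)
    table = ae.specific_rates(counts, pop, 14)
    std = ae.StandardPopulation(pop_frame)
    est = ae.direct_standardize(table, std)
    crude = ae.crude_rate(counts.total(), pop.total() * 14)
    assert est.rate == pytest.approx(crude.rate, rel=1e-12)


def test_constant_rate_is_invariant_under_any_standard():
    rates = _rate_table({})  # all cells rate 1.0
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(
        rng.uniform(100, 10_000, size=(len(BAND_LABELS), 2)),
        index=list(BAND_LABELS), columns=list(SEXES),
    )
    est = ae.direct_standardize(rates, ae.StandardPopulation(frame))
    assert est.rate == pytest.approx(1.0)


def test_standardized_rate_bounded_by_band_rates():
    rng = np.random.default_rng(1)
    cell_rates = {
        (s, b): float(rng.uniform(0.5, 5)) for s in SEXES for b in BAND_LABELS
    }
    rates = _rate_table(cell_rates)
    frame = pd.DataFrame(
        rng.uniform(100, 10_000, size=(len(BAND_LABELS), 2)),
        index=list(BAND_LABELS), columns=list(SEXES),
    )
    est = ae.direct_standardize(rates, ae.StandardPopulation(frame))
    assert min(cell_rates.values()) <= est.rate <= max(cell_rates.values())


def test_binomial_se_scaling_and_printed_interval_shape():
    se, low, high = ae.standardized_rate_se(2.74, 62_760_000)
    # the binomial-SE reading reproduces the printed pooled CI to ~0.05
    assert low == pytest.approx(2.59, abs=0.05)
    assert high == pytest.approx(2.88, abs=0.05)
    se2, _, _ = ae.standardized_rate_se(2.74, 2 * 62_760_000)
    assert se2 == pytest.approx(se / np.sqrt(2))
    se0, lo0, hi0 = ae.standardized_rate_se(0.0, 1000)
    assert se0 == 0 and lo0 == 0 and hi0 == 0


# ---------------------------------------------------------------------------
# standardized rate ratio


def _estimate(rate, lo, hi):
    return ae.RateEstimate(rate, lo, hi, 0.95, "binomial_se", 100, 1e6)


def test_rate_ratio_of_printed_standardized_rates():
    canterbury = _estimate(3.25, 3.09, 3.40)
    lsl = _estimate(2.10, 1.97, 2.22)
    ratio, lo, hi = ae.standardized_rate_ratio(canterbury, lsl)
    assert round(ratio, 2) == 1.55
    assert lo == pytest.approx(1.43, abs=0.02)
    assert hi == pytest.approx(1.67, abs=0.02)


def test_rate_ratio_identity_and_reciprocity():
    a = _estimate(2.5, 2.3, 2.7)
    b = _estimate(1.9, 1.7, 2.1)
    assert ae.standardized_rate_ratio(a, a)[0] == pytest.approx(1.0)
    assert (
        ae.standardized_rate_ratio(a, b)[0] * ae.standardized_rate_ratio(b, a)[0]
        == pytest.approx(1.0)
    )


# ---------------------------------------------------------------------------
# pooling


def test_pooling_identity_and_mediant_bounds():
    counts_a = _uniform_table(1.0)
    counts_b = _uniform_table(3.0)
    pop = _uniform_pop(10_000, "a")
    pooled, pooled_counts, pooled_pop = ae.pool_regions(counts_a, pop, counts_b, pop, 14)
    # equal populations: pooled cell rate is the mean of the two cell rates
    ra = ae.specific_rates(counts_a, pop, 14).rate("male", "65-69")
    rb = ae.specific_rates(counts_b, pop, 14).rate("male", "65-69")
    assert pooled.rate("male", "65-69") == pytest.approx((ra + rb) / 2)
    # pooled crude between the regional crude rates
    crude_pooled = pooled_counts.total() / (pooled_pop.total() * 14)
    assert min(counts_a.total(), counts_b.total()) / (pop.total() * 14) <= crude_pooled
    assert crude_pooled <= max(counts_a.total(), counts_b.total()) / (pop.total() * 14)


def test_pooling_re_evaluates_zero_cell_substitution():
    a = ae.CountTable(study_years=14)
    b = ae.CountTable(study_years=14)
    b.set("male", "65-69", 4.0)
    a_sub = ae.substitute_zero_cells(a)
    b_sub = ae.substitute_zero_cells(b)
    pop = _uniform_pop(10_000)
    _pooled, pooled_counts, _ = ae.pool_regions(a_sub, pop, b_sub, pop, 14)
    # the cell with real cases is rescued from substitution after pooling
    assert pooled_counts["male", "65-69"] == 4.0
    assert ("male", "65-69") not in pooled_counts.substituted
    # still-empty cells get a fresh single 0.5, not 0.5 + 0.5
    assert pooled_counts["female", "15-19"] == 0.5


# ---------------------------------------------------------------------------
# Wilson intervals and prevalence


def test_wilson_frozen_value_and_boundaries():
    low, high = ae.wilson_ci(5, 100, 0.95)
    assert low == pytest.approx(0.021543, abs=1e-5)
    assert high == pytest.approx(0.111750, abs=1e-5)
    assert ae.wilson_ci(0, 100)[0] == 0.0
    with pytest.raises(ValueError):
        ae.wilson_ci(101, 100)


def test_wilson_matches_statsmodels_reference():
    from statsmodels.stats.proportion import proportion_confint

    for k, n in [(0, 10), (3, 17), (44, 530_000), (250, 500)]:
        low, high = ae.wilson_ci(k, n, 0.95)
        ref_low, ref_high = proportion_confint(k, n, alpha=0.05, method="wilson")
        assert low == pytest.approx(ref_low, abs=1e-10)
        assert high == pytest.approx(ref_high, abs=1e-10)


@given(st.integers(min_value=0, max_value=1000), st.integers(min_value=1, max_value=10_000))
@settings(max_examples=100, deadline=None)
def test_wilson_interval_within_unit_range(k, n):
    if k > n:
        k = n
    low, high = ae.wilson_ci(k, n)
    assert 0 <= low <= k / n <= high <= 1


def test_point_prevalence_matches_hand_division():
    est = ae.point_prevalence(44, 530_000)
    assert est.rate == pytest.approx(44 / 530_000 * 1e5)
    assert round(est.rate, 2) == 8.30
    assert ae.point_prevalence(0, 1000).rate == 0
    # scale invariance of the point estimate
    assert ae.point_prevalence(88, 1_060_000).rate == pytest.approx(est.rate)


def test_prevalence_requires_positive_population():
    with pytest.raises(ValueError):
        ae.point_prevalence(1, 0)
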