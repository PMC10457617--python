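"""Natural-history unit tests against closed-form and hand-computed oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_cancer, make_individual

import crcscreen.natural_history as nh
from crcscreen.params import ConfigurationError, LifeTable


def deterministic_life_table(death_year: int = 80) -> LifeTable:
    q = np.zeros(101)
    q[death_year] = 1.0
    q[100] = 1.0
    return LifeTable(np.arange(101), {"female": q, "male": q})


# ---------------------------------------------------------------------------
# draw_individual


def test_zero_frailty_variance_gives_zero_frailty(params_factory, rng):
    p = params_factory({"frailty_sd": 0.0})
    frailties = {nh.draw_individual(p, i, rng).frailty for i in range(50)}
    assert frailties == {0.0}


def test_deterministic_life_table_fixes_death_year(params_factory, rng):
    p = params_factory({"frailty_sd": 0.0})
    table = deterministic_life_table(80)
    ages = [table.draw_death_age("female", rng, from_age=40) for _ in range(200)]
    assert all(80.0 <= a < 81.0 for a in ages)


def test_death_age_mean_matches_life_table_expectation(params, rng):
    """Inverse-CDF draws must reproduce the discrete survival-curve mean
    (computed here by direct summation, independent of the draw path)."""
    table = params.life_table
    # independent oracle: direct summation of the conditional survival curve
    q = table.qx["male"][40:]
    surv = np.concatenate([[1.0], np.cumprod(1.0 - q)[:-1]])
    pmf = surv * q
    pmf /= pmf.sum()
    expected = float(np.sum(pmf * (np.arange(40, 101) + 0.5)))
    n = 30_000
    draws = np.array([table.draw_death_age("male", rng, from_age=40) for _ in range(n)])
    se = draws.std() / math.sqrt(n)
    assert abs(draws.mean() - expected) < 3 * se


def test_invalid_params_raise_configuration_error_naming_field(params_factory):
    with pytest.raises(ConfigurationError, match="frailty_sd"):
        params_factory({"frailty_sd": -1.0})
    with pytest.raises(ConfigurationError, match="stage_dwell_means"):
        params_factory({"stage_dwell_means": [1.0, -2.0, 1.0]})
    with pytest.raises(ConfigurationError, match="unknown parameter keys"):
        params_factory({"not_a_real_knob": 1.0})


# ---------------------------------------------------------------------------
# generate_adenomas


def test_zero_intensity_yields_no_adenomas(params_factory, rng):
    p = params_factory({"adenoma_baseline_log_rate": -math.inf})
    ind = nh.draw_individual(p, 0, rng)
    assert nh.generate_adenomas(ind, p, rng) == []


def test_adenoma_counts_are_poisson_with_closed_form_mean(params_factory, rng):
    """Homogeneous case (flat age effect, no frailty or sex effect): counts
    over ages 40-100 are Poisson(rate * 60); mean and variance to 3 SE."""
    log_rate = -4.0
    p = params_factory({
        "adenoma_baseline_log_rate": log_rate,
        "frailty_sd": 0.0,
        "sex_log_effect": 0.0,
        "age_effect_knots": [[40, 1.0]],
    })
    lam = math.exp(log_rate) * 60.0  # closed-form Poisson mean
    n = 30_000
    counts = np.empty(n)
    for i in range(n):
        ind = nh.draw_individual(p, i, rng)
        counts[i] = len(nh.generate_adenomas(ind, p, rng))
    se_mean = math.sqrt(lam / n)
    assert abs(counts.mean() - lam) < 3 * se_mean
    # Var = mean for Poisson; SE of sample variance ~ sqrt(2/n)*lam for small lam
    se_var = math.sqrt((lam + 3 * lam**2 + lam) / n)
    assert abs(counts.var() - lam) < 3 * se_var


def test_doubling_baseline_rate_doubles_mean_count(params_factory, rng):
    common = {"frailty_sd": 0.0, "sex_log_effect": 0.0, "age_effect_knots": [[40, 1.0]]}
    n = 20_000
    means = []
    for log_rate in (-4.0, -4.0 + math.log(2)):
        p = params_factory({**common, "adenoma_baseline_log_rate": log_rate})
        total = 0
        for i in range(n):
            ind = nh.draw_individual(p, i, rng)
            total += len(nh.generate_adenomas(ind, p, rng))
        means.append(total / n)
    lam = math.exp(-4.0) * 60
    se = math.sqrt(2 * lam / n) * 2  # conservative combined SE
    assert abs(means[1] - 2 * means[0]) < 3 * se


def test_onset_ages_respect_age_effect_support(params_factory, rng):
    p = params_factory({"adenoma_baseline_log_rate": -2.0, "frailty_sd": 0.0})
    ind = nh.draw_individual(p, 0, rng)
    adenomas = nh.generate_adenomas(ind, p, rng)
    assert adenomas  # rate is high enough that emptiness would be astonishing
    assert all(20.0 <= a.onset_age <= 100.0 for a in adenomas)
    assert [a.onset_age for a in adenomas] == sorted(a.onset_age for a in adenomas)


# ---------------------------------------------------------------------------
# adenoma_diameter


def test_diameter_boundary_and_anchor(params):
    a = nh.Adenoma(onset_age=50.0, segment="colon", growth_years_to_10mm=8.0)
    assert nh.adenoma_diameter(a, 50.0, params) == pytest.approx(params.initial_diameter_mm)
    assert nh.adenoma_diameter(a, 58.0, params) == pytest.approx(10.0)
    with pytest.raises(ValueError):
        nh.adenoma_diameter(a, 49.9, params)


@given(st.floats(0.1, 60.0), st.floats(0.1, 60.0))
def test_diameter_monotone_and_bounded(t1, t2):
    from crcscreen.params import default_params

    p = default_params()
    a = nh.Adenoma(onset_age=40.0, segment="colon", growth_years_to_10mm=12.0)
    lo, hi = sorted((t1, t2))
    d1, d2 = nh.adenoma_diameter(a, 40 + lo, p), nh.adenoma_diameter(a, 40 + hi, p)
    assert d1 <= d2 + 1e-12
    assert d2 <= p.max_diameter_mm


# ---------------------------------------------------------------------------
# assign_transformation


def test_zero_hazard_never_transforms(params_factory, rng):
    p = params_factory({"transition_coeffs.log_hazard_at_10mm": -math.inf})
    for i in range(100):
        a = nh.Adenoma(onset_age=50.0, segment="colon", growth_years_to_10mm=10.0)
        assert nh.assign_transformation(a, "female", p, rng).transformation_age is None


def test_constant_hazard_transformation_is_exponential(params_factory, rng):
    """size_power 0 makes the hazard flat at exp(log_hazard): waiting times
    are Exponential with mean 1/h (truncation at age 100 negligible)."""
    h = 0.5
    p = params_factory({
        "transition_coeffs.log_hazard_at_10mm": math.log(h),
        "transition_coeffs.size_power": 0.0,
        "transition_coeffs.age_log_slope": 0.0,
        "transition_coeffs.male_log_effect": 0.0,
    })
    n = 20_000
    waits = []
    for _ in range(n):
        a = nh.Adenoma(onset_age=40.0, segment="colon", growth_years_to_10mm=10.0)
        nh.assign_transformation(a, "female", p, rng)
        assert a.transformation_age is not None
        waits.append(a.transformation_age - 40.0)
    waits = np.array(waits)
    assert abs(waits.mean() - 1 / h) < 3 * (1 / h) / math.sqrt(n)


def test_doubled_hazard_gives_stochastically_earlier_transformation(params_factory, rng):
    from scipy.stats import ks_2samp

    waits = {}
    for mult, h in (("x1", 0.2), ("x2", 0.4)):
        p = params_factory({
            "transition_coeffs.log_hazard_at_10mm": math.log(h),
            "transition_coeffs.size_power": 0.0,
            "transition_coeffs.age_log_slope": 0.0,
        })
        w = []
        for _ in range(10_000):
            a = nh.Adenoma(onset_age=40.0, segment="colon", growth_years_to_10mm=10.0)
            nh.assign_transformation(a, "female", p, rng)
            w.append(a.transformation_age - 40.0)
        waits[mult] = np.array(w)
    # doubled hazard must dominate: its CDF lies above (smaller values)
    res = ks_2samp(waits["x2"], waits["x1"], alternative="greater")
    assert res.pvalue < 1e-6
    assert waits["x2"].mean() < waits["x1"].mean()


# ---------------------------------------------------------------------------
# build_cancer / stages


def test_infinite_dwell_means_give_stage_one_at_detection(params_factory, rng):
    p = params_factory({"stage_dwell_means": [1e9, 1e9, 1e9]})
    for _ in range(50):
        a = nh.Adenoma(onset_age=55.0, segment="colon", growth_years_to_10mm=10.0,
                       transformation_age=60.0)
        cancer = nh.build_cancer(a, p, rng)
        assert cancer.stage_at(cancer.clinical_detection_age) == 1


def test_stage_at_is_arithmetic_on_entry_ages():
    cancer = make_cancer(onset=60.0, sojourn=4.0, dwells=(1.0, 1.0, 1.0))
    assert cancer.clinical_detection_age == 64.0
    assert [cancer.stage_at(a) for a in (60.0, 60.5, 61.5, 62.5, 64.0)] == [1, 1, 2, 3, 4]
    with pytest.raises(ValueError):
        cancer.stage_at(59.9)


def test_stage_distribution_matches_numeric_convolution(params_factory, rng):
    """Stage at clinical detection = which partial sum of exponential dwells
    the lognormal sojourn falls below; oracle by numeric integration of the
    hypoexponential CDF against the lognormal density."""
    from scipy.integrate import quad

    m = (1.0, 0.85, 0.75)
    mu, sd = 0.95, 0.5
    p = params_factory({"stage_dwell_means": list(m),
                        "sojourn_params": {"meanlog": mu, "sdlog": sd}})

    r = [1 / x for x in m]

    def hypo_cdf(t, rates):  # P(sum of independent exponentials < t), distinct rates
        tot = 0.0
        for i, ri in enumerate(rates):
            w = 1.0
            for j, rj in enumerate(rates):
                if i != j:
                    w *= rj / (rj - ri)
            tot += w * (1 - math.exp(-ri * t))
        return tot

    def lognorm_pdf(s):
        return math.exp(-((math.log(s) - mu) ** 2) / (2 * sd**2)) / (s * sd * math.sqrt(2 * math.pi))

    p_ge = [1.0]  # P(stage >= 1)
    for k in (1, 2, 3):
        val, _ = quad(lambda s: lognorm_pdf(s) * hypo_cdf(s, r[:k]), 0, 200, limit=200)
        p_ge.append(val)
    expected = [p_ge[i] - (p_ge[i + 1] if i < 3 else 0.0) for i in range(4)]

    n = 50_000
    counts = np.zeros(4)
    for _ in range(n):
        a = nh.Adenoma(onset_age=55.0, segment="colon", growth_years_to_10mm=10.0,
                       transformation_age=60.0)
        cancer = nh.build_cancer(a, p, rng)
        counts[cancer.stage_at(cancer.clinical_detection_age) - 1] += 1
    freq = counts / n
    for stage in range(4):
        se = math.sqrt(expected[stage] * (1 - expected[stage]) / n)
        assert abs(freq[stage] - expected[stage]) < 3.5 * se


# ---------------------------------------------------------------------------
# crc_death_age


def test_cure_or_zero_hazard_means_no_cancer_death(params_factory, rng):
    p = params_factory({"survival_params.excess_hazard": {1: 0.0, 2: 0.1, 3: 0.2, 4: 0.3}})
    assert all(nh.crc_death_age(1, 60.0, "female", p, rng) is None for _ in range(100))
    p2 = params_factory({"survival_params.cure_prob": {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0}})
    assert all(nh.crc_death_age(4, 60.0, "female", p2, rng) is None for _ in range(100))


def test_unknown_stage_rejected(params, rng):
    with pytest.raises(ConfigurationError):
        nh.crc_death_age(5, 60.0, "female", params, rng)


def test_constant_hazard_survival_curve(params_factory, rng):
    h = 0.3
    p = params_factory({
        "survival_params.cure_prob": {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0},
        "survival_params.excess_hazard": {1: h, 2: h, 3: h, 4: h},
        "survival_params.age_band_multipliers": [1.0, 1.0, 1.0],
    })
    n = 20_000
    times = np.array([nh.crc_death_age(2, 50.0, "male", p, rng) - 50.0 for _ in range(n)])
    for t in (1.0, 5.0, 10.0):
        s_emp = (times > t).mean()
        s_true = math.exp(-h * t)
        se = math.sqrt(s_true * (1 - s_true) / n)
        assert abs(s_emp - s_true) < 3 * se


def test_higher_stage_dies_sooner(params, rng):
    n = 5_000
    dead5 = {}
    for stage in (1, 4):
        deaths = [nh.crc_death_age(stage, 60.0, "female", params, rng) for _ in range(n)]
        dead5[stage] = np.mean([d is not None and d < 65.0 for d in deaths])
    assert dead5[4] > dead5[1]


# ---------------------------------------------------------------------------
# simulate_unscreened & cohort invariants


def test_no_adenomas_is_pure_other_cause_death(params):
    ind = make_individual(0, death_age=83.25)
    h = nh.simulate_unscreened(ind, params)
    assert [(e.age, e.kind, e.detail) for e in h.events] == [(83.25, "death", ("other",))]


def test_clinical_detection_after_death_is_censored(params):
    a = nh.Adenoma(onset_age=55.0, segment="colon", growth_years_to_10mm=9.0,
                   transformation_age=64.0, cancer=make_cancer(64.0, 6.5))
    ind = make_individual(1, death_age=70.0, adenomas=[a])
    h = nh.simulate_unscreened(ind, params)  # clinical detection would be 70.5
    assert h.crc_diagnosis is None
    assert h.death_age == 70.0 and h.death_cause == "other"


def test_three_person_unscreened_hand_trace(params):
    """Full event lists for a scripted cohort must match hand-written traces."""
    # person 0: cancer presents clinically at 67 in stage IV, dies of it
    a0 = nh.Adenoma(onset_age=50.0, segment="colon", growth_years_to_10mm=8.0,
                    transformation_age=62.0,
                    cancer=make_cancer(62.0, 5.0, dwells=(1.0, 1.0, 1.0),
                                       u_cure=0.9, u_time=0.5))
    p0 = make_individual(0, death_age=90.0, adenomas=[a0])
    # person 1: lesion-free
    p1 = make_individual(1, death_age=82.3)
    # person 2: would present at 70.5 but dies at 70
    a2 = nh.Adenoma(onset_age=58.0, segment="rectum", growth_years_to_10mm=7.0,
                    transformation_age=65.2, cancer=make_cancer(65.2, 5.3))
    p2 = make_individual(2, death_age=70.0, adenomas=[a2])

    h0, h1, h2 = (nh.simulate_unscreened(i, params) for i in (p0, p1, p2))

    # hand computation for person 0: stage_at(67) with entries 62,63,64,65 -> IV;
    # not cured (u_cure 0.9 > 0.02); hazard 0.85 * 1.15 (age band 65-75);
    # death = 67 - ln(0.5)/0.9775
    death0 = 67.0 + math.log(2) / (0.85 * 1.15)
    assert [(e.age, e.kind) for e in h0.events] == [
        (67.0, "colonoscopy"), (67.0, "crc_diagnosis"), (pytest.approx(death0), "death")]
    assert h0.events[1].detail == (4, "clinical")
    assert h0.death_cause == "crc"
    assert [(e.age, e.kind, e.detail) for e in h1.events] == [(82.3, "death", ("other",))]
    assert h2.crc_diagnosis is None and h2.death_age == 70.0

    total_ly = sum(h.death_age - 40.0 for h in (h0, h1, h2))
    assert total_ly == pytest.approx((death0 - 40) + 42.3 + 30.0)


def test_zero_intensity_cohort_matches_life_table_and_has_no_crc(params_factory):
    p = params_factory({"adenoma_baseline_log_rate": -math.inf})
    n = 20_000
    cohort = nh.build_cohort(p, n, master_seed=5)
    histories = [nh.simulate_unscreened(ind, p) for ind in cohort]
    assert all(h.crc_diagnosis is None for h in histories)
    death_ages = np.array([h.death_age for h in histories])
    expected = 0.5 * (p.life_table.expected_death_age("female")
                      + p.life_table.expected_death_age("male"))
    se = death_ages.std() / math.sqrt(n)
    assert abs(death_ages.mean() - expected) < 3 * se


def test_every_diagnosis_has_generating_adenoma(params):
    cohort = nh.build_cohort(params, 3_000, master_seed=9)
    for ind in cohort:
        h = nh.simulate_unscreened(ind, params)
        dx = h.crc_diagnosis
        if dx is not None:
            assert any(a.transformation_age is not None and a.transformation_age < dx.age
                       for a in ind.adenomas)


def test_cohort_regeneration_is_byte_identical(params):
    a = nh.build_cohort(params, 300, master_seed=123)
    b = nh.build_cohort(params, 300, master_seed=123)
    ha = [nh.simulate_unscreened(i, params).events for i in a]
    hb = [nh.simulate_unscreened(i, params).events for i in b]
    assert ha == hb
    # free of diagnosed cancer at entry, and alive at entry
    assert all(i.other_cause_death_age > 40.0 for i in a)
    for ind in a:
        for ad in ind.adenomas:
            if ad.cancer is not None:
                assert ad.cancer.clinical_detection_age >= 40.0
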