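"""Agreement statistics against hand values and a brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import betainc

from canalarea.evaluation import (
    correlation_band,
    evaluate_level,
    mean_difference,
    paired_t_test,
    pearson_r,
    percent_error,
)
from canalarea.shapes import approximate_cohort

from conftest import ellipse_exact_cohort

# ---------------------------------------------------------------------------
# Brute-force oracle: plain-Python sums; t-tail via the regularized
# incomplete beta function, a different route than scipy.stats.ttest_rel.


def oracle_mean(v):
    return sum(v) / len(v)


def oracle_sd(v):
    m = oracle_mean(v)
    return math.sqrt(sum((x - m) ** 2 for x in v) / (len(v) - 1))


def oracle_mean_difference(a, m):
    d = [x - y for x, y in zip(a, m)]
    return oracle_mean(d), oracle_sd(d)


def oracle_percent_error(a, m, mode):
    if mode == "of_means":
        return 100.0 * (oracle_mean(a) - oracle_mean(m)) / oracle_mean(m)
    return oracle_mean([100.0 * (x - y) / y for x, y in zip(a, m)])


def oracle_pearson(x, y):
    mx, my = oracle_mean(x), oracle_mean(y)
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    return num / den


def oracle_paired_t(x, y):
    d = [a - b for a, b in zip(x, y)]
    n = len(d)
    t = oracle_mean(d) / (oracle_sd(d) / math.sqrt(n))
    df = n - 1
    p = betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, p


# ---------------------------------------------------------------------------


def test_oracle_equivalence_on_random_vectors():
    """All four statistics match the brute-force oracle to 1e-10."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        n = int(rng.integers(3, 11))
        a = rng.uniform(50.0, 400.0, n)
        m = rng.uniform(50.0, 400.0, n)
        md, sd = mean_difference(a, m)
        omd, osd = oracle_mean_difference(a, m)
        assert md == pytest.approx(omd, abs=1e-10)
        assert sd == pytest.approx(osd, abs=1e-10)
        for mode in ("of_means", "mean_of_ratios"):
            assert percent_error(a, m, mode) == pytest.approx(
                oracle_percent_error(a, m, mode), abs=1e-10
            )
        assert pearson_r(a, m) == pytest.approx(oracle_pearson(a, m), abs=1e-10)
        t, p, nn = paired_t_test(a, m)
        ot, op = oracle_paired_t(a, m)
        assert t == pytest.approx(ot, abs=1e-10)
        assert p == pytest.approx(op, abs=1e-10)
        assert nn == n


def test_mean_difference_hand_example():
    md, sd = mean_difference([10, 20, 30], [12, 19, 32])
    assert md == pytest.approx(-1.0)
    assert sd == pytest.approx(math.sqrt(3.0))


def test_identical_pairs_degenerate_cases():
    assert mean_difference([5.0, 5.0], [5.0, 5.0]) == (0.0, 0.0)
    assert percent_error([5.0, 5.0], [5.0, 5.0]) == 0.0
    t, p, n = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert (t, p, n) == (0.0, 1.0, 3)
    t, p, _ = paired_t_test([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
    assert t == math.inf and p == 0.0


def test_paired_t_hand_example():
    t, p, _ = paired_t_test([10.0, 21.0, 28.0], [12.0, 20.0, 30.0])
    assert t == pytest.approx(-1.0, abs=1e-12)
    assert p == pytest.approx(0.42264973, abs=1e-6)


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ([1, 2, 3], [3, 5, 7], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
    ],
)
def test_pearson_hand_examples(x, y, expected):
    assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "r, band",
    [(0.0, "weak"), (0.39, "weak"), (0.4, "moderate"), (-0.55, "moderate"),
     (0.699, "moderate"), (0.7, "strong"), (1.0, "strong")],
)
def test_correlation_bands(r, band):
    assert correlation_band(r) == band


@settings(max_examples=50, deadline=None)
@given(
    data=st.lists(
        st.tuples(
            st.floats(min_value=10, max_value=500),
            st.floats(min_value=10, max_value=500),
        ),
        min_size=3,
        max_size=12,
    ),
    k=st.floats(min_value=0.1, max_value=10),
    b=st.floats(min_value=-5, max_value=5),
)
def test_invariance_properties(data, k, b):
    a = np.array([p[0] for p in data])
    m = np.array([p[1] for p in data])
    # antisymmetry of the mean difference; symmetric SD
    md_am, sd_am = mean_difference(a, m)
    md_ma, sd_ma = mean_difference(m, a)
    assert md_am == pytest.approx(-md_ma, abs=1e-9)
    assert sd_am == pytest.approx(sd_ma, abs=1e-9)
    # percent error (of means) invariant under joint positive rescaling
    assert percent_error(k * a, k * m) == pytest.approx(
        percent_error(a, m), abs=1e-8
    )
    # Pearson r invariant under positive affine maps of one argument
    if a.std() > 1e-6 and m.std() > 1e-6:
        assert pearson_r(k * a + b, m) == pytest.approx(pearson_r(a, m), abs=1e-8)
    # t sign equals mean-difference sign; p in [0, 1]
    if sd_am > 1e-9:
        t, p, _ = paired_t_test(a, m)
        assert 0.0 <= p <= 1.0
        if abs(md_am) > 1e-9:
            assert math.copysign(1, t) == math.copysign(1, md_am)


def test_input_validation_errors():
    with pytest.raises(ValueError):
        mean_difference([1.0, 2.0], [1.0])
    with pytest.raises(ValueError):
        paired_t_test([1.0], [2.0])
    with pytest.raises(ValueError):
        pearson_r([1.0, 2.0], [2.0, 3.0])  # fewer than 3 pairs
    with pytest.raises(ValueError):
        pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])  # zero variance
    with pytest.raises(ValueError):
        percent_error([1.0, 2.0], [1.0, -2.0])  # non-positive measured
    with pytest.raises(ValueError):
        percent_error([1.0, 2.0], [1.0, 2.0], mode="nonsense")


def test_evaluate_level_on_exact_ellipse_cohort():
    """measured == ellipse: MD 0, 0% error, r = 1, p = 1 on the ellipse row."""
    cohort = ellipse_exact_cohort(level="C5-6", n=6)
    table = evaluate_level(cohort, approximate_cohort(cohort), "C5-6")
    row = table[table["approximation"] == "ellipse"].iloc[0]
    assert row["mean_difference"] == pytest.approx(0.0, abs=1e-10)
    assert row["percent_error"] == pytest.approx(0.0, abs=1e-10)
    assert row["pearson_r"] == pytest.approx(1.0, abs=1e-12)
    assert row["p_value"] == pytest.approx(1.0)
    assert set(table["approximation"]) == {"ellipse", "triangle", "rectangle"}
    assert table["pearson_r"].nunique() == 1 or np.allclose(
        table["pearson_r"], row["pearson_r"], atol=1e-12
    )


def test_evaluate_level_toy_fully_hand_computed():
    """3-record level checked against hand-computed statistics."""
    from conftest import make_cohort_from_arrays

    ap = [10.0, 12.0, 14.0]
    ipd = [20.0, 22.0, 24.0]
    measured = [180.0, 230.0, 260.0]
    cohort = make_cohort_from_arrays("C2-3", ap, ipd, measured)
    table = evaluate_level(cohort, approximate_cohort(cohort), "C2-3")
    rect = table[table["approximation"] == "rectangle"].iloc[0]
    # rectangle areas: 200, 264, 336 -> differences 20, 34, 76
    assert rect["mean_difference"] == pytest.approx((20 + 34 + 76) / 3)
    assert rect["sd_difference"] == pytest.approx(oracle_sd([20.0, 34.0, 76.0]))
    assert rect["percent_error"] == pytest.approx(
        100 * (800 / 3 - 670 / 3) / (670 / 3)
    )
    assert rect["pearson_r"] == pytest.approx(
        oracle_pearson([200.0, 264.0, 336.0], measured)
    )
    t, p = oracle_paired_t([200.0, 264.0, 336.0], measured)
    assert rect["t_statistic"] == pytest.approx(t)
    assert rect["p_value"] == pytest.approx(p)
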