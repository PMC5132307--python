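"""Normalization, Mann-Whitney/Holm comparisons and dose-response fits."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beadassay.quantification import ActivityMeasurement
from beadassay.stats import (
    AssayGroup,
    compare_groups,
    fit_dose_response,
    holm_adjust,
    mann_whitney,
    normalize,
    significance_tier,
)


def group(condition, solvent, ratios, pct=()):
    ms = tuple(
        ActivityMeasurement(
            image_id=f"{condition}_{i}",
            Aw=100,
            Am=1,
            bead_sum=r * 100,
            ratio=r,
            condition=condition,
            solvent=solvent,
        )
        for i, r in enumerate(ratios)
    )
    return AssayGroup(condition, solvent, ms, tuple(pct))


class TestNormalize:
    def test_control_group_mean_is_exactly_100(self):
        groups = [group("BE", "water", [3.0, 5.0, 7.0]), group("water", "water", [1.0, 2.0])]
        out = normalize(groups, "BE")
        control = next(g for g in out if g.condition == "BE")
        assert np.mean(control.normalized_pct) == pytest.approx(100.0, abs=1e-12)

    def test_simple_arithmetic(self):
        groups = [group("BE", "water", [2.0, 4.0]), group("NAD", "water", [6.0])]
        out = normalize(groups, "BE")
        nad = next(g for g in out if g.condition == "NAD")
        assert nad.normalized_pct == (200.0,)

    def test_maximum_effect_solvent_rule(self):
        # BE in water (mean 80) and BE in NaOH (mean 120): the NaOH group is
        # the control and normalizes to 100.
        groups = [
            group("BE", "water", [70.0, 90.0]),
            group("BE", "NaOH", [110.0, 130.0]),
            group("NAD", "NaOH", [60.0]),
        ]
        out = normalize(groups, "BE")
        naoh = next(g for g in out if g.condition == "BE" and g.solvent == "NaOH")
        water = next(g for g in out if g.condition == "BE" and g.solvent == "water")
        assert np.mean(naoh.normalized_pct) == pytest.approx(100.0)
        assert np.mean(water.normalized_pct) == pytest.approx(80 / 120 * 100)
        nad = next(g for g in out if g.condition == "NAD")
        assert nad.normalized_pct[0] == pytest.approx(50.0)

    def test_global_gain_rescaling_is_invariant(self, rng):
        ratios = {c: rng.uniform(0, 50, 6) for c in "ABC"}
        ratios["BE"] = rng.uniform(10, 50, 6)
        base = [group(c, "water", list(v)) for c, v in ratios.items()]
        scaled = [group(c, "water", list(17.3 * v)) for c, v in ratios.items()]
        out_a = normalize(base, "BE")
        out_b = normalize(scaled, "BE")
        for ga, gb in zip(out_a, out_b):
            assert np.allclose(ga.normalized_pct, gb.normalized_pct, rtol=1e-9)

    def test_missing_or_zero_control_rejected(self):
        with pytest.raises(ValueError):
            normalize([group("water", "water", [1.0])], "BE")
        with pytest.raises(ValueError):
            normalize([group("BE", "water", [0.0, 0.0])], "BE")


def exact_two_sided_p(a, b):
    """Full enumeration of the Mann-Whitney null for tie-free samples."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(sample_a, sample_b):
        return sum(1 for x in sample_a for y in sample_b if x > y) + 0.5 * sum(
            1 for x in sample_a for y in sample_b if x == y
        )

    observed = u_stat(a, b)
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), n1):
        total += 1
        sa = [pooled[i] for i in combo]
        sb = [pooled[i] for i in range(n) if i not in combo]
        if abs(u_stat(sa, sb) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_small_example_by_enumeration(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.U == 0
        assert res.method == "exact"
        assert res.p_raw == pytest.approx(1 / 3, abs=1e-12)
        assert res.p_raw == pytest.approx(exact_two_sided_p([1, 2], [3, 4]))

    def test_symmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=8)
        assert mann_whitney(a, b).p_raw == pytest.approx(mann_whitney(b, a).p_raw)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_ties_use_corrected_normal_approximation(self):
        res = mann_whitney([0, 0, 0, 1], [0, 0, 2, 3])
        assert res.method == "asymptotic"
        assert 0 <= res.p_raw <= 1

    def test_large_samples_use_approximation(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=15) + 0.5
        assert mann_whitney(a, b).method == "asymptotic"

    def test_exact_matches_enumeration_oracle(self, rng):
        for n1, n2 in [(3, 3), (4, 5), (2, 6)]:
            a = rng.normal(size=n1)
            b = rng.normal(size=n2) + rng.uniform(-1, 1)
            res = mann_whitney(a, b)
            assert res.method == "exact"
            assert res.p_raw == pytest.approx(exact_two_sided_p(list(a), list(b)), abs=1e-10)

    def test_exact_vs_approximate_agreement(self, rng):
        # Tie-free samples with n1, n2 <= 8: the corrected normal
        # approximation stays within 0.05 of the exact p.
        from scipy.stats import mannwhitneyu

        for _ in range(30):
            a = rng.normal(size=int(rng.integers(3, 9)))
            b = rng.normal(size=int(rng.integers(3, 9)))
            p_exact = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            p_approx = mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(p_exact - p_approx) <= 0.05


def holm_stepdown_oracle(p_values, alpha):
    """Textbook step-down: sort ascending, reject while p(k) <= a/(m-k+1)."""
    m = len(p_values)
    order = np.argsort(p_values, kind="stable")
    reject = [False] * m
    for k, idx in enumerate(order):
        if p_values[idx] <= alpha / (m - k):
            reject[idx] = True
        else:
            break
    return reject


class TestHolm:
    def test_single_test_reduces_to_plain_alpha(self):
        assert holm_adjust([0.04], 0.05) == [True]
        assert holm_adjust([0.06], 0.05) == [False]

    def test_stepdown_example(self):
        assert holm_adjust([0.01, 0.04, 0.03], 0.05) == [True, False, False]

    def test_all_ones_no_rejections(self):
        assert holm_adjust([1.0] * 5, 0.05) == [False] * 5

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_matches_stepdown_definition(self, p_values, alpha):
        assert holm_adjust(p_values, alpha) == holm_stepdown_oracle(p_values, alpha)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=10))
    def test_between_bonferroni_and_per_test_alpha(self, p_values):
        alpha = 0.05
        m = len(p_values)
        holm = holm_adjust(p_values, alpha)
        for p, rej in zip(p_values, holm):
            if rej:
                assert p <= alpha  # never more permissive than per-test alpha
            if p <= alpha / m:  # Bonferroni rejection implies Holm rejection
                assert rej


class TestTiers:
    @pytest.mark.parametrize(
        "p, holm, expected",
        [
            (5e-4, False, "*"),
            (1e-3, False, "*"),
            (5e-5, False, "**"),
            (1e-6, False, "***"),
            (0.01, True, "(*)"),
            (0.01, False, "ns"),
            (0.5, True, "(*)"),
        ],
    )
    def test_tier_thresholds(self, p, holm, expected):
        assert significance_tier(p, holm) == expected


class TestCompareGroups:
    def test_comparisons_against_reference(self):
        groups = [
            group("BE", "water", [10.0] * 4, pct=[100.0, 110, 90, 100]),
            group("water", "water", [0.1] * 4, pct=[1.0, 2.0, 1.5, 0.5]),
            group("NAD", "water", [8.0] * 4, pct=[80.0, 95, 85, 90]),
        ]
        res = compare_groups(groups, "water")
        assert {c.pair for c in res} == {("BE", "water"), ("NAD", "water")}
        for c in res:
            assert 0 <= c.p_raw <= 1
            assert c.tier in {"ns", "(*)", "*", "**", "***"}

    def test_unknown_reference_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([group("BE", "water", [1.0], pct=[100.0])], "water")


class TestDoseResponse:
    def test_noiseless_cubic_recovered(self):
        x = np.array([0.0, 0.1, 0.3, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = 2.0 - 3.0 * x + 0.5 * x**2 + 0.25 * x**3
        fit = fit_dose_response(x, y)
        assert np.abs(y - fit.fitted).max() <= 1e-8
        # Zero residual variance collapses the confidence band onto the fit.
        assert np.abs(fit.band_upper - fit.band_lower).max() <= 1e-6

    def test_basis_columns_orthogonal_on_design_points(self, rng):
        x = np.sort(rng.uniform(0, 3, 12))
        fit = fit_dose_response(x, rng.normal(size=12))
        gram = fit.basis.T @ fit.basis
        off_diag = gram - np.diag(np.diag(gram))
        assert np.abs(off_diag).max() <= 1e-10

    def test_matches_raw_power_cubic_least_squares(self, rng):
        for _ in range(5):
            x = np.sort(rng.uniform(0, 3, 15))
            y = rng.normal(size=15) * 20 + 50
            fit = fit_dose_response(x, y)
            coeffs = np.polyfit(x, y, 3)
            assert np.allclose(fit.fitted, np.polyval(coeffs, x), atol=1e-8)

    def test_band_brackets_fit(self, rng):
        x = np.repeat([0.0, 0.5, 1.0, 2.0, 3.0], 5)
        y = 100 / (1 + np.exp(-3 * (x - 1))) + rng.normal(0, 5, x.size)
        fit = fit_dose_response(x, y)
        assert (fit.band_lower <= fit.fitted + 1e-12).all()
        assert (fit.band_upper >= fit.fitted - 1e-12).all()
        assert fit.residual_df == x.size - 4

    def test_insufficient_design_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([0, 1, 2, 3], [1, 2, 3, 4])  # too few points
        with pytest.raises(ValueError):
            # replicated concentrations: only 3 distinct levels for a cubic
            fit_dose_response([0, 0, 1, 1, 2, 2], [1, 2, 3, 4, 5, 6])
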