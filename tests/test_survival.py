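"""Survival estimators: chip empirical curve, Kaplan-Meier, comparisons."""

import math

import numpy as np
import pytest

from wormchip.survival import (
    SurvivalRecord,
    chip_survival,
    compare_curves,
    kaplan_meier,
    lost_fraction_course,
    median_survival,
    records_from_death_times,
)


class TestChipSurvival:
    def test_all_alive_is_unity(self):
        c = chip_survival([10, 10, 10], [0, 12, 24], initial_n=10)
        assert np.allclose(c.survival, 1.0)

    def test_simple_division(self):
        c = chip_survival([10, 10, 8, 5, 0], [0, 12, 24, 36, 48], initial_n=10)
        assert np.allclose(c.survival, [1, 1, 0.8, 0.5, 0])
        assert c.std_err[0] == 0.0
        assert c.std_err[3] == pytest.approx(math.sqrt(0.5 * 0.5 / 10))

    def test_isotonic_correction_of_count_jitter(self):
        c = chip_survival([10, 8, 9, 5], [0, 1, 2, 3], initial_n=10)
        assert c.corrected
        assert (np.diff(c.survival) <= 1e-12).all()
        # pool-adjacent-violators: the 8,9 violation pools to 8.5
        assert c.survival[1] == pytest.approx(0.85)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        deaths = rng.exponential(24, size=25)
        grid = np.arange(0, 80, 2.0)
        counts = [(deaths > t).sum() for t in grid]
        c = chip_survival(counts, grid, 25)
        assert (np.diff(c.survival) <= 1e-12).all()
        assert c.survival.min() >= 0 and c.survival.max() <= 1
        assert (np.diff(c.n_at_risk) <= 0).all()

    def test_validation(self):
        with pytest.raises(ValueError):
            chip_survival([1], [0.0], initial_n=0)
        with pytest.raises(ValueError):
            chip_survival([1, 2], [0.0], initial_n=5)


class TestKaplanMeier:
    def test_worked_product_limit_example(self):
        # 10 subjects: death at t=1, censored at t=2, death at t=3
        # S(3) = (9/10) * (7/8) = 0.7875
        recs = [SurvivalRecord("a", 1.0, "died"),
                SurvivalRecord("b", 2.0, "censored")]
        recs += [SurvivalRecord(f"s{i}", 3.0, "died") for i in range(1)]
        recs += [SurvivalRecord(f"x{i}", 10.0, "alive_at_end") for i in range(7)]
        curve = kaplan_meier(recs)
        assert curve.at(3.0) == pytest.approx(0.7875, abs=1e-12)

    def test_no_censoring_equals_chip_estimator(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            deaths = np.round(rng.exponential(20, size=n), 1)
            recs = records_from_death_times(deaths, end_time_h=1e9)
            km = kaplan_meier(recs)
            grid = np.unique(deaths)
            chip = chip_survival([(deaths > t).sum() for t in grid], grid, n)
            for t in grid:
                assert km.at(t) == pytest.approx(chip.at(t), abs=1e-12)

    def test_single_subject_step(self):
        curve = kaplan_meier([SurvivalRecord("w", 5.0, "died")])
        assert curve.at(4.99) == 1.0
        assert curve.at(5.0) == 0.0

    def test_all_censored_warns_and_returns_unity(self):
        recs = [SurvivalRecord("a", 5.0, "censored")]
        with pytest.warns(UserWarning):
            curve = kaplan_meier(recs)
        assert np.allclose(curve.survival, 1.0)

    def test_greenwood_se_matches_lifelines(self):
        # independent oracle: lifelines' KaplanMeierFitter on random data
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(7)
        times = np.round(rng.exponential(15, size=40), 1) + 0.1
        observed = rng.random(40) < 0.8
        recs = [
            SurvivalRecord(f"w{i}", float(t), "died" if o else "censored")
            for i, (t, o) in enumerate(zip(times, observed))
        ]
        km = kaplan_meier(recs)
        kmf = KaplanMeierFitter().fit(times, observed)
        for t in sorted({t for t, o in zip(times, observed) if o}):
            assert km.at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10)
        # Greenwood SE is positive in the curve interior (it can collapse to
        # zero at the end, when the last death empties the risk set)
        assert km.std_err[len(km.std_err) // 2] > 0

    def test_rejects_empty_and_bad_records(self):
        with pytest.raises(ValueError):
            kaplan_meier([])
        with pytest.raises(ValueError):
            SurvivalRecord("w", -1.0, "died")
        with pytest.raises(ValueError):
            SurvivalRecord("w", 1.0, "vanished")


class TestLostFraction:
    def test_chip_mode_identically_zero(self):
        course = lost_fraction_course(times_h=[0, 24, 48], chip_mode=True)
        assert (course["lost_fraction"] == 0).all()

    def test_plate_two_of_twenty_lost(self):
        recs = [SurvivalRecord(f"l{i}", 30.0, "censored") for i in range(2)]
        recs += [SurvivalRecord(f"d{i}", 40.0, "died") for i in range(18)]
        course = lost_fraction_course(recs, times_h=[0, 24, 48])
        assert course["lost_fraction"].tolist() == [0.0, 0.0, 0.10]

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(5)
        recs = [
            SurvivalRecord(f"w{i}", float(rng.uniform(0, 50)),
                           "censored" if rng.random() < 0.3 else "died")
            for i in range(30)
        ]
        course = lost_fraction_course(recs)
        assert (np.diff(course["lost_fraction"]) >= 0).all()


class TestCompareCurves:
    def test_identical_curves_zero_logrank_and_median_diff(self):
        deaths = [5.0, 10, 15, 20, 25, 30, 35, 40]
        recs = records_from_death_times(deaths, end_time_h=100)
        a = kaplan_meier(recs)
        cmp = compare_curves(a, a, recs, recs)
        assert cmp.median_a == cmp.median_b
        assert cmp.logrank_stat == pytest.approx(0.0, abs=1e-12)
        assert (cmp.pointwise_diff["difference"] == 0).all()

    def test_median_interpolation(self):
        c = chip_survival([10, 6, 4, 0], [0, 10, 20, 30], initial_n=10)
        med, sentinel = median_survival(c)
        # S crosses 0.5 between t=10 (0.6) and t=20 (0.4): midpoint
        assert med == pytest.approx(15.0)
        assert sentinel is None

    def test_never_reaching_half_gives_sentinel(self):
        c = chip_survival([10, 9, 8], [0, 10, 20], initial_n=10)
        med, sentinel = median_survival(c)
        assert math.isinf(med)
        assert sentinel == ">20"

    def test_double_rate_halves_median(self):
        # Monte-Carlo vs exponential medians ln2/r: ratio within 25% at n=30
        rng = np.random.default_rng(21)
        ratios = []
        for _ in range(20):
            fast = rng.exponential(12, size=30)
            slow = rng.exponential(24, size=30)
            ca = kaplan_meier(records_from_death_times(slow, 1e9))
            cb = kaplan_meier(records_from_death_times(fast, 1e9))
            ma, _ = median_survival(ca)
            mb, _ = median_survival(cb)
            ratios.append(ma / mb)
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.25)


def test_plot_survival_returns_axes():
    import matplotlib
    matplotlib.use("Agg")
    from wormchip.survival import plot_survival

    curve = chip_survival([10, 8, 4, 0], [0, 12, 24, 36], initial_n=10)
    ax = plot_survival([curve], labels=["chip"])
    assert ax.get_ylabel().startswith("survival")
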