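import numpy as np
import pytest
import statsmodels.api as sm
from scipy.integrate import quad

from eyespot_origins import onset, synthetic_data as syn
from eyespot_origins.onset import (
    LogisticCurve,
    bootstrap_delta_test,
    curve_auc,
    delta_obs,
    fit_logistic,
    pairwise_onset_report,
    significance_stars,
)


class TestFitLogistic:
    def test_matches_statsmodels_on_overlapping_data(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 200)
        y = (rng.random(200) < 1 / (1 + np.exp(-(-10 + 2 * x)))).astype(float)
        curve = fit_logistic((x, y))
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        assert curve.a == pytest.approx(ref.params[0], abs=1e-5)
        assert curve.b == pytest.approx(ref.params[1], abs=1e-5)

    def test_perfect_separation_caps_slope_keeps_midpoint(self):
        x = np.linspace(0, 10, 60)
        y = (x > 5).astype(float)
        curve = fit_logistic((x, y))
        assert curve.flagged
        assert abs(curve.b) == onset.SLOPE_CAP
        assert 4.5 <= curve.midpoint <= 5.5

    def test_midpoint_recovery_under_simulation(self):
        ok = 0
        for i in range(50):
            rng = np.random.default_rng(1000 + i)
            x = rng.uniform(0, 10, 200)
            y = (rng.random(200) < 1 / (1 + np.exp(-(-10 + 2 * x)))).astype(float)
            curve = fit_logistic((x, y))
            if abs(curve.midpoint - 5.0) <= 0.3:
                ok += 1
        assert ok >= 45  # >= 90% of replicates

    def test_balanced_outcomes_give_flat_curve(self):
        x = np.repeat([1.0, 2.0, 3.0, 4.0], 10)
        y = np.tile([0, 1], 20).astype(float)
        curve = fit_logistic((x, y))
        assert curve.b == pytest.approx(0.0, abs=1e-4)
        assert curve.predict(2.5) == pytest.approx(0.5, abs=1e-4)

    def test_one_sided_outcomes_flagged_boundary(self):
        curve = fit_logistic(([1, 2, 3, 4], [1, 1, 1, 1]))
        assert curve.flagged
        assert curve.predict(2.5) > 0.999

    def test_too_few_rows_is_error(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_logistic(([1, 2, 3], [0, 1, 0]))

    def test_identical_stages_mixed_outcomes_flat_flagged(self):
        curve = fit_logistic(([2, 2, 2, 2], [0, 1, 1, 0]))
        assert curve.flagged
        assert curve.b == 0.0
        assert curve.predict(2) == pytest.approx(0.5)


class TestCurveAuc:
    def test_constant_half_curve(self):
        assert curve_auc(LogisticCurve(0, 0, 0, 10), 0, 10) == pytest.approx(5.0)

    def test_sigmoid_symmetry_limit(self):
        T = 50.0
        assert curve_auc(LogisticCurve(0, 1, -T, T), -T, T) == pytest.approx(T, abs=1e-6)

    def test_matches_quadrature_on_random_curves(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = rng.normal(0, 4), rng.normal(0, 3)
            lo = rng.uniform(-10, 5)
            hi = lo + rng.uniform(0.5, 15)
            analytic = curve_auc(LogisticCurve(a, b, lo, hi), lo, hi)
            numeric = quad(lambda t: 1 / (1 + np.exp(-(a + b * t))), lo, hi, limit=200)[0]
            assert analytic == pytest.approx(numeric, abs=1e-8)


class TestDelta:
    def test_identity_and_symmetry(self):
        d = syn.simulate_onset({"A": (-8, 2), "B": (-12, 2)}, range(10), 4, seed=1)
        a = d[d.gene == "A"]
        b = d[d.gene == "B"]
        assert delta_obs(a, a) == 0.0
        assert delta_obs(a, b) == pytest.approx(delta_obs(b, a))

    def test_saturated_midpoint_shift_equals_delta(self):
        # Two steep curves differing only by a 2-unit midpoint shift and
        # saturated well inside the range: delta -> the shift.
        x = np.linspace(0, 20, 400)
        ya = (x > 9).astype(float)
        yb = (x > 11).astype(float)
        assert delta_obs((x, ya), (x, yb)) == pytest.approx(2.0, abs=0.1)


class TestBootstrapDeltaTest:
    def test_identical_data_p_is_one(self):
        d = syn.simulate_onset({"A": (-10, 2)}, [0, 2, 4, 6, 8, 10], 5, seed=2)
        res = bootstrap_delta_test(d, d, n_boot=200, seed=3)
        assert res.delta_obs == 0.0
        assert res.p_value == 1.0

    def test_exactly_reproducible_for_fixed_seed(self):
        d = syn.simulate_onset({"A": (-10, 2), "B": (-12, 2)}, [0, 2, 4, 6, 8, 10], 5, seed=4)
        a, b = d[d.gene == "A"], d[d.gene == "B"]
        r1 = bootstrap_delta_test(a, b, n_boot=200, seed=9)
        r2 = bootstrap_delta_test(a, b, n_boot=200, seed=9)
        assert r1.p_value == r2.p_value
        assert r1.null_quantiles == r2.null_quantiles

    def test_p_value_definition_bounds(self):
        d = syn.simulate_onset({"A": (-10, 2), "B": (-16, 2)}, [0, 2, 4, 6, 8, 10], 5, seed=5)
        res = bootstrap_delta_test(d[d.gene == "A"], d[d.gene == "B"], n_boot=200, seed=6)
        assert 1 / 201 <= res.p_value <= 1.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_delta_test(([1, 2], [0, 1]), ([1, 2, 3, 4], [0, 0, 1, 1]), n_boot=200, seed=0)

    def test_power_grows_with_separation(self):
        # expected p decreases as the true midpoint separation grows
        mean_p = []
        for shift in (0.0, 2.0, 4.0):
            ps = []
            for i in range(8):
                d = syn.simulate_onset(
                    {"A": (-10.0, 2.0), "B": (-10.0 - 2.0 * shift, 2.0)},
                    [0, 2, 4, 6, 8, 10], 10, seed=300 + i,
                )
                res = bootstrap_delta_test(
                    d[d.gene == "A"], d[d.gene == "B"], n_boot=200, seed=400 + i
                )
                ps.append(res.p_value)
            mean_p.append(np.mean(ps))
        assert mean_p[0] > mean_p[1] > mean_p[2]


class TestPairwiseReport:
    def test_identical_genes_not_significant(self):
        d = syn.simulate_onset({"A": (-10, 2), "B": (-10, 2)}, [0, 2, 4, 6, 8, 10], 8, seed=7)
        # make B literally identical to A's draws
        d.loc[d.gene == "B", "expression"] = d.loc[d.gene == "A", "expression"].to_numpy()
        rep = pairwise_onset_report(d, [("A", "B")], n_boot=200, seed=8)
        assert rep.iloc[0]["stars"] == "ns"

    def test_row_count_matches_requested_pairs(self):
        d = syn.simulate_onset(
            {"Antp": (-4, 2), "sal": (-8, 2), "Notch": (-12, 2)}, range(10), 5, seed=9
        )
        rep = pairwise_onset_report(d, [("Antp", "sal"), ("sal", "Notch")], n_boot=150, seed=10)
        assert len(rep) == 2

    def test_missing_gene_named_in_error(self):
        d = syn.simulate_onset({"A": (-10, 2)}, range(8), 5, seed=11)
        with pytest.raises(KeyError, match="nope"):
            pairwise_onset_report(d, [("A", "nope")], n_boot=150, seed=12)

    def test_star_thresholds(self):
        assert significance_stars(5e-5) == "***"
        assert significance_stars(5e-3) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.06) == "ns"

    def test_staggered_cascade_all_adjacent_pairs_significant(self):
        genes = {"g1": (-2, 2), "g2": (-8, 2), "g3": (-14, 2), "g4": (-20, 2)}
        d = syn.simulate_onset(genes, np.linspace(0, 12, 13), 8, seed=13)  # ~100/gene
        pairs = [("g1", "g2"), ("g2", "g3"), ("g3", "g4")]
        rep = pairwise_onset_report(d, pairs, n_boot=300, seed=14)
        assert (rep["p_value"] < 0.05).all()
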