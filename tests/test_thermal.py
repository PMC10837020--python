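import numpy as np
import pytest

from photothermal.errors import InsufficientDataError, InvalidInputError, InvalidParameterError
from photothermal.kinetics import PeakedParams, celsius_to_kelvin, peaked_arrhenius
from photothermal.thermal import (
    ThermalSeries,
    anova_posthoc,
    compare_regressions,
    fit_peaked,
    fit_quadratic,
)

TEMPS6 = np.array([20.0, 25.0, 30.0, 35.0, 40.0, 50.0])


def peaked_series(truth: PeakedParams, temps=TEMPS6, noise_sd=0.0, rng=None, trait="Vcmax"):
    y = peaked_arrhenius(truth, celsius_to_kelvin(temps))
    if noise_sd:
        y = y * (1 + rng.normal(0, noise_sd, temps.size))
    return ThermalSeries(trait, temps, y)


class TestFitPeaked:
    def test_noiseless_recovery(self):
        truth = PeakedParams(k_ref=300, Ea=65, dS=0.66)
        fit = fit_peaked(peaked_series(truth))
        assert fit.params.k_ref == pytest.approx(300, rel=5e-3)
        assert fit.params.Ea == pytest.approx(65, rel=5e-3)
        assert fit.params.dS == pytest.approx(0.66, rel=5e-3)
        assert fit.params.Ed == 200.0  # held fixed, returned unchanged
        assert fit.converged

    def test_value_at_topt_consistent(self):
        truth = PeakedParams(k_ref=300, Ea=65, dS=0.66)
        fit = fit_peaked(peaked_series(truth))
        expect = peaked_arrhenius(fit.params, celsius_to_kelvin(fit.t_opt))
        assert fit.value_at_topt == pytest.approx(expect, rel=1e-12)

    def test_noisy_topt_error(self):
        rng = np.random.default_rng(7)
        truth = PeakedParams(k_ref=300, Ea=65, dS=0.66)
        from photothermal.kinetics import topt_from_peaked

        t_true = topt_from_peaked(truth) - 273.15
        errs = []
        for _ in range(30):  # acceptance runs the full 200
            fit = fit_peaked(peaked_series(truth, noise_sd=0.05, rng=rng))
            if fit.converged:
                errs.append(abs(fit.t_opt - t_true))
        assert np.median(errs) < 1.5

    def test_monotone_series_flagged(self):
        y = 10 * np.exp(0.05 * TEMPS6)
        fit = fit_peaked(ThermalSeries("Vcmax", TEMPS6, y))
        assert not fit.converged
        assert fit.flag == "no optimum resolvable"

    def test_span_too_small(self):
        with pytest.raises(InsufficientDataError):
            fit_peaked(ThermalSeries("Vcmax", [20, 22, 25, 28.0], [1, 2, 3, 4.0]))

    def test_randomized_recovery(self):
        rng = np.random.default_rng(11)
        for _ in range(10):  # invariant asks 50; acceptance covers more
            truth = PeakedParams(
                k_ref=rng.uniform(50, 400), Ea=rng.uniform(40, 90),
                dS=rng.uniform(0.62, 0.70),
            )
            fit = fit_peaked(peaked_series(truth))
            if not fit.converged:
                continue
            assert fit.params.k_ref == pytest.approx(truth.k_ref, rel=5e-3)
            assert fit.params.Ea == pytest.approx(truth.Ea, rel=5e-3)
            assert fit.params.dS == pytest.approx(truth.dS, rel=5e-3)


class TestFitQuadratic:
    def test_constructed_vertex(self):
        t = np.array([15, 20, 25, 30, 35.0])
        y = -0.1 * (t - 25) ** 2 + 30
        fit = fit_quadratic(ThermalSeries("An", t, y))
        assert fit.has_optimum
        assert fit.t_opt == pytest.approx(25.0, abs=1e-9)
        assert fit.value_at_topt == pytest.approx(30.0, abs=1e-9)

    def test_machine_precision_coefficients(self):
        t = np.array([18, 22, 27, 33, 41.0])
        a, b, c = -0.07, 3.1, -12.0
        fit = fit_quadratic(ThermalSeries("An", t, a * t**2 + b * t + c))
        assert fit.a == pytest.approx(a, rel=1e-10)
        assert fit.b == pytest.approx(b, rel=1e-10)
        assert fit.c == pytest.approx(c, rel=1e-10)

    def test_known_vertex_27_5(self):
        t = np.linspace(20, 40, 9)
        y = -0.08 * (t - 27.5) ** 2 + 24.0
        fit = fit_quadratic(ThermalSeries("An", t, y))
        assert fit.t_opt == pytest.approx(27.5, abs=1e-9)
        assert fit.value_at_topt == pytest.approx(24.0, abs=1e-9)

    def test_upward_curvature_flagged(self):
        t = np.array([20, 25, 30, 35.0])
        fit = fit_quadratic(ThermalSeries("An", t, 0.2 * (t - 25) ** 2 + 3))
        assert not fit.has_optimum
        assert fit.t_opt is None
        assert fit.flag == "no optimum in range"

    def test_degenerate_design(self):
        with pytest.raises(InsufficientDataError):
            fit_quadratic(ThermalSeries("An", [25, 25, 25.0], [1, 2, 3.0]))


class TestCompareRegressions:
    def _series(self, t, y):
        return ThermalSeries("An", np.asarray(t, float), np.asarray(y, float))

    def test_common_truth_selects_m0(self):
        t = np.array([20, 25, 30, 35, 40.0])
        y = -0.1 * (t - 28) ** 2 + 25
        rep = compare_regressions({"a": self._series(t, y), "b": self._series(t, y)})
        assert rep["selected"] == "M0"
        assert rep["tests"]["M1_vs_M0"]["F"] == 0.0

    def test_intercept_shift_selects_m1_f_matches_hand_calc(self):
        # 2 groups x 6 points, same curvature, intercepts differ by 10
        rng = np.random.default_rng(5)
        t = np.array([20, 24, 28, 32, 36, 40.0])
        base = -0.1 * (t - 30) ** 2 + 30
        ya = base + rng.normal(0, 0.1, 6)
        yb = base + 10 + rng.normal(0, 0.1, 6)
        rep = compare_regressions({"a": self._series(t, ya), "b": self._series(t, yb)})
        assert rep["selected"] == "M1"

        # hand extra-sum-of-squares on the same data via plain lstsq
        tt = np.concatenate([t, t])
        yy = np.concatenate([ya, yb])
        g = np.array([1.0] * 6 + [0.0] * 6)
        X0 = np.column_stack([np.ones(12), tt, tt**2])
        X1 = np.column_stack([g, 1 - g, tt, tt**2])
        r0 = yy - X0 @ np.linalg.lstsq(X0, yy, rcond=None)[0]
        r1 = yy - X1 @ np.linalg.lstsq(X1, yy, rcond=None)[0]
        rss0, rss1 = float(r0 @ r0), float(r1 @ r1)
        f_hand = ((rss0 - rss1) / 1) / (rss1 / (12 - 4))
        assert rep["tests"]["M1_vs_M0"]["F"] == pytest.approx(f_hand, rel=1e-10)

    def test_distinct_curvature_selects_m2(self):
        rng = np.random.default_rng(6)
        t = np.array([20, 24, 28, 32, 36, 40.0])
        ya = -0.05 * (t - 28) ** 2 + 25 + rng.normal(0, 0.05, 6)
        yb = -0.30 * (t - 33) ** 2 + 28 + rng.normal(0, 0.05, 6)
        rep = compare_regressions({"a": self._series(t, ya), "b": self._series(t, yb)})
        assert rep["selected"] == "M2"
        assert rep["rss"]["M2"] < rep["rss"]["M1"]

    def test_rss_ordering_property(self, rng):
        t = np.array([20, 25, 30, 35, 40.0])
        for _ in range(100):
            groups = {
                g: self._series(t, rng.normal(20, 5) - rng.uniform(0.01, 0.3) *
                                (t - rng.uniform(25, 35)) ** 2 + rng.normal(0, 1, t.size))
                for g in ("a", "b", "c")
            }
            rep = compare_regressions(groups)
            assert rep["rss"]["M0"] >= rep["rss"]["M1"] >= rep["rss"]["M2"]
            for tst in rep["tests"].values():
                assert tst["F"] >= 0

    def test_single_group_rejected(self):
        t = np.array([20, 25, 30.0])
        with pytest.raises(InvalidInputError):
            compare_regressions({"a": self._series(t, t)})


class TestAnovaPosthoc:
    def test_identical_groups(self):
        out = anova_posthoc({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        row = out["table"][0]
        assert row["F"] == 0.0
        assert row["p"] == 1.0
        assert out["letters"]["a"] == out["letters"]["b"]

    def test_hand_worked_three_groups(self):
        # integer textbook example, n=3 each
        vals = {"g1": [1, 2, 3], "g2": [4, 5, 6], "g3": [7, 8, 9]}
        # grand mean 5; SSB = 3*((2-5)^2 + (5-5)^2 + (8-5)^2) = 54; SSW = 6
        out = anova_posthoc(vals)
        row = out["table"][0]
        assert row["SS"] == pytest.approx(54.0)
        assert out["table"][1]["SS"] == pytest.approx(6.0)
        f_hand = (54.0 / 2) / (6.0 / 6)
        assert row["F"] == pytest.approx(f_hand)

    def test_streaming_oracle_equivalence(self, rng):
        # classic between/within MS ratio computed independently
        vals = {g: rng.normal(rng.uniform(0, 2), 1.0, rng.integers(3, 7)) for g in "abcd"}
        out = anova_posthoc(vals)
        allv = np.concatenate(list(vals.values()))
        grand = allv.mean()
        ssb = sum(len(v) * (np.mean(v) - grand) ** 2 for v in vals.values())
        ssw = sum(((np.asarray(v) - np.mean(v)) ** 2).sum() for v in vals.values())
        f_hand = (ssb / (len(vals) - 1)) / (ssw / (allv.size - len(vals)))
        assert out["table"][0]["F"] == pytest.approx(f_hand, rel=1e-10)

    def test_two_way_pure_interaction(self):
        rng = np.random.default_rng(3)
        vals = {}
        for a in ("A1", "A2"):
            for b in ("B1", "B2"):
                mu = 5.0 if (a == "A1") == (b == "B1") else -5.0  # pure interaction
                vals[(a, b)] = mu + rng.normal(0, 0.1, 4)
        out = anova_posthoc(vals)
        rows = {r["source"]: r for r in out["table"]}
        assert rows["interaction"]["F"] > 100
        assert rows["factor_a"]["F"] < 5
        assert rows["factor_b"]["F"] < 5

    def test_lsd_less_conservative_than_hsd(self, rng):
        vals = {g: rng.normal(m, 1.0, 5) for g, m in zip("abcd", (0, 0.8, 1.6, 2.4))}
        lsd = anova_posthoc(vals, method="LSD")
        hsd = anova_posthoc(vals, method="HSD")
        for pair in lsd["pairwise_p"]:
            assert lsd["pairwise_p"][pair] <= hsd["pairwise_p"][pair] + 1e-12

    def test_insufficient_replication(self):
        with pytest.raises(InsufficientDataError):
            anova_posthoc({"a": [1.0], "b": [2.0]})

    def test_method_validation(self):
        with pytest.raises(InvalidParameterError):
            anova_posthoc({"a": [1, 2.0], "b": [3, 4.0]}, method="bonferroni")
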