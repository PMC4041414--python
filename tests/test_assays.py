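"""Flow/gel quantification and saturation-binding Kd fitting."""

import numpy as np
import pandas as pd
import pytest

from lhekit.assays import (
    BindingTitration,
    FlowEventSet,
    binding_model,
    cleavage_index,
    expression_band_gate,
    fit_binding,
    gate_from_negative_control,
    gel_fraction,
    tlr_fractions,
)
from lhekit.simulate import gen_flow_events, gen_titration


def events(values, channel="A647"):
    return FlowEventSet(pd.DataFrame({channel: values}))


class TestCleavageIndex:
    def test_identical_distributions_give_zero(self):
        e = events([100.0, 200.0, 300.0])
        assert cleavage_index(e, e) == 0.0

    def test_full_release_gives_one(self):
        mg = events([0.0, 0.0, 0.0])
        ca = events([100.0, 200.0, 300.0])
        assert cleavage_index(mg, ca) == 1.0

    def test_planted_median_ratio(self):
        rng = np.random.default_rng(0)
        base = rng.lognormal(5, 0.3, size=2000)
        mg = events(base * 0.3)
        ca = events(base)
        assert cleavage_index(mg, ca) == pytest.approx(0.7, abs=1e-9)

    def test_invariant_to_common_scale(self):
        rng = np.random.default_rng(1)
        a, b = rng.lognormal(5, 0.3, 1000), rng.lognormal(5.5, 0.3, 1000)
        idx1 = cleavage_index(events(a), events(b))
        idx2 = cleavage_index(events(a * 7.3), events(b * 7.3))
        assert idx1 == pytest.approx(idx2)

    def test_zero_control_median_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            cleavage_index(events([1.0]), events([0.0]))


class TestTlrFractions:
    def test_all_expressing_cells_positive(self):
        df = pd.DataFrame({"BFP": [1000.0] * 10, "mCherry": [1000.0] * 10})
        res = tlr_fractions(FlowEventSet(df), {"BFP": 10.0, "mCherry": 10.0})
        assert res.fractions["NHEJ"] == 1.0

    def test_mock_mode_uses_total_population(self):
        df = pd.DataFrame({"mCherry": [1000.0] * 3 + [1.0] * 7})
        res = tlr_fractions(
            FlowEventSet(df), {"mCherry": 10.0}, mock=True
        )
        assert res.n_in_gate == 10
        assert res.fractions["NHEJ"] == pytest.approx(0.3)

    def test_planted_fractions_recovered_with_threshold_gates(self):
        neg, pos = (1.0, 0.2), (3.0, 0.2)  # log10 mean/sd, well separated
        ev, truth = gen_flow_events(
            [
                (0.6, {"BFP": neg, "mCherry": neg, "GFP": neg}),
                (0.1, {"BFP": pos, "mCherry": pos, "GFP": neg}),   # NHEJ
                (0.1, {"BFP": pos, "mCherry": neg, "GFP": pos}),   # HDR
                (0.2, {"BFP": pos, "mCherry": neg, "GFP": neg}),   # unmodified
            ],
            n=20_000,
            seed=2,
        )
        th = {"BFP": 100.0, "mCherry": 100.0, "GFP": 100.0}
        res = tlr_fractions(ev, th)
        assert res.n_in_gate == 8000  # deterministic planted counts
        assert res.fractions["NHEJ"] == pytest.approx(0.25, abs=0.01)
        assert res.fractions["HDR"] == pytest.approx(0.25, abs=0.01)
        total = res.fractions["NHEJ"] + res.fractions["HDR"] + res.fractions["unmodified"]
        assert total == pytest.approx(1.0, abs=0.01)

    def test_empty_expression_gate_raises(self):
        df = pd.DataFrame({"BFP": [1.0] * 5, "mCherry": [1.0] * 5})
        with pytest.raises(ValueError):
            tlr_fractions(FlowEventSet(df), {"BFP": 100.0, "mCherry": 100.0})

    def test_negative_control_gate_quantile(self):
        rng = np.random.default_rng(3)
        ctl = events(rng.lognormal(3, 0.3, 10_000), channel="mCherry")
        cut = gate_from_negative_control(ctl, "mCherry", quantile=0.995)
        frac_above = (ctl.data["mCherry"] > cut).mean()
        assert frac_above == pytest.approx(0.005, abs=0.002)

    def test_expression_band_captures_requested_fraction(self):
        rng = np.random.default_rng(4)
        ev = events(rng.lognormal(5, 0.5, 50_000), channel="Myc")
        lo, hi = expression_band_gate(ev, "Myc", fraction=0.10)
        inside = ((ev.data["Myc"] >= lo) & (ev.data["Myc"] <= hi)).mean()
        assert inside == pytest.approx(0.10, abs=0.01)


class TestGelFraction:
    @pytest.mark.parametrize(
        "cleaved,uncut,expected", [(50, 50, 0.5), (0, 10, 0.0), (10, 0, 1.0)]
    )
    def test_examples(self, cleaved, uncut, expected):
        assert gel_fraction(cleaved, uncut) == expected

    def test_random_pairs_match_direct_arithmetic(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            a, b = rng.uniform(0.01, 100, 2)
            assert gel_fraction(a, b) == pytest.approx(a / (a + b))

    def test_both_zero_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            gel_fraction(0.0, 0.0)


class TestBindingFit:
    def test_noiseless_recovery_is_exact(self):
        t, truth = gen_titration(10.0, 1000.0, 50.0, sigma=0.0, seed=6)
        fit = fit_binding(t)
        assert fit.converged
        assert fit.kd == pytest.approx(10.0, rel=1e-6)
        assert fit.fmax == pytest.approx(1000.0, rel=1e-6)
        assert fit.f0 == pytest.approx(50.0, rel=1e-4)
        assert fit.rss < 1e-12 * 1000.0**2

    def test_flat_titration_flagged_unidentifiable(self):
        t = BindingTitration((1.0, 10.0, 100.0, 500.0), (100.0, 100.0, 100.0, 100.0))
        fit = fit_binding(t)
        assert any("unidentifiable" in w for w in fit.warnings)

    def test_concentrations_below_kd_flagged(self):
        # all c << Kd: the curve is locally linear, Kd cannot be pinned down
        c = (1.0, 1.5, 2.2, 3.3, 5.0)
        y = tuple(binding_model(np.array(c), 5000.0, 1000.0, 10.0))
        fit = fit_binding(BindingTitration(c, y))
        assert fit.warnings  # out-of-range Kd and/or narrow span

    def test_matches_grid_search_oracle_on_noisy_data(self):
        t, _ = gen_titration(25.0, 800.0, 30.0, sigma=0.02, seed=7)
        c = np.array(t.concentrations)
        y = np.array(t.responses)
        fit = fit_binding(t)

        def rss_for_kd(kd):
            # profile out the linear parameters for fixed Kd
            x = c / (kd + c)
            A = np.column_stack([np.ones_like(x), x])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            return float(np.sum((A @ coef - y) ** 2))

        grid = np.geomspace(1, 500, 4000)
        best_kd = grid[np.argmin([rss_for_kd(k) for k in grid])]
        assert fit.kd == pytest.approx(best_kd, rel=0.01)
        assert fit.rss <= rss_for_kd(best_kd) + 1e-9

    def test_first_order_optimality(self):
        t, _ = gen_titration(15.0, 600.0, 20.0, sigma=0.03, seed=8)
        fit = fit_binding(t)
        c = np.array(t.concentrations)
        y = np.array(t.responses)

        def rss(params):
            kd, fmax, f0 = params
            return float(np.sum((binding_model(c, kd, fmax, f0) - y) ** 2))

        x0 = np.array([fit.kd, fit.fmax, fit.f0])
        scale = np.maximum(np.abs(x0), 1.0)
        for i in range(3):
            h = np.zeros(3)
            h[i] = 1e-6 * scale[i]
            grad = (rss(x0 + h) - rss(x0 - h)) / (2 * h[i])
            assert abs(grad) < 1e-3 * max(rss(x0), 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            BindingTitration((1.0, 10.0, 100.0), (1.0, 2.0, 3.0))

    def test_unsorted_concentrations_rejected(self):
        with pytest.raises(ValueError):
            BindingTitration((10.0, 1.0, 100.0, 500.0), (1.0, 2.0, 3.0, 4.0))
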