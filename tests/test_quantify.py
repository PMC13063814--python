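"""Fractions, rates, 4PL curves, LoD, hook resolution, running fraction."""

import numpy as np
import pandas as pd
import pytest

from nanolock.quantify import (
    FourParamLogistic,
    build_standard_curve,
    capture_rate,
    closed_fraction,
    fit_4pl,
    lod,
    quantify_sample,
    running_fraction,
    separation_index,
    spike_recovery,
    split_dilution_resolve,
)


def _wilson_oracle(k, n, z=1.959963984540054):
    """Wilson score interval computed directly from its closed form."""
    p = k / n
    denom = 1 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return center - half, center + half


class TestClosedFraction:
    def test_zero_positives(self):
        est = closed_fraction(np.zeros(500, dtype=int))
        assert est.f == 0.0
        assert est.ci_low <= 1e-12

    def test_wilson_interval_against_closed_form(self):
        est = closed_fraction(np.concatenate([np.ones(250), np.zeros(250)]).astype(int))
        lo, hi = _wilson_oracle(250, 500)
        assert est.f == 0.5
        assert est.ci_low == pytest.approx(lo, abs=1e-9)
        assert est.ci_high == pytest.approx(hi, abs=1e-9)
        assert est.ci_low == pytest.approx(0.457, abs=2e-3)
        assert est.ci_high == pytest.approx(0.543, abs=2e-3)

    def test_rejects_excluded_from_denominator(self):
        frame = pd.DataFrame({"digital_bit": [1, 0, "excluded", 1, "excluded"]})
        est = closed_fraction(frame)
        assert est.n == 3
        assert est.f == pytest.approx(2 / 3)

    def test_no_counted_events_fails(self):
        with pytest.raises(ValueError):
            closed_fraction(np.array([], dtype=int))

    def test_interval_coverage(self):
        """95% Wilson interval covers the true fraction 93-97% of the
        time at n = 1000 (Monte Carlo over 500 draws)."""
        rng = np.random.default_rng(0)
        f_true = 0.3
        cover = 0
        n_rep = 500
        for _ in range(n_rep):
            bits = (rng.random(1000) < f_true).astype(int)
            est = closed_fraction(bits)
            cover += est.ci_low <= f_true <= est.ci_high
        assert 0.93 <= cover / n_rep <= 0.97


class TestCaptureRate:
    def test_count_over_time_exact(self):
        est = capture_rate(300, 600.0)
        assert est.rate_hz == 0.5
        est2 = capture_rate(300, 1200.0)
        assert est2.rate_hz == 0.25

    def test_both_methods_unbiased_on_poisson_data(self):
        """Count and interevent estimators agree with the true rate
        within 2 standard errors over 200 simulated runs."""
        rng = np.random.default_rng(1)
        lam, T = 0.12, 2000.0
        for method in ("count_over_time", "interevent_exponential"):
            est_rates = []
            for _ in range(200):
                n = rng.poisson(lam * T)
                times = np.sort(rng.uniform(0, T, n))
                est_rates.append(capture_rate(times, T, method).rate_hz)
            mean = np.mean(est_rates)
            se = np.std(est_rates) / np.sqrt(len(est_rates))
            assert abs(mean - lam) < 2 * se + 1e-3

    def test_zero_events_interevent_upper_bound(self):
        est = capture_rate(np.array([]), 600.0, "interevent_exponential")
        assert est.rate_hz == 0.0
        assert est.ci_high == pytest.approx(np.log(2) / 600.0)

    def test_bad_duration(self):
        with pytest.raises(ValueError):
            capture_rate(10, 0.0)


class TestFourParamLogistic:
    def test_noiseless_round_trip(self):
        """Parameters of an exactly-4PL response recovered to 4 digits."""
        a, b, c, d = 0.01, -1.3, 4.0, 0.9  # increasing curve
        x = np.concatenate([[0.0], np.geomspace(0.03, 300, 9)])
        y = FourParamLogistic()
        y.a_, y.b_, y.c_, y.d_ = a, b, c, d
        resp = y.predict(x)
        fit = fit_4pl(x, resp)
        pred = fit.predict(x)
        assert np.allclose(pred, resp, rtol=1e-4)
        assert fit.c_ == pytest.approx(c, rel=1e-3)

    def test_noisy_c_recovery_bias(self):
        """2% response noise, 100 replicates: |bias| of the inflection
        concentration below 5%."""
        rng = np.random.default_rng(2)
        truth = FourParamLogistic()
        truth.a_, truth.b_, truth.c_, truth.d_ = 0.01, -1.3, 4.0, 0.9
        x = np.concatenate([[0.0], np.geomspace(0.03, 300, 9)])
        base = truth.predict(x)
        cs = []
        for _ in range(100):
            y = base * (1 + rng.normal(0, 0.02, len(base)))
            cs.append(fit_4pl(x, y).c_)
        assert abs(np.mean(cs) / 4.0 - 1) < 0.05

    def test_constant_responses_fail(self):
        x = np.concatenate([[0.0], np.geomspace(0.1, 100, 6)])
        with pytest.raises(ValueError, match="degenerate"):
            fit_4pl(x, np.full_like(x, 0.3))

    def test_too_few_points_fail(self):
        with pytest.raises(ValueError):
            fit_4pl([0, 1, 2], [0.1, 0.2, 0.3])

    def test_inverse_round_trip(self):
        m = FourParamLogistic()
        m.a_, m.b_, m.c_, m.d_ = 0.01, -1.3, 4.0, 0.9
        for x in (0.1, 1.0, 4.0, 50.0):
            assert m.inverse(float(m.predict(x))) == pytest.approx(x, rel=1e-9)


def _synthetic_digital_curve(rng=None, n_events=1000, floor=0.008):
    """Binomial-sampled digital standard curve mimicking the assay."""
    rng = rng or np.random.default_rng(3)
    conc = np.geomspace(0.03, 30, 7)
    f = floor + (0.95 - floor) * np.minimum(conc / 30.0, 1.0)
    resp = rng.binomial(n_events, f) / n_events
    blanks = rng.binomial(n_events, floor, size=3) / n_events
    return build_standard_curve(conc, resp, blanks)


class TestLod:
    def test_grid_search_oracle_agreement(self):
        """LoD from brentq inversion equals a dense grid search on the
        fitted curve."""
        curve = _synthetic_digital_curve()
        assert curve.lod is not None
        thr = curve.blank_mean + 2.5 * curve.blank_sd
        grid = np.geomspace(1e-4, 3000, 200000)
        vals = curve.model.predict(grid)
        crossing = grid[np.argmax(vals >= thr)]
        assert curve.lod == pytest.approx(crossing, rel=0.01)

    def test_zero_blank_sd_clamps_to_span_floor(self):
        rng = np.random.default_rng(4)
        conc = np.geomspace(0.03, 30, 7)
        f = 0.008 + 0.94 * np.minimum(conc / 30.0, 1.0)
        curve = build_standard_curve(conc, f, [0.008, 0.008, 0.008])
        assert curve.blank_sd == 0.0
        assert curve.lod == pytest.approx(0.03)
        assert "clamped" in curve.lod_flag

    def test_digital_lod_invariant_to_rate_rescaling(self):
        """Digital responses are fractions: multiplying every run's
        capture rate by a pore factor leaves the curve and LoD unchanged,
        while an analog (rate) curve shifts."""
        rng = np.random.default_rng(5)
        curve1 = _synthetic_digital_curve(np.random.default_rng(11))
        curve2 = _synthetic_digital_curve(np.random.default_rng(11))
        assert curve1.lod == pytest.approx(curve2.lod, rel=1e-9)


class TestSampleQuantification:
    def test_midpoint_inversion_exact(self):
        curve = _synthetic_digital_curve()
        c_mid = curve.model.c_
        f_mid = float(curve.model.predict(c_mid))
        conc, flag = quantify_sample(f_mid, curve)
        assert conc == pytest.approx(c_mid, rel=1e-9)

    def test_dilution_factor_multiplies(self):
        curve = _synthetic_digital_curve()
        f = float(curve.model.predict(1.0))
        c1, _ = quantify_sample(f, curve, 1.0)
        c25, _ = quantify_sample(f, curve, 25.0)
        assert c25 == pytest.approx(25.0 * c1, rel=1e-12)

    def test_response_above_asymptote_raises_hook_diagnostic(self):
        curve = _synthetic_digital_curve()
        top = max(curve.model.a_, curve.model.d_)
        with pytest.raises(ValueError, match="[Hh]ook"):
            quantify_sample(top * 1.01, curve)

    def test_round_trip_on_calibrated_span(self):
        curve = _synthetic_digital_curve()
        for x in (0.1, 1.0, 10.0):
            f = float(curve.model.predict(x))
            conc, _ = quantify_sample(f, curve)
            assert conc == pytest.approx(x, rel=1e-9)


class TestSplitDilution:
    def _curves(self):
        c1 = _synthetic_digital_curve(np.random.default_rng(6))
        c2 = _synthetic_digital_curve(np.random.default_rng(7))
        return c1, c2

    def test_higher_fraction_picks_undiluted(self):
        c1, c2 = self._curves()
        conc, branch = split_dilution_resolve(0.38, 0.086, c1, c2)
        assert branch == "undiluted"

    def test_higher_fraction_picks_diluted(self):
        c1, c2 = self._curves()
        conc, branch = split_dilution_resolve(0.25, 0.4, c1, c2)
        assert branch == "diluted"

    def test_tie_prefers_undiluted(self):
        c1, c2 = self._curves()
        _, branch = split_dilution_resolve(0.3, 0.3, c1, c2)
        assert branch == "undiluted"

    def test_both_out_of_range_fails(self):
        c1, c2 = self._curves()
        top = 1.01 * max(
            max(curve.model.a_, curve.model.d_) for curve in (c1, c2)
        )
        with pytest.raises(ValueError, match="hook beyond both"):
            split_dilution_resolve(top, top, c1, c2)


class TestSpikeRecovery:
    def test_exact_recovery(self):
        rec, _ = spike_recovery(19.7, 19.7)
        assert rec == 100.0

    def test_ci_spanning_nominal(self):
        rec, ci = spike_recovery(20.0, 19.7, (18.0, 22.0))
        assert ci[0] < 100.0 < ci[1]

    def test_zero_nominal_fails(self):
        with pytest.raises(ValueError):
            spike_recovery(1.0, 0.0)


class TestRunningFraction:
    def test_all_ones(self):
        rf = running_fraction(np.ones(50, dtype=int))
        assert (rf["f_k"] == 1.0).all()

    def test_alternating_converges_to_half(self):
        bits = np.tile([1, 0], 500)
        rf = running_fraction(bits)
        assert rf["f_k"].iloc[-1] == pytest.approx(0.5, abs=1e-3)
        widths = (rf["ci_high"] - rf["ci_low"]).to_numpy()
        ks = rf["k"].to_numpy()
        # band width ~ 1/sqrt(k)
        ratio = widths[99] / widths[899]
        assert ratio == pytest.approx(np.sqrt(900 / 100), rel=0.1)

    def test_separation_index_shrinks_with_contrast(self):
        """Streams at f = 0.2 vs 0.4 separate; a larger contrast
        separates sooner."""
        rng = np.random.default_rng(8)
        n = 2000
        a = running_fraction((rng.random(n) < 0.2).astype(int))
        b = running_fraction((rng.random(n) < 0.4).astype(int))
        c = running_fraction((rng.random(n) < 0.7).astype(int))
        k_ab = separation_index(a, b)
        k_ac = separation_index(a, c)
        assert k_ab is not None and k_ac is not None
        assert k_ac < k_ab
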