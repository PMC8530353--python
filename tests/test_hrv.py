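"""Tachogram windowing, quality gating, Burg spectra and HRV indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ansrisk import hrv, synthetic
from conftest import clean_rri


class TestWindowing:
    def test_tumbling_window_count(self):
        # 600 s of 1000-ms beats -> five 120-s windows
        rri = hrv.RRISeries.from_rri(np.full(600, 1000.0))
        assert len(hrv.window_rri(rri, 120.0)) == 5

    def test_short_series_yields_no_window(self):
        rri = hrv.RRISeries.from_rri(np.full(119, 1000.0))
        assert hrv.window_rri(rri, 120.0) == []

    def test_boundary_beat_belongs_to_next_window(self):
        # first beat at exactly t0 + 120 s must open window 2, not close window 1
        rri = hrv.RRISeries.from_rri(np.full(240, 1000.0))
        wins = hrv.window_rri(rri, 120.0)
        t0 = rri.t_ms[0] - rri.rri_ms[0]
        assert wins[0].t_ms[-1] < t0 + 120_000.0
        assert wins[1].t_ms[0] == t0 + 120_000.0

    def test_rest_mode_returns_leading_90s(self):
        rri = hrv.RRISeries.from_rri(np.full(200, 1000.0))
        wins = hrv.window_rri(rri, mode="rest")
        assert len(wins) == 1
        assert wins[0].t_ms[-1] - wins[0].t_ms[0] <= 90_000.0


class TestQualityGate:
    @pytest.mark.parametrize("n_flagged,expected", [
        (0, True),       # clean window passes
        (15, True),      # exactly 10% of 150 beats: rule is "exceeds", so pass
        (16, False),     # just above 10%: fail
    ])
    def test_flagged_fraction_boundary(self, n_flagged, expected):
        flags = np.zeros(150, bool)
        flags[:n_flagged] = True
        w = hrv.RRISeries.from_rri(np.full(150, 800.0), flag=flags)
        assert hrv.assess_window_quality(w) is expected

    def test_abnormal_jump_counts_as_bad(self):
        vals = np.full(150, 800.0)
        vals[50] = 1200.0  # 50% jump from the neighbor
        w = hrv.RRISeries.from_rri(vals)
        assert hrv.abnormal_beats(w).sum() >= 1

    def test_implausible_heart_rate_fails(self):
        w = hrv.RRISeries.from_rri(np.full(80, 2500.0))  # 24 bpm
        assert not hrv.assess_window_quality(w)

    def test_gate_is_monotone_in_flags(self):
        # flagging more beats can never rescue a failing window
        rng = np.random.default_rng(0)
        vals = 800 + rng.uniform(-30, 30, 150)
        flags = np.zeros(150, bool)
        flags[:20] = True
        w_fail = hrv.RRISeries.from_rri(vals, flag=flags)
        assert not hrv.assess_window_quality(w_fail)
        flags2 = flags.copy()
        flags2[20:40] = True
        assert not hrv.assess_window_quality(
            hrv.RRISeries.from_rri(vals, flag=flags2))


class TestMemPsd:
    def test_constant_series_has_negligible_power(self, driver):
        psd_const = hrv.mem_psd(clean_rri(160, 800.0))
        params = synthetic.RRIParams(a_lf0=0.04, k_lf=0.0, a_hf0=0.0,
                                     noise_ms=0.0)
        modulated = synthetic.generate_rri(driver, np.zeros(150), 150,
                                           params, seed=0)
        psd_mod = hrv.mem_psd(modulated)
        total = np.trapezoid(psd_const.density, psd_const.freq)
        total_mod = np.trapezoid(psd_mod.density, psd_mod.freq)
        assert total <= 1e-6 * total_mod

    @pytest.mark.parametrize("f_tone", [0.10, 0.25])
    def test_peak_location_matches_modulation_frequency(self, driver, f_tone):
        params = synthetic.RRIParams(
            f_lf=f_tone, a_lf0=0.04, k_lf=0.0, a_hf0=0.0, noise_ms=0.0)
        rri = synthetic.generate_rri(driver, np.zeros(150), 150, params, seed=1)
        psd = hrv.mem_psd(rri)
        peak = psd.freq[np.argmax(psd.density)]
        assert abs(peak - f_tone) <= 0.01

    def test_psd_integral_matches_series_variance(self, driver):
        from scipy.interpolate import CubicSpline
        from scipy.signal import detrend

        rri = synthetic.generate_rri(driver, np.full(150, 0.3), 150,
                                     synthetic.RRIParams(), seed=2)
        psd = hrv.mem_psd(rri)
        t_s = rri.t_ms / 1000.0
        grid = np.arange(t_s[0], t_s[-1], 1.0 / hrv.RESAMPLE_HZ)
        tach = detrend(CubicSpline(t_s, rri.rri_ms)(grid), type="linear")
        integral = np.trapezoid(psd.density, psd.freq)
        assert integral == pytest.approx(tach.var(), rel=0.05)

    def test_white_noise_band_power_tracks_band_width(self, driver):
        # flat-spectrum input: power ratio of two bands ~ width ratio
        ratios = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            rri = hrv.RRISeries.from_rri(800 + 15 * rng.standard_normal(480))
            psd = hrv.mem_psd(rri)
            lf = hrv.band_power(psd, *hrv.LF_BAND)
            hf = hrv.band_power(psd, *hrv.HF_BAND)
            ratios.append(lf / hf)
        width_ratio = (0.15 - 0.04) / (0.40 - 0.15)
        assert np.mean(ratios) == pytest.approx(width_ratio, rel=0.20)

    def test_aic_order_policy_runs(self, driver):
        rri = synthetic.generate_rri(driver, np.zeros(150), 150,
                                     synthetic.RRIParams(), seed=3)
        psd = hrv.mem_psd(rri, order_policy="aic")
        assert 2 <= psd.ar_order <= 30

    def test_too_few_beats_raises(self):
        with pytest.raises(ValueError):
            hrv.mem_psd(clean_rri(30))


class TestBandPower:
    def test_flat_density_rectangle_area(self):
        freq = np.linspace(0, 2.0, 1001)
        psd = hrv.PSD(freq, np.full_like(freq, 3.0), ar_order=0)
        assert hrv.band_power(psd, 0.04, 0.15) == pytest.approx(3.0 * 0.11)
        assert hrv.band_power(psd, 0.0, 0.5) == pytest.approx(1.5)

    def test_zero_density_zero_power(self):
        freq = np.linspace(0, 2.0, 101)
        psd = hrv.PSD(freq, np.zeros_like(freq), ar_order=0)
        assert hrv.band_power(psd, 0.15, 0.40) == 0.0

    def test_band_partition_additivity(self, driver):
        rri = synthetic.generate_rri(driver, np.full(150, 0.4), 150,
                                     synthetic.RRIParams(), seed=4)
        psd = hrv.mem_psd(rri)
        vlf = hrv.band_power(psd, 0.0033, 0.04)
        lf = hrv.band_power(psd, 0.04, 0.15)
        hf = hrv.band_power(psd, 0.15, 0.40)
        total = hrv.band_power(psd, 0.0033, 0.40)
        assert vlf + lf + hf == pytest.approx(total, rel=1e-6)

    def test_band_outside_grid_raises(self):
        freq = np.linspace(0, 0.3, 31)
        psd = hrv.PSD(freq, np.ones_like(freq), ar_order=0)
        with pytest.raises(ValueError):
            hrv.band_power(psd, 0.15, 0.40)


class TestDeviationScores:
    def test_mean_input_scores_50(self, toy_normative):
        lf = np.exp(3.0) * 700.0          # log(LF/RRI) == mu_LF
        hf = 1.0 * 700.0                  # HF/RRI == mu_HF
        lf_s, hf_s = hrv.deviation_scores(lf, hf, 700.0, 40, toy_normative)
        assert lf_s == pytest.approx(50.0)
        assert hf_s == pytest.approx(50.0)

    def test_one_sigma_adds_ten_points(self, toy_normative):
        lf = np.exp(3.5) * 700.0          # mu + sigma on the log scale
        hf = 1.2 * 700.0                  # mu + sigma on the raw scale
        lf_s, hf_s = hrv.deviation_scores(lf, hf, 700.0, 40, toy_normative)
        assert lf_s == pytest.approx(60.0)
        assert hf_s == pytest.approx(60.0)

    def test_hand_evaluated_example(self, toy_normative):
        # mu_LF=3.0, sigma_LF=0.5, log(LF/RRI)=3.8 -> 10*(0.8/0.5)+50 = 66
        lf_s, _ = hrv.deviation_scores(np.exp(3.8) * 700.0, 700.0, 700.0,
                                       40, toy_normative)
        assert lf_s == pytest.approx(66.0)

    def test_affine_in_standardized_input(self, normative_table):
        row = normative_table.row(45)
        rri_avg = 820.0
        base = np.exp(row["mu_lf"] - 0.3) * rri_avg
        plus = np.exp(row["mu_lf"] - 0.3 + row["sigma_lf"]) * rri_avg
        s0, _ = hrv.deviation_scores(base, 1.0, rri_avg, 45, normative_table)
        s1, _ = hrv.deviation_scores(plus, 1.0, rri_avg, 45, normative_table)
        assert s1 - s0 == pytest.approx(10.0)

    def test_domain_errors(self, normative_table):
        with pytest.raises(ValueError):
            hrv.deviation_scores(0.0, 1.0, 800.0, 45, normative_table)
        with pytest.raises(KeyError):
            hrv.deviation_scores(100.0, 1.0, 800.0, 95, normative_table)


class TestTimeDomain:
    def test_toy_series(self):
        w = hrv.RRISeries.from_rri([800.0, 810.0, 790.0, 860.0])
        avghr, sdnn, nn50, rmssd = hrv.time_domain_features(w)
        assert nn50 == 1                                   # only |790-860|=70 > 50
        assert rmssd == pytest.approx(np.sqrt(1800.0))     # (100+400+4900)/3
        assert sdnn == pytest.approx(31.0913, abs=1e-3)
        assert avghr == pytest.approx(60000.0 / 815.0, abs=1e-3)

    def test_constant_series(self):
        avghr, sdnn, nn50, rmssd = hrv.time_domain_features(
            hrv.RRISeries.from_rri(np.full(100, 1000.0)))
        assert (avghr, sdnn, nn50, rmssd) == (60.0, 0.0, 0, 0.0)

    def test_alternating_51ms_counts_every_difference(self):
        vals = np.tile([800.0, 851.0], 50)
        _, _, nn50, _ = hrv.time_domain_features(hrv.RRISeries.from_rri(vals))
        assert nn50 == len(vals) - 1

    def test_flagged_beats_excluded(self):
        vals = np.full(100, 800.0)
        vals[10] = 1600.0
        flags = np.zeros(100, bool)
        flags[10] = True
        _, sdnn, _, _ = hrv.time_domain_features(
            hrv.RRISeries.from_rri(vals, flag=flags))
        assert sdnn == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=400.0, max_value=1500.0),
                    min_size=3, max_size=200))
    def test_matches_brute_force(self, vals):
        """Vectorized implementation equals element-by-element arithmetic."""
        w = hrv.RRISeries.from_rri(vals)
        avghr, sdnn, nn50, rmssd = hrv.time_domain_features(w)
        n = len(vals)
        mean = sum(vals) / n
        bf_sdnn = (sum((v - mean) ** 2 for v in vals) / (n - 1)) ** 0.5
        diffs = [vals[i + 1] - vals[i] for i in range(n - 1)]
        bf_nn50 = sum(1 for d in diffs if abs(d) > 50.0)
        bf_rmssd = (sum(d * d for d in diffs) / len(diffs)) ** 0.5
        assert avghr == pytest.approx(60000.0 / mean)
        assert sdnn == pytest.approx(bf_sdnn)
        assert nn50 == bf_nn50
        assert rmssd == pytest.approx(bf_rmssd)


class TestAnfSeries:
    def test_clean_series_all_windows_pass(self, driver, normative_table):
        rri = synthetic.generate_rri(driver, np.full(620, 0.3), 610,
                                     synthetic.RRIParams(), seed=5)
        windows = hrv.compute_anf_series(rri, driver.age, normative_table)
        assert len(windows) == 5
        assert all(w.quality_pass for w in windows)
        assert all(w.lf is not None and w.lf >= 0 for w in windows)

    def test_single_corrupted_window_fails_alone(self, driver, normative_table):
        rri = synthetic.generate_rri(driver, np.full(620, 0.3), 610,
                                     synthetic.RRIParams(), seed=6)
        # flag 20% of the beats inside the third window only
        m = (rri.t_ms >= 240_000 + rri.t_ms[0]) & (rri.t_ms < 360_000 + rri.t_ms[0])
        idx = np.nonzero(m)[0]
        flags = rri.flag.copy()
        flags[idx[:int(0.2 * len(idx))]] = True
        corrupted = hrv.RRISeries(rri.t_ms, rri.rri_ms, flags)
        windows = hrv.compute_anf_series(corrupted, driver.age, normative_table)
        assert [w.quality_pass for w in windows] == [True, True, False, True, True]

    def test_high_stress_raises_lfhf(self, driver, normative_table):
        """Planted stress -> LF/HF direction survives the whole pipeline."""
        means = {}
        for label, level in [("high", 0.9), ("low", 0.1)]:
            vals = []
            for seed in range(4):
                rri = synthetic.generate_rri(driver, np.full(630, level), 620,
                                             synthetic.RRIParams(), seed=seed)
                ws = hrv.compute_anf_series(rri, driver.age, normative_table)
                vals += [w.lfhf_ratio for w in ws if w.quality_pass]
            means[label] = np.mean(vals)
        assert means["high"] > means["low"]

    def test_frame_round_trip(self, driver, normative_table):
        rri = synthetic.generate_rri(driver, np.full(260, 0.3), 250,
                                     synthetic.RRIParams(), seed=7)
        windows = hrv.compute_anf_series(rri, driver.age, normative_table)
        df = hrv.anf_windows_to_frame(windows)
        assert list(df["quality_pass"]) == [w.quality_pass for w in windows]
        assert {"lf", "hf", "lf_score", "hf_score", "sdnn"} <= set(df.columns)
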