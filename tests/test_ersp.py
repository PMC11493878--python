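"""Time-frequency maps, dB baselining, band scores, summed activity."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from plaslab.cluster import Cluster, ClusterResult
from plaslab.erp import EpochSet
from plaslab.ersp import (BandSpec, TimeFreqMap, band_response_score,
                          baseline_db, morlet_tfr, night_trend_and_group_tests,
                          significant_channel_fraction, standard_bands,
                          summed_activity)
from plaslab.layout import spiral_layout


def make_epochs(signal, n_trials=3, n_ch=2, rate=200.0):
    """EpochSet spanning [-1.5, 3] s filled with `signal(t)` on every
    trial/channel."""
    times = np.arange(-int(1.5 * rate), int(3.0 * rate) + 1) / rate
    x = signal(times)
    data = np.tile(x, (n_trials, n_ch, 1))
    return EpochSet(epochs=data, times=times, rate=rate,
                    channel_names=[f"c{i}" for i in range(n_ch)],
                    night="E1", n_stimulations=n_trials)


def make_tfr(power, freqs, times, night="E1", n_stim=100, units="power"):
    n_ch = power.shape[0]
    return TimeFreqMap(power=power, freqs=np.asarray(freqs, float),
                       times=np.asarray(times, float),
                       channel_names=[f"c{i}" for i in range(n_ch)],
                       night=night, n_stimulations=n_stim, units=units)


class TestMorlet:
    def test_oscillator_peaks_at_its_frequency(self):
        es = make_epochs(lambda t: np.sin(2 * np.pi * 10.0 * t))
        tfr = morlet_tfr(es)
        interior = (tfr.times > -0.5) & (tfr.times < 1.5)
        peak_bins = tfr.power[0][:, interior].argmax(axis=0)
        assert np.all(np.abs(tfr.freqs[peak_bins] - 10.0) <= 0.5)

    def test_zero_signal_zero_power(self):
        es = make_epochs(lambda t: 0.0 * t)
        assert np.allclose(morlet_tfr(es).power, 0.0)

    def test_burst_localized_in_time(self):
        rng = np.random.default_rng(0)

        def sig(t):
            burst = np.where((t >= 1.0) & (t <= 1.4),
                             np.sin(2 * np.pi * 13.0 * t), 0.0)
            return 5.0 * burst

        es = make_epochs(sig)
        es = dataclasses.replace(
            es, epochs=es.epochs + rng.normal(0, 0.3, es.epochs.shape))
        tfr = morlet_tfr(es)
        spindle = (tfr.freqs >= 12) & (tfr.freqs <= 16)
        course = tfr.power[0][spindle].mean(axis=0)
        t_peak = tfr.times[np.argmax(course)]
        assert 0.8 <= t_peak <= 1.6

    def test_unresolvable_frequency_rejected(self):
        es = make_epochs(lambda t: 0.0 * t)
        with pytest.raises(ValueError, match="unresolvable"):
            morlet_tfr(es, freqs=np.array([0.5]), cycles=np.array([5.0]))


class TestBaselineDb:
    def test_stationary_signal_near_zero_db(self):
        es = make_epochs(lambda t: np.sin(2 * np.pi * 8.0 * t))
        db = baseline_db(morlet_tfr(es))
        inner = (db.times > -0.5) & (db.times < 1.5)
        sel = (db.freqs >= 6) & (db.freqs <= 10)
        assert np.abs(db.power[0][np.ix_(sel, inner.nonzero()[0])]).max() < 1.0

    def test_tenfold_power_is_ten_db(self):
        freqs = np.array([1.0, 2.0])
        times = np.linspace(-1.5, 2.5, 81)
        power = np.ones((1, 2, 81))
        power[0, 0, times >= 0.5] = 10.0
        power[0, :, times >= 2.0] = 1.0     # baseline window flat at 1
        db = baseline_db(make_tfr(power, freqs, times))
        assert db.power[0, 0, 40] == pytest.approx(10.0)
        assert db.units == "dB"

    def test_uniform_scaling_cancels(self):
        es = make_epochs(lambda t: np.sin(2 * np.pi * 6.0 * t))
        scaled = dataclasses.replace(es, epochs=3.7 * es.epochs)
        db1 = baseline_db(morlet_tfr(es))
        db2 = baseline_db(morlet_tfr(scaled))
        np.testing.assert_allclose(db1.power, db2.power, atol=1e-8)

    def test_zero_baseline_rejected(self):
        power = np.zeros((1, 2, 81))
        tfr = make_tfr(power, [1.0, 2.0], np.linspace(-1.5, 2.5, 81))
        with pytest.raises(ValueError):
            baseline_db(tfr)


class TestChannelFraction:
    def _result(self, clusters, shape):
        return ClusterResult(clusters=clusters, alpha=0.01, n_permutations=200,
                             t_threshold=2.0, shape=shape)

    def test_no_clusters_all_zero(self):
        res = self._result([], (8, 5, 10))
        assert not significant_channel_fraction(res).any()

    def test_full_channel_cluster_is_one(self):
        shape = (4, 3, 6)
        bins = np.ravel_multi_index(
            (np.arange(4), np.full(4, 1), np.full(4, 2)), shape)
        res = self._result([Cluster(bins=bins, mass=50.0, p_value=0.001,
                                    sign=1)], shape)
        frac = significant_channel_fraction(res)
        assert frac[1, 2] == 1.0

    def test_partial_coverage_counts(self):
        shape = (8, 3, 6)
        bins = np.ravel_multi_index((np.array([0, 1]), np.array([0, 0]),
                                     np.array([3, 3])), shape)
        res = self._result([Cluster(bins=bins, mass=9.0, p_value=0.005,
                                    sign=1)], shape)
        assert significant_channel_fraction(res)[0, 3] == pytest.approx(0.25)

    def test_nonsignificant_clusters_ignored(self):
        shape = (4, 3, 6)
        bins = np.array([0])
        res = self._result([Cluster(bins=bins, mass=3.0, p_value=0.5,
                                    sign=1)], shape)
        assert not significant_channel_fraction(res).any()


class TestBandScore:
    def _tfr_const(self, value, night, n_stim):
        freqs = np.arange(0.5, 20.5, 0.5)
        times = np.linspace(-1.5, 2.5, 81)
        power = np.full((3, len(freqs), len(times)), float(value))
        tfr = make_tfr(power, freqs, times, night, n_stim)
        tfr.units = "dB"
        return tfr

    def _band(self):
        return BandSpec("delta", 1.0, 4.0, 0.75, 1.5, ["c0", "c1"])

    def test_identical_nights_zero(self):
        tfrs = {n: self._tfr_const(2.0, n, 100) for n in ("BL", "E1", "E2", "E3")}
        assert band_response_score(tfrs, self._band()).value == 0.0

    def test_constant_differences_any_weights(self):
        tfrs = {"BL": self._tfr_const(0.0, "BL", 500),
                "E1": self._tfr_const(1.0, "E1", 17),
                "E2": self._tfr_const(1.0, "E2", 203),
                "E3": self._tfr_const(1.0, "E3", 88)}
        assert band_response_score(tfrs, self._band()).value == pytest.approx(1.0)

    def test_hand_weighted_mean(self):
        tfrs = {"BL": self._tfr_const(0.0, "BL", 500),
                "E1": self._tfr_const(0.0, "E1", 50),
                "E2": self._tfr_const(3.0, "E2", 100),
                "E3": self._tfr_const(3.0, "E3", 150)}
        score = band_response_score(tfrs, self._band())
        assert score.value == pytest.approx((0 * 50 + 3 * 100 + 3 * 150) / 300)

    def test_empty_band_selection_rejected(self):
        tfrs = {n: self._tfr_const(1.0, n, 100) for n in ("BL", "E1", "E2", "E3")}
        band = BandSpec("none", 1.0, 4.0, 0.75, 1.5, ["nope"])
        with pytest.raises(ValueError):
            band_response_score(tfrs, band)

    def test_standard_band_definitions(self):
        names, pos = spiral_layout(64)
        bands = standard_bands(names, pos)
        assert (bands["sw"].f_lo, bands["sw"].f_hi) == (0.75, 1.5)
        assert (bands["beta"].f_lo, bands["beta"].f_hi) == (16.0, 20.0)
        assert len(bands["spindle"].channel_set) == 13
        assert "Cz" in bands["spindle"].channel_set
        assert len(bands["delta"].channel_set) == 17
        assert "Fz" in bands["delta"].channel_set


class TestSummedActivity:
    def _grids(self):
        freqs = np.linspace(1.0, 15.0, 5)
        times = np.linspace(0.1, 2.4, 8)
        return freqs, times

    def test_equal_maps_zero(self):
        freqs, times = self._grids()
        p = np.ones((2, 5, 8))
        sa = summed_activity(make_tfr(p, freqs, times),
                             make_tfr(p.copy(), freqs, times, "BL"),
                             np.ones_like(p, bool), "E1")
        assert sa.value == 0.0

    def test_worked_exclusion_example(self):
        # masked |dB| values {1,1,1,1,12}: mean 3.2, SD 4.92, cutoff 10.58
        # -> the 12-dB bin is excluded, sum = 4
        freqs, times = np.array([1.0]), np.linspace(0.2, 2.2, 5)
        bl = np.ones((1, 1, 5))
        db = np.array([1.0, 1.0, 1.0, 1.0, 12.0])
        exp = 10.0 ** (db / 10.0)[None, None, :]
        sa = summed_activity(make_tfr(exp, freqs, times),
                             make_tfr(bl, freqs, times, "BL"),
                             np.ones((1, 1, 5), bool), "E1")
        assert sa.value == pytest.approx(4.0)
        assert sa.n_bins_used == 4 and sa.n_bins_excluded == 1

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            freqs = np.linspace(0.5, 18.0, 6)
            times = np.linspace(-0.5, 2.5, 9)
            exp = np.exp(rng.normal(0, 1, (3, 6, 9)))
            bl = np.exp(rng.normal(0, 1, (3, 6, 9)))
            mask = rng.random((3, 6, 9)) < 0.4
            sa = summed_activity(make_tfr(exp, freqs, times),
                                 make_tfr(bl, freqs, times, "BL"), mask, "E2")
            # independent brute force: loop over bins
            vals = []
            for c in range(3):
                for i, f in enumerate(freqs):
                    for j, t in enumerate(times):
                        if mask[c, i, j] and 0 <= f <= 16 and 0 <= t <= 2.5:
                            vals.append(abs(10 * np.log10(exp[c, i, j]
                                                          / bl[c, i, j])))
            vals = np.array(vals)
            if len(vals) == 0:
                assert sa.value == 0.0
                continue
            if len(vals) > 1:
                keep = vals <= vals.mean() + 1.5 * vals.std(ddof=1)
            else:
                keep = np.ones(1, bool)
            assert sa.value == pytest.approx(vals[keep].sum(), abs=1e-12)
            assert sa.n_bins_used == int(keep.sum())

    def test_empty_mask_warns_zero(self):
        freqs, times = self._grids()
        p = np.ones((2, 5, 8))
        with pytest.warns(UserWarning):
            sa = summed_activity(make_tfr(p, freqs, times),
                                 make_tfr(p, freqs, times, "BL"),
                                 np.zeros_like(p, bool), "E1")
        assert sa.value == 0.0


class TestNightTrend:
    def _table(self, values):
        rows = []
        for (pid, group, night), v in values:
            rows.append({"participant_id": pid, "group": group,
                         "night": night, "value": v})
        return pd.DataFrame(rows)

    def test_flat_values_zero_slope(self):
        vals = [((f"{g}{i}", g, n), 5.0)
                for g in ("HC", "CI") for i in range(4)
                for n in ("E1", "E2", "E3")]
        res = night_trend_and_group_tests(self._table(vals))
        for fit in res["trends"].values():
            assert fit.coefficients["night"] == pytest.approx(0.0, abs=1e-10)

    def test_linear_values_recovered(self):
        rng = np.random.default_rng(8)
        vals = [((f"HC{i}", "HC", n), 2.0 * k + rng.normal(0, 1e-6))
                for i in range(5) for k, n in enumerate(("E1", "E2", "E3"), 1)]
        vals += [((f"CI{i}", "CI", n), 1.0) for i in range(5)
                 for n in ("E1", "E2", "E3")]
        res = night_trend_and_group_tests(self._table(vals))
        assert res["trends"]["HC"].coefficients["night"] == pytest.approx(2.0,
                                                                          abs=1e-4)
        assert res["trends"]["HC"].p < 1e-6

    def test_single_participant_group_rejected(self):
        vals = [(("HC1", "HC", n), 1.0) for n in ("E1", "E2", "E3")]
        vals += [((f"CI{i}", "CI", n), 1.0) for i in range(3)
                 for n in ("E1", "E2", "E3")]
        with pytest.raises(ValueError):
            night_trend_and_group_tests(self._table(vals))
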