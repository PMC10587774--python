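import numpy as np
import pandas as pd
import pytest

from hfoprime import unitfiring
from hfoprime.config import AnalysisConfig
from hfoprime.io import UnitSpikeTrain

ACFG = AnalysisConfig()


def _events(rows):
    return pd.DataFrame(rows, columns=["patient_id", "channel", "class",
                                       "onset_s", "offset_s", "duration_ms",
                                       "log10_power"])


class TestSmoothing:
    def test_single_spike_peak_is_gaussian_peak(self):
        raster = np.zeros(2000, np.uint8)
        raster[1000] = 1
        series = unitfiring.smooth_rate(raster, ACFG)
        assert series.max() == pytest.approx(1.0 / (0.1 * np.sqrt(2 * np.pi)),
                                             rel=1e-3)
        assert np.argmax(series) == 1000

    def test_spike_count_conserved_exactly(self):
        rng = np.random.default_rng(0)
        raster = (rng.uniform(size=2000) < 0.02).astype(np.uint8)
        full = unitfiring.smooth_rate(raster, ACFG, mode="full")
        assert full.sum() * 1e-3 == pytest.approx(raster.sum(), rel=1e-12)

    def test_empty_raster_all_zero(self):
        assert not unitfiring.smooth_rate(np.zeros(2000), ACFG).any()

    def test_homogeneous_train_mean_rate(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(40):
            raster = (rng.uniform(size=2000) < 0.01).astype(np.uint8)
            series = unitfiring.downsample_rate(
                unitfiring.smooth_rate(raster, ACFG), ACFG)
            vals.append(series[20:60].mean())
        assert np.mean(vals) == pytest.approx(10.0, rel=0.1)


class TestTrialRates:
    def test_constant_series(self):
        series = np.full(80, 5.0)
        assert unitfiring.trial_rates(series, 60.0, ACFG) == (5.0, 5.0, 0.0)

    def test_short_event_uses_only_in_window_samples(self):
        """A 30 ms event sees exactly the 40 Hz samples at 0 and +25 ms."""
        series = np.zeros(80)
        series[40] = 2.0    # t = 0 ms
        series[41] = 3.0    # t = +25 ms
        series[42] = 9.0    # t = +50 ms, outside a 30 ms event
        bl, pk, diff = unitfiring.trial_rates(series, 30.0, ACFG)
        assert pk == 3.0
        assert diff == pytest.approx(3.0 - series[10:40].mean())

    def test_overlong_event_clamped(self):
        series = np.zeros(80)
        series[-1] = 7.0
        _, pk, _ = unitfiring.trial_rates(series, 5000.0, ACFG)
        assert pk == 7.0


class TestBuildTrials:
    def _units(self):
        rng = np.random.default_rng(2)
        return [UnitSpikeTrain(f"u{i}", "P", "c00", "single",
                               np.sort(rng.uniform(0, 60e3, 300)))
                for i in range(2)]

    def test_one_trial_per_event_unit_pair(self):
        ev = _events([("P", "c00", "fRonO", 10.0 + 5 * i, 10.05 + 5 * i,
                       50.0, 1.0) for i in range(3)])
        trials = unitfiring.build_trials(ev, self._units(), ACFG)
        assert len(trials) == 6
        assert all(t.raster.size == 2000 for t in trials)
        assert all(t.rate_series.size == 80 for t in trials)

    def test_unit_on_other_bundle_excluded(self):
        ev = _events([("P", "c01", "fRonO", 10.0, 10.05, 50.0, 1.0)])
        assert unitfiring.build_trials(ev, self._units(), ACFG) == []

    def test_event_near_record_start_dropped(self):
        ev = _events([("P", "c00", "fRonO", 0.4, 0.45, 50.0, 1.0)])
        assert unitfiring.build_trials(ev, self._units(), ACFG) == []

    def test_rates_identity(self):
        ev = _events([("P", "c00", "RonO", 20.0, 20.06, 60.0, 1.0)])
        for t in unitfiring.build_trials(ev, self._units(), ACFG):
            assert t.hfodiff_fr == pytest.approx(t.hfo_fr - t.bl_fr)
            assert t.bl_fr >= 0 and t.hfo_fr >= 0

    def test_null_train_peak_bias_positive(self):
        """For homogeneous trains the max-over-window statistic sits above
        the baseline mean on average (known smoothing/max bias)."""
        rng = np.random.default_rng(3)
        units = [UnitSpikeTrain("u", "P", "c00", "single",
                                np.sort(rng.uniform(0, 600e3, 3000)))]
        ev = _events([("P", "c00", "fRonO", 5.0 + i, 5.06 + i, 60.0, 1.0)
                      for i in range(300)])
        trials = unitfiring.build_trials(ev, units, ACFG)
        assert np.mean([t.hfodiff_fr for t in trials]) > 0


class TestInclusion:
    def test_holm_step_down_arithmetic(self):
        reject = unitfiring.holm_bonferroni(np.array([1e-4, 0.5]), 0.001)
        assert list(reject) == [True, False]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_step_down(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 12)
        p = 10 ** rng.uniform(-6, 0, m)
        alpha = 10 ** rng.uniform(-4, -1)
        fast = unitfiring.holm_bonferroni(p, alpha)
        order = np.argsort(p, kind="mergesort")
        slow = np.zeros(m, bool)
        for rank, i in enumerate(order):
            if p[i] <= alpha / (m - rank):
                slow[i] = True
            else:
                break
        assert np.array_equal(fast, slow)

    def _trials_for_unit(self, uid, gain, n, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for _ in range(n):
            bl = max(rng.normal(5, 1), 0)
            pk = max(rng.normal(5 * gain, 1.5), 0)
            rows.append({"unit_id": uid, "class": "fRonO", "bl_fr": bl,
                         "hfo_fr": pk})
        return pd.DataFrame(rows)

    def test_responsive_unit_included_flat_unit_excluded(self):
        df = pd.concat([self._trials_for_unit("u_resp", 3.0, 200, 0),
                        self._trials_for_unit("u_flat", 1.0, 200, 1)])
        out = unitfiring.unit_inclusion_test(df, "fRonO", alpha=0.001)
        out = out.set_index("unit_id")
        assert bool(out.loc["u_resp", "included"])
        assert not bool(out.loc["u_flat", "included"])

    def test_zero_variance_differences_excluded(self):
        df = pd.DataFrame({"unit_id": "u0", "class": "fRonO",
                           "bl_fr": [5.0] * 10, "hfo_fr": [5.0] * 10})
        out = unitfiring.unit_inclusion_test(df, "fRonO")
        assert out.p.iloc[0] == 1.0 and not out.included.iloc[0]


class TestSummaries:
    def _trial(self, series):
        return unitfiring.EventUnitTrial(
            unit_id="u", contact="c", patient_id="P", klass="fRonO",
            event_onset_s=1.0, duration_ms=50.0, log10_power=1.0, prespike=0,
            followed_fRonO=0, followed_RonO=0, unit_type="single",
            raster=np.zeros(2000, np.uint8), rate_series=np.asarray(series),
            bl_fr=0.0, hfo_fr=0.0, hfodiff_fr=0.0)

    def test_identical_trials_zero_ci(self):
        tr = [self._trial(np.full(80, 4.0)), self._trial(np.full(80, 4.0))]
        mean, lo, hi = unitfiring.grand_average(tr)
        assert np.allclose(mean, 4.0) and np.allclose(lo, hi)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            unitfiring.grand_average([])

    def test_peak_histogram_and_tie_rule(self):
        s = np.zeros(80)
        s[44] = 2.0   # +100 ms
        tr = [self._trial(s), self._trial(np.zeros(80))]
        bins = np.array([-1000.0, 0.0, 200.0, 1000.0])
        hist = unitfiring.peak_time_histogram(tr, bins, ACFG)
        # flat trial argmax resolves to the earliest sample (-1000 ms)
        assert list(hist) == [1, 1, 0]

    def test_effect_size_reference_points(self):
        a = np.array([1.0, 2.0, 3.0])
        assert unitfiring.effect_size(a, a) == 0.0
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 2000)
        y = rng.normal(1, 1, 2000)
        d = unitfiring.effect_size(y, x)
        na, nb = y.size, x.size
        sp = np.sqrt(((na - 1) * y.var(ddof=1) + (nb - 1) * x.var(ddof=1))
                     / (na + nb - 2))
        assert d == pytest.approx((y.mean() - x.mean()) / sp)
        with pytest.raises(ValueError):
            unitfiring.effect_size(np.array([1.0]), x)

    def test_power_by_latency_half_open_bins(self):
        ev = pd.DataFrame({
            "class": ["fRonO"] * 3, "prespike": [1, 1, 1],
            "latency_to_spike_ms": [5.0, 10.0, 150.0],
            "log10_power": [3.0, 1.0, 2.0]})
        out = unitfiring.power_by_latency(ev, np.array([0.0, 10.0, 300.0]))
        assert out.mean_log10_power.iloc[0] == pytest.approx(3.0)
        assert out.mean_log10_power.iloc[1] == pytest.approx(1.5)
        assert out.n.tolist() == [1, 2]
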