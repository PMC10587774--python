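import numpy as np
import pytest
from scipy import ndimage

from hfoprime import detect, synth, tfclassify
from hfoprime.config import AnalysisConfig, SynthConfig
from hfoprime.io import IEEGRecording


@pytest.fixture(scope="module")
def acfg():
    return AnalysisConfig()


def _gauss_blob(shape, center, sigma, amp=1.0):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return amp * np.exp(-(((yy - center[0]) / sigma[0]) ** 2
                          + ((xx - center[1]) / sigma[1]) ** 2) / 2)


def _map_from(power, fs=2000.0):
    nf, nt = power.shape
    return tfclassify.TFMap(power=power,
                            freqs=np.geomspace(60, 650, nf),
                            times=np.arange(nt) / fs)


class TestWavelet:
    def test_sinusoid_peak_frequency_on_grid(self, acfg):
        fs = 2000.0
        t = np.arange(int(fs)) / fs
        tf = tfclassify.wavelet_tfr(np.sin(2 * np.pi * 150.0 * t), fs, acfg)
        prof = tf.power.mean(axis=1)
        fpk = tf.freqs[np.argmax(prof)]
        step = tf.freqs[1] / tf.freqs[0]
        assert fpk / step <= 150.0 <= fpk * step

    def test_deterministic_and_quadratic_in_amplitude(self, acfg):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        a = tfclassify.wavelet_tfr(x, 2000.0, acfg)
        b = tfclassify.wavelet_tfr(x, 2000.0, acfg)
        c = tfclassify.wavelet_tfr(2 * x, 2000.0, acfg)
        assert np.array_equal(a.power, b.power)
        assert np.allclose(c.power, 4 * a.power)

    def test_short_segment_rejected(self, acfg):
        with pytest.raises(ValueError):
            tfclassify.wavelet_tfr(np.zeros(100), 2000.0, acfg)


class TestThreshold:
    def test_formula_on_known_extrema(self):
        power = np.full((4, 300), 1.0)
        power[2, 150] = 5.0
        assert tfclassify.contour_threshold(_map_from(power)) == \
            pytest.approx(1.8)

    def test_constant_map_gives_no_contours(self, acfg):
        tf = _map_from(np.full((8, 300), 2.0))
        assert tfclassify.contour_threshold(tf) == pytest.approx(2.0)
        cs = tfclassify.extract_contours(tf, cfg=acfg)
        assert cs.contours == []
        assert tfclassify.classify_event(cs, acfg) is None

    def test_threshold_scales_with_map(self):
        power = np.full((4, 300), 1.0)
        power[2, 150] = 5.0
        t1 = tfclassify.contour_threshold(_map_from(power))
        t2 = tfclassify.contour_threshold(_map_from(10 * power))
        assert t2 == pytest.approx(10 * t1)


class TestContours:
    def test_interior_blob_forms_one_closed_group(self, acfg):
        power = _gauss_blob((64, 400), (32, 200), (5, 30)) + 0.01
        cs = tfclassify.extract_contours(_map_from(power), cfg=acfg)
        closed = [c for c in cs.contours if c.closed]
        assert len(closed) >= 1
        assert len(cs.groups) == 1
        for c in cs.contours:
            assert c.closed == bool(np.allclose(c.vertices[0], c.vertices[-1]))

    def test_edge_truncated_blob_has_open_outermost(self, acfg):
        power = _gauss_blob((64, 400), (32, 395), (5, 30)) + 0.01
        cs = tfclassify.extract_contours(_map_from(power), cfg=acfg)
        assert len(cs.open_idx) >= 1
        lowest = min(cs.contours, key=lambda c: c.level)
        assert not lowest.closed

    @pytest.mark.parametrize("seed", range(6))
    def test_grouping_matches_connected_components(self, acfg, seed):
        """CLC groups coincide with connected components of the
        suprathreshold mask (independent pixel-labelling oracle)."""
        rng = np.random.default_rng(seed)
        power = np.full((64, 300), 0.01)
        nb = rng.integers(1, 4)
        for _ in range(nb):
            c = (rng.integers(12, 52), rng.integers(40, 260))
            power += _gauss_blob((64, 300), c, (rng.uniform(3, 6),
                                                rng.uniform(10, 25)),
                                 amp=rng.uniform(0.5, 2.0))
        tf = _map_from(power)
        cs = tfclassify.extract_contours(tf, cfg=acfg)
        thr = tfclassify.contour_threshold(tf)
        labels, _ = ndimage.label(power >= thr)
        from matplotlib.path import Path as MplPath
        yy, xx = np.mgrid[:labels.shape[0], :labels.shape[1]]
        pts = np.column_stack([yy.ravel(), xx.ravel()])
        comp_of_group = []
        for g in cs.groups:
            comps = set()
            for i in g:
                inside = MplPath(cs.contours[i].vertices).contains_points(pts)
                lab = labels.ravel()[inside]
                lab = lab[lab > 0]
                if lab.size:
                    comps.add(int(np.bincount(lab).argmax()))
            assert len(comps) == 1, "a CLC group must sit in one component"
            comp_of_group.append(comps.pop())
        border = set(labels[0, :]) | set(labels[-1, :]) \
            | set(labels[:, 0]) | set(labels[:, -1])
        interior = [c for c in comp_of_group if c not in border]
        assert len(interior) == len(set(interior)), \
            "distinct CLC groups must occupy distinct interior components"


def _render_window(klass, freq, seed, snr_db=15.0, latency_ms=None):
    """One-event recording plus a stage-1-style candidate around it."""
    cfg = SynthConfig(n_contacts_per_patient=1, recording_minutes=1.0,
                      snr_db=snr_db, seed=seed, rate_RonO=0, rate_fRonO=0,
                      rate_spike=0, p_prime=0)
    truth = synth.gen_events(cfg, np.random.default_rng(seed))
    row = {"patient_id": "P01", "channel": "c00", "class": klass,
           "onset_s": 30.0, "offset_s": 30.06, "freq_hz": freq,
           "amp_rel": 1.0, "power": 10.0, "is_primer": False,
           "latency_ms": np.nan, "hfo_onset_s": np.nan, "hfo_offset_s": np.nan}
    if klass in ("fRonS", "RonS"):
        row["hfo_onset_s"] = 30.01
        row["hfo_offset_s"] = 30.05
    if klass in ("fRonO", "RonO"):
        row["offset_s"] = 30.0 + max(0.02, min(0.1, 10.0 / freq))
    import pandas as pd
    truth.events = pd.DataFrame([row], columns=synth.TRUTH_COLUMNS)
    rng = np.random.default_rng(seed + 1)
    x, _ = synth.render_channel(truth, "c00", cfg, rng)
    rec = IEEGRecording(samples=x[None, :], fs=cfg.fs_ieeg,
                        channel_labels=["c00"])
    return rec


class TestClassifyRules:
    @pytest.mark.parametrize("klass,freq,expect", [
        ("fRonO", 300.0, "fRonO"),
        ("RonO", 120.0, "RonO"),
        ("fRonS", 300.0, "fRonS"),
        ("RonS", 120.0, "RonS"),
    ])
    def test_single_event_windows(self, acfg, klass, freq, expect):
        hits = 0
        for seed in range(5):
            rec = _render_window(klass, freq, seed=100 + seed)
            band = "fr" if freq >= 200 else "ripple"
            cands = detect.band_envelope_detect(rec, band, acfg)
            cands += detect.band_envelope_detect(rec, "spk", acfg)
            events = tfclassify.classify_all(rec, cands, acfg)
            hits += any(e.klass == expect for e in events)
        assert hits >= 4

    def test_sharp_spike_without_hfo(self, acfg):
        hits = 0
        for seed in range(10):
            rec = _render_window("SharpSpike", np.nan, seed=200 + seed)
            cands = detect.band_envelope_detect(rec, "spk", acfg)
            cands += detect.band_envelope_detect(rec, "ripple", acfg)
            cands += detect.band_envelope_detect(rec, "fr", acfg)
            events = [e for e in tfclassify.classify_all(rec, cands, acfg)
                      if e.onset_s < 30.2 and e.offset_s > 29.9]
            hits += any(e.klass == "SharpSpike" for e in events) and \
                not any(e.klass in ("fRonS", "RonS") for e in events)
        assert hits >= 9

    def test_zero_candidates_gives_empty_list(self, acfg, small_recording):
        _, rec, _ = small_recording
        assert tfclassify.classify_all(rec, [], acfg) == []

    def test_power_monotone_in_amplitude(self, acfg):
        rec_lo = _render_window("fRonO", 300.0, seed=301, snr_db=13.0)
        rec_hi = _render_window("fRonO", 300.0, seed=301, snr_db=19.0)
        out = []
        for rec in (rec_lo, rec_hi):
            cands = detect.band_envelope_detect(rec, "fr", acfg)
            evs = [e for e in tfclassify.classify_all(rec, cands, acfg)
                   if e.klass == "fRonO"]
            assert evs
            out.append(max(e.log10_power for e in evs))
        assert out[1] > out[0]

    def test_band_boundary_exactly_at_200(self, acfg):
        """Ripple/FR split is [80,200) vs [200,600] on the CLC mean
        frequency."""
        power = np.full((64, 400), 0.01)
        freqs = np.geomspace(60, 650, 64)
        for target, expect in ((185.0, "RonO"), (215.0, "fRonO")):
            row = int(np.argmin(np.abs(freqs - target)))
            p = power + _gauss_blob((64, 400), (row, 200), (2.5, 25))
            cs = tfclassify.extract_contours(_map_from(p), cfg=acfg)
            res = tfclassify.classify_event(cs, acfg)
            assert res is not None and res.klass == expect
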