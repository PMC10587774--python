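"""Synthetic iEEG cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* background = pink (1/f) noise plus a high-amplitude 0.5-2 Hz slow wave,
  as recorded during non-REM sleep;
* ripples (80-200 Hz) and fast ripples (200-600 Hz) as Gaussian-windowed
  sinusoids riding on the background (``RonO``/``fRonO``) or on epileptiform
  spikes (``RonS``/``fRonS``);
* epileptiform spikes as biphasic sharp transients (difference of Gaussians),
  with or without a superimposed HFO;
* a tunable excess probability ``p_prime`` that a spike is preceded by a
  fRonO at a latency uniform on (0, 300] ms, with those priming fRonO
  amplified by ``power_gain_prespike`` and optionally concentrated on SOZ
  contacts;
* inhomogeneous-Poisson unit trains whose in-event rate scales with
  log10(event power).

Everything is driven by one :class:`numpy.random.Generator`, so a fixed seed
reproduces the cohort bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .config import AnalysisConfig, SynthConfig, save_config
from .io import IEEGRecording, UnitSpikeTrain, write_edf

EDGE_MARGIN_S = 1.0        # keep events clear of record edges
HFO_ON_SPIKE_DELAY_MS = (5.0, 20.0)   # HFO onset after spike onset for RonS/fRonS
HFO_CYCLES = (8.0, 16.0)   # oscillation cycles per burst
HFO_DUR_MS = (20.0, 100.0)             # duration clamp
SPIKE_DUR_MS = (50.0, 100.0)
# centre-frequency draws keep bursts' spectral mass inside the nominal band
FR_FREQ_HZ = (250.0, 500.0)
RIPPLE_FREQ_HZ = (80.0, 200.0)


def _hfo_duration_ms(freq_hz: float, rng: np.random.Generator) -> float:
    """Burst duration from a cycle count, so every HFO holds real oscillations."""
    n_cyc = rng.uniform(*HFO_CYCLES)
    return float(np.clip(n_cyc / freq_hz * 1e3, *HFO_DUR_MS))

TRUTH_COLUMNS = ["patient_id", "channel", "class", "onset_s", "offset_s",
                 "freq_hz", "amp_rel", "power", "is_primer", "latency_ms",
                 "hfo_onset_s", "hfo_offset_s"]


@dataclass
class GroundTruth:
    """Injected events, unit parameters and contact metadata for one patient."""

    patient_id: str
    duration_s: float
    channels: list[str]
    events: pd.DataFrame                    # TRUTH_COLUMNS
    electrodes: pd.DataFrame                # io.ElectrodeTable schema
    units: pd.DataFrame = field(default_factory=pd.DataFrame)
    epochs: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def spikes(self, channel: str) -> np.ndarray:
        ev = self.events
        m = (ev.channel == channel) & ev["class"].isin(("fRonS", "RonS", "SharpSpike"))
        return np.sort(ev.loc[m, "onset_s"].to_numpy())


def _soz_flags(n: int, frac: float, rng: np.random.Generator) -> np.ndarray:
    k = int(round(frac * n))
    flags = np.zeros(n, int)
    flags[rng.choice(n, size=k, replace=False)] = 1
    return flags


def gen_events(cfg: SynthConfig, rng: np.random.Generator | None = None,
               patient_id: str = "P01") -> GroundTruth:
    """Draw the event skeleton (no waveforms) for one synthetic patient.

    Per channel: independent homogeneous-Poisson streams of fRonO, RonO and
    epileptiform spikes (subdivided fRonS/RonS/sharp); with probability
    ``p_prime`` (rescaled by ``soz_priming_enrichment`` for SOZ contacts while
    preserving the cohort mean) an extra fRonO is planted before a spike at a
    latency uniform on (0, 300] ms.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    T = cfg.recording_minutes * 60.0
    lo, hi = EDGE_MARGIN_S, T - EDGE_MARGIN_S
    if hi <= lo:
        raise ValueError("recording too short for event placement")
    nch = cfg.n_contacts_per_patient
    channels = [f"c{j:02d}" for j in range(nch)]
    soz = _soz_flags(nch, cfg.soz_fraction, rng)

    fs_ = cfg.soz_fraction

    def _split(mean: float, enrich: float) -> tuple[float, float]:
        # SOZ value enrich-fold the non-SOZ value, cohort mean preserved
        denom = fs_ * enrich + (1.0 - fs_)
        if denom <= 0:
            return 0.0, 0.0
        return mean * enrich / denom, mean / denom

    p_soz, p_non = (min(1.0, v) for v in _split(cfg.p_prime,
                                                cfg.soz_priming_enrichment))
    spike_soz, spike_non = _split(cfg.rate_spike, cfg.soz_spike_enrichment)
    fro_soz, fro_non = _split(cfg.rate_fRonO, cfg.soz_fro_enrichment)

    # per-channel rates; under focal topology the non-SOZ share concentrates
    # on a compact remote secondary cluster, the rest of the tissue is quiet
    spike_rate = np.where(soz == 1, spike_soz, spike_non)
    fro_rate = np.where(soz == 1, fro_soz, fro_non)
    secondary = np.zeros(nch, bool)
    if cfg.focal_topology:
        non_idx = np.flatnonzero(soz == 0)
        k2 = max(2, int(round(cfg.secondary_focus_fraction * non_idx.size)))
        sec_idx = rng.choice(non_idx, size=min(k2, non_idx.size), replace=False)
        secondary[sec_idx] = True
        boost = non_idx.size / secondary.sum()
        spike_rate = np.where(soz == 1, spike_soz,
                              np.where(secondary, spike_non * boost, 0.0))
        fro_rate = np.where(soz == 1, fro_soz,
                            np.where(secondary, fro_non * boost, 0.0))

    rows: list[dict] = []
    for j, ch in enumerate(channels):
        is_soz = bool(soz[j])

        def _uniform_onsets(rate_per_min: float) -> np.ndarray:
            n = rng.poisson(rate_per_min * cfg.recording_minutes)
            return np.sort(rng.uniform(lo, hi, size=n))

        def _add(klass: str, onset: float, dur_ms: float, freq: float | None,
                 amp_rel: float = 1.0, is_primer: bool = False,
                 latency_ms: float = np.nan, hfo_onset: float = np.nan,
                 hfo_dur_ms: float = np.nan) -> None:
            log10p = rng.normal(1.0, 0.3) + 2.0 * np.log10(max(amp_rel, 1e-12))
            rows.append(dict(
                patient_id=patient_id, channel=ch, **{"class": klass},
                onset_s=onset, offset_s=onset + dur_ms * 1e-3,
                freq_hz=np.nan if freq is None else freq, amp_rel=amp_rel,
                power=10.0 ** log10p, is_primer=is_primer, latency_ms=latency_ms,
                hfo_onset_s=hfo_onset,
                hfo_offset_s=(hfo_onset + hfo_dur_ms * 1e-3
                              if np.isfinite(hfo_onset) else np.nan)))

        # spikes first so priming fRonO can reference them
        spike_onsets = _uniform_onsets(spike_rate[j])
        for t0 in spike_onsets:
            u = rng.uniform()
            sdur = rng.uniform(*SPIKE_DUR_MS)
            if u < cfg.p_fRonS or u < cfg.p_fRonS + cfg.p_RonS:
                klass = "fRonS" if u < cfg.p_fRonS else "RonS"
                f = (rng.uniform(*FR_FREQ_HZ) if klass == "fRonS"
                     else rng.uniform(*RIPPLE_FREQ_HZ))
                delay = rng.uniform(*HFO_ON_SPIKE_DELAY_MS)
                _add(klass, t0, sdur, f, hfo_onset=t0 + delay * 1e-3,
                     hfo_dur_ms=_hfo_duration_ms(f, rng))
            else:
                _add("SharpSpike", t0, sdur, None)

        # priming fRonO inserted before a subset of spikes
        p_pr = p_soz if is_soz else p_non
        for t0 in spike_onsets:
            if rng.uniform() < p_pr:
                if cfg.prime_latency_lock_ms > 0:
                    lat = rng.uniform(0.0, cfg.prime_latency_lock_ms)
                else:
                    lat = rng.uniform(0.0, 300.0)
                onset = t0 - lat * 1e-3
                if onset <= lo:
                    continue
                f = rng.uniform(*FR_FREQ_HZ)
                _add("fRonO", onset, _hfo_duration_ms(f, rng), f,
                     amp_rel=cfg.power_gain_prespike,
                     is_primer=True, latency_ms=lat)

        # background HFOs on oscillations
        for t0 in _uniform_onsets(fro_rate[j]):
            if (not is_soz and cfg.nonsoz_suppression > 0 and spike_onsets.size
                    and np.any((spike_onsets - t0 > 0)
                               & (spike_onsets - t0 < 0.3))
                    and rng.uniform() < cfg.nonsoz_suppression):
                continue
            f = rng.uniform(*FR_FREQ_HZ)
            _add("fRonO", t0, _hfo_duration_ms(f, rng), f)
        for t0 in _uniform_onsets(cfg.rate_RonO):
            f = rng.uniform(*RIPPLE_FREQ_HZ)
            _add("RonO", t0, _hfo_duration_ms(f, rng), f)

    events = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    # strictly increasing onsets per channel: nudge collisions by 1 ms
    events = events.sort_values(["channel", "onset_s"], kind="mergesort")
    for _, idx in events.groupby("channel").groups.items():
        on = events.loc[idx, "onset_s"].to_numpy().copy()
        for i in range(1, len(on)):
            if on[i] <= on[i - 1]:
                on[i] = on[i - 1] + 1e-3
        events.loc[idx, "onset_s"] = on
    events = events.reset_index(drop=True)

    xyz = rng.uniform(-50.0, 50.0, size=(nch, 3))
    # SOZ contacts drawn toward a common focus so rate-distance metrics see
    # a spatially compact generator region; the secondary cluster mirrors it
    focus = rng.uniform(-25.0, 25.0, size=3)
    xyz[soz == 1] = focus + rng.normal(0.0, 7.0, size=(int(soz.sum()), 3))
    if secondary.any():
        xyz[secondary] = -focus + rng.normal(0.0, 7.0,
                                             size=(int(secondary.sum()), 3))
    # resection covers a configurable share of the SOZ, then fills up with
    # neighbouring non-SOZ contacts (emulates incomplete resections)
    resected = np.zeros(nch, int)
    soz_idx = np.flatnonzero(soz == 1)
    k_cov = int(round(cfg.resection_coverage * soz_idx.size))
    if k_cov > 0:
        resected[rng.choice(soz_idx, size=k_cov, replace=False)] = 1
    extra = int(round(cfg.resected_fraction * nch)) - int(resected.sum())
    if extra > 0:
        pool = np.flatnonzero(resected == 0)
        resected[rng.choice(pool, size=min(extra, pool.size), replace=False)] = 1
    electrodes = pd.DataFrame({
        "patient_id": patient_id, "channel": channels,
        "x_mm": xyz[:, 0], "y_mm": xyz[:, 1], "z_mm": xyz[:, 2],
        "soz": soz, "resected": resected})

    epochs = {ch: [(0.0, T)] for ch in channels}
    return GroundTruth(patient_id=patient_id, duration_s=T, channels=channels,
                       events=events, electrodes=electrodes, epochs=epochs)


def truth_to_events(truth: GroundTruth) -> pd.DataFrame:
    """Ground-truth table in the classified-events schema (oracle labels).

    Lets the coincidence / firing / localization stages run on perfect labels,
    bypassing waveform detection.
    """
    ev = truth.events
    out = pd.DataFrame({
        "patient_id": ev.patient_id, "channel": ev.channel,
        "class": ev["class"], "onset_s": ev.onset_s, "offset_s": ev.offset_s,
        "peak_freq_hz": ev.freq_hz, "log10_power": np.log10(ev.power),
        "duration_ms": (ev.offset_s - ev.onset_s) * 1e3,
        "prespike": 0, "latency_to_spike_ms": np.nan,
        "followed_fRonO": 0, "followed_RonO": 0})
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# waveform rendering
# ---------------------------------------------------------------------------

def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via FFT spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _band_sd(x: np.ndarray, fs: float, lo: float, hi: float) -> float:
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return float(signal.sosfiltfilt(sos, x).std())


def render_channel(truth: GroundTruth, channel: str, cfg: SynthConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, dict]:
    """Render one channel's waveform; returns (samples µV, amplitude scales)."""
    fs = cfg.fs_ieeg
    n = int(round(truth.duration_s * fs))
    t = np.arange(n) / fs

    bg_sd = 25.0   # µV, broadband background
    x = bg_sd * _pink_noise(n, rng)
    sw_f = rng.uniform(0.5, 2.0)
    x += 50.0 * np.sin(2 * np.pi * sw_f * t + rng.uniform(0, 2 * np.pi))

    # reference amplitude = median analytic envelope of the band-filtered
    # background (~1.18x the band sd for Gaussian noise), so snr_db is honored
    # on the scale the envelope detector actually sees
    scales = {
        "ripple": 1.18 * _band_sd(x, fs, 80.0, 200.0),
        "fr": 1.18 * _band_sd(x, fs, 200.0, min(600.0, 0.49 * fs)),
        "broad": float(np.std(x)),
    }
    a_hfo = 10.0 ** (cfg.snr_db / 20.0)
    a_spk = 10.0 ** (cfg.spike_snr_db / 20.0) * scales["broad"]

    ev = truth.events[truth.events.channel == channel]
    for r in ev.itertuples():
        klass = r[3]
        if klass in ("fRonO", "RonO", "fRonS", "RonS"):
            if klass in ("fRonO", "RonO"):
                h_on, h_off = r.onset_s, r.offset_s
            else:
                h_on, h_off = r.hfo_onset_s, r.hfo_offset_s
            dur = h_off - h_on
            tc = 0.5 * (h_on + h_off)
            sd = dur / 5.0
            band = "fr" if klass.startswith("f") else "ripple"
            amp = a_hfo * scales[band] * r.amp_rel
            i0, i1 = int((tc - dur) * fs), int((tc + dur) * fs)
            i0, i1 = max(i0, 0), min(i1, n)
            tt = t[i0:i1]
            x[i0:i1] += amp * np.exp(-0.5 * ((tt - tc) / sd) ** 2) * np.cos(
                2 * np.pi * r.freq_hz * (tt - tc) + rng.uniform(0, 2 * np.pi))
        if klass in ("fRonS", "RonS", "SharpSpike"):
            # biphasic sharp transient: fast downstroke + slower rebound
            t1 = r.onset_s + 0.010
            t2 = t1 + 0.028
            i0 = max(int((r.onset_s - 0.05) * fs), 0)
            i1 = min(int((r.offset_s + 0.15) * fs), n)
            tt = t[i0:i1]
            x[i0:i1] += a_spk * (np.exp(-0.5 * ((tt - t1) / 0.004) ** 2)
                                 - 0.55 * np.exp(-0.5 * ((tt - t2) / 0.016) ** 2))
    return x, scales


def gen_ieeg(cfg: SynthConfig,
             patient_id: str = "P01") -> tuple[IEEGRecording, GroundTruth]:
    """Generate one patient's recording and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    truth = gen_events(cfg, rng, patient_id=patient_id)
    rows = []
    for ch in truth.channels:
        x, _ = render_channel(truth, ch, cfg, rng)
        rows.append(x)
    rec = IEEGRecording(samples=np.array(rows), fs=cfg.fs_ieeg,
                        channel_labels=list(truth.channels),
                        patient_id=patient_id,
                        epochs={ch: list(v) for ch, v in truth.epochs.items()})
    return rec, truth


# ---------------------------------------------------------------------------
# unit trains
# ---------------------------------------------------------------------------

def gen_unit_trains(cfg: SynthConfig, truth: GroundTruth,
                    rng: np.random.Generator | None = None) -> list[UnitSpikeTrain]:
    """Inhomogeneous-Poisson unit trains tied to the truth's contact bundles.

    Rate is ``unit_base_rate`` everywhere, scaled inside HFO windows by
    ``1 + unit_gain_per_log10power * log10(power)`` and inside sharp-transient
    windows by ``unit_spike_gain`` (events drawn additively/by thinning so the
    homogeneous-Poisson marginal is exact outside events).
    """
    if truth.events is None:
        raise ValueError("ground truth required")
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    T = truth.duration_s
    base = cfg.unit_base_rate
    units: list[UnitSpikeTrain] = []
    uid = 0
    for ch in truth.channels:
        ev = truth.events[truth.events.channel == ch]
        windows: list[tuple[float, float, float]] = []   # (start, end, rate)
        for r in ev.itertuples():
            klass = r[3]
            if klass in ("fRonO", "RonO"):
                w = (r.onset_s, r.offset_s)
            elif klass in ("fRonS", "RonS"):
                w = (r.hfo_onset_s, r.hfo_offset_s)
            else:
                w = None
            if w is not None:
                rate = base * (1.0 + cfg.unit_gain_per_log10power
                               * np.log10(r.power))
                windows.append((w[0], w[1], max(rate, 0.0)))
            if klass in ("fRonS", "RonS", "SharpSpike"):
                windows.append((r.onset_s, r.offset_s, base * cfg.unit_spike_gain))
        for _ in range(cfg.n_units_per_contact):
            n0 = rng.poisson(base * T)
            times = rng.uniform(0.0, T, size=n0)
            keep = np.ones(n0, bool)
            extras = []
            for (a, b, rate) in windows:
                if rate >= base:
                    lam = (rate - base) * (b - a)
                    k = rng.poisson(lam)
                    if k:
                        extras.append(rng.uniform(a, b, size=k))
                else:
                    inw = (times >= a) & (times < b)
                    keep[inw] &= rng.uniform(size=int(inw.sum())) < rate / base
            times = np.concatenate([times[keep]] + extras) if extras else times[keep]
            utype = "single" if rng.uniform() < 0.7 else "multi"
            units.append(UnitSpikeTrain(
                unit_id=f"{truth.patient_id}u{uid:03d}",
                patient_id=truth.patient_id, contact=ch, unit_type=utype,
                ap_times_ms=np.sort(times) * 1e3))
            uid += 1
    return units


# ---------------------------------------------------------------------------
# cohort on disk
# ---------------------------------------------------------------------------

def gen_cohort(cfg: SynthConfig, outdir: str | Path) -> Path:
    """Write a full synthetic cohort (EDF + CSV tables + config) to *outdir*."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(cfg.seed)
    elec_rows, unit_rows, truth_rows, epoch_rows = [], [], [], []
    for p in range(cfg.n_patients):
        pid = f"P{p + 1:02d}"
        sub = dataclasses.replace(cfg, seed=int(master.integers(0, 2**31 - 1)))
        rec, truth = gen_ieeg(sub, patient_id=pid)
        write_edf(out / f"{pid}.edf", rec)
        units = gen_unit_trains(sub, truth)
        elec_rows.append(truth.electrodes)
        truth_rows.append(truth.events)
        for u in units:
            unit_rows.append(pd.DataFrame({
                "patient_id": u.patient_id, "unit_id": u.unit_id,
                "contact": u.contact, "unit_type": u.unit_type,
                "spike_time_ms": u.ap_times_ms}))
        for ch, ivals in truth.epochs.items():
            for a, b in ivals:
                epoch_rows.append({"patient_id": pid, "channel": ch,
                                   "start_s": a, "end_s": b})
    pd.concat(elec_rows, ignore_index=True).to_csv(out / "electrodes.csv", index=False)
    cols = ["patient_id", "unit_id", "contact", "unit_type", "spike_time_ms"]
    (pd.concat(unit_rows, ignore_index=True) if unit_rows
     else pd.DataFrame(columns=cols)).to_csv(out / "units.csv", index=False)
    pd.concat(truth_rows, ignore_index=True).to_csv(out / "events_truth.csv", index=False)
    pd.DataFrame(epoch_rows).to_csv(out / "epochs.csv", index=False)
    save_config(out / "config.yaml", cfg, AnalysisConfig())
    return out
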