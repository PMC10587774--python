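"""Stage-1 candidate detection: transient band-amplitude elevations.

A zero-phase FIR band-pass (ripple 80-200 Hz, fast-ripple 200-600 Hz, plus a
low "spike" band used only to seed sharp-transient candidates for stage 2),
analytic envelope, and a robust per-channel z-score of the envelope against
its median/MAD inside artifact-free epochs.  Runs above ``z_hi`` that contain
at least ``min_cycles`` oscillation cycles become candidates; boundaries are
extended down to ``z_lo`` so onset timing is not biased by the high
threshold, and nearby candidates are merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .config import AnalysisConfig
from .io import IEEGRecording

BANDS = {"ripple": (80.0, 200.0), "fr": (200.0, 600.0), "spk": (20.0, 70.0)}


@dataclass
class CandidateEvent:
    channel: str
    band: str
    onset_s: float
    offset_s: float
    peak_z: float

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must exceed onset")


def _fir_bandpass(lo: float, hi: float, fs: float) -> np.ndarray:
    hi = min(hi, 0.49 * fs)
    if lo >= 0.5 * fs or hi >= 0.5 * fs:
        raise ValueError("band edges must be below Nyquist")
    # transition width 15% of the low edge (>=10 Hz) keeps in-band events
    # near the edges unattenuated
    tw = max(0.15 * lo, 10.0)
    ntaps = int(2 * round(1.65 * fs / tw) + 1)
    return signal.firwin(ntaps, [lo, hi], pass_zero=False, fs=fs)


def band_filter(x: np.ndarray, fs: float, band: str) -> np.ndarray:
    # single centred pass of the symmetric (linear-phase) FIR == zero phase
    lo, hi = BANDS[band]
    taps = _fir_bandpass(lo, hi, fs)
    return signal.oaconvolve(x, taps, mode="same")


def band_envelope(x: np.ndarray, fs: float, band: str) -> np.ndarray:
    return np.abs(signal.hilbert(band_filter(x, fs, band)))


def _epoch_mask(n: int, fs: float, epochs: list[tuple[float, float]]) -> np.ndarray:
    m = np.zeros(n, bool)
    for a, b in epochs:
        m[int(np.ceil(a * fs)):int(np.floor(b * fs))] = True
    return m


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs of True."""
    d = np.diff(mask.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def artifact_mask(rec: IEEGRecording,
                  cfg: AnalysisConfig | None = None) -> dict[str, list[tuple[float, float]]]:
    """Shrink each channel's artifact-free epochs around broadband outliers.

    Samples with MAD-scaled broadband |z| above ``z_art`` or a slew rate above
    ``slew_uv_per_ms`` are excluded together with a guard interval.
    """
    cfg = cfg or AnalysisConfig()
    fs = rec.fs
    guard = cfg.artifact_guard_ms * 1e-3
    out: dict[str, list[tuple[float, float]]] = {}
    for i, ch in enumerate(rec.channel_labels):
        x = rec.samples[i]
        med = np.median(x)
        mad = np.median(np.abs(x - med)) * 1.4826
        if mad == 0:
            # flat or saturated channel carries no usable signal
            out[ch] = []
            continue
        z = np.abs(x - med) / mad
        slew = np.abs(np.diff(x, prepend=x[0])) * fs * 1e-3   # µV per ms
        bad = (z > cfg.z_art) | (slew > cfg.slew_uv_per_ms)
        if not bad.any():
            out[ch] = list(rec.epochs.get(ch, []))
            continue
        bad_t = [(s / fs - guard, e / fs + guard) for s, e in _runs(bad)]
        ivals = []
        for a, b in rec.epochs.get(ch, [(0.0, rec.duration_s)]):
            cur = a
            for ba, bb in bad_t:
                if bb <= cur or ba >= b:
                    continue
                if ba > cur:
                    ivals.append((cur, ba))
                cur = max(cur, bb)
            if cur < b:
                ivals.append((cur, b))
        out[ch] = [(a, b) for a, b in ivals if b - a > 0.1]
    return out


def band_envelope_detect(rec: IEEGRecording, band: str,
                         cfg: AnalysisConfig | None = None,
                         epochs: dict[str, list[tuple[float, float]]] | None = None,
                         ) -> list[CandidateEvent]:
    """Detect transient band-amplitude elevations on every channel."""
    cfg = cfg or AnalysisConfig()
    lo, hi = BANDS[band]
    if hi > 0.5 * rec.fs and band != "fr":
        raise ValueError("band upper edge above Nyquist")
    epochs = epochs or rec.epochs
    fs = rec.fs
    out: list[CandidateEvent] = []
    for i, ch in enumerate(rec.channel_labels):
        ivals = epochs.get(ch, [])
        if not ivals:
            continue
        x = rec.samples[i]
        filt = band_filter(x, fs, band)
        analytic = signal.hilbert(filt)
        env = np.abs(analytic)
        phase = np.unwrap(np.angle(analytic))
        ok = _epoch_mask(x.size, fs, ivals)
        # guard the record edges against filter transients
        n_edge = int(0.25 * fs)
        ok[:n_edge] = False
        ok[-n_edge:] = False
        if not ok.any():
            continue
        med = np.median(env[ok])
        mad = np.median(np.abs(env[ok] - med)) * 1.4826
        if mad == 0:
            continue
        z = (env - med) / mad
        z_hi = cfg.spk_z_hi if band == "spk" else cfg.z_hi
        hi_mask = (z > z_hi) & ok
        lo_mask = (z > cfg.z_lo) & ok
        # candidate seed: a z_mid excursion that reaches z_hi and holds
        # >= min_cycles oscillation cycles
        mid_runs = _runs((z > cfg.z_mid) & ok)
        cands: list[tuple[int, int, float]] = []
        for s0, e0 in mid_runs:
            if not hi_mask[s0:e0].any():
                continue
            if band != "spk":
                if e0 - s0 < 4:
                    continue
                n_cycles = (phase[e0 - 1] - phase[s0]) / (2 * np.pi)
                if n_cycles < cfg.min_cycles:
                    continue
            elif (e0 - s0) / fs < 0.005:
                continue
            # extend to the surrounding z_lo run for unbiased onset timing
            s, e = s0, e0
            while s > 0 and lo_mask[s - 1]:
                s -= 1
            while e < z.size and lo_mask[e]:
                e += 1
            if cands and s <= cands[-1][1]:
                ps, pe, pz = cands[-1]
                cands[-1] = (ps, max(pe, e), max(pz, float(z[s:e].max())))
            else:
                cands.append((s, e, float(z[s:e].max())))
        for s, e, pz in cands:
            out.append(CandidateEvent(ch, band, s / fs, e / fs, pz))
    return merge_events(out, cfg.merge_gap_ms)


def merge_events(cands: list[CandidateEvent], gap_ms: float) -> list[CandidateEvent]:
    """Merge same-channel/band candidates that overlap or sit within *gap_ms*."""
    gap = gap_ms * 1e-3
    out: list[CandidateEvent] = []
    key = lambda c: (c.channel, c.band, c.onset_s)
    for c in sorted(cands, key=key):
        if (out and out[-1].channel == c.channel and out[-1].band == c.band
                and c.onset_s - out[-1].offset_s <= gap):
            prev = out[-1]
            out[-1] = CandidateEvent(prev.channel, prev.band, prev.onset_s,
                                     max(prev.offset_s, c.offset_s),
                                     max(prev.peak_z, c.peak_z))
        else:
            out.append(CandidateEvent(c.channel, c.band, c.onset_s,
                                      c.offset_s, c.peak_z))
    return out


def candidates_to_frame(cands: list[CandidateEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"channel": c.channel, "band": c.band, "onset_s": c.onset_s,
          "offset_s": c.offset_s, "peak_z": c.peak_z} for c in cands],
        columns=["channel", "band", "onset_s", "offset_s", "peak_z"])
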