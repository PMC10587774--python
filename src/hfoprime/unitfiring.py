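"""Event-aligned unit firing: trials, smoothed rates, inclusion test, summaries.

For every (HFO event, unit on the same contact bundle) pair a trial is built:
a 2 s binary raster at 1 ms resolution centred on event onset, convolved with
a 100 ms-sigma Gaussian kernel (unit area, so the series is in Hz) and
downsampled to 40 Hz by taking every 25th sample.  From the 40 Hz series:

* ``bl_fr``  - mean rate over [-750, 0) ms before onset,
* ``hfo_fr`` - maximum rate over [0, event duration],
* ``hfodiff_fr = hfo_fr - bl_fr``.

Units whose bl_fr vs hfo_fr paired t-test does not survive Holm-Bonferroni
step-down at 0.001 within an event class are excluded from model fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .io import UnitSpikeTrain

logger = logging.getLogger(__name__)


@dataclass
class EventUnitTrial:
    unit_id: str
    contact: str
    patient_id: str
    klass: str
    event_onset_s: float
    duration_ms: float
    log10_power: float
    prespike: int
    followed_fRonO: int
    followed_RonO: int
    unit_type: str
    raster: np.ndarray        # (window_ms,) uint8, 1 ms bins
    rate_series: np.ndarray   # (window_ms / 25,) Hz at 40 Hz
    bl_fr: float
    hfo_fr: float
    hfodiff_fr: float


def gaussian_kernel(sigma_ms: float, truncate: float = 4.0) -> np.ndarray:
    """Unit-area Gaussian kernel on a 1 ms grid; values in 1/s so that
    convolving a 0/1 spike raster yields a rate in Hz."""
    half = int(round(truncate * sigma_ms))
    t = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (t / sigma_ms) ** 2)
    k /= k.sum() * 1e-3          # sum(k) * dt = 1
    return k


def smooth_rate(raster: np.ndarray, cfg: AnalysisConfig | None = None,
                mode: str = "same") -> np.ndarray:
    """Gaussian-smoothed firing rate (Hz) of a 1 ms binary raster.

    ``mode='full'`` returns the complete convolution, whose integral equals
    the raster's spike count exactly (used by the conservation check).
    """
    cfg = cfg or AnalysisConfig()
    k = gaussian_kernel(cfg.kernel_ms)
    full = np.convolve(np.asarray(raster, float), k, mode="full")
    if mode == "full":
        return full
    half = (k.size - 1) // 2
    return full[half:half + len(raster)]


def downsample_rate(series_1k: np.ndarray, cfg: AnalysisConfig | None = None) -> np.ndarray:
    cfg = cfg or AnalysisConfig()
    step = int(round(1000.0 / cfg.rate_fs_hz))
    return series_1k[::step]


def trial_rates(rate_series: np.ndarray, duration_ms: float,
                cfg: AnalysisConfig | None = None) -> tuple[float, float, float]:
    """(bl_fr, hfo_fr, hfodiff_fr) from a 40 Hz rate series centred on onset.

    Sample k sits at ``-window/2 + k * 25`` ms; baseline is the mean over
    [-750, 0) ms and the peak is the max over [0, duration] (inclusive),
    clamped to the window end if the event outlasts the window.
    """
    cfg = cfg or AnalysisConfig()
    step = 1000.0 / cfg.rate_fs_hz
    t = -cfg.window_ms / 2.0 + step * np.arange(rate_series.size)
    bl = rate_series[(t >= -cfg.baseline_ms) & (t < 0.0)]
    if duration_ms > cfg.window_ms / 2.0:
        logger.warning("event duration %.0f ms exceeds the half-window; clamping",
                       duration_ms)
        duration_ms = cfg.window_ms / 2.0
    inev = rate_series[(t >= 0.0) & (t <= duration_ms)]
    bl_fr = float(bl.mean()) if bl.size else 0.0
    hfo_fr = float(inev.max()) if inev.size else 0.0
    return bl_fr, hfo_fr, hfo_fr - bl_fr


def build_trials(events: pd.DataFrame, units: list[UnitSpikeTrain],
                 cfg: AnalysisConfig | None = None,
                 classes: tuple[str, ...] = ("fRonO", "RonO", "fRonS", "RonS"),
                 recording_duration_s: float | None = None,
                 ) -> list[EventUnitTrial]:
    """One trial per (event, unit-on-same-bundle) pair.

    Comparison is strictly within the macro-micro electrode pair: a unit
    contributes only to events on its own contact.  Trials whose 2 s window
    would overrun the recording edge are dropped.
    """
    cfg = cfg or AnalysisConfig()
    win = int(round(cfg.window_ms))
    half = win // 2
    trials: list[EventUnitTrial] = []
    by_contact: dict[tuple[str, str], list[UnitSpikeTrain]] = {}
    for u in units:
        by_contact.setdefault((u.patient_id, u.contact), []).append(u)
    ev = events.rename(columns={"class": "klass"})
    for r in ev.itertuples():
        klass = r.klass
        if klass not in classes:
            continue
        onset_ms = r.onset_s * 1e3
        t0 = onset_ms - half
        if t0 < 0:
            continue
        if (recording_duration_s is not None
                and onset_ms + half > recording_duration_s * 1e3):
            continue
        for u in by_contact.get((r.patient_id, r.channel), []):
            rel = u.ap_times_ms - t0
            sel = rel[(rel >= 0) & (rel < win)]
            raster = np.zeros(win, np.uint8)
            np.add.at(raster, sel.astype(int), 1)
            raster = np.minimum(raster, 1)
            series = downsample_rate(smooth_rate(raster, cfg), cfg)
            dur = r.duration_ms if hasattr(r, "duration_ms") else \
                (r.offset_s - r.onset_s) * 1e3
            bl, pk, diff = trial_rates(series, float(dur), cfg)
            trials.append(EventUnitTrial(
                unit_id=u.unit_id, contact=u.contact, patient_id=u.patient_id,
                klass=klass, event_onset_s=r.onset_s, duration_ms=float(dur),
                log10_power=float(getattr(r, "log10_power", np.nan)),
                prespike=int(getattr(r, "prespike", 0)),
                followed_fRonO=int(getattr(r, "followed_fRonO", 0)),
                followed_RonO=int(getattr(r, "followed_RonO", 0)),
                unit_type=u.unit_type, raster=raster, rate_series=series,
                bl_fr=bl, hfo_fr=pk, hfodiff_fr=diff))
    return trials


def trials_to_frame(trials: list[EventUnitTrial]) -> pd.DataFrame:
    return pd.DataFrame([{
        "unit_id": t.unit_id, "contact": t.contact, "patient_id": t.patient_id,
        "class": t.klass, "event_onset_s": t.event_onset_s,
        "duration_ms": t.duration_ms, "log10_power": t.log10_power,
        "prespike": t.prespike, "followed_fRonO": t.followed_fRonO,
        "followed_RonO": t.followed_RonO, "unit_type": t.unit_type,
        "bl_fr": t.bl_fr, "hfo_fr": t.hfo_fr, "hfodiff_fr": t.hfodiff_fr,
    } for t in trials])


def holm_bonferroni(pvals: np.ndarray, alpha: float) -> np.ndarray:
    """Step-down Holm rejections: True where the hypothesis is rejected."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    reject = np.zeros(m, bool)
    for rank, i in enumerate(order):
        if p[i] <= alpha / (m - rank):
            reject[i] = True
        else:
            break
    return reject


def unit_inclusion_test(trials: pd.DataFrame, klass: str,
                        alpha: float = 0.001) -> pd.DataFrame:
    """Paired t-test bl_fr vs hfo_fr per unit, Holm-corrected across units.

    A unit is *included* when its firing rate change during events of *klass*
    survives the step-down at *alpha*; zero-variance differences give p = 1.
    """
    sub = trials[trials["class"] == klass]
    rows = []
    for uid, g in sub.groupby("unit_id", sort=True):
        if len(g) < 2:
            rows.append({"unit_id": uid, "class": klass, "t": np.nan,
                         "p": 1.0, "n_trials": len(g)})
            continue
        d = g.hfo_fr.to_numpy() - g.bl_fr.to_numpy()
        if np.allclose(d.std(ddof=1), 0.0):
            rows.append({"unit_id": uid, "class": klass, "t": np.nan,
                         "p": 1.0, "n_trials": len(g)})
            continue
        t, p = stats.ttest_rel(g.hfo_fr, g.bl_fr)
        rows.append({"unit_id": uid, "class": klass, "t": float(t),
                     "p": float(p), "n_trials": len(g)})
    out = pd.DataFrame(rows, columns=["unit_id", "class", "t", "p", "n_trials"])
    if len(out):
        out["included"] = holm_bonferroni(out.p.to_numpy(), alpha)
    else:
        out["included"] = pd.Series(dtype=bool)
    return out


def grand_average(trials: list[EventUnitTrial]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean rate and normal 95% CI half-width across trials."""
    if not trials:
        raise ValueError("empty trial group")
    mat = np.stack([t.rate_series for t in trials])
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 \
        else np.zeros_like(mean)
    return mean, mean - 1.96 * sem, mean + 1.96 * sem


def peak_time_histogram(trials: list[EventUnitTrial],
                        bins_ms: np.ndarray,
                        cfg: AnalysisConfig | None = None) -> np.ndarray:
    """Histogram of per-trial argmax times (ms, relative to event onset).

    Flat series resolve their argmax tie to the earliest sample.
    """
    cfg = cfg or AnalysisConfig()
    step = 1000.0 / cfg.rate_fs_hz
    times = []
    for t in trials:
        k = int(np.argmax(t.rate_series))    # first max = earliest time
        times.append(-cfg.window_ms / 2.0 + step * k)
    return np.histogram(times, bins=bins_ms)[0]


def effect_size(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with the pooled standard deviation."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per sample")
    na, nb = a.size, b.size
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                 / (na + nb - 2))
    if sp == 0:
        return 0.0
    return float((a.mean() - b.mean()) / sp)


def power_by_latency(events: pd.DataFrame,
                     bins_ms: np.ndarray = np.array([0.0, 10.0, 300.0]),
                     ) -> pd.DataFrame:
    """Mean log10 power of pre-spike HFOs per latency bin (half-open [lo, hi))."""
    ev = events[(events.prespike == 1) & np.isfinite(events.latency_to_spike_ms)]
    rows = []
    for lo, hi in zip(bins_ms[:-1], bins_ms[1:]):
        m = (ev.latency_to_spike_ms >= lo) & (ev.latency_to_spike_ms < hi)
        rows.append({"bin_lo_ms": lo, "bin_hi_ms": hi,
                     "mean_log10_power": float(ev.loc[m, "log10_power"].mean())
                     if m.any() else np.nan,
                     "n": int(m.sum())})
    return pd.DataFrame(rows)
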