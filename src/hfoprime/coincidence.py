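"""HFO -> spike latency, pre-spike/followed flags, and surrogate coincidence nulls.

All coincidence arithmetic is within-channel.  For each HFO on oscillation,
the latency to the next epileptiform spike is the minimum strictly positive
difference ``spike_onset - hfo_onset``; an HFO "primes" a spike when that
latency is below 300 ms (strict).  Whether the number of such pairings
exceeds chance is tested against a bootstrap null in which HFO onsets are
redrawn uniformly within the channel's artifact-free epochs (spike onsets
held fixed, per-channel HFO counts preserved), 500 times by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SPIKE_CLASSES


@dataclass
class SurrogateResult:
    observed: int
    surrogate_counts: np.ndarray
    z: float
    empirical_p: float
    scope: str = "pooled"
    spike_subset: str = "all"
    sd_zero: bool = False


def min_positive_latency(hfo_onsets: np.ndarray,
                         spike_onsets: np.ndarray) -> np.ndarray:
    """Per-HFO minimum strictly positive latency to a spike, in ms (NaN if none)."""
    h = np.asarray(hfo_onsets, float)
    s = np.sort(np.asarray(spike_onsets, float))
    out = np.full(h.shape, np.nan)
    if s.size == 0 or h.size == 0:
        return out
    idx = np.searchsorted(s, h, side="right")   # first spike strictly later
    ok = idx < s.size
    out[ok] = (s[idx[ok]] - h[ok]) * 1e3
    return out


def flag_coincidence(events: pd.DataFrame, window_ms: float = 300.0,
                     spike_subset: str = "all") -> pd.DataFrame:
    """Fill prespike / latency / followed_* flags on a classified event table.

    ``prespike`` on fRonO/RonO means a spike of *spike_subset* follows within
    the window (strict <); fRonS/RonS get ``followed_fRonO``/``followed_RonO``
    when such an HFO onset lies strictly within ``window_ms`` before their
    onset.  Solitary events are the complement.
    """
    ev = events.copy()
    if spike_subset == "all":
        spike_classes = SPIKE_CLASSES
    elif spike_subset in SPIKE_CLASSES:
        spike_classes = (spike_subset,)
    else:
        raise ValueError(f"unknown spike subset {spike_subset!r}")
    ev["prespike"] = 0
    ev["latency_to_spike_ms"] = np.nan
    ev["followed_fRonO"] = 0
    ev["followed_RonO"] = 0
    for (_, _), idx in ev.groupby(["patient_id", "channel"]).groups.items():
        sub = ev.loc[idx]
        spikes = np.sort(sub.loc[sub["class"].isin(spike_classes), "onset_s"].to_numpy())
        for klass in ("fRonO", "RonO"):
            m = sub["class"] == klass
            if not m.any():
                continue
            lat = min_positive_latency(sub.loc[m, "onset_s"].to_numpy(), spikes)
            ev.loc[sub.index[m], "latency_to_spike_ms"] = lat
            ev.loc[sub.index[m], "prespike"] = (lat < window_ms).astype(int)
        for klass in ("fRonS", "RonS"):
            m = sub["class"] == klass
            if not m.any():
                continue
            onsets = sub.loc[m, "onset_s"].to_numpy()
            for hk, col in (("fRonO", "followed_fRonO"), ("RonO", "followed_RonO")):
                h = np.sort(sub.loc[sub["class"] == hk, "onset_s"].to_numpy())
                if h.size == 0:
                    continue
                # an HFO onset strictly inside (onset - window, onset)
                lo = np.searchsorted(h, onsets - window_ms * 1e-3, side="right")
                hi = np.searchsorted(h, onsets, side="left")
                ev.loc[sub.index[m], col] = (hi > lo).astype(int)
    return ev


def _count_coincidences(hfo: np.ndarray, spikes: np.ndarray,
                        window_s: float) -> int:
    if hfo.size == 0 or spikes.size == 0:
        return 0
    idx = np.searchsorted(spikes, hfo, side="right")
    ok = idx < spikes.size
    lat = spikes[idx[ok]] - hfo[ok]
    return int(np.count_nonzero(lat < window_s))


def surrogate_null(events: pd.DataFrame,
                   epochs: dict[str, list[tuple[float, float]]],
                   n: int = 500, seed: int = 0, window_ms: float = 300.0,
                   hfo_class: str = "fRonO", spike_subset: str = "all",
                   channels: list[str] | None = None) -> SurrogateResult:
    """Bootstrap test of the <window coincidence count against uniform HFO onsets.

    Spike onsets are held fixed; per channel, the observed number of HFOs is
    redrawn uniformly within that channel's artifact-free epochs for each of
    the *n* resamples; the pooled statistic is the sum of per-channel counts.
    """
    if spike_subset == "all":
        spike_classes = SPIKE_CLASSES
    elif spike_subset in SPIKE_CLASSES:
        spike_classes = (spike_subset,)
    else:
        raise ValueError(f"unknown spike subset {spike_subset!r}")
    rng = np.random.default_rng(seed)
    window_s = window_ms * 1e-3
    if channels is None:
        channels = sorted(events.channel.unique())
    obs = 0
    surr = np.zeros(n)
    for ch in channels:
        sub = events[events.channel == ch]
        hfo = np.sort(sub.loc[sub["class"] == hfo_class, "onset_s"].to_numpy())
        spikes = np.sort(sub.loc[sub["class"].isin(spike_classes), "onset_s"].to_numpy())
        obs += _count_coincidences(hfo, spikes, window_s)
        if hfo.size == 0 or spikes.size == 0:
            continue
        ivals = epochs.get(ch)
        if not ivals:
            raise ValueError(f"no artifact-free epochs for channel {ch}")
        lens = np.array([b - a for a, b in ivals], float)
        starts = np.array([a for a, _ in ivals], float)
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        u = rng.uniform(0.0, cum[-1], size=(n, hfo.size))
        seg = np.searchsorted(cum, u, side="right") - 1
        onsets = starts[seg] + (u - cum[seg])
        onsets.sort(axis=1)
        idx = np.searchsorted(spikes, onsets, side="right")
        ok = idx < spikes.size
        lat = np.where(ok, spikes[np.minimum(idx, spikes.size - 1)] - onsets, np.inf)
        surr += np.count_nonzero(lat < window_s, axis=1)
    mu, sd = float(surr.mean()), float(surr.std(ddof=0))
    sd_zero = sd == 0.0
    z = math.nan if sd_zero else (obs - mu) / sd
    p = (1.0 + np.count_nonzero(np.abs(surr - mu) >= abs(obs - mu))) / (n + 1.0)
    return SurrogateResult(observed=obs, surrogate_counts=surr, z=z,
                           empirical_p=float(p), spike_subset=spike_subset,
                           sd_zero=sd_zero)


def ratio_timeseries(events: pd.DataFrame, bin_s: float = 60.0,
                     duration_s: float | None = None) -> pd.DataFrame:
    """Cumulative fRonS:fRonO and RonS:fRonO count ratios per channel per bin."""
    if duration_s is None:
        duration_s = float(events.onset_s.max()) if len(events) else bin_s
    n_bins = int(np.ceil(duration_s / bin_s))
    edges = np.arange(n_bins + 1) * bin_s
    rows = []
    for ch, sub in events.groupby("channel"):
        counts = {}
        for klass in ("fRonO", "fRonS", "RonS"):
            on = sub.loc[sub["class"] == klass, "onset_s"].to_numpy()
            counts[klass] = np.cumsum(np.histogram(on, bins=edges)[0])
        denom = counts["fRonO"].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            r_f = np.where(denom > 0, counts["fRonS"] / denom, np.nan)
            r_r = np.where(denom > 0, counts["RonS"] / denom, np.nan)
        for b in range(n_bins):
            rows.append({"channel": ch, "bin_end_s": edges[b + 1],
                         "fRonS_to_fRonO": r_f[b], "RonS_to_fRonO": r_r[b]})
    return pd.DataFrame(rows, columns=["channel", "bin_end_s",
                                       "fRonS_to_fRonO", "RonS_to_fRonO"])


def latency_histogram(events: pd.DataFrame,
                      epochs: dict[str, list[tuple[float, float]]],
                      bins_ms: np.ndarray, n_surrogates: int = 500,
                      seed: int = 0, hfo_class: str = "fRonO",
                      spike_subset: str = "all") -> pd.DataFrame:
    """Unit-mass histogram of HFO->spike latencies with a surrogate overlay.

    Returns per-bin observed mass plus surrogate mean and sd of the mass under
    uniform HFO placement.
    """
    if spike_subset == "all":
        spike_classes = SPIKE_CLASSES
    else:
        spike_classes = (spike_subset,)
    rng = np.random.default_rng(seed)
    bins_ms = np.asarray(bins_ms, float)
    obs_counts = np.zeros(bins_ms.size - 1)
    surr_counts = np.zeros((n_surrogates, bins_ms.size - 1))
    for ch, sub in events.groupby("channel"):
        hfo = np.sort(sub.loc[sub["class"] == hfo_class, "onset_s"].to_numpy())
        spikes = np.sort(sub.loc[sub["class"].isin(spike_classes), "onset_s"].to_numpy())
        if hfo.size == 0 or spikes.size == 0:
            continue
        lat = min_positive_latency(hfo, spikes)
        obs_counts += np.histogram(lat[np.isfinite(lat)], bins=bins_ms)[0]
        ivals = epochs.get(ch) or []
        if not ivals:
            continue
        lens = np.array([b - a for a, b in ivals])
        starts = np.array([a for a, _ in ivals])
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        u = rng.uniform(0.0, cum[-1], size=(n_surrogates, hfo.size))
        seg = np.searchsorted(cum, u, side="right") - 1
        onsets = starts[seg] + (u - cum[seg])
        idx = np.searchsorted(spikes, onsets, side="right")
        ok = idx < spikes.size
        lat_s = np.where(ok, spikes[np.minimum(idx, spikes.size - 1)] - onsets,
                         np.nan) * 1e3
        for r in range(n_surrogates):
            row = lat_s[r]
            surr_counts[r] += np.histogram(row[np.isfinite(row)], bins=bins_ms)[0]
    tot = obs_counts.sum()
    obs_mass = obs_counts / tot if tot > 0 else obs_counts
    st = surr_counts.sum(axis=1, keepdims=True)
    st[st == 0] = 1.0
    surr_mass = surr_counts / st
    return pd.DataFrame({
        "bin_lo_ms": bins_ms[:-1], "bin_hi_ms": bins_ms[1:],
        "observed_mass": obs_mass,
        "surrogate_mean": surr_mass.mean(axis=0),
        "surrogate_sd": surr_mass.std(axis=0, ddof=0),
        "observed_count": obs_counts,
        "surrogate_count_mean": surr_counts.mean(axis=0),
        "surrogate_count_sd": surr_counts.std(axis=0, ddof=0),
    })
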