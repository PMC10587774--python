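"""Stage-2 classification by topographical analysis of the wavelet transform.

Each stage-1 candidate is windowed, Morlet-transformed on a log-spaced
60-650 Hz grid, and iso-power contours are traced at a ladder of levels at
and above ``0.2 * (max - min) + min`` of the map.  A contour is a closed-loop
contour (CLC) when its first and last vertices coincide, an open-loop contour
(OLC) otherwise.  Closed contours nesting around a common local power maximum
form a CLC group; the event class follows from the contour topology:

* CLC group with no earlier spike-rooted OLC -> ripple / fast ripple on
  oscillation (RonO / fRonO);
* CLC group with an earlier-onset spike-rooted OLC -> RonS / fRonS;
* only OLCs -> sharp spike without an HFO.

Ripples and fast ripples are separated at 200 Hz by the mean frequency of
the CLC group; peak frequency and power come from the largest iso-power
contour value in the group, duration and onset from the group's outermost
contour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.path import Path as MplPath
from skimage import measure

from .config import AnalysisConfig
from .detect import CandidateEvent
from .io import HfoEvent, IEEGRecording


@dataclass
class TFMap:
    power: np.ndarray        # (n_freqs, n_times), >= 0
    freqs: np.ndarray        # Hz, strictly increasing (log-spaced)
    times: np.ndarray        # s, strictly increasing
    channel: str = ""
    valid: np.ndarray | None = None   # per-time cone-of-influence mask

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("grids must be strictly increasing")


@dataclass
class Contour:
    vertices: np.ndarray     # (n, 2) fractional (freq_idx, time_idx)
    level: float
    closed: bool
    times: np.ndarray = field(repr=False, default=None)   # vertex times (s)
    freqs: np.ndarray = field(repr=False, default=None)   # vertex freqs (Hz)

    @property
    def onset_s(self) -> float:
        return float(self.times.min())

    @property
    def offset_s(self) -> float:
        return float(self.times.max())

    @property
    def mean_freq_hz(self) -> float:
        return float(self.freqs.mean())

    @property
    def min_freq_hz(self) -> float:
        return float(self.freqs.min())


@dataclass
class ContourSet:
    contours: list[Contour]
    groups: list[list[int]]          # CLC groups as indices into contours
    open_idx: list[int]              # indices of open contours
    tf: TFMap


def wavelet_tfr(segment: np.ndarray, fs: float,
                cfg: AnalysisConfig | None = None, channel: str = "",
                t0: float = 0.0) -> TFMap:
    """Morlet power map of *segment* on a log-spaced frequency grid.

    Wavelets are L1-normalized so a sinusoid of amplitude *a* yields the same
    power (about a^2/4) at any centre frequency.
    """
    cfg = cfg or AnalysisConfig()
    x = np.asarray(segment, float)
    if x.size < 256:
        raise ValueError("segment too short for time-frequency analysis")
    if fs < 1200.0:
        raise ValueError("sampling rate must be >= 1200 Hz")
    freqs = np.geomspace(cfg.freq_lo_hz, cfg.freq_hi_hz, cfg.n_freqs)
    n = x.size
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    X = np.fft.fft(x - x.mean(), nfft)
    power = np.empty((freqs.size, n))
    tgrid = (np.arange(nfft) - nfft // 2) / fs
    for k, f in enumerate(freqs):
        s = cfg.n_cycles / (2 * np.pi * f)
        w = np.exp(-0.5 * (tgrid / s) ** 2) * np.exp(2j * np.pi * f * tgrid)
        w /= np.sum(np.abs(w))
        W = np.fft.fft(np.fft.ifftshift(w), nfft)
        conv = np.fft.ifft(X * np.conj(W))[:n]
        power[k] = np.abs(conv) ** 2
    coi = 2.0 * cfg.n_cycles / (2 * np.pi * freqs[0])
    times = t0 + np.arange(n) / fs
    valid = (times - times[0] > coi) & (times[-1] - times > coi)
    return TFMap(power=power, freqs=freqs, times=times, channel=channel,
                 valid=valid)


def contour_threshold(tf: TFMap) -> float:
    """Iso-power floor: ``0.2 * (max - min) + min`` of the map."""
    pmax, pmin = float(tf.power.max()), float(tf.power.min())
    return 0.2 * (pmax - pmin) + pmin


def extract_contours(tf: TFMap, level: float | None = None,
                     cfg: AnalysisConfig | None = None) -> ContourSet:
    """Trace iso-power contours at a ladder of levels from the floor to the max.

    Contours below the floor are never traced; each contour is labelled
    closed/open by the first==last vertex rule, and closed contours are
    grouped by mutual nesting (containment) into CLC groups.
    """
    cfg = cfg or AnalysisConfig()
    thr = contour_threshold(tf) if level is None else level
    pmax = float(tf.power.max())
    contours: list[Contour] = []
    if pmax > thr:
        levels = np.linspace(thr, pmax, cfg.n_contour_levels + 1)[:-1]
        nt = tf.times.size
        nf = tf.freqs.size
        logf = np.log(tf.freqs)
        for lev in levels:
            for verts in measure.find_contours(tf.power, lev):
                closed = bool(np.allclose(verts[0], verts[-1]))
                vt = np.interp(verts[:, 1], np.arange(nt), tf.times)
                vf = np.exp(np.interp(verts[:, 0], np.arange(nf), logf))
                contours.append(Contour(verts, float(lev), closed, vt, vf))
    open_idx = [i for i, c in enumerate(contours) if not c.closed]
    closed_idx = [i for i, c in enumerate(contours) if c.closed]

    # union-find over the containment relation
    parent = {i: i for i in closed_idx}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    paths = {i: MplPath(contours[i].vertices) for i in closed_idx}
    for a in closed_idx:
        for b in closed_idx:
            if b <= a:
                continue
            if (paths[a].contains_point(contours[b].vertices[0])
                    or paths[b].contains_point(contours[a].vertices[0])):
                parent[find(a)] = find(b)
    comp: dict[int, list[int]] = {}
    for i in closed_idx:
        comp.setdefault(find(i), []).append(i)
    groups = sorted(comp.values(), key=lambda g: -max(contours[i].level for i in g))
    return ContourSet(contours=contours, groups=groups, open_idx=open_idx, tf=tf)


@dataclass
class Classification:
    klass: str
    onset_s: float
    offset_s: float
    peak_freq_hz: float
    log10_power: float


def classify_event(cs: ContourSet, cfg: AnalysisConfig | None = None,
                   core: tuple[float, float] | None = None,
                   olc_margin_ms: float = 10.0) -> Classification | None:
    """Apply the contour-topology rules to one window's contour set.

    *core*, when given, restricts attention to contours whose time span
    intersects it (so neighbouring events inside the same analysis window do
    not hijack the classification).  Returns ``None`` when no structure
    qualifies (stage-2 rejection).
    """
    cfg = cfg or AnalysisConfig()
    if not cs.contours:
        return None

    def _intersects(c: Contour) -> bool:
        return core is None or (c.offset_s > core[0] and c.onset_s < core[1])

    # candidate CLC groups: HFO-band mean frequency, intersecting the core
    scored = []
    for g in cs.groups:
        members = [cs.contours[i] for i in g]
        outer = min(members, key=lambda c: (c.level, -(c.offset_s - c.onset_s)))
        if not _intersects(outer):
            continue
        mean_f = float(np.mean([c.mean_freq_hz for c in members]))
        if mean_f < 80.0:
            continue
        # a real burst spans several ladder levels; a blob that only grazes
        # the threshold level is background
        if len({c.level for c in members}) < cfg.min_clc_levels:
            continue
        top = max(members, key=lambda c: c.level)
        scored.append((top.level, outer, top, mean_f))

    # spike-signature OLCs: rooted below spike_root_hz (broadband transient)
    spike_olcs = [cs.contours[i] for i in cs.open_idx
                  if cs.contours[i].min_freq_hz <= cfg.spike_root_hz
                  and _intersects(cs.contours[i])]

    if not scored:
        if spike_olcs:
            outer = min(spike_olcs, key=lambda c: c.level)
            return Classification("SharpSpike", outer.onset_s, outer.offset_s,
                                  float(outer.mean_freq_hz),
                                  float(np.log10(max(outer.level, 1e-300))))
        return None

    top_level, outer, top, mean_f = max(scored, key=lambda s: s[0])
    band_is_fr = mean_f >= 200.0
    # an OLC marks a spike under the HFO when it starts clearly earlier and
    # reaches the CLC group (overlap, or a gap below 50 ms: the CLC tightens
    # around the burst peak while the spike blob roots at low frequency)
    margin = olc_margin_ms * 1e-3
    on_spike = any(
        o.onset_s < outer.onset_s - margin
        and o.onset_s < outer.offset_s
        and outer.onset_s - o.offset_s < 0.05
        for o in spike_olcs)
    if on_spike:
        klass = "fRonS" if band_is_fr else "RonS"
    else:
        klass = "fRonO" if band_is_fr else "RonO"
    return Classification(klass, outer.onset_s, outer.offset_s,
                          float(top.mean_freq_hz),
                          float(np.log10(max(top_level, 1e-300))))


def crop_tfmap(tf: TFMap, t_lo: float, t_hi: float) -> TFMap:
    """Restrict a map to a time window (keeps wavelet edges out of the crop)."""
    m = (tf.times >= t_lo) & (tf.times <= t_hi)
    if m.sum() < 8:
        raise ValueError("crop window too narrow")
    return TFMap(power=tf.power[:, m], freqs=tf.freqs, times=tf.times[m],
                 channel=tf.channel,
                 valid=tf.valid[m] if tf.valid is not None else None)


def classify_all(rec: IEEGRecording, candidates: list[CandidateEvent],
                 cfg: AnalysisConfig | None = None) -> list[HfoEvent]:
    """Window, transform and classify every stage-1 candidate; deduplicate.

    The wavelet transform runs on a +-500 ms window (padding against edge
    artifacts) but the contour analysis is restricted to the candidate's own
    neighbourhood, so the 0.2-of-max threshold reflects this event rather
    than a stronger neighbour in the same window.
    """
    cfg = cfg or AnalysisConfig()
    fs = rec.fs
    half = cfg.classify_halfwin_ms * 1e-3
    raw: list[tuple[Classification, CandidateEvent]] = []
    for cand in candidates:
        ci = rec.channel_labels.index(cand.channel)
        center = 0.5 * (cand.onset_s + cand.offset_s)
        i0 = max(int((center - half) * fs), 0)
        i1 = min(int((center + half) * fs), rec.samples.shape[1])
        if i1 - i0 < 256:
            continue
        tf = wavelet_tfr(rec.samples[ci, i0:i1], fs, cfg, channel=cand.channel,
                         t0=i0 / fs)
        try:
            tfc = crop_tfmap(tf, cand.onset_s - 0.1, cand.offset_s + 0.1)
        except ValueError:
            continue
        cs = extract_contours(tfc, cfg=cfg)
        res = classify_event(cs, cfg)
        if res is not None:
            raw.append((res, cand))

    # deduplicate: keep the strongest of same-channel same-class overlaps and
    # drop sharp spikes swallowed by an HFO-on-spike event
    raw.sort(key=lambda rc: -rc[0].log10_power)
    kept: list[tuple[Classification, str]] = []
    for res, cand in raw:
        dup = False
        for kres, kch in kept:
            if kch != cand.channel:
                continue
            ov = (min(res.offset_s, kres.offset_s)
                  - max(res.onset_s, kres.onset_s))
            minlen = max(min(res.offset_s - res.onset_s,
                             kres.offset_s - kres.onset_s), 1e-9)
            same = kres.klass == res.klass
            swallowed = (res.klass == "SharpSpike"
                         and kres.klass in ("fRonS", "RonS"))
            if ov > 0.5 * minlen and (same or swallowed):
                dup = True
                break
        if not dup:
            kept.append((res, cand.channel))
    events = [HfoEvent(patient_id=rec.patient_id, channel=ch, klass=r.klass,
                       onset_s=r.onset_s, offset_s=r.offset_s,
                       peak_freq_hz=r.peak_freq_hz, log10_power=r.log10_power)
              for r, ch in kept]
    events.sort(key=lambda e: (e.channel, e.onset_s))
    return events
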