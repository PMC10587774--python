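"""Readers/writers for on-disk artifacts and the canonical in-memory data model.

All times are seconds unless a column name says ``_ms``.  Intervals are
half-open ``[start, end)``; sample ``i`` covers ``[i/fs, (i+1)/fs)``.

iEEG is exchanged as 16-bit EDF.  Reading goes through :mod:`mne`; writing is
done by a small EDF writer below because the analysis only needs plain
continuous multichannel records with one sampling rate.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: the five-event vocabulary of the classifier
EVENT_CLASSES = ("fRonO", "RonO", "fRonS", "RonS", "SharpSpike")

#: classes that count as epileptiform spikes
SPIKE_CLASSES = ("fRonS", "RonS", "SharpSpike")

EVENT_COLUMNS = [
    "patient_id", "channel", "class", "onset_s", "offset_s", "peak_freq_hz",
    "log10_power", "duration_ms", "prespike", "latency_to_spike_ms",
    "followed_fRonO", "followed_RonO",
]


@dataclass
class IEEGRecording:
    """Multichannel iEEG in microvolts with artifact-free epochs per channel."""

    samples: np.ndarray          # (n_channels, n_samples), float, µV
    fs: float                    # Hz
    channel_labels: list[str]
    patient_id: str = "P00"
    #: per-channel list of (start_s, end_s) artifact-free intervals
    epochs: dict[str, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError("channel_labels length must match samples rows")
        dur = self.duration_s
        if not self.epochs:
            self.epochs = {ch: [(0.0, dur)] for ch in self.channel_labels}
        for ch, ivals in self.epochs.items():
            ivals.sort()
            for (a, b), (c, _) in zip(ivals, ivals[1:]):
                if c < b:
                    raise ValueError(f"overlapping epochs on channel {ch}")
            for a, b in ivals:
                if a < 0 or b > dur + 1e-9 or b <= a:
                    raise ValueError(f"epoch ({a},{b}) outside [0,{dur}] on {ch}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.samples[self.channel_labels.index(label)]


@dataclass
class ElectrodeTable:
    """Contact coordinates (mm) plus clinician SOZ / resection flags."""

    table: pd.DataFrame  # patient_id, channel, x_mm, y_mm, z_mm, soz, resected

    REQUIRED = ("patient_id", "channel", "x_mm", "y_mm", "z_mm", "soz", "resected")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"electrode table missing column {col!r}")
        coords = self.table[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("electrode coordinates must be finite")
        for col in ("soz", "resected"):
            vals = set(self.table[col].astype(int).unique())
            if not vals <= {0, 1}:
                raise ValueError(f"{col} flags must be 0/1, got {sorted(vals)}")
            self.table[col] = self.table[col].astype(int)

    def coords(self, patient_id: str, channels: list[str]) -> np.ndarray:
        sub = self.table[self.table.patient_id == patient_id].set_index("channel")
        return sub.loc[channels, ["x_mm", "y_mm", "z_mm"]].to_numpy(float)

    def flags(self, patient_id: str, which: str) -> dict[str, int]:
        sub = self.table[self.table.patient_id == patient_id]
        return dict(zip(sub.channel, sub[which].astype(int)))


@dataclass
class UnitSpikeTrain:
    """Action-potential times of one sorted unit, tied to one contact bundle."""

    unit_id: str
    patient_id: str
    contact: str
    unit_type: str               # "single" | "multi"
    ap_times_ms: np.ndarray      # sorted, non-negative

    def __post_init__(self) -> None:
        t = np.asarray(self.ap_times_ms, dtype=float)
        if t.size and t.min() < 0:
            raise ValueError("AP times must be non-negative")
        if np.any(np.diff(t) < 0):
            logger.warning("unsorted AP times for unit %s; sorting", self.unit_id)
            t = np.sort(t)
        self.ap_times_ms = t
        if self.unit_type not in ("single", "multi"):
            raise ValueError(f"unknown unit_type {self.unit_type!r}")


@dataclass
class HfoEvent:
    """One classified inter-ictal event (HFO on oscillation/spike, or sharp spike)."""

    patient_id: str
    channel: str
    klass: str
    onset_s: float
    offset_s: float
    peak_freq_hz: float
    log10_power: float
    # coincidence flags, filled by the coincidence module
    prespike: int = 0
    latency_to_spike_ms: float = math.nan
    followed_fRonO: int = 0
    followed_RonO: int = 0

    def __post_init__(self) -> None:
        if self.klass not in EVENT_CLASSES:
            raise ValueError(f"unknown event class {self.klass!r}")
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must exceed onset")

    @property
    def duration_ms(self) -> float:
        return (self.offset_s - self.onset_s) * 1e3


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def write_edf(path: str | os.PathLike, rec: IEEGRecording) -> None:
    """Write a recording as a plain continuous 16-bit EDF file (µV).

    One data record per second; physical range chosen per channel to cover the
    data symmetrically, so quantization error is at most one least-significant
    bit of the 16-bit code.
    """
    x = rec.samples
    n_ch, n_samp = x.shape
    fs = rec.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(fs)                      # samples per 1 s record
    n_rec = int(np.ceil(n_samp / spr))
    pad = n_rec * spr - n_samp
    if pad:
        x = np.pad(x, ((0, 0), (0, pad)), mode="edge")

    phys_max = np.maximum(np.abs(x).max(axis=1), 1.0)
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768

    def _f(s: str, n: int) -> bytes:
        b = str(s)[:n].encode("ascii")
        return b + b" " * (n - len(b))

    hdr = b"".join([
        _f("0", 8), _f("X X X X", 80), _f("X X X", 80),
        _f("01.01.00", 8), _f("00.00.00", 8),
        _f(str(256 * (1 + n_ch)), 8), _f("", 44),
        _f(str(n_rec), 8), _f("1", 8), _f(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_f(lbl, 16) for lbl in rec.channel_labels),
        b"".join(_f("iEEG", 80) for _ in range(n_ch)),
        b"".join(_f("uV", 8) for _ in range(n_ch)),
        b"".join(_f(f"{v:.3f}"[:8], 8) for v in phys_min),
        b"".join(_f(f"{v:.3f}"[:8], 8) for v in phys_max),
        b"".join(_f(str(dig_min), 8) for _ in range(n_ch)),
        b"".join(_f(str(dig_max), 8) for _ in range(n_ch)),
        b"".join(_f("", 80) for _ in range(n_ch)),
        b"".join(_f(str(spr), 8) for _ in range(n_ch)),
        b"".join(_f("", 32) for _ in range(n_ch)),
    ])
    # re-read the rounded physical bounds so scaling matches the header exactly
    pmin = np.array([float(f"{v:.3f}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.3f}"[:8]) for v in phys_max])
    scale = (dig_max - dig_min) / (pmax - pmin)
    dig = np.rint((x - pmin[:, None]) * scale[:, None] + dig_min)
    dig = np.clip(dig, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(hdr + sig)
        for r in range(n_rec):
            fh.write(dig[:, r * spr:(r + 1) * spr].tobytes())


def read_edf(path: str | os.PathLike) -> IEEGRecording:
    """Read an EDF file into a µV-scaled :class:`IEEGRecording` (via MNE)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs_set = {int(round(raw.info["sfreq"]))}
    if len(fs_set) != 1:
        raise ValueError("mixed sampling rates are not supported")
    data = raw.get_data() * 1e6      # MNE returns volts
    if data.shape[0] == 0:
        raise ValueError("EDF file contains no channels")
    pid = Path(path).stem
    return IEEGRecording(samples=data, fs=float(raw.info["sfreq"]),
                         channel_labels=list(raw.ch_names), patient_id=pid)


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def read_tables(dirpath: str | os.PathLike):
    """Read ``electrodes.csv``, ``units.csv`` and ``epochs.csv`` from a cohort dir.

    Returns ``(ElectrodeTable, list[UnitSpikeTrain], epochs)`` where ``epochs``
    maps ``(patient_id, channel) -> [(start_s, end_s), ...]``.
    """
    d = Path(dirpath)
    elec = ElectrodeTable(pd.read_csv(d / "electrodes.csv",
                                      dtype={"patient_id": str, "channel": str}))

    units: list[UnitSpikeTrain] = []
    upath = d / "units.csv"
    udf = pd.read_csv(upath, dtype={"patient_id": str, "unit_id": str, "contact": str})
    if len(udf):
        need = {"patient_id", "unit_id", "contact", "unit_type", "spike_time_ms"}
        if not need <= set(udf.columns):
            raise ValueError(f"units.csv missing columns {need - set(udf.columns)}")
        for (pid, uid, contact, utype), grp in udf.groupby(
                ["patient_id", "unit_id", "contact", "unit_type"], sort=True):
            units.append(UnitSpikeTrain(uid, pid, contact, utype,
                                        np.sort(grp.spike_time_ms.to_numpy(float))))

    edf_ = pd.read_csv(d / "epochs.csv", dtype={"patient_id": str, "channel": str})
    epochs: dict[tuple[str, str], list[tuple[float, float]]] = {}
    for row in edf_.itertuples():
        epochs.setdefault((row.patient_id, row.channel), []).append(
            (float(row.start_s), float(row.end_s)))
    for v in epochs.values():
        v.sort()
    return elec, units, epochs


def events_to_frame(events: list[HfoEvent]) -> pd.DataFrame:
    rows = [{
        "patient_id": e.patient_id, "channel": e.channel, "class": e.klass,
        "onset_s": e.onset_s, "offset_s": e.offset_s,
        "peak_freq_hz": e.peak_freq_hz, "log10_power": e.log10_power,
        "duration_ms": e.duration_ms, "prespike": e.prespike,
        "latency_to_spike_ms": e.latency_to_spike_ms,
        "followed_fRonO": e.followed_fRonO, "followed_RonO": e.followed_RonO,
    } for e in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def frame_to_events(df: pd.DataFrame) -> list[HfoEvent]:
    out = []
    for r in df.itertuples():
        out.append(HfoEvent(
            patient_id=str(r.patient_id), channel=str(r.channel), klass=r[3],
            onset_s=float(r.onset_s), offset_s=float(r.offset_s),
            peak_freq_hz=float(r.peak_freq_hz), log10_power=float(r.log10_power),
            prespike=int(r.prespike),
            latency_to_spike_ms=float(r.latency_to_spike_ms),
            followed_fRonO=int(r.followed_fRonO),
            followed_RonO=int(r.followed_RonO)))
    return out


def write_events(events: list[HfoEvent], path: str | os.PathLike) -> None:
    """Write classified events as CSV (empty list gives a header-only file)."""
    events_to_frame(events).to_csv(path, index=False, float_format="%.6f")


def read_events(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "channel": str})
    bad = set(df["class"].unique()) - set(EVENT_CLASSES)
    if bad:
        raise ValueError(f"unknown event classes in {path}: {sorted(bad)}")
    return df
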