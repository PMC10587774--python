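"""Resection-cohort metrics: SOZ/resection ratios and rate-distance radii.

The rate-distance graph weights each contact pair by the mean of their event
rates (events/min; fRonS plus fRonO with peak frequency above 350 Hz) times
their Euclidean distance in mm; pairs with zero weight carry no edge.  The
graph radius is the minimum node eccentricity of that weight matrix read
directly as a distance matrix, and
``radius_difference = sqrt(radius_all - radius_resected)`` quantifies
residual fast-ripple-generating tissue after resection (smaller = less).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ElectrodeTable


@dataclass
class RateDistanceGraph:
    channels: list[str]
    weights: np.ndarray      # symmetric, zero diagonal; NaN where no edge
    rates: np.ndarray        # events/min per contact


@dataclass
class LocalizationMetrics:
    patient_id: str
    soz_ratio: dict[str, float]
    resection_ratio: dict[str, float]
    radius_all: float
    radius_resected: float
    radius_difference: float
    negative_argument: bool = False


def event_ratios(events: pd.DataFrame, electrodes: ElectrodeTable,
                 patient_id: str, region: str = "soz",
                 mask: pd.Series | None = None) -> float:
    """Share of (optionally masked) events on flagged contacts, within patient.

    Returns NaN when the patient has no qualifying events.
    """
    if region not in ("soz", "resected"):
        raise ValueError("region must be 'soz' or 'resected'")
    ev = events[events.patient_id == patient_id]
    if mask is not None:
        ev = ev[mask.reindex(ev.index, fill_value=False)]
    if not len(ev):
        return float("nan")
    flags = electrodes.flags(patient_id, region)
    on = ev.channel.map(flags).fillna(0).astype(int)
    return float(on.sum() / len(ev))


def fr_localizing_mask(events: pd.DataFrame, fr_freq_cut_hz: float = 350.0) -> pd.Series:
    """Events entering the rate-distance graph: fRonS, plus fRonO above the cut."""
    return (events["class"] == "fRonS") | (
        (events["class"] == "fRonO") & (events.peak_freq_hz > fr_freq_cut_hz))


def rate_distance_matrix(events: pd.DataFrame, electrodes: ElectrodeTable,
                         patient_id: str, minutes: float,
                         subset: str = "all",
                         fr_freq_cut_hz: float = 350.0) -> RateDistanceGraph:
    """Rate-distance adjacency over a patient's contacts (or resected subset)."""
    sub = electrodes.table[electrodes.table.patient_id == patient_id]
    if subset == "resected":
        sub = sub[sub.resected == 1]
    elif subset != "all":
        raise ValueError("subset must be 'all' or 'resected'")
    channels = list(sub.channel)
    if len(channels) < 2:
        raise ValueError("need at least two contacts")
    ev = events[(events.patient_id == patient_id)
                & fr_localizing_mask(events, fr_freq_cut_hz)
                & events.channel.isin(channels)]
    counts = ev.groupby("channel").size()
    rates = np.array([counts.get(ch, 0) / minutes for ch in channels])
    xyz = electrodes.coords(patient_id, channels)
    diff = xyz[:, None, :] - xyz[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    w = 0.5 * (rates[:, None] + rates[None, :]) * dist
    np.fill_diagonal(w, 0.0)
    # an edge requires both contacts to generate qualifying events: contacts
    # with zero rate are isolated and drop out of the radius
    both = (rates[:, None] > 0) & (rates[None, :] > 0)
    w = np.where((both & (w > 0)) | np.eye(len(channels), dtype=bool), w, np.nan)
    return RateDistanceGraph(channels=channels, weights=w, rates=rates)


def graph_radius(g: RateDistanceGraph | np.ndarray) -> float:
    """Minimum eccentricity of the weight matrix read as a distance matrix.

    Absent edges (NaN) are excluded from eccentricities; nodes with no finite
    off-diagonal entry do not contribute.
    """
    w = g.weights if isinstance(g, RateDistanceGraph) else np.asarray(g, float)
    n = w.shape[0]
    if n < 2:
        raise ValueError("need at least two nodes")
    ecc = []
    for i in range(n):
        row = np.delete(w[i], i)
        row = row[np.isfinite(row)]
        if row.size:
            ecc.append(row.max())
    if not ecc:
        raise ValueError("graph has no finite edges")
    return float(min(ecc))


def radius_difference(r_all: float, r_resected: float) -> tuple[float, bool]:
    """sqrt(r_all - r_resected); (NaN, True) when the argument is negative."""
    if r_all < r_resected:
        return float("nan"), True
    return float(np.sqrt(r_all - r_resected)), False


def patient_metrics(events: pd.DataFrame, electrodes: ElectrodeTable,
                    patient_id: str, minutes: float,
                    fr_freq_cut_hz: float = 350.0) -> LocalizationMetrics:
    ev = events[events.patient_id == patient_id]
    prespike_fr = (ev["class"] == "fRonO") & (ev.prespike == 1)
    solitary_fr = (ev["class"] == "fRonO") & (ev.prespike == 0)
    spikes = ev["class"].isin(("fRonS", "RonS", "SharpSpike"))
    soz_ratio, res_ratio = {}, {}
    for name, m in (("fRonO", ev["class"] == "fRonO"),
                    ("fRonO_prespike", prespike_fr),
                    ("fRonO_solitary", solitary_fr),
                    ("spikes", spikes)):
        soz_ratio[name] = event_ratios(ev, electrodes, patient_id, "soz", m)
        res_ratio[name] = event_ratios(ev, electrodes, patient_id, "resected", m)
    try:
        r_all = graph_radius(rate_distance_matrix(
            events, electrodes, patient_id, minutes, "all", fr_freq_cut_hz))
        r_res = graph_radius(rate_distance_matrix(
            events, electrodes, patient_id, minutes, "resected", fr_freq_cut_hz))
        rdiff, neg = radius_difference(r_all, r_res)
    except ValueError:
        r_all = r_res = rdiff = float("nan")
        neg = False
    return LocalizationMetrics(patient_id, soz_ratio, res_ratio,
                               r_all, r_res, rdiff, neg)


def cohort_report(metrics: list[LocalizationMetrics],
                  outcomes: dict[str, int]) -> pd.DataFrame:
    """Compare localization metrics between Engel-1 and >Engel-1 patients.

    *outcomes* maps patient_id to Engel class (1 = seizure-free).  Wilcoxon
    rank-sum statistics are reported per metric; requires at least two
    patients per outcome group.
    """
    rows = []
    for m in metrics:
        rows.append({"patient_id": m.patient_id,
                     "engel": outcomes[m.patient_id],
                     "soz_ratio_prespike": m.soz_ratio["fRonO_prespike"],
                     "soz_ratio_solitary": m.soz_ratio["fRonO_solitary"],
                     "resection_ratio_fRonO": m.resection_ratio["fRonO"],
                     "radius_difference": m.radius_difference})
    df = pd.DataFrame(rows)
    free = df[df.engel == 1]
    notfree = df[df.engel > 1]
    if len(free) < 2 or len(notfree) < 2:
        raise ValueError("need at least two patients per outcome group")
    out = []
    for col in ("soz_ratio_prespike", "soz_ratio_solitary",
                "resection_ratio_fRonO", "radius_difference"):
        a = free[col].dropna()
        b = notfree[col].dropna()
        stat, p = stats.ranksums(a, b) if len(a) >= 2 and len(b) >= 2 \
            else (np.nan, np.nan)
        out.append({"metric": col, "median_seizure_free": float(a.median()),
                    "median_not_free": float(b.median()),
                    "ranksum_stat": float(stat), "ranksum_p": float(p)})
    return pd.DataFrame(out)
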