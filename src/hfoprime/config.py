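"""Run configuration: synthetic-cohort parameters and analysis parameters.

Both blocks serialize to a flat YAML key-value file so a whole run is
reproducible from one plain-text artifact.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class SynthConfig:
    """Parameters of the synthetic iEEG cohort generator.

    Rates are per contact per minute.  ``p_prime`` is the probability that an
    epileptiform spike is preceded by a fast ripple on oscillation (fRonO) at
    a latency drawn uniformly on (0, 300] ms; ``power_gain_prespike``
    multiplies the amplitude of those priming fRonO.  ``snr_db`` is the
    in-band event-to-background amplitude ratio.  Unit trains are
    inhomogeneous Poisson with in-event rate
    ``unit_base_rate * (1 + unit_gain_per_log10power * log10(power))``.
    """

    n_patients: int = 1
    n_contacts_per_patient: int = 12
    recording_minutes: float = 10.0
    fs_ieeg: float = 2000.0
    rate_fRonO: float = 1.5          # events/min/contact
    rate_RonO: float = 2.0
    rate_spike: float = 3.0          # all epileptiform spikes combined
    # spike subtype split (fRonS / RonS / sharp spike without HFO)
    p_fRonS: float = 0.2
    p_RonS: float = 0.7
    p_prime: float = 0.1
    power_gain_prespike: float = 2.0
    prime_latency_lock_ms: float = 0.0   # >0: priming latency fixed below this (spike-locked mode)
    soz_priming_enrichment: float = 1.0  # relative priming probability on SOZ contacts
    soz_spike_enrichment: float = 1.0    # relative spike rate on SOZ contacts
    soz_fro_enrichment: float = 1.0      # relative background fRonO rate on SOZ contacts
    # focal topology: the non-SOZ share of spikes and background fRonO falls on
    # a compact remote secondary cluster instead of spreading over all contacts
    focal_topology: bool = False
    secondary_focus_fraction: float = 0.15
    nonsoz_suppression: float = 0.0      # P(drop background fRonO <300 ms before a non-SOZ spike)
    unit_base_rate: float = 5.0          # Hz
    unit_gain_per_log10power: float = 0.5
    unit_spike_gain: float = 2.0         # rate multiplier during the sharp transient
    n_units_per_contact: int = 2
    snr_db: float = 15.0
    spike_snr_db: float = 14.0           # sharp-transient peak vs broadband background sd
    soz_fraction: float = 0.25
    resected_fraction: float = 0.25
    resection_coverage: float = 1.0      # fraction of SOZ contacts inside the resection
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("rate_fRonO", "rate_RonO", "rate_spike", "unit_base_rate"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")
        for f in ("p_prime", "p_fRonS", "p_RonS", "soz_fraction",
                  "resected_fraction", "nonsoz_suppression"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must lie in [0, 1], got {v}")
        if self.p_fRonS + self.p_RonS > 1.0 + 1e-12:
            raise ValueError("p_fRonS + p_RonS must not exceed 1")
        if self.fs_ieeg < 1200.0:
            raise ValueError("fs_ieeg must be >= 1200 Hz (Nyquist for 600 Hz)")


@dataclass
class AnalysisConfig:
    """Analysis parameters shared across the pipeline stages."""

    # stage-1 detection
    z_hi: float = 3.0                # envelope peak threshold (MAD-scaled z)
    spk_z_hi: float = 6.0            # sharp-transient band threshold
    z_mid: float = 1.4               # span over which oscillation cycles count
    z_lo: float = 1.0                # boundary extension threshold
    min_cycles: float = 3.0
    merge_gap_ms: float = 10.0
    z_art: float = 8.0               # broadband artifact threshold
    artifact_guard_ms: float = 50.0
    slew_uv_per_ms: float = 300.0
    # stage-2 wavelet classification
    n_cycles: float = 7.0
    freq_lo_hz: float = 60.0
    freq_hi_hz: float = 650.0
    n_freqs: int = 64
    n_contour_levels: int = 10
    min_clc_levels: int = 4          # ladder levels a CLC group must span
    classify_halfwin_ms: float = 500.0
    spike_root_hz: float = 80.0      # an OLC qualifies as a spike only if rooted below this
    # firing-rate trials
    window_ms: float = 2000.0
    kernel_ms: float = 100.0         # Gaussian sigma
    baseline_ms: float = 750.0
    rate_fs_hz: float = 40.0
    alpha_unit: float = 0.001
    # coincidence
    prespike_ms: float = 300.0
    n_surrogates: int = 500
    # localization
    fr_freq_cut_hz: float = 350.0


def save_config(path, synth: SynthConfig, analysis: AnalysisConfig | None = None) -> None:
    blob = {"synth": dataclasses.asdict(synth)}
    if analysis is not None:
        blob["analysis"] = dataclasses.asdict(analysis)
    Path(path).write_text(yaml.safe_dump(blob, sort_keys=True))


def load_config(path) -> tuple[SynthConfig, AnalysisConfig]:
    blob = yaml.safe_load(Path(path).read_text())
    synth = SynthConfig(**blob.get("synth", {}))
    analysis = AnalysisConfig(**blob.get("analysis", {}))
    return synth, analysis
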