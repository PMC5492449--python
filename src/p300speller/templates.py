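"""ERP component templates and noise model for the synthetic EEG generator.

The generator injects two condition-dependent components at every target
flash: an early posterior negativity (N1, latency 130-200 ms) and a late
centro-parietal positivity (P300, latency 250-450 ms).  Reference amplitudes
and latencies per channel and STIM x COLOR condition are the grand-average
values observed with slow stimulation timing; they double as the default
generative parameters so that downstream peak extraction can be validated by
parameter recovery.

Component waveforms are Hann (raised-cosine) bumps parameterized by
(amplitude uV, latency ms, width ms): simple, smooth, and with the peak value
exactly equal to the nominal amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .design import EEG_CHANNELS
from .exceptions import ConfigError

# N1 (amplitude uV, latency ms) per condition label and channel; training phase.
N1_TRAINING = {
    "WH-CH": {"Fz": (-3.309, 185.156), "Cz": (-2.742, 181.250), "Pz": (-1.742, 177.344),
              "Oz": (-1.938, 185.156), "P3": (-2.226, 181.250), "P4": (-1.777, 181.250),
              "PO7": (-1.119, 192.969), "PO8": (-2.131, 181.250)},
    "GR-CH": {"Fz": (-3.325, 177.344), "Cz": (-3.253, 173.438), "Pz": (-1.778, 181.250),
              "Oz": (-2.167, 177.344), "P3": (-2.732, 181.250), "P4": (-3.835, 177.344),
              "PO7": (-1.618, 185.156), "PO8": (-2.110, 177.344)},
    "WH-IC": {"Fz": (-3.226, 169.531), "Cz": (-2.445, 177.344), "Pz": (-3.348, 173.438),
              "Oz": (-2.656, 177.344), "P3": (-3.314, 173.438), "P4": (-3.485, 181.250),
              "PO7": (-3.269, 173.438), "PO8": (-2.762, 181.250)},
    "GR-IC": {"Fz": (-2.439, 177.344), "Cz": (-2.014, 189.063), "Pz": (-4.621, 165.625),
              "Oz": (-1.251, 173.438), "P3": (-4.332, 177.344), "P4": (-2.568, 177.344),
              "PO7": (-3.731, 185.156), "PO8": (-3.007, 177.344)},
}

# Same layout for the performance phase.
N1_PERFORMANCE = {
    "WH-CH": {"Fz": (-4.037, 177.344), "Cz": (-3.473, 177.344), "Pz": (-4.122, 185.156),
              "Oz": (-1.244, 177.344), "P3": (-4.425, 181.250), "P4": (-3.046, 169.531),
              "PO7": (-1.351, 181.250), "PO8": (-3.610, 185.156)},
    "GR-CH": {"Fz": (-3.765, 177.344), "Cz": (-4.994, 189.063), "Pz": (-2.763, 196.875),
              "Oz": (-3.462, 189.063), "P3": (-3.144, 189.063), "P4": (-2.115, 185.156),
              "PO7": (-1.338, 196.875), "PO8": (-4.231, 181.250)},
    "WH-IC": {"Fz": (-2.213, 173.438), "Cz": (-5.153, 177.344), "Pz": (-2.020, 169.531),
              "Oz": (-1.367, 173.438), "P3": (-2.985, 173.438), "P4": (-2.909, 177.344),
              "PO7": (-2.264, 169.531), "PO8": (-2.148, 185.156)},
    "GR-IC": {"Fz": (-4.323, 173.438), "Cz": (-2.304, 177.344), "Pz": (-1.472, 177.344),
              "Oz": (-0.576, 185.156), "P3": (-1.576, 181.250), "P4": (-2.108, 181.250),
              "PO7": (-1.028, 189.063), "PO8": (-1.114, 196.875)},
}

# P300 (amplitude uV, latency ms) at Cz per condition, slow timing, training
# phase.  Other channels are scaled by the centro-parietal topography below.
P300_CZ = {
    "WH-CH": (2.781, 439.063),
    "GR-CH": (2.917, 423.438),
    "WH-IC": (5.999, 392.188),
    "GR-IC": (4.612, 407.813),
}

# Relative P300 scalp gain (Cz maximum, falling off anteriorly/posteriorly).
P300_TOPOGRAPHY = {"Fz": 0.6, "Cz": 1.0, "P3": 0.8, "Pz": 0.9, "P4": 0.8,
                   "PO7": 0.5, "Oz": 0.5, "PO8": 0.5}

N1_WINDOW_MS = (130.0, 200.0)
P300_WINDOW_MS = (250.0, 450.0)


@dataclass(frozen=True)
class ComponentTemplate:
    """One ERP component: a Hann bump of given amplitude, latency and width."""

    amplitude_uv: float
    latency_ms: float
    width_ms: float

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Component value at post-onset times ``t_ms`` (vectorized)."""
        d = np.asarray(t_ms, dtype=float) - self.latency_ms
        out = np.zeros_like(d)
        inside = np.abs(d) <= self.width_ms / 2.0
        out[inside] = self.amplitude_uv * 0.5 * (
            1.0 + np.cos(2.0 * np.pi * d[inside] / self.width_ms)
        )
        return out


@dataclass(frozen=True)
class ChannelTemplate:
    n1: ComponentTemplate
    p300: ComponentTemplate

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        return self.n1.evaluate(t_ms) + self.p300.evaluate(t_ms)


@dataclass(frozen=True)
class ErpTemplateSet:
    """Per-channel N1 + P300 templates for one condition and phase.

    ``nontarget_fraction`` scales the early visual response added at
    non-target flashes (a fraction of the target N1, no P300): non-target
    flashes still drive visual cortex, just without the attention-dependent
    components.
    """

    channels: dict[str, ChannelTemplate]
    condition_label: str = ""
    phase: str = "training"
    nontarget_fraction: float = 0.25

    def __post_init__(self):
        lo, hi = N1_WINDOW_MS
        for name, tpl in self.channels.items():
            if tpl.n1.amplitude_uv > 0:
                raise ConfigError(f"N1 amplitude must be <= 0 on {name}")
            if tpl.p300.amplitude_uv < 0:
                raise ConfigError(f"P300 amplitude must be >= 0 on {name}")
            if not lo <= tpl.n1.latency_ms <= hi:
                raise ConfigError(f"N1 latency outside {N1_WINDOW_MS} on {name}")
            if not P300_WINDOW_MS[0] <= tpl.p300.latency_ms <= P300_WINDOW_MS[1]:
                raise ConfigError(f"P300 latency outside {P300_WINDOW_MS} on {name}")

    @classmethod
    def from_reference(
        cls,
        stim: str,
        color: str,
        phase: str = "training",
        n1_width_ms: float = 80.0,
        p300_width_ms: float = 200.0,
        amplitude_scale: float = 1.0,
        nontarget_fraction: float = 0.25,
    ) -> "ErpTemplateSet":
        """Templates seeded from the slow-timing grand-average reference values."""
        label = f"{'WH' if color == 'white' else 'GR'}-{stim}"
        n1_table = N1_TRAINING if phase == "training" else N1_PERFORMANCE
        cz_amp, cz_lat = P300_CZ[label]
        channels = {}
        for ch in EEG_CHANNELS:
            n1_amp, n1_lat = n1_table[label][ch]
            channels[ch] = ChannelTemplate(
                n1=ComponentTemplate(n1_amp * amplitude_scale, n1_lat, n1_width_ms),
                p300=ComponentTemplate(cz_amp * P300_TOPOGRAPHY[ch] * amplitude_scale,
                                       cz_lat, p300_width_ms),
            )
        return cls(channels=channels, condition_label=label, phase=phase,
                   nontarget_fraction=nontarget_fraction)

    def scaled(self, factor: float) -> "ErpTemplateSet":
        """Uniformly rescale all component amplitudes (SNR manipulation)."""
        channels = {
            name: ChannelTemplate(
                n1=replace(tpl.n1, amplitude_uv=tpl.n1.amplitude_uv * factor),
                p300=replace(tpl.p300, amplitude_uv=tpl.p300.amplitude_uv * factor),
            )
            for name, tpl in self.channels.items()
        }
        return replace(self, channels=channels)


@dataclass(frozen=True)
class NoiseModel:
    """Stochastic background of the synthetic recording.

    Background EEG is band-limited (0.5-30 Hz, matching the acquisition
    filter) Gaussian noise at ``background_rms_uv``.  EOG electrodes carry a
    smaller instrumental noise plus ocular events: blinks (vertical bipolar
    derivation) and saccade-like deflections (horizontal derivation), mixed
    into the EEG channels through fixed propagation coefficients that decay
    from frontal to occipital sites.  In fast mode, a flicker-locked
    sinusoid of ``ssvep_amplitude_uv`` is added over posterior channels.
    """

    background_rms_uv: float = 8.0
    eog_background_rms_uv: float = 2.0
    ssvep_amplitude_uv: float = 1.5
    blink_rate_hz: float = 0.15
    blink_amplitude_uv: float = 120.0
    blink_width_s: float = 0.25
    saccade_rate_hz: float = 0.1
    saccade_amplitude_uv: float = 30.0
    saccade_width_s: float = 0.4
    veog_mixing: dict[str, float] = field(default_factory=lambda: {
        "Fz": 0.15, "Cz": 0.08, "P3": 0.04, "Pz": 0.04, "P4": 0.04,
        "PO7": 0.02, "Oz": 0.02, "PO8": 0.02})
    heog_mixing: dict[str, float] = field(default_factory=lambda: {
        "Fz": 0.05, "Cz": 0.03, "P3": 0.02, "Pz": 0.01, "P4": 0.02,
        "PO7": 0.01, "Oz": 0.01, "PO8": 0.01})
    ssvep_topography: dict[str, float] = field(default_factory=lambda: {
        "Oz": 1.0, "PO7": 0.6, "PO8": 0.6, "Pz": 0.3})
    seed: int = 0

    def __post_init__(self):
        if self.background_rms_uv < 0 or self.eog_background_rms_uv < 0:
            raise ConfigError("noise rms must be >= 0")
        for coefs in (self.veog_mixing, self.heog_mixing):
            if not all(np.isfinite(list(coefs.values()))):
                raise ConfigError("EOG mixing coefficients must be finite")

    def with_(self, **kwargs) -> "NoiseModel":
        return replace(self, **kwargs)
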