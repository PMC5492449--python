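"""Synthetic continuous EEG/EOG generator for speller sessions.

Given a flash schedule, a set of ERP templates and a noise model, the
generator produces a 12-channel continuous record (8 EEG + 4 EOG electrodes
at 256 Hz, physical units uV) with the statistical structure the analysis
pipeline assumes:

* every target flash adds the channel-wise N1 + P300 template time-locked to
  its onset; non-target flashes add an attenuated early visual response;
* fast-mode sessions carry a flicker-locked sinusoid at the steady-state
  frequency over posterior channels;
* blinks and saccades appear on the EOG electrodes and propagate into the
  EEG through the noise model's mixing coefficients;
* band-limited (0.5-30 Hz) Gaussian background noise emulates the
  acquisition filter chain.

Everything is reproducible from the noise model's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .design import EEG_CHANNELS, EOG_CHANNELS, FlashSchedule
from .exceptions import ConfigError
from .templates import ComponentTemplate, ErpTemplateSet, NoiseModel


@dataclass
class Recording:
    """A continuous multichannel record in uV.

    ``data`` is (n_channels, n_samples); ``meta`` holds free-form header
    fields (condition labels, generator parameters).
    """

    data: np.ndarray
    ch_names: list[str]
    sampling_rate_hz: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.ch_names):
            raise ConfigError("data must be (n_channels, n_samples) matching ch_names")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def pick(self, names: list[str]) -> "Recording":
        idx = [self.ch_names.index(n) for n in names]
        return Recording(self.data[idx].copy(), list(names),
                         self.sampling_rate_hz, dict(self.meta))


def _band_limited_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                        fs: float, rms: float) -> np.ndarray:
    """White Gaussian noise band-passed to 0.5-30 Hz and scaled to target rms."""
    if rms == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    sos = sp_signal.butter(4, [0.5, 30.0], btype="bandpass", fs=fs, output="sos")
    shaped = sp_signal.sosfiltfilt(sos, white, axis=1)
    std = shaped.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return shaped * (rms / std)


def _add_bump(trace: np.ndarray, fs: float, t0_s: float,
              component: ComponentTemplate, scale: float = 1.0) -> None:
    """Add a Hann component time-locked to ``t0_s`` into a 1-D trace (in place)."""
    half = component.width_ms / 2000.0
    center = t0_s + component.latency_ms / 1000.0
    j0 = max(0, int(np.ceil((center - half) * fs)))
    j1 = min(trace.shape[0] - 1, int(np.floor((center + half) * fs)))
    if j1 < j0:
        return
    t_ms = (np.arange(j0, j1 + 1) / fs - t0_s) * 1000.0
    trace[j0:j1 + 1] += scale * component.evaluate(t_ms)


def _ocular_events(rng: np.random.Generator, n_samples: int, fs: float,
                   rate_hz: float, amp: float, width_s: float,
                   signed: bool) -> np.ndarray:
    """Poisson train of Hann-shaped ocular deflections (blinks or saccades)."""
    out = np.zeros(n_samples)
    duration = n_samples / fs
    n_events = rng.poisson(rate_hz * duration)
    onsets = rng.uniform(0.0, duration, size=n_events)
    comp_width = width_s * 1000.0
    for onset in onsets:
        sign = rng.choice([-1.0, 1.0]) if signed else 1.0
        comp = ComponentTemplate(amplitude_uv=sign * amp, latency_ms=comp_width / 2.0,
                                 width_ms=comp_width)
        _add_bump(out, fs, onset, comp)
    return out


def synthesize_session_eeg(
    schedule: FlashSchedule,
    templates: ErpTemplateSet,
    noise: NoiseModel,
    padding_s: float = 1.5,
) -> tuple[Recording, pd.DataFrame]:
    """Render a flash schedule into a continuous 12-channel record.

    Returns the record and the flash-event table.  The record covers the
    schedule plus ``padding_s`` of tail so that the last 700 ms epoch fits.
    """
    cond = schedule.condition
    if templates.condition_label and templates.condition_label != cond.label:
        raise ConfigError(
            f"templates are for condition {templates.condition_label!r}, "
            f"schedule is {cond.label!r}")
    fs = schedule.config.sampling_rate_hz
    n_samples = int(np.ceil((schedule.duration_s + padding_s) * fs))
    rng = np.random.default_rng(noise.seed)

    eeg = _band_limited_noise(rng, len(EEG_CHANNELS), n_samples, fs,
                              noise.background_rms_uv)
    eog = _band_limited_noise(rng, len(EOG_CHANNELS), n_samples, fs,
                              noise.eog_background_rms_uv)

    # Evoked components, time-locked to each flash onset.
    for ci, ch in enumerate(EEG_CHANNELS):
        tpl = templates.channels[ch]
        for ev in schedule.events:
            if ev.is_target:
                _add_bump(eeg[ci], fs, ev.onset_s, tpl.n1)
                _add_bump(eeg[ci], fs, ev.onset_s, tpl.p300)
            elif templates.nontarget_fraction:
                _add_bump(eeg[ci], fs, ev.onset_s, tpl.n1,
                          scale=templates.nontarget_fraction)

    # Flicker-locked steady-state response in fast mode, phase-locked to the
    # first flash of each symbol's flashing block.
    if cond.speed == "fast" and noise.ssvep_amplitude_uv > 0:
        f_flicker = 1000.0 / schedule.config.soa_ms
        t = np.arange(n_samples) / fs
        ssvep = np.zeros(n_samples)
        events = schedule.to_frame()
        for _, block in events.groupby("symbol_index"):
            t_start = block["onset_s"].iloc[0]
            t_end = block["onset_s"].iloc[-1] + schedule.config.soa_ms / 1000.0
            mask = (t >= t_start) & (t < t_end)
            ssvep[mask] = np.sin(2.0 * np.pi * f_flicker * (t[mask] - t_start))
        for ch, gain in noise.ssvep_topography.items():
            eeg[EEG_CHANNELS.index(ch)] += noise.ssvep_amplitude_uv * gain * ssvep

    # Ocular activity: blinks on the vertical derivation, saccades on the
    # horizontal one; propagate into EEG via the mixing coefficients.
    veog_art = _ocular_events(rng, n_samples, fs, noise.blink_rate_hz,
                              noise.blink_amplitude_uv, noise.blink_width_s,
                              signed=False)
    heog_art = _ocular_events(rng, n_samples, fs, noise.saccade_rate_hz,
                              noise.saccade_amplitude_uv, noise.saccade_width_s,
                              signed=True)
    eog[EOG_CHANNELS.index("EOGa")] += 0.8 * veog_art
    eog[EOG_CHANNELS.index("EOGb")] += -0.2 * veog_art
    eog[EOG_CHANNELS.index("EOGl")] += 0.5 * heog_art
    eog[EOG_CHANNELS.index("EOGr")] += -0.5 * heog_art
    for ci, ch in enumerate(EEG_CHANNELS):
        eeg[ci] += noise.veog_mixing.get(ch, 0.0) * veog_art
        eeg[ci] += noise.heog_mixing.get(ch, 0.0) * heog_art

    data = np.vstack([eeg, eog])
    record = Recording(
        data=data,
        ch_names=list(EEG_CHANNELS) + list(EOG_CHANNELS),
        sampling_rate_hz=fs,
        meta={
            "stim": cond.stim, "color": cond.color, "speed": cond.speed,
            "phase": cond.phase, "seed": noise.seed, "units": "uV",
        },
    )
    return record, schedule.to_frame()
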