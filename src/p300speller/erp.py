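"""Condition-wise ERP averaging, N1/P300 peak extraction, Cz window means.

Peaks are measured on the 256 Hz epochs (before any down-sampling), so
every reported latency lies on the -100 ms-anchored grid with step
1000/256 = 3.90625 ms.  The N1 is the local maximal *negative* deflection
in 130-200 ms, the P300 the local maximal *positive* deflection in
250-450 ms; when the window contains no interior local extremum of the
required polarity, the windowed extremum is returned and flagged
``boundary``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, MontageError, WindowError
from .preprocess import EpochArray
from .templates import N1_WINDOW_MS, P300_WINDOW_MS

CZ_WINDOWS_MS = ((200.0, 250.0), (250.0, 300.0), (300.0, 350.0))


@dataclass
class ErpWaveform:
    """An averaged ERP for one channel (and bookkeeping of what was averaged)."""

    samples: np.ndarray
    times_ms: np.ndarray
    channel: str
    condition: str = ""
    n_trials: int = 0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.samples.shape != self.times_ms.shape:
            raise WindowError("waveform and time grid must have equal length")
        if self.n_trials < 1:
            raise DomainError("an ERP must average at least one trial")


@dataclass
class ErpPeak:
    component: str                 # 'N1' or 'P300'
    amplitude_uv: float
    latency_ms: float
    window_ms: tuple[float, float]
    channel: str
    condition: str = ""
    flags: frozenset[str] = field(default_factory=frozenset)


def average_erp(
    epochs: EpochArray,
    which: str = "target",
    condition: str = "",
) -> dict[str, ErpWaveform]:
    """Per-channel trial average of the target (or non-target) epochs."""
    if which == "target":
        mask = epochs.labels.astype(bool)
    elif which == "nontarget":
        mask = ~epochs.labels.astype(bool)
    elif which == "all":
        mask = np.ones(epochs.n_trials, dtype=bool)
    else:
        raise DomainError(f"unknown trial class {which!r}")
    n = int(mask.sum())
    if n == 0:
        raise DomainError(f"no {which} trials to average")
    mean = epochs.data[mask].mean(axis=0)
    return {
        ch: ErpWaveform(samples=mean[i], times_ms=epochs.times_ms, channel=ch,
                        condition=condition, n_trials=n)
        for i, ch in enumerate(epochs.ch_names)
    }


def grand_average(
    per_subject: list[dict[str, ErpWaveform]],
) -> dict[str, ErpWaveform]:
    """Unweighted mean across subjects of per-subject average waveforms.

    Channels missing for some subject are reported as missing (omitted from
    the output), never zero-filled.
    """
    if not per_subject:
        raise DomainError("no subject averages supplied")
    common = set(per_subject[0])
    for d in per_subject[1:]:
        common &= set(d)
    out = {}
    for ch in sorted(common):
        waves = [d[ch] for d in per_subject]
        grid = waves[0].times_ms
        for w in waves[1:]:
            if w.samples.shape != grid.shape or not np.allclose(w.times_ms, grid):
                raise WindowError(f"subject waveforms for {ch} are on different grids")
        out[ch] = ErpWaveform(
            samples=np.mean([w.samples for w in waves], axis=0),
            times_ms=grid, channel=ch, condition=waves[0].condition,
            n_trials=len(waves))
    return out


def extract_peak(
    erp: ErpWaveform,
    component: str,
    window_ms: tuple[float, float] | None = None,
) -> ErpPeak:
    """Most extreme deflection of the component's polarity inside the window.

    Interior local extrema (relative to immediate neighbours on the full
    waveform) are preferred; among equally extreme candidates the earliest
    latency wins and the result is flagged ``tie``.  If the window holds no
    interior local extremum of the right polarity, the windowed extremum is
    returned flagged ``boundary``.
    """
    if component == "N1":
        window = window_ms or N1_WINDOW_MS
        sign = -1.0
    elif component == "P300":
        window = window_ms or P300_WINDOW_MS
        sign = +1.0
    else:
        raise DomainError(f"unknown component {component!r}")
    t = erp.times_ms
    if window[0] < t[0] or window[1] > t[-1]:
        raise WindowError(f"window {window} outside the epoch grid "
                          f"[{t[0]}, {t[-1]}] ms")
    idx = np.flatnonzero((t >= window[0]) & (t <= window[1]))
    v = sign * erp.samples  # maximize v

    candidates = [i for i in idx
                  if 0 < i < len(t) - 1
                  and v[i] >= v[i - 1] and v[i] >= v[i + 1]]
    flags = set()
    if candidates:
        best_val = max(v[i] for i in candidates)
        winners = [i for i in candidates if v[i] == best_val]
        if len(winners) > 1:
            flags.add("tie")
        peak = winners[0]
    else:
        flags.add("boundary")
        in_window = v[idx]
        best_val = in_window.max()
        winners = idx[np.flatnonzero(in_window == best_val)]
        if len(winners) > 1:
            flags.add("tie")
        peak = int(winners[0])

    return ErpPeak(component=component, amplitude_uv=float(erp.samples[peak]),
                   latency_ms=float(t[peak]), window_ms=tuple(window),
                   channel=erp.channel, condition=erp.condition,
                   flags=frozenset(flags))


def window_means_cz(
    erps: dict[str, ErpWaveform] | ErpWaveform,
    windows_ms: tuple[tuple[float, float], ...] = CZ_WINDOWS_MS,
) -> np.ndarray:
    """Mean amplitude in half-open [lo, hi) windows on the Cz waveform."""
    if isinstance(erps, dict):
        if "Cz" not in erps:
            raise MontageError("Cz waveform is missing")
        erp = erps["Cz"]
    else:
        erp = erps
    t = erp.times_ms
    means = []
    for lo, hi in windows_ms:
        mask = (t >= lo) & (t < hi)
        if not mask.any():
            raise WindowError(f"window [{lo}, {hi}) holds no samples")
        means.append(float(erp.samples[mask].mean()))
    return np.array(means)


def peak_table(
    peaks: list[ErpPeak],
) -> pd.DataFrame:
    """Long-format table of peaks: condition x channel x component rows."""
    return pd.DataFrame(
        {
            "condition": [p.condition for p in peaks],
            "channel": [p.channel for p in peaks],
            "component": [p.component for p in peaks],
            "amplitude_uv": [p.amplitude_uv for p in peaks],
            "latency_ms": [p.latency_ms for p in peaks],
            "flags": ["|".join(sorted(p.flags)) for p in peaks],
        }
    )
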