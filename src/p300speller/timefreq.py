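"""Morlet wavelet family and phase-locking factor (PLF) analysis.

A Morlet wavelet at center frequency f0 is

    w(t, f0) = A exp(-t^2 / 2 sigma_t^2) exp(2 i pi f0 t),

with spectral width sigma_f = f0 / k for a constant family ratio k (here
k = 7), temporal width sigma_t = 1 / (2 pi sigma_f), and normalization
A = (sigma_t sqrt(pi))^(-1/2).  The normalized complex energy of trial j is

    P_j(t, f0) = (w * s_j)(t) / |(w * s_j)(t)|,

a unit-modulus phase trace, and the phase-locking factor is the modulus of
the across-trials mean of P_j: 0 means random phase across trials, 1 means
perfect stimulus-locked phase alignment.  PLF is invariant to signal
amplitude and to the wavelet normalization constant by construction.

Edge handling: the wavelet support is truncated at +/-4 sigma_t, and output
samples whose support extends beyond the epoch are marked undefined rather
than zero-padded (``edge='strict'``, the default).  On an 800 ms epoch this
leaves family members below ~12 Hz entirely undefined -- a deliberate choice
that avoids boundary bias; ``edge='pad'`` enables conventional zero-padded
convolution over the full grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from .exceptions import (AliasingError, BookkeepingError, DomainError,
                         WindowError)
from .preprocess import EpochArray

DEFAULT_F0_GRID = tuple(float(f) for f in range(5, 21))


@dataclass(frozen=True)
class Wavelet:
    f0: float
    sigma_f: float
    sigma_t: float
    amplitude: float
    waveform: np.ndarray   # complex samples on times
    times_s: np.ndarray


@dataclass(frozen=True)
class WaveletFamily:
    members: tuple[Wavelet, ...]
    k: float
    sampling_rate_hz: float

    def __iter__(self):
        return iter(self.members)

    def __len__(self):
        return len(self.members)

    @property
    def f0_grid(self) -> np.ndarray:
        return np.array([w.f0 for w in self.members])


def make_wavelet_family(
    k: float = 7.0,
    f0_grid: tuple[float, ...] = DEFAULT_F0_GRID,
    sampling_rate_hz: float = 256.0,
    support_sigmas: float = 4.0,
) -> WaveletFamily:
    """Build the constant-ratio Morlet family (k = f0 / sigma_f).

    k below 5 trades frequency resolution for too few cycles and triggers a
    warning; a sampling rate at or below twice the highest f0 is an error.
    """
    if k <= 0:
        raise DomainError("k must be positive")
    if k < 5:
        warnings.warn(f"family ratio k={k} is below the conventional minimum of 5",
                      UserWarning, stacklevel=2)
    f_max = max(f0_grid)
    if sampling_rate_hz <= 2 * f_max:
        raise AliasingError(
            f"sampling rate {sampling_rate_hz} Hz cannot represent {f_max} Hz")
    members = []
    for f0 in f0_grid:
        sigma_f = f0 / k
        sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
        amplitude = (sigma_t * np.sqrt(np.pi)) ** -0.5
        n_half = int(np.ceil(support_sigmas * sigma_t * sampling_rate_hz))
        t = np.arange(-n_half, n_half + 1) / sampling_rate_hz
        waveform = (amplitude * np.exp(-t**2 / (2.0 * sigma_t**2))
                    * np.exp(2j * np.pi * f0 * t))
        members.append(Wavelet(f0=float(f0), sigma_f=sigma_f, sigma_t=sigma_t,
                               amplitude=amplitude, waveform=waveform, times_s=t))
    return WaveletFamily(members=tuple(members), k=float(k),
                         sampling_rate_hz=float(sampling_rate_hz))


def normalized_energy(
    trial: np.ndarray,
    wavelet: Wavelet,
    edge: str = "strict",
    eps_scale: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-modulus phase trace of one trial at one frequency.

    Returns ``(P, defined)`` where ``P`` is complex with NaN at undefined
    samples and ``defined`` is a boolean mask.  Samples are undefined where
    the truncated wavelet support leaves the epoch (strict mode) or where
    the convolution modulus falls below a floor proportional to the trial
    rms (near-zero signal: phase is meaningless, not zero-divided).
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 1:
        raise DomainError("trial must be a 1-D signal")
    n = trial.shape[0]
    half = (len(wavelet.waveform) - 1) // 2
    conv = sp_signal.convolve(trial, wavelet.waveform, mode="same", method="auto")
    modulus = np.abs(conv)

    rms = float(np.sqrt(np.mean(trial**2)))
    floor = eps_scale * rms * np.sum(np.abs(wavelet.waveform))
    defined = modulus > floor
    if edge == "strict":
        idx = np.arange(n)
        defined &= (idx >= half) & (idx <= n - 1 - half)
    elif edge != "pad":
        raise DomainError(f"unknown edge mode {edge!r}")

    P = np.full(n, np.nan + 0j)
    P[defined] = conv[defined] / modulus[defined]
    return P, defined


@dataclass
class PlfMatrix:
    """Phase-locking factor over frequency x time for one set of trials."""

    values: np.ndarray          # (n_freq, n_samples), NaN where undefined
    effective_n: np.ndarray     # usable trials per cell
    freqs_hz: np.ndarray
    times_ms: np.ndarray | None = None
    n_trials: int = 0
    channel: str = ""
    trial_class: str = ""
    outcome: str = ""

    def __post_init__(self):
        finite = np.isfinite(self.values)
        if finite.any():
            vals = self.values[finite]
            if (vals < -1e-9).any() or (vals > 1 + 1e-9).any():
                raise DomainError("PLF values must lie in [0, 1]")


def plf_from_phase_traces(P_stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Modulus of the across-trials mean of unit-modulus traces.

    ``P_stack`` is (n_trials, n_samples) complex with NaN marking undefined
    samples; those are excluded pairwise and the usable count returned.
    """
    P_stack = np.atleast_2d(np.asarray(P_stack, dtype=complex))
    defined = np.isfinite(P_stack.real) & np.isfinite(P_stack.imag)
    counts = defined.sum(axis=0)
    summed = np.where(defined, P_stack, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        plf = np.where(counts > 0, np.abs(summed) / np.maximum(counts, 1), np.nan)
    plf = np.where(counts > 0, plf, np.nan)
    return plf, counts


def phase_locking_factor(
    trials: np.ndarray,
    family: WaveletFamily,
    times_ms: np.ndarray | None = None,
    edge: str = "strict",
    channel: str = "",
    trial_class: str = "",
    outcome: str = "",
) -> PlfMatrix:
    """PLF over the family's frequency grid for a stack of single-channel trials."""
    trials = np.atleast_2d(np.asarray(trials, dtype=float))
    if trials.shape[0] < 1:
        raise DomainError("at least one trial is required")
    n_trials, n_samples = trials.shape
    values = np.empty((len(family), n_samples))
    counts = np.empty((len(family), n_samples), dtype=int)
    for fi, wavelet in enumerate(family):
        P = np.stack([normalized_energy(trials[j], wavelet, edge=edge)[0]
                      for j in range(n_trials)])
        values[fi], counts[fi] = plf_from_phase_traces(P)
    return PlfMatrix(values=values, effective_n=counts,
                     freqs_hz=family.f0_grid,
                     times_ms=None if times_ms is None else np.asarray(times_ms),
                     n_trials=n_trials, channel=channel,
                     trial_class=trial_class, outcome=outcome)


def collapse_time_median(plf: PlfMatrix, post_only: bool = True) -> np.ndarray:
    """Median PLF over (defined) time samples, one value per frequency.

    By default only post-stimulus samples (time >= 0) enter the median; pass
    ``post_only=False`` to collapse over the whole epoch.  Frequencies with
    no defined sample come back as NaN.
    """
    values = plf.values
    if post_only and plf.times_ms is not None:
        mask = plf.times_ms >= 0
        if not mask.any():
            raise WindowError("no post-stimulus samples on this grid")
        values = values[:, mask]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
        return np.nanmedian(values, axis=1)


def partition_trials_by_outcome(
    epochs: EpochArray,
    selections,
) -> tuple[dict[tuple[str, str], EpochArray], dict[tuple[str, str], int]]:
    """Split epochs into {target, nontarget} x {correct, wrong} sets.

    ``selections`` must cover exactly the symbols present in the epochs;
    the partition is exhaustive and disjoint, and the counts obey
    N = (#selections with the outcome) x (flashes of that class per symbol).
    """
    outcome_by_symbol = {}
    for sel in selections:
        if sel.correct is None:
            raise BookkeepingError("selections must carry ground truth")
        outcome_by_symbol[sel.symbol_index] = "correct" if sel.correct else "wrong"
    epoch_symbols = set(int(s) for s in np.unique(epochs.symbol_index))
    if epoch_symbols != set(outcome_by_symbol):
        raise BookkeepingError(
            f"selections cover symbols {sorted(outcome_by_symbol)} but epochs "
            f"contain {sorted(epoch_symbols)}")

    outcome_per_trial = np.array(
        [outcome_by_symbol[int(s)] for s in epochs.symbol_index])
    parts: dict[tuple[str, str], EpochArray] = {}
    counts: dict[tuple[str, str], int] = {}
    for cls, cls_mask in (("target", epochs.labels.astype(bool)),
                          ("nontarget", ~epochs.labels.astype(bool))):
        for outcome in ("correct", "wrong"):
            mask = cls_mask & (outcome_per_trial == outcome)
            parts[(cls, outcome)] = epochs.subset(mask)
            counts[(cls, outcome)] = int(mask.sum())
    return parts, counts
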