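"""From continuous records to baseline-corrected epochs and classifier features.

The classifier branch mirrors the on-line system: ocular-artifact removal by
EOG regression, 800 ms epochs (-100 to +700 ms around each flash onset),
pre-stimulus baseline correction, down-sampling to 64 Hz, a 3-sample moving
average, and decimation of the post-stimulus window to 15 time samples per
electrode -- 120 features over the 8-channel montage.

Epoch timing convention: the first epoch sample is anchored at exactly
-100 ms, so sample ``i`` sits at ``-100 + i * (1000 / rate)`` ms.  At 256 Hz
an 800 ms epoch spans 205 samples (indices 0..204).  The true flash onset
need not fall on this grid; the anchor sample is the one nearest to
(onset - 100 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .design import EEG_CHANNELS
from .exceptions import (AlignmentError, BoundaryError, DegenerateRegressorError,
                         MontageError, RateError, WindowError)
from .simulate import Recording


@dataclass
class EpochArray:
    """Trials x channels x samples, with the -100 ms-anchored time grid."""

    data: np.ndarray
    ch_names: list[str]
    sampling_rate_hz: float
    anchor_time_ms: float = -100.0
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    symbol_index: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    units: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    repetition: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise WindowError("epoch data must be trials x channels x samples")
        for name in ("labels", "symbol_index", "units", "repetition"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (self.data.shape[0],):
                raise WindowError(f"{name} length must equal the number of trials")
            setattr(self, name, arr)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate_hz
        return self.anchor_time_ms + np.arange(self.n_samples) * step

    def channel(self, name: str) -> np.ndarray:
        if name not in self.ch_names:
            raise MontageError(f"channel {name!r} not in montage {self.ch_names}")
        return self.data[:, self.ch_names.index(name), :]

    def subset(self, mask: np.ndarray) -> "EpochArray":
        mask = np.asarray(mask)
        return replace(self, data=self.data[mask], labels=self.labels[mask],
                       symbol_index=self.symbol_index[mask],
                       units=self.units[mask], repetition=self.repetition[mask])


@dataclass
class FeatureMatrix:
    """Flashes x (time samples x electrodes) classifier input.

    ``column_labels`` is a list of (channel, time_ms) pairs in column order;
    ``row_labels`` carries is_target / unit / symbol_index per flash.
    """

    X: np.ndarray
    row_labels: pd.DataFrame
    column_labels: list[tuple[str, float]]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.shape != (len(self.row_labels), len(self.column_labels)):
            raise WindowError("feature matrix shape does not match its labels")

    @property
    def channels(self) -> list[str]:
        seen: list[str] = []
        for ch, _ in self.column_labels:
            if ch not in seen:
                seen.append(ch)
        return seen

    @property
    def labels(self) -> np.ndarray:
        return self.row_labels["is_target"].to_numpy(dtype=bool)

    def drop_channels(self, names: list[str]) -> "FeatureMatrix":
        unknown = [n for n in names if n not in self.channels]
        if unknown:
            raise MontageError(f"cannot drop unknown channels {unknown}")
        keep = [i for i, (ch, _) in enumerate(self.column_labels)
                if ch not in names]
        return FeatureMatrix(self.X[:, keep], self.row_labels.copy(),
                             [self.column_labels[i] for i in keep])

    def for_symbol(self, symbol_index: int) -> "FeatureMatrix":
        mask = (self.row_labels["symbol_index"] == symbol_index).to_numpy()
        return FeatureMatrix(self.X[mask],
                             self.row_labels.loc[mask].reset_index(drop=True),
                             list(self.column_labels))

    def to_csv(self, path) -> None:
        header = [f"{ch}@{t:.3f}ms" for ch, t in self.column_labels]
        frame = pd.concat(
            [self.row_labels.reset_index(drop=True),
             pd.DataFrame(self.X, columns=header)], axis=1)
        frame.to_csv(path, index=False)


def remove_eog(eeg: Recording, eog: Recording) -> tuple[Recording, pd.DataFrame]:
    """Subtract the least-squares EOG projection from every EEG channel.

    Bipolar derivations VEOG = (above - below) and HEOG = (left - right) are
    the regressors; each EEG channel is cleaned by removing its least-squares
    projection onto the mean-centered derivations.  Returns the cleaned
    record and the propagation coefficients per channel.

    Exactly constant derivations (e.g. all-zero EOG) carry no information and
    are treated as null regressors; non-constant but collinear derivations
    raise :class:`DegenerateRegressorError`.
    """
    if eeg.n_samples != eog.n_samples:
        raise AlignmentError("EEG and EOG records differ in length")
    if eeg.sampling_rate_hz != eog.sampling_rate_hz:
        raise AlignmentError("EEG and EOG records differ in sampling rate")
    if len(eog.ch_names) != 4:
        raise MontageError("expected 4 EOG channels (above, below, left, right)")

    above, below, left, right = (eog.data[i] for i in range(4))
    derivations = np.stack([above - below, left - right], axis=1)  # (n, 2)
    centered = derivations - derivations.mean(axis=0)
    variances = centered.var(axis=0)
    active = variances > 0.0

    coef = np.zeros((len(eeg.ch_names), 2))
    cleaned = eeg.data.copy()
    if active.any():
        regressors = centered[:, active]
        gram = regressors.T @ regressors
        if np.linalg.matrix_rank(gram, tol=1e-10 * np.trace(gram)) < regressors.shape[1]:
            raise DegenerateRegressorError(
                "VEOG and HEOG derivations are collinear; regression is not "
                "identifiable")
        beta, *_ = np.linalg.lstsq(regressors, eeg.data.T, rcond=None)
        cleaned = eeg.data - (regressors @ beta).T
        coef[:, active] = beta.T

    table = pd.DataFrame(coef, index=list(eeg.ch_names), columns=["VEOG", "HEOG"])
    out = Recording(cleaned, list(eeg.ch_names), eeg.sampling_rate_hz,
                    dict(eeg.meta))
    return out, table


def epoch_records(
    record: Recording,
    events: pd.DataFrame,
    window_ms: tuple[float, float] = (-100.0, 700.0),
) -> EpochArray:
    """Cut one epoch per flash event from a continuous record.

    The epoch has ``floor((hi - lo) * rate / 1000) + 1`` samples whose first
    sample is anchored at ``lo`` ms relative to the flash onset (205 samples
    for the default 800 ms window at 256 Hz).
    """
    lo, hi = window_ms
    if hi <= lo:
        raise WindowError("epoch window must have positive length")
    fs = record.sampling_rate_hz
    n_samp = int(np.floor((hi - lo) * fs / 1000.0)) + 1

    onsets = events["onset_s"].to_numpy(dtype=float) if len(events) else np.zeros(0)
    starts = np.round((onsets + lo / 1000.0) * fs).astype(int)
    bad = np.flatnonzero((starts < 0) | (starts + n_samp > record.n_samples))
    if bad.size:
        raise BoundaryError(
            f"{bad.size} event(s) too close to the record edge",
            offending_events=bad.tolist())

    data = np.empty((len(onsets), len(record.ch_names), n_samp))
    for i, s0 in enumerate(starts):
        data[i] = record.data[:, s0:s0 + n_samp]

    def col(name, dtype, default):
        if name in events.columns:
            return events[name].to_numpy(dtype=dtype)
        return np.full(len(onsets), default, dtype=dtype)

    return EpochArray(
        data=data, ch_names=list(record.ch_names), sampling_rate_hz=fs,
        anchor_time_ms=lo,
        labels=col("is_target", bool, False),
        symbol_index=col("symbol_index", int, 0),
        units=col("unit", int, -1),
        repetition=col("repetition", int, 0),
    )


def baseline_correct(epochs: EpochArray) -> EpochArray:
    """Subtract the pre-stimulus (t < 0) mean per trial and channel."""
    if epochs.anchor_time_ms >= 0:
        raise WindowError("no pre-stimulus samples: anchor time must be < 0")
    pre = epochs.times_ms < 0
    if not pre.any():
        raise WindowError("no pre-stimulus samples in the epoch grid")
    baseline = epochs.data[:, :, pre].mean(axis=2, keepdims=True)
    return replace(epochs, data=epochs.data - baseline)


def downsample_epochs(epochs: EpochArray, target_rate_hz: float = 64.0) -> EpochArray:
    """Keep every k-th sample starting at index 0 (k = rate ratio)."""
    ratio = epochs.sampling_rate_hz / target_rate_hz
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise RateError(
            f"{epochs.sampling_rate_hz} Hz is not an integer multiple of "
            f"{target_rate_hz} Hz")
    k = int(round(ratio))
    return replace(epochs, data=epochs.data[:, :, ::k],
                   sampling_rate_hz=target_rate_hz)


def moving_average_filter(epochs: EpochArray, width: int = 3) -> EpochArray:
    """Centered moving average; window shrinks symmetrically at the edges."""
    if width % 2 == 0 or width < 1:
        raise WindowError("moving-average width must be odd and >= 1")
    n = epochs.n_samples
    if width > n:
        raise WindowError(f"width {width} exceeds epoch length {n}")
    kernel = np.ones(width)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    sums = ndimage.convolve1d(epochs.data, kernel, axis=2, mode="constant", cval=0.0)
    return replace(epochs, data=sums / counts)


def assemble_feature_matrix(
    epochs: EpochArray,
    channels: tuple[str, ...] = EEG_CHANNELS,
    decimation: int = 3,
    post_window_ms: tuple[float, float] = (0.0, 700.0),
) -> FeatureMatrix:
    """Concatenate decimated post-stimulus samples per channel into features.

    At 64 Hz the 0-700 ms window holds 45 samples; keeping every third yields
    the 15 time samples per electrode of the classifier's 120-column layout.
    """
    missing = [ch for ch in channels if ch not in epochs.ch_names]
    if missing:
        raise MontageError(f"epochs lack channels {missing}")
    times = epochs.times_ms
    post = np.flatnonzero((times >= post_window_ms[0]) & (times <= post_window_ms[1]))
    if post.size == 0:
        raise WindowError("post-stimulus window is empty on this grid")
    keep = post[::decimation]

    blocks = []
    column_labels: list[tuple[str, float]] = []
    for ch in channels:
        ci = epochs.ch_names.index(ch)
        blocks.append(epochs.data[:, ci, keep])
        column_labels.extend((ch, float(times[j])) for j in keep)
    X = np.hstack(blocks) if blocks else np.zeros((epochs.n_trials, 0))
    row_labels = pd.DataFrame({
        "is_target": epochs.labels.astype(int),
        "unit": epochs.units,
        "symbol_index": epochs.symbol_index,
        "repetition": epochs.repetition,
    })
    return FeatureMatrix(X=X, row_labels=row_labels, column_labels=column_labels)
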