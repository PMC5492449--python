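"""Experimental design for a 6x6 row/column P300 speller.

The speller presents a 6x6 symbol matrix whose 6 rows and 6 columns flash in
random order.  The attended (target) symbol sits at the intersection of one
row and one column, so 2 of every 12 flashes are targets -- the oddball
structure that elicits the P300.  Two stimulation timings are modelled:

* slow -- 100 ms flash, 900 ms dark interval;
* fast -- 60 ms flash, 10 ms dark interval.

Stimuli are rendered on a 60 Hz display, so designed durations are quantized
to whole refresh frames.  A 60 ms flash becomes 4 frames of 16.66 ms =
66.64 ms of actual exposure, and the steady-state flicker driven by the fast
timing falls in the 12-15 Hz band.

The study crosses three two-level factors within subjects: stimulus type
(STIM: characters ``CH`` vs icons ``IC``), stimulus color (COLOR: white vs
green) and timing (SPEED: slow vs fast), with the four SPEED x COLOR
combinations ordered by a balanced Latin square inside each STIM block and
the STIM block order counterbalanced across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DesignError, DomainError, NotApplicableError

#: EEG montage used by the speller (extended 10-20 names).
EEG_CHANNELS = ("Fz", "Cz", "P3", "Pz", "P4", "PO7", "Oz", "PO8")

#: Four periocular electrodes: above/below the left eye, left/right canthi.
EOG_CHANNELS = ("EOGa", "EOGb", "EOGl", "EOGr")

STIM_LEVELS = ("CH", "IC")
COLOR_LEVELS = ("white", "green")
SPEED_LEVELS = ("slow", "fast")
PHASE_LEVELS = ("training", "performance")


@dataclass(frozen=True)
class SpellerConfig:
    """Geometry, timing and acquisition parameters of one speller variant.

    Durations are in milliseconds unless suffixed otherwise.  The refresh
    frame defaults to the printed 16.66 ms figure for a 60 Hz display rather
    than the exact 1000/60 ms, so that 4 frames reproduce the 66.64 ms
    actual exposure bit-for-bit; pass ``refresh_frame_ms=1000/60`` for the
    exact-period variant.
    """

    speed: str = "slow"
    matrix_rows: int = 6
    matrix_cols: int = 6
    n_repetitions: int = 15
    n_symbols_per_phase: int = 5
    flash_ms_designed: float = 100.0
    dark_ms_designed: float = 900.0
    refresh_frame_ms: float = 16.66
    pause_after_feedback_s: float = 4.0
    sampling_rate_hz: float = 256.0

    def __post_init__(self):
        if self.speed not in SPEED_LEVELS:
            raise ConfigError(f"unknown speed level {self.speed!r}")
        if self.matrix_rows < 2 or self.matrix_cols < 2:
            raise ConfigError("speller matrix needs at least 2 rows and 2 columns")
        if self.n_repetitions < 1 or self.n_symbols_per_phase < 1:
            raise ConfigError("repetitions and symbols per phase must be >= 1")
        for name in ("flash_ms_designed", "dark_ms_designed", "refresh_frame_ms",
                     "pause_after_feedback_s", "sampling_rate_hz"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    @classmethod
    def slow(cls, **kwargs) -> "SpellerConfig":
        """100 ms flash / 900 ms dark timing."""
        kwargs.setdefault("flash_ms_designed", 100.0)
        kwargs.setdefault("dark_ms_designed", 900.0)
        return cls(speed="slow", **kwargs)

    @classmethod
    def fast(cls, **kwargs) -> "SpellerConfig":
        """60 ms flash / 10 ms dark timing (frame-quantized on screen)."""
        kwargs.setdefault("flash_ms_designed", 60.0)
        kwargs.setdefault("dark_ms_designed", 10.0)
        return cls(speed="fast", **kwargs)

    @property
    def n_units(self) -> int:
        return self.matrix_rows + self.matrix_cols

    @property
    def flash_ms_actual(self) -> float:
        return quantize_to_frames(self.flash_ms_designed, self.refresh_frame_ms)

    @property
    def dark_ms_actual(self) -> float:
        return quantize_to_frames(self.dark_ms_designed, self.refresh_frame_ms)

    @property
    def soa_ms(self) -> float:
        """Onset-to-onset interval: quantized flash plus quantized dark time."""
        return self.flash_ms_actual + self.dark_ms_actual

    def with_(self, **kwargs) -> "SpellerConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Condition:
    """One cell of the STIM x COLOR x SPEED design, within a session phase."""

    stim: str
    color: str
    speed: str
    phase: str = "training"

    def __post_init__(self):
        if self.stim not in STIM_LEVELS:
            raise ConfigError(f"unknown STIM level {self.stim!r}")
        if self.color not in COLOR_LEVELS:
            raise ConfigError(f"unknown COLOR level {self.color!r}")
        if self.speed not in SPEED_LEVELS:
            raise ConfigError(f"unknown SPEED level {self.speed!r}")
        if self.phase not in PHASE_LEVELS:
            raise ConfigError(f"unknown phase {self.phase!r}")

    @property
    def label(self) -> str:
        color = "WH" if self.color == "white" else "GR"
        return f"{color}-{self.stim}"

    def with_phase(self, phase: str) -> "Condition":
        return replace(self, phase=phase)


@dataclass(frozen=True)
class FlashEvent:
    """A single row or column flash.

    ``unit`` indexes the 12 flashable units: 0-5 are rows, 6-11 columns.
    """

    onset_s: float
    unit: int
    is_target: bool
    symbol_index: int
    actual_exposure_ms: float
    repetition: int = 0


@dataclass
class FlashSchedule:
    """Complete stimulus timeline for one phase of one session."""

    events: list[FlashEvent]
    config: SpellerConfig
    condition: Condition
    targets: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def n_target(self) -> int:
        return sum(e.is_target for e in self.events)

    @property
    def n_nontarget(self) -> int:
        return len(self.events) - self.n_target

    @property
    def duration_s(self) -> float:
        if not self.events:
            return 0.0
        return self.events[-1].onset_s + self.config.soa_ms / 1000.0

    def to_frame(self) -> pd.DataFrame:
        """Event table with one row per flash (TSV-ready)."""
        return pd.DataFrame(
            {
                "onset_s": [e.onset_s for e in self.events],
                "unit": [e.unit for e in self.events],
                "is_target": [int(e.is_target) for e in self.events],
                "symbol_index": [e.symbol_index for e in self.events],
                "repetition": [e.repetition for e in self.events],
                "stim": self.condition.stim,
                "color": self.condition.color,
                "speed": self.condition.speed,
                "phase": self.condition.phase,
            }
        )


def quantize_to_frames(designed_ms: float, frame_ms: float) -> float:
    """Quantize a designed duration to whole display-refresh frames.

    Returns ``n * frame_ms`` with ``n = max(1, round(designed_ms / frame_ms))``
    (nearest-integer rounding, at least one frame).  A designed 60 ms flash on
    a 16.66 ms frame gives 4 frames = 66.64 ms.
    """
    if designed_ms <= 0 or frame_ms <= 0:
        raise DomainError("durations must be positive")
    n_frames = max(1, int(round(designed_ms / frame_ms)))
    return n_frames * frame_ms


def ssvep_band(config: SpellerConfig) -> tuple[int, int]:
    """Frequency band of the flicker-driven steady-state response (fast mode).

    The upper edge is the reciprocal of the quantized flash exposure, the
    lower edge the reciprocal of exposure plus one dark frame; both are
    rounded to the nearest integer Hz.  For the 60/10 ms design on a 60 Hz
    display this is (12, 15) Hz.
    """
    if config.speed != "fast":
        raise NotApplicableError("SSVEP band is defined for fast-mode configs only")
    exposure = config.flash_ms_actual
    f_max = int(round(1000.0 / exposure))
    f_min = int(round(1000.0 / (exposure + config.refresh_frame_ms)))
    return (f_min, f_max)


def _williams_square(n: int) -> np.ndarray:
    """Balanced (Williams) Latin square of even order ``n``; rows are orders."""
    # First row 0, 1, n-1, 2, n-2, ... (alternating ends); subsequent rows
    # shift by +1 mod n.
    first = [0]
    low, high = 1, n - 1
    use_low = True
    while len(first) < n:
        if use_low:
            first.append(low)
            low += 1
        else:
            first.append(high)
            high -= 1
        use_low = not use_low
    first = np.array(first)
    return np.stack([(first + i) % n for i in range(n)])


def build_latin_square_design(n_subjects: int, seed: int) -> list[list[Condition]]:
    """Assign each subject an ordered list of session conditions.

    Subjects are split into two equal groups by STIM block order (CH-then-IC
    vs IC-then-CH).  Within each STIM block, the four SPEED x COLOR
    combinations follow the rows of a balanced 4x4 Latin square, cycled over
    subjects, so every combination occupies every ordinal position equally
    often when ``n_subjects`` is a multiple of 4.  The seed randomizes the
    mapping of combinations onto square symbols and the group interleaving.
    """
    if n_subjects < 4 or n_subjects % 2:
        raise DesignError("need an even number of at least 4 subjects "
                          "(two STIM-sequence groups)")
    rng = np.random.default_rng(seed)
    combos = [(speed, color) for speed in SPEED_LEVELS for color in COLOR_LEVELS]
    relabel = rng.permutation(4)
    square = _williams_square(4)

    stim_orders = [("CH", "IC")] * (n_subjects // 2) + [("IC", "CH")] * (n_subjects // 2)
    design: list[list[Condition]] = []
    for subject in range(n_subjects):
        row = square[subject % 4]
        ordered = [combos[relabel[sym]] for sym in row]
        sessions = [
            Condition(stim=stim, color=color, speed=speed)
            for stim in stim_orders[subject]
            for (speed, color) in ordered
        ]
        design.append(sessions)
    return design


def build_flash_schedule(
    config: SpellerConfig,
    targets: list[tuple[int, int]],
    condition: Condition,
    seed: int,
    start_offset_s: float = 1.0,
) -> FlashSchedule:
    """Randomized flashing timeline for a list of target symbols.

    For every symbol, the 12 units flash once per repetition block in a fresh
    random permutation, ``config.n_repetitions`` blocks in all, giving each
    unit exactly ``n_repetitions`` flashes (2 x n_repetitions targets and
    10 x n_repetitions non-targets per symbol).  Successive onsets are spaced
    by the frame-quantized flash+dark interval; a feedback pause separates
    symbols.
    """
    for row, col in targets:
        if not (0 <= row < config.matrix_rows and 0 <= col < config.matrix_cols):
            raise DomainError(f"target ({row}, {col}) outside the "
                              f"{config.matrix_rows}x{config.matrix_cols} matrix")
    rng = np.random.default_rng(seed)
    soa_s = config.soa_ms / 1000.0
    exposure = config.flash_ms_actual
    t = start_offset_s
    events: list[FlashEvent] = []
    for symbol_index, (row, col) in enumerate(targets):
        target_units = {row, config.matrix_rows + col}
        for rep in range(config.n_repetitions):
            for unit in rng.permutation(config.n_units):
                events.append(
                    FlashEvent(
                        onset_s=t,
                        unit=int(unit),
                        is_target=int(unit) in target_units,
                        symbol_index=symbol_index,
                        actual_exposure_ms=exposure,
                        repetition=rep,
                    )
                )
                t += soa_s
        t += config.pause_after_feedback_s
    return FlashSchedule(events=events, config=config, condition=condition,
                         targets=list(targets))
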