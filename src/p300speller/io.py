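"""File formats: event tables (TSV), the internal record container, EDF input.

The canonical on-disk pair for a synthetic session is a ``.npz`` array
container holding the signal plus a JSON sidecar with the header (channel
names, sampling rate, units, condition metadata).  Real recordings in
European Data Format are read through :mod:`mne` when it is installed
(optional ``edf`` extra).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .simulate import Recording

EVENT_COLUMNS = ["onset_s", "unit", "is_target", "symbol_index", "repetition",
                 "stim", "color", "speed", "phase"]


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> Path:
    """Write a flash-event table as TSV with the documented column set."""
    path = Path(path)
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ConfigError(f"event table lacks columns {missing}")
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ConfigError(f"event table {path} lacks columns {missing}")
    return events


def save_record(record: Recording, stem: str | Path) -> tuple[Path, Path]:
    """Persist a record as ``<stem>.npz`` plus ``<stem>.json`` header."""
    stem = Path(stem)
    npz_path = stem.with_suffix(".npz")
    json_path = stem.with_suffix(".json")
    np.savez_compressed(npz_path, data=record.data)
    header = {
        "ch_names": list(record.ch_names),
        "sampling_rate_hz": record.sampling_rate_hz,
        "n_samples": int(record.n_samples),
        "units": "uV",
        "meta": record.meta,
    }
    json_path.write_text(json.dumps(header, indent=2, sort_keys=True))
    return npz_path, json_path


def load_record(stem: str | Path) -> Recording:
    stem = Path(stem)
    with np.load(stem.with_suffix(".npz")) as archive:
        data = archive["data"]
    header = json.loads(stem.with_suffix(".json").read_text())
    return Recording(data=data, ch_names=header["ch_names"],
                     sampling_rate_hz=header["sampling_rate_hz"],
                     meta=header.get("meta", {}))


def read_edf(path: str | Path, ch_names: list[str] | None = None) -> Recording:
    """Read an EDF recording into a :class:`Recording` (requires mne).

    Signals are converted from Volts to uV.  ``ch_names`` optionally
    restricts and orders the channels.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading EDF requires the optional 'mne' dependency "
            "(pip install p300speller[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if ch_names is not None:
        raw.pick(ch_names)
    return Recording(data=raw.get_data() * 1e6, ch_names=list(raw.ch_names),
                     sampling_rate_hz=float(raw.info["sfreq"]),
                     meta={"source": str(path)})
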