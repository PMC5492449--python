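"""End-to-end synthetic replication: design -> simulate -> preprocess ->
classify -> ERP -> PLF -> statistics.

``run_study`` generates a full multi-subject experiment from a master seed,
runs every analysis stage, and returns a :class:`StudyReport` whose tables
can be written as CSV plus a JSON run manifest.  Per-subject and per-session
seeds are derived from the master seed with a fixed counter scheme so any
single session can be regenerated in isolation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import ablate_channels, classify_phase, selection_accuracy, train_lda
from .design import (Condition, SpellerConfig, build_flash_schedule,
                     build_latin_square_design)
from .erp import average_erp, extract_peak, window_means_cz
from .exceptions import SpellerError
from .preprocess import (assemble_feature_matrix, baseline_correct,
                         downsample_epochs, epoch_records,
                         moving_average_filter, remove_eog)
from .simulate import synthesize_session_eeg
from .stats import RmDataset, exact_sign_test, holm_adjust, perm_rm_anova_2x2
from .templates import ErpTemplateSet, NoiseModel
from .timefreq import (collapse_time_median, make_wavelet_family,
                       partition_trials_by_outcome, phase_locking_factor)

PLF_CHANNELS = ("Oz", "PO8")


@dataclass
class StudyConfig:
    """Everything needed to reproduce a synthetic study run."""

    master_seed: int = 0
    n_subjects: int = 8
    n_repetitions: int = 15
    n_symbols_per_phase: int = 5
    amplitude_scale: float = 1.0
    nontarget_fraction: float = 0.25
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_perm: int = 2000
    shrinkage: float | str | None = "lw"
    ablation: tuple[str, ...] = ("Pz", "PO7", "PO8")
    conditions: tuple[tuple[str, str, str], ...] | None = None  # (stim, color, speed)
    plf_edge: str = "strict"

    def speller_config(self, speed: str) -> SpellerConfig:
        factory = SpellerConfig.slow if speed == "slow" else SpellerConfig.fast
        return factory(n_repetitions=self.n_repetitions,
                       n_symbols_per_phase=self.n_symbols_per_phase)

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["noise"] = asdict(self.noise)
        return d


@dataclass
class StudyReport:
    """All study-level tables plus the reproducibility manifest."""

    accuracy: pd.DataFrame
    ablation: pd.DataFrame
    n1_peaks: pd.DataFrame
    p300_peaks: pd.DataFrame
    cz_window_means: pd.DataFrame
    anova: pd.DataFrame
    posthoc: pd.DataFrame
    plf_medians: pd.DataFrame
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "accuracy": self.accuracy, "ablation": self.ablation,
            "n1_peaks": self.n1_peaks, "p300_peaks": self.p300_peaks,
            "cz_window_means": self.cz_window_means, "anova": self.anova,
            "posthoc": self.posthoc, "plf_medians": self.plf_medians,
        }

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in self.tables().items():
            frame.to_csv(out / f"{name}.csv", index=False, float_format="%.6g")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, sort_keys=True))
        return out


def _session_seed(master_seed: int, subject: int, session: int, stage: int) -> int:
    """Deterministic per-(subject, session, stage) seed below 2**31."""
    payload = f"{master_seed}:{subject}:{session}:{stage}".encode()
    return int.from_bytes(hashlib.sha256(payload).digest()[:4], "big") % (2**31)


def _random_targets(rng: np.random.Generator, config: SpellerConfig) -> list:
    rows = rng.integers(0, config.matrix_rows, size=config.n_symbols_per_phase)
    cols = rng.integers(0, config.matrix_cols, size=config.n_symbols_per_phase)
    return list(zip(rows.tolist(), cols.tolist()))


def run_session_phase(
    cfg: StudyConfig,
    condition: Condition,
    subject: int,
    session: int,
):
    """Simulate and preprocess one phase; returns epochs, features and truth."""
    speller = cfg.speller_config(condition.speed)
    stage_base = 0 if condition.phase == "training" else 100
    rng = np.random.default_rng(
        _session_seed(cfg.master_seed, subject, session, stage_base + 1))
    targets = _random_targets(rng, speller)
    schedule = build_flash_schedule(
        speller, targets, condition,
        seed=_session_seed(cfg.master_seed, subject, session, stage_base + 2))
    templates = ErpTemplateSet.from_reference(
        condition.stim, condition.color, phase=condition.phase,
        amplitude_scale=cfg.amplitude_scale,
        nontarget_fraction=cfg.nontarget_fraction)
    noise = cfg.noise.with_(
        seed=_session_seed(cfg.master_seed, subject, session, stage_base + 3))
    record, events = synthesize_session_eeg(schedule, templates, noise)

    eeg = record.pick([c for c in record.ch_names if not c.startswith("EOG")])
    eog = record.pick([c for c in record.ch_names if c.startswith("EOG")])
    cleaned, _coefs = remove_eog(eeg, eog)
    epochs = baseline_correct(epoch_records(cleaned, events))
    features = assemble_feature_matrix(
        moving_average_filter(downsample_epochs(epochs)))
    return epochs, features, targets


def run_study(cfg: StudyConfig, out_dir: str | Path | None = None) -> StudyReport:
    """Run the full synthetic study and assemble every results table."""
    design = build_latin_square_design(cfg.n_subjects,
                                       seed=_session_seed(cfg.master_seed, 0, 0, 0))
    wanted = None if cfg.conditions is None else set(cfg.conditions)

    acc_rows, abl_rows, n1_rows, p300_rows, cz_rows, plf_rows = [], [], [], [], [], []
    family = make_wavelet_family()
    n1_slow_training: dict[str, dict] = {}
    n1_slow_performance: dict[str, dict] = {}

    for subject, sessions in enumerate(design):
        for session, condition in enumerate(sessions):
            key = (condition.stim, condition.color, condition.speed)
            if wanted is not None and key not in wanted:
                continue
            try:
                train_epochs, train_features, _ = run_session_phase(
                    cfg, condition.with_phase("training"), subject, session)
                perf_epochs, perf_features, _ = run_session_phase(
                    cfg, condition.with_phase("performance"), subject, session)
            except SpellerError as exc:
                raise SpellerError(
                    f"subject {subject} session {session} "
                    f"({condition.label}/{condition.speed}): {exc}") from exc

            model = train_lda(train_features, shrinkage=cfg.shrinkage)
            selections = classify_phase(model, perf_features)
            accuracy = selection_accuracy(selections)
            acc_rows.append({
                "subject": subject, "stim": condition.stim,
                "color": condition.color, "speed": condition.speed,
                "accuracy_pct": accuracy,
            })
            ablation = ablate_channels(train_features, perf_features,
                                       drop=cfg.ablation, shrinkage=cfg.shrinkage)
            abl_rows.append({
                "subject": subject, "stim": condition.stim,
                "color": condition.color, "speed": condition.speed,
                "full_accuracy_pct": ablation.full_accuracy,
                "reduced_accuracy_pct": ablation.reduced_accuracy,
                "reduction_pct": ablation.reduction_pct,
            })

            # Time-domain ERP branch (slow timing only: fast flashing
            # distorts the waveform morphology).
            if condition.speed == "slow":
                for phase, epochs, store in (
                        ("training", train_epochs, n1_slow_training),
                        ("performance", perf_epochs, n1_slow_performance)):
                    erps = average_erp(epochs, "target",
                                       condition=condition.label)
                    for ch, wave in erps.items():
                        n1 = extract_peak(wave, "N1")
                        p3 = extract_peak(wave, "P300")
                        base = {"subject": subject, "phase": phase,
                                "stim": condition.stim, "color": condition.color,
                                "channel": ch}
                        n1_rows.append({**base, "amplitude_uv": n1.amplitude_uv,
                                        "latency_ms": n1.latency_ms,
                                        "flags": "|".join(sorted(n1.flags))})
                        p300_rows.append({**base, "amplitude_uv": p3.amplitude_uv,
                                          "latency_ms": p3.latency_ms,
                                          "flags": "|".join(sorted(p3.flags))})
                        store.setdefault(ch, {}).setdefault(
                            subject, {})[(condition.stim, condition.color)] = \
                            n1.amplitude_uv
                    means = window_means_cz(average_erp(epochs, "target"))
                    cz_rows.append({"subject": subject, "phase": phase,
                                    "stim": condition.stim,
                                    "color": condition.color,
                                    "mean_200_250_uv": means[0],
                                    "mean_250_300_uv": means[1],
                                    "mean_300_350_uv": means[2]})

            # Time-frequency branch: fast-timing performance phase.
            if condition.speed == "fast":
                parts, counts = partition_trials_by_outcome(perf_epochs, selections)
                for (cls, outcome), part in parts.items():
                    if part.n_trials == 0:
                        continue
                    for ch in PLF_CHANNELS:
                        plf = phase_locking_factor(
                            part.channel(ch), family, times_ms=part.times_ms,
                            edge=cfg.plf_edge, channel=ch, trial_class=cls,
                            outcome=outcome)
                        medians = collapse_time_median(plf)
                        for f, m in zip(plf.freqs_hz, medians):
                            plf_rows.append({
                                "subject": subject, "stim": condition.stim,
                                "color": condition.color, "channel": ch,
                                "trial_class": cls, "outcome": outcome,
                                "n_trials": counts[(cls, outcome)],
                                "freq_hz": f, "median_plf": m})

    anova_rows, posthoc_rows = [], []
    for phase, store in (("training", n1_slow_training),
                         ("performance", n1_slow_performance)):
        anova_rows.extend(_n1_anova_rows(cfg, phase, store))
        posthoc_rows.extend(_n1_posthoc_rows(phase, store))

    manifest = {
        "package_version": __version__,
        "master_seed": cfg.master_seed,
        "config": cfg.to_jsonable(),
        "config_sha256": hashlib.sha256(
            json.dumps(cfg.to_jsonable(), sort_keys=True).encode()).hexdigest(),
    }
    report = StudyReport(
        accuracy=pd.DataFrame(acc_rows),
        ablation=pd.DataFrame(abl_rows),
        n1_peaks=pd.DataFrame(n1_rows),
        p300_peaks=pd.DataFrame(p300_rows),
        cz_window_means=pd.DataFrame(cz_rows),
        anova=pd.DataFrame(anova_rows),
        posthoc=pd.DataFrame(posthoc_rows),
        plf_medians=pd.DataFrame(plf_rows),
        manifest=manifest,
    )
    if out_dir is not None:
        report.write(out_dir)
    return report


def _complete_cells(store_ch: dict, n_subjects_expected: int | None = None):
    """Subject x 4-cell matrix for one channel, or None if incomplete."""
    cells = []
    for subject in sorted(store_ch):
        vals = store_ch[subject]
        if len(vals) != 4:
            return None
        cells.append([vals[("CH", "white")], vals[("CH", "green")],
                      vals[("IC", "white")], vals[("IC", "green")]])
    if len(cells) < 2:
        return None
    return np.array(cells)


def _n1_anova_rows(cfg: StudyConfig, phase: str, store: dict) -> list[dict]:
    """Permutation ANOVA on N1 amplitude per channel, Holm over channels."""
    rows = []
    per_channel = {}
    for ch, store_ch in sorted(store.items()):
        cells = _complete_cells(store_ch)
        if cells is None:
            continue
        per_channel[ch] = perm_rm_anova_2x2(
            RmDataset(cells), n_perm=cfg.n_perm,
            seed=_session_seed(cfg.master_seed, 999, sum(ch.encode()), 7))
    for effect in ("STIM", "COLOR", "STIM:COLOR"):
        channels = list(per_channel)
        if not channels:
            continue
        p_raw = np.array([per_channel[ch][effect].p_value for ch in channels])
        p_holm = holm_adjust(p_raw)
        for ch, pr, ph in zip(channels, p_raw, p_holm):
            res = per_channel[ch][effect]
            rows.append({"phase": phase, "channel": ch, "effect": effect,
                         "F": res.statistic, "p_raw": pr, "p_holm": ph,
                         "ges": res.effect_size, "n_perm": res.n_permutations})
    return rows


def _n1_posthoc_rows(phase: str, store: dict) -> list[dict]:
    """Sign tests (IC vs CH, color-collapsed) on the posterior channels."""
    from .stats import cliffs_delta

    channels = ("Pz", "PO7") if phase == "training" else ("PO7", "PO8")
    rows = []
    for ch in channels:
        store_ch = store.get(ch, {})
        cells = _complete_cells(store_ch)
        if cells is None:
            continue
        ch_mean = cells[:, :2].mean(axis=1)
        ic_mean = cells[:, 2:].mean(axis=1)
        diffs = ch_mean - ic_mean  # N1 negative: IC more negative -> diffs > 0
        try:
            res = exact_sign_test(diffs, alternative="greater")
        except SpellerError:
            continue
        rows.append({"phase": phase, "channel": ch,
                     "comparison": "N1 amplitude CH minus IC (color-collapsed)",
                     "n_positive": res.statistic, "p_value": res.p_value,
                     "n_ties": res.n_ties,
                     "cliffs_delta": cliffs_delta(ic_mean, ch_mean)})
    return rows
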