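"""Nonparametric statistics for the 2x2 within-subject design.

The study's factorial analysis crosses STIM (characters vs icons) and COLOR
(white vs green) within subjects.  Because two-level within factors admit an
exact contrast formulation, each F statistic equals the squared paired t of
the corresponding per-subject contrast; null distributions come from
permuting the four condition labels independently within each subject
(exact under exchangeability of conditions given the subject).  Effect
sizes are generalized eta squared,

    eta^2_G = SS_effect / (SS_effect + SS_subjects + sum of error SS),

comparable across within- and between-subject designs.  Paired comparisons
use the exact sign test (binomial tail at p = 1/2, ties dropped) with
Cliff's delta as the dominance effect size, and families of p-values are
Holm-adjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DesignError, DomainError, NoInformationError

EFFECTS = ("STIM", "COLOR", "STIM:COLOR")


@dataclass
class RmDataset:
    """Complete subject x STIM x COLOR value table.

    ``cells`` is (n_subjects, 4) with factor A (STIM) varying slowest:
    [(A0,B0), (A0,B1), (A1,B0), (A1,B1)].  ``from_frame`` orders factor
    levels alphabetically; the level order only flips contrast signs and
    leaves every F, p-value and effect size unchanged.
    """

    cells: np.ndarray
    subject_ids: list | None = None

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.ndim != 2 or self.cells.shape[1] != 4:
            raise DesignError("expected an (n_subjects, 4) cell matrix")
        if self.cells.shape[0] < 2:
            raise DesignError("at least 2 subjects are required")
        if not np.isfinite(self.cells).all():
            raise DesignError("design is incomplete: missing or non-finite cells")

    @property
    def n_subjects(self) -> int:
        return self.cells.shape[0]

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, value: str = "value",
                   subject: str = "subject", a: str = "stim",
                   b: str = "color") -> "RmDataset":
        """Build from a tidy frame with subject/stim/color/value columns."""
        wide = frame.pivot_table(index=subject, columns=[a, b], values=value)
        if wide.isna().any().any() or wide.shape[1] != 4:
            raise DesignError("design is incomplete: every subject needs all "
                              "4 STIM x COLOR cells")
        a_levels = sorted(frame[a].unique())
        b_levels = sorted(frame[b].unique())
        order = [(la, lb) for la in a_levels for lb in b_levels]
        return cls(cells=wide[order].to_numpy(), subject_ids=list(wide.index))


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    effect_size: float | None = None
    n_permutations: int | None = None
    exact: bool = False
    seed: int | None = None
    n_ties: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise DomainError("p-value outside [0, 1]")


def _contrast_f(cells: np.ndarray) -> np.ndarray:
    """F statistics (A, B, AxB) for 2x2 within data; vectorized over leading axes.

    ``cells`` has shape (..., n_subjects, 4) with column order
    [(A0,B0), (A0,B1), (A1,B0), (A1,B1)].  For a two-level within factor,
    F = n * Lbar^2 / var(L) with L the per-subject contrast.
    """
    y = np.asarray(cells, dtype=float)
    n = y.shape[-2]
    L = np.stack([
        (y[..., 2] + y[..., 3] - y[..., 0] - y[..., 1]) / 2.0,   # A (STIM)
        (y[..., 1] + y[..., 3] - y[..., 0] - y[..., 2]) / 2.0,   # B (COLOR)
        (y[..., 0] - y[..., 1] - y[..., 2] + y[..., 3]) / 2.0,   # A x B
    ])
    mean = L.mean(axis=-1)
    var = L.var(axis=-1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = n * mean**2 / var
    return np.where(var > 0, F, np.inf * np.sign(mean**2 + 1))


def perm_rm_anova_2x2(
    data: RmDataset,
    n_perm: int = 2000,
    seed: int = 0,
) -> dict[str, TestResult]:
    """Permutational repeated-measures ANOVA for the 2x2 within design.

    The observed F statistics come from the standard within-subject
    decomposition; the null resamples permute the 4 condition labels
    independently within each subject, and
    p = (1 + #{F* >= F}) / (1 + n_perm), so p >= 1/(n_perm + 1).
    """
    if n_perm < 999:
        raise DomainError("use at least 999 permutations")
    y = data.cells
    F_obs = _contrast_f(y)

    rng = np.random.default_rng(seed)
    perm_idx = rng.permuted(
        np.broadcast_to(np.arange(4), (n_perm, data.n_subjects, 4)).copy(), axis=2)
    y_perm = y[np.arange(data.n_subjects)[None, :, None], perm_idx]
    F_null = _contrast_f(y_perm)          # (3, n_perm)

    ges = generalized_eta_squared(data)
    out = {}
    for i, effect in enumerate(EFFECTS):
        exceed = int(np.sum(F_null[i] >= F_obs[i]))
        out[effect] = TestResult(
            statistic=float(F_obs[i]),
            p_value=(1 + exceed) / (1 + n_perm),
            method="permutation RM-ANOVA (within-subject label exchange)",
            effect_size=ges[effect],
            n_permutations=n_perm,
            seed=seed,
        )
    return out


def generalized_eta_squared(data: RmDataset) -> dict[str, float]:
    """Generalized eta squared per effect for the 2x2 within design.

    Returns NaN for every effect when the data carry no variance at all.
    """
    y = data.cells
    n = data.n_subjects
    L = np.stack([
        (y[:, 2] + y[:, 3] - y[:, 0] - y[:, 1]) / 2.0,
        (y[:, 1] + y[:, 3] - y[:, 0] - y[:, 2]) / 2.0,
        (y[:, 0] - y[:, 1] - y[:, 2] + y[:, 3]) / 2.0,
    ])
    ss_effect = n * L.mean(axis=1) ** 2
    ss_error = ((L - L.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    subj_means = y.mean(axis=1)
    ss_subjects = 4.0 * ((subj_means - y.mean()) ** 2).sum()
    denom_common = ss_subjects + ss_error.sum()
    if denom_common + ss_effect.sum() == 0:
        return {effect: float("nan") for effect in EFFECTS}
    return {
        effect: float(ss_effect[i] / (ss_effect[i] + denom_common))
        for i, effect in enumerate(EFFECTS)
    }


def exact_sign_test(
    differences: np.ndarray,
    alternative: str = "greater",
) -> TestResult:
    """Exact sign test on paired differences (binomial tail at p = 1/2).

    Zero differences are dropped and reported via ``n_ties``; ``alternative``
    refers to the median of the differences being greater/less than zero.
    """
    d = np.asarray(differences, dtype=float)
    if d.size == 0:
        raise NoInformationError("no differences supplied")
    nonzero = d[d != 0]
    n_ties = int(d.size - nonzero.size)
    if nonzero.size == 0:
        raise NoInformationError("all differences are ties; the sign test is "
                                 "uninformative")
    k = int((nonzero > 0).sum())
    result = sp_stats.binomtest(k, nonzero.size, 0.5, alternative=alternative)
    return TestResult(statistic=float(k), p_value=float(result.pvalue),
                      method=f"exact sign test ({alternative})",
                      exact=True, n_ties=n_ties)


def cliffs_delta(x: np.ndarray, y: np.ndarray) -> float:
    """Cliff's dominance delta over all cross pairs; in [-1, 1].

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (|x| |y|).  Outputs are integer
    multiples of 1/(|x||y|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("both samples must be non-empty")
    diff = x[:, None] - y[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (x.size * y.size))


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise DomainError("p-values must lie in [0, 1]")
    if p.size == 1:
        return p.copy()
    return multipletests(p, method="holm")[1]


# Thin pass-throughs for the one-way / correlation analyses the study
# delegates to standard implementations.

def friedman_test(*samples) -> TestResult:
    stat, p = sp_stats.friedmanchisquare(*samples)
    return TestResult(statistic=float(stat), p_value=float(p),
                      method="Friedman chi-square")


def wilcoxon_signed_rank(x, y=None, alternative="two-sided") -> TestResult:
    res = sp_stats.wilcoxon(x, y, alternative=alternative)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method=f"Wilcoxon signed-rank ({alternative})")


def spearman_rho(x, y) -> TestResult:
    res = sp_stats.spearmanr(x, y)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="Spearman rank correlation")


def results_table(results: dict[str, TestResult],
                  holm: bool = True) -> pd.DataFrame:
    """Tidy results frame: effect, statistic, p_raw, p_holm, effect size."""
    effects = list(results)
    p_raw = np.array([results[e].p_value for e in effects])
    p_holm = holm_adjust(p_raw) if holm else p_raw
    return pd.DataFrame({
        "effect": effects,
        "statistic": [results[e].statistic for e in effects],
        "p_raw": p_raw,
        "p_holm": p_holm,
        "effect_size": [results[e].effect_size for e in effects],
        "n_perm": [results[e].n_permutations for e in effects],
        "seed": [results[e].seed for e in effects],
    })
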