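"""Group statistics: within-subject SEM, paired t tests, and the 2x2
repeated-measures ANOVA (with generalized eta-squared) used for the TMS
behavioral contrasts.

The within-subject SEM removes each subject's mean level before computing
the between-subject spread (Cousineau normalisation), which is the
appropriate error bar for repeated-measures designs.  The 2x2 ANOVA is
computed from its sum-of-squares decomposition directly; each effect is
tested against its own subject-by-effect interaction stratum, and
generalized eta-squared uses SS_effect / (SS_effect + SS_subjects + all
within-subject error strata).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedTestResult",
    "AnovaEffect",
    "within_subject_sem",
    "paired_t",
    "rm_anova_2x2",
]


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float
    degenerate: bool = False        # zero-variance differences

    def __str__(self):
        return (f"t({self.df}) = {self.t:.2f}, p = {self.p:.3g}, "
                f"CI = [{self.ci_low:.3g}, {self.ci_high:.3g}]")


def paired_t(a, b, ci: float = 0.95) -> PairedTestResult:
    """Two-sided paired t test with a confidence interval on the mean difference."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    md = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        t = 0.0 if md == 0.0 else np.inf * np.sign(md)
        p = 1.0 if md == 0.0 else 0.0
        return PairedTestResult(float(t), df, p, float(md), float(md), float(md),
                                degenerate=md != 0.0)
    se = sd / np.sqrt(n)
    t = md / se
    p = 2.0 * sps.t.sf(abs(t), df)
    half = sps.t.ppf(0.5 + ci / 2.0, df) * se
    return PairedTestResult(float(t), df, float(p), float(md),
                            float(md - half), float(md + half))


def within_subject_sem(table, morey: bool = False) -> np.ndarray:
    """Per-condition SEM after removing each subject's mean level.

    ``table`` is subjects x conditions (array or DataFrame).  Each subject's
    mean is subtracted and the grand mean added back before computing the
    ordinary between-subject SEM per condition.  With ``morey=True`` the
    small-sample bias correction factor sqrt(C / (C - 1)) is applied.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D table with at least two subjects")
    n, c = x.shape
    centered = x - x.mean(axis=1, keepdims=True) + x.mean()
    sem = centered.std(axis=0, ddof=1) / np.sqrt(n)
    if morey:
        sem = sem * np.sqrt(c / (c - 1))
    return sem


@dataclass(frozen=True)
class AnovaEffect:
    name: str
    F: float
    df: tuple
    p: float
    ges: float                      # generalized eta-squared


def rm_anova_2x2(table) -> dict:
    """Two-way fully-within-subject ANOVA on a complete 2x2 design.

    ``table`` is an array of shape (subjects, 2, 2) — factor A (e.g. task)
    by factor B (e.g. stimulation period) — or a DataFrame with a 2-level
    MultiIndex / 4 columns orderable as (A1B1, A1B2, A2B1, A2B2).  Returns
    ``{"A": AnovaEffect, "B": ..., "AxB": ...}``, each tested with
    F(1, n-1) against its own interaction-with-subjects stratum.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim == 2 and x.shape[1] == 4:
        x = x.reshape(-1, 2, 2)
    if x.ndim != 3 or x.shape[1:] != (2, 2):
        raise ValueError("expected a complete subjects x 2 x 2 table")
    if np.isnan(x).any():
        raise ValueError("table has missing cells")
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")

    grand = x.mean()
    m_s = x.mean(axis=(1, 2))                 # subject means
    m_a = x.mean(axis=(0, 2))                 # factor-A level means
    m_b = x.mean(axis=(0, 1))
    m_ab = x.mean(axis=0)                     # cell means
    m_as = x.mean(axis=2)                     # subject x A
    m_bs = x.mean(axis=1)                     # subject x B

    ss_a = 2 * n * ((m_a - grand) ** 2).sum()
    ss_b = 2 * n * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_subj = 4 * ((m_s - grand) ** 2).sum()
    ss_as = 2 * ((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_bs = 2 * ((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_abs = ss_tot - ss_a - ss_b - ss_ab - ss_subj - ss_as - ss_bs
    ss_abs = max(ss_abs, 0.0)

    err_all = ss_as + ss_bs + ss_abs
    df_e = n - 1

    def effect(name, ss_eff, ss_err):
        if ss_err == 0.0:
            f = 0.0 if ss_eff == 0.0 else np.inf
            p = 1.0 if ss_eff == 0.0 else 0.0
        else:
            f = (ss_eff / 1.0) / (ss_err / df_e)
            p = float(sps.f.sf(f, 1, df_e))
        denom = ss_eff + ss_subj + err_all
        ges = 0.0 if denom == 0.0 else ss_eff / denom
        return AnovaEffect(name, float(f), (1, df_e), float(p), float(ges))

    return {
        "A": effect("A", ss_a, ss_as),
        "B": effect("B", ss_b, ss_bs),
        "AxB": effect("AxB", ss_ab, ss_abs),
    }
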