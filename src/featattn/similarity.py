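"""Accuracy-contingent cross-task pattern similarity (attentional priority).

The quality of attentional selection on correct vs incorrect trials is
indexed by correlating the attention task's voxel-amplitude patterns with
the baseline task's correct-rejection patterns for the *matching* direction
(attention-CW with baseline-CW, attention-CCW with baseline-CCW).  The two
matched-direction Pearson correlations are averaged per accuracy condition
and Fisher-transformed for inference; mismatched-direction correlations are
returned as a diagnostic but never enter the index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import PairedTestResult, paired_t

__all__ = ["PriorityIndex", "priority_index", "accuracy_contrast", "fisher_z"]

_R_CLAMP = 1.0 - 1e-7


def fisher_z(r) -> np.ndarray | float:
    """Variance-stabilising atanh, with r clamped away from +-1."""
    r = np.clip(np.asarray(r, dtype=float), -_R_CLAMP, _R_CLAMP)
    z = np.arctanh(r)
    return z if z.ndim else float(z)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("zero-variance pattern: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass(frozen=True)
class PriorityIndex:
    """Mean matched-direction correlation per accuracy condition."""

    r_correct: float
    r_incorrect: float
    z_correct: float
    z_incorrect: float
    cross_r_correct: float          # mismatched-direction diagnostic
    cross_r_incorrect: float

    @property
    def contrast(self) -> float:
        return self.z_correct - self.z_incorrect


def priority_index(attention_patterns, baseline_patterns, mask=None) -> PriorityIndex:
    """Attentional-priority index from amplitude patterns.

    Parameters
    ----------
    attention_patterns : mapping
        ``{("CW", "correct"): vector, ("CW", "incorrect"): ..., ("CCW", ...)}``
        — amplitude vectors for cued direction crossed with response accuracy.
    baseline_patterns : mapping
        ``{"CW": vector, "CCW": vector}`` — correct-rejection amplitude
        patterns from the baseline task.
    mask : boolean array, optional
        Common voxel keep-mask (the >5% exclusion), applied to every pattern.
    """
    def take(v):
        v = np.asarray(v, dtype=float)
        return v[mask] if mask is not None else v

    base = {d: take(baseline_patterns[d]) for d in ("CW", "CCW")}
    n = len(base["CW"])
    if n < 3:
        raise ValueError(f"only {n} voxels after masking; need >= 3")

    out = {}
    cross = {}
    for acc in ("correct", "incorrect"):
        rs = [_pearson(take(attention_patterns[(d, acc)]), base[d])
              for d in ("CW", "CCW")]
        out[acc] = float(np.mean(rs))
        xs = [_pearson(take(attention_patterns[(d, acc)]), base[o])
              for d, o in (("CW", "CCW"), ("CCW", "CW"))]
        cross[acc] = float(np.mean(xs))
    return PriorityIndex(
        r_correct=out["correct"], r_incorrect=out["incorrect"],
        z_correct=fisher_z(out["correct"]), z_incorrect=fisher_z(out["incorrect"]),
        cross_r_correct=cross["correct"], cross_r_incorrect=cross["incorrect"],
    )


def accuracy_contrast(indices) -> PairedTestResult:
    """Planned paired t test of z_correct vs z_incorrect across subjects."""
    z_c = np.array([ix.z_correct for ix in indices])
    z_i = np.array([ix.z_incorrect for ix in indices])
    return paired_t(z_c, z_i)
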