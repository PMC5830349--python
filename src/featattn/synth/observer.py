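"""Generative observer: psychometric responding coupled to attentional fidelity.

The observer detects a speed increment according to a Weibull psychometric.
In the attention task a latent per-trial selection fidelity ``g_t in [0, 1]``
scales the observer's sensitivity: the effective threshold on trial ``t`` is
``alpha / g_t``, so trials on which the cued direction was well selected
(high ``g_t``) are more likely to be hits.  The same ``g_t`` later mixes the
direction-selective voxel patterns in the BOLD generator, which is what
couples behavioral accuracy to pattern fidelity — the causal structure the
downstream similarity and decoding analyses are designed to detect.

The baseline task involves a single, unambiguous direction, so responses
there use the raw threshold (``g_t`` fixed at 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..staircase import StaircaseState, WeibullPsychometric, classify_outcome, weibull_p
from .design import TASK_VARIANTS, SessionDesign

__all__ = [
    "BetaFidelity",
    "ConstantFidelity",
    "ObserverModel",
    "staircase_for_variant",
    "STAIRCASE_TARGETS",
    "simulate_behavior",
]

#: Target hit rate held by the staircase in each task variant.
STAIRCASE_TARGETS = {
    "attention": 0.65,
    "baseline": 0.50,
    "tms_attention": 0.80,
    "tms_baseline": 0.80,
}


@dataclass(frozen=True)
class BetaFidelity:
    """Beta-distributed per-trial selection fidelity g_t."""

    a: float = 3.0
    b: float = 1.3

    def __post_init__(self):
        if self.a <= 0 or self.b <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return rng.beta(self.a, self.b, size=n)


@dataclass(frozen=True)
class ConstantFidelity:
    """Degenerate fidelity distribution (g_t identically equal to a value)."""

    value: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.value <= 1.0):
            raise ValueError("fidelity must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return self.value

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return np.full(n, self.value)


@dataclass(frozen=True)
class ObserverModel:
    """A simulated observer.

    Parameters
    ----------
    psychometric : WeibullPsychometric
        True detection psychometric (threshold in speed-increment units).
    fidelity : BetaFidelity | ConstantFidelity
        Distribution of the latent per-trial selection fidelity g_t, applied
        in the attention task only.
    false_alarm_rate : float
        Probability of reporting "present" when no target occurred in the
        monitored channel (target-absent baseline trials; invalid attention
        trials under the task's response rule).
    tms_effect : float
        Multiplicative scaling of the true threshold after stimulation
        (1.0 = no effect; > 1 = impaired sensitivity).
    """

    psychometric: WeibullPsychometric
    fidelity: BetaFidelity | ConstantFidelity = ConstantFidelity(1.0)
    false_alarm_rate: float = 0.05
    tms_effect: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.false_alarm_rate < 1.0):
            raise ValueError("false_alarm_rate must lie in [0, 1)")
        if self.tms_effect <= 0:
            raise ValueError("tms_effect must be positive")

    def with_tms(self) -> "ObserverModel":
        """Observer with the post-stimulation threshold scaling applied."""
        psi = replace(self.psychometric,
                      threshold=self.psychometric.threshold * self.tms_effect)
        return replace(self, psychometric=psi)

    def p_hit(self, intensity: float, g: float = 1.0):
        """Hit probability at a given intensity and selection fidelity."""
        if g <= 0:
            # fully failed selection: only guesses remain
            return self.psychometric.guess_rate
        eff = replace(self.psychometric, threshold=self.psychometric.threshold / g)
        return weibull_p(intensity, eff)


def staircase_for_variant(task_variant: str, anchor: float = 1.0,
                          **kwargs) -> StaircaseState:
    """Staircase configured with the task variant's target hit rate."""
    if task_variant not in STAIRCASE_TARGETS:
        raise ValueError(f"unknown task variant {task_variant!r}")
    return StaircaseState(target=STAIRCASE_TARGETS[task_variant],
                          anchor=anchor, **kwargs)


def simulate_behavior(
    design: SessionDesign,
    observer: ObserverModel,
    staircase: StaircaseState | None = None,
    seed: int | None = None,
    fixed_intensity: float | None = None,
    decouple_fidelity: bool = False,
) -> pd.DataFrame:
    """Play the observer through a session, trial by trial.

    Attention variants: valid trials draw their intensity from the staircase
    (which is updated with the response); invalid trials reuse the magnitude
    of the preceding valid trial (carried across run boundaries within the
    session) and are scored against the false-alarm rate, since no target
    appears in the cued direction.  Baseline variants: target-present trials
    are staircase-controlled; target-absent trials are scored against the
    false-alarm rate.

    If ``fixed_intensity`` is given the staircase is bypassed entirely and
    every target-bearing trial uses that magnitude (TMS pre/post blocks run
    at the threshold found in a prior calibration session).

    ``decouple_fidelity`` severs the accuracy-fidelity coupling while
    keeping every marginal distribution intact: the fidelity that drives
    the response is drawn independently of the fidelity recorded for the
    voxel patterns, so correct and incorrect trials have identical pattern
    statistics (a null-model control).

    Returns the design's trial table augmented with: intensity, g (latent
    fidelity; 1.0 for baseline variants), p_response, response, outcome.
    """
    if staircase is None and fixed_intensity is None:
        staircase = staircase_for_variant(design.task_variant)
    if staircase is not None and staircase.target != STAIRCASE_TARGETS[design.task_variant]:
        raise ValueError(
            f"staircase target {staircase.target} does not match the "
            f"{design.task_variant!r} variant "
            f"(expected {STAIRCASE_TARGETS[design.task_variant]})"
        )
    rng = np.random.default_rng(seed)
    cued = design.cued
    flag_col = "valid" if cued else "target_present"

    trials = design.trials.copy()
    n = len(trials)
    intensity = np.full(n, np.nan)
    g_arr = np.ones(n)
    p_arr = np.full(n, np.nan)
    responses = np.empty(n, dtype=object)
    outcomes = np.empty(n, dtype=object)

    last_valid_intensity = (
        fixed_intensity if fixed_intensity is not None
        else staircase.next_intensity()
    )
    for i, row in enumerate(trials.itertuples(index=False)):
        target_here = bool(getattr(row, flag_col))
        if cued:
            g = float(observer.fidelity.sample(rng, 1)[0])
            g_arr[i] = g
        if target_here:
            x = (fixed_intensity if fixed_intensity is not None
                 else staircase.next_intensity())
            last_valid_intensity = x
            g_resp = g_arr[i]
            if cued and decouple_fidelity:
                g_resp = float(observer.fidelity.sample(rng, 1)[0])
            p = float(observer.p_hit(x, g_resp if cued else 1.0))
            present = bool(rng.random() < p)
            if fixed_intensity is None:
                staircase.update(x, present)
        else:
            # invalid attention trial or target-absent baseline trial
            x = last_valid_intensity if cued else 0.0
            p = observer.false_alarm_rate
            present = bool(rng.random() < p)
        intensity[i] = x
        p_arr[i] = p
        responses[i] = "present" if present else "absent"
        outcomes[i] = classify_outcome(target_here, responses[i])

    trials["intensity"] = intensity
    trials["g"] = g_arr
    trials["p_response"] = p_arr
    trials["response"] = responses
    trials["outcome"] = outcomes
    return trials
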