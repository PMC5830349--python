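"""Best-PEST adaptive staircase over a Weibull psychometric function.

The staircase maintains a maximum-likelihood estimate of the observer's
threshold on a fixed grid of candidate values and places every trial at the
intensity where the fitted psychometric predicts the target performance
level.  Signal-detection bookkeeping (hit / miss / false alarm / correct
rejection and the hit-minus-false-alarm performance metric) lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WeibullPsychometric",
    "weibull_p",
    "weibull_inverse",
    "StaircaseState",
    "pest_next_intensity",
    "classify_outcome",
    "performance_metric",
]


@dataclass(frozen=True)
class WeibullPsychometric:
    """Weibull psychometric function.

    psi(x) = gamma + (1 - gamma - lambda) * (1 - exp(-(x / alpha)**beta))

    Parameters
    ----------
    threshold : float
        Alpha, the intensity at which performance reaches
        ``gamma + (1 - gamma - lambda) * (1 - 1/e)``.
    slope : float
        Beta, fixed at 2 in the tasks modelled here.
    guess_rate : float
        Gamma, probability of a correct "present" response at zero intensity.
    lapse_rate : float
        Lambda, the asymptotic miss probability at very large intensity.
    """

    threshold: float
    slope: float = 2.0
    guess_rate: float = 0.01
    lapse_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if not (0 <= self.guess_rate < 1) or not (0 <= self.lapse_rate < 1):
            raise ValueError("guess and lapse rates must lie in [0, 1)")
        if self.guess_rate + self.lapse_rate >= 1:
            raise ValueError("guess_rate + lapse_rate must be < 1")

    def p(self, x) :
        return weibull_p(x, self)

    def inverse(self, p: float) -> float:
        return weibull_inverse(p, self)


def weibull_p(x, psi: WeibullPsychometric):
    """Probability of a "present" response at intensity ``x``.

    Accepts scalars or arrays; raises on negative intensities.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("intensity must be non-negative")
    gamma, lam = psi.guess_rate, psi.lapse_rate
    out = gamma + (1.0 - gamma - lam) * (1.0 - np.exp(-((x / psi.threshold) ** psi.slope)))
    return out if out.ndim else float(out)


def weibull_inverse(p: float, psi: WeibullPsychometric) -> float:
    """Intensity at which the psychometric predicts performance ``p``.

    Only defined on the open interval (guess_rate, 1 - lapse_rate).
    """
    gamma, lam = psi.guess_rate, psi.lapse_rate
    if not (gamma < p < 1.0 - lam):
        raise ValueError(
            f"performance {p} has no finite inverse for guess={gamma}, lapse={lam}"
        )
    q = (p - gamma) / (1.0 - gamma - lam)
    return psi.threshold * (-np.log1p(-q)) ** (1.0 / psi.slope)


def _default_grid(anchor: float, span: float = 30.0, n: int = 201) -> np.ndarray:
    return np.geomspace(anchor / span, anchor * span, n)


@dataclass
class StaircaseState:
    """Best-PEST staircase state.

    The candidate thresholds are a log-spaced grid around an anchor; after
    every response the Bernoulli log-likelihood of the full history is
    accumulated per candidate, and the maximum-likelihood candidate (ties
    broken toward the smaller threshold) drives the next intensity.

    Parameters
    ----------
    target : float
        Hit rate the staircase tries to hold (0.65 attention task,
        0.50 baseline task, 0.80 TMS variants).
    anchor : float
        Centre of the log-spaced candidate-threshold grid, in the task's
        intensity units (speed-increment magnitude).
    slope, guess_rate, lapse_rate : float
        Assumed psychometric shape (shared across all candidates).
    max_intensity : float
        Physical ceiling; proposed intensities are clipped to
        ``[0, max_intensity]``.
    """

    target: float
    anchor: float = 1.0
    slope: float = 2.0
    guess_rate: float = 0.01
    lapse_rate: float = 0.01
    grid_span: float = 30.0
    grid_size: int = 201
    max_intensity: float = np.inf
    grid: np.ndarray = field(init=False, repr=False)
    _loglik: np.ndarray = field(init=False, repr=False)
    history: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not (self.guess_rate < self.target < 1.0 - self.lapse_rate):
            raise ValueError(
                "target performance must lie strictly between the guess rate "
                "and 1 - lapse rate for the inverse psychometric to exist"
            )
        self.grid = _default_grid(self.anchor, self.grid_span, self.grid_size)
        self._loglik = np.zeros_like(self.grid)

    # -- likelihood bookkeeping -------------------------------------------
    def update(self, intensity: float, correct: bool) -> None:
        """Fold one (intensity, response) pair into the likelihood."""
        gamma, lam = self.guess_rate, self.lapse_rate
        p = gamma + (1.0 - gamma - lam) * (
            1.0 - np.exp(-((intensity / self.grid) ** self.slope))
        )
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        self._loglik += np.log(p) if correct else np.log1p(-p)
        self.history.append((float(intensity), bool(correct)))

    @property
    def ml_threshold(self) -> float:
        """Grid candidate maximising the history likelihood.

        With no history the likelihood is flat and the tie-break toward the
        smaller candidate would be degenerate, so the anchor (the grid's
        geometric midpoint) is returned instead.
        """
        if not self.history:
            return float(self.grid[(len(self.grid) - 1) // 2])
        # argmax returns the first maximum: the grid is ascending, so ties
        # resolve toward the smaller threshold.
        return float(self.grid[int(np.argmax(self._loglik))])

    def psychometric(self) -> WeibullPsychometric:
        return WeibullPsychometric(
            self.ml_threshold, self.slope, self.guess_rate, self.lapse_rate
        )

    def next_intensity(self) -> float:
        return pest_next_intensity(self)

    def trace(self) -> pd.DataFrame:
        """History as a tidy table (trial, intensity, correct, ml threshold)."""
        rows = []
        replay = StaircaseState(
            target=self.target, anchor=self.anchor, slope=self.slope,
            guess_rate=self.guess_rate, lapse_rate=self.lapse_rate,
            grid_span=self.grid_span, grid_size=self.grid_size,
            max_intensity=self.max_intensity,
        )
        for i, (x, c) in enumerate(self.history):
            replay.update(x, c)
            rows.append({"trial": i, "intensity": x, "correct": c,
                         "ml_threshold": replay.ml_threshold})
        return pd.DataFrame(rows, columns=["trial", "intensity", "correct", "ml_threshold"])


def pest_next_intensity(state: StaircaseState) -> float:
    """Intensity at which the ML-fitted Weibull predicts the target rate."""
    x = weibull_inverse(state.target, state.psychometric())
    return float(np.clip(x, 0.0, state.max_intensity))


_OUTCOMES = ("hit", "miss", "false_alarm", "correct_rejection")


def classify_outcome(target_present: bool, response: str) -> str:
    """Signal-detection outcome of one trial.

    ``target_present`` means a target occurred in the monitored channel: a
    valid trial in the attention task (speedup in the cued direction) or a
    target-present trial in the baseline task.  Invalid attention trials
    (speedup only in the uncued direction) count as target-absent under the
    task's response rule.
    """
    if response not in ("present", "absent"):
        raise ValueError(f"unknown response {response!r}")
    if target_present:
        return "hit" if response == "present" else "miss"
    return "false_alarm" if response == "present" else "correct_rejection"


def performance_metric(outcomes) -> float:
    """Hit rate minus false-alarm rate.

    ``outcomes`` is an iterable of outcome strings.  The hit rate is taken
    over target-present opportunities (hits + misses) and the false-alarm
    rate over target-absent opportunities (false alarms + correct
    rejections); both denominators must be non-empty.
    """
    counts = {o: 0 for o in _OUTCOMES}
    for o in outcomes:
        if o not in counts:
            raise ValueError(f"unknown outcome {o!r}")
        counts[o] += 1
    n_present = counts["hit"] + counts["miss"]
    n_absent = counts["false_alarm"] + counts["correct_rejection"]
    if n_present == 0 or n_absent == 0:
        raise ValueError("need at least one target-present and one target-absent trial")
    return counts["hit"] / n_present - counts["false_alarm"] / n_absent
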