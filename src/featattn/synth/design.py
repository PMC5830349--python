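"""Trial-sequence and timing generators for the attention and baseline tasks.

Two families of designs are produced:

* fMRI variants (``attention``, ``baseline``): 0.3-s cue (or fixation), 4.1-s
  dot fields, 0.2-s speedup window, ITIs of 4.2/6.4/8.6/10.8 s in exact
  40/30/20/10% proportions, preceded by an 8.8-s fixation lead.  All trial
  durations are multiples of the 2.2-s TR, so a 30-trial run lasts exactly
  338.8 s.
* TMS variants (``tms_attention``, ``tms_baseline``): 3.7-s dot fields and
  compressed ITIs (1.35/1.8/2.25/2.7 s, same proportions) so that a 100-trial
  run lasts 600 s, matching the stimulation protocol; no fixation lead.

Cue validity is 80% for the fMRI attention task and 70% for the TMS variant;
the baseline task presents a target on 70% of trials.  Directions (CW/CCW)
are balanced within each run, separately within each validity / presence
stratum, to within one trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SessionDesign", "make_session_design", "TASK_VARIANTS"]

TR_DEFAULT = 2.2


@dataclass(frozen=True)
class _VariantSpec:
    cue_s: float
    stim_s: float
    speedup_s: float
    itis: tuple
    iti_props: tuple
    fixation_lead: float
    cued: bool              # attention-style (cue + validity) vs baseline-style
    valid_prop: float       # P(valid) if cued, else P(target present)


TASK_VARIANTS = {
    "attention": _VariantSpec(0.3, 4.1, 0.2, (4.2, 6.4, 8.6, 10.8),
                              (0.4, 0.3, 0.2, 0.1), 8.8, True, 0.80),
    "baseline": _VariantSpec(0.3, 4.1, 0.2, (4.2, 6.4, 8.6, 10.8),
                             (0.4, 0.3, 0.2, 0.1), 8.8, False, 0.70),
    "tms_attention": _VariantSpec(0.3, 3.7, 0.2, (1.35, 1.8, 2.25, 2.7),
                                  (0.4, 0.3, 0.2, 0.1), 0.0, True, 0.70),
    "tms_baseline": _VariantSpec(0.3, 3.7, 0.2, (1.35, 1.8, 2.25, 2.7),
                                 (0.4, 0.3, 0.2, 0.1), 0.0, False, 0.70),
}


@dataclass
class SessionDesign:
    """A full session's trial sequence with onsets and timing.

    ``trials`` has one row per trial with columns: run, trial (index within
    run), onset (s from run start), cue_s, stim_s, speedup_s, iti, duration,
    direction (cued direction for attention variants, displayed direction for
    baseline variants), and either ``valid`` (attention) or ``target_present``
    (baseline).
    """

    task_variant: str
    tr: float
    fixation_lead: float
    trials: pd.DataFrame
    seed: int | None = None

    @property
    def n_runs(self) -> int:
        return 0 if self.trials.empty else int(self.trials["run"].max()) + 1

    @property
    def cued(self) -> bool:
        return TASK_VARIANTS[self.task_variant].cued

    def run_duration(self, run: int = 0) -> float:
        sub = self.trials[self.trials["run"] == run]
        return round(self.fixation_lead + float(sub["duration"].sum()), 10)

    def n_volumes(self, run: int = 0) -> int:
        return int(round(self.run_duration(run) / self.tr))

    @property
    def discard_lead(self) -> int:
        return int(round(self.fixation_lead / self.tr))


def _balanced_binary(n: int, prop: float, rng: np.random.Generator) -> np.ndarray:
    """Shuffled boolean vector with exactly round(n * prop) True entries."""
    k = int(round(n * prop))
    out = np.zeros(n, dtype=bool)
    out[:k] = True
    rng.shuffle(out)
    return out


def _balanced_directions(flags: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """CW/CCW assignment balanced to within +-1 inside each stratum of flags."""
    dirs = np.empty(len(flags), dtype=object)
    for level in (True, False):
        idx = np.flatnonzero(flags == level)
        half = len(idx) // 2
        n_cw = half + (rng.integers(2) if len(idx) % 2 else 0)
        lab = np.array(["CW"] * n_cw + ["CCW"] * (len(idx) - n_cw), dtype=object)
        rng.shuffle(lab)
        dirs[idx] = lab
    return dirs


def make_session_design(
    task_variant: str,
    n_runs: int,
    trials_per_run: int,
    seed: int | None = None,
    tr: float = TR_DEFAULT,
) -> SessionDesign:
    """Build a session's trial sequence for one task variant.

    ``trials_per_run`` must be divisible by 10 so the ITI proportions and
    validity / target-presence rates are realised exactly within each run
    (a run of zero trials, i.e. fixation only, is allowed).
    """
    if task_variant not in TASK_VARIANTS:
        raise ValueError(
            f"unknown task variant {task_variant!r}; expected one of {sorted(TASK_VARIANTS)}"
        )
    if trials_per_run % 10 != 0 or trials_per_run < 0:
        raise ValueError(
            f"trials_per_run must be a non-negative multiple of 10, got {trials_per_run}"
        )
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")

    spec = TASK_VARIANTS[task_variant]
    rng = np.random.default_rng(seed)
    trial_s = spec.cue_s + spec.stim_s + spec.speedup_s

    rows = []
    for run in range(n_runs):
        # exact ITI multiset for this run, randomly ordered
        itis = np.repeat(spec.itis,
                         [int(round(p * trials_per_run)) for p in spec.iti_props])
        rng.shuffle(itis)
        flags = _balanced_binary(trials_per_run, spec.valid_prop, rng)
        dirs = _balanced_directions(flags, rng)
        onset = spec.fixation_lead
        for t in range(trials_per_run):
            dur = trial_s + itis[t]
            row = {
                "run": run, "trial": t, "onset": round(onset, 10),
                "cue_s": spec.cue_s, "stim_s": spec.stim_s,
                "speedup_s": spec.speedup_s, "iti": itis[t],
                "duration": round(dur, 10), "direction": dirs[t],
            }
            row["valid" if spec.cued else "target_present"] = bool(flags[t])
            rows.append(row)
            onset += dur

    cols = ["run", "trial", "onset", "cue_s", "stim_s", "speedup_s", "iti",
            "duration", "direction", "valid" if spec.cued else "target_present"]
    trials = pd.DataFrame(rows, columns=cols)
    return SessionDesign(task_variant, tr, spec.fixation_lead, trials, seed)
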