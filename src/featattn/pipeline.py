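"""End-to-end simulated experiments: subject and cohort drivers.

One simulated subject consists of an observer (Weibull threshold + latent
selection-fidelity distribution), an ROI (direction patterns), a
staircase-controlled attention session and a baseline session, each rendered
into voxel time series.  Analysis mirrors the experimental pipeline:
preprocessing, FIR deconvolution per task, peak-window amplitude read-out,
the >5% voxel exclusion, the matched-direction pattern-similarity index,
and cross-task SVM decoding.  Cohort drivers repeat this over subjects with
independent seed streams and run the group statistics.

The TMS driver simulates the behavioral experiments: per subject and task,
a thresholding phase fixes the speed-increment magnitude, and pre/post
blocks are run with the post-stimulation block under a multiplicative
threshold scaling that is selective for the attention task (emulating
disruption of a priority-maintaining region) or absent (sham).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import glm
from .decoding import (
    TrialInstanceSet,
    extract_instances,
    permutation_null,
    select_voxels,
    train_test,
)
from .similarity import PriorityIndex, accuracy_contrast, priority_index
from .staircase import (
    StaircaseState,
    WeibullPsychometric,
    performance_metric,
    weibull_p,
)
from .stats import paired_t, rm_anova_2x2
from .synth.bold import GeneratedDataset, NoiseSpec, ROISpec, make_roi, simulate_bold
from .synth.design import SessionDesign, make_session_design
from .synth.observer import (
    BetaFidelity,
    ConstantFidelity,
    ObserverModel,
    STAIRCASE_TARGETS,
    simulate_behavior,
    staircase_for_variant,
)

__all__ = [
    "SubjectConfig",
    "SubjectData",
    "SubjectResult",
    "calibrate_staircase",
    "staircase_closed_loop",
    "simulate_subject",
    "simulate_subject_behavior",
    "analyze_subject",
    "run_cohort",
    "cohort_summary",
    "simulate_tms_experiment",
    "tms_statistics",
]


def staircase_closed_loop(task_variant: str, n_trials: int,
                          seed: int | None = None,
                          threshold: float = 1.0) -> np.ndarray:
    """Run a task's staircase against a matched Weibull observer.

    The observer's true psychometric belongs to the family the staircase
    assumes (slope 2, guess and lapse 1%), so the achieved hit rate should
    settle at the task's target.  Returns the boolean hit sequence over the
    ``n_trials`` target-bearing trials.
    """
    rng = np.random.default_rng(seed)
    stair = staircase_for_variant(task_variant, anchor=threshold)
    psi = WeibullPsychometric(threshold)
    hits = np.empty(n_trials, dtype=bool)
    for t in range(n_trials):
        x = stair.next_intensity()
        hits[t] = rng.random() < weibull_p(x, psi)
        stair.update(x, bool(hits[t]))
    return hits


@dataclass(frozen=True)
class SubjectConfig:
    """Study conditions for one simulated fMRI subject.

    Defaults follow the experimental design: 6 runs of 30 trials per task,
    80% cue validity (attention) and 70% target presence (baseline), a
    staircase pre-calibrated with 100 trials, and an ROI comfortably larger
    than the 55 voxels the decoder keeps.
    """

    n_runs: int = 6
    trials_per_run: int = 30
    n_voxels: int = 200
    selectivity: float = 0.3
    threshold: float = 1.0
    fidelity: BetaFidelity | ConstantFidelity = BetaFidelity(1.0, 0.45)
    fa_attention: float = 0.10
    fa_baseline: float = 0.05
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    calibration_trials: int = 100
    k_voxels: int = 55
    decouple_fidelity: bool = False   # null-model control: g independent of accuracy

    def observer(self, task: str) -> ObserverModel:
        psi = WeibullPsychometric(self.threshold)
        if task == "attention":
            return ObserverModel(psi, self.fidelity, self.fa_attention)
        return ObserverModel(psi, ConstantFidelity(1.0), self.fa_baseline)


@dataclass
class SubjectData:
    roi: ROISpec
    attention: GeneratedDataset
    baseline: GeneratedDataset
    config: SubjectConfig
    seed: int | None = None


def calibrate_staircase(
    staircase: StaircaseState,
    observer: ObserverModel,
    n_trials: int,
    rng: np.random.Generator,
    attention: bool = True,
) -> StaircaseState:
    """Warm up a staircase against an observer (pre-scan calibration trials).

    Every calibration trial is target-bearing (a valid trial for the
    attention task); attention calibration samples the observer's fidelity
    fluctuations, so the staircase settles on the intensity at which the
    observer's *composite* psychometric meets the target rate.
    """
    for _ in range(n_trials):
        x = staircase.next_intensity()
        g = float(observer.fidelity.sample(rng, 1)[0]) if attention else 1.0
        staircase.update(x, bool(rng.random() < observer.p_hit(x, g)))
    return staircase


def _child_seeds(seed, n):
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def simulate_subject_behavior(config: SubjectConfig = SubjectConfig(),
                              seed: int | None = None) -> dict:
    """Simulate only the behavioral part of one subject's two sessions.

    Returns ``{"attention": trials, "baseline": trials}``, identical to what
    :func:`simulate_subject` would record (same seed streams), without
    rendering BOLD time series.
    """
    _, s_att_d, s_att_b, _, s_base_d, s_base_b, _, s_cal = _child_seeds(seed, 8)
    out = {}
    for task, s_design, s_behav in (
        ("attention", s_att_d, s_att_b),
        ("baseline", s_base_d, s_base_b),
    ):
        observer = config.observer(task)
        design = make_session_design(task, config.n_runs, config.trials_per_run,
                                     seed=s_design)
        stair = staircase_for_variant(task, anchor=config.threshold)
        calibrate_staircase(stair, observer, config.calibration_trials,
                            np.random.default_rng(s_cal + (task == "baseline")),
                            attention=(task == "attention"))
        out[task] = simulate_behavior(design, observer, stair, seed=s_behav,
                                      decouple_fidelity=(config.decouple_fidelity
                                                         and task == "attention"))
    return out


def simulate_subject(config: SubjectConfig = SubjectConfig(),
                     seed: int | None = None) -> SubjectData:
    """Simulate one subject's attention and baseline sessions."""
    s_roi, s_att_d, s_att_b, s_att_bold, s_base_d, s_base_b, s_base_bold, s_cal = \
        _child_seeds(seed, 8)
    roi = make_roi(config.n_voxels, config.selectivity, s_roi)
    data = {}
    for task, s_design, s_behav, s_bold in (
        ("attention", s_att_d, s_att_b, s_att_bold),
        ("baseline", s_base_d, s_base_b, s_base_bold),
    ):
        observer = config.observer(task)
        design = make_session_design(task, config.n_runs, config.trials_per_run,
                                     seed=s_design)
        stair = staircase_for_variant(task, anchor=config.threshold)
        calibrate_staircase(stair, observer, config.calibration_trials,
                            np.random.default_rng(s_cal + (task == "baseline")),
                            attention=(task == "attention"))
        trials = simulate_behavior(design, observer, stair, seed=s_behav,
                                   decouple_fidelity=(config.decouple_fidelity
                                                      and task == "attention"))
        data[task] = simulate_bold(design, trials, roi, config.noise,
                                   seed=s_bold)
    return SubjectData(roi, data["attention"], data["baseline"], config, seed)


_ATTN_PATTERN_KEYS = {
    ("CW", "correct"): "CW_hit", ("CW", "incorrect"): "CW_miss",
    ("CCW", "correct"): "CCW_hit", ("CCW", "incorrect"): "CCW_miss",
}


@dataclass
class SubjectResult:
    priority: PriorityIndex
    acc_correct: float
    acc_incorrect: float
    predictions: np.ndarray         # classifier output on pooled attention trials
    peak_tap: int
    n_excluded: int
    counts: dict                    # behavioral trial-count bookkeeping


def analyze_subject(data: SubjectData, k: int | None = None) -> SubjectResult:
    """Run the full analysis pipeline on one simulated subject."""
    cfg = data.config
    k = cfg.k_voxels if k is None else k

    ts = {}
    est = {}
    for task, ds, conds in (
        ("attention", data.attention, glm.ATTENTION_CONDITIONS),
        ("baseline", data.baseline, glm.BASELINE_CONDITIONS),
    ):
        raw = glm.VoxelTimeSeries.from_dataset(ds)
        pre = glm.preprocess(raw)
        design = glm.build_fir_design(ds.events, pre.run_lengths, pre.tr,
                                      conditions=conds,
                                      discard_lead=ds.discard_lead)
        ts[task] = pre
        est[task] = glm.deconvolve(pre, design)

    # one response profile per subject: average the two tasks' mean profiles
    profile = np.mean(
        [est[t].responses.mean(axis=(0, 1)) for t in ("attention", "baseline")],
        axis=0,
    )
    lo, hi = glm.PEAK_TAP_RANGE
    peak_tap = lo + int(np.argmax(profile[lo - 1:hi]))

    amp = {t: glm.peak_and_amplitude(est[t], peak_tap=peak_tap)
           for t in ("attention", "baseline")}
    mask = glm.exclude_voxels(amp["attention"]) & glm.exclude_voxels(amp["baseline"])

    attn_patterns = {key: amp["attention"].vector(cond)
                     for key, cond in _ATTN_PATTERN_KEYS.items()}
    base_patterns = {d: amp["baseline"].vector(f"{d}_correct_rejection")
                     for d in ("CW", "CCW")}
    prio = priority_index(attn_patterns, base_patterns, mask=mask)

    # decoding: top-k baseline-task r2 voxels among the non-excluded ones
    kept_idx = np.flatnonzero(mask)
    sel = kept_idx[select_voxels(est["baseline"].r2[kept_idx], k)]

    base_ev = data.baseline.events
    cr_ev = base_ev[base_ev["outcome"] == "correct_rejection"]
    train_set = extract_instances(ts["baseline"], cr_ev, peak_tap, sel,
                                  discard_lead=data.baseline.discard_lead)

    att_ev = data.attention.events
    valid_ev = att_ev[att_ev["trial_type"] != "invalid"].copy()
    valid_ev["accuracy"] = np.where(valid_ev["outcome"] == "hit",
                                    "correct", "incorrect")
    test_set = extract_instances(ts["attention"], valid_ev, peak_tap, sel,
                                 label_cols=("direction", "accuracy"),
                                 discard_lead=data.attention.discard_lead)

    res = train_test(train_set, test_set)

    att_trials = data.attention.trials
    base_trials = data.baseline.trials
    valid = att_trials[att_trials["valid"].astype(bool)]
    counts = {
        "valid_hits": int((valid["outcome"] == "hit").sum()),
        "valid_misses": int((valid["outcome"] == "miss").sum()),
        "correct_rejections": int((base_trials["outcome"] == "correct_rejection").sum()),
        "cw_correct_rejections": int(((base_trials["outcome"] == "correct_rejection")
                                      & (base_trials["direction"] == "CW")).sum()),
        "n_train": len(train_set),
        "n_test_correct": res["n_correct"],
        "n_test_incorrect": res["n_incorrect"],
    }
    return SubjectResult(prio, res["correct"], res["incorrect"],
                         res["predictions"], peak_tap,
                         int((~mask).sum()), counts)


def run_cohort(n_subjects: int = 12, config: SubjectConfig = SubjectConfig(),
               seed: int | None = None) -> list:
    """Simulate and analyze a cohort; returns one SubjectResult per subject."""
    seeds = _child_seeds(seed, n_subjects)
    return [analyze_subject(simulate_subject(config, s)) for s in seeds]


def cohort_summary(results, n_subject_perms: int = 0, n_group_perms: int = 0,
                   perm_seed: int | None = None) -> dict:
    """Group statistics over a cohort of subject results.

    Always returns the similarity and decoding accuracy contrasts; if
    permutation counts are given, also the two-level null and significance
    flags for the correct- and incorrect-trial group accuracies.
    """
    prios = [r.priority for r in results]
    acc_c = np.array([r.acc_correct for r in results])
    acc_i = np.array([r.acc_incorrect for r in results])
    out = {
        "similarity_contrast": accuracy_contrast(prios),
        "decoding_contrast": paired_t(acc_c, acc_i),
        "z_correct": np.array([p.z_correct for p in prios]),
        "z_incorrect": np.array([p.z_incorrect for p in prios]),
        "acc_correct": acc_c,
        "acc_incorrect": acc_i,
    }
    if n_subject_perms and n_group_perms:
        null = permutation_null([r.predictions for r in results],
                                n_subject_perms, n_group_perms, perm_seed)
        out["null"] = null
        out["flag_correct"] = null.flag(float(acc_c.mean()))
        out["flag_incorrect"] = null.flag(float(acc_i.mean()))
    return out


# ---------------------------------------------------------------------------
# TMS behavioral experiments
# ---------------------------------------------------------------------------

def simulate_tms_experiment(
    n_subjects: int = 12,
    tms_effects: dict | None = None,
    threshold: float = 1.0,
    fidelity: BetaFidelity | ConstantFidelity = BetaFidelity(1.0, 0.45),
    fa_attention: float = 0.10,
    fa_baseline: float = 0.05,
    thresholding_trials: int = 300,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate pre/post-stimulation blocks of both TMS task variants.

    ``tms_effects`` maps task ("attention" | "baseline") to the
    post-stimulation multiplicative threshold scaling (1.0 = no effect).
    The default emulates a parietal stimulation that selectively degrades
    feature selection in the attention task.  Each block is one 100-trial
    run at the magnitude fixed during thresholding; performance is hit rate
    minus false-alarm rate.  Returns a tidy table with columns subject,
    task, period, hit_minus_fa.
    """
    if tms_effects is None:
        tms_effects = {"attention": 1.3, "baseline": 1.0}
    rows = []
    subj_seeds = _child_seeds(seed, n_subjects)
    for s, s_seed in enumerate(subj_seeds):
        task_seeds = _child_seeds(s_seed, 2)
        for task, t_seed in zip(("attention", "baseline"), task_seeds):
            variant = f"tms_{task}"
            fid = fidelity if task == "attention" else ConstantFidelity(1.0)
            fa = fa_attention if task == "attention" else fa_baseline
            observer = ObserverModel(WeibullPsychometric(threshold), fid, fa,
                                     tms_effect=tms_effects[task])
            s_cal, s_pre_d, s_pre_b, s_post_d, s_post_b = _child_seeds(t_seed, 5)
            stair = staircase_for_variant(variant, anchor=threshold)
            calibrate_staircase(stair, observer, thresholding_trials,
                                np.random.default_rng(s_cal),
                                attention=(task == "attention"))
            fixed = stair.next_intensity()
            for period, s_d, s_b, obs in (
                ("pre", s_pre_d, s_pre_b, observer),
                ("post", s_post_d, s_post_b, observer.with_tms()),
            ):
                design = make_session_design(variant, 1, 100, seed=s_d)
                trials = simulate_behavior(design, obs, seed=s_b,
                                           fixed_intensity=fixed)
                rows.append({
                    "subject": s, "task": task, "period": period,
                    "hit_minus_fa": performance_metric(trials["outcome"]),
                })
    return pd.DataFrame(rows)


def tms_statistics(table: pd.DataFrame) -> dict:
    """Planned pre/post t tests per task and the 2x2 task-by-period ANOVA."""
    wide = table.pivot_table(index="subject", columns=["task", "period"],
                             values="hit_minus_fa")
    arr = np.stack([
        np.stack([wide[("attention", "pre")], wide[("attention", "post")]], axis=1),
        np.stack([wide[("baseline", "pre")], wide[("baseline", "post")]], axis=1),
    ], axis=1)                                        # subjects x task x period
    return {
        "attention_pre_post": paired_t(wide[("attention", "pre")],
                                       wide[("attention", "post")]),
        "baseline_pre_post": paired_t(wide[("baseline", "pre")],
                                      wide[("baseline", "post")]),
        "anova": rm_anova_2x2(arr),
        "cell_means": wide.mean(axis=0),
    }
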