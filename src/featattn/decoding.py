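"""Cross-task decoding of the attended direction with a two-level
permutation null.

A linear support-vector machine is trained to discriminate CW from CCW
motion using single-trial patterns from the baseline task's correct
rejections, restricted to the top-k voxels ranked by baseline-task
r-squared (k = 55 by default).  It is then tested on single-trial attention
patterns — standardized with the *training* mean and SD — separately for
correct and incorrect trials.  Training and test data come from different
tasks acquired in separate runs, so no cross-validation is needed.

Chance level is characterised by a two-level permutation scheme: per
subject, the pooled attention trial labels (accuracy crossed with
direction) are shuffled and split into two equal classes, and the fixed
classifier's accuracy against the shuffled labels is recorded (10,000
shuffles); at the group level, one value per subject is resampled and
averaged (10,000 resamples).  Observed group accuracies below the 2.5th or
above the 97.5th percentile of the group null are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

__all__ = [
    "TrialInstanceSet",
    "TrainedClassifier",
    "NullDistribution",
    "select_voxels",
    "extract_instances",
    "train_classifier",
    "train_test",
    "subject_null",
    "permutation_null",
]


def select_voxels(r2: np.ndarray, k: int = 55) -> np.ndarray:
    """Indices of the k voxels with the largest r-squared.

    Ranking uses the baseline task's deconvolution fit.  Ties resolve
    deterministically toward the lower voxel index (stable sort on -r2).
    """
    r2 = np.asarray(r2, dtype=float)
    if k > len(r2):
        raise ValueError(f"k={k} exceeds the {len(r2)} available voxels")
    order = np.argsort(-r2, kind="stable")
    return np.sort(order[:k])


@dataclass
class TrialInstanceSet:
    """Single-trial voxel response vectors with their labels.

    ``labels`` has one row per instance with at least ``direction``
    (CW | CCW); attention-task sets also carry ``accuracy``
    (correct | incorrect).
    """

    X: np.ndarray                   # instances x voxels
    labels: pd.DataFrame
    window_volumes: tuple           # onset-relative volume indices averaged

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask) -> "TrialInstanceSet":
        mask = np.asarray(mask)
        return TrialInstanceSet(self.X[mask],
                                self.labels.iloc[mask].reset_index(drop=True),
                                self.window_volumes)


def extract_instances(
    ts,
    events: pd.DataFrame,
    peak_volume: int,
    voxel_indices: np.ndarray | None = None,
    label_cols=("direction",),
    discard_lead: int | None = None,
) -> TrialInstanceSet:
    """Average each trial's volumes from the response peak to 8.8 s.

    ``peak_volume`` is the 1-based onset-relative volume of the subject's
    response peak (3, 4 or 5); the averaging window runs from there through
    the 5th volume (the shortest trial duration, 8.8 s), i.e. one to three
    volumes.  ``ts`` is a preprocessed :class:`~featattn.glm.VoxelTimeSeries`
    and ``events`` needs ``run``, ``onset`` and the requested label columns.
    Event onsets are measured from the run start *including* any fixation
    lead; ``discard_lead`` (default: the series' own flag) says how many
    lead volumes the current representation has already dropped, so a
    preprocessed series should be given the original lead count.  Trials
    whose window is truncated by the run end are dropped with a warning.
    """
    if peak_volume not in (3, 4, 5):
        raise ValueError("peak_volume must be 3, 4 or 5 (1-based, taps 3-5)")
    if discard_lead is None:
        discard_lead = ts.discard_lead
    window = tuple(range(peak_volume, 6))             # 1-based volumes
    rel_idx = np.array(window) - 1                    # onset volume = index 0
    run_lengths = list(ts.run_lengths)
    offsets = np.concatenate([[0], np.cumsum(run_lengths)])
    rows_X, rows_lab, dropped = [], [], 0
    for row in events.itertuples(index=False):
        run = int(row.run)
        v0 = int(round(row.onset / ts.tr)) - discard_lead
        idx = v0 + rel_idx
        if idx[-1] >= run_lengths[run] or idx[0] < 0:
            dropped += 1
            continue
        inst = ts.data[:, offsets[run] + idx].mean(axis=1)
        rows_X.append(inst if voxel_indices is None else inst[voxel_indices])
        rows_lab.append({c: getattr(row, c) for c in label_cols})
    if dropped:
        warnings.warn(f"{dropped} trial(s) truncated before the instance "
                      "window were dropped", RuntimeWarning, stacklevel=2)
    X = np.array(rows_X) if rows_X else np.empty((0, ts.n_voxels))
    return TrialInstanceSet(X, pd.DataFrame(rows_lab), window)


@dataclass
class TrainedClassifier:
    """Linear SVM with its training standardization statistics."""

    svm: SVC
    mean: np.ndarray
    sd: np.ndarray
    kept: np.ndarray                # voxels with non-zero training SD
    classes: tuple = ("CW", "CCW")

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (X[:, self.kept] - self.mean[self.kept]) / self.sd[self.kept]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svm.predict(self.standardize(X))

    def accuracy(self, X: np.ndarray, labels) -> float:
        return float(np.mean(self.predict(X) == np.asarray(labels)))


def train_classifier(train_set: TrialInstanceSet, C: float = 1.0) -> TrainedClassifier:
    """Fit the linear SVM on z-scored baseline correct-rejection instances."""
    y = train_set.labels["direction"].to_numpy()
    for cls in ("CW", "CCW"):
        if not np.any(y == cls):
            raise ValueError(f"training class {cls!r} is empty")
    X = train_set.X
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    kept = sd > 0
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} zero-variance training "
                      "voxel(s) from the classifier", RuntimeWarning, stacklevel=2)
    if not kept.any():
        raise ValueError("all training voxels have zero variance")
    svm = SVC(kernel="linear", C=C)
    svm.fit((X[:, kept] - mean[kept]) / sd[kept], y)
    return TrainedClassifier(svm, mean, sd, kept)


def train_test(
    baseline_instances: TrialInstanceSet,
    attention_instances: TrialInstanceSet,
    C: float = 1.0,
) -> dict:
    """Train on baseline correct rejections, test on attention trials.

    Returns per-accuracy-condition test accuracies along with the fitted
    classifier and its predictions on the full attention set (reused by the
    permutation null).
    """
    clf = train_classifier(baseline_instances, C=C)
    preds = clf.predict(attention_instances.X)
    truth = attention_instances.labels["direction"].to_numpy()
    acc_col = attention_instances.labels["accuracy"].to_numpy()
    out = {"classifier": clf, "predictions": preds}
    for acc in ("correct", "incorrect"):
        m = acc_col == acc
        out[acc] = float(np.mean(preds[m] == truth[m])) if m.any() else np.nan
        out[f"n_{acc}"] = int(m.sum())
    return out


@dataclass
class NullDistribution:
    """Subject- and group-level permutation null of classification accuracy."""

    subject_nulls: list             # one accuracy array per subject
    group_null: np.ndarray
    lo: float                       # 2.5th percentile of the group null
    hi: float                       # 97.5th percentile

    def flag(self, observed: float) -> str | None:
        if observed > self.hi:
            return "above"
        if observed < self.lo:
            return "below"
        return None


def subject_null(predictions: np.ndarray, n_shuffles: int = 10_000,
                 rng: np.random.Generator | None = None,
                 classes=("CW", "CCW")) -> np.ndarray:
    """Subject-level null: accuracy of fixed predictions vs shuffled labels.

    The pooled attention trials (all four accuracy-by-direction classes) are
    relabelled by a random split into two equal classes on every shuffle;
    with an odd pool the split is floor/ceil with the extra label assigned
    to either class at random.
    """
    if rng is None:
        rng = np.random.default_rng()
    preds = np.asarray(predictions)
    n = len(preds)
    if n < 4:
        raise ValueError("need at least 4 pooled instances")
    pred_bin = (preds == classes[0])
    out = np.empty(n_shuffles)
    half, odd = divmod(n, 2)
    labels = np.zeros(n, dtype=bool)
    for s in range(n_shuffles):
        k = half + (int(rng.integers(2)) if odd else 0)
        labels[:] = False
        labels[rng.choice(n, size=k, replace=False)] = True
        out[s] = np.mean(pred_bin == labels)
    return out


def permutation_null(
    per_subject_predictions,
    n_subject: int = 10_000,
    n_group: int = 10_000,
    seed: int | None = None,
) -> NullDistribution:
    """Two-level permutation null across a cohort.

    ``per_subject_predictions`` is a list with each subject's fixed
    classifier predictions over the pooled attention instances.  Subject
    nulls are built by label shuffling; the group null resamples one value
    per subject and averages, ``n_group`` times.
    """
    rng = np.random.default_rng(seed)
    subject_nulls = [subject_null(p, n_subject, rng) for p in per_subject_predictions]
    S = len(subject_nulls)
    picks = rng.integers(0, n_subject, size=(n_group, S))
    stacked = np.stack(subject_nulls)                 # S x n_subject
    group = stacked[np.arange(S)[None, :], picks].mean(axis=1)
    lo, hi = np.percentile(group, [2.5, 97.5])
    return NullDistribution(subject_nulls, group, float(lo), float(hi))
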