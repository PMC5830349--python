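"""Preprocessing and FIR deconvolution of voxel time series.

Preprocessing follows the standard event-related pipeline: per run, drop the
lead volumes acquired during the initial fixation, convert to percent signal
change against the voxel's run mean, remove a linear trend, high-pass filter
at 0.01 Hz (hard frequency-domain cutoff), and concatenate runs per task.

The response to each condition is then estimated without assuming a response
shape, as a set of finite impulse responses covering a 17.6-s window after
trial onset (8 taps at TR = 2.2 s): the indicator design matrix is
pseudo-inverted and applied to the time series.  A per-voxel r-squared
quantifies how strongly the task drives the voxel and later ranks voxels for
decoding.  Response amplitudes are read out around the peak of the average
response profile (constrained to taps 3-5, i.e. 4.4-8.8 s post onset), and
voxels with implausibly large responses (> 5% signal change in any
condition) are excluded from all downstream analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import detrend as _linear_detrend

__all__ = [
    "VoxelTimeSeries",
    "FIRDesignMatrix",
    "DeconvolutionEstimates",
    "AmplitudePattern",
    "preprocess",
    "build_fir_design",
    "deconvolve",
    "peak_and_amplitude",
    "exclude_voxels",
    "ATTENTION_CONDITIONS",
    "BASELINE_CONDITIONS",
]

#: FIR regressor sets: 2 directions x {hit, miss} on valid trials + invalid.
ATTENTION_CONDITIONS = (
    "CW_hit", "CW_miss", "CCW_hit", "CCW_miss", "invalid",
)
#: 2 directions x {hit, miss, correct rejection} + false alarms.
BASELINE_CONDITIONS = (
    "CW_hit", "CW_miss", "CW_correct_rejection",
    "CCW_hit", "CCW_miss", "CCW_correct_rejection",
    "false_alarm",
)

FIR_WINDOW_S = 17.6
HIGHPASS_HZ = 0.01


@dataclass
class VoxelTimeSeries:
    """Voxels x volumes matrix with run structure.

    ``data`` holds raw scanner units before :func:`preprocess` and percent
    signal change afterwards; ``run_lengths`` gives volumes per run (in the
    current representation) and ``discard_lead`` the number of lead volumes
    per run still to be dropped (0 once preprocessed).
    """

    data: np.ndarray
    tr: float
    run_lengths: list
    discard_lead: int = 0

    def __post_init__(self):
        if sum(self.run_lengths) != self.data.shape[1]:
            raise ValueError("run_lengths do not sum to the number of volumes")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def run_slices(self) -> list:
        out, start = [], 0
        for n in self.run_lengths:
            out.append(slice(start, start + n))
            start += n
        return out

    @classmethod
    def from_dataset(cls, ds) -> "VoxelTimeSeries":
        """Wrap a synthetic :class:`~featattn.synth.bold.GeneratedDataset`."""
        return cls(ds.concatenated(), ds.tr, list(ds.run_lengths), ds.discard_lead)


def _highpass(x: np.ndarray, tr: float, cutoff_hz: float) -> np.ndarray:
    """Remove all Fourier components strictly below the cutoff (incl. DC)."""
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr)
    spec = np.fft.rfft(x, axis=-1)
    spec[..., freqs < cutoff_hz] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def preprocess(raw: VoxelTimeSeries, cutoff_hz: float = HIGHPASS_HZ) -> VoxelTimeSeries:
    """Percent-signal-change conversion, detrending and high-pass filtering.

    Per run: drop the flagged lead volumes, divide each voxel by its run
    mean (x100, minus 100) to get percent signal change, remove a linear
    trend, and apply a hard 0.01-Hz high-pass in the frequency domain.  Runs
    are then concatenated.
    """
    out_runs = []
    for sl in raw.run_slices:
        seg = raw.data[:, sl][:, raw.discard_lead:]
        if seg.shape[1] < 2:
            raise ValueError("run shorter than its discard lead")
        mean = seg.mean(axis=1, keepdims=True)
        if np.any(mean == 0):
            raise ValueError("zero-mean voxel: percent signal change undefined")
        pct = 100.0 * (seg / mean - 1.0)
        pct = _linear_detrend(pct, axis=1)
        pct = _highpass(pct, raw.tr, cutoff_hz)
        out_runs.append(pct)
    data = np.concatenate(out_runs, axis=1)
    return VoxelTimeSeries(data, raw.tr, [r.shape[1] for r in out_runs], 0)


@dataclass
class FIRDesignMatrix:
    """Indicator design matrix: volumes x (n_conditions * n_taps)."""

    X: np.ndarray
    conditions: tuple
    n_taps: int

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def column(self, condition: str, tap: int) -> int:
        """Flat column index of (condition, tap); tap is 0-based."""
        return self.conditions.index(condition) * self.n_taps + tap


def build_fir_design(
    events: pd.DataFrame,
    run_lengths,
    tr: float,
    window_s: float = FIR_WINDOW_S,
    conditions=None,
    discard_lead: int = 0,
) -> FIRDesignMatrix:
    """Build the FIR indicator matrix for a concatenated, preprocessed series.

    ``events`` needs columns ``run``, ``onset`` (seconds from run start,
    including any fixation lead) and ``trial_type``; ``run_lengths`` are the
    post-discard volumes per run.  Onsets are snapped to the nearest volume
    (designs here are TR-locked, so snapping is exact); taps extending past
    the end of a run are truncated.  ``conditions`` fixes the column order
    and must cover every label present; conditions with no events produce
    all-zero columns.
    """
    if conditions is None:
        conditions = tuple(sorted(events["trial_type"].unique()))
    labels = set(events["trial_type"])
    unknown = labels - set(conditions)
    if unknown:
        raise ValueError(f"unknown condition labels: {sorted(unknown)}")
    n_taps = int(round(window_s / tr))
    run_lengths = list(run_lengths)
    offsets = np.concatenate([[0], np.cumsum(run_lengths)])
    n_volumes = int(offsets[-1])
    X = np.zeros((n_volumes, len(conditions) * n_taps))
    for row in events.itertuples(index=False):
        run = int(row.run)
        if run >= len(run_lengths):
            raise ValueError(f"event in run {run} outside the series")
        v0 = int(round(row.onset / tr)) - discard_lead
        if v0 < 0 or v0 >= run_lengths[run]:
            raise ValueError(
                f"event onset {row.onset} s maps outside run {run}"
            )
        c = conditions.index(row.trial_type)
        for k in range(n_taps):
            v = v0 + k
            if v >= run_lengths[run]:
                break                     # truncated at the run end
            X[offsets[run] + v, c * n_taps + k] = 1.0
    return FIRDesignMatrix(X, tuple(conditions), n_taps)


@dataclass
class DeconvolutionEstimates:
    """Per-voxel, per-condition FIR response curves plus an r-squared map."""

    responses: np.ndarray           # voxels x conditions x taps, % signal
    conditions: tuple
    r2: np.ndarray                  # per voxel, clamped to [0, 1]
    tr: float

    def condition_curve(self, condition: str) -> np.ndarray:
        return self.responses[:, self.conditions.index(condition), :]


def deconvolve(ts: VoxelTimeSeries, design: FIRDesignMatrix) -> DeconvolutionEstimates:
    """Estimate FIR responses by pseudo-inverse of the design matrix.

    ``beta = pinv(X) @ y`` per voxel; r-squared is the fraction of each
    voxel's variance captured by the fitted model, clamped to [0, 1] against
    floating-point excursions.  A rank-deficient design (e.g. a condition
    with no events) is still estimable by the pseudo-inverse; a diagnostic
    warning is emitted.
    """
    X = design.X
    if X.shape[0] != ts.data.shape[1]:
        raise ValueError("design matrix rows do not match the series length")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("FIR design matrix is rank deficient; minimum-norm "
                      "estimates returned", RuntimeWarning, stacklevel=2)
    Y = ts.data.T                                     # volumes x voxels
    beta = np.linalg.pinv(X) @ Y                      # columns x voxels
    fitted = X @ beta
    resid = Y - fitted
    ss_res = (resid ** 2).sum(axis=0)
    ss_tot = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    n_cond = len(design.conditions)
    responses = beta.T.reshape(ts.n_voxels, n_cond, design.n_taps)
    return DeconvolutionEstimates(responses, design.conditions, r2, ts.tr)


@dataclass
class AmplitudePattern:
    """Voxels x conditions amplitude matrix around the response peak."""

    amplitudes: np.ndarray
    conditions: tuple
    peak_tap: int                   # 1-based tap index of the profile peak
    window_taps: tuple              # 1-based taps averaged into the amplitude

    def vector(self, condition: str) -> np.ndarray:
        return self.amplitudes[:, self.conditions.index(condition)]


PEAK_TAP_RANGE = (3, 5)             # 1-based; 4.4 to 8.8 s post onset


def peak_and_amplitude(
    estimates: DeconvolutionEstimates,
    conditions=None,
    peak_tap: int | None = None,
) -> AmplitudePattern:
    """Amplitude read-out around the peak of the mean response profile.

    The profile is the across-voxel, across-condition mean FIR curve; its
    peak is located within taps 3-5 (ties toward the earlier tap), unless a
    ``peak_tap`` is supplied.  Amplitudes are the mean of the taps from the
    one immediately preceding the peak to the one following it, intersected
    with the estimated window.
    """
    if conditions is None:
        conditions = estimates.conditions
    idx = [estimates.conditions.index(c) for c in conditions]
    sub = estimates.responses[:, idx, :]
    if peak_tap is None:
        profile = sub.mean(axis=(0, 1))
        if np.allclose(profile, 0.0):
            raise ValueError("flat (all-zero) response profile: no peak")
        lo, hi = PEAK_TAP_RANGE
        window = profile[lo - 1: hi]
        peak_tap = lo + int(np.argmax(window))        # first max = earlier tap
    elif not (PEAK_TAP_RANGE[0] <= peak_tap <= PEAK_TAP_RANGE[1]):
        raise ValueError(f"peak_tap must lie in {PEAK_TAP_RANGE}")
    n_taps = estimates.responses.shape[2]
    taps = tuple(t for t in range(peak_tap - 1, peak_tap + 2) if 1 <= t <= n_taps)
    tap_idx = [t - 1 for t in taps]
    amplitudes = sub[:, :, tap_idx].mean(axis=2)
    return AmplitudePattern(amplitudes, tuple(conditions), peak_tap, taps)


def exclude_voxels(patterns: AmplitudePattern, threshold: float = 5.0) -> np.ndarray:
    """Keep-mask over voxels: drop any voxel exceeding the amplitude bound.

    A voxel whose absolute amplitude exceeds ``threshold`` (% signal change)
    in any condition is excluded from all downstream analyses; such
    responses are treated as noise.
    """
    return ~(np.abs(patterns.amplitudes) > threshold).any(axis=1)
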