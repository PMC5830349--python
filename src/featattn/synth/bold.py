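"""Synthetic voxel-level BOLD time series for one region of interest.

The neural amplitude of voxel ``v`` on trial ``t`` is

* baseline task:   mu_v + p_dir(v)                      (dir = displayed direction)
* attention task:  mu_v + g_t * p_cued(v) + (1 - g_t) * p_uncued(v)

where ``p_CW`` and ``p_CCW`` are independently drawn direction-pattern
vectors and ``g_t`` is the latent selection fidelity from the behavioral
simulation.  A boxcar spanning the dot-field window is convolved with a
canonical double-gamma HRF (normalised so a unit-amplitude trial peaks at
1% signal change), sampled at the TR, and corrupted with a linear drift,
a slow sinusoidal drift, and AR(1) noise.  The output is a raw-scanner-unit
series (baseline level ~1000) so that the percent-signal-change conversion
in the preprocessing stage is exercised for real.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import SessionDesign

__all__ = [
    "ROISpec",
    "NoiseSpec",
    "make_roi",
    "double_gamma_hrf",
    "simulate_bold",
    "GeneratedDataset",
]


@dataclass(frozen=True)
class ROISpec:
    """Voxel population of one simulated ROI.

    mu is each voxel's direction-unspecific response amplitude (% signal);
    p_cw / p_ccw are the direction-selective pattern components, drawn
    independently so their expected correlation is zero.
    """

    n_voxels: int
    mu: np.ndarray
    p_cw: np.ndarray
    p_ccw: np.ndarray
    selectivity: float
    seed: int | None = None

    def pattern(self, direction: str) -> np.ndarray:
        if direction == "CW":
            return self.p_cw
        if direction == "CCW":
            return self.p_ccw
        raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive nuisance components, all in % signal change.

    white_sd is the innovation SD of the AR(1) process; drift_slope is the
    total linear drift accumulated over one run; the slow sinusoid has a
    random phase per voxel.
    """

    white_sd: float = 1.0
    ar1: float = 0.3
    drift_slope: float = 0.5
    slow_amp: float = 0.3
    slow_period: float = 128.0

    def __post_init__(self):
        if not (-1.0 < self.ar1 < 1.0):
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        if self.white_sd < 0:
            raise ValueError("white_sd must be non-negative")


def make_roi(
    n_voxels: int,
    selectivity: float = 0.3,
    seed: int | None = None,
    mu_mean: float = 1.0,
    mu_sd: float = 0.2,
) -> ROISpec:
    """Draw an ROI's mean responses and direction patterns.

    ``selectivity`` is the SD (% signal) of the direction-pattern entries;
    zero selectivity yields identical (all-zero) CW and CCW patterns.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    if selectivity < 0:
        raise ValueError("selectivity must be >= 0")
    rng = np.random.default_rng(seed)
    mu = rng.normal(mu_mean, mu_sd, n_voxels)
    p_cw = rng.normal(0.0, selectivity, n_voxels) if selectivity else np.zeros(n_voxels)
    p_ccw = rng.normal(0.0, selectivity, n_voxels) if selectivity else np.zeros(n_voxels)
    return ROISpec(n_voxels, mu, p_cw, p_ccw, selectivity, seed)


def double_gamma_hrf(t: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak."""
    from scipy.stats import gamma as gamma_dist

    t = np.asarray(t, dtype=float)
    h = gamma_dist.pdf(t, peak) - ratio * gamma_dist.pdf(t, undershoot)
    h[t < 0] = 0.0
    m = h.max()
    return h / m if m > 0 else h


@dataclass
class GeneratedDataset:
    """One task's simulated session: raw series, events, and ground truth."""

    task_variant: str
    tr: float
    runs: list                      # list of (n_voxels, n_volumes) raw arrays
    discard_lead: int               # lead volumes per run flagged for discard
    events: pd.DataFrame            # BIDS-style events (one row per trial)
    trials: pd.DataFrame            # behavior table incl. latent g
    roi: ROISpec
    noise: NoiseSpec
    seed: int | None = None
    baseline_signal: float = 1000.0

    @property
    def n_voxels(self) -> int:
        return self.roi.n_voxels

    @property
    def run_lengths(self) -> list:
        return [r.shape[1] for r in self.runs]

    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.runs, axis=1)


def _ar1_noise(rng, shape, phi, sd):
    eps = rng.normal(0.0, sd, size=shape)
    if phi == 0.0:
        return eps
    out = np.empty_like(eps)
    out[..., 0] = eps[..., 0] / np.sqrt(1.0 - phi**2)  # stationary start
    for k in range(1, shape[-1]):
        out[..., k] = phi * out[..., k - 1] + eps[..., k]
    return out


def simulate_bold(
    design: SessionDesign,
    trials: pd.DataFrame,
    roi: ROISpec,
    noise: NoiseSpec | None = None,
    hrf=None,
    tr: float | None = None,
    dt: float = 0.1,
    baseline_signal: float = 1000.0,
    seed: int | None = None,
) -> GeneratedDataset:
    """Render a session's trial sequence into raw voxel time series.

    ``trials`` is the behavior table from :func:`simulate_behavior` (it must
    align row-for-row with ``design.trials``).  ``hrf`` may be a callable
    ``h(t)``; the default is the canonical double-gamma.  The single-trial
    response shape (boxcar over the dot-field window convolved with the HRF)
    is normalised to unit peak, so trial amplitudes are peak % signal change.
    """
    if noise is None:
        noise = NoiseSpec()
    if hrf is None:
        hrf = double_gamma_hrf
    tr = design.tr if tr is None else tr
    if len(trials) != len(design.trials):
        raise ValueError(
            f"behavior table has {len(trials)} rows but the design has "
            f"{len(design.trials)} trials"
        )
    rng = np.random.default_rng(seed)
    cued = design.cued

    # canonical single-trial response shape on the fine grid, unit peak
    spec_row = design.trials.iloc[0] if len(design.trials) else None
    stim_delay = float(spec_row["cue_s"]) if spec_row is not None else 0.3
    stim_dur = (float(spec_row["stim_s"] + spec_row["speedup_s"])
                if spec_row is not None else 4.3)
    hrf_span = 32.0
    shape_t = np.arange(0.0, stim_delay + stim_dur + hrf_span, dt)
    boxcar = ((shape_t >= stim_delay) & (shape_t < stim_delay + stim_dur)).astype(float)
    h = hrf(np.arange(0.0, hrf_span, dt))
    shape = np.convolve(boxcar, h)[: len(shape_t)] * dt
    peak = shape.max()
    if peak > 0:
        shape = shape / peak

    runs_raw = []
    event_rows = []
    n_runs = max(design.n_runs, 1)
    for run in range(n_runs):
        dur = design.run_duration(run)
        n_vol = int(round(dur / tr))
        n_fine = int(round(dur / dt)) + len(shape)
        signal = np.zeros((roi.n_voxels, n_fine))
        sub = trials[trials["run"] == run]
        for row in sub.itertuples(index=False):
            if cued:
                g = float(row.g)
                cued_dir = row.direction
                uncued_dir = "CCW" if cued_dir == "CW" else "CW"
                amp = roi.mu + g * roi.pattern(cued_dir) + (1 - g) * roi.pattern(uncued_dir)
            else:
                amp = roi.mu + roi.pattern(row.direction)
            i0 = int(round(row.onset / dt))
            signal[:, i0:i0 + len(shape)] += np.outer(amp, shape)
            event_rows.append({
                "run": run, "onset": row.onset,
                "duration": row.cue_s + row.stim_s + row.speedup_s,
                "trial_type": _condition_label(row, cued),
                "direction": row.direction,
                "response": row.response, "outcome": row.outcome,
            })
        # sample at the TR grid
        vol_idx = np.round(np.arange(n_vol) * tr / dt).astype(int)
        pct = signal[:, vol_idx]
        # nuisance components
        tt = np.arange(n_vol) * tr
        drift = noise.drift_slope * tt / max(dur, tr)
        phases = rng.uniform(0, 2 * np.pi, roi.n_voxels)
        slow = noise.slow_amp * np.sin(
            2 * np.pi * tt[None, :] / noise.slow_period + phases[:, None])
        ar = _ar1_noise(rng, (roi.n_voxels, n_vol), noise.ar1, noise.white_sd)
        pct = pct + drift[None, :] + slow + ar
        runs_raw.append(baseline_signal * (1.0 + pct / 100.0))

    events = pd.DataFrame(
        event_rows,
        columns=["run", "onset", "duration", "trial_type", "direction",
                 "response", "outcome"],
    )
    return GeneratedDataset(
        task_variant=design.task_variant, tr=tr, runs=runs_raw,
        discard_lead=design.discard_lead, events=events, trials=trials,
        roi=roi, noise=noise, seed=seed, baseline_signal=baseline_signal,
    )


def _condition_label(row, cued: bool) -> str:
    """FIR condition label for one trial, per the task's regressor scheme."""
    if cued:
        if not bool(row.valid):
            return "invalid"
        return f"{row.direction}_{row.outcome}"       # hit | miss
    if row.outcome == "false_alarm":
        return "false_alarm"
    return f"{row.direction}_{row.outcome}"           # hit | miss | correct_rejection
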