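"""Preprocessing, FIR deconvolution, amplitude read-out and voxel exclusion."""

import numpy as np
import pandas as pd
import pytest

from featattn import glm
from featattn.glm import (
    ATTENTION_CONDITIONS,
    BASELINE_CONDITIONS,
    AmplitudePattern,
    VoxelTimeSeries,
    build_fir_design,
    deconvolve,
    exclude_voxels,
    peak_and_amplitude,
    preprocess,
)

TR = 2.2


def _raw(data, run_lengths=None, discard=0):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return VoxelTimeSeries(data, TR, run_lengths or [data.shape[1]], discard)


class TestPreprocess:
    def test_constant_series_becomes_zero(self):
        ts = preprocess(_raw(np.full((3, 200), 7.0)))
        assert np.allclose(ts.data, 0.0, atol=1e-10)

    def test_linear_ramp_removed(self):
        ramp = 100.0 + np.linspace(0, 5, 200)
        ts = preprocess(_raw(ramp))
        assert np.max(np.abs(ts.data)) < 1e-8

    def test_lead_volumes_dropped_per_run(self):
        data = np.arange(2 * 154, dtype=float).reshape(1, -1) + 500.0
        ts = preprocess(_raw(data, [154, 154], discard=4))
        assert ts.run_lengths == [150, 150]
        assert ts.discard_lead == 0

    def test_run_mean_zero_after_preprocessing(self):
        rng = np.random.default_rng(0)
        data = 1000 + 10 * rng.standard_normal((4, 300))
        ts = preprocess(_raw(data, [150, 150]))
        for sl in ts.run_slices:
            assert np.allclose(ts.data[:, sl].mean(axis=1), 0.0, atol=1e-9)

    def test_highpass_frequency_response(self):
        """0.005-Hz power attenuated >10x, 0.05-Hz preserved within 5%."""
        n = 1000                                   # 2200 s of signal
        t = np.arange(n) * TR
        slow = np.sin(2 * np.pi * 0.005 * t)
        fast = np.sin(2 * np.pi * 0.05 * t)
        base = 1000.0
        ts = preprocess(_raw(base * (1 + (slow + fast) / 100.0)))

        def band_amp(x, f):
            spec = np.abs(np.fft.rfft(x)) / (n / 2)
            freqs = np.fft.rfftfreq(n, TR)
            return spec[np.argmin(np.abs(freqs - f))]

        out = ts.data[0]
        assert band_amp(out, 0.005) < 0.1          # input amplitude 1 -> >10x down
        assert band_amp(out, 0.05) == pytest.approx(1.0, rel=0.05)

    def test_short_run_rejected(self):
        with pytest.raises(ValueError, match="discard"):
            preprocess(_raw(np.ones((1, 4)), [4], discard=4))


def _events(onsets, labels, runs=None):
    return pd.DataFrame({
        "run": runs or [0] * len(onsets),
        "onset": onsets,
        "trial_type": labels,
    })


class TestFIRDesign:
    def test_attention_scheme_has_40_columns(self):
        ev = _events([0.0], ["CW_hit"])
        X = build_fir_design(ev, [100], TR, conditions=ATTENTION_CONDITIONS)
        assert X.n_columns == 5 * 8 == 40

    def test_baseline_scheme_has_56_columns(self):
        ev = _events([0.0], ["CW_correct_rejection"])
        X = build_fir_design(ev, [100], TR, conditions=BASELINE_CONDITIONS)
        assert X.n_columns == 7 * 8 == 56

    def test_single_event_makes_identity_stripe(self):
        ev = _events([0.0], ["only"])
        X = build_fir_design(ev, [20], TR, conditions=("only",))
        expected = np.zeros((20, 8))
        expected[:8] = np.eye(8)
        np.testing.assert_array_equal(X.X, expected)

    def test_taps_truncated_at_run_end(self):
        ev = _events([4 * TR], ["only"])
        X = build_fir_design(ev, [8], TR, conditions=("only",))
        assert X.X[:, :4].sum() == 4            # taps 1-4 fit
        assert X.X[:, 4:].sum() == 0            # taps 5-8 truncated

    def test_unknown_label_rejected(self):
        ev = _events([0.0], ["mystery"])
        with pytest.raises(ValueError, match="unknown condition"):
            build_fir_design(ev, [50], TR, conditions=("only",))

    def test_event_outside_run_rejected(self):
        ev = _events([300.0], ["only"])
        with pytest.raises(ValueError, match="outside"):
            build_fir_design(ev, [50], TR, conditions=("only",))


def _synth_from_taps(onset_vols, labels, taps_by_cond, n_volumes, conditions):
    """Build a series by pasting known tap responses at event onsets."""
    y = np.zeros(n_volumes)
    for v0, lab in zip(onset_vols, labels):
        curve = taps_by_cond[lab]
        end = min(v0 + len(curve), n_volumes)
        y[v0:end] += curve[: end - v0]
    return y


class TestDeconvolve:
    @pytest.mark.parametrize("overlap", [False, True])
    def test_exact_recovery_of_injected_taps(self, overlap):
        """Noiseless linear recovery is exact while the design has full rank,
        even when responses overlap (ITI < FIR window).  Overlapping onsets
        are jittered: a strictly periodic overlapped design would be
        collinear and unidentifiable."""
        rng = np.random.default_rng(1)
        taps = {"a": rng.standard_normal(8), "b": rng.standard_normal(8)}
        onsets, v = [], 4
        while v < 180:
            onsets.append(v)
            v += 10 if not overlap else int(rng.integers(4, 8))
        labels = ["a" if i % 2 else "b" for i in range(len(onsets))]
        y = _synth_from_taps(onsets, labels, taps, 200, ("a", "b"))
        ev = _events([v * TR for v in onsets], labels)
        X = build_fir_design(ev, [200], TR, conditions=("a", "b"))
        ts = VoxelTimeSeries(y[None, :], TR, [200])
        est = deconvolve(ts, X)
        np.testing.assert_allclose(est.condition_curve("a")[0], taps["a"], atol=1e-9)
        np.testing.assert_allclose(est.condition_curve("b")[0], taps["b"], atol=1e-9)
        assert est.r2[0] == pytest.approx(1.0)

    def test_r2_near_zero_for_orthogonal_noise(self):
        rng = np.random.default_rng(2)
        ev = _events([0.0, 44.0, 88.0], ["a", "a", "a"])
        X = build_fir_design(ev, [100], TR, conditions=("a",))
        noise = rng.standard_normal(100)
        # project out the design space so the model can explain nothing
        Q, _ = np.linalg.qr(X.X)
        resid = noise - Q @ (Q.T @ noise)
        est = deconvolve(VoxelTimeSeries(resid[None, :], TR, [100]), X)
        assert est.r2[0] < 1e-10

    def test_r2_decreases_with_noise_in_expectation(self):
        rng = np.random.default_rng(3)
        taps = {"a": np.array([0, 0.4, 1.0, 1.3, 0.9, 0.4, 0.1, 0.0])}
        onsets = list(range(2, 190, 6))
        y0 = _synth_from_taps(onsets, ["a"] * len(onsets), taps, 200, ("a",))
        ev = _events([v * TR for v in onsets], ["a"] * len(onsets))
        X = build_fir_design(ev, [200], TR, conditions=("a",))
        r2s = []
        for sd in (0.1, 0.5, 2.0):
            vals = [deconvolve(VoxelTimeSeries(
                (y0 + sd * rng.standard_normal(200))[None, :], TR, [200]), X).r2[0]
                for _ in range(5)]
            r2s.append(np.mean(vals))
        assert r2s[0] > r2s[1] > r2s[2]

    def test_rank_deficient_design_warns(self):
        ev = _events([0.0], ["a"])
        X = build_fir_design(ev, [50], TR, conditions=("a", "empty"))
        ts = VoxelTimeSeries(np.random.default_rng(4).standard_normal((1, 50)),
                             TR, [50])
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            deconvolve(ts, X)


def _estimates(curves, conditions):
    resp = np.asarray(curves, dtype=float)
    return glm.DeconvolutionEstimates(resp, tuple(conditions),
                                      np.ones(resp.shape[0]), TR)


class TestPeakAndAmplitude:
    def test_peak_at_tap4_averages_taps_3_to_5(self):
        curve = np.array([0, 0.2, 0.6, 1.0, 0.7, 0.3, 0.1, 0.0])
        est = _estimates([[curve]], ["a"])
        amp = peak_and_amplitude(est)
        assert amp.peak_tap == 4
        assert amp.window_taps == (3, 4, 5)
        assert amp.amplitudes[0, 0] == pytest.approx(np.mean(curve[2:5]))

    def test_peak_at_tap5_uses_taps_4_to_6(self):
        curve = np.array([0, 0.1, 0.3, 0.6, 1.0, 0.7, 0.2, 0.0])
        amp = peak_and_amplitude(_estimates([[curve]], ["a"]))
        assert amp.peak_tap == 5
        assert amp.window_taps == (4, 5, 6)

    def test_peak_search_restricted_to_taps_3_to_5(self):
        # true maximum at tap 7 is ignored; within 3-5 the best is tap 5
        curve = np.array([0, 0.1, 0.2, 0.3, 0.4, 0.5, 2.0, 0.0])
        amp = peak_and_amplitude(_estimates([[curve]], ["a"]))
        assert amp.peak_tap == 5

    def test_constant_taps_give_that_amplitude(self):
        curve = np.full(8, 0.8)
        amp = peak_and_amplitude(_estimates([[curve]], ["a"]))
        assert amp.amplitudes[0, 0] == pytest.approx(0.8)

    def test_flat_profile_rejected(self):
        with pytest.raises(ValueError, match="no peak"):
            peak_and_amplitude(_estimates([[np.zeros(8)]], ["a"]))

    def test_invariant_to_voxel_order_and_zero_conditions(self):
        rng = np.random.default_rng(5)
        resp = rng.standard_normal((6, 2, 8)) + np.array([0, 0, 1, 2, 1.2, 0.3, 0, 0])
        est = _estimates(resp, ["a", "b"])
        amp = peak_and_amplitude(est)
        perm = rng.permutation(6)
        amp_perm = peak_and_amplitude(_estimates(resp[perm], ["a", "b"]))
        np.testing.assert_allclose(amp_perm.amplitudes, amp.amplitudes[perm])
        # adding an all-zero condition leaves per-condition amplitudes intact
        resp3 = np.concatenate([resp, np.zeros((6, 1, 8))], axis=1)
        amp3 = peak_and_amplitude(_estimates(resp3, ["a", "b", "z"]),
                                  conditions=("a", "b"))
        np.testing.assert_allclose(amp3.amplitudes, amp.amplitudes)


class TestExcludeVoxels:
    def test_small_amplitudes_keep_everything(self):
        amp = AmplitudePattern(np.full((10, 3), 1.0), ("a", "b", "c"), 4, (3, 4, 5))
        assert exclude_voxels(amp).all()

    def test_single_large_response_excludes_voxel_everywhere(self):
        amps = np.ones((5, 2))
        amps[2, 1] = 6.0                           # one condition over 5%
        amp = AmplitudePattern(amps, ("a", "b"), 4, (3, 4, 5))
        mask = exclude_voxels(amp)
        assert not mask[2] and mask.sum() == 4

    def test_negative_excursions_count(self):
        amps = np.ones((3, 1))
        amps[0, 0] = -5.5
        assert not exclude_voxels(
            AmplitudePattern(amps, ("a",), 4, (3, 4, 5)))[0]

    def test_infinite_threshold_keeps_all(self):
        amps = np.array([[100.0], [-40.0]])
        amp = AmplitudePattern(amps, ("a",), 4, (3, 4, 5))
        assert exclude_voxels(amp, threshold=np.inf).all()
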