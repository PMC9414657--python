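"""Peak-finder wrapper: thresholding, local maxima, refractory correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ppgpeakkit as pk
from ppgpeakkit.peaks import (
    DetectedPeaks,
    PeakFinderConfig,
    correct_peaks,
    detect_from_probs,
    local_max_peaks,
    refractory_ms_from_max_hr,
    threshold_filter,
)

FIG9_PROBS = np.array([0.2, 0.6, 0.7, 0.85, 0.7, 0.65, 0.55, 0.52, 0.3])


def _simulate_correction(indices, probs, gap, check_both=True):
    """Independent step-by-step hand simulation of the correction procedure.

    Scan in time order marking peaks closer than ``gap`` to the preceding
    raw peak as false; then repeatedly take the highest-probability false
    peak and re-admit it only if it keeps ``gap`` to its accepted
    neighbors (preceding only when check_both is False).
    """
    accepted, false = [], []
    for i, idx in enumerate(indices):
        if i > 0 and idx - indices[i - 1] < gap:
            false.append(i)
        else:
            accepted.append(i)
    while false:
        best = max(false, key=lambda i: (probs[i], -indices[i]))
        false.remove(best)
        pos = indices[best]
        before = [indices[i] for i in accepted if indices[i] < pos]
        after = [indices[i] for i in accepted if indices[i] > pos]
        ok = (not before or pos - max(before) >= gap)
        if check_both and after and min(after) - pos < gap:
            ok = False
        if ok:
            accepted.append(best)
    accepted.sort(key=lambda i: indices[i])
    return [indices[i] for i in accepted]


class TestRefractoryConstant:
    def test_300ms_from_200bpm_ceiling(self):
        assert refractory_ms_from_max_hr(200.0) == 300.0
        cfg = PeakFinderConfig(fs=100.0)
        assert cfg.refractory_ms == 300.0
        assert cfg.refractory_samples == 30

    def test_rounds_up_conservatively(self):
        assert PeakFinderConfig(refractory_ms=305.0, fs=100.0).refractory_samples == 31


class TestThresholdFilter:
    def test_seven_samples_above_half(self):
        mask = threshold_filter(FIG9_PROBS, PeakFinderConfig(prob_threshold=0.5))
        assert mask.sum() == 7

    def test_all_below_gives_empty(self):
        mask = threshold_filter(np.full(10, 0.4), PeakFinderConfig(prob_threshold=0.9))
        assert not mask.any()

    def test_ties_kept(self):
        mask = threshold_filter(np.array([0.5, 0.49]), PeakFinderConfig(prob_threshold=0.5))
        assert mask.tolist() == [True, False]

    @given(st.floats(0.05, 0.45), st.floats(0.5, 0.95))
    @settings(deadline=None, max_examples=40)
    def test_mask_monotone_in_threshold(self, lo, hi):
        rng = np.random.default_rng(0)
        probs = rng.random(100)
        m_lo = threshold_filter(probs, PeakFinderConfig(prob_threshold=lo))
        m_hi = threshold_filter(probs, PeakFinderConfig(prob_threshold=hi))
        assert np.all(m_lo[m_hi])  # hi-mask is a subset of lo-mask

    def test_out_of_range_probs_rejected(self):
        with pytest.raises(ValueError):
            threshold_filter(np.array([0.5, 1.2]), PeakFinderConfig())


class TestLocalMaxPeaks:
    def test_run_maximum_is_chosen(self):
        cfg = PeakFinderConfig(prob_threshold=0.5)
        peaks = local_max_peaks(FIG9_PROBS, threshold_filter(FIG9_PROBS, cfg))
        assert peaks.indices.tolist() == [3]
        assert peaks.probabilities.tolist() == [0.85]

    def test_tie_resolves_to_first_index(self):
        probs = np.array([0.1, 0.6, 0.8, 0.8, 0.6, 0.1])
        peaks = local_max_peaks(probs, probs >= 0.5)
        assert peaks.indices.tolist() == [2]

    def test_empty_mask_gives_no_peaks(self):
        peaks = local_max_peaks(np.full(20, 0.2), np.zeros(20, dtype=bool))
        assert len(peaks) == 0

    def test_multiple_runs_give_one_peak_each(self):
        probs = np.array([0.9, 0.1, 0.6, 0.7, 0.1, 0.8])
        peaks = local_max_peaks(probs, probs >= 0.5)
        assert peaks.indices.tolist() == [0, 3, 5]


class TestCorrectPeaks:
    def test_worked_example_keeps_higher_probability_neighbor(self):
        # peaks at 0/250/350/800 ms, fs 100 Hz; P3 outranks P2
        cfg = PeakFinderConfig(fs=100.0)
        peaks = DetectedPeaks(np.array([0, 25, 35, 80]), np.array([0.9, 0.6, 0.8, 0.95]))
        out = correct_peaks(peaks, cfg)
        assert out.indices.tolist() == [0, 35, 80]
        # the preceding-only literal variant agrees on this example
        out2 = correct_peaks(peaks, PeakFinderConfig(fs=100.0, neighbor_check="preceding"))
        assert out2.indices.tolist() == [0, 35, 80]

    def test_well_spaced_peaks_pass_through(self):
        cfg = PeakFinderConfig(fs=100.0)
        peaks = DetectedPeaks(np.array([10, 50, 90, 130]), np.array([0.9, 0.8, 0.7, 0.6]))
        out = correct_peaks(peaks, cfg)
        assert np.array_equal(out.indices, peaks.indices)
        assert np.array_equal(out.probabilities, peaks.probabilities)

    def test_matches_hand_simulation_on_random_instances(self):
        cfg = PeakFinderConfig(fs=100.0)
        gap = cfg.refractory_samples
        rng = np.random.default_rng(99)
        for _ in range(300):
            n = int(rng.integers(1, 11))
            idx = np.sort(rng.choice(1500, size=n, replace=False)).astype(np.int64)
            probs = rng.uniform(0.5, 1.0, size=n)
            out = correct_peaks(DetectedPeaks(idx, probs), cfg)
            expected = _simulate_correction(idx.tolist(), probs.tolist(), gap)
            assert out.indices.tolist() == expected
            if len(out) > 1:
                assert np.diff(out.indices).min() >= gap

    def test_idempotent(self):
        cfg = PeakFinderConfig(fs=100.0)
        rng = np.random.default_rng(5)
        idx = np.sort(rng.choice(1000, size=8, replace=False))
        probs = rng.uniform(0.5, 1.0, size=8)
        once = correct_peaks(DetectedPeaks(idx, probs), cfg)
        twice = correct_peaks(once, cfg)
        assert np.array_equal(once.indices, twice.indices)

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=100)
    def test_min_gap_invariant_holds_for_any_input(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 15))
        idx = np.sort(rng.choice(1500, size=n, replace=False))
        probs = rng.uniform(0.0, 1.0, size=n)
        cfg = PeakFinderConfig(fs=100.0)
        out = correct_peaks(DetectedPeaks(idx, probs), cfg)
        if len(out) > 1:
            assert np.diff(out.indices).min() >= cfg.refractory_samples

    def test_returned_probabilities_track_indices(self):
        cfg = PeakFinderConfig(fs=100.0)
        idx = np.array([0, 25, 35, 80])
        probs = np.array([0.9, 0.6, 0.8, 0.95])
        out = correct_peaks(DetectedPeaks(idx, probs), cfg)
        lookup = dict(zip(idx.tolist(), probs.tolist()))
        for i, p in zip(out.indices, out.probabilities):
            assert p == lookup[int(i)]


class TestDetectPipeline:
    def test_synthetic_probability_profile_recovers_peaks(self):
        # a probability vector shaped like the training labels
        truth = np.array([200, 320, 450, 600, 780])
        labels = pk.make_labels(pk.PeakAnnotations(truth), 1000)
        probs = labels * 0.9 + 0.05
        out = detect_from_probs(probs, PeakFinderConfig(fs=100.0))
        assert len(out) == len(truth)
        assert np.all(np.abs(out.indices - truth) <= 2)  # within the 5-one run

    def test_subthreshold_probabilities_give_no_peaks(self):
        probs = np.full(1500, 0.3)
        out = detect_from_probs(probs, PeakFinderConfig(prob_threshold=0.5))
        assert len(out) == 0

    def test_raising_threshold_never_adds_candidates(self):
        # unimodal probability bumps (the shape a trained model emits):
        # a higher threshold shrinks runs but cannot split them
        t = np.arange(1000)
        probs = np.zeros(1000)
        rng = np.random.default_rng(3)
        for center in rng.choice(np.arange(50, 950, 60), size=8, replace=False):
            probs += rng.uniform(0.4, 1.0) * np.exp(-0.5 * ((t - center) / 6.0) ** 2)
        probs = np.clip(probs, 0.0, 1.0)
        counts = []
        for thr in (0.3, 0.5, 0.7, 0.9):
            cfg = PeakFinderConfig(prob_threshold=thr)
            counts.append(len(local_max_peaks(probs, threshold_filter(probs, cfg))))
        assert counts == sorted(counts, reverse=True)
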