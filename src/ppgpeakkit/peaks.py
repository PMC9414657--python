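"""Peak-finder wrapper: probabilities -> corrected systolic-peak indices.

Three stages follow the model's per-sample probabilities:

1. threshold filter — samples below the probability threshold are dropped;
2. local-maximum extraction — each contiguous supra-threshold run yields one
   candidate peak at its maximum probability (first index on ties);
3. refractory correction — assuming a maximum heart rate of 200 bpm, two
   true beats cannot be closer than 300 ms; offending candidates go to a
   false-peak list and are re-admitted in descending probability order only
   if they keep the minimum gap to the already-accepted peaks.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

import numpy as np

from .model import DilatedConvNet, predict

__all__ = [
    "PeakFinderConfig",
    "DetectedPeaks",
    "threshold_filter",
    "local_max_peaks",
    "correct_peaks",
    "detect",
]

MAX_HEART_RATE_BPM = 200.0


def refractory_ms_from_max_hr(max_hr_bpm: float = MAX_HEART_RATE_BPM) -> float:
    """Minimum beat spacing implied by a heart-rate ceiling (200 bpm -> 300 ms)."""
    if max_hr_bpm <= 0:
        raise ValueError("max heart rate must be > 0")
    return 60000.0 / max_hr_bpm


@dataclass(frozen=True)
class PeakFinderConfig:
    """Wrapper parameters.

    prob_threshold trades recall for precision (lower keeps more candidate
    peaks). refractory_ms defaults to the 300 ms implied by a 200 bpm
    ceiling. neighbor_check selects whether re-admitted false peaks are
    checked against the preceding accepted peak only ("preceding") or both
    neighbors ("both", default — the only variant that guarantees the
    minimum gap on every input).
    """

    prob_threshold: float = 0.5
    refractory_ms: float = field(default_factory=refractory_ms_from_max_hr)
    fs: float = 100.0
    neighbor_check: str = "both"

    def __post_init__(self) -> None:
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be > 0")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if self.neighbor_check not in ("both", "preceding"):
            raise ValueError("neighbor_check must be 'both' or 'preceding'")

    @property
    def refractory_samples(self) -> int:
        """ms -> samples, rounded up so a sub-refractory pair is never kept."""
        return int(math.ceil(self.refractory_ms * self.fs / 1000.0))


@dataclass(frozen=True)
class DetectedPeaks:
    """Sorted peak sample indices with the model probability at each."""

    indices: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        pr = np.asarray(self.probabilities, dtype=float)
        if idx.shape != pr.shape or idx.ndim != 1:
            raise ValueError("indices and probabilities must be matching 1-D arrays")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "probabilities", pr)

    def __len__(self) -> int:
        return int(self.indices.size)


def threshold_filter(probs: np.ndarray, config: PeakFinderConfig) -> np.ndarray:
    """Boolean mask keeping samples with probability >= threshold (ties kept)."""
    p = np.asarray(probs, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return p >= config.prob_threshold


def local_max_peaks(probs: np.ndarray, mask: np.ndarray) -> DetectedPeaks:
    """One candidate per contiguous supra-threshold run.

    The candidate is the run's probability argmax; on ties the first
    (earliest) index wins. An empty mask yields no peaks.
    """
    p = np.asarray(probs, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if p.shape != m.shape:
        raise ValueError("probs and mask must have equal length")
    idx: list[int] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8), [0]))))
    for start, stop in zip(edges[::2], edges[1::2]):
        run = p[start:stop]
        idx.append(int(start + np.argmax(run)))  # argmax returns first on ties
    indices = np.asarray(idx, dtype=np.int64)
    return DetectedPeaks(indices, p[indices])


def correct_peaks(peaks: DetectedPeaks, config: PeakFinderConfig) -> DetectedPeaks:
    """Discard candidates violating the refractory minimum spacing.

    First pass, in time order: a candidate closer than the refractory
    distance to the raw candidate before it joins the false-peak list;
    everything else is accepted. Then false peaks are revisited in
    descending probability order and re-admitted only if they keep the
    minimum gap (to both accepted neighbors by default; with
    neighbor_check="preceding", only the preceding accepted peak is
    checked). The result is sorted and, under the default check, always
    satisfies the minimum spacing.
    """
    n = len(peaks)
    if n == 0:
        return peaks
    gap = config.refractory_samples
    idx = peaks.indices
    prob = peaks.probabilities

    accepted: list[int] = [int(idx[0])]
    false_list: list[int] = []  # positions into idx
    for i in range(1, n):
        if int(idx[i]) - int(idx[i - 1]) < gap:
            false_list.append(i)
        else:
            accepted.append(int(idx[i]))

    # Highest-probability false peaks get the first chance at re-admission;
    # ties resolve to the earlier peak.
    false_list.sort(key=lambda i: (-prob[i], idx[i]))
    accepted_probs = {int(idx[0]): float(prob[0])}
    for i in range(1, n):
        if i not in false_list:
            accepted_probs[int(idx[i])] = float(prob[i])
    for i in false_list:
        pos = int(idx[i])
        j = bisect.bisect_left(accepted, pos)
        ok = True
        if j > 0 and pos - accepted[j - 1] < gap:
            ok = False
        if config.neighbor_check == "both" and j < len(accepted) and accepted[j] - pos < gap:
            ok = False
        if ok:
            accepted.insert(j, pos)
            accepted_probs[pos] = float(prob[i])
    final = np.asarray(accepted, dtype=np.int64)
    return DetectedPeaks(final, np.asarray([accepted_probs[int(v)] for v in final]))


def detect(
    signal: np.ndarray,
    model: DilatedConvNet,
    config: PeakFinderConfig | None = None,
) -> DetectedPeaks:
    """Full wrapper: predict -> threshold -> local maxima -> correction."""
    cfg = config or PeakFinderConfig()
    probs = predict(model, signal)
    mask = threshold_filter(probs, cfg)
    candidates = local_max_peaks(probs, mask)
    return correct_peaks(candidates, cfg)


def detect_from_probs(probs: np.ndarray, config: PeakFinderConfig | None = None) -> DetectedPeaks:
    """Wrapper stages applied to an existing probability vector."""
    cfg = config or PeakFinderConfig()
    return correct_peaks(local_max_peaks(probs, threshold_filter(probs, cfg)), cfg)
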