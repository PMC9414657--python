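"""Beat-to-beat evaluation: tolerance matching and SNR-binned metrics.

A detected peak counts as a true positive when it falls within a 50 ms
tolerance of an unmatched true systolic peak (one-to-one matching);
leftover detections are false positives and leftover true peaks false
negatives. Precision, recall and F1 are reported per 5 dB SNR bin and
overall, the overall row pooling raw counts across bins rather than
averaging bin metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .generator import LabeledSegment, snr_bin_label

__all__ = [
    "MatchCounts",
    "MetricsTable",
    "match_peaks",
    "metrics",
    "evaluate_by_snr",
]

DEFAULT_TOLERANCE_MS = 50.0


@dataclass(frozen=True)
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def match_peaks(
    detected: Sequence[int] | np.ndarray,
    truth: Sequence[int] | np.ndarray,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
    fs: float = 100.0,
) -> MatchCounts:
    """Greedy nearest-first one-to-one matching within the tolerance window.

    Candidate (detected, true) pairs within the tolerance are visited in
    order of increasing timing error (ties broken by true-peak index); a
    pair is matched when both members are still free. Both inputs must be
    sorted ascending.
    """
    det = np.asarray(detected, dtype=np.int64)
    tru = np.asarray(truth, dtype=np.int64)
    for name, arr in (("detected", det), ("truth", tru)):
        if arr.size and np.any(np.diff(arr) < 0):
            raise ValueError(f"{name} peak list must be sorted ascending")
    tol = tolerance_ms * fs / 1000.0
    pairs = [
        (abs(int(d) - int(t)), ti, di)
        for di, d in enumerate(det)
        for ti, t in enumerate(tru)
        if abs(int(d) - int(t)) <= tol
    ]
    pairs.sort()
    det_used = np.zeros(det.size, dtype=bool)
    tru_used = np.zeros(tru.size, dtype=bool)
    tp = 0
    for _, ti, di in pairs:
        if not det_used[di] and not tru_used[ti]:
            det_used[di] = True
            tru_used[ti] = True
            tp += 1
    return MatchCounts(tp=tp, fp=int(det.size - tp), fn=int(tru.size - tp))


def metrics(counts: MatchCounts) -> tuple[float, float, float]:
    """(precision, recall, F1); a zero denominator yields 0 by convention.

    precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2*TP/(2*TP + FP + FN).
    """
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return precision, recall, f1


@dataclass(frozen=True)
class MetricsTable:
    """Per-SNR-bin and pooled-overall detection metrics."""

    per_bin: pd.DataFrame  # columns: bin, snr_label_db, tp, fp, fn, precision, recall, f1, n_segments
    overall: MatchCounts

    @property
    def overall_metrics(self) -> tuple[float, float, float]:
        return metrics(self.overall)

    def to_frame(self) -> pd.DataFrame:
        """Table mirroring the per-bin layout with an appended Overall row."""
        p, r, f1 = self.overall_metrics
        overall_row = pd.DataFrame(
            [
                {
                    "bin": -1,
                    "snr_label_db": "overall",
                    "tp": self.overall.tp,
                    "fp": self.overall.fp,
                    "fn": self.overall.fn,
                    "precision": p,
                    "recall": r,
                    "f1": f1,
                    "n_segments": int(self.per_bin.n_segments.sum()),
                }
            ]
        )
        return pd.concat([self.per_bin, overall_row], ignore_index=True)


def evaluate_by_snr(
    detector: Callable[[LabeledSegment], Sequence[int] | np.ndarray],
    test_segments: Iterable[LabeledSegment],
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
    fs: float = 100.0,
) -> MetricsTable:
    """Run a detector over labeled segments and pool counts per SNR bin.

    ``detector(segment)`` returns detected peak indices. Empty bins are
    simply absent from the table. The overall row pools TP/FP/FN across
    every segment.
    """
    bins: dict[int, MatchCounts] = {}
    seg_counts: dict[int, int] = {}
    total = MatchCounts()
    for seg in test_segments:
        counts = match_peaks(detector(seg), seg.true_peaks.indices, tolerance_ms, fs)
        k = seg.snr_bin
        bins[k] = bins.get(k, MatchCounts()) + counts
        seg_counts[k] = seg_counts.get(k, 0) + 1
        total = total + counts
    rows = []
    for k in sorted(bins):
        p, r, f1 = metrics(bins[k])
        rows.append(
            {
                "bin": k,
                "snr_label_db": snr_bin_label(k),
                "tp": bins[k].tp,
                "fp": bins[k].fp,
                "fn": bins[k].fn,
                "precision": p,
                "recall": r,
                "f1": f1,
                "n_segments": seg_counts[k],
            }
        )
    return MetricsTable(per_bin=pd.DataFrame(rows), overall=total)
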