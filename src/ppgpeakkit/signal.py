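"""Core containers for sampled waveforms and systolic-peak annotations.

A photoplethysmogram (PPG) is stored as a plain sampled sequence with its
sampling rate; peak annotations are 0-based sample indices of systolic
maxima. Both round-trip through single-column text files so fixtures and
pipeline outputs stay human-inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Signal", "PeakAnnotations", "resample_linear"]


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled single-channel waveform.

    Parameters
    ----------
    samples : ndarray of float
        The waveform, arbitrary amplitude units. Must be finite and
        non-empty.
    fs : float
        Sampling rate in Hz, > 0, constant over the record.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("signal must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite values")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be > 0, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Record duration in seconds under the n/fs convention."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds (t_i = i / fs)."""
        return np.arange(len(self)) / self.fs


@dataclass(frozen=True)
class PeakAnnotations:
    """Strictly increasing 0-based sample indices of systolic peaks."""

    indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int64)
        if idx.ndim != 1:
            raise ValueError("peak indices must be 1-D")
        if idx.size and (np.any(idx < 0) or np.any(np.diff(idx) <= 0)):
            raise ValueError("peak indices must be nonnegative and strictly increasing")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)

    def validate_against(self, signal_length: int) -> None:
        if len(self) and int(self.indices[-1]) >= signal_length:
            raise ValueError(
                f"peak index {int(self.indices[-1])} outside signal of length {signal_length}"
            )

    def shifted(self, offset: int) -> "PeakAnnotations":
        return PeakAnnotations(self.indices + int(offset))


def resample_linear(
    signal: Signal,
    fs_out: float,
    annotations: PeakAnnotations | None = None,
):
    """Upsample a signal by linear interpolation between consecutive samples.

    The output keeps the n/fs duration convention: a 15 s record at 20 Hz
    (300 samples) becomes 1500 samples at 100 Hz. Output sample times past
    the last input sample (at most one input period) hold the final value.
    Annotations, if given, are rescaled by ``fs_out / fs`` and rounded to
    the nearest output sample.

    Raises
    ------
    ValueError
        If ``fs_out`` is below the input rate (downsampling is out of scope).
    """
    if fs_out < signal.fs:
        raise ValueError(f"fs_out={fs_out} < fs={signal.fs}: downsampling not supported")
    n_out = int(round(signal.duration_s * fs_out))
    t_out = np.arange(n_out) / fs_out
    resampled = np.interp(t_out, signal.times, signal.samples)
    out = Signal(resampled, fs_out)
    if annotations is None:
        return out
    scale = fs_out / signal.fs
    idx = np.round(annotations.indices * scale).astype(np.int64)
    idx = np.unique(np.clip(idx, 0, n_out - 1))
    return out, PeakAnnotations(idx)


def write_signal(path: str | Path, signal: Signal) -> None:
    """Write one sample per line; fs travels in a sidecar config/manifest."""
    np.savetxt(path, signal.samples, fmt="%.10g")


def read_signal(path: str | Path, fs: float) -> Signal:
    return Signal(np.loadtxt(path, ndmin=1), fs)


def write_peaks(path: str | Path, peaks: PeakAnnotations) -> None:
    np.savetxt(path, peaks.indices, fmt="%d")


def read_peaks(path: str | Path) -> PeakAnnotations:
    idx = np.loadtxt(path, dtype=np.int64, ndmin=1)
    return PeakAnnotations(idx)
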