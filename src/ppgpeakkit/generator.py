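"""Noisy-PPG generator: weighted clean/noise mixing with SNR-binned labeling.

A noisy training segment is S = wX*X + wN*N where X is a randomly chosen
clean PPG window (weight wX fixed at 1) and N a randomly chosen noise
window, wN ~ U(0, 5). The mixed signal is min-max normalized to [-1, 1];
binary labels put five ones (peak, two preceding, two succeeding samples)
at each systolic peak of the CLEAN signal; the segment SNR in dB is
10*log10 of the weighted-signal over weighted-noise power ratio. Segments
span roughly -2.5 to 47.5 dB and are grouped into ten 5 dB bins; optional
balancing draws segments near-uniformly across bins so training is not
dominated by any one noise level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signal import PeakAnnotations, Signal
from .synthetic import BurstSpec, SimConfig, simulate_baseline_wander, simulate_clean_ppg, simulate_motion_artifact

__all__ = [
    "GeneratorConfig",
    "LabeledSegment",
    "SignalBank",
    "mix",
    "compute_snr",
    "make_labels",
    "normalize",
    "snr_bin",
    "snr_bin_label",
    "build_clean_bank",
    "build_noise_bank",
    "generate_batch",
]

SNR_MIN_DB = -2.5
SNR_BIN_WIDTH_DB = 5.0
N_SNR_BINS = 10
LABEL_HALF_WIDTH = 2  # five ones: peak +/- 2 samples


@dataclass(frozen=True)
class GeneratorConfig:
    """Batch-generation parameters.

    wN is drawn from U(wn_low, wn_high) = U(0, 5); wX is fixed at 1.
    noise_rms_ratio scales each noise window to that multiple of the clean
    window's RMS before weighting, so wN alone controls the realized SNR.
    """

    win_size_s: float = 15.0
    fs: float = 100.0
    batch_size: int = 32
    wx: float = 1.0
    wn_low: float = 0.0
    wn_high: float = 5.0
    noise_rms_ratio: float = 1.0
    balance_snr_bins: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.wx != 1.0:
            raise ValueError("clean weight wX is fixed at 1")
        if not 0 <= self.wn_low < self.wn_high:
            raise ValueError("need 0 <= wn_low < wn_high")
        if self.win_size_s <= 0 or self.fs <= 0:
            raise ValueError("win_size_s and fs must be > 0")

    @property
    def segment_length(self) -> int:
        return int(round(self.win_size_s * self.fs))


@dataclass(frozen=True)
class LabeledSegment:
    """One normalized noisy segment with labels, SNR and provenance.

    clean_component / noise_component hold the weighted, pre-normalization
    terms of the mix so the stored snr_db can be recomputed exactly.
    """

    signal: np.ndarray
    labels: np.ndarray
    snr_db: float
    true_peaks: PeakAnnotations
    clean_component: np.ndarray | None = None
    noise_component: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.signal.shape != self.labels.shape:
            raise ValueError("signal and labels must have equal length")

    @property
    def snr_bin(self) -> int:
        return snr_bin(self.snr_db)


def mix(x: Signal, n: Signal, wx: float, wn: float) -> Signal:
    """Weighted arithmetic mean S[i] = wX*X[i] + wN*N[i]."""
    if len(x) != len(n):
        raise ValueError(f"length mismatch: {len(x)} vs {len(n)}")
    if x.fs != n.fs:
        raise ValueError(f"sampling-rate mismatch: {x.fs} vs {n.fs}")
    return Signal(wx * x.samples + wn * n.samples, x.fs)


def compute_snr(
    signal_component: Signal | np.ndarray,
    noise_component: Signal | np.ndarray,
    allow_inf: bool = False,
) -> float:
    """SNR in dB: 10*log10(P_signal / P_noise), P = mean of squared samples.

    The arguments are the already-weighted mix terms (wX*X and wN*N). Zero
    noise power raises by default; with allow_inf=True it returns +inf.
    """
    s = signal_component.samples if isinstance(signal_component, Signal) else np.asarray(signal_component)
    n = noise_component.samples if isinstance(noise_component, Signal) else np.asarray(noise_component)
    p_signal = float(np.mean(np.square(s)))
    p_noise = float(np.mean(np.square(n)))
    if p_noise == 0.0:
        if allow_inf:
            return float("inf")
        raise ValueError("noise power is zero; SNR undefined")
    return 10.0 * float(np.log10(p_signal / p_noise))


def make_labels(peaks: PeakAnnotations, length: int) -> np.ndarray:
    """Binary label vector: ones at {p-2..p+2} clipped to [0, length)."""
    peaks.validate_against(length)
    labels = np.zeros(length, dtype=np.int8)
    for p in peaks.indices:
        labels[max(0, p - LABEL_HALF_WIDTH) : min(length, p + LABEL_HALF_WIDTH + 1)] = 1
    return labels


def normalize(signal: Signal | np.ndarray) -> np.ndarray:
    """Affine min-max map onto [-1, 1]; a constant signal maps to zeros."""
    x = signal.samples if isinstance(signal, Signal) else np.asarray(signal, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.zeros_like(x)
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def snr_bin(snr_db: float) -> int:
    """Map an SNR to one of ten half-open 5 dB bins [-2.5+5k, 2.5+5k).

    Out-of-range values clamp to the nearest end bin.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    k = int(np.floor((snr_db - SNR_MIN_DB) / SNR_BIN_WIDTH_DB))
    return min(max(k, 0), N_SNR_BINS - 1)


def snr_bin_label(k: int) -> int:
    """Center (dB) of bin k: 0, 5, ..., 45."""
    if not 0 <= k < N_SNR_BINS:
        raise ValueError(f"bin index {k} out of range")
    return int(SNR_BIN_WIDTH_DB * k)


@dataclass(frozen=True)
class SignalBank:
    """A pool of records windows are drawn from.

    records: list of (Signal, PeakAnnotations) for clean banks or
    (Signal, None) for noise banks.
    """

    records: tuple
    fs: float

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("bank must contain at least one record")

    def draw_window(self, win_len: int, rng: np.random.Generator):
        """Random record + random start; returns (samples, peaks-in-window)."""
        rec_idx = int(rng.integers(0, len(self.records)))
        sig, peaks = self.records[rec_idx]
        if len(sig) < win_len:
            raise ValueError(f"bank record shorter ({len(sig)}) than window ({win_len})")
        start = int(rng.integers(0, len(sig) - win_len + 1))
        window = sig.samples[start : start + win_len]
        if peaks is None:
            return window, None
        inside = peaks.indices[(peaks.indices >= start) & (peaks.indices < start + win_len)]
        return window, PeakAnnotations(inside - start)


def build_clean_bank(
    n_records: int = 24,
    record_duration_s: float = 60.0,
    fs: float = 100.0,
    hr_range_bpm: tuple[float, float] = (45.0, 180.0),
    hr_jitter_sigma: float = 0.03,
    seed: int = 0,
) -> SignalBank:
    """Simulate a bank of clean PPG records ('virtual subjects').

    Each record gets its own mean heart rate, drawn uniformly from
    hr_range_bpm, and its own jittered rhythm.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_records):
        hr = float(rng.uniform(*hr_range_bpm))
        cfg = SimConfig(
            duration_s=record_duration_s,
            fs=fs,
            heart_rate_bpm=hr,
            hr_jitter_sigma=hr_jitter_sigma,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        records.append(simulate_clean_ppg(cfg))
    return SignalBank(tuple(records), fs)


def build_noise_bank(
    n_records: int = 24,
    record_duration_s: float = 60.0,
    fs: float = 100.0,
    wander_band_hz: tuple[float, float] = (0.05, 0.5),
    burst_spec: BurstSpec | None = None,
    seed: int = 0,
) -> SignalBank:
    """Simulate a noise bank of baseline wander plus motion-artifact bursts.

    Records cycle through three noise characters: wander-dominated,
    artifact-dominated, and an even combination, mirroring the variety of
    free-living recordings.
    """
    spec = burst_spec or BurstSpec(rate_per_min=6.0)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_records):
        s1 = int(rng.integers(0, 2**31 - 1))
        s2 = int(rng.integers(0, 2**31 - 1))
        wander = simulate_baseline_wander(
            record_duration_s, fs, wander_band_hz, amplitude=1.0, seed=s1
        ).samples
        bursts = simulate_motion_artifact(record_duration_s, fs, spec, seed=s2).samples
        kind = i % 3
        if kind == 0:
            noise = wander + 0.3 * bursts
        elif kind == 1:
            noise = 0.3 * wander + bursts
        else:
            noise = wander + bursts
        records.append((Signal(noise, fs), None))
    return SignalBank(tuple(records), fs)


def _wn_interval_for_bin(k: int, snr_at_unit_wn: float, cfg: GeneratorConfig) -> tuple[float, float]:
    """wN range mapping to SNR bin k, given SNR(wN) = snr_at_unit_wn - 20*log10(wN).

    End bins absorb the clamped tails of the SNR range.
    """
    lo_db = SNR_MIN_DB + k * SNR_BIN_WIDTH_DB
    hi_db = lo_db + SNR_BIN_WIDTH_DB
    wn_lo = 10.0 ** ((snr_at_unit_wn - hi_db) / 20.0)
    wn_hi = 10.0 ** ((snr_at_unit_wn - lo_db) / 20.0)
    if k == 0:
        wn_hi = cfg.wn_high
    if k == N_SNR_BINS - 1:
        wn_lo = max(cfg.wn_low, 1e-9)
    wn_lo = max(wn_lo, cfg.wn_low, 1e-9)
    wn_hi = min(wn_hi, cfg.wn_high)
    return wn_lo, wn_hi


def generate_batch(
    config: GeneratorConfig,
    clean_bank: SignalBank,
    noise_bank: SignalBank,
    seed: int | None = None,
) -> list[LabeledSegment]:
    """Assemble a batch of labeled noisy segments.

    Per segment: draw a clean window and its peaks, draw a noise window
    scaled to noise_rms_ratio times the clean RMS, draw wN, mix, compute
    the SNR from the weighted components, normalize to [-1, 1], and label
    from the clean-signal peaks. With balancing on, a target SNR bin is
    chosen uniformly and wN is drawn from the sub-interval of U(wn_low,
    wn_high) that realizes it, leaving per-bin counts near-uniform.
    """
    if clean_bank.fs != config.fs or noise_bank.fs != config.fs:
        raise ValueError("bank sampling rate differs from generator fs")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    win_len = config.segment_length
    segments: list[LabeledSegment] = []
    for _ in range(config.batch_size):
        x, peaks = clean_bank.draw_window(win_len, rng)
        noise_raw, _ = noise_bank.draw_window(win_len, rng)
        clean_rms = float(np.sqrt(np.mean(np.square(x))))
        noise_rms = float(np.sqrt(np.mean(np.square(noise_raw))))
        while noise_rms == 0.0:  # all-quiet window: redraw
            noise_raw, _ = noise_bank.draw_window(win_len, rng)
            noise_rms = float(np.sqrt(np.mean(np.square(noise_raw))))
        n = noise_raw * (config.noise_rms_ratio * clean_rms / noise_rms)

        if config.balance_snr_bins:
            snr_at_unit = compute_snr(config.wx * x, n)
            k = int(rng.integers(0, N_SNR_BINS))
            wn_lo, wn_hi = _wn_interval_for_bin(k, snr_at_unit, config)
            wn = float(rng.uniform(wn_lo, wn_hi))
        else:
            wn = float(rng.uniform(config.wn_low, config.wn_high))
            while wn <= 0.0:
                wn = float(rng.uniform(config.wn_low, config.wn_high))

        clean_term = config.wx * x
        noise_term = wn * n
        mixed = clean_term + noise_term
        snr_db = compute_snr(clean_term, noise_term)
        segments.append(
            LabeledSegment(
                signal=normalize(mixed),
                labels=make_labels(peaks, win_len),
                snr_db=snr_db,
                true_peaks=peaks,
                clean_component=clean_term,
                noise_component=noise_term,
            )
        )
    return segments


def training_stream(
    config: GeneratorConfig,
    clean_bank: SignalBank,
    noise_bank: SignalBank,
    seed: int = 0,
):
    """A zero-argument callable yielding (signals, labels) array batches.

    Suitable as the ``generator_fn`` of the model trainer; successive calls
    advance one shared random stream, so the whole run is reproducible from
    ``seed``.
    """
    rng = np.random.default_rng(seed)

    def next_batch():
        segs = generate_batch(config, clean_bank, noise_bank, seed=int(rng.integers(0, 2**31 - 1)))
        x = np.stack([s.signal for s in segs])
        y = np.stack([s.labels for s in segs]).astype(float)
        return x, y

    return next_batch


def save_batch(out_dir: str | Path, segments: list[LabeledSegment]) -> None:
    """Persist signals/labels as delimited arrays plus a manifest table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "signals.csv", np.stack([s.signal for s in segments]), delimiter=",", fmt="%.8g")
    np.savetxt(out / "labels.csv", np.stack([s.labels for s in segments]), delimiter=",", fmt="%d")
    with open(out / "peaks.txt", "w") as fh:
        for s in segments:
            fh.write(" ".join(str(int(i)) for i in s.true_peaks.indices) + "\n")
    manifest = pd.DataFrame(
        {
            "segment_id": range(len(segments)),
            "snr_db": [s.snr_db for s in segments],
            "snr_bin": [s.snr_bin for s in segments],
            "n_peaks": [len(s.true_peaks) for s in segments],
        }
    )
    manifest.to_csv(out / "manifest.csv", index=False)


def load_batch(in_dir: str | Path) -> list[LabeledSegment]:
    out = Path(in_dir)
    signals = np.loadtxt(out / "signals.csv", delimiter=",", ndmin=2)
    labels = np.loadtxt(out / "labels.csv", delimiter=",", dtype=np.int8, ndmin=2)
    manifest = pd.read_csv(out / "manifest.csv")
    peak_lists = []
    with open(out / "peaks.txt") as fh:
        for line in fh:
            vals = [int(v) for v in line.split()]
            peak_lists.append(PeakAnnotations(np.asarray(vals, dtype=np.int64)))
    return [
        LabeledSegment(
            signal=signals[i],
            labels=labels[i],
            snr_db=float(manifest.snr_db[i]),
            true_peaks=peak_lists[i],
        )
        for i in range(signals.shape[0])
    ]
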