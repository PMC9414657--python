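"""Synthetic PPG, baseline-wander, and motion-artifact simulators.

Real smartwatch PPG banks are private; these simulators stand in for them.
Each cardiac cycle of the clean waveform is modeled as a systolic pulse
plus a smaller, delayed diastolic/dicrotic component (two Gaussians per
cycle), which reproduces the canonical two-wave PPG morphology. Cycle
lengths carry multiplicative lognormal jitter to emulate heart-rate
variability in healthy adults. Baseline wander is a sum of random-phase
sub-hertz sinusoids; motion artifacts are Tukey-tapered bursts of
band-passed white noise whose spectrum overlaps the PPG band (0.5-5 Hz),
so bursts can masquerade as pulses.

All simulators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signal import PeakAnnotations, Signal

__all__ = [
    "SimConfig",
    "BurstSpec",
    "simulate_clean_ppg",
    "simulate_baseline_wander",
    "simulate_motion_artifact",
]

# Morphology constants (fractions of the cycle period T): systolic pulse of
# width 0.11*T at the annotated peak; dicrotic wave of 0.35 relative
# amplitude, width 0.18*T, delayed by 0.38*T.
_SYS_WIDTH = 0.11
_DIA_AMP = 0.35
_DIA_WIDTH = 0.18
_DIA_DELAY = 0.38


@dataclass(frozen=True)
class BurstSpec:
    """Motion-artifact burst statistics.

    rate_per_min is the expected number of bursts per minute (Poisson);
    n_bursts, when set, fixes the count instead. Burst durations are drawn
    uniformly from duration_range_s, spectra confined to band_hz, and
    amplitudes scaled so each burst has RMS ~ amplitude.
    """

    rate_per_min: float = 4.0
    duration_range_s: tuple[float, float] = (0.5, 3.0)
    band_hz: tuple[float, float] = (0.5, 5.0)
    amplitude: float = 1.0
    taper: float = 0.25
    n_bursts: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.duration_range_s
        if not (0 < lo <= hi):
            raise ValueError(f"invalid duration range {self.duration_range_s}")
        if self.rate_per_min < 0:
            raise ValueError("burst rate must be >= 0")
        blo, bhi = self.band_hz
        if not (0 < blo < bhi):
            raise ValueError(f"invalid burst band {self.band_hz}")


@dataclass(frozen=True)
class SimConfig:
    """Clean-PPG simulation parameters.

    heart_rate_bpm is the mean rate; hr_jitter_sigma is the lognormal sigma
    of multiplicative beat-to-beat cycle-length jitter (0.03 = ~3% HRV).
    """

    duration_s: float = 15.0
    fs: float = 100.0
    heart_rate_bpm: float = 70.0
    hr_jitter_sigma: float = 0.03
    amp_jitter_sigma: float = 0.05
    wander_band_hz: tuple[float, float] = (0.05, 0.5)
    artifact_burst_spec: BurstSpec = field(default_factory=BurstSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_s > 0:
            raise ValueError("duration_s must be > 0")
        if not 40.0 <= self.heart_rate_bpm <= 200.0:
            raise ValueError(
                f"heart rate {self.heart_rate_bpm} bpm outside supported [40, 200]"
            )
        if not self.fs > 0:
            raise ValueError("fs must be > 0")


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def simulate_clean_ppg(config: SimConfig) -> tuple[Signal, PeakAnnotations]:
    """Generate a clean quasi-periodic PPG with exact systolic-peak labels.

    Returns the waveform and the annotated systolic maxima. Peaks are
    snapped to the local waveform argmax (within ±3 samples of the nominal
    systolic center) so annotations coincide with true local maxima even
    where neighboring-cycle tails overlap. Deterministic in (config, seed).
    """
    rng = np.random.default_rng(config.seed)
    fs, dur = config.fs, config.duration_s
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    mean_period = 60.0 / config.heart_rate_bpm

    # Beat centers: start half a period in, lognormal multiplicative jitter,
    # clipped so instantaneous HR stays within a physiological band.
    sigma = config.hr_jitter_sigma
    centers: list[float] = []
    c = 0.5 * mean_period
    while c < dur + mean_period:  # one beat past the end for tail overlap
        centers.append(c)
        if sigma > 0:
            mult = float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
            mult = float(np.clip(mult, 0.75, 1.3))
        else:
            mult = 1.0
        c += mean_period * mult

    wave = np.zeros(n)
    sys_width = _SYS_WIDTH * mean_period
    dia_width = _DIA_WIDTH * mean_period
    annotated: list[int] = []
    for ck in centers:
        amp = 1.0
        if config.amp_jitter_sigma > 0:
            amp = float(np.exp(rng.normal(0.0, config.amp_jitter_sigma)))
        wave += amp * _gauss(t, ck, sys_width)
        wave += amp * _DIA_AMP * _gauss(t, ck + _DIA_DELAY * mean_period, dia_width)
        idx = int(round(ck * fs))
        if 0 <= idx < n:
            annotated.append(idx)

    # Snap each annotation to the local maximum of the realized waveform.
    peaks = []
    for idx in annotated:
        lo, hi = max(0, idx - 3), min(n, idx + 4)
        peaks.append(lo + int(np.argmax(wave[lo:hi])))
    peaks = sorted(set(peaks))
    return Signal(wave, fs), PeakAnnotations(np.asarray(peaks, dtype=np.int64))


def simulate_baseline_wander(
    duration_s: float,
    fs: float,
    band_hz: tuple[float, float] = (0.05, 0.5),
    amplitude: float = 1.0,
    seed: int = 0,
    n_components: int = 6,
) -> Signal:
    """Low-frequency drift: a sum of random-phase sinusoids inside band_hz.

    ``amplitude`` sets the RMS of the result; 0 yields an all-zero signal.
    """
    lo, hi = band_hz
    if not (0 < lo < hi <= fs / 2):
        raise ValueError(f"wander band {band_hz} outside (0, fs/2)")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    wave = np.zeros(n)
    freqs = rng.uniform(lo, hi, size=n_components)
    phases = rng.uniform(0, 2 * np.pi, size=n_components)
    amps = rng.uniform(0.5, 1.0, size=n_components)
    for f, ph, a in zip(freqs, phases, amps):
        wave += a * np.sin(2 * np.pi * f * t + ph)
    rms = float(np.sqrt(np.mean(wave**2)))
    if rms > 0 and amplitude != 0:
        wave *= amplitude / rms
    else:
        wave[:] = 0.0
    return Signal(wave, fs)


def _bandpassed_noise(n: int, fs: float, band: tuple[float, float], rng) -> np.ndarray:
    lo, hi = band
    nyq = fs / 2
    white = rng.standard_normal(n)
    # pad so filtfilt transients stay outside the burst
    pad = min(3 * n, max(64, int(fs)))
    white = np.concatenate([rng.standard_normal(pad), white, rng.standard_normal(pad)])
    b, a = sps.butter(2, [lo / nyq, min(hi / nyq, 0.99)], btype="bandpass")
    filtered = sps.filtfilt(b, a, white)
    return filtered[pad : pad + n]


def simulate_motion_artifact(
    duration_s: float,
    fs: float,
    burst_spec: BurstSpec | None = None,
    seed: int = 0,
) -> Signal:
    """Burst-like motion artifact: mostly zero with band-limited bursts.

    Bursts are band-passed white noise shaped by a Tukey taper, placed at
    uniformly random onsets. Deterministic in (spec, seed).
    """
    spec = burst_spec or BurstSpec()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    wave = np.zeros(n)
    if spec.n_bursts is not None:
        n_bursts = int(spec.n_bursts)
    else:
        n_bursts = int(rng.poisson(spec.rate_per_min * duration_s / 60.0))
    for _ in range(n_bursts):
        burst_dur = rng.uniform(*spec.duration_range_s)
        m = max(4, int(round(burst_dur * fs)))
        m = min(m, n)
        start = int(rng.integers(0, n - m + 1))
        burst = _bandpassed_noise(m, fs, spec.band_hz, rng)
        burst *= sps.windows.tukey(m, alpha=spec.taper)
        rms = float(np.sqrt(np.mean(burst**2)))
        if rms > 0:
            burst *= spec.amplitude / rms
        wave[start : start + m] += burst
    return Signal(wave, fs)
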