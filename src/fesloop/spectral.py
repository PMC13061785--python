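"""Movement-cycle-locked EEG spectral analysis.

The evaluation pipeline quantifies sensorimotor rhythm changes during
pedaling or walking relative to rest:

1. re-reference to the common average (CAR),
2. band-pass 8-45 Hz (zero-phase Butterworth),
3. segment the recording into movement cycles using the IMU-derived
   boundaries — each cycle is one trial — and length-normalize each trial
   to a 0-100% cycle grid,
4. per-trial FFT power spectra and Morlet time-frequency maps,
5. express task power in dB relative to a rest reference (or to the cycle
   mean power, for within-cycle maps),
6. summarize per-electrode mean dB in the mu (8-13 Hz), low-beta (13-20 Hz)
   and high-beta (20-30 Hz) bands.

Event-related desynchronization (ERD) shows up as negative dB values,
synchronization (ERS) as positive, conventionally focal at Cz for
lower-limb movement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .imu import CycleSegmentation, resample_cycle

__all__ = [
    "EegRecording",
    "TrialMatrix",
    "TimeFrequencyMap",
    "BandPowerSummary",
    "BANDS",
    "common_average_reference",
    "bandpass_filter",
    "segment_trials",
    "power_spectrum",
    "morlet_cwt",
    "relative_power_db",
    "band_topography",
    "grand_average",
    "preprocess",
    "rest_spectrum",
    "trial_spectra",
    "band_relative_power",
    "cycle_time_frequency",
]

#: analysis band edges in Hz
BANDS: dict[str, tuple[float, float]] = {
    "mu": (8.0, 13.0),
    "low_beta": (13.0, 20.0),
    "high_beta": (20.0, 30.0),
}

DEFAULT_BANDPASS = (8.0, 45.0)
#: Morlet wavelet cycle count and default analysis frequency grid
MORLET_N_CYCLES = 6.0
DEFAULT_CWT_FREQS = np.arange(8.0, 45.0 + 1e-9, 0.5)


@dataclass
class EegRecording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    rate: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.labels = list(self.labels)
        if self.data.shape[0] != len(self.labels):
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("EEG samples must be finite")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.labels.index(label)]


@dataclass
class TrialMatrix:
    """Cycle-locked trials: trials x channels x cycle-percent grid."""

    data: np.ndarray  # (n_trials, n_channels, n_grid)
    labels: list[str]
    cycle_percent: np.ndarray
    n_dropped: int = 0
    trial_samples: list[np.ndarray] = field(default_factory=list)
    trial_durations: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class TimeFrequencyMap:
    """Power over the movement cycle: frequencies x cycle-percent, dB or linear."""

    frequencies: np.ndarray
    cycle_percent: np.ndarray
    power: np.ndarray  # (n_freqs, n_percent)

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.frequencies), len(self.cycle_percent)):
            raise ValueError("power must be frequencies x cycle_percent")


@dataclass
class BandPowerSummary:
    """Per-electrode mean relative power (dB) within one frequency band."""

    band: str
    lo: float
    hi: float
    labels: list[str]
    power_db: np.ndarray

    def at(self, label: str) -> float:
        return float(self.power_db[self.labels.index(label)])


# ---------------------------------------------------------------------------
# preprocessing


def common_average_reference(rec: EegRecording) -> EegRecording:
    """Subtract the instantaneous mean across channels from every channel.

    After CAR the channel sum is zero at every time point; applying CAR
    twice equals applying it once.
    """
    if rec.n_channels < 2:
        raise ValueError("CAR requires at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    return EegRecording(data=data, rate=rec.rate, labels=list(rec.labels))


def bandpass_filter(
    rec: EegRecording, lo: float = DEFAULT_BANDPASS[0], hi: float = DEFAULT_BANDPASS[1]
) -> EegRecording:
    """Zero-phase 4th-order Butterworth band-pass between ``lo`` and ``hi`` Hz.

    Applied forward-backward (``sosfiltfilt``) so cycle-locked features are
    not phase-shifted.
    """
    if not 0.0 < lo < hi < rec.rate / 2.0:
        raise ValueError(f"invalid band ({lo}, {hi}) for rate {rec.rate}")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
    data = signal.sosfiltfilt(sos, rec.data, axis=1)
    return EegRecording(data=data, rate=rec.rate, labels=list(rec.labels))


def preprocess(rec: EegRecording, lo: float = DEFAULT_BANDPASS[0],
               hi: float = DEFAULT_BANDPASS[1]) -> EegRecording:
    """CAR followed by the 8-45 Hz zero-phase band-pass."""
    return bandpass_filter(common_average_reference(rec), lo, hi)


# ---------------------------------------------------------------------------
# trials


def segment_trials(
    rec: EegRecording,
    seg: CycleSegmentation,
    grid_points: int = 101,
    reject_outliers: bool = True,
) -> TrialMatrix:
    """Cut the recording into one trial per movement cycle.

    The segmentation's boundary *times* (from the IMU pipeline, which runs
    at its own rate) are mapped onto EEG sample indices at the recording's
    rate.  Each channel of each cycle is linearly resampled onto the 0-100%
    grid.  Cycles shorter than 2 samples or extending past the recording are
    dropped, as are (when ``reject_outliers``) cycles whose duration deviates
    from the median period by more than 3 median absolute deviations; the
    drop count is recorded and reported as a warning.
    """
    percent = np.linspace(0.0, 100.0, grid_points)
    if seg.n_cycles < 1:
        return TrialMatrix(
            data=np.empty((0, rec.n_channels, grid_points)),
            labels=list(rec.labels),
            cycle_percent=percent,
        )
    keep = np.ones(seg.n_cycles, dtype=bool)
    if reject_outliers and seg.n_cycles >= 3:
        med = np.median(seg.periods)
        dev = np.abs(seg.periods - med)
        # MAD scale; fall back to the mean deviation when over half the
        # periods are identical (MAD = 0 would reject nothing), and floor the
        # scale at 1% of the median so near-identical periods are never culled
        # over float-level jitter
        scale = np.median(dev)
        if scale == 0:
            scale = dev.mean()
        scale = max(scale, 0.01 * med)
        keep &= dev <= 3.0 * scale

    sample_idx = np.round(seg.boundary_times * rec.rate).astype(int)
    trials, raw, durations = [], [], []
    n_dropped = int(np.sum(~keep))
    for k in range(seg.n_cycles):
        if not keep[k]:
            continue
        i0, i1 = sample_idx[k], sample_idx[k + 1]
        if i0 < 0 or i1 > rec.n_samples:
            n_dropped += 1
            continue
        chunk = rec.data[:, i0:i1]
        if chunk.shape[1] < 2:
            n_dropped += 1
            continue
        trials.append(np.stack([resample_cycle(ch, grid_points) for ch in chunk]))
        raw.append(chunk)
        durations.append(seg.periods[k])
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} unusable cycle(s)")
    data = np.stack(trials) if trials else np.empty((0, rec.n_channels, grid_points))
    return TrialMatrix(
        data=data,
        labels=list(rec.labels),
        cycle_percent=percent,
        n_dropped=n_dropped,
        trial_samples=raw,
        trial_durations=np.asarray(durations),
    )


# ---------------------------------------------------------------------------
# spectra


def power_spectrum(
    segment: np.ndarray, rate: float, window: str = "boxcar"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sided periodogram (power spectral density, units^2/Hz).

    With the default boxcar window this is the plain FFT periodogram and the
    integral of the density over frequency equals the signal variance
    (Parseval).
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1 or segment.size < 2:
        raise ValueError("segment must be 1-D with at least 2 samples")
    freqs, psd = signal.periodogram(
        segment, fs=rate, window=window, detrend="constant", scaling="density"
    )
    return freqs, psd


def morlet_cwt(
    segment: np.ndarray,
    rate: float,
    freqs: Optional[np.ndarray] = None,
    n_cycles: float = MORLET_N_CYCLES,
) -> tuple[np.ndarray, np.ndarray]:
    """Morlet continuous wavelet power of one channel.

    Returns ``(freqs, power)`` with ``power`` of shape (n_freqs, n_times),
    computed with a fixed-cycle-count (default 6) complex Morlet wavelet.
    Power is rescaled by frequency to undo the 1/f amplitude tilt of
    energy-normalized wavelets, so a stationary sinusoid's ridge peaks at
    its own frequency (matching the periodogram); this per-frequency
    scaling cancels in every relative (dB) comparison downstream.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.ndim != 1:
        raise ValueError("segment must be 1-D")
    freqs = np.asarray(DEFAULT_CWT_FREQS if freqs is None else freqs, dtype=float)
    if np.any(freqs <= 0) or np.any(freqs >= rate / 2.0):
        raise ValueError("analysis frequencies must lie in (0, rate/2)")
    from mne.time_frequency import tfr_array_morlet

    power = tfr_array_morlet(
        segment[np.newaxis, np.newaxis, :],
        sfreq=rate,
        freqs=freqs,
        n_cycles=n_cycles,
        output="power",
        zero_mean=True,
        verbose="error",
    )[0, 0]
    return freqs, power * freqs[:, np.newaxis]


def relative_power_db(task_power: np.ndarray, rest_power: np.ndarray) -> np.ndarray:
    """Elementwise 10*log10(task/rest) in dB; the reference must be positive."""
    task_power = np.asarray(task_power, dtype=float)
    rest_power = np.asarray(rest_power, dtype=float)
    if task_power.shape != rest_power.shape:
        raise ValueError("task and rest arrays must have matching shapes")
    if np.any(rest_power <= 0):
        raise ValueError("rest reference power must be positive everywhere")
    return 10.0 * np.log10(task_power / rest_power)


def band_topography(
    freqs: np.ndarray,
    rel_power_db: np.ndarray,
    labels: Sequence[str],
    band: str,
) -> BandPowerSummary:
    """Mean dB within one named band, per electrode.

    ``rel_power_db`` is electrodes x frequencies; the band edges are the
    fixed mu / low-beta / high-beta definitions.
    """
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; expected one of {sorted(BANDS)}")
    lo, hi = BANDS[band]
    freqs = np.asarray(freqs, dtype=float)
    mask = (freqs >= lo) & (freqs <= hi)
    if not np.any(mask):
        raise ValueError(f"spectrum does not cover the {band} band ({lo}-{hi} Hz)")
    rel_power_db = np.atleast_2d(rel_power_db)
    return BandPowerSummary(
        band=band,
        lo=lo,
        hi=hi,
        labels=list(labels),
        power_db=rel_power_db[:, mask].mean(axis=1),
    )


def grand_average(maps: Sequence[TimeFrequencyMap]) -> TimeFrequencyMap:
    """Average linear-power maps across trials, then normalize per frequency.

    The dB values are centered on each frequency row's mean log power
    ("relative to the movement cycle mean power"), so every row averages to
    exactly 0 dB across the cycle.
    """
    if len(maps) < 1:
        raise ValueError("need at least one trial map")
    f0, p0 = maps[0].frequencies, maps[0].cycle_percent
    for m in maps[1:]:
        if not (np.array_equal(m.frequencies, f0) and np.array_equal(m.cycle_percent, p0)):
            raise ValueError("all trial maps must share the same grids")
    mean_power = np.mean([m.power for m in maps], axis=0)
    if np.any(mean_power <= 0):
        raise ValueError("grand average requires positive linear power inputs")
    log_power = 10.0 * np.log10(mean_power)
    db = log_power - log_power.mean(axis=1, keepdims=True)
    return TimeFrequencyMap(frequencies=f0, cycle_percent=p0, power=db)


# ---------------------------------------------------------------------------
# composite pipeline stages


def rest_spectrum(
    rec: EegRecording, window_s: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Welch rest reference: mean periodogram over ``window_s`` windows, 50% overlap.

    Returns ``(freqs, psd)`` with ``psd`` channels x frequencies.
    """
    nperseg = int(round(window_s * rec.rate))
    freqs, psd = signal.welch(
        rec.data, fs=rec.rate, nperseg=nperseg, noverlap=nperseg // 2, axis=1
    )
    return freqs, psd


def trial_spectra(
    trials: TrialMatrix,
    rate: float,
    freq_grid: Optional[np.ndarray] = None,
    window: str = "hann",
) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-trial power spectral density on a common frequency grid.

    Each trial keeps its native duration (spectra are computed on the raw,
    non-length-normalized cycle samples), and per-trial densities are
    linearly interpolated onto the shared grid before averaging.
    Returns ``(freqs, psd)`` with ``psd`` channels x frequencies.
    """
    if trials.n_trials < 1 or not trials.trial_samples:
        raise ValueError("no trials to average")
    if freq_grid is None:
        freq_grid = np.arange(0.0, 45.0 + 1e-9, 0.25)
    n_ch = len(trials.labels)
    acc = np.zeros((n_ch, freq_grid.size))
    for chunk in trials.trial_samples:
        f, p = signal.periodogram(
            chunk, fs=rate, window=window, detrend="constant", scaling="density", axis=1
        )
        for c in range(n_ch):
            acc[c] += np.interp(freq_grid, f, p[c])
    return freq_grid, acc / len(trials.trial_samples)


def _band_integral(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Band power (units^2) per channel: PSD summed over band bins times df."""
    mask = (freqs >= lo) & (freqs <= hi)
    df = freqs[1] - freqs[0]
    return psd[..., mask].sum(axis=-1) * df


def band_relative_power(
    task: EegRecording,
    rest: EegRecording,
    seg: CycleSegmentation,
    band: str = "mu",
    lo: float = DEFAULT_BANDPASS[0],
    hi: float = DEFAULT_BANDPASS[1],
) -> BandPowerSummary:
    """Per-electrode band power during movement relative to rest, in dB.

    Both recordings are preprocessed identically (CAR + band-pass); task
    band power is the mean over per-cycle band integrals on each cycle's
    native periodogram, rest band power comes from the Welch reference, and
    the summary is 10*log10(task/rest) per electrode.
    """
    band_lo, band_hi = BANDS[band]
    task_p = preprocess(task, lo, hi)
    rest_p = preprocess(rest, lo, hi)
    trials = segment_trials(task_p, seg)
    if trials.n_trials < 1:
        raise ValueError("no usable movement cycles in the task recording")
    task_bp = np.zeros(task.n_channels)
    for chunk in trials.trial_samples:
        f, p = signal.periodogram(
            chunk, fs=task.rate, window="hann", detrend="constant",
            scaling="density", axis=1,
        )
        task_bp += _band_integral(f, p, band_lo, band_hi)
    task_bp /= len(trials.trial_samples)
    f_rest, psd_rest = rest_spectrum(rest_p)
    rest_bp = _band_integral(f_rest, psd_rest, band_lo, band_hi)
    return BandPowerSummary(
        band=band,
        lo=band_lo,
        hi=band_hi,
        labels=list(task.labels),
        power_db=relative_power_db(task_bp, rest_bp),
    )


def relative_spectra(
    task: EegRecording,
    rest: EegRecording,
    seg: CycleSegmentation,
    freq_grid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-electrode movement spectra in dB relative to rest.

    Both recordings are preprocessed (CAR + 8-45 Hz); the task density is the
    mean per-cycle periodogram, the rest density the Welch reference, both on
    the shared grid.  Returns ``(freqs, db)`` with ``db`` channels x freqs.
    """
    if freq_grid is None:
        freq_grid = np.arange(DEFAULT_BANDPASS[0], DEFAULT_BANDPASS[1] + 1e-9, 0.25)
    task_p = preprocess(task)
    rest_p = preprocess(rest)
    trials = segment_trials(task_p, seg)
    freqs, task_psd = trial_spectra(trials, task.rate, freq_grid)
    f_rest, rest_psd = rest_spectrum(rest_p)
    rest_on_grid = np.stack([np.interp(freq_grid, f_rest, row) for row in rest_psd])
    return freqs, relative_power_db(task_psd, rest_on_grid)


def cycle_time_frequency(
    task: EegRecording,
    seg: CycleSegmentation,
    channel: str = "Cz",
    freqs: Optional[np.ndarray] = None,
    grid_points: int = 101,
    reference: str = "cycle_mean",
    rest: Optional[EegRecording] = None,
) -> TimeFrequencyMap:
    """Grand-average Morlet time-frequency map of one channel over the cycle.

    Per cycle, the Morlet power of the preprocessed channel is computed on
    the native samples and resampled onto the 0-100% grid; trials are then
    combined by :func:`grand_average` (``reference='cycle_mean'``) or
    averaged and expressed in dB against the rest recording's mean Morlet
    power per frequency (``reference='rest'``).
    """
    freqs = np.asarray(DEFAULT_CWT_FREQS if freqs is None else freqs, dtype=float)
    task_p = preprocess(task)
    trials = segment_trials(task_p, seg)
    if trials.n_trials < 1:
        raise ValueError("no usable movement cycles")
    ci = trials.labels.index(channel)
    percent = np.linspace(0.0, 100.0, grid_points)
    maps = []
    for chunk in trials.trial_samples:
        _, power = morlet_cwt(chunk[ci], task.rate, freqs)
        gridded = np.stack([resample_cycle(row, grid_points) for row in power])
        maps.append(TimeFrequencyMap(freqs, percent, gridded))
    if reference == "cycle_mean":
        return grand_average(maps)
    if reference == "rest":
        if rest is None:
            raise ValueError("reference='rest' requires a rest recording")
        rest_p = preprocess(rest)
        _, rest_power = morlet_cwt(rest_p.channel(channel), rest.rate, freqs)
        rest_mean = rest_power.mean(axis=1, keepdims=True)
        mean_power = np.mean([m.power for m in maps], axis=0)
        db = relative_power_db(mean_power, np.broadcast_to(rest_mean, mean_power.shape))
        return TimeFrequencyMap(freqs, percent, db)
    raise ValueError(f"unknown reference {reference!r}")
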