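"""Stimulation parameters and sampled biphasic pulse-train synthesis.

The stimulator delivers charge-balanced, symmetric biphasic rectangular
pulses: a positive phase immediately followed by an equal negative phase,
each ``pulse_width`` microseconds long, repeated at ``frequency`` Hz.
Amplitude is normalized — ``intensity`` is a percentage of the channel
maximum, so samples lie in [-intensity/100, +intensity/100]; absolute
milliamps are a property of the hardware, not of this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimParams",
    "PulseTrain",
    "generate_pulse_train",
    "measure_pulse_rate",
    "measure_pulse_width",
    "ramp_intensity",
]

#: protocol defaults used in the assisted-cycling sessions
DEFAULT_FREQUENCY_HZ = 35.0
DEFAULT_PULSE_WIDTH_US = 300.0
DEFAULT_INTENSITY_PCT = 75.0
DEFAULT_SAMPLE_RATE_HZ = 100_000.0


@dataclass(frozen=True)
class StimParams:
    """Stimulation settings for one channel.

    frequency : pulse repetition rate, Hz
    pulse_width : per-phase width, microseconds
    intensity : percent of the channel maximum, 0-100
    waveform_sample_rate : synthesis sample rate, Hz
    """

    frequency: float = DEFAULT_FREQUENCY_HZ
    pulse_width: float = DEFAULT_PULSE_WIDTH_US
    intensity: float = DEFAULT_INTENSITY_PCT
    waveform_sample_rate: float = DEFAULT_SAMPLE_RATE_HZ

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.pulse_width <= 0:
            raise ValueError("pulse_width must be positive")
        if not 0.0 <= self.intensity <= 100.0:
            raise ValueError("intensity must be in [0, 100] percent")
        if 2.0 * self.pulse_width * 1e-6 >= 1.0 / self.frequency:
            raise ValueError(
                "biphasic pulse (2 x pulse_width) does not fit in one period: "
                f"{self.pulse_width} us at {self.frequency} Hz"
            )

    @property
    def pulse_width_s(self) -> float:
        return self.pulse_width * 1e-6


@dataclass
class PulseTrain:
    """Sampled stimulation waveform: time (s) and normalized amplitude."""

    t: np.ndarray
    amplitude: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.t.shape != self.amplitude.shape:
            raise ValueError("t and amplitude must have the same length")


def generate_pulse_train(params: StimParams, duration: float) -> PulseTrain:
    """Synthesize a sampled biphasic pulse train of the given duration (s).

    Each pulse starts at k/frequency: positive phase for ``pulse_width``,
    negative phase for another ``pulse_width``, no interphase gap, amplitude
    +/- intensity/100.  The sample rate must resolve each phase with at least
    20 samples so measured widths are meaningful.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    fs = params.waveform_sample_rate
    if fs * params.pulse_width_s < 20:
        raise ValueError(
            "waveform_sample_rate too low: need >= 20 samples per pulse phase"
        )
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    amp = np.zeros(n)
    a = params.intensity / 100.0
    period = 1.0 / params.frequency
    width_n = int(round(params.pulse_width_s * fs))
    n_pulses = int(np.floor((duration - 1e-12) * params.frequency)) + 1
    for k in range(n_pulses):
        start = int(round(k * period * fs))
        if start >= n:
            break
        pos_end = min(start + width_n, n)
        neg_end = min(start + 2 * width_n, n)
        amp[start:pos_end] = a
        amp[pos_end:neg_end] = -a
    return PulseTrain(t=t, amplitude=amp, sample_rate=fs)


def _onsets(train: PulseTrain) -> np.ndarray:
    """Indices where the waveform rises from non-positive to positive."""
    pos = train.amplitude > 0
    rising = np.flatnonzero(pos[1:] & ~pos[:-1]) + 1
    if pos.size and pos[0]:
        rising = np.concatenate([[0], rising])
    return rising


def measure_pulse_rate(train: PulseTrain) -> float:
    """Pulse repetition rate in Hz from onset spacing.

    (number of onsets - 1) divided by the span between first and last onset.
    """
    onsets = _onsets(train)
    if onsets.size < 2:
        raise ValueError("need at least 2 pulses to measure a rate")
    span = train.t[onsets[-1]] - train.t[onsets[0]]
    return float((onsets.size - 1) / span)


def measure_pulse_width(train: PulseTrain) -> float:
    """Mean positive-phase duration in microseconds across all pulses."""
    pos = np.concatenate([[False], train.amplitude > 0, [False]])
    edges = np.diff(pos.astype(int))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    if starts.size == 0:
        raise ValueError("train contains no pulses")
    widths = (ends - starts) / train.sample_rate
    return float(np.mean(widths) * 1e6)


def ramp_intensity(
    params: StimParams, target_pct: float, step_pct: float
) -> list[StimParams]:
    """Gradual intensity ramp-up schedule, as applied before a session.

    Returns parameter sets stepping from ``step_pct`` up to exactly
    ``target_pct`` in increments of ``step_pct`` (final step clamped).
    """
    if not 0.0 <= target_pct <= 100.0:
        raise ValueError("target intensity must be in [0, 100] percent")
    if step_pct <= 0:
        raise ValueError("step must be positive")
    levels: list[float] = []
    level = step_pct
    while level < target_pct:
        levels.append(level)
        level += step_pct
    if target_pct > 0:
        levels.append(target_pct)
    return [
        StimParams(
            frequency=params.frequency,
            pulse_width=params.pulse_width,
            intensity=lvl,
            waveform_sample_rate=params.waveform_sample_rate,
        )
        for lvl in levels
    ]
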