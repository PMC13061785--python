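"""Synthetic data generation: IMU motion traces, multichannel EEG, and
end-to-end closed-loop sessions without hardware.

Motion model
------------
The accelerometer is modeled as seeing the gravity vector rotate through its
(x, y) plane once per movement cycle:

    ax = sin(psi(t)) + noise,   ay = cos(psi(t)) + noise,

so the angle pipeline recovers ``psi`` exactly in the noise-free case.  In
pedaling mode ``psi`` advances uniformly (crank rotation); in gait mode the
angular velocity is piecewise constant — stance occupies 60% of the period
while sweeping half the circle, swing the remaining 40% — which reproduces
the stance/swing asymmetry of walking while keeping the ground truth
analytic.

EEG model
---------
Each channel is spectrally shaped 1/f background noise plus mu- and
beta-band sinusoidal oscillators whose amplitude is focal at Cz and decays
exponentially with scalp distance.  During movement the Cz mu power differs
from its rest power by ``erd_db_at_cz`` dB (negative = desynchronization),
with the dB modulation following the same spatial falloff.  An optional FES
bleed-through artifact mixes a low-passed biphasic pulse train into all
channels during commanded-on intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .controller import COMMAND_TOPIC, MessageBus, PhaseController, StimCommand, TaskConfig
from .imu import AngleTrace, CycleSegmentation, ImuSample, accel_to_angle, segment_cycles
from .spectral import EegRecording
from .stim import StimParams

__all__ = [
    "MotionSimConfig",
    "EegSimConfig",
    "SessionRecord",
    "DEFAULT_MONTAGE",
    "simulate_motion_imu",
    "simulate_eeg",
    "simulate_rest",
    "run_closed_loop_session",
]

#: the 16-electrode 10-20 montage of the recording system
DEFAULT_MONTAGE = [
    "Fp1", "Fp2", "F3", "F4", "FC1", "FC2", "C3", "Cz",
    "C4", "CP1", "CP2", "P3", "P4", "P7", "P8", "Pz",
]


@dataclass
class MotionSimConfig:
    """Kinematic simulation settings.

    cycle_period: movement cycle duration T in seconds.
    imu_rate: accelerometer sampling rate, 20 Hz nominal.
    noise_sigma: Gaussian noise std on each axis, in g.
    stance_fraction: gait only — fraction of the period spent in stance
        (sweeping the first half circle).
    """

    mode: str = "pedaling"  # "pedaling" | "gait"
    cycle_period: float = 2.5
    duration: float = 60.0
    imu_rate: float = 20.0
    noise_sigma: float = 0.0
    start_angle: float = -90.0
    stance_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("pedaling", "gait"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.cycle_period <= 0 or self.duration <= 0 or self.imu_rate <= 0:
            raise ValueError("cycle_period, duration and imu_rate must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must be in (0, 1)")


@dataclass
class EegSimConfig:
    """Synthetic EEG settings.

    The oscillator amplitudes are scalp-realistic microvolt scales; the
    movement-related change at Cz is ``erd_db_at_cz`` dB of mu power
    (``beta_erd_db`` for the beta oscillator), both decaying with
    ``space_lambda`` meters of scalp distance from Cz.
    """

    montage: list[str] = field(default_factory=lambda: list(DEFAULT_MONTAGE))
    eeg_rate: float = 512.0
    background_exponent: float = 1.0
    background_rms: float = 5.0  # microvolts, broadband
    mu_center: float = 10.0  # Hz
    beta_center: float = 22.0  # Hz
    mu_amp: float = 20.0  # microvolts at Cz
    beta_amp: float = 10.0  # microvolts at Cz
    erd_db_at_cz: float = -3.0
    beta_erd_db: float = 2.0
    space_lambda: float = 0.05  # meters
    cycle_mod_depth: float = 0.0  # optional within-cycle power modulation
    artifact_params: Optional[StimParams] = None
    artifact_amp: float = 5.0  # microvolts, FES bleed-through
    seed: int = 0

    def __post_init__(self) -> None:
        if self.eeg_rate <= 0:
            raise ValueError("eeg_rate must be positive")
        if len(set(self.montage)) != len(self.montage):
            raise ValueError("montage labels must be unique")
        if "Cz" not in self.montage:
            raise ValueError("montage must include Cz")


@dataclass
class SessionRecord:
    """All aligned streams from one simulated closed-loop session."""

    imu: list[ImuSample]
    angle: AngleTrace
    commands: list[StimCommand]
    eeg: EegRecording
    segmentation: CycleSegmentation
    motion_config: MotionSimConfig
    task_config: TaskConfig
    eeg_config: EegSimConfig


# ---------------------------------------------------------------------------
# motion


def _unwrapped_angle(t: np.ndarray, cfg: MotionSimConfig) -> np.ndarray:
    """Ground-truth unwrapped angle in degrees at times ``t``."""
    u = (t % cfg.cycle_period) / cfg.cycle_period
    turns = np.floor(t / cfg.cycle_period)
    if cfg.mode == "pedaling":
        within = 360.0 * u
    else:  # gait: slow stance over first half circle, fast swing over second
        sf = cfg.stance_fraction
        within = np.where(
            u < sf,
            180.0 * u / sf,
            180.0 + 180.0 * (u - sf) / (1.0 - sf),
        )
    return cfg.start_angle + 360.0 * turns + within


def simulate_motion_imu(config: MotionSimConfig) -> list[ImuSample]:
    """Generate a two-axis accelerometer stream for one simulated session."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = int(round(config.duration * config.imu_rate))
    t = np.arange(n) / config.imu_rate
    psi = np.radians(_unwrapped_angle(t, config))
    ax = np.sin(psi) + rng.normal(0.0, config.noise_sigma, n)
    ay = np.cos(psi) + rng.normal(0.0, config.noise_sigma, n)
    return [ImuSample(float(a), float(b), float(c)) for a, b, c in zip(t, ax, ay)]


# ---------------------------------------------------------------------------
# EEG


def _electrode_positions(montage: Sequence[str]) -> dict[str, np.ndarray]:
    """3-D scalp positions (meters) from the standard 10-20 montage."""
    import warnings

    from mne.channels import make_standard_montage

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        pos = make_standard_montage("standard_1020").get_positions()["ch_pos"]
    return {label: np.asarray(pos[label]) for label in montage}


def _background_1f(rng: np.random.Generator, n: int, rate: float,
                   exponent: float, rms: float) -> np.ndarray:
    """Spectrally shaped Gaussian noise with PSD proportional to 1/f^exponent."""
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    shape = np.zeros_like(freqs)
    nz = freqs >= 1.0  # flat below 1 Hz to avoid the DC singularity
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[(freqs > 0) & ~nz] = 1.0
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * shape
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    std = x.std()
    return x * (rms / std) if std > 0 else x


def _cycle_fraction(t: np.ndarray, boundary_times: np.ndarray) -> np.ndarray:
    """Cycle phase in [0, 1) at each time, from the boundary event list."""
    frac = np.zeros_like(t)
    if boundary_times.size >= 2:
        idx = np.clip(np.searchsorted(boundary_times, t, side="right") - 1, 0,
                      boundary_times.size - 2)
        t0 = boundary_times[idx]
        t1 = boundary_times[idx + 1]
        frac = np.clip((t - t0) / (t1 - t0), 0.0, 1.0)
    return frac


def _synthesize(
    config: EegSimConfig,
    duration: float,
    moving: bool,
    boundary_times: np.ndarray,
    stim_on: Optional[np.ndarray],
) -> EegRecording:
    n = int(round(duration * config.eeg_rate))
    t = np.arange(n) / config.eeg_rate
    seq = np.random.SeedSequence(config.seed)
    bg_seeds, osc_seed = seq.spawn(2)
    bg_rngs = [np.random.default_rng(s) for s in bg_seeds.spawn(len(config.montage))]
    osc_rng = np.random.default_rng(osc_seed)

    pos = _electrode_positions(config.montage)
    cz = pos["Cz"]
    dist = np.array([np.linalg.norm(pos[ch] - cz) for ch in config.montage])
    falloff = np.exp(-dist / config.space_lambda)

    cyc = _cycle_fraction(t, boundary_times) if boundary_times.size else None

    # Each site's rhythm sits at a slightly different peak frequency (as on a
    # real scalp); the 0.05 Hz ladder keeps same-band oscillators at distinct
    # channels incoherent over a recording, so re-referencing cross-terms
    # average out of band-power estimates.
    n_ch = len(config.montage)
    detune = (np.arange(n_ch) - (n_ch - 1) / 2.0) * 0.05

    data = np.empty((n_ch, n))
    for i, ch in enumerate(config.montage):
        x = _background_1f(
            bg_rngs[i], n, config.eeg_rate, config.background_exponent,
            config.background_rms,
        )
        for center, amp, erd_db in (
            (config.mu_center, config.mu_amp, config.erd_db_at_cz),
            (config.beta_center, config.beta_amp, config.beta_erd_db),
        ):
            phase = osc_rng.uniform(0.0, 2.0 * np.pi)
            env = np.ones(n)
            if moving:
                env *= 10.0 ** (erd_db * falloff[i] / 20.0)
                if config.cycle_mod_depth > 0 and cyc is not None:
                    env *= np.sqrt(
                        1.0 + config.cycle_mod_depth * np.cos(2.0 * np.pi * cyc)
                    )
            freq = center + detune[i]
            x = x + amp * falloff[i] * env * np.sin(2.0 * np.pi * freq * t + phase)
        data[i] = x

    if config.artifact_params is not None and stim_on is not None and stim_on.any():
        data += config.artifact_amp * _fes_artifact(
            config.artifact_params, n, config.eeg_rate, stim_on
        )
    return EegRecording(data=data, rate=config.eeg_rate, labels=list(config.montage))


def _fes_artifact(params: StimParams, n: int, eeg_rate: float,
                  stim_on: np.ndarray, cutoff: float = 120.0) -> np.ndarray:
    """Band-limited stimulation bleed-through at the EEG rate, unit peak.

    What survives of a biphasic pulse train after the acquisition chain's
    anti-alias filtering is its harmonic stack below the cutoff, so the
    artifact is synthesized directly as the truncated Fourier series of the
    train: c_k = (1 - e^{-i w_k W})^2 / (i w_k T) for the +W/-W rectangular
    pulse pair, summed for harmonics k f0 below min(cutoff, 0.45 rate).
    The result is normalized to unit peak and gated by the commanded-on mask
    (one bool per EEG sample).
    """
    f0 = params.frequency
    width_s = params.pulse_width_s
    fmax = min(cutoff, 0.45 * eeg_rate)
    n_harm = int(np.floor(fmax / f0))
    if n_harm < 1:
        return np.zeros(n)
    t = np.arange(n) / eeg_rate
    art = np.zeros(n)
    for k in range(1, n_harm + 1):
        omega = 2.0 * np.pi * k * f0
        ck = (1.0 - np.exp(-1j * omega * width_s)) ** 2 / (1j * omega / f0)
        art += 2.0 * np.real(ck * np.exp(1j * omega * t))
    peak = np.abs(art).max()
    if peak > 0:
        art = art / peak
    return art * stim_on.astype(float)


def simulate_eeg(
    config: EegSimConfig,
    cycle_boundaries: Sequence[float] | np.ndarray,
    duration: float,
    stim_on_intervals: Optional[Sequence[tuple[float, float]]] = None,
) -> EegRecording:
    """Synthetic movement-condition EEG with cycle-locked modulation.

    ``cycle_boundaries`` are the IMU-detected cycle start times (seconds);
    ``stim_on_intervals`` optionally lists (start, stop) windows during which
    the FES artifact is mixed in (requires ``config.artifact_params``).
    """
    boundary_times = np.asarray(cycle_boundaries, dtype=float)
    if boundary_times.size and (boundary_times.min() < 0 or boundary_times.max() > duration):
        raise ValueError("cycle boundaries must lie within the recording span")
    stim_on = None
    if stim_on_intervals is not None:
        n = int(round(duration * config.eeg_rate))
        t = np.arange(n) / config.eeg_rate
        stim_on = np.zeros(n, dtype=bool)
        for a, b in stim_on_intervals:
            stim_on |= (t >= a) & (t < b)
    return _synthesize(config, duration, True, boundary_times, stim_on)


def simulate_rest(config: EegSimConfig, duration: float) -> EegRecording:
    """Synthetic baseline (rest) EEG: background plus rest-power oscillators."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return _synthesize(config, duration, False, np.empty(0), None)


# ---------------------------------------------------------------------------
# end-to-end


def _on_intervals(commands: Sequence[StimCommand]) -> list[tuple[float, float]]:
    """Merge the command log into (start, stop) windows with any channel on."""
    intervals: list[tuple[float, float]] = []
    start = None
    prev_t = None
    for c in commands:
        on = bool(c.active_channels)
        if on and start is None:
            start = c.t
        elif not on and start is not None:
            intervals.append((start, c.t))
            start = None
        prev_t = c.t
    if start is not None and prev_t is not None:
        intervals.append((start, prev_t))
    return intervals


def run_closed_loop_session(
    motion: MotionSimConfig,
    task: TaskConfig,
    eeg: EegSimConfig,
    emergency_stop_at: Optional[float] = None,
) -> SessionRecord:
    """Simulate a full session: motion -> controller -> commands -> EEG.

    The IMU stream is fed through the phase controller tick by tick (commands
    are also published on an in-process bus, as the deployed system publishes
    them over its transport); cycles are segmented from the angle trace; EEG
    is then generated conditioned on the cycle events and, when an artifact
    model is configured, on the commanded-on intervals.
    """
    samples = simulate_motion_imu(motion)
    bus = MessageBus()
    published: list[StimCommand] = []
    bus.subscribe(COMMAND_TOPIC, published.append)
    controller = PhaseController(task, bus=bus)
    commands: list[StimCommand] = []
    for s in samples:
        if emergency_stop_at is not None and s.t >= emergency_stop_at:
            controller.trigger_emergency_stop()
        cmd = controller.step(s)
        if cmd is not None:
            commands.append(cmd)
    trace = accel_to_angle(samples)
    seg = segment_cycles(trace)
    intervals = _on_intervals(commands) if eeg.artifact_params is not None else None
    recording = simulate_eeg(
        eeg, seg.boundary_times, motion.duration, stim_on_intervals=intervals
    )
    return SessionRecord(
        imu=samples,
        angle=trace,
        commands=commands,
        eeg=recording,
        segmentation=seg,
        motion_config=motion,
        task_config=task,
        eeg_config=eeg,
    )
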