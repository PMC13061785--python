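"""Closed-loop phase controller: angle -> movement phase -> stimulation command.

Each IMU sample is converted to a segment angle and classified into one of
the configured movement phases (two for pedaling, four for gait); the
controller then emits a per-channel stimulation command.  Software safety
interlocks mirror the device's hardware ones: a latched emergency stop that
forces every subsequent command all-off until an explicit reset, and a
maximum-frequency lock that clamps any requested stimulation rate.

Commands are also published on an in-process message bus (a topic-keyed
subscriber registry) so downstream consumers — loggers, simulators — can
observe the command stream without coupling to the controller.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .imu import ImuSample, angle_from_components
from .stim import StimParams

__all__ = [
    "PhaseDefinition",
    "TaskConfig",
    "ControllerState",
    "StimCommand",
    "MessageBus",
    "PhaseController",
    "classify_phase",
    "enforce_frequency_lock",
    "build_pedaling_config",
    "build_gait_config",
    "PEDALING_PHASES",
    "GAIT_PHASES",
    "DEFAULT_GAIT_RANGES",
]

logger = logging.getLogger(__name__)

COMMAND_TOPIC = "stim/commands"


@dataclass(frozen=True)
class PhaseDefinition:
    """A named movement phase: inclusive angle range and its stimulation channels.

    Ranges that straddle the +/-180 deg wrap are expressed as two definitions
    sharing a name.  ``muscles`` maps each channel id to a descriptive label.
    """

    name: str
    theta_min: float
    theta_max: float
    channels: frozenset[int]
    muscles: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -180.0 <= self.theta_min <= self.theta_max <= 180.0:
            raise ValueError(
                f"phase {self.name!r}: need -180 <= theta_min <= theta_max <= 180"
            )
        if not self.channels:
            raise ValueError(f"phase {self.name!r}: channel set must be nonempty")
        if not all(1 <= c <= 8 for c in self.channels):
            raise ValueError(f"phase {self.name!r}: channel ids must be 1-8")

    def contains(self, theta: float) -> bool:
        return self.theta_min <= theta <= self.theta_max


@dataclass
class TaskConfig:
    """A complete therapist configuration for one task mode."""

    mode: str  # "pedaling" | "gait"
    phases: list[PhaseDefinition]
    stim: StimParams = field(default_factory=StimParams)
    min_dwell: float = 0.1
    max_command_rate: float = 50.0

    def __post_init__(self) -> None:
        if self.mode not in ("pedaling", "gait"):
            raise ValueError(f"unknown mode {self.mode!r}")
        names = []
        for p in self.phases:
            if p.name not in names:
                names.append(p.name)
        expected = {"pedaling": 2, "gait": 4}[self.mode]
        if len(names) != expected:
            raise ValueError(
                f"{self.mode} mode requires exactly {expected} named phases, "
                f"got {len(names)}"
            )
        self._check_disjoint()
        if self.min_dwell < 0:
            raise ValueError("min_dwell must be non-negative")
        if self.max_command_rate <= 0:
            raise ValueError("max_command_rate must be positive")

    def _check_disjoint(self) -> None:
        for i, a in enumerate(self.phases):
            for b in self.phases[i + 1 :]:
                if a.theta_min <= b.theta_max and b.theta_min <= a.theta_max:
                    raise ValueError(
                        f"phase ranges overlap: {a.name!r} "
                        f"[{a.theta_min}, {a.theta_max}] and {b.name!r} "
                        f"[{b.theta_min}, {b.theta_max}]"
                    )

    @property
    def phase_names(self) -> list[str]:
        seen: list[str] = []
        for p in self.phases:
            if p.name not in seen:
                seen.append(p.name)
        return seen

    def channels_for(self, name: str) -> frozenset[int]:
        chans: set[int] = set()
        for p in self.phases:
            if p.name == name:
                chans |= p.channels
        return frozenset(chans)


@dataclass
class ControllerState:
    current_phase: Optional[str] = None
    phase_entry_time: float = 0.0
    emergency_stopped: bool = False
    last_command_time: Optional[float] = None


@dataclass(frozen=True)
class StimCommand:
    """One controller tick: active channels (empty = all off) and settings."""

    t: float
    phase: Optional[str]
    active_channels: frozenset[int]
    params: StimParams


class MessageBus:
    """Minimal in-process publish/subscribe hub keyed by topic string."""

    def __init__(self) -> None:
        self._subs: dict[str, list[Callable]] = defaultdict(list)

    def subscribe(self, topic: str, callback: Callable) -> None:
        self._subs[topic].append(callback)

    def publish(self, topic: str, message) -> None:
        for cb in self._subs[topic]:
            cb(message)


def classify_phase(theta: float, config: TaskConfig) -> Optional[str]:
    """Name of the unique phase whose inclusive range contains ``theta``.

    Returns ``None`` when the angle falls in a gap between phase ranges
    (gaps command all channels off).  Range disjointness is validated when
    the config is built, so at most one phase can match here.
    """
    if not -180.0 < theta <= 180.0:
        raise ValueError(f"theta {theta} outside (-180, 180]")
    for p in config.phases:
        if p.contains(theta):
            return p.name
    return None


def enforce_frequency_lock(requested_rate: float, config: TaskConfig) -> float:
    """Clamp a requested rate (Hz) to the configured maximum-frequency lock."""
    if requested_rate < 0:
        raise ValueError("requested rate must be non-negative")
    return min(requested_rate, config.max_command_rate)


class PhaseController:
    """Stateful closed-loop controller over a :class:`TaskConfig`.

    Phase transitions are debounced: once a phase (including the all-off gap
    state) is entered, a change is honored only after ``min_dwell`` seconds,
    which prevents chattering when the angle jitters at a range boundary.
    An emergency stop latches until :meth:`reset`.
    """

    def __init__(self, config: TaskConfig, bus: Optional[MessageBus] = None) -> None:
        self.config = config
        self.bus = bus
        self.state = ControllerState()
        self._started = False
        # stimulation frequency passes through the maximum-frequency lock
        granted = enforce_frequency_lock(config.stim.frequency, config)
        self._params = replace(config.stim, frequency=granted)

    # -- state transitions -------------------------------------------------
    def trigger_emergency_stop(self) -> ControllerState:
        """Latch the emergency stop; every later command is all-off. Idempotent."""
        self.state.emergency_stopped = True
        return self.state

    def reset(self) -> ControllerState:
        """Clear a latched emergency stop and the phase memory."""
        self.state = ControllerState()
        self._started = False
        return self.state

    def step(self, sample: ImuSample) -> Optional[StimCommand]:
        """Process one IMU sample and emit the stimulation command for it.

        Malformed samples (non-finite or all-zero acceleration) are skipped
        with a logged warning and return ``None``.
        """
        try:
            if not (np.isfinite(sample.ax) and np.isfinite(sample.ay)):
                raise ValueError("non-finite acceleration")
            theta = angle_from_components(sample.ax, sample.ay)
        except ValueError as exc:
            logger.warning("skipping malformed IMU sample at t=%s: %s", sample.t, exc)
            warnings.warn(f"skipping malformed IMU sample at t={sample.t}: {exc}")
            return None

        st = self.state
        if st.emergency_stopped:
            command = StimCommand(sample.t, None, frozenset(), self._params)
        else:
            candidate = classify_phase(theta, self.config)
            if not self._started:
                st.current_phase = candidate
                st.phase_entry_time = sample.t
                self._started = True
            elif candidate != st.current_phase:
                if sample.t - st.phase_entry_time >= self.config.min_dwell:
                    st.current_phase = candidate
                    st.phase_entry_time = sample.t
            phase = st.current_phase
            channels = self.config.channels_for(phase) if phase else frozenset()
            command = StimCommand(sample.t, phase, channels, self._params)
        st.last_command_time = sample.t
        if self.bus is not None:
            self.bus.publish(COMMAND_TOPIC, command)
        return command

    def run(self, samples: Sequence[ImuSample]) -> list[StimCommand]:
        """Run the controller over a whole sample stream; returns the command log."""
        return [c for c in map(self.step, samples) if c is not None]


# ---------------------------------------------------------------------------
# Configuration builders

#: pedaling: two phases, printed angle ranges, channel -> muscle per device map
PEDALING_PHASES = (
    ("flexion", 150.0, 175.0, (1, 2)),
    ("extension", -179.0, -150.0, (3, 4)),
)

PEDALING_MUSCLES = {
    1: "right quadriceps",
    2: "left hamstring",
    3: "left quadriceps",
    4: "right hamstring",
}

#: gait: four phases in cycle order with their target muscle groups
GAIT_PHASES = (
    ("initial_contact", ("quadriceps", "tibialis anterior")),
    ("mid_stance", ("quadriceps",)),
    ("terminal_stance", ("quadriceps", "triceps surae")),
    ("initial_swing", ("hamstrings", "tibialis anterior")),
)

#: default gait angle ranges simply quarter the circle in cycle order; real
#: sessions require therapist-supplied ranges fitted to the patient
DEFAULT_GAIT_RANGES = (
    (-180.0, -91.0),
    (-90.0, -1.0),
    (0.0, 89.0),
    (90.0, 179.0),
)

# channels 1-4 on device A (right leg), 5-8 on device B (left leg)
_GAIT_CHANNELS = {
    "initial_contact": {1: "right quadriceps", 2: "right tibialis anterior",
                        5: "left quadriceps", 6: "left tibialis anterior"},
    "mid_stance": {1: "right quadriceps", 5: "left quadriceps"},
    "terminal_stance": {1: "right quadriceps", 3: "right triceps surae",
                        5: "left quadriceps", 7: "left triceps surae"},
    "initial_swing": {4: "right hamstrings", 2: "right tibialis anterior",
                      8: "left hamstrings", 6: "left tibialis anterior"},
}


def build_pedaling_config(
    stim: Optional[StimParams] = None,
    min_dwell: float = 0.1,
    max_command_rate: float = 50.0,
) -> TaskConfig:
    """Two-phase pedaling task at the protocol settings (35 Hz, 300 us, 75%).

    Channels 1-2 (right quadriceps, left hamstring) fire for
    150 <= theta <= 175 deg; channels 3-4 (left quadriceps, right hamstring)
    for -179 <= theta <= -150 deg, alternately supporting flexion and
    extension.
    """
    phases = [
        PhaseDefinition(
            name=name,
            theta_min=lo,
            theta_max=hi,
            channels=frozenset(chans),
            muscles={c: PEDALING_MUSCLES[c] for c in chans},
        )
        for name, lo, hi, chans in PEDALING_PHASES
    ]
    return TaskConfig(
        mode="pedaling",
        phases=phases,
        stim=stim or StimParams(),
        min_dwell=min_dwell,
        max_command_rate=max_command_rate,
    )


def build_gait_config(
    angle_ranges: Optional[Sequence[tuple[float, float]]] = None,
    stim: Optional[StimParams] = None,
    min_dwell: float = 0.1,
    max_command_rate: float = 50.0,
) -> TaskConfig:
    """Four-phase gait task; angle ranges are therapist-adjustable.

    Phases in cycle order: initial contact (quadriceps + tibialis anterior),
    mid-stance (quadriceps), terminal stance (quadriceps + triceps surae),
    initial swing (hamstrings + tibialis anterior), each mapped onto
    left/right channel pairs across the two 4-channel devices.
    """
    ranges = tuple(angle_ranges) if angle_ranges is not None else DEFAULT_GAIT_RANGES
    if len(ranges) != 4:
        raise ValueError(f"gait mode requires exactly 4 angle ranges, got {len(ranges)}")
    phases = []
    for (name, _muscle_groups), (lo, hi) in zip(GAIT_PHASES, ranges):
        chan_map = _GAIT_CHANNELS[name]
        phases.append(
            PhaseDefinition(
                name=name,
                theta_min=lo,
                theta_max=hi,
                channels=frozenset(chan_map),
                muscles=dict(chan_map),
            )
        )
    return TaskConfig(
        mode="gait",
        phases=phases,
        stim=stim or StimParams(),
        min_dwell=min_dwell,
        max_command_rate=max_command_rate,
    )
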