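"""IMU kinematics: accelerometer-to-angle conversion and movement-cycle segmentation.

A single two-axis accelerometer mounted on a rotating limb segment sees the
gravity vector sweep through its (x, y) plane once per movement cycle, so the
segment angle is recovered as the full-quadrant arctangent of the two
acceleration components.  All angles are in degrees, wrapped into the
half-open interval (-180, 180]; time is in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImuSample",
    "AngleTrace",
    "CycleSegmentation",
    "accel_to_angle",
    "angle_from_components",
    "unwrap_angle",
    "wrap_angle",
    "segment_cycles",
    "estimate_frequency",
    "resample_cycle",
    "regularize_samples",
]


@dataclass(frozen=True)
class ImuSample:
    """One accelerometer reading: time (s) and the two axis accelerations (g)."""

    t: float
    ax: float
    ay: float


@dataclass
class AngleTrace:
    """Time-stamped segment angle in degrees, each value in (-180, 180]."""

    t: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.t.shape != self.theta.shape:
            raise ValueError("t and theta must have the same length")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size


@dataclass
class CycleSegmentation:
    """Cycle boundaries (sample indices) and per-cycle periods in seconds."""

    boundaries: np.ndarray
    boundary_times: np.ndarray
    periods: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=int)
        self.boundary_times = np.asarray(self.boundary_times, dtype=float)
        if self.boundaries.size != self.boundary_times.size:
            raise ValueError("boundaries and boundary_times must match")
        if self.boundaries.size >= 2 and not np.all(np.diff(self.boundaries) > 0):
            raise ValueError("boundaries must be strictly increasing")
        self.periods = np.diff(self.boundary_times)

    @property
    def n_cycles(self) -> int:
        return max(self.boundaries.size - 1, 0)


def wrap_angle(theta_deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles (degrees) into (-180, 180]."""
    wrapped = -((-np.asarray(theta_deg, dtype=float) + 180.0) % 360.0 - 180.0)
    return wrapped


def angle_from_components(ax: float, ay: float) -> float:
    """Segment angle (degrees, in (-180, 180]) from one accelerometer sample.

    Uses the two-argument arctangent of (ax, ay) so the whole circle is
    reachable; the plain ratio arctan(ax/ay) would fold opposite quadrants
    together and could never produce the phase ranges near +/-180 deg that the
    pedaling task uses.
    """
    if ax == 0.0 and ay == 0.0:
        raise ValueError("both acceleration components are zero")
    theta = float(np.degrees(np.arctan2(ax, ay)))
    return 180.0 if theta == -180.0 else theta


def accel_to_angle(samples) -> AngleTrace:
    """Convert a sequence of :class:`ImuSample` into an :class:`AngleTrace`.

    Raises ``ValueError`` (naming the sample index) if any sample has both
    acceleration components equal to zero, since the angle is then undefined.
    """
    samples = list(samples)
    t = np.array([s.t for s in samples], dtype=float)
    ax = np.array([s.ax for s in samples], dtype=float)
    ay = np.array([s.ay for s in samples], dtype=float)
    degenerate = np.flatnonzero((ax == 0.0) & (ay == 0.0))
    if degenerate.size:
        raise ValueError(
            f"degenerate IMU sample at index {int(degenerate[0])}: ax == ay == 0"
        )
    theta = np.degrees(np.arctan2(ax, ay))
    theta[theta == -180.0] = 180.0
    return AngleTrace(t=t, theta=theta)


def unwrap_angle(trace: AngleTrace) -> np.ndarray:
    """Unwrap the wrapped angle into a continuous (unbounded) degree vector.

    Successive differences of the result are below 180 deg in magnitude and
    wrapping the result back into (-180, 180] reproduces the input exactly.
    """
    return np.unwrap(trace.theta, period=360.0)


def segment_cycles(trace: AngleTrace, reference_angle: float = 0.0) -> CycleSegmentation:
    """Segment an angle trace into movement cycles.

    A cycle boundary is placed at each upward crossing of ``reference_angle``
    (plus any whole number of turns) in the *unwrapped* trace, which makes the
    segmentation insensitive to the +/-180 deg wrap.  The boundary index is the
    first sample at or above the crossing; the boundary time is refined by
    linear interpolation between the bracketing samples so periods are not
    quantized to the IMU sample interval.

    Fewer than two crossings yield an empty segmentation (zero cycles).
    """
    if len(trace) < 2:
        return CycleSegmentation(np.empty(0, int), np.empty(0, float))
    unwrapped = unwrap_angle(trace)
    # Count each whole turn past the reference exactly once: noise can make the
    # angle jitter back and forth across the reference, so crossings are taken
    # on the running maximum, which cannot retreat and re-cross.
    x = (unwrapped - reference_angle) / 360.0
    cummax = np.maximum.accumulate(x)
    levels = np.arange(np.floor(cummax[0]) + 1.0, np.floor(cummax[-1]) + 1.0)
    if levels.size < 2:
        return CycleSegmentation(np.empty(0, int), np.empty(0, float))
    indices = np.searchsorted(cummax, levels, side="left")
    times = np.empty(indices.size, dtype=float)
    for k, i in enumerate(indices):
        target = levels[k] * 360.0 + reference_angle
        y0, y1 = unwrapped[i - 1], unwrapped[i]
        frac = (target - y0) / (y1 - y0) if y1 != y0 else 0.0
        times[k] = trace.t[i - 1] + frac * (trace.t[i] - trace.t[i - 1])
    return CycleSegmentation(indices, times)


def estimate_frequency(seg: CycleSegmentation) -> float:
    """Movement frequency (cadence) in Hz: reciprocal of the mean cycle period."""
    if seg.n_cycles < 1:
        raise ValueError("cannot estimate frequency from an empty segmentation")
    return float(1.0 / np.mean(seg.periods))


def instantaneous_frequencies(seg: CycleSegmentation) -> np.ndarray:
    """Per-cycle instantaneous frequencies in Hz (reciprocal of each period)."""
    if seg.n_cycles < 1:
        raise ValueError("cannot estimate frequency from an empty segmentation")
    return 1.0 / seg.periods


def resample_cycle(values: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Resample one cycle onto an evenly spaced 0-100% grid of ``n_points``.

    Linear interpolation; the first and last samples are preserved exactly.
    The default of 101 points maps grid indices to integer cycle percentages.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("cycle must be a 1-D array with at least 2 samples")
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    src = np.linspace(0.0, 1.0, values.size)
    dst = np.linspace(0.0, 1.0, n_points)
    return np.interp(dst, src, values)


def regularize_samples(samples, rate: float = 20.0) -> list[ImuSample]:
    """Resample irregularly timed IMU samples onto a uniform grid at ``rate`` Hz.

    Linear interpolation of each axis; used before segmentation when a stream
    arrives with jittered timestamps.  The nominal acquisition rate of the
    sensor is 20 Hz.
    """
    samples = list(samples)
    if len(samples) < 2:
        return samples
    t = np.array([s.t for s in samples])
    ax = np.array([s.ax for s in samples])
    ay = np.array([s.ay for s in samples])
    tt = np.arange(t[0], t[-1] + 0.5 / rate, 1.0 / rate)
    tt = tt[tt <= t[-1]]
    axi = np.interp(tt, t, ax)
    ayi = np.interp(tt, t, ay)
    return [ImuSample(float(a), float(b), float(c)) for a, b, c in zip(tt, axi, ayi)]
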