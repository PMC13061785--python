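# Methods

## Angle computation and cycle segmentation

The control law reduces limb kinematics to a single angle
θ = atan2(aₓ, a_y), in degrees, wrapped to (−180°, 180]. The two-argument
arctangent is deliberate: a plain ratio arctan(aₓ/a_y) folds opposite
quadrants together and cannot produce the pedaling phase ranges near ±180°.
A sample with aₓ = a_y = 0 has no defined angle and is rejected (batch
conversion) or skipped with a warning (the live controller).

Cycle boundaries are upward crossings of a configurable reference angle
(default 0°) in the unwrapped trace. Crossings are detected on the running
maximum of the unwrapped angle, so measurement noise that jitters the angle
back and forth across the reference cannot double-count a cycle: each whole
turn past the reference is counted exactly once. Boundary times are refined
by linear interpolation between the bracketing samples, which makes period
estimates sub-sample accurate; movement frequency is the reciprocal of the
mean period. No smoothing is applied to θ before classification or
segmentation by default; a moving-average window can be applied upstream if
a noisier sensor requires it.

Trials are length-normalized by linear interpolation onto a 0–100% cycle
grid of 101 points, so grid indices are integer cycle percentages.

## Controller semantics

- Phase ranges are inclusive and validated as pairwise disjoint at
  configuration time; an angle in a gap between ranges commands all
  channels off (explicitly, not by holding the previous command).
- Transitions are debounced: after entering any state (a phase or the
  all-off gap state) the controller holds it for `min_dwell` (default
  0.1 s) before honoring a change, preventing chatter at range boundaries.
- The emergency stop latches: every subsequent command has an empty channel
  set until an explicit reset. The maximum-frequency lock clamps the
  configured stimulation frequency to `max_command_rate`.
- Pedaling uses the two printed ranges with channels 1–2 (right quadriceps,
  left hamstring) and 3–4 (left quadriceps, right hamstring) at 35 Hz /
  300 μs / 75%. Gait ranges are mandatory, therapist-supplied
  configuration; the package ships quarter-circle defaults
  ([−180,−91], [−90,−1], [0,89], [90,179] degrees) that are an artifact
  choice for simulation, not measured values. The four gait muscle groups ×
  two legs map onto 8 channels (1–4 right-leg device, 5–8 left-leg device).
- Commands are published on an in-process topic-keyed bus; a network
  transport is out of scope and would subscribe to the same topic.
- Controller output is a pure function of (sample stream, config), so
  command logs are byte-identical across runs.

## Stimulation waveform model

Symmetric biphasic rectangular pulses — positive phase then negative phase,
each `pulse_width` μs, no interphase gap — at `frequency` Hz, amplitude
normalized to `intensity`/100 of the channel maximum (absolute current is a
hardware property and intentionally not modeled). Validity requires
2·pulse_width < 1/frequency. Synthesis at 100 kHz by default (30 samples
per 300 μs phase; at least 20 samples per phase enforced). Verification
measures the repetition rate from onset spacing and the pulse width from
positive-run lengths; charge balance holds to one sample's area per period.
Ramp-up schedules step intensity from zero to the target with the final
step clamped, mirroring how stimulation is brought up before a session.

## Synthetic data generator

The generator's defaults are the study conditions, not free dials.

**Motion.** aₓ = sin ψ(t) + ε, a_y = cos ψ(t) + ε with ε ~ N(0, σ²) per
axis, IMU rate 20 Hz. Pedaling: ψ advances uniformly (360°/period).
Gait: piecewise-constant angular velocity — stance occupies 60% of the
period while sweeping the first half circle, swing the remaining 40% —
giving the stance/swing asymmetry of walking with analytic ground truth.
Reference conditions: cycle periods 2.5 s (gait, 0.4 Hz) and 5/3 s
(pedaling, 0.6 Hz), noise σ = 0.05 g, 60 s traces.

**EEG.** 16 channels at 512 Hz in microvolts. Per channel: spectrally
shaped Gaussian background with PSD ∝ 1/f^β (β = 1, flat below 1 Hz,
broadband RMS 5 μV) plus two sinusoidal oscillators, mu (10 Hz, 20 μV at
Cz) and beta (22 Hz, 10 μV at Cz). Oscillator amplitude decays as
exp(−d/λ) with scalp distance d from Cz (λ = 0.05 m, positions from the
standard 10–20 montage), making the rhythms Cz-focal. During movement the
mu power at Cz changes by `erd_db_at_cz` dB (amplitude × 10^(dB·falloff/20)
per channel, so the dB modulation follows the same spatial falloff); the
beta oscillator has its own `beta_erd_db` (default +2 dB, a
movement-related synchronization). Each channel's oscillator is detuned on
a 0.05 Hz ladder around the band center: real rhythms differ in peak
frequency across sites, and without the detuning the common-average
reference leaks the large Cz tone coherently into every channel, where it
interferes with the local tone and corrupts off-center band-power ratios.
The oscillator-to-background power ratio in the mu band (~90:1 at Cz) keeps
the broadband background from biasing recovered dB values by more than
~0.1 dB; estimates through the full pipeline recover injected ERD within
±0.5 dB from ≥ 120 s sessions.

**FES artifact (optional).** What survives of a biphasic pulse train after
the acquisition chain's anti-alias filtering is its harmonic stack, so the
bleed-through is synthesized as the truncated Fourier series of the train
(harmonics of the stimulation frequency below min(120 Hz, 0.45·rate)),
normalized to unit peak, scaled by `artifact_amp` (default 5 μV) and gated
by the commanded-on intervals. Its amplitude has no empirical calibration;
it exists to test that analysis stages confine stimulation-band power to
stimulation-on epochs.

All randomness derives from one seed per record via seed-sequence
splitting; identical configs and seeds give identical records.

What the generator does **not** emulate: movement and ocular artifacts,
volume conduction (channel backgrounds are independent), non-sinusoidal or
non-stationary rhythm morphology, electrode impedance drift, and
biomechanically realistic gait kinematics. Passing recovery tests therefore
demonstrates correctness of the processing chain, not robustness to real
scalp data.

## Spectral pipeline choices

- CAR then zero-phase band-pass 8–45 Hz (4th-order Butterworth,
  forward–backward), chosen to avoid phase-shifting cycle-locked features.
  Design attenuation ≥ 20 dB at half the low edge and 10 Hz above the high
  edge.
- Per-trial spectra are plain periodograms of each cycle's native samples
  (a Hann taper is used where trials of different lengths are combined or
  band powers are integrated); the rest reference is a Welch estimate with
  2 s windows and 50% overlap. Band power is the PSD integral over the
  band; relative power is 10·log₁₀(task/rest). Whole normalized cycles are
  the FFT segments — one cycle, one trial.
- Morlet maps use a 6-cycle complex wavelet on an 8–45 Hz grid at 0.5 Hz
  steps. Power is rescaled by frequency to undo the 1/f amplitude tilt of
  energy-normalized wavelets, so a stationary tone's ridge peaks at its own
  frequency, matching the periodogram; the scaling cancels in every dB
  comparison.
- Two dB references are implemented: `cycle_mean` (within-cycle maps)
  centers each frequency row's log power on its cycle mean — a geometric-
  mean normalization, so rows average to exactly 0 dB; `rest` compares
  against the rest recording's mean wavelet power per frequency.
- Trial rejection: cycles whose period deviates from the median by more
  than 3 robust scale units are dropped (MAD scale, falling back to the
  mean deviation when most periods are identical, floored at 1% of the
  median so float-level jitter never culls cycles); drop counts are
  reported.
- Band edges are fixed: mu 8–13, low beta 13–20, high beta 20–30 Hz.
- No artifact-removal stage (ICA etc.) is included; the pipeline applies
  only CAR and the band-pass.

## File formats

IMU, angle, events and command logs are comma-separated CSV with header
rows; task configuration is YAML; EEG travels as EDF. EDF writing is
implemented directly (continuous 16-bit EDF, 1 s records, shared symmetric
physical range, quantization below physical_max/32767); reading goes
through MNE, which doubles as an independent check on written files in the
tests. EDF headers carry a fixed start date so seeded runs are
byte-identical; wall-clock timestamps live only in the run manifest, which
snapshots configs, seeds, paths and the tool version for every CLI run.

## Problem sizes

The shipped tests and the acceptance script use 30–120 s simulated sessions
(up to ~70 movement cycles, 16 × 61 440 EEG samples) and 1 s stimulation
waveforms at 100 kHz; these sizes give estimator noise well inside every
asserted tolerance while keeping a full run in seconds on one core.

## Known limitations

- The gait angle profile is a two-segment approximation; real thigh angle
  trajectories are smoother and asymmetric in range, not only in speed.
- Oscillators are pure (detuned) sinusoids; band-power recovery on broadband
  or bursty rhythms will carry more variance than the tests exhibit.
- Per-channel stimulation parameter individualization (different intensity
  per muscle) is not modeled; one parameter set applies to all channels of
  a task.
- The EDF writer covers exactly the continuous, uniform-rate case this
  package produces; it is not a general EDF+ implementation.
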