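"""Synthetic A-mode ultrasound generation.

Emulates a wearable multi-transducer pulse-echo system: each single-element
transducer (SET) fires a short broadband pulse and records the returning RF
line, so a tissue boundary at depth ``d`` produces an echo centred at the
round-trip sample index ``2 d fs / c``.  Scenes are described by continuous
boundary-depth trajectories, per-boundary echo amplitudes, and multiplicative
intensity-modulation functions that mimic angle-of-incidence changes.  The
generators return the exact ground truth alongside the frames so that
tracking algorithms can be validated against known motion.

The echo model is deliberately minimal: a linear superposition of
Gaussian-windowed cosines (Gabor pulses) evaluated in continuous time at each
sample instant, plus optional white Gaussian noise.  Sub-sample boundary
positions are therefore represented exactly, with no interpolation artefacts.
No speckle texture, attenuation, or beam physics is modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PulseWaveform",
    "SimScenario",
    "UltrasoundFrameSeries",
    "GroundTruth",
    "generate_pulse",
    "simulate_frame_series",
    "make_mechanical_test_scenario",
    "make_contraction_scenario",
]

# Acquisition defaults of the wearable system: 50 MHz digitiser, soft-tissue
# speed of sound 1540 m/s, echoes recorded to 80 mm, 90 frames/s, 4 SETs.
DEFAULT_SAMPLING_FREQUENCY = 50e6
DEFAULT_SPEED_OF_SOUND = 1540.0
DEFAULT_MAX_DEPTH_MM = 80.0
DEFAULT_FRAME_RATE = 90.0
DEFAULT_N_TRANSDUCERS = 4

_SQRT_2LN2 = math.sqrt(2.0 * math.log(2.0))


def _gabor_sigma_t(center_frequency: float, fractional_bandwidth: float) -> float:
    """Time-domain Gaussian width giving a -6 dB (half-amplitude) spectral
    full width of ``fractional_bandwidth * center_frequency``."""
    bandwidth = fractional_bandwidth * center_frequency
    sigma_f = bandwidth / (2.0 * _SQRT_2LN2)
    return 1.0 / (2.0 * math.pi * sigma_f)


@dataclass(frozen=True)
class PulseWaveform:
    """A transmit/receive pulse model: Gaussian-windowed cosine (Gabor).

    ``samples`` holds the pulse sampled symmetrically about its peak, which
    is normalised to 1.
    """

    center_frequency: float
    fractional_bandwidth: float
    sampling_frequency: float
    samples: np.ndarray

    @property
    def sigma_t(self) -> float:
        return _gabor_sigma_t(self.center_frequency, self.fractional_bandwidth)


def generate_pulse(
    center_frequency: float = 5e6,
    fractional_bandwidth: float = 0.4,
    sampling_frequency: float = DEFAULT_SAMPLING_FREQUENCY,
) -> PulseWaveform:
    """Build a Gabor pulse with the given centre frequency and -6 dB
    fractional bandwidth.

    Raises
    ------
    ValueError
        If ``center_frequency`` is not strictly between 0 and Nyquist, or the
        bandwidth is non-positive.
    """
    if not 0.0 < center_frequency < sampling_frequency / 2.0:
        raise ValueError(
            f"center_frequency must lie in (0, Nyquist={sampling_frequency / 2:g}) Hz; "
            f"got {center_frequency:g} Hz"
        )
    if fractional_bandwidth <= 0.0:
        raise ValueError("fractional_bandwidth must be positive")
    sigma_t = _gabor_sigma_t(center_frequency, fractional_bandwidth)
    half = int(math.ceil(4.0 * sigma_t * sampling_frequency))
    t = np.arange(-half, half + 1) / sampling_frequency
    samples = np.exp(-0.5 * (t / sigma_t) ** 2) * np.cos(2.0 * math.pi * center_frequency * t)
    return PulseWaveform(center_frequency, fractional_bandwidth, sampling_frequency, samples)


Trajectory = Callable[[np.ndarray], np.ndarray]


@dataclass
class SimScenario:
    """A simulated scene: boundary trajectories plus acquisition settings.

    ``boundary_trajectories`` are callables mapping time (s, vectorised) to
    depth (mm); ``intensity_modulation`` entries are callables mapping time
    to a positive multiplicative gain (``None`` means constant gain 1).
    ``noise_snr`` is in dB relative to the strongest noiseless echo peak;
    ``None`` disables noise.
    """

    boundary_trajectories: Sequence[Trajectory]
    echo_amplitudes: Sequence[float]
    intensity_modulation: Sequence[Trajectory | None] | None = None
    per_transducer_gain: Sequence[float] = (1.0,)
    noise_snr: float | None = None
    duration: float = 10.0
    frame_rate: float = DEFAULT_FRAME_RATE
    max_depth_mm: float = DEFAULT_MAX_DEPTH_MM
    speed_of_sound: float = DEFAULT_SPEED_OF_SOUND
    sampling_frequency: float = DEFAULT_SAMPLING_FREQUENCY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if len(self.echo_amplitudes) != len(self.boundary_trajectories):
            raise ValueError("need one echo amplitude per boundary")
        if self.intensity_modulation is not None and len(self.intensity_modulation) != len(
            self.boundary_trajectories
        ):
            raise ValueError("need one intensity modulation entry per boundary")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class UltrasoundFrameSeries:
    """Raw RF frame stack, ``data`` indexed transducer x frame x sample."""

    data: np.ndarray
    sampling_frequency: float
    frame_rate: float
    speed_of_sound: float
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (transducer, frame, sample)")
        if len(self.timestamps) != self.data.shape[1]:
            raise ValueError("timestamps must match the frame count")

    @property
    def n_transducers(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def sample_spacing_mm(self) -> float:
        """Depth increment per sample: c / (2 fs), in mm."""
        return self.speed_of_sound / (2.0 * self.sampling_frequency) * 1e3

    @property
    def max_depth_mm(self) -> float:
        return self.n_samples * self.sample_spacing_mm

    def depth_axis_mm(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.sample_spacing_mm


@dataclass
class GroundTruth:
    """Exact per-frame boundary depths and derived quantities of a scene."""

    boundary_depths_mm: np.ndarray  # (n_boundaries, n_frames)
    thickness_mm: np.ndarray  # empty when fewer than 2 boundaries
    angle_deg: np.ndarray | None = None
    torque_nm: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.boundary_depths_mm.shape[1] if self.boundary_depths_mm.size else 0


def _n_samples_for(max_depth_mm: float, sampling_frequency: float, speed_of_sound: float) -> int:
    return int(round(2.0 * (max_depth_mm * 1e-3) * sampling_frequency / speed_of_sound))


def simulate_frame_series(
    scenario: SimScenario, pulse: PulseWaveform
) -> tuple[UltrasoundFrameSeries, GroundTruth]:
    """Render a scenario into an RF frame stack with exact ground truth.

    Each RF line is the superposition, over boundaries, of the continuous
    Gabor pulse centred at the boundary's round-trip delay and scaled by
    (base amplitude x intensity modulation x per-transducer gain); white
    Gaussian noise is added at ``scenario.noise_snr`` dB relative to the
    strongest noiseless echo.  Bit-identical under a fixed seed.

    Raises
    ------
    ValueError
        If any trajectory leaves (0, max_depth) at any frame, or the pulse
        and scenario sampling frequencies disagree.
    """
    if not math.isclose(pulse.sampling_frequency, scenario.sampling_frequency):
        raise ValueError("pulse and scenario sampling frequencies differ")
    fs = scenario.sampling_frequency
    c = scenario.speed_of_sound
    n_samples = _n_samples_for(scenario.max_depth_mm, fs, c)
    times = scenario.frame_times
    n_frames = scenario.n_frames
    n_td = len(scenario.per_transducer_gain)

    depths = np.empty((len(scenario.boundary_trajectories), n_frames))
    for b, traj in enumerate(scenario.boundary_trajectories):
        d = np.asarray(traj(times), dtype=float)
        if d.shape != times.shape:
            raise ValueError("trajectory must return one depth per frame")
        if np.any(d <= 0.0) or np.any(d >= scenario.max_depth_mm):
            raise ValueError(
                f"boundary {b} leaves the valid depth range (0, {scenario.max_depth_mm}) mm"
            )
        depths[b] = d

    sigma_t = pulse.sigma_t
    sigma_samples = sigma_t * fs
    half_w = int(math.ceil(8.0 * sigma_samples))
    offsets = np.arange(-half_w, half_w + 1)

    base = np.zeros((n_frames, n_samples))
    for b in range(depths.shape[0]):
        t0 = 2.0 * (depths[b] * 1e-3) / c  # round-trip delay, s
        center = t0 * fs
        ci = np.round(center).astype(np.int64)
        idx = ci[:, None] + offsets[None, :]
        dt = idx / fs - t0[:, None]
        vals = np.exp(-0.5 * (dt / sigma_t) ** 2) * np.cos(
            2.0 * math.pi * pulse.center_frequency * dt
        )
        gain = np.full(n_frames, float(scenario.echo_amplitudes[b]))
        if scenario.intensity_modulation is not None:
            mod = scenario.intensity_modulation[b]
            if mod is not None:
                m = np.asarray(mod(times), dtype=float)
                if np.any(m <= 0.0):
                    raise ValueError("intensity modulation must stay positive")
                gain = gain * m
        vals *= gain[:, None]
        valid = (idx >= 0) & (idx < n_samples)
        rows = np.broadcast_to(np.arange(n_frames)[:, None], idx.shape)
        np.add.at(base, (rows[valid], idx[valid]), vals[valid])

    gains = np.asarray(scenario.per_transducer_gain, dtype=float)
    data = (gains[:, None, None] * base[None, :, :]).astype(np.float32)

    if scenario.noise_snr is not None and np.isfinite(scenario.noise_snr):
        peak = float(np.max(np.abs(base))) * float(np.max(np.abs(gains)))
        if peak == 0.0:
            peak = 1.0  # pure-noise scene: unit-amplitude reference
        sigma = peak / 10.0 ** (scenario.noise_snr / 20.0)
        rng = np.random.default_rng(scenario.seed)
        data = data + rng.standard_normal(data.shape, dtype=np.float32) * np.float32(sigma)

    series = UltrasoundFrameSeries(
        data=data,
        sampling_frequency=fs,
        frame_rate=scenario.frame_rate,
        speed_of_sound=c,
        timestamps=times,
    )
    if depths.shape[0] >= 2:
        thickness = depths[-1] - depths[0]
    else:
        thickness = np.empty(0)
    truth = GroundTruth(boundary_depths_mm=depths, thickness_mm=thickness)
    return series, truth


def make_mechanical_test_scenario(
    displacement_amplitude_mm: float = 10.0,
    motion_frequency: float = 0.5,
    modulation_depth: float = 0.5,
    duration: float = 30.0,
    seed: int = 0,
    *,
    mid_depth_mm: float = 30.0,
    modulation_frequency: float = 0.23,
    noise_snr: float | None = 20.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
    sampling_frequency: float = DEFAULT_SAMPLING_FREQUENCY,
    speed_of_sound: float = DEFAULT_SPEED_OF_SOUND,
    max_depth_mm: float = DEFAULT_MAX_DEPTH_MM,
) -> SimScenario:
    """Scenario emulating the cyclic-displacement bench test.

    One reflective boundary oscillates sinusoidally about ``mid_depth_mm``
    with peak-to-peak excursion ``displacement_amplitude_mm`` at
    ``motion_frequency``; the echo gain is modulated sinusoidally by
    ``1 +/- modulation_depth`` at an incommensurate frequency to mimic
    angle-of-incidence intensity changes.  Four transducers with distinct
    gains are simulated.
    """
    if displacement_amplitude_mm <= 0:
        raise ValueError("displacement_amplitude_mm must be positive")
    if not 0.0 <= modulation_depth < 1.0:
        raise ValueError("modulation_depth must lie in [0, 1); 1 would null the echo")
    amp = displacement_amplitude_mm / 2.0

    def trajectory(t: np.ndarray) -> np.ndarray:
        return mid_depth_mm + amp * np.sin(2.0 * math.pi * motion_frequency * t)

    def modulation(t: np.ndarray) -> np.ndarray:
        return 1.0 + modulation_depth * np.sin(2.0 * math.pi * modulation_frequency * t)

    return SimScenario(
        boundary_trajectories=[trajectory],
        echo_amplitudes=[1.0],
        intensity_modulation=[modulation if modulation_depth > 0 else None],
        per_transducer_gain=(1.0, 0.75, 0.55, 0.4),
        noise_snr=noise_snr,
        duration=duration,
        frame_rate=frame_rate,
        max_depth_mm=max_depth_mm,
        speed_of_sound=speed_of_sound,
        sampling_frequency=sampling_frequency,
        seed=seed,
    )


def make_contraction_scenario(
    model,
    angle_profile: Trajectory,
    thickness_profile: Trajectory,
    noise_snr: float | None = 20.0,
    seed: int = 0,
    *,
    duration: float = 20.0,
    superficial_depth_mm: float = 5.0,
    frame_rate: float = DEFAULT_FRAME_RATE,
    sampling_frequency: float = DEFAULT_SAMPLING_FREQUENCY,
    speed_of_sound: float = DEFAULT_SPEED_OF_SOUND,
    max_depth_mm: float = DEFAULT_MAX_DEPTH_MM,
) -> tuple[SimScenario, GroundTruth]:
    """Scenario of a contracting muscle with torque ground truth.

    The superficial boundary is constant at ``superficial_depth_mm`` and the
    deep boundary follows ``superficial + thickness_profile(t)``; the
    ground-truth torque is ``model`` (a fitted or hand-built quadratic torque
    model) evaluated pointwise on (thickness, angle) — or on thickness alone
    for a single-input model.
    """
    n_inputs = len(model.input_names)
    if n_inputs not in (1, 2):
        raise ValueError(
            f"model must take (thickness,) or (thickness, angle); got {n_inputs} inputs"
        )

    def deep(t: np.ndarray) -> np.ndarray:
        return superficial_depth_mm + np.asarray(thickness_profile(t), dtype=float)

    scenario = SimScenario(
        boundary_trajectories=[lambda t: np.full_like(np.asarray(t, float), superficial_depth_mm), deep],
        echo_amplitudes=[1.0, 1.0],
        intensity_modulation=None,
        per_transducer_gain=(1.0, 0.75, 0.55, 0.4),
        noise_snr=noise_snr,
        duration=duration,
        frame_rate=frame_rate,
        max_depth_mm=max_depth_mm,
        speed_of_sound=speed_of_sound,
        sampling_frequency=sampling_frequency,
        seed=seed,
    )
    times = scenario.frame_times
    thickness = np.asarray(thickness_profile(times), dtype=float)
    angle = np.asarray(angle_profile(times), dtype=float)
    if n_inputs == 1:
        inputs = thickness[:, None]
    else:
        inputs = np.column_stack([thickness, angle])
    torque = np.asarray(model.predict(inputs), dtype=float)
    truth = GroundTruth(
        boundary_depths_mm=np.vstack(
            [np.full_like(times, superficial_depth_mm), superficial_depth_mm + thickness]
        ),
        thickness_mm=thickness,
        angle_deg=angle,
        torque_nm=torque,
    )
    return scenario, truth
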