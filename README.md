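# sonomyo

Muscle and joint mechanical loads are hard to monitor outside the lab:
dynamometers and instrumented treadmills measure joint torque accurately but
immobilize the participant. Wearable A-mode (amplitude-mode) ultrasound
offers a way out — a few single-element transducers (SETs) strapped over a
muscle belly record one echo line each per pulse, and the depth of the deep
muscle boundary tracks muscle deformation during contraction. Muscle
thickness, combined with joint kinematics, predicts joint torque well enough
for biomechanics, rehabilitation, and wearable-robotics applications.

`sonomyo` implements that pipeline end to end for researchers working with
single-element-transducer data (or wanting to prototype against realistic
synthetic data):

- **`sonomyo.simulate`** — a pulse-echo simulator producing multi-transducer
  RF frame stacks with exact ground truth: Gabor transmit pulses, moving
  specular boundaries, angle-of-incidence–style echo-intensity modulation,
  and white noise at a chosen SNR.
- **`sonomyo.tracking`** — the muscle boundary tracker: per-transducer
  selection by mean peak echo intensity, a brightness tracker (Hilbert
  envelope → 2.5 mm × 0.05 s box filter → peak localization) fused with a
  cross-correlation tracker (frame-to-frame RF delays, parabolic sub-sample
  refinement, integrated over time) through complementary low/high-pass
  filtering at 1.5 Hz, and thickness as deep-boundary depth minus a constant
  superficial depth.
- **`sonomyo.torque`** — full second-order polynomial ("quadratic fit")
  torque models T(MT, θ) with intercept, linear, squared, and interaction
  terms; sinusoidal gravitational-torque correction fitted on passive
  trials; per-participant normalization; RMSE / NRMSE / R² metrics.
- **`sonomyo.kinematics`** — hinge-joint segment angles from IMU
  quaternions, joint angles by segment subtraction, zero-lag Butterworth
  filtering, heel-strike/toe-off detection from foot angle and angular
  velocity, and stance-phase time normalization.
- **`sonomyo.rigidbody`** — reference elbow torque for dumbbell curls from a
  rod + point-mass model: T = (m₀gL/2)·sin θ + mgL·sin θ + I·α with
  I = m₀(L/2)² + mL².

## The tracking model in brief

For a boundary at depth *d* the echo arrives at round-trip sample index
2·d·f_s/c (f_s = 50 MHz sampling, c = 1540 m/s), so one sample spans
c/(2·f_s) = 15.4 µm of depth. The brightness tracker is anchored to absolute
depth but jitters when echo intensity varies with the angle of incidence;
the cross-correlation tracker is precise frame to frame but accumulates
drift when integrated. The fused estimate

&nbsp;&nbsp;&nbsp;&nbsp;d̂ = LP₁.₅ₕᵤ(d̂_brightness) + HP₁.₅ₕᵤ(d̂_xcorr)

keeps the reliable band of each. Torque is then estimated from muscle
thickness MT and joint angle(s) θ by ordinary least squares on the degree-2
basis {1, MT, θ, MT², θ², MT·θ}.

## Worked example

Simulate the cyclic-displacement bench validation — one reflective boundary
oscillating 10 mm peak-to-peak at 0.5 Hz for 30 s, echo intensity modulated
±50% to mimic angle-of-incidence changes, 20 dB SNR — and track it:

```python
import numpy as np
import sonomyo as sm

scenario = sm.make_mechanical_test_scenario(
    displacement_amplitude_mm=10.0, motion_frequency=0.5,
    modulation_depth=0.5, duration=30.0, seed=1,
)
pulse = sm.generate_pulse(5e6, 0.4, 50e6)
series, truth = sm.simulate_frame_series(scenario, pulse)

fused, transducer = sm.track_boundary(series, sm.DepthWindow(20, 40))
g = truth.boundary_depths_mm[0]
rmse = np.sqrt(np.mean((fused.depth_mm - g) ** 2))
print(f"selected transducer: {transducer}")
print(f"frames tracked:      {series.n_frames}")
print(f"tracking RMSE:       {rmse:.4f} mm")
print(f"tracking NRMSE:      {100 * rmse / np.ptp(g):.3f} %")

thickness, _ = sm.run_mbta(series, sm.DepthWindow(20, 40), superficial_depth_mm=5.0)
print(f"mean thickness:      {thickness.thickness_mm.mean():.2f} mm")
```

Output:

```
selected transducer: 0
frames tracked:      2700
tracking RMSE:       0.0033 mm
tracking NRMSE:      0.033 %
mean thickness:      25.00 mm
```

The tracker follows the 10 mm motion to a few microns RMS — about a fifth of
a depth sample — despite the ±50% intensity modulation and the noise: the
boundary sits 25 mm below the assumed 5 mm superficial depth, oscillating
±5 mm. The same workflow is available from the shell via the `sonomyo`
console script (`simulate`, `track`, `gait`, `fit`, `estimate`,
`rigid-body`, `evaluate`, `run`).

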