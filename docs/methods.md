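# Methods

This note records the models implemented in `sonomyo`, the assumptions they
make, the defaults and why, and what the synthetic data does and does not
emulate.

## Echo simulation

The simulator models an A-mode pulse-echo line as a linear superposition of
specular boundary echoes. The transmit/receive pulse is a Gabor function — a
Gaussian-windowed cosine at the transducer centre frequency (default 5 MHz)
whose −6 dB spectral full width equals the fractional bandwidth times the
centre frequency (default 0.4, i.e. a 2 MHz band consistent with a 4–6 MHz
analog receive band). A boundary at depth *d* (mm) contributes the
continuous Gabor expression centred at round-trip delay 2d/c, evaluated at
each sample instant of the 50 MHz grid. Because the continuous expression is
sampled directly, sub-sample boundary positions are represented exactly and
the recorded ground truth is exact, which is what makes sub-sample tracker
accuracy testable. Echo amplitude is (base amplitude × per-boundary
intensity modulation × per-transducer gain); intensity modulation is a
strictly positive gain-versus-time function standing in for
angle-of-incidence changes, with no beam physics. White Gaussian noise is
added at a configurable SNR in dB defined against the strongest noiseless
echo peak in the stack — one intuitive knob; the simulator deliberately does
*not* band-limit the noise the way a real receive chain's analog filter
would, so trackers must cope with broadband noise.

Acquisition defaults mirror the wearable system: 50 MHz sampling, c =
1540 m/s, echoes to 80 mm (5195 samples, since one sample spans
c/(2f_s) = 15.4 µm), 90 frames/s, 4 transducers. All are arguments.

The *mechanical bench scenario* emulates a rig that cyclically displaces a
transducer relative to a printed surface: one boundary oscillating
sinusoidally about 30 mm depth (default 10 mm peak-to-peak at 0.5 Hz — the
rig's true amplitude and rate are not published, so these are configurable
assumptions chosen to make the reported absolute and normalized errors
mutually consistent), echo gain modulated ±50% at 0.23 Hz (incommensurate
with the motion so modulation and motion phases decorrelate over the run),
20 dB SNR, 30 s. The *contraction scenario* couples a constant superficial
boundary with a deep boundary at superficial + thickness(t) and records
ground-truth torque as a user-supplied quadratic surface evaluated on
(thickness, angle); it exists to close the loop simulator → tracker → model
fit.

What the synthetic data does not emulate: speckle texture from
sub-resolution scatterers (real windows carry correlated signal everywhere,
which if anything *helps* correlation tracking), frequency-dependent
attenuation and time-gain compensation, reverberation, refraction, probe
decoupling, and out-of-plane motion. Passing the bench reproduction
therefore demonstrates correctness of the algorithm on the modelled physics,
not performance on tissue.

## Boundary tracking

The tracker operates on a manually chosen depth window assumed to contain
exactly one boundary of interest, matching how a user crops real data.

**Transducer selection.** For each transducer, the per-frame maximum of the
Hilbert envelope inside the window is averaged over frames; the largest mean
wins, ties to the lowest index. The choice is made once per recording.

**Brightness tracker.** Band-pass the RF to the transducer band (default
4–6 MHz, zero-phase 4th-order Butterworth; disable with
`bandpass_hz=None`), take the envelope, smooth with a 2-D box filter of
2.5 mm (depth) × 0.05 s (time) — physical extents converted to odd sample
counts by rounding up (163 samples × 5 frames at the defaults), replicate
padding at the edges — and locate the per-frame peak in the window, ties
toward smaller depth. Because the box flattens a sharp echo into a plateau
whose discrete argmax wanders under noise, the coarse argmax is refined by
locating the unsmoothed envelope's peak within half a box width and
interpolating it parabolically; refinement is exact on noiseless static
scenes and can be disabled (`refine=False`).

**Cross-correlation tracker.** For each consecutive frame pair, the
normalized cross-correlation of the windowed, band-limited RF lines is
computed via FFT; the per-pair correlation functions are then averaged over
a 0.05 s running window (the same extent as the brightness box's time axis)
before peak picking. The inter-frame delay changes by well under a sample
between neighbouring pairs at physiological speeds, so this averaging does
not bias the delay, but it strongly suppresses carrier-period lobe hopping:
the RF correlation oscillates at the transducer centre frequency, and under
broadband noise an adjacent lobe (±1 carrier period ≈ ±10 samples at the
defaults) can otherwise narrowly beat the true peak. The peak lag is refined
by three-point parabolic interpolation (clipped to ±0.5 samples), delays are
converted to mm via c/(2f_s), and cumulatively summed into a relative
displacement trace starting at 0. Zero-energy windows raise an error naming
the offending frame. Set `corr_time_s=0` for strictly independent pairs.

**Fusion.** The brightness trace is low-pass filtered and the
cross-correlation trace high-pass filtered at a shared cutoff (1.5 Hz
default) and summed. Both filters derive from one zero-phase 2nd-order
Butterworth low-pass applied forward-backward (filtfilt); the high-pass is
the exact spectral complement x − LP(x), so LP(a) + HP(a) = a holds
identically — the fusion passes a common input through unchanged, which
makes the identity testable. The low order keeps filtfilt edge transients
short on brief recordings; the first and last ⌈frame rate / cutoff⌉ frames
are still flagged on the output trace (`transient_frames`) so users may trim
them. The relative cross-correlation trace is re-referenced to absolute
depth by adding the brightness-trace mean before filtering.

**Thickness.** Deep-boundary depth minus a constant, manually measured
superficial depth; a non-positive result raises, since it means the assumed
boundary ordering is violated.

Filter order and realization, box edge handling, the band-pass prefilter,
the correlation averaging window, and the peak refinement are all
implementation choices the algorithm's published description leaves open;
they are exposed as arguments and noted here because they materially affect
robustness: without the prefilter, correlation averaging, and refinement,
bench-emulation errors grow by one to two orders of magnitude under 20 dB
broadband noise with ±50% intensity modulation.

## Torque models

The "quadratic fit" is the full d-variate second-order polynomial —
intercept, d linear, d squared, and d(d−1)/2 pairwise interaction terms —
fitted by ordinary least squares. The full basis is the standard reading of
a quadratic fit on several inputs and degenerates gracefully to fewer terms
when the data do not excite them. Rank-deficient designs are solved by the
minimum-norm solution with a warning; there is no regularization.
Dynamometer-style models use (thickness mm, joint angle deg); locomotion
models use thickness plus pelvis, thigh, and shank segment angles (d = 4),
reflecting the biarticular geometry of the rectus femoris. Angles enter the
polynomial in degrees as measured; thickness in mm.

Gravitational torque is modelled as T_g(θ) = a1·sin θ + a2·cos θ + c0
(θ in radians inside the trigonometry), fitted by linear least squares on
passive trials and subtracted from all trials. The sin/cos/offset form is
the linear-in-parameters equivalent of an amplitude–phase sinusoid plus
offset; the exact parametrization is an assumption. At least 3 distinct
angles are required.

Metrics: RMSE; NRMSE = 100·RMSE / range(ground truth); R² = 1 −
SS_res/SS_tot. Constant ground truth makes NRMSE (and R²) undefined and
raises. For generalized (cross-participant) models, each participant's
thickness and torque are divided by their own maxima — one global maximum
per participant, not per condition; angles are not normalized since they
already share a physical scale.

## Kinematics and gait

Segment angles assume perfect hinge joints with one sensor axis exactly
along the joint axis — the drift-robust reading of consumer IMU orientation
output. Per frame, the joint axis is rotated into the global frame, the
gravity-opposing direction and the rotated segment axis are projected into
the plane normal to the joint axis, and their signed planar angle is taken
(degrees, unwrapped over frames). The local segment reference is the
gravity-opposing direction at the neutral pose, orthogonalized against the
joint axis; the gravity reference is static (no online re-estimation of the
global frame). The computation is exact for pure hinge rotations and raises
when the joint axis comes within 5° of the gravity line, where the plane is
undefined. Joint angles are differences of adjacent segment angles (knee =
thigh − shank, hip = pelvis − thigh).

Joint traces are filtered with a zero-lag 4th-order Butterworth low-pass —
5 Hz for dynamometer and dumbbell data, 10 Hz for locomotion — implemented
as forward-backward `sosfiltfilt`.

Heel strikes are local maxima of the foot angle with a minimum separation of
0.4 s and a prominence of at least 20% of the trace's peak-to-peak
amplitude; toe-offs are the minimum of the foot angular velocity (centred
finite differences) strictly between consecutive heel strikes. The
separation and prominence guards are additions — a bare local-extremum rule
is noise-fragile — and are configurable. Stance segments (heel strike →
toe-off) and generic segments are time-normalized by linear interpolation
onto 101 points (0–100% in 1% steps, the biomechanics convention).
Synchronization across instruments is plain linear interpolation onto the
ultrasound frame clock, with extrapolation refused.

## Rigid-body reference torque

Forearm + hand as a uniform rod (mass m₀, length L from cubital fossa to
hand centre), dumbbell as a point mass m at the distal end:
T = (m₀gL/2)·sin θ + mgL·sin θ + I·α with I = m₀(L/2)² + mL², θ the angle
between forearm and the gravity line (0° = hanging). θ is converted to
radians before differentiation; α uses centred finite differences with
one-sided endpoints. An optional 5 Hz zero-lag prefilter on θ is recommended
for measured data and is kept separate from the core computation (the
function accepts 3-frame traces, too short to filter). m₀ is a required
input — anthropometric segment-mass fractions are table-dependent, so a
helper multiplies body mass by a user-supplied fraction rather than
hardcoding one.

## Numerical choices and degenerate inputs

- Argmax ties break toward smaller depth / smaller (more negative) lag;
  all outputs are deterministic for fixed inputs and seeds.
- Parabolic peak refinements are applied only at proper (concave) maxima
  and clipped to ±0.5 samples.
- Kernel extents round *up* to odd integer counts so the stated physical
  extent is always covered.
- Sample count per line is round(2 · max_depth · f_s / c); depth of sample
  i is i · c/(2f_s).
- Empty scenes, zero-energy windows, Nyquist-violating pulses or cutoffs,
  out-of-range trajectories, non-positive thickness, constant ground truth,
  and degenerate gait/fit inputs all raise informative errors rather than
  producing silent nonsense.

## Problem sizes and runtime

The bench reproduction uses the full 30 s × 90 Hz × 4 transducers × 5195
samples stack (2700 frames) and runs in well under a minute on one CPU; the
end-to-end contraction check uses 20 s recordings. These sizes were chosen
as the smallest runs that exercise several motion and modulation cycles
with stable error statistics.

## Known limitations

- Single-boundary windows only; track multiple boundaries by running the
  tracker once per window.
- The superficial boundary is a constant, as appropriate for superficial
  muscles; deep-muscle thickness would need two tracked boundaries.
- No real ultrasound physics beyond specular echoes (see simulator
  section); quantitative claims transfer to tissue only insofar as the
  modelled effects dominate.
- The quadratic torque map is empirical: it interpolates the calibration
  envelope and should not be extrapolated far outside it, and it does not
  model co-contraction, which biases reference torques from the rigid-body
  model during real curls.
- IMU yaw drift is handled only through the hinge assumption; non-hinge
  joints and magnetometer fusion are out of scope.
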