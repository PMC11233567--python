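"""Muscle boundary tracking from A-mode RF frame stacks.

The tracker estimates the per-frame depth of one tissue boundary inside a
manually chosen depth window, then derives muscle thickness by subtracting a
constant superficial-boundary depth.  Two complementary estimators are fused:

* a *brightness* tracker — Hilbert envelope, 2-D box smoothing
  (2.5 mm x 0.05 s by default), per-frame peak location.  It is anchored to
  absolute depth but jitters at high frequency when echo intensity varies
  with the angle of incidence;
* a *cross-correlation* tracker — normalised cross-correlation of raw RF
  between consecutive frames with parabolic sub-sample refinement, delays
  integrated over time.  It is smooth and precise frame-to-frame but drifts
  at low frequency as integration errors accumulate.

The fusion sums the low-pass-filtered brightness trace and the
high-pass-filtered (complementary) cross-correlation trace at a shared
cutoff (1.5 Hz by default), combining the reliable band of each.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .simulate import UltrasoundFrameSeries

__all__ = [
    "DepthWindow",
    "BoundaryTrace",
    "ThicknessTrace",
    "select_transducer",
    "envelope",
    "track_brightness",
    "track_xcorr",
    "fuse_tracks",
    "compute_thickness",
    "track_boundary",
    "run_mbta",
]

DEFAULT_FUSION_CUTOFF_HZ = 1.5
DEFAULT_BOX_DEPTH_MM = 2.5
DEFAULT_BOX_TIME_S = 0.05
# receive band of the 5 MHz transducers (the hardware's analog band-pass);
# used to reject out-of-band noise before tracking
DEFAULT_BANDPASS_HZ: tuple[float, float] = (4e6, 6e6)
DEFAULT_CORR_TIME_S = 0.05


def _bandpass_rf(rf: np.ndarray, sampling_frequency: float,
                 bandpass_hz: tuple[float, float] | None) -> np.ndarray:
    """Zero-phase band-pass along the depth axis, restricted to the
    transducer band; a no-op when ``bandpass_hz`` is None."""
    rf = np.asarray(rf, dtype=float)
    if bandpass_hz is None:
        return rf
    lo, hi = bandpass_hz
    if not 0 < lo < hi < sampling_frequency / 2:
        raise ValueError("band-pass edges must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(4, (lo, hi), btype="band", fs=sampling_frequency, output="sos")
    return signal.sosfiltfilt(sos, rf, axis=-1)


@dataclass(frozen=True)
class DepthWindow:
    """Depth range (mm) cropped to contain only the boundary of interest."""

    min_depth_mm: float
    max_depth_mm: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_depth_mm < self.max_depth_mm:
            raise ValueError("require 0 <= min_depth < max_depth")

    def to_slice(self, series: UltrasoundFrameSeries) -> slice:
        dz = series.sample_spacing_mm
        if self.max_depth_mm > series.max_depth_mm + dz:
            raise ValueError(
                f"window exceeds recorded depth ({series.max_depth_mm:.1f} mm)"
            )
        lo = int(math.floor(self.min_depth_mm / dz))
        hi = min(int(math.ceil(self.max_depth_mm / dz)) + 1, series.n_samples)
        if hi - lo < 1:
            raise ValueError("depth window contains no samples")
        return slice(lo, hi)


@dataclass
class BoundaryTrace:
    """Per-frame boundary depth in mm.

    ``kind`` is ``"absolute"`` (referenced to the skin surface) or
    ``"relative"`` (displacement from the first frame, which is 0).
    ``transient_frames`` marks how many frames at each end of a fused trace
    are affected by zero-phase filter edge transients.
    """

    depth_mm: np.ndarray
    frame_rate: float
    kind: str = "absolute"
    transient_frames: int = 0

    def __post_init__(self) -> None:
        self.depth_mm = np.asarray(self.depth_mm, dtype=float)
        if not np.all(np.isfinite(self.depth_mm)):
            raise ValueError("boundary trace contains non-finite values")
        if self.kind not in ("absolute", "relative"):
            raise ValueError("kind must be 'absolute' or 'relative'")
        if self.kind == "relative" and self.depth_mm.size and self.depth_mm[0] != 0.0:
            raise ValueError("relative traces must start at 0")

    def __len__(self) -> int:
        return self.depth_mm.size


@dataclass
class ThicknessTrace:
    """Muscle thickness (deep minus superficial boundary depth) per frame."""

    thickness_mm: np.ndarray
    frame_rate: float
    superficial_depth_mm: float

    def __post_init__(self) -> None:
        self.thickness_mm = np.asarray(self.thickness_mm, dtype=float)
        if np.any(self.thickness_mm <= 0.0):
            raise ValueError("thickness must be positive at every frame")

    def __len__(self) -> int:
        return self.thickness_mm.size


def envelope(rf: np.ndarray) -> np.ndarray:
    """Echo envelope: magnitude of the analytic signal along the last axis."""
    rf = np.asarray(rf)
    if rf.shape[-1] < 8:
        raise ValueError("need at least 8 samples per RF line")
    return np.abs(signal.hilbert(rf.astype(float), axis=-1))


def select_transducer(series: UltrasoundFrameSeries, window: DepthWindow) -> int:
    """Pick the transducer with the best angle of incidence.

    Returns the index maximising the mean (over frames) of the per-frame peak
    envelope amplitude inside ``window``; ties break toward the lowest index.
    """
    if series.n_transducers < 1:
        raise ValueError("series has no transducers")
    sl = window.to_slice(series)
    scores = np.empty(series.n_transducers)
    for k in range(series.n_transducers):
        env = envelope(series.data[k])[:, sl]
        scores[k] = env.max(axis=1).mean()
    return int(np.argmax(scores))


def _odd_kernel(extent: float) -> int:
    """Physical extent -> odd integer sample count, rounding up, at least 1."""
    k = max(1, int(math.ceil(extent - 1e-9)))
    return k if k % 2 == 1 else k + 1


def box_kernel_shape(series: UltrasoundFrameSeries, box_depth_mm: float, box_time_s: float) -> tuple[int, int]:
    """(frames, samples) shape of the 2-D smoothing box for this series."""
    n_depth = _odd_kernel(box_depth_mm / series.sample_spacing_mm)
    n_time = _odd_kernel(box_time_s * series.frame_rate)
    return n_time, n_depth


def track_brightness(
    series: UltrasoundFrameSeries,
    window: DepthWindow,
    transducer: int = 0,
    box_depth_mm: float = DEFAULT_BOX_DEPTH_MM,
    box_time_s: float = DEFAULT_BOX_TIME_S,
    bandpass_hz: tuple[float, float] | None = DEFAULT_BANDPASS_HZ,
    refine: bool = True,
) -> BoundaryTrace:
    """Brightness-based tracker: smoothed-envelope peak depth per frame.

    The RF is band-limited to the transducer band, its envelope smoothed
    with a 2-D box filter (``box_depth_mm`` in depth by ``box_time_s`` in
    time, converted to odd sample/frame counts with replicate edge padding),
    and the per-frame argmax inside the window is converted to mm.  Ties
    break toward the smaller depth.

    With ``refine`` (the default), the coarse argmax of the box-smoothed
    envelope is sharpened by locating the unsmoothed envelope's peak within
    half a box width and interpolating it parabolically to sub-sample
    precision: the box flattens the peak into a plateau whose discrete
    argmax wanders under noise, while the underlying echo peak is sharp.
    """
    sl = window.to_slice(series)
    n_time, n_depth = box_kernel_shape(series, box_depth_mm, box_time_s)
    if sl.stop - sl.start < n_depth:
        raise ValueError(
            f"depth window spans {sl.stop - sl.start} samples but the smoothing box "
            f"needs {n_depth}; enlarge the window"
        )
    rf = _bandpass_rf(series.data[transducer], series.sampling_frequency, bandpass_hz)
    env = envelope(rf)[:, sl]
    smooth = ndimage.uniform_filter(env, size=(n_time, n_depth), mode="nearest")
    coarse = np.argmax(smooth, axis=1)
    if not refine:
        return BoundaryTrace(
            (coarse + sl.start) * series.sample_spacing_mm, series.frame_rate, kind="absolute"
        )
    half = n_depth // 2
    peak = np.empty(coarse.size, dtype=float)
    for i, c in enumerate(coarse):
        a = max(c - half, 1)
        b = min(c + half + 1, env.shape[1] - 1)
        k = a + int(np.argmax(env[i, a:b]))
        c0, cm, cp = env[i, k], env[i, k - 1], env[i, k + 1]
        den = cm - 2.0 * c0 + cp
        frac = 0.5 * (cm - cp) / den if den < 0 else 0.0
        peak[i] = k + min(max(frac, -0.5), 0.5)
    return BoundaryTrace(
        (peak + sl.start) * series.sample_spacing_mm, series.frame_rate, kind="absolute"
    )


def track_xcorr(
    series: UltrasoundFrameSeries,
    window: DepthWindow,
    transducer: int = 0,
    bandpass_hz: tuple[float, float] | None = DEFAULT_BANDPASS_HZ,
    corr_time_s: float = DEFAULT_CORR_TIME_S,
) -> BoundaryTrace:
    """Cross-correlation tracker: integrated inter-frame delays.

    For each consecutive frame pair the delay is the argmax of the normalised
    cross-correlation of the windowed, band-limited RF lines, refined to
    sub-sample precision by three-point parabolic interpolation, then
    converted to mm via c/(2 fs) and cumulatively summed.  The result is a
    *relative* displacement trace starting at 0.

    Before peak picking, the normalised correlation functions are averaged
    over a short ``corr_time_s`` running window across consecutive pairs
    (the same extent as the brightness box's time axis).  The inter-frame
    delay varies slowly relative to the frame rate, so this sharpens the
    true peak against carrier-period ambiguities (the RF correlation is
    oscillatory at the transducer centre frequency) without biasing the
    delay.  Set ``corr_time_s=0`` to disable.
    """
    if series.n_frames < 2:
        raise ValueError("need at least 2 frames for cross-correlation tracking")
    sl = window.to_slice(series)
    rf = _bandpass_rf(series.data[transducer], series.sampling_frequency, bandpass_hz)[:, sl]
    n = rf.shape[1]
    energies = np.einsum("ij,ij->i", rf, rf)
    if np.any(energies == 0.0):
        bad = int(np.flatnonzero(energies == 0.0)[0])
        raise ValueError(f"zero-energy depth window in frame {bad}; cannot correlate")

    nfft = 1 << int(math.ceil(math.log2(2 * n - 1)))
    spectra = np.fft.rfft(rf, n=nfft, axis=1)
    cross = np.fft.irfft(spectra[1:] * np.conj(spectra[:-1]), n=nfft, axis=1)
    norm = np.sqrt(energies[1:] * energies[:-1])
    cross /= norm[:, None]
    lags = np.arange(nfft)
    lags[lags > nfft // 2] -= nfft
    order = np.argsort(lags, kind="stable")
    lags_sorted = lags[order]
    cs = cross[:, order]
    # restrict to physically meaningful lags; argmax on ascending lags makes
    # ties break toward the smaller (more negative) lag
    valid = np.abs(lags_sorted) <= n - 1
    cs = cs[:, valid]
    lags_sorted = lags_sorted[valid]
    if corr_time_s > 0:
        n_pairs = _odd_kernel(corr_time_s * series.frame_rate)
        if n_pairs > 1:
            cs = ndimage.uniform_filter1d(cs, size=n_pairs, axis=0, mode="nearest")
    peak = np.argmax(cs, axis=1)
    delays = lags_sorted[peak].astype(float)
    interior = (peak > 0) & (peak < cs.shape[1] - 1)
    rows = np.flatnonzero(interior)
    c0 = cs[rows, peak[rows]]
    cm = cs[rows, peak[rows] - 1]
    cp = cs[rows, peak[rows] + 1]
    denom = cm - 2.0 * c0 + cp
    frac = np.zeros_like(c0)
    nz = denom != 0.0
    frac[nz] = 0.5 * (cm[nz] - cp[nz]) / denom[nz]
    delays[rows] += np.clip(frac, -0.5, 0.5)

    disp = np.concatenate([[0.0], np.cumsum(delays)]) * series.sample_spacing_mm
    return BoundaryTrace(disp, series.frame_rate, kind="relative")


def _lowpass(x: np.ndarray, frame_rate: float, cutoff: float) -> np.ndarray:
    # 2nd-order Butterworth applied forward-backward: zero phase, and low
    # order keeps edge transients short on brief traces
    sos = signal.butter(2, cutoff, btype="low", fs=frame_rate, output="sos")
    return signal.sosfiltfilt(sos, x)


def fuse_tracks(
    brightness: BoundaryTrace,
    xcorr: BoundaryTrace,
    cutoff: float = DEFAULT_FUSION_CUTOFF_HZ,
) -> BoundaryTrace:
    """Complementary fusion of the two trackers at a shared cutoff.

    Output = LP(brightness) + HP(xcorr), with the high-pass realised as the
    spectral complement ``x - LP(x)`` of the same zero-phase low-pass, so
    that LP(a) + HP(a) == a holds exactly.  The relative cross-correlation
    trace is re-referenced to absolute depth by adding the brightness mean
    before filtering.
    """
    if len(brightness) != len(xcorr):
        raise ValueError("traces must have equal length")
    if not math.isclose(brightness.frame_rate, xcorr.frame_rate):
        raise ValueError("traces must share a frame rate")
    if cutoff <= 0 or cutoff >= brightness.frame_rate / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    b = brightness.depth_mm
    x = xcorr.depth_mm
    if xcorr.kind == "relative":
        x = x + b.mean()
    fused = _lowpass(b, brightness.frame_rate, cutoff) + (
        x - _lowpass(x, brightness.frame_rate, cutoff)
    )
    transient = int(math.ceil(brightness.frame_rate / cutoff))
    return BoundaryTrace(fused, brightness.frame_rate, kind="absolute", transient_frames=transient)


def compute_thickness(deep: BoundaryTrace, superficial_depth_mm: float) -> ThicknessTrace:
    """Thickness = deep boundary depth minus a constant superficial depth."""
    if deep.kind != "absolute":
        raise ValueError("deep trace must be absolute")
    if superficial_depth_mm < 0:
        raise ValueError("superficial depth must be non-negative")
    thickness = deep.depth_mm - superficial_depth_mm
    if np.any(thickness <= 0.0):
        raise ValueError(
            "non-positive thickness: deep boundary crosses the superficial depth"
        )
    return ThicknessTrace(thickness, deep.frame_rate, superficial_depth_mm)


def track_boundary(
    series: UltrasoundFrameSeries,
    window: DepthWindow,
    cutoff: float = DEFAULT_FUSION_CUTOFF_HZ,
    transducer: int | None = None,
    box_depth_mm: float = DEFAULT_BOX_DEPTH_MM,
    box_time_s: float = DEFAULT_BOX_TIME_S,
    bandpass_hz: tuple[float, float] | None = DEFAULT_BANDPASS_HZ,
    corr_time_s: float = DEFAULT_CORR_TIME_S,
) -> tuple[BoundaryTrace, int]:
    """Full fused boundary tracking on the best (or given) transducer."""
    if transducer is None:
        transducer = select_transducer(series, window)
    bright = track_brightness(series, window, transducer, box_depth_mm, box_time_s, bandpass_hz)
    xc = track_xcorr(series, window, transducer, bandpass_hz, corr_time_s)
    return fuse_tracks(bright, xc, cutoff), transducer


def run_mbta(
    series: UltrasoundFrameSeries,
    window: DepthWindow,
    superficial_depth_mm: float,
    cutoff: float = DEFAULT_FUSION_CUTOFF_HZ,
    transducer: int | None = None,
    box_depth_mm: float = DEFAULT_BOX_DEPTH_MM,
    box_time_s: float = DEFAULT_BOX_TIME_S,
    bandpass_hz: tuple[float, float] | None = DEFAULT_BANDPASS_HZ,
    corr_time_s: float = DEFAULT_CORR_TIME_S,
) -> tuple[ThicknessTrace, int]:
    """End-to-end muscle thickness tracking.

    Composes transducer selection, brightness and cross-correlation tracking
    of the deep boundary inside ``window``, complementary fusion at
    ``cutoff``, and thickness computation against the manually measured
    constant superficial depth.
    """
    fused, idx = track_boundary(
        series, window, cutoff, transducer, box_depth_mm, box_time_s, bandpass_hz, corr_time_s
    )
    return compute_thickness(fused, superficial_depth_mm), idx
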