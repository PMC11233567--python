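"""End-to-end composition: track -> synchronise -> filter -> model -> evaluate."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .kinematics import AngleTrace, lowpass_zero_lag, resample_to
from .simulate import UltrasoundFrameSeries
from .torque import (
    Metrics,
    QuadraticTorqueModel,
    TorqueTrace,
    evaluate,
    fit_quadratic_model,
    predict_torque,
)
from .tracking import DepthWindow, ThicknessTrace, run_mbta

log = logging.getLogger("sonomyo")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    thickness: ThicknessTrace
    transducer: int
    model: QuadraticTorqueModel
    prediction: TorqueTrace
    metrics: Metrics | None


def run_pipeline(
    config: PipelineConfig,
    series: UltrasoundFrameSeries,
    angle: AngleTrace | None = None,
    torque: TorqueTrace | None = None,
    model: QuadraticTorqueModel | None = None,
) -> PipelineResult:
    """Run tracking plus torque modelling on one recording.

    Muscle thickness is tracked with the fused boundary tracker, the angle
    and torque traces are resampled onto the ultrasound frame clock and
    low-pass filtered together with the thickness, then either a quadratic
    torque model is fitted (when ``torque`` ground truth is given and no
    ``model``) or an existing model is applied.  Metrics are computed
    whenever ground-truth torque is available.
    """
    window = DepthWindow(config.window_min_mm, config.window_max_mm)
    log.info("tracking: window=%s superficial=%.2f mm cutoff=%.2f Hz",
             window, config.superficial_depth_mm, config.fusion_cutoff_hz)
    thickness, idx = run_mbta(
        series,
        window,
        config.superficial_depth_mm,
        cutoff=config.fusion_cutoff_hz,
        box_depth_mm=config.box_depth_mm,
        box_time_s=config.box_time_s,
    )
    log.info("selected transducer %d", idx)

    frame_times = series.timestamps

    def sync(values: np.ndarray, frame_rate: float) -> np.ndarray:
        if values.size == series.n_frames:
            return np.asarray(values, float)
        t = np.arange(values.size) / frame_rate
        return resample_to(values, t, np.clip(frame_times, t[0], t[-1]))

    thickness = lowpass_zero_lag(thickness, config.lowpass_cutoff_hz, config.lowpass_order)
    columns = [thickness.thickness_mm]
    names = ["thickness_mm"]
    if angle is not None:
        a = sync(angle.angle_deg, angle.frame_rate)
        a = lowpass_zero_lag(a, config.lowpass_cutoff_hz, config.lowpass_order,
                             frame_rate=series.frame_rate)
        columns.append(a)
        names.append("angle_deg")
    inputs = np.column_stack(columns)

    truth = None
    if torque is not None:
        q = sync(torque.torque_nm, torque.frame_rate or series.frame_rate)
        q = lowpass_zero_lag(q, config.lowpass_cutoff_hz, config.lowpass_order,
                             frame_rate=series.frame_rate)
        truth = TorqueTrace(q, series.frame_rate)

    if model is None:
        if truth is None:
            raise ValueError(
                "no model given and no ground-truth torque to fit one; "
                "provide `model` or `torque`"
            )
        log.info("fitting quadratic model on inputs %s", names)
        model = fit_quadratic_model(inputs, truth.torque_nm, tuple(names))
    prediction = predict_torque(model, inputs, series.frame_rate)
    metrics = evaluate(prediction, truth) if truth is not None else None
    if metrics is not None:
        log.info("metrics: rmse=%.3f N·m nrmse=%.2f%% r2=%.4f",
                 metrics.rmse, metrics.nrmse_pct, metrics.r2)
    return PipelineResult(thickness, idx, model, prediction, metrics)
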