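"""Rigid-body reference torque for dumbbell elbow curls.

The forearm and hand are modelled as a rigid rod of mass m0 with uniformly
distributed mass, and the dumbbell as a point mass m at the distal end of
the rod, length L from the elbow.  With θ the angle between the forearm and
the line of gravity (0° = forearm hanging vertically), the elbow flexor
torque is

    T = (m0 g L / 2) sin θ + m g L sin θ + I α,

where α is the angular acceleration (second time derivative of θ, in
rad/s²) and the moment of inertia about the elbow is

    I = m0 (L/2)² + m L².
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass

from .kinematics import AngleTrace, lowpass_zero_lag
from .torque import TorqueTrace

__all__ = ["RigidBodyParams", "moment_of_inertia", "elbow_torque", "forearm_hand_mass"]

STANDARD_GRAVITY = 9.81


@dataclass(frozen=True)
class RigidBodyParams:
    """Masses (kg), elbow-to-hand-centre length L (m), and gravity (m/s²)."""

    m0: float
    m: float
    L: float
    g: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        if self.m0 < 0 or self.m < 0:
            raise ValueError("masses must be non-negative")
        if self.L <= 0 or self.g <= 0:
            raise ValueError("L and g must be positive")


def forearm_hand_mass(body_mass_kg: float, fraction: float) -> float:
    """Forearm+hand mass from body mass and a user-supplied anthropometric
    segment-mass fraction (table-dependent, hence not hardcoded)."""
    if body_mass_kg <= 0 or not 0 < fraction < 1:
        raise ValueError("body mass must be positive and fraction in (0, 1)")
    return body_mass_kg * fraction


def moment_of_inertia(params: RigidBodyParams) -> float:
    """I = m0 (L/2)² + m L², about the elbow axis."""
    return params.m0 * (params.L / 2.0) ** 2 + params.m * params.L**2


def elbow_torque(
    params: RigidBodyParams,
    theta: AngleTrace,
    prefilter_cutoff_hz: float | None = None,
) -> TorqueTrace:
    """Elbow flexor torque from the forearm angle trace.

    θ is converted to radians before differentiation; α uses centred finite
    differences with one-sided differences at the endpoints.  Pass
    ``prefilter_cutoff_hz`` (e.g. 5 Hz) to low-pass the angle first, which
    suppresses noise amplification in the second derivative on measured
    data; raw short traces (≥ 3 frames) are differentiated as-is.
    """
    if len(theta) < 3:
        raise ValueError("need at least 3 frames to compute angular acceleration")
    trace = theta
    if prefilter_cutoff_hz is not None:
        trace = lowpass_zero_lag(theta, prefilter_cutoff_hz)
    th = np.deg2rad(trace.angle_deg)
    dt = 1.0 / theta.frame_rate
    alpha = np.gradient(np.gradient(th, dt), dt)
    inertia = moment_of_inertia(params)
    gravity_arm = (params.m0 * params.g * params.L / 2.0) + params.m * params.g * params.L
    torque = gravity_arm * np.sin(th) + inertia * alpha
    return TorqueTrace(torque, theta.frame_rate)
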