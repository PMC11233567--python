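"""Joint-torque estimation from muscle thickness and joint kinematics.

A full second-order polynomial (intercept, linear, squared, and pairwise
interaction terms) maps d input channels — typically muscle thickness in mm
and one or more joint/segment angles in degrees — to joint torque in N·m.
The module also provides the supporting steps of a dynamometer workflow:
gravitational-torque correction (a sinusoid-of-angle model fitted on passive
trials), per-participant normalisation for generalized models, and the
RMSE / NRMSE / R² evaluation metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tracking import ThicknessTrace

__all__ = [
    "QuadraticTorqueModel",
    "TorqueTrace",
    "GravityModel",
    "Metrics",
    "quadratic_design",
    "fit_quadratic_model",
    "predict_torque",
    "fit_gravity_model",
    "correct_gravitational_torque",
    "evaluate",
    "normalize_participant",
]


@dataclass
class TorqueTrace:
    """Joint torque in N·m per frame."""

    torque_nm: np.ndarray
    frame_rate: float | None = None

    def __post_init__(self) -> None:
        self.torque_nm = np.asarray(self.torque_nm, dtype=float)
        if not np.all(np.isfinite(self.torque_nm)):
            raise ValueError("torque trace contains non-finite values")

    def __len__(self) -> int:
        return self.torque_nm.size


def quadratic_design(inputs: np.ndarray, input_names: tuple[str, ...]) -> tuple[np.ndarray, tuple[str, ...]]:
    """Design matrix of the full degree-2 polynomial basis.

    Column order: intercept, linear terms, pure squares, then pairwise
    products (i < j).  Total 1 + d + d + d(d-1)/2 columns.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != len(input_names):
        raise ValueError(
            f"inputs have {X.shape[1]} columns but {len(input_names)} names were given"
        )
    d = X.shape[1]
    cols = [np.ones(X.shape[0])]
    labels = ["1"]
    for i in range(d):
        cols.append(X[:, i])
        labels.append(input_names[i])
    for i in range(d):
        cols.append(X[:, i] ** 2)
        labels.append(f"{input_names[i]}^2")
    for i in range(d):
        for j in range(i + 1, d):
            cols.append(X[:, i] * X[:, j])
            labels.append(f"{input_names[i]}*{input_names[j]}")
    return np.column_stack(cols), tuple(labels)


@dataclass
class QuadraticTorqueModel:
    """Second-order polynomial torque model.

    ``coefficients`` follows the column order of :func:`quadratic_design`;
    ``term_labels`` names each coefficient.  ``n`` and ``residual_variance``
    record the fit size and the unbiased residual variance estimate.
    """

    input_names: tuple[str, ...]
    coefficients: np.ndarray
    term_labels: tuple[str, ...] = field(default=())
    n: int | None = None
    residual_variance: float | None = None

    def __post_init__(self) -> None:
        self.input_names = tuple(self.input_names)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        d = len(self.input_names)
        expected = 1 + 2 * d + d * (d - 1) // 2
        if self.coefficients.size != expected:
            raise ValueError(
                f"{d} inputs require {expected} coefficients, got {self.coefficients.size}"
            )
        if not self.term_labels:
            _, self.term_labels = quadratic_design(np.zeros((1, d)), self.input_names)

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(inputs, dtype=float))
        if X.shape[1] != len(self.input_names):
            raise ValueError(
                f"model expects {len(self.input_names)} input columns "
                f"({', '.join(self.input_names)}), got {X.shape[1]}"
            )
        design, _ = quadratic_design(X, self.input_names)
        return design @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "input_names": list(self.input_names),
            "term_labels": list(self.term_labels),
            "coefficients": self.coefficients.tolist(),
            "n": self.n,
            "residual_variance": self.residual_variance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticTorqueModel":
        return cls(
            input_names=tuple(d["input_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            term_labels=tuple(d.get("term_labels", ())),
            n=d.get("n"),
            residual_variance=d.get("residual_variance"),
        )


def fit_quadratic_model(
    inputs: np.ndarray,
    torque: np.ndarray,
    input_names: tuple[str, ...] | None = None,
) -> QuadraticTorqueModel:
    """Ordinary least squares on the full degree-2 polynomial basis.

    Rank-deficient designs are solved by the minimum-norm solution with a
    warning.  Raises if there are fewer observations than coefficients or
    any entry is non-finite.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(torque).size == X.shape[1]:
        X = X.T  # 1-D input vector given as a row
    y = np.asarray(torque, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("inputs and torque lengths differ")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("inputs contain non-finite entries")
    d = X.shape[1]
    if input_names is None:
        input_names = tuple(f"x{i}" for i in range(d))
    design, labels = quadratic_design(X, input_names)
    p = design.shape[1]
    if y.size <= p:
        raise ValueError(
            f"underdetermined fit: {y.size} observations for {p} coefficients"
        )
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < p:
        warnings.warn(
            f"rank-deficient design (rank {rank} < {p}); using the minimum-norm solution",
            stacklevel=2,
        )
    resid = y - design @ coef
    dof = y.size - rank
    residual_variance = float(resid @ resid / dof) if dof > 0 else float("nan")
    return QuadraticTorqueModel(
        input_names=input_names,
        coefficients=coef,
        term_labels=labels,
        n=int(y.size),
        residual_variance=residual_variance,
    )


def predict_torque(
    model: QuadraticTorqueModel,
    inputs: np.ndarray,
    frame_rate: float | None = None,
) -> TorqueTrace:
    """Evaluate the polynomial model pointwise on an input matrix."""
    return TorqueTrace(model.predict(inputs), frame_rate)


@dataclass
class GravityModel:
    """Gravitational torque as a sinusoid of joint angle:
    T_g(θ) = a1 sin θ + a2 cos θ + c0 (θ in degrees at the interface,
    radians inside the trigonometry).  Fitted on passive trials only."""

    a1: float
    a2: float
    c0: float

    def predict(self, angle_deg: np.ndarray) -> np.ndarray:
        th = np.deg2rad(np.asarray(angle_deg, dtype=float))
        return self.a1 * np.sin(th) + self.a2 * np.cos(th) + self.c0


def fit_gravity_model(passive_angle_deg: np.ndarray, passive_torque_nm: np.ndarray) -> GravityModel:
    """Least-squares fit of the sinusoidal gravity model on passive data."""
    angle = np.asarray(passive_angle_deg, dtype=float).ravel()
    torque = np.asarray(passive_torque_nm, dtype=float).ravel()
    if angle.size != torque.size:
        raise ValueError("angle and torque lengths differ")
    if np.unique(angle).size < 3:
        raise ValueError("degenerate fit: need at least 3 distinct angles")
    th = np.deg2rad(angle)
    design = np.column_stack([np.sin(th), np.cos(th), np.ones_like(th)])
    coef, *_ = np.linalg.lstsq(design, torque, rcond=None)
    return GravityModel(a1=float(coef[0]), a2=float(coef[1]), c0=float(coef[2]))


def correct_gravitational_torque(
    model: GravityModel,
    angle_deg: np.ndarray,
    torque_nm: np.ndarray,
    frame_rate: float | None = None,
) -> TorqueTrace:
    """Subtract the modelled gravitational torque, isolating biological torque."""
    angle = np.asarray(angle_deg, dtype=float)
    torque = np.asarray(torque_nm, dtype=float)
    if angle.shape != torque.shape:
        raise ValueError("angle and torque lengths differ")
    return TorqueTrace(torque - model.predict(angle), frame_rate)


@dataclass(frozen=True)
class Metrics:
    """Torque-estimation agreement metrics.

    ``nrmse_pct`` is the RMSE divided by the range of the ground truth,
    as a percentage.
    """

    rmse: float
    nrmse_pct: float
    r2: float


def evaluate(pred, truth) -> Metrics:
    """RMSE, NRMSE (% of ground-truth range), and R² of an estimate."""
    p = np.asarray(getattr(pred, "torque_nm", pred), dtype=float).ravel()
    t = np.asarray(getattr(truth, "torque_nm", truth), dtype=float).ravel()
    if p.size != t.size:
        raise ValueError("prediction and truth lengths differ")
    if p.size == 0:
        raise ValueError("empty traces")
    rmse = float(np.sqrt(np.mean((p - t) ** 2)))
    rng = float(np.ptp(t))
    if rng == 0.0:
        raise ValueError("constant ground truth: NRMSE and R² are undefined")
    ss_res = float(np.sum((t - p) ** 2))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    return Metrics(rmse=rmse, nrmse_pct=100.0 * rmse / rng, r2=1.0 - ss_res / ss_tot)


def normalize_participant(
    thickness: ThicknessTrace, torque: TorqueTrace
) -> tuple[ThicknessTrace, TorqueTrace]:
    """Divide thickness and torque by their own maxima (for generalized
    models pooling participants of different muscle size and strength)."""
    t_max = float(np.max(thickness.thickness_mm))
    q_max = float(np.max(torque.torque_nm))
    if t_max <= 0.0 or q_max <= 0.0:
        raise ValueError("normalisation requires positive maxima")
    norm_thick = ThicknessTrace(
        thickness.thickness_mm / t_max,
        thickness.frame_rate,
        thickness.superficial_depth_mm,
    )
    return norm_thick, TorqueTrace(torque.torque_nm / q_max, torque.frame_rate)
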