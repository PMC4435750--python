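"""Conditioning of time-course data for linear-ODE identification.

The rate-equation model dX/dt = A X(t) (+ B u(t)) is identified as a linear
regression. Two equivalent data layouts are produced here:

``gradient`` mode
    response = finite-difference estimates of dX/dt, design = X itself.
``integral`` mode
    the ODE integrated from t_0 to t_f: response row f = X(t_f) - X(t_0),
    design row f = trapezoidal cumulative integral of X — the
    finite-difference form used by the integral variant of time-series
    network identification, which is more robust to noise because
    integration smooths rather than amplifies it.

Log transformation, per-node z-scoring and first-order-hold interpolation
are provided as the standard pre-processing steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .simulate import TimeCourse

__all__ = [
    "RegressionData",
    "normalize",
    "first_order_hold",
    "estimate_rates",
    "cumulative_integrals",
    "build_regression_data",
]

LOG_OFFSET = 1e-6  # guards against exact zeros left by noise clamping


@dataclass
class RegressionData:
    """Paired response/design matrices for per-node linear regression."""

    response: np.ndarray
    design: np.ndarray
    times: np.ndarray
    mode: str  # "gradient" or "integral"
    perturbation_design: np.ndarray | None = None
    node_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.response = np.asarray(self.response, dtype=float)
        self.design = np.asarray(self.design, dtype=float)
        if self.response.shape[0] != self.design.shape[0]:
            raise ValueError("response and design must share row count")
        if self.mode not in ("gradient", "integral"):
            raise ValueError("mode must be 'gradient' or 'integral'")

    @property
    def n_nodes(self) -> int:
        return self.design.shape[1]


def normalize(tc: TimeCourse, log_transform: bool = False,
              zscore: bool = True, offset: float = LOG_OFFSET) -> TimeCourse:
    """Log-transform and/or z-score a course per node.

    The log is ln(x + offset). Z-scoring maps each node column to mean 0 and
    unit sd; a constant column maps to all zeros rather than dividing by 0.
    """
    out = tc.copy()
    x = out.states
    if log_transform:
        if np.any(x + offset <= 0):
            raise ValueError("log transform requires states > -offset")
        x = np.log(x + offset)
    if zscore:
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        safe = np.where(sd > 0, sd, 1.0)
        x = np.where(sd > 0, (x - mu) / safe, 0.0)
    out.states = x
    return out


def first_order_hold(tc: TimeCourse, query_times: np.ndarray) -> TimeCourse:
    """Piecewise-linear interpolation of every node at the query times."""
    q = np.asarray(query_times, dtype=float)
    if np.any(np.diff(q) <= 0):
        raise ValueError("query_times must be strictly increasing")
    if q.min() < tc.times[0] or q.max() > tc.times[-1]:
        raise ValueError("query_times outside the sampled range (no extrapolation)")
    states = np.column_stack(
        [np.interp(q, tc.times, tc.states[:, j]) for j in range(tc.n_nodes)]
    )
    out = tc.copy()
    out.times = q
    out.states = states
    out.perturbation = None if tc.perturbation is None else np.column_stack(
        [np.interp(q, tc.times, tc.perturbation[:, j])
         for j in range(tc.perturbation.shape[1])]
    )
    return out


def estimate_rates(tc: TimeCourse) -> RegressionData:
    """Finite-difference derivative estimates aligned with the states.

    Central (three-point Lagrange, exact for quadratics on uneven grids)
    differences at interior points, one-sided at the ends — numpy's
    ``gradient`` with explicit sample times.
    """
    if tc.n_points < 3:
        raise ValueError("rate estimation requires at least 3 time points")
    rates = np.gradient(tc.states, tc.times, axis=0)
    return RegressionData(
        response=rates,
        design=tc.states.copy(),
        times=tc.times.copy(),
        mode="gradient",
        perturbation_design=None if tc.perturbation is None else tc.perturbation.copy(),
        node_labels=list(tc.node_labels),
    )


def cumulative_integrals(tc: TimeCourse) -> RegressionData:
    """State increments paired with trapezoidal cumulative integrals.

    Row f (f = 1..m-1) of the response is X(t_f) - X(t_0); the matching
    design row is the trapezoid-rule integral of X over [t_0, t_f]. The
    all-zero f = 0 row is dropped. A perturbation trace, when present, is
    integrated the same way.
    """
    if tc.n_points < 2:
        raise ValueError("integral form requires at least 2 time points")
    increments = tc.states[1:] - tc.states[0]
    integrals = cumulative_trapezoid(tc.states, tc.times, axis=0)
    pert = None
    if tc.perturbation is not None:
        pert = cumulative_trapezoid(tc.perturbation, tc.times, axis=0)
    return RegressionData(
        response=increments,
        design=integrals,
        times=tc.times[1:].copy(),
        mode="integral",
        perturbation_design=pert,
        node_labels=list(tc.node_labels),
    )


def build_regression_data(
    courses: list[TimeCourse] | TimeCourse,
    mode: str = "gradient",
    log_transform: bool = False,
    zscore: bool = False,
) -> RegressionData:
    """Normalize and stack one or more courses into a single RegressionData.

    Courses are processed independently (the integral response resets at
    each course's own t_0, since initial conditions are independent) and
    row-concatenated.
    """
    if isinstance(courses, TimeCourse):
        courses = [courses]
    if not courses:
        raise ValueError("at least one course is required")
    parts = []
    for tc in courses:
        tc = normalize(tc, log_transform=log_transform, zscore=zscore)
        if mode == "gradient":
            parts.append(estimate_rates(tc))
        elif mode == "integral":
            parts.append(cumulative_integrals(tc))
        else:
            raise ValueError("mode must be 'gradient' or 'integral'")
    pert = None
    if all(p.perturbation_design is not None for p in parts):
        pert = np.vstack([p.perturbation_design for p in parts])
    return RegressionData(
        response=np.vstack([p.response for p in parts]),
        design=np.vstack([p.design for p in parts]),
        times=np.concatenate([p.times for p in parts]),
        mode=mode,
        perturbation_design=pert,
        node_labels=parts[0].node_labels,
    )
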