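"""Model / Results interface over the inference routes.

`TimeCourseNetworkModel` is constructed from one or more time courses (or a
tidy DataFrame) and `fit(method=...)` dispatches to the linear-ODE routes
(stepwise truncation, PLS projection with either latent-count rule, or the
integral finite-difference form) or to the time-delay information-theoretic
route. The returned `NetworkFitResults` carries the continuous weight
matrix, exposes quantile pruning to a signed network, direction-only
evaluation against a reference, and a text summary.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import ode
from .consensus import EvaluationResult, evaluate
from .networks import SignedNetwork
from .preprocess import build_regression_data
from .simulate import TimeCourse
from .tdaracne import TDParams, infer_tdaracne

__all__ = ["TimeCourseNetworkModel", "NetworkFitResults"]

_ODE_METHODS = {
    "stepwise": ode.infer_stepwise,
    "broken_stick": ode.infer_projection,
    "bartlett": ode.infer_projection,
    "tsni_integral": ode.infer_tsni_integral,
}


class TimeCourseNetworkModel:
    """Directed-network identification model for time-course data.

    Parameters
    ----------
    courses : TimeCourse or list of TimeCourse
        The observed trajectories. Multiple courses are stacked row-wise
        for the regression routes (each keeps its own initial condition).
    log_transform, zscore : bool
        Standard pre-processing applied per course before building the
        regression matrices. Defaults keep the data untouched so that
        weights stay on the scale of the generating system.
    """

    def __init__(
        self,
        courses: TimeCourse | list[TimeCourse],
        log_transform: bool = False,
        zscore: bool = False,
    ):
        self.courses = [courses] if isinstance(courses, TimeCourse) else list(courses)
        if not self.courses:
            raise ValueError("at least one time course is required")
        self.log_transform = log_transform
        self.zscore = zscore
        self.node_labels = list(self.courses[0].node_labels)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time",
                       course_col: str | None = None, **kwargs
                       ) -> "TimeCourseNetworkModel":
        """Build from a tidy frame with a time column (and optional course id)."""
        groups = [df] if course_col is None else [g for _, g in df.groupby(course_col)]
        courses = []
        for g in groups:
            labels = [c for c in g.columns if c not in (time_col, course_col)]
            courses.append(TimeCourse(
                times=g[time_col].to_numpy(),
                states=g[labels].to_numpy(),
                node_labels=labels,
            ))
        return cls(courses, **kwargs)

    def fit(
        self,
        method: str = "broken_stick",
        params: ode.InferenceParams | None = None,
        td_params: TDParams | None = None,
        seed: int = 0,
    ) -> "NetworkFitResults":
        """Fit the requested inference route and return a results object.

        ``method`` is one of "stepwise", "broken_stick", "bartlett",
        "tsni_integral" or "tdaracne". The first four consume the stacked
        regression data (gradient form, or integral form for the TSNI
        route); the last operates on the first time course directly.
        """
        if method == "tdaracne":
            net = infer_tdaracne(self.courses[0], td_params, seed=seed)
            weights = ode.WeightedAdjacency(
                net.adjacency.astype(float), method_tag="tdaracne",
                node_labels=self.node_labels,
            )
            return NetworkFitResults(self, weights, method)
        if method not in _ODE_METHODS:
            raise ValueError(f"unknown method {method!r}")
        params = params or ode.InferenceParams()
        if method in ("broken_stick", "bartlett"):
            params = replace(params, lv_rule=method)
        mode = "integral" if method == "tsni_integral" else "gradient"
        data = build_regression_data(
            self.courses, mode=mode,
            log_transform=self.log_transform, zscore=self.zscore,
        )
        weights = _ODE_METHODS[method](data, params)
        return NetworkFitResults(self, weights, method)


class NetworkFitResults:
    """Inference output: continuous weights plus pruning/evaluation helpers."""

    def __init__(self, model: TimeCourseNetworkModel,
                 weights: ode.WeightedAdjacency, method: str):
        self.model = model
        self.weights = weights
        self.method = method
        self.params_used = weights.params_used

    def network(self, quantile_q: float | None = None) -> SignedNetwork:
        """Signed network after quantile pruning (default: fitted q)."""
        if quantile_q is None:
            quantile_q = self.params_used.quantile_q if self.params_used else 0.0
        return ode.quantile_prune(self.weights, quantile_q)

    def evaluate(self, reference: SignedNetwork,
                 quantile_q: float | None = None,
                 ignore_diagonal: bool = True) -> EvaluationResult:
        return evaluate(self.network(quantile_q), reference, ignore_diagonal)

    def summary(self) -> str:
        net = self.network()
        w = self.weights.weights
        lines = [
            "Time-course network inference results",
            "=" * 46,
            f"method:            {self.method}",
            f"nodes:             {w.shape[0]}",
            f"courses:           {len(self.model.courses)}",
            f"edges after prune: {net.n_edges}",
            f"weight range:      [{w.min():+.4f}, {w.max():+.4f}]",
            "-" * 46,
            "edges (source -> target, sign, weight):",
        ]
        labels = self.weights.node_labels
        for s, t, sign in net.edges():
            lines.append(
                f"  {labels[s]:>6} -> {labels[t]:<6} {'+' if sign > 0 else '-'}"
                f"  {w[t, s]:+.4f}"
            )
        return "\n".join(lines)

    def plot_weights(self, ax=None):
        """Heatmap of the inferred weight matrix (regulators on columns)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        vmax = np.abs(self.weights.weights).max() or 1.0
        im = ax.imshow(self.weights.weights, cmap="RdBu_r", vmin=-vmax, vmax=vmax)
        ax.set_xlabel("regulator j")
        ax.set_ylabel("target i")
        ax.figure.colorbar(im, ax=ax, label="inferred weight")
        return ax
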