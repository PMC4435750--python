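"""Constrained simulated-annealing tuning of inference parameters.

Inference performance depends strongly on its thresholds (entry/removal
p-values, VIP cut, edge-weight quantile, sparsity cap), and good values
shift with network size, noise and sampling. Parameters are therefore tuned
per problem scenario: a bounded box is searched by simulated annealing with
one-parameter-at-a-time Gaussian proposals, maximizing the median (or mean)
F score over a set of training scenarios, where each scenario is scored by
per-course inference followed by quorum consensus at the F-optimal
threshold. The tuned objective is optimistic when training and evaluation
share scenarios; a held-out evaluation helper is provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .consensus import optimize_quorum
from .model import TimeCourseNetworkModel
from .networks import SignedNetwork
from .ode import InferenceParams
from .simulate import TimeCourse

__all__ = ["TuningSpec", "Scenario", "tune", "score_scenarios"]

# search box per tunable parameter: (low, high, proposal sd, integer?)
DEFAULT_BOUNDS: dict[str, tuple[float, float, float, bool]] = {
    "p_enter": (1e-4, 0.30, 0.05, False),
    "p_remove": (0.05, 0.60, 0.08, False),
    "vip_threshold": (0.0, 2.0, 0.25, False),
    "quantile_q": (0.0, 0.95, 0.12, False),
    "max_regressors": (1, 10, 2, True),
}


@dataclass
class Scenario:
    """One training unit: a dataset of courses plus its reference network."""

    courses: list[TimeCourse]
    reference: SignedNetwork


@dataclass
class TuningSpec:
    """Search space and annealing schedule.

    The schedule defaults (T0 = 1, geometric cooling 0.95, 200 iterations)
    favour thoroughness at desk scale; reduce ``n_iterations`` for quick
    exploratory runs.
    """

    bounds: dict[str, tuple[float, float, float, bool]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    objective: str = "median_f"
    initial_temperature: float = 1.0
    cooling: float = 0.95
    n_iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in ("median_f", "mean_f"):
            raise ValueError("objective must be 'median_f' or 'mean_f'")
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")


def _scenario_f(method: str, scenario: Scenario, params: InferenceParams) -> float:
    nets = [
        TimeCourseNetworkModel(tc).fit(method, params=params).network()
        for tc in scenario.courses
    ]
    _, _, res = optimize_quorum(nets, scenario.reference)
    return res.f_score


def score_scenarios(method: str, scenarios: list[Scenario],
                    params: InferenceParams, objective: str = "median_f") -> float:
    """Aggregate consensus F over scenarios (median or mean)."""
    scores = [_scenario_f(method, s, params) for s in scenarios]
    return float(np.median(scores) if objective == "median_f" else np.mean(scores))


def _clamp_params(params: InferenceParams,
                  bounds: dict[str, tuple[float, float, float, bool]],
                  override: dict[str, float] | None = None) -> InferenceParams:
    """Project (optionally perturbed) parameters back into the search box."""
    values = {}
    for name, (lo, hi, _, is_int) in bounds.items():
        v = (override or {}).get(name, getattr(params, name))
        if v is None:
            continue
        v = min(max(v, lo), hi)
        values[name] = int(round(v)) if is_int else float(v)
    # keep the stepwise invariant p_enter < p_remove
    pe = values.get("p_enter", params.p_enter)
    pr = values.get("p_remove", params.p_remove)
    if pe >= pr:
        values["p_remove"] = min(pe + 0.05, 0.99)
    return replace(params, **values)


def tune(
    method: str,
    training_scenarios: list[Scenario],
    spec: TuningSpec | None = None,
    start: InferenceParams | None = None,
) -> tuple[InferenceParams, float, pd.DataFrame]:
    """Simulated annealing over the bounded parameter box.

    One randomly chosen parameter is perturbed per iteration (Gaussian step,
    clamped to its bounds); proposals are accepted when they improve the
    objective or with Metropolis probability exp(delta / T) under the
    geometric cooling schedule. Returns the best-so-far parameters, their
    objective, and the full trace. Deterministic given ``spec.seed``.
    """
    if not training_scenarios:
        raise ValueError("at least one training scenario is required")
    spec = spec or TuningSpec()
    rng = np.random.default_rng(spec.seed)
    names = list(spec.bounds)

    current = _clamp_params(start or InferenceParams(), spec.bounds)
    current_obj = score_scenarios(method, training_scenarios, current, spec.objective)
    best, best_obj = current, current_obj
    temperature = spec.initial_temperature

    rows = [{"iteration": 0, "parameter": None, "objective": current_obj,
             "accepted": True, "best_objective": best_obj,
             "temperature": temperature}]
    for it in range(1, spec.n_iterations + 1):
        name = names[int(rng.integers(len(names)))]
        lo, hi, step, is_int = spec.bounds[name]
        value = getattr(current, name)
        if value is None:  # e.g. unlimited max_regressors: start mid-box
            value = (lo + hi) / 2.0
        proposal_value = value + rng.normal(0.0, step)
        proposal = _clamp_params(current, spec.bounds, {name: proposal_value})
        obj = score_scenarios(method, training_scenarios, proposal, spec.objective)
        delta = obj - current_obj
        accepted = delta >= 0 or rng.random() < np.exp(delta / temperature)
        if accepted:
            current, current_obj = proposal, obj
            if obj > best_obj:
                best, best_obj = proposal, obj
        temperature *= spec.cooling
        rows.append({"iteration": it, "parameter": name, "objective": obj,
                     "accepted": bool(accepted), "best_objective": best_obj,
                     "temperature": temperature})
    return best, best_obj, pd.DataFrame(rows)


def save_tuning_result(path, params: InferenceParams, objective: float,
                       spec: TuningSpec) -> None:
    payload = {
        "best_params": {k: getattr(params, k) for k in (
            "p_enter", "p_remove", "lv_rule", "bartlett_alpha",
            "vip_threshold", "quantile_q", "max_regressors", "include_self")},
        "best_objective": objective,
        "objective": spec.objective,
        "seed": spec.seed,
        "n_iterations": spec.n_iterations,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
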