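"""Fuzzy-logic time-course simulator with subsampling and noise injection.

Expression trajectories are generated on a normalized [0, 1] scale by a
discrete-time update in which each node moves incrementally toward a target
state resolved from its regulators by fuzzy logic: activators are combined
with fuzzy OR (max), inhibitors with fuzzy NOT of fuzzy OR, and the two are
combined multiplicatively. The incremental move is modulated by a sigmoid of
the distance to target and weighted by a per-node time constant capturing
synthesis/degradation kinetics, drawn once per node from a Gaussian.

This deliberately differs in model class from the linear-ODE and
information-theoretic inference engines applied to it, so recovery is never
a same-model exercise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import SignedNetwork

__all__ = [
    "TimeCourse",
    "DynamicsParams",
    "simulate_time_course",
    "sample_time_points",
    "add_noise",
    "generate_dataset",
    "write_time_course",
    "read_time_course",
    "write_dataset",
]


@dataclass
class TimeCourse:
    """A sampled trajectory: strictly increasing times and an m×n state matrix."""

    times: np.ndarray
    states: np.ndarray
    perturbation: np.ndarray | None = None
    noise_fraction: float = 0.0
    network_id: str = ""
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be a 1-D vector")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.ndim != 2 or self.states.shape[0] != self.times.size:
            raise ValueError("states must be m×n with m == len(times)")
        if self.perturbation is not None:
            self.perturbation = np.asarray(self.perturbation, dtype=float)
            if self.perturbation.shape[0] != self.times.size:
                raise ValueError("perturbation rows must match times length")
        if not self.node_labels:
            self.node_labels = [f"g{i + 1}" for i in range(self.states.shape[1])]

    @property
    def n_points(self) -> int:
        return self.times.size

    @property
    def n_nodes(self) -> int:
        return self.states.shape[1]

    def copy(self) -> "TimeCourse":
        return replace(
            self,
            times=self.times.copy(),
            states=self.states.copy(),
            perturbation=None if self.perturbation is None else self.perturbation.copy(),
            node_labels=list(self.node_labels),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=self.node_labels)
        df.insert(0, "time", self.times)
        return df


@dataclass
class DynamicsParams:
    """Kinetic parameters of the fuzzy-logic simulator.

    tau_mean, tau_sd
        Mean and spread of the per-node time constant (time units); each
        node's tau is drawn once from Normal(tau_mean, tau_sd), truncated
        below at tau_mean/10 so no node becomes unphysically fast.
    sigmoid_gain
        Steepness of the logistic modulation of the step toward the target.
    basal_level
        Baseline drive; a node with no activators relaxes toward
        0.5 * basal_level.
    dt, n_steps
        Internal Euler step and number of simulated points.
    """

    tau_mean: float = 5.0
    tau_sd: float = 1.0
    sigmoid_gain: float = 10.0
    basal_level: float = 0.5
    dt: float = 0.1
    n_steps: int = 500

    def __post_init__(self) -> None:
        for name in ("tau_mean", "tau_sd", "sigmoid_gain", "basal_level", "dt"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.tau_mean <= 0 or self.dt <= 0:
            raise ValueError("tau_mean and dt must be positive")
        if self.tau_sd < 0:
            raise ValueError("tau_sd must be non-negative")
        if not 0 <= self.basal_level <= 1:
            raise ValueError("basal_level must be in [0, 1]")
        if self.n_steps < 2:
            raise ValueError("n_steps must be at least 2")


def _fuzzy_target(x: np.ndarray, activators: list[np.ndarray],
                  inhibitors: list[np.ndarray], basal: float) -> np.ndarray:
    n = x.size
    target = np.empty(n)
    for i in range(n):
        act = x[activators[i]].max() if activators[i].size else 0.5 * basal
        inh = 1.0 - x[inhibitors[i]].max() if inhibitors[i].size else 1.0
        target[i] = act * inh
    return np.clip(target, 0.0, 1.0)


def simulate_time_course(
    network: SignedNetwork, params: DynamicsParams, seed: int = 0
) -> TimeCourse:
    """Simulate a noise-free trajectory of ``params.n_steps`` points.

    Initial states are uniform on [0, 1]; per-node time constants are drawn
    from the truncated Gaussian described in :class:`DynamicsParams`. The
    update for node i with target T_i is

        x_i <- x_i + (dt / tau_i) * (sigmoid(gain * (T_i - x_i)) - 0.5) * 2 * |T_i - x_i|

    which moves x_i monotonically toward T_i (the signed logistic factor has
    the sign of T_i - x_i and magnitude <= 1, and dt/tau_i <= 1 by the
    truncation), so states remain in [0, 1].
    """
    rng = np.random.default_rng(seed)
    n = network.n_nodes
    adj = network.adjacency
    activators = [np.flatnonzero(adj[i] > 0) for i in range(n)]
    inhibitors = [np.flatnonzero(adj[i] < 0) for i in range(n)]

    tau = rng.normal(params.tau_mean, params.tau_sd, size=n)
    tau = np.maximum(tau, params.tau_mean / 10.0)
    x = rng.uniform(0.0, 1.0, size=n)

    states = np.empty((params.n_steps, n))
    states[0] = x
    for step in range(1, params.n_steps):
        target = _fuzzy_target(x, activators, inhibitors, params.basal_level)
        delta = target - x
        drive = 2.0 * (1.0 / (1.0 + np.exp(-params.sigmoid_gain * delta)) - 0.5)
        x = x + (params.dt / tau) * drive * np.abs(delta)
        states[step] = x
    times = np.arange(params.n_steps) * params.dt
    return TimeCourse(times=times, states=states)


def sample_time_points(tc: TimeCourse, m: int) -> TimeCourse:
    """Restrict a course to m indices evenly spaced between its endpoints."""
    if m < 2:
        raise ValueError("at least 2 time points are required")
    if m > tc.n_points:
        raise ValueError("m exceeds available time points")
    idx = np.unique(np.round(np.linspace(0, tc.n_points - 1, m)).astype(int))
    out = tc.copy()
    out.times = tc.times[idx]
    out.states = tc.states[idx]
    if tc.perturbation is not None:
        out.perturbation = tc.perturbation[idx]
    return out


def add_noise(
    tc: TimeCourse,
    fraction: float,
    seed: int = 0,
    reference: str = "per_node_sd",
) -> TimeCourse:
    """Add zero-mean Gaussian noise scaled to each node's signal.

    With ``reference="per_node_sd"`` (default) the noise sd for node i is
    ``fraction`` times the standard deviation of that node's noise-free
    trajectory; with ``"range"`` it is ``fraction`` times the node's dynamic
    range. Noisy states are clamped below at 0 (expression cannot be
    negative). ``fraction=0`` returns a bit-identical copy.
    """
    if fraction < 0:
        raise ValueError("noise fraction must be non-negative")
    out = tc.copy()
    out.noise_fraction = float(fraction)
    if fraction == 0:
        return out
    if reference == "per_node_sd":
        scale = tc.states.std(axis=0, ddof=0)
    elif reference == "range":
        scale = tc.states.max(axis=0) - tc.states.min(axis=0)
    else:
        raise ValueError("reference must be 'per_node_sd' or 'range'")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, 1.0, size=tc.states.shape) * (fraction * scale)
    out.states = np.maximum(tc.states + eps, 0.0)
    return out


def generate_dataset(
    network: SignedNetwork,
    n_courses: int,
    m: int,
    noise: float,
    params: DynamicsParams | None = None,
    seed: int = 0,
    network_id: str = "",
) -> list[TimeCourse]:
    """Simulate, subsample and perturb n_courses independent trajectories.

    Each course gets an independent child seed spawned from the master seed,
    so a dataset is reproducible from (network, seed) alone. Courses differ
    in their random initial states and time constants but share the network.
    """
    if n_courses < 1:
        raise ValueError("n_courses must be positive")
    params = params or DynamicsParams()
    child_seeds = np.random.SeedSequence(seed).generate_state(2 * n_courses)
    courses = []
    for c in range(n_courses):
        tc = simulate_time_course(network, params, seed=int(child_seeds[2 * c]))
        tc = sample_time_points(tc, m)
        tc = add_noise(tc, noise, seed=int(child_seeds[2 * c + 1]))
        tc.network_id = network_id
        tc.node_labels = list(network.node_labels)
        courses.append(tc)
    return courses


# ---------------------------------------------------------------------------
# CSV I/O: first column `time`, one column per node; manifest JSON per dataset.

def write_time_course(tc: TimeCourse, path) -> None:
    tc.to_frame().to_csv(path, index=False)


def read_time_course(path, network_id: str = "") -> TimeCourse:
    df = pd.read_csv(path)
    labels = [c for c in df.columns if c != "time"]
    return TimeCourse(
        times=df["time"].to_numpy(),
        states=df[labels].to_numpy(),
        network_id=network_id,
        node_labels=labels,
    )


def write_dataset(courses: list[TimeCourse], directory, seed: int | None = None,
                  network_file: str | None = None) -> Path:
    """Write one CSV per course plus a manifest JSON; returns manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for k, tc in enumerate(courses):
        name = f"course_{k:03d}.csv"
        write_time_course(tc, directory / name)
        files.append(name)
    manifest = {
        "files": files,
        "seed": seed,
        "network_file": network_file,
        "noise_fraction": courses[0].noise_fraction if courses else None,
    }
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
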