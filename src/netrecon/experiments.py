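"""Scenario runner reproducing the benchmark's experiment designs.

A scenario bundles everything needed to reproduce one experiment: how many
networks to draw and at what size/density, how many courses per network,
sampling depth, noise level, the inference methods to compare, and the
master seed. Running it generates the networks and data, infers one network
per course per method, aggregates per-network inferences by F-optimal
quorum consensus, and emits a long-format results table with one row per
(network, method, course) plus one consensus row per (network, method).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from .consensus import evaluate, optimize_quorum
from .model import TimeCourseNetworkModel
from .networks import edge_count_for_density, generate_network
from .ode import InferenceParams
from .simulate import DynamicsParams, generate_dataset
from .tdaracne import TDParams

logger = logging.getLogger("netrecon")

__all__ = ["ScenarioConfig", "run_scenario", "summarize", "PRESETS"]

_VALID_METHODS = ("stepwise", "broken_stick", "bartlett", "tsni_integral", "tdaracne")


@dataclass
class ScenarioConfig:
    """Full experiment descriptor; every run is reproducible from it."""

    n_nodes: int
    n_networks: int = 1
    n_edges: int | None = None
    density: float | None = None
    density_range: tuple[float, float] | None = None
    n_courses: int = 1
    n_timepoints: int = 10
    noise_fraction: float = 0.0
    methods: tuple[str, ...] = ("broken_stick",)
    params: InferenceParams = field(default_factory=InferenceParams)
    td_params: TDParams = field(default_factory=TDParams)
    dynamics: DynamicsParams = field(default_factory=DynamicsParams)
    n_modules: int = 3
    p_inhibition: float = 0.3
    master_seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        problems = []
        if self.n_nodes < 2:
            problems.append("n_nodes: must be at least 2")
        if self.n_networks < 1:
            problems.append("n_networks: must be positive")
        spec_count = sum(
            x is not None for x in (self.n_edges, self.density, self.density_range)
        )
        if spec_count != 1:
            problems.append(
                "n_edges/density/density_range: exactly one must be given"
            )
        if self.n_courses < 1:
            problems.append("n_courses: must be positive")
        if self.n_timepoints < 2:
            problems.append("n_timepoints: must be at least 2")
        if self.noise_fraction < 0:
            problems.append("noise_fraction: must be non-negative")
        bad = [m for m in self.methods if m not in _VALID_METHODS]
        if bad:
            problems.append(f"methods: unknown {bad}; valid are {_VALID_METHODS}")
        if problems:
            raise ValueError("invalid scenario config: " + "; ".join(problems))

    def to_yaml(self, path) -> None:
        payload = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if hasattr(v, "__dataclass_fields__"):
                v = {k: getattr(v, k) for k in v.__dataclass_fields__}
            elif isinstance(v, tuple):
                v = list(v)
            payload[f.name] = v
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        for key, klass in (("params", InferenceParams), ("td_params", TDParams),
                           ("dynamics", DynamicsParams)):
            if key in payload and isinstance(payload[key], dict):
                payload[key] = klass(**payload[key])
        for key in ("methods", "density_range"):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        return cls(**payload)


def _edge_count(config: ScenarioConfig, rng: np.random.Generator) -> int:
    if config.n_edges is not None:
        return config.n_edges
    if config.density is not None:
        return edge_count_for_density(config.n_nodes, config.density)
    lo, hi = config.density_range
    return edge_count_for_density(config.n_nodes, float(rng.uniform(lo, hi)))


def run_scenario(config: ScenarioConfig) -> pd.DataFrame:
    """Execute a scenario and return the long-format results table.

    Per-course rows carry ``group_size = 1``; consensus rows carry the full
    group size and the F-optimal quorum that produced them.
    """
    config.validate()
    seeds = np.random.SeedSequence(config.master_seed)
    rng = np.random.default_rng(seeds.spawn(1)[0])
    net_seeds = seeds.generate_state(2 * config.n_networks)

    rows = []
    for nid in range(config.n_networks):
        n_edges = _edge_count(config, rng)
        network = generate_network(
            config.n_nodes, n_edges, n_modules=min(config.n_modules, config.n_nodes),
            p_inhibition=config.p_inhibition, seed=int(net_seeds[2 * nid]),
        )
        courses = generate_dataset(
            network, config.n_courses, config.n_timepoints,
            config.noise_fraction, config.dynamics,
            seed=int(net_seeds[2 * nid + 1]), network_id=f"net{nid}",
        )
        logger.info(
            "network %d: %d nodes, %d edges, %d courses (seed %d)",
            nid, config.n_nodes, n_edges, config.n_courses, net_seeds[2 * nid],
        )
        for method in config.methods:
            nets = []
            for cid, tc in enumerate(courses):
                result = TimeCourseNetworkModel(tc).fit(
                    method, params=config.params, td_params=config.td_params,
                    seed=int(net_seeds[2 * nid + 1]) + cid,
                )
                inferred = result.network()
                nets.append(inferred)
                res = evaluate(inferred, network)
                rows.append(_row(nid, method, cid, "course", 1,
                                 config, res, quorum=None))
            k, _, cres = optimize_quorum(nets, network)
            rows.append(_row(nid, method, None, "consensus",
                             len(nets), config, cres, quorum=k))
    return pd.DataFrame(rows)


def _row(nid, method, cid, kind, group_size, config, res, quorum):
    return {
        "network_id": f"net{nid}",
        "method": method,
        "course_id": cid,
        "kind": kind,
        "group_size": group_size,
        "timepoints": config.n_timepoints,
        "noise": config.noise_fraction,
        "quorum": quorum,
        "tp": res.tp,
        "fp": res.fp,
        "fn": res.fn,
        "ppv": res.ppv,
        "recall": res.recall,
        "f": res.f_score,
    }


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Median PPV/recall/F per method and row kind, recomputed from the table."""
    return (
        table.groupby(["method", "kind"])[["ppv", "recall", "f"]]
        .median()
        .reset_index()
    )


# Scenario presets mirroring the benchmark's experiment designs.
PRESETS: dict[str, ScenarioConfig] = {
    # 20 different sparse modular 10-node networks, single course each
    "single_course_20nets": ScenarioConfig(
        n_nodes=10, n_networks=20, density_range=(0.10, 0.20), n_courses=1,
        n_timepoints=50, noise_fraction=0.2,
        methods=("stepwise", "broken_stick", "bartlett", "tsni_integral"),
    ),
    # scaling ladder: 5..50 nodes at decreasing density
    "scaling_ladder": ScenarioConfig(
        n_nodes=5, n_networks=1, density=0.40, n_courses=20, n_timepoints=50,
        noise_fraction=0.2, methods=("broken_stick", "bartlett", "tsni_integral"),
    ),
    # group-size / sampling-frequency sweeps on 10-node networks
    "group_sweep": ScenarioConfig(
        n_nodes=10, n_networks=10, density_range=(0.10, 0.20), n_courses=20,
        n_timepoints=50, noise_fraction=0.2,
        methods=("broken_stick", "bartlett", "tsni_integral"),
    ),
}

SCALING_LADDER = ((5, 0.40), (10, 0.21), (15, 0.11), (20, 0.08),
                  (30, 0.05), (50, 0.03))
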