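"""Quorum consensus across inferred networks and direction-only scoring.

Networks inferred from individual time courses are aggregated edge-wise: an
edge enters the consensus when it appears in at least k of the M input
networks, with the quorum k either fixed or chosen by scanning k = 1..M for
the maximum F score against a reference. Scoring is direction-only
(an edge counts as recovered when source and target match, regardless of
sign), the convention used throughout this benchmark:

    PPV    = TP / (TP + FP)        over inferred edges,
    recall = TP / (TP + FN)        over reference edges,
    F      = 2 * PPV * recall / (PPV + recall).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .networks import SignedNetwork

__all__ = ["EvaluationResult", "evaluate", "quorum_consensus", "optimize_quorum"]


@dataclass
class EvaluationResult:
    tp: int
    fp: int
    fn: int
    ppv: float
    recall: float
    f_score: float
    compared_edges: str = "directed, sign-ignored, diagonal excluded"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _edge_mask(network: SignedNetwork, ignore_diagonal: bool) -> np.ndarray:
    mask = network.adjacency != 0
    if ignore_diagonal:
        np.fill_diagonal(mask, False)
    return mask


def evaluate(
    inferred: SignedNetwork,
    reference: SignedNetwork,
    ignore_diagonal: bool = True,
) -> EvaluationResult:
    """Score an inferred network against a reference, direction only.

    PPV of an empty prediction is 0 by convention (the 0/0 case), which
    also forces F to 0, so vacuous output is never rewarded.
    """
    if inferred.n_nodes != reference.n_nodes:
        raise ValueError("networks must have the same number of nodes")
    pred = _edge_mask(inferred, ignore_diagonal)
    true = _edge_mask(reference, ignore_diagonal)
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    ppv = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = 2 * ppv * recall / (ppv + recall) if ppv + recall > 0 else 0.0
    convention = "directed, sign-ignored, diagonal {}".format(
        "excluded" if ignore_diagonal else "included"
    )
    return EvaluationResult(tp, fp, fn, ppv, recall, f, convention)


def quorum_consensus(networks: list[SignedNetwork], k: int) -> SignedNetwork:
    """Keep edges present in at least k of the input networks.

    The consensus sign is the majority sign among the supporting networks,
    ties resolved to +1. k = 1 gives the union, k = M the intersection.
    """
    if not networks:
        raise ValueError("at least one network is required")
    n = networks[0].n_nodes
    if any(net.n_nodes != n for net in networks):
        raise ValueError("all networks must have the same number of nodes")
    if not 1 <= k <= len(networks):
        raise ValueError("quorum k must be in [1, number of networks]")
    stack = np.stack([net.adjacency for net in networks])
    counts = (stack != 0).sum(axis=0)
    sign_sum = np.sign(stack).sum(axis=0)
    adj = np.where(counts >= k, np.where(sign_sum < 0, -1, 1), 0)
    return SignedNetwork(adj.astype(int), list(networks[0].node_labels))


def optimize_quorum(
    networks: list[SignedNetwork],
    reference: SignedNetwork,
    ignore_diagonal: bool = True,
) -> tuple[int, SignedNetwork, EvaluationResult]:
    """Exhaustive scan of the quorum threshold for maximum F score.

    Returns the smallest k attaining the maximum, with its consensus
    network and evaluation.
    """
    best = None
    for k in range(1, len(networks) + 1):
        cons = quorum_consensus(networks, k)
        res = evaluate(cons, reference, ignore_diagonal)
        if best is None or res.f_score > best[2].f_score:
            best = (k, cons, res)
    return best
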