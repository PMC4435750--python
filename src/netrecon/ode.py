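"""Identification of the interaction matrix A of a linear rate-equation model.

Each row of A (the regulators of one target node) is estimated by an
independent linear regression of that node's response (rate estimate or
state increment) on all node states (or their cumulative integrals). Three
feature-selection routes control collinearity:

truncation
    forward-backward stepwise selection driven by partial-F tests
    (enter when p < p_enter, drop when p > p_remove);
projection
    PLS regression onto a small number of latent vectors — chosen by the
    broken-stick rule or Bartlett's trailing-eigenvalue equality test —
    followed by VIP screening of the original predictors and an OLS refit
    on the survivors;
integral stepwise
    forward stepwise regression on the integral (finite-difference) form,
    with an optional hard cap on the number of regressors per node that
    imposes sparseness directly.

Continuous weight matrices are reduced to signed networks by thresholding
at a quantile of the absolute edge weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .networks import SignedNetwork
from .preprocess import RegressionData

__all__ = [
    "InferenceParams",
    "WeightedAdjacency",
    "stepwise_select",
    "broken_stick_count",
    "bartlett_count",
    "fit_pls",
    "PLSFit",
    "infer_stepwise",
    "infer_projection",
    "infer_tsni_integral",
    "quantile_prune",
]

_RSS_EPS = 1e-9


@dataclass
class InferenceParams:
    """Tunable parameters shared by the inference routes.

    p_enter, p_remove
        Partial-F p-value thresholds for stepwise recruitment and pruning;
        must satisfy 0 < p_enter < p_remove < 1.
    lv_rule
        Latent-vector count rule for the projection route:
        "broken_stick" or "bartlett".
    vip_threshold
        Predictors with VIP below this are dropped before the refit
        (1.0 is the conventional significance cut).
    quantile_q
        Quantile of |edge weight| used as the pruning threshold.
    max_regressors
        Per-node cap on recruited terms for the integral route
        (None = unlimited); the knob that imposes sparseness.
    include_self
        Whether a node's own state may appear among its regressors.
    """

    p_enter: float = 0.05
    p_remove: float = 0.10
    lv_rule: str = "broken_stick"
    bartlett_alpha: float = 0.05
    vip_threshold: float = 1.0
    quantile_q: float = 0.0
    max_regressors: int | None = None
    include_self: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.p_enter < self.p_remove < 1:
            raise ValueError("require 0 < p_enter < p_remove < 1")
        if self.lv_rule not in ("broken_stick", "bartlett"):
            raise ValueError("lv_rule must be 'broken_stick' or 'bartlett'")
        if not 0 <= self.quantile_q <= 1:
            raise ValueError("quantile_q must be in [0, 1]")
        if self.vip_threshold < 0:
            raise ValueError("vip_threshold must be non-negative")
        if self.max_regressors is not None and self.max_regressors < 0:
            raise ValueError("max_regressors must be non-negative or None")


@dataclass
class WeightedAdjacency:
    """Real-valued inferred interaction strengths prior to pruning.

    ``weights[i, j]`` is the inferred effect of node j on the rate of node
    i; exact zero means "no inferred interaction".
    """

    weights: np.ndarray
    perturbation_gains: np.ndarray | None = None
    method_tag: str = ""
    params_used: InferenceParams | None = None
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")
        if not self.node_labels:
            self.node_labels = [f"g{i + 1}" for i in range(self.weights.shape[0])]


# ---------------------------------------------------------------------------
# Stepwise truncation


def _rss(X: np.ndarray, y: np.ndarray, support: list[int]) -> float:
    if not support:
        return float(y @ y)
    beta, *_ = np.linalg.lstsq(X[:, support], y, rcond=None)
    resid = y - X[:, support] @ beta
    return float(resid @ resid)


def _partial_f_pvalue(rss_small: float, rss_big: float, df_resid: int,
                      scale: float) -> float:
    """p-value for one term's partial F = (RSS0-RSS1)/(RSS1/df_resid).

    ``scale`` (total response sum of squares) sets the resolution below
    which a residual counts as an exact fit, so numerically perfect models
    neither recruit spurious terms nor shed needed ones.
    """
    if df_resid <= 0:
        return 1.0
    tol = _RSS_EPS * max(scale, 1.0)
    if rss_small <= tol:
        return 1.0  # smaller model already fits exactly; the term adds nothing
    if rss_big <= tol:
        return 0.0  # the term is needed for an exact fit
    num = max(rss_small - rss_big, 0.0)
    f = num / (rss_big / df_resid)
    return float(stats.f.sf(f, 1, df_resid))


def stepwise_select(
    design: np.ndarray,
    response: np.ndarray,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_terms: int | None = None,
    forward_only: bool = False,
) -> tuple[list[int], np.ndarray]:
    """Forward-backward stepwise least squares driven by partial-F tests.

    Repeatedly recruits the candidate with the smallest partial-F p-value
    when it falls below ``p_enter``, then drops any recruited term whose
    p-value has risen above ``p_remove``; stops when neither step changes
    the model. Returns the selected column indices and the OLS coefficients
    on that support (no intercept — the rate-equation model has none).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("stepwise selection requires at least 3 rows")
    if not forward_only and p_enter >= p_remove:
        raise ValueError("p_enter must be smaller than p_remove")

    support: list[int] = []
    scale = float(y @ y)
    rss_cur = scale
    for _ in range(4 * p + 4):  # oscillation guard
        changed = False
        # forward step
        if (max_terms is None or len(support) < max_terms) and len(support) < p:
            best_j, best_p, best_rss = None, 1.0, np.inf
            df = n - (len(support) + 1)
            for j in range(p):
                if j in support:
                    continue
                rss_j = _rss(X, y, support + [j])
                pval = _partial_f_pvalue(rss_cur, rss_j, df, scale)
                # ties (e.g. several exact-fit candidates) go to the
                # strongest RSS reducer
                if pval < best_p or (pval == best_p and rss_j < best_rss):
                    best_j, best_p, best_rss = j, pval, rss_j
            if best_j is not None and best_p < p_enter:
                support.append(best_j)
                rss_cur = best_rss
                changed = True
        # backward step
        if not forward_only and support:
            worst_j, worst_p = None, -1.0
            df = n - len(support)
            for j in support:
                reduced = [k for k in support if k != j]
                pval = _partial_f_pvalue(_rss(X, y, reduced), rss_cur, df, scale)
                if pval > worst_p:
                    worst_j, worst_p = j, pval
            if worst_j is not None and worst_p > p_remove:
                support.remove(worst_j)
                rss_cur = _rss(X, y, support)
                changed = True
        if not changed:
            break

    if support:
        coefs, *_ = np.linalg.lstsq(X[:, support], y, rcond=None)
        # terms whose refit coefficient is numerically zero (possible when
        # an exact fit was reached after they entered) carry no interaction
        floor = 1e-9 * max(np.abs(coefs).max(), 1e-300)
        keep = np.abs(coefs) > floor
        support = [j for j, k in zip(support, keep) if k]
        coefs = coefs[keep]
    else:
        coefs = np.zeros(0)
    return sorted_support_and_coefs(support, coefs)


def sorted_support_and_coefs(support: list[int], coefs: np.ndarray):
    order = np.argsort(support)
    return [support[k] for k in order], np.asarray([coefs[k] for k in order])


# ---------------------------------------------------------------------------
# Latent-vector count rules


def broken_stick_count(variance_fractions: np.ndarray) -> int:
    """Number of leading components exceeding broken-stick expectations.

    The expectation for rank i of p is b_i = (1/p) * sum_{j=i..p} 1/j; the
    count is the largest k such that every fraction up to rank k exceeds
    its b_i, floored at one component.
    """
    fracs = np.asarray(variance_fractions, dtype=float)
    if fracs.size == 0:
        raise ValueError("variance_fractions must be non-empty")
    if np.any(fracs < 0):
        raise ValueError("variance_fractions must be non-negative")
    p = fracs.size
    inv = 1.0 / np.arange(1, p + 1)
    b = np.cumsum(inv[::-1])[::-1] / p  # b_i = (1/p) sum_{j>=i} 1/j
    k = 0
    for i in range(p):
        if fracs[i] > b[i]:
            k += 1
        else:
            break
    return max(k, 1)


def bartlett_count(
    eigenvalues: np.ndarray, n_samples: int, alpha: float = 0.05
) -> int:
    """Components to retain by Bartlett's trailing-eigenvalue equality test.

    For k = 0, 1, ... the null "the last p-k eigenvalues are equal" is
    tested with the chi-square statistic
    (n - k - (2(p-k)+11)/6) * [(p-k) ln(mean of trailing) - sum ln trailing]
    on (p-k+2)(p-k-1)/2 degrees of freedom; the count is the smallest k
    whose null is retained at level ``alpha``, floored at 1.
    """
    eigs = np.asarray(eigenvalues, dtype=float)
    p = eigs.size
    if np.any(eigs <= 0):
        raise ValueError("eigenvalues must be positive")
    if n_samples <= p:
        raise ValueError("bartlett test requires n_samples > p")
    for k in range(p - 1):
        trailing = eigs[k:]
        r = p - k
        statistic = (n_samples - k - (2 * r + 11) / 6.0) * (
            r * np.log(trailing.mean()) - np.log(trailing).sum()
        )
        df = (r + 2) * (r - 1) / 2.0
        if stats.chi2.sf(max(statistic, 0.0), df) > alpha:
            return max(k, 1)
    return p - 1 if p > 1 else 1


# ---------------------------------------------------------------------------
# PLS projection


@dataclass
class PLSFit:
    coefficients: np.ndarray
    vip_scores: np.ndarray
    variance_fractions: np.ndarray
    n_latent: int


def fit_pls(design: np.ndarray, response: np.ndarray, n_latent: int) -> PLSFit:
    """PLS1 regression with VIP scores and X-variance shares per component.

    VIP_j = sqrt(p * sum_a SS_a (w_ja / ||w_a||)^2 / sum_a SS_a) over the
    fitted components, where SS_a is the response sum of squares explained
    by component a; the scores satisfy sum_j VIP_j^2 = p.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(response, dtype=float).ravel()
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if n_latent < 1:
        raise ValueError("n_latent must be positive")
    if n_latent > rank:
        raise ValueError(f"n_latent={n_latent} exceeds design rank {rank}")

    pls = PLSRegression(n_components=n_latent, scale=False)
    pls.fit(X, y)
    coefficients = np.asarray(pls.coef_).reshape(-1)

    W = pls.x_weights_            # (p, a)
    T = pls.x_scores_             # (n, a)
    P = pls.x_loadings_           # (p, a)
    q = pls.y_loadings_.ravel()   # (a,)

    ss_y = (q ** 2) * np.einsum("na,na->a", T, T)
    w_norm2 = np.einsum("pa,pa->a", W, W)
    vip = np.sqrt(p * ((W ** 2 / w_norm2) @ ss_y) / ss_y.sum())

    total_x = float((Xc ** 2).sum())
    expl = np.einsum("na,na->a", T, T) * np.einsum("pa,pa->a", P, P)
    variance_fractions = expl / total_x if total_x > 0 else np.zeros_like(expl)
    return PLSFit(coefficients, vip, variance_fractions, n_latent)


# ---------------------------------------------------------------------------
# Full-matrix inference routes


def _candidate_columns(n: int, target: int, include_self: bool) -> np.ndarray:
    cols = np.arange(n)
    if not include_self:
        cols = cols[cols != target]
    return cols


def infer_stepwise(data: RegressionData, params: InferenceParams) -> WeightedAdjacency:
    """Row-wise forward-backward stepwise identification of A."""
    n = data.n_nodes
    weights = np.zeros((n, n))
    for i in range(n):
        y = data.response[:, i]
        cols = _candidate_columns(n, i, params.include_self)
        if np.std(y) < 1e-14:
            continue
        support, coefs = stepwise_select(
            data.design[:, cols], y, params.p_enter, params.p_remove
        )
        weights[i, cols[support]] = coefs
    return WeightedAdjacency(
        weights, method_tag="stepwise", params_used=replace(params),
        node_labels=list(data.node_labels or []),
    )


def _choose_n_latent(X: np.ndarray, y: np.ndarray, params: InferenceParams) -> int:
    Xc = X - X.mean(axis=0)
    rank = int(np.linalg.matrix_rank(Xc))
    if rank < 1:
        return 0
    if params.lv_rule == "broken_stick":
        full = fit_pls(X, y, rank)
        fracs = np.sort(full.variance_fractions)[::-1]
        total = fracs.sum()
        if total <= 0:
            return 1
        k = broken_stick_count(fracs / total)
    else:
        cov = np.cov(X, rowvar=False)
        eigs = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eigs = np.clip(eigs, 1e-12, None)
        k = bartlett_count(eigs, n_samples=X.shape[0], alpha=params.bartlett_alpha)
    return min(k, rank)


def infer_projection(data: RegressionData, params: InferenceParams) -> WeightedAdjacency:
    """Row-wise PLS projection with latent-count rule, VIP screen, OLS refit."""
    n = data.n_nodes
    weights = np.zeros((n, n))
    for i in range(n):
        y = data.response[:, i]
        cols = _candidate_columns(n, i, params.include_self)
        X = data.design[:, cols]
        if np.std(y) < 1e-14:
            continue
        # VIP is only meaningful on comparably scaled predictors, so the
        # projection/screening stage sees unit-variance columns; the final
        # coefficients are refit on the raw columns and keep their units.
        sd = X.std(axis=0, ddof=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Xs = (X - X.mean(axis=0)) / sd_safe
        k = _choose_n_latent(Xs, y, params)
        if k < 1:
            continue
        fit = fit_pls(Xs, y, k)
        survivors = np.flatnonzero((fit.vip_scores >= params.vip_threshold) & (sd > 0))
        if survivors.size == 0:
            continue
        coefs, *_ = np.linalg.lstsq(X[:, survivors], y, rcond=None)
        coefs[np.abs(coefs) <= 1e-9 * np.abs(coefs).max()] = 0.0
        weights[i, cols[survivors]] = coefs
    return WeightedAdjacency(
        weights, method_tag=f"projection_{params.lv_rule}",
        params_used=replace(params), node_labels=list(data.node_labels or []),
    )


def infer_tsni_integral(data: RegressionData, params: InferenceParams) -> WeightedAdjacency:
    """Forward stepwise regression on the integral (finite-difference) form.

    Recruitment stops when ``max_regressors`` terms are in the model or no
    candidate passes ``p_enter``. When a perturbation trace is present its
    integrated columns are always kept in the model and their coefficients
    are reported as perturbation gains (the matrix B).
    """
    if data.mode != "integral":
        raise ValueError("TSNI-integral requires RegressionData in integral mode")
    n = data.n_nodes
    pert = data.perturbation_design
    q = 0 if pert is None else pert.shape[1]
    weights = np.zeros((n, n))
    gains = np.zeros((n, q)) if q else None
    for i in range(n):
        y = data.response[:, i]
        cols = _candidate_columns(n, i, params.include_self)
        if np.std(y) < 1e-14:
            continue
        X = data.design[:, cols]
        if q:
            # forced perturbation columns first, candidates after
            full = np.hstack([pert, X])
            resid_basis, *_ = np.linalg.lstsq(pert, y, rcond=None)
            if params.max_regressors == 0:
                gains[i] = resid_basis
                continue
            support, _ = stepwise_select(
                X, y - pert @ resid_basis, params.p_enter, params.p_remove,
                max_terms=params.max_regressors, forward_only=True,
            )
            chosen = np.concatenate([np.arange(q), q + np.asarray(support, dtype=int)])
            coefs, *_ = np.linalg.lstsq(full[:, chosen], y, rcond=None)
            gains[i] = coefs[:q]
            weights[i, cols[support]] = coefs[q:]
        else:
            if params.max_regressors == 0:
                continue
            support, coefs = stepwise_select(
                X, y, params.p_enter, params.p_remove,
                max_terms=params.max_regressors, forward_only=True,
            )
            weights[i, cols[support]] = coefs
    return WeightedAdjacency(
        weights, perturbation_gains=gains, method_tag="tsni_integral",
        params_used=replace(params), node_labels=list(data.node_labels or []),
    )


def quantile_prune(w: WeightedAdjacency, q: float) -> SignedNetwork:
    """Threshold a weight matrix at the q-quantile of |nonzero weights|.

    Edges with |weight| >= threshold survive and carry the sign of their
    weight; an all-zero matrix yields an empty network. Monotone in q:
    larger q never adds edges.
    """
    if not 0 <= q <= 1:
        raise ValueError("q must be in [0, 1]")
    weights = w.weights
    nonzero = np.abs(weights[weights != 0])
    adj = np.zeros_like(weights, dtype=int)
    if nonzero.size:
        tau = np.quantile(nonzero, q)
        keep = np.abs(weights) >= tau
        adj[keep] = np.sign(weights[keep]).astype(int)
    return SignedNetwork(adj, list(w.node_labels))
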