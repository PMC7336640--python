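"""Cross-L1 ("CLASSO") penalized estimation.

The cross-L1 penalty

    P_c(beta) = n * lambda_c * sum_{l != m} sum_j |beta_lj beta_mj| / (w_lj w_mj)

penalizes products of coefficients of the same covariate across different
components (ordered pairs both counted), with adaptive weights w_kj from a
pilot maximum partial-likelihood fit.  As lambda_c grows the solution
becomes cross-sparse: each covariate acts in at most one component.  The
penalized surrogate is maximized component-wise by a sign-restricted
full-gradient method whose step never crosses zero (the t_edge rule);
coordinates parked at zero stay there unless the surrogate gradient
exceeds the penalty's subgradient bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SurvivalDataset
from .params import QuasiLinearParams, groups_to_mask
from .likelihood import Workspace, surrogate_beta_gradient
from .fitting import (
    FitControl,
    FitResult,
    fit_mle,
    _component_sums,
    _update_pi_ws,
)

__all__ = ["PenaltyConfig", "cross_l1_penalty", "penalized_objective",
           "adaptive_weights", "gradient_direction", "step_sizes",
           "fit_classo"]

DEFAULT_WEIGHT_FLOOR = 1e-3


@dataclass
class PenaltyConfig:
    """Strengths and adaptive weights of the CLASSO (+ optional L2) penalty.

    ``n`` is the sample size entering the n*lambda prefactors.  Weights are
    floored away from zero so the penalty stays finite while near-zero
    pilot coefficients are penalized heavily.
    """

    lambda_c: float
    weights: np.ndarray
    n: int
    lambda_2: float = 0.0
    floor: float = DEFAULT_WEIGHT_FLOOR

    def __post_init__(self):
        if self.lambda_c < 0 or self.lambda_2 < 0:
            raise ValueError("penalty strengths must be nonnegative")
        w = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.weights = np.maximum(np.abs(w), self.floor)


def adaptive_weights(fit, floor: float = DEFAULT_WEIGHT_FLOOR) -> np.ndarray:
    """Adaptive penalty denominators |beta_hat_kj| from a pilot MLE fit,
    floored at ``floor``.  Accepts a FitResult, params, or a bare matrix."""
    if isinstance(fit, FitResult):
        beta = fit.params.beta
    elif isinstance(fit, QuasiLinearParams):
        beta = fit.beta
    else:
        beta = np.asarray(fit, dtype=float)
    return np.maximum(np.abs(beta), floor)


def cross_l1_penalty(beta: np.ndarray, config: PenaltyConfig) -> float:
    """P_c(beta): ordered pairs l != m both counted."""
    B = np.abs(np.atleast_2d(beta)) / config.weights
    col = B.sum(axis=0)
    cross = float(np.sum(col * col) - np.sum(B * B))
    return config.n * config.lambda_c * cross


def penalized_objective(data_or_ws, params: QuasiLinearParams,
                        config: PenaltyConfig) -> float:
    """l(theta) - P_2(beta) - P_c(beta)."""
    ws = data_or_ws if isinstance(data_or_ws, Workspace) else Workspace.build(data_or_ws)
    pen2 = config.n * config.lambda_2 * float(np.sum(params.beta ** 2))
    return ws.loglik(params) - pen2 - cross_l1_penalty(params.beta, config)


# ---------------------------------------------------------------------------
# Full-gradient direction and step sizes.
# ---------------------------------------------------------------------------

def _penalty_factor(beta: np.ndarray, config: PenaltyConfig, m: int) -> np.ndarray:
    """Subgradient bound of P_c in beta_m:
    2 n lambda_c sum_{k != m} |beta_kj| / (w_mj w_kj), per coordinate j."""
    B = np.abs(beta) / config.weights
    other = B.sum(axis=0) - B[m]
    return 2.0 * config.n * config.lambda_c * other / config.weights[m]


def _direction(beta_m: np.ndarray, grad: np.ndarray, penfac: np.ndarray,
               free: np.ndarray = None) -> np.ndarray:
    """Sign-aware composite gradient direction d_m.

    Three branches: active coordinates subtract the penalty subgradient at
    sign(beta_mj); zero coordinates move only if the surrogate gradient
    exceeds the penalty bound (and then toward the gradient's sign);
    otherwise the coordinate is dead and stays at zero.
    """
    active = beta_m != 0.0
    d = np.where(active, grad - penfac * np.sign(beta_m), 0.0)
    wake = (~active) & (np.abs(grad) > penfac)
    d = np.where(wake, grad - penfac * np.sign(grad), d)
    if free is not None:
        d = np.where(free, d, 0.0)
    return d


def gradient_direction(params: QuasiLinearParams, params_s: QuasiLinearParams,
                       data: SurvivalDataset, config: PenaltyConfig,
                       m: int) -> np.ndarray:
    """d_m at ``params`` for the surrogate anchored at ``params_s``."""
    grad = surrogate_beta_gradient(params, params_s, data)[m]
    if config.lambda_2 > 0:
        grad = grad - 2.0 * config.n * config.lambda_2 * params.beta[m]
    penfac = _penalty_factor(params.beta, config, m)
    free = params.mask[m] if params.mask is not None else None
    return _direction(params.beta[m], grad, penfac, free)


def _edge_step(beta_m: np.ndarray, d: np.ndarray):
    """Largest step along d before any coordinate changes sign.

    Returns (t_edge, hit) with hit the boolean set of coordinates that
    reach exactly zero at t_edge; t_edge is +inf when no coordinate moves
    toward zero.
    """
    opposing = (np.sign(beta_m) == -np.sign(d)) & (np.sign(d) != 0)
    if not np.any(opposing):
        return np.inf, np.zeros_like(d, dtype=bool)
    ratios = np.full_like(d, np.inf)
    ratios[opposing] = -beta_m[opposing] / d[opposing]
    t_edge = ratios.min()
    return float(t_edge), ratios == t_edge


def step_sizes(params: QuasiLinearParams, d_m: np.ndarray,
               data: SurvivalDataset, m: int = 0):
    """(t_opt, t_edge) for a full-gradient step on component m.

    t_opt maximizes the local quadratic model along d_m, (d'd)/(d'Hd)
    with H the negative surrogate Hessian block; t_edge stops the step at
    the first sign change.  Nonpositive curvature returns t_opt = inf so
    the caller falls back to backtracking.
    """
    ws = Workspace.build(data)
    _, pstar_s = ws.posteriors(params)
    wstar = ws.delta * pstar_s[:, m]
    v = ws.X @ params.beta[m]
    logD = ws.log_risk_sum(v)
    _, _, H = _component_sums(ws, v, logD, wstar, True)
    quad = float(d_m @ H @ d_m)
    t_opt = float(d_m @ d_m) / quad if quad > 0 else np.inf
    t_edge, _ = _edge_step(params.beta[m], d_m)
    return t_opt, t_edge


# ---------------------------------------------------------------------------
# Penalized MM loop.
# ---------------------------------------------------------------------------

def _inner_beta_classo(ws: Workspace, beta: np.ndarray, m: int,
                       target: np.ndarray, wstar: np.ndarray,
                       logD: np.ndarray, config: PenaltyConfig,
                       free: np.ndarray, control: FitControl) -> np.ndarray:
    """Full-gradient maximization of the penalized surrogate in beta_m.

    The anchor (risk-sum denominators, posterior weights) is fixed for the
    whole inner loop; other components' coefficients enter only through
    the penalty factors.
    """
    b = beta[m].copy()
    n2l2 = config.n * config.lambda_2
    penfac = _penalty_factor(beta, config, m)  # others fixed during inner loop

    def q_fast(bv):
        scalar, _, _ = _component_sums(ws, ws.X @ bv, logD, wstar, False)
        return (float(target @ bv) - scalar
                - float(np.abs(bv) @ penfac) - n2l2 * float(bv @ bv))

    q0 = q_fast(b)
    for _ in range(control.max_inner_grad):
        scalar, rhs, J = _component_sums(ws, ws.X @ b, logD, wstar, True)
        grad = target - rhs - 2.0 * n2l2 * b
        d = _direction(b, grad, penfac, free)
        if np.abs(d).max() < 1e-12:
            break
        H = J + 2.0 * n2l2 * np.eye(b.size)
        quad = float(d @ H @ d)
        t_opt = float(d @ d) / quad if quad > 0 else np.inf
        t_edge, hit = _edge_step(b, d)
        t = min(t_opt, t_edge)
        if not np.isfinite(t):
            t = 1.0 / (1.0 + np.abs(d).max())
            hit = np.zeros_like(hit)
        on_edge = t == t_edge
        accepted = False
        for _ in range(30):
            bn = b + t * d
            if on_edge:
                bn[hit] = 0.0
            if q_fast(bn) >= q0 - 1e-12:
                accepted = True
                break
            t *= 0.5
            on_edge = False
        if not accepted:
            break
        move = np.abs(bn - b).max()
        b = bn
        q0 = q_fast(b)
        if move < control.inner_grad_tol:
            break
    return b


def fit_classo(data: SurvivalDataset, K: int, lambda_c: float,
               control: FitControl = None, pilot: FitResult = None,
               groups=None, lambda_2: float = 0.0,
               weights: np.ndarray = None, init: QuasiLinearParams = None,
               weight_floor: float = DEFAULT_WEIGHT_FLOOR) -> FitResult:
    """CLASSO estimator: MM sweeps with the coefficient update replaced by
    the sign-restricted full-gradient method.

    The pilot MLE fit supplies the adaptive weights and (unless ``init``
    is given) the starting point, freezing the component order for the
    penalized path.  Exact zeros in the returned coefficients are the
    support; no post-hoc thresholding is applied.
    """
    control = control or FitControl()
    mask = groups_to_mask(groups, K, data.p) if groups is not None else None
    ws = Workspace.build(data)
    if weights is None or init is None:
        if pilot is None:
            pilot = fit_mle(data, K, control, groups=groups)
        if weights is None:
            weights = adaptive_weights(pilot, floor=weight_floor)
        if init is None:
            init = pilot.params
    config = PenaltyConfig(lambda_c=lambda_c, weights=weights, n=data.n,
                           lambda_2=lambda_2, floor=weight_floor)
    params = QuasiLinearParams(init.pi, init.beta.copy(), mask)
    free_all = mask if mask is not None else np.ones_like(params.beta, bool)

    obj = penalized_objective(ws, params, config)
    ll_trace = [ws.loglik(params)]
    obj_trace = [obj]
    best = (obj, params)
    converged = False
    for _ in range(control.max_outer_iter):
        p_s, pstar_s = ws.posteriors(params)
        A = ws.X @ params.beta.T
        beta_new = params.beta.copy()
        for m in range(K):
            target = ((ws.delta * p_s[:, m])[:, None] * ws.X).sum(axis=0)
            wstar = ws.delta * pstar_s[:, m]
            logD = ws.log_risk_sum(A[:, m])
            beta_new[m] = _inner_beta_classo(
                ws, beta_new, m, target, wstar, logD, config,
                free_all[m], control)
        pi_new = _update_pi_ws(ws, params, beta_new)
        params = QuasiLinearParams(pi_new, beta_new, mask)
        obj_new = penalized_objective(ws, params, config)
        ll_trace.append(ws.loglik(params))
        obj_trace.append(obj_new)
        if obj_new > best[0]:
            best = (obj_new, params)
        if abs(obj_new - obj) / (abs(obj) + 1.0) < control.tol:
            converged = True
            break
        obj = obj_new
    params = best[1]
    return FitResult(
        params=params,
        loglik=ws.loglik(params),
        trace=np.asarray(ll_trace),
        converged=converged,
        n_iter=len(ll_trace) - 1,
        meta={
            "lambda_c": float(lambda_c),
            "lambda_2": float(lambda_2),
            "objective": best[0],
            "objective_trace": list(map(float, obj_trace)),
            "K": K,
        },
    )
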