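"""Maximum partial-likelihood estimation by an MM fixed-point algorithm.

One outer sweep minorizes l(theta) at the current iterate with the
tangent surrogate G(theta, theta^(s)) and maximizes it: every component's
coefficient vector solves a weighted Cox-type estimating equation (inner
damped Newton), then the mixing vector is updated in closed form.  The
partial log-likelihood is nondecreasing along the sweeps; because the
likelihood need not be unimodal the fitter restarts from several random
initializations and keeps the best run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import SurvivalDataset
from .params import QuasiLinearParams, groups_to_mask
from .likelihood import (
    Workspace,
    observed_information,
    information_covariance,
)

__all__ = ["FitControl", "FitResult", "init_params", "fit_mle",
           "update_beta", "update_pi", "cox_newton"]


@dataclass
class FitControl:
    """Iteration and convergence settings for the MM fitters.

    ``tol`` is the relative log-likelihood (or penalized objective) change
    |l_{s+1} - l_s| / (|l_s| + 1) below which the outer loop stops.
    """

    max_outer_iter: int = 500
    tol: float = 1e-8
    max_inner_iter: int = 25
    n_restarts: int = 5
    seed: int = 0
    max_inner_grad: int = 200      # full-gradient steps per component (CLASSO)
    inner_grad_tol: float = 1e-8   # max coordinate update stopping rule

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if min(self.max_outer_iter, self.max_inner_iter, self.n_restarts) < 1:
            raise ValueError("iteration caps and restart count must be >= 1")


@dataclass
class FitResult:
    """Outcome of an MM fit.

    ``trace`` holds l(theta^(s)) per outer sweep (for penalized fits, the
    unpenalized log-likelihood; the penalized objective trace is in
    ``meta['objective_trace']``).
    """

    params: QuasiLinearParams
    loglik: float
    trace: np.ndarray
    converged: bool
    n_iter: int
    covariance: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "params": self.params.to_dict(),
            "loglik": self.loglik,
            "trace": np.asarray(self.trace).tolist(),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
        }
        if self.covariance is not None:
            d["covariance"] = np.asarray(self.covariance).tolist()
        d["meta"] = {k: v for k, v in self.meta.items()
                     if isinstance(v, (int, float, str, bool, list))}
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            params=QuasiLinearParams.from_dict(d["params"]),
            loglik=d["loglik"],
            trace=np.asarray(d["trace"]),
            converged=d["converged"],
            n_iter=d["n_iter"],
            covariance=np.asarray(d["covariance"]) if "covariance" in d else None,
            meta=d.get("meta", {}),
        )


# ---------------------------------------------------------------------------
# Standard Cox partial-likelihood Newton solver (K = 1 building block).
# ---------------------------------------------------------------------------

def cox_newton(data: SurvivalDataset, ridge: float = 0.0, max_iter: int = 50,
               tol: float = 1e-10, columns=None, b0=None) -> np.ndarray:
    """Newton-Raphson maximizer of the standard Cox partial likelihood.

    ``ridge`` adds a small quadratic penalty, used only to keep pilot fits
    on tiny subsamples finite under separation.
    """
    ws = Workspace.build(data if columns is None else
                         SurvivalDataset(data.time, data.event,
                                         data.covariates[:, columns]))
    p = ws.X.shape[1]
    b = np.zeros(p) if b0 is None else np.asarray(b0, dtype=float).copy()

    def value_grad_hess(b):
        v = ws.X @ b
        c, s0, s1, s2 = ws.risk_moments(v)
        ll = float(np.sum(ws.delta * (v - (c + np.log(s0))))) - 0.5 * ridge * b @ b
        xbar = s1 / s0[:, None]
        g = (ws.delta[:, None] * (ws.X - xbar)).sum(axis=0) - ridge * b
        V = s2 / s0[:, None, None] - xbar[:, :, None] * xbar[:, None, :]
        H = np.einsum("i,ijk->jk", ws.delta, V) + ridge * np.eye(p)
        return ll, g, H

    ll, g, H = value_grad_hess(b)
    for _ in range(max_iter):
        if np.linalg.norm(g) < tol * (1 + abs(ll)):
            break
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), g)
        except np.linalg.LinAlgError:
            step = g
        t = 1.0
        for _ in range(30):
            bt = b + t * step
            llt, gt, Ht = value_grad_hess(bt)
            if llt >= ll:
                break
            t *= 0.5
        if llt < ll:
            break
        b, ll, g, H = bt, llt, gt, Ht
    return b


# ---------------------------------------------------------------------------
# MM updates.
# ---------------------------------------------------------------------------

def _component_sums(ws: Workspace, v: np.ndarray, logD: np.ndarray,
                    wstar: np.ndarray, need_hessian: bool):
    """Risk-weighted sums entering the component estimating equation.

    For weights exp(v) over risk sets, with fixed denominators exp(logD):
    ``scalar`` = sum_i wstar_i * [sum_R exp(v)] / exp(logD_i), ``rhs`` the
    matching x-weighted vector sum, ``J`` its Jacobian in the coefficient.
    """
    c, s0, s1, s2 = ws.risk_moments(v, second=need_hessian)
    g = wstar * np.exp(c + np.log(s0) - logD)
    scalar = float(g.sum())
    rhs = (g / s0) @ s1
    J = np.einsum("i,ijk->jk", g / s0, s2) if need_hessian else None
    return scalar, rhs, J


def _solve_beta_component(ws: Workspace, b0: np.ndarray, free: np.ndarray,
                          target: np.ndarray, wstar: np.ndarray,
                          logD: np.ndarray, max_iter: int) -> np.ndarray:
    """Damped Newton solve of the component estimating equation.

    Solves sum_i delta_i p_ki x_i = sum_i delta_i p*_ki
    [sum_R exp(b'x) x / sum_R exp(beta_k'x)] for b, warm-started at the
    current beta_k; coordinates outside ``free`` stay fixed at zero.
    """
    b = b0.copy()
    if free.sum() == 0:
        return b
    fidx = np.flatnonzero(free)
    scale = 1.0 + np.linalg.norm(target[fidx])
    tol = 1e-11 * scale

    def residual(b, need_hessian):
        _, rhs, J = _component_sums(ws, ws.X @ b, logD, wstar, need_hessian)
        return target[fidx] - rhs[fidx], J

    F, J = residual(b, True)
    for _ in range(max_iter):
        nF = np.linalg.norm(F)
        if nF < tol:
            break
        Jf = J[np.ix_(fidx, fidx)]
        try:
            step = np.linalg.solve(Jf + 1e-12 * np.eye(fidx.size), F)
        except np.linalg.LinAlgError:
            step = F  # gradient fallback; line search below damps it
        t = 1.0
        accepted = False
        for _ in range(30):
            bt = b.copy()
            bt[fidx] += t * step
            Ft, Jt = residual(bt, True)
            if np.linalg.norm(Ft) < nF:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            break
        b, F, J = bt, Ft, Jt
    return b


def update_beta(params: QuasiLinearParams, data: SurvivalDataset,
                risk_sets=None, control: FitControl = None) -> np.ndarray:
    """One MM coefficient update: solve the estimating equation per component."""
    control = control or FitControl()
    ws = Workspace.build(data)
    return _update_beta_ws(ws, params, control)


def _update_beta_ws(ws: Workspace, params: QuasiLinearParams,
                    control: FitControl) -> np.ndarray:
    p_s, pstar_s = ws.posteriors(params)
    A = ws.X @ params.beta.T
    K, p = params.beta.shape
    free_all = params.mask if params.mask is not None else np.ones((K, p), bool)
    beta_new = np.zeros_like(params.beta)
    for k in range(K):
        target = ((ws.delta * p_s[:, k])[:, None] * ws.X).sum(axis=0)
        wstar = ws.delta * pstar_s[:, k]
        logD = ws.log_risk_sum(A[:, k])
        beta_new[k] = _solve_beta_component(
            ws, params.beta[k], free_all[k], target, wstar, logD,
            control.max_inner_iter)
    return beta_new


def update_pi(params: QuasiLinearParams, data: SurvivalDataset,
              risk_sets=None, beta_new: np.ndarray = None) -> np.ndarray:
    """Closed-form mixing-vector update of the MM sweep.

    pi_k is rescaled by the ratio of event membership mass to risk-set
    mass (the latter corrected by the just-updated coefficients through
    the risk-sum ratio), then normalized to the simplex.
    """
    ws = Workspace.build(data)
    if beta_new is None:
        beta_new = params.beta
    return _update_pi_ws(ws, params, beta_new)


def _update_pi_ws(ws: Workspace, params: QuasiLinearParams,
                  beta_new: np.ndarray) -> np.ndarray:
    p_s, pstar_s = ws.posteriors(params)
    K = params.K
    unnorm = np.empty(K)
    for k in range(K):
        logD = ws.log_risk_sum(ws.X @ params.beta[k])
        logN = ws.log_risk_sum(ws.X @ beta_new[k])
        rho = np.exp(logN - logD)
        num = float((ws.delta * p_s[:, k]).sum())
        den = float((ws.delta * pstar_s[:, k] * rho).sum())
        unnorm[k] = params.pi[k] * num / den
    pi = unnorm / unnorm.sum()
    pi = np.maximum(pi, 1e-10)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# Initialization and the outer loop.
# ---------------------------------------------------------------------------

def init_params(data: SurvivalDataset, K: int, seed: int = 0,
                mask: np.ndarray = None, max_retries: int = 50) -> QuasiLinearParams:
    """Equal mixing weights; component coefficients from Cox fits on a
    random disjoint K-way split of the subjects.

    Deterministic given ``seed``.  A split leaving any subsample with
    fewer than two events is redrawn (bounded retries).
    """
    rng = np.random.default_rng(seed)
    n, p = data.n, data.p
    if K == 1:
        chunks = [np.arange(n)]
    else:
        chunks = None
        for _ in range(max_retries):
            perm = rng.permutation(n)
            cand = np.array_split(perm, K)
            if all(data.event[c].sum() >= 2 for c in cand):
                chunks = cand
                break
        if chunks is None:
            raise ValueError(
                f"could not split {n} subjects into {K} subsamples with events")
    beta = np.zeros((K, p))
    for k, idx in enumerate(chunks):
        sub = data.subset(np.sort(idx))
        cols = np.flatnonzero(mask[k]) if mask is not None else np.arange(p)
        if cols.size:
            # light ridge keeps tiny-subsample pilot fits finite
            b = cox_newton(sub, ridge=1e-4 * max(1, sub.n_events), columns=cols)
            beta[k, cols] = np.clip(b, -20, 20)
    pi = np.full(K, 1.0 / K)
    return QuasiLinearParams(pi, beta, mask)


def _mm_loop(ws: Workspace, params: QuasiLinearParams, control: FitControl):
    ll = ws.loglik(params)
    if not np.isfinite(ll):
        raise FloatingPointError(
            f"non-finite partial log-likelihood at initialization "
            f"(max |beta| = {np.abs(params.beta).max():.3g})")
    trace = [ll]
    best = (ll, params)
    converged = False
    for _ in range(control.max_outer_iter):
        beta_new = _update_beta_ws(ws, params, control)
        pi_new = _update_pi_ws(ws, params, beta_new)
        params = QuasiLinearParams(pi_new, beta_new, params.mask)
        ll_new = ws.loglik(params)
        trace.append(ll_new)
        if ll_new > best[0]:
            best = (ll_new, params)
        if abs(ll_new - ll) / (abs(ll) + 1.0) < control.tol:
            converged = True
            ll = ll_new
            break
        ll = ll_new
    return best[1], best[0], np.asarray(trace), converged


def fit_mle(data: SurvivalDataset, K: int, control: FitControl = None,
            groups=None, compute_covariance: bool = False) -> FitResult:
    """Maximum partial-likelihood fit of the K-component quasi-linear
    Cox model by MM sweeps, best of ``control.n_restarts`` random starts.
    """
    control = control or FitControl()
    mask = groups_to_mask(groups, K, data.p) if groups is not None else None
    ws = Workspace.build(data)
    seeds = np.random.SeedSequence(control.seed).generate_state(control.n_restarts)
    best = None
    for r in range(control.n_restarts):
        init = init_params(data, K, int(seeds[r]) % (2 ** 31), mask=mask)
        params, ll, trace, converged = _mm_loop(ws, init, control)
        if best is None or ll > best[1]:
            best = (params, ll, trace, converged, r)
    params, ll, trace, converged, r_best = best
    if K == 1 and (params.mask is None or params.mask.all()):
        # K = 1 is ordinary Cox regression; polish the MM fixed point with
        # a full Newton solve on the exact partial likelihood
        b = cox_newton(data, tol=1e-13, b0=params.beta[0])
        polished = QuasiLinearParams(params.pi, b[None, :], params.mask)
        ll_pol = ws.loglik(polished)
        if ll_pol >= ll:
            params, ll = polished, ll_pol
            trace = np.append(trace, ll_pol)
    result = FitResult(params=params, loglik=ll, trace=trace,
                       converged=converged, n_iter=len(trace) - 1,
                       meta={"restart": r_best, "K": K})
    if compute_covariance:
        info = observed_information(data, params)
        result.covariance = information_covariance(info)
    return result
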