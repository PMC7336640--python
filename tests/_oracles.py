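"""Independent brute-force oracles used to validate the library.

Everything here is written directly from the defining formulas with plain
loops and no reuse of the package's vectorized machinery.
"""

import math

import numpy as np


def risk_set(times, i):
    """{ l : t_l >= t_i } by quadratic scan."""
    return [l for l in range(len(times)) if times[l] >= times[i]]


def eta(pi, beta, x, k):
    return pi[k] * math.exp(float(np.dot(beta[k], x)))


def brute_loglik(times, events, X, pi, beta):
    """Mixture partial log-likelihood summed term by term."""
    n = len(times)
    K = len(pi)
    total = 0.0
    for i in range(n):
        if events[i] == 0:
            continue
        num = sum(eta(pi, beta, X[i], k) for k in range(K))
        den = sum(eta(pi, beta, X[l], k)
                  for l in risk_set(times, i) for k in range(K))
        total += math.log(num) - math.log(den)
    return total


def brute_posteriors(times, events, X, pi, beta):
    """(p_mi, p*_mi) as K x n matrices by direct arithmetic."""
    n, K = len(times), len(pi)
    p = np.zeros((K, n))
    pstar = np.zeros((K, n))
    for i in range(n):
        tot = sum(eta(pi, beta, X[i], k) for k in range(K))
        R = risk_set(times, i)
        tot_star = sum(eta(pi, beta, X[l], k) for l in R for k in range(K))
        for m in range(K):
            p[m, i] = eta(pi, beta, X[i], m) / tot
            pstar[m, i] = sum(eta(pi, beta, X[l], m) for l in R) / tot_star
    return p, pstar


def cox_loglik_grad_hess(times, events, X, b):
    """Standard Cox partial likelihood pieces, direct double loop."""
    n, p = X.shape
    ll = 0.0
    g = np.zeros(p)
    H = np.zeros((p, p))
    for i in range(n):
        if events[i] == 0:
            continue
        R = risk_set(times, i)
        w = np.array([math.exp(float(X[l] @ b)) for l in R])
        s0 = w.sum()
        s1 = (w[:, None] * X[R]).sum(axis=0)
        s2 = sum(w[j] * np.outer(X[R][j], X[R][j]) for j in range(len(R)))
        ll += float(X[i] @ b) - math.log(s0)
        g += X[i] - s1 / s0
        H += s2 / s0 - np.outer(s1 / s0, s1 / s0)
    return ll, g, H


def cox_newton_oracle(times, events, X, max_iter=100, tol=1e-12):
    """Textbook Newton-Raphson Cox MLE with step halving."""
    b = np.zeros(X.shape[1])
    ll, g, H = cox_loglik_grad_hess(times, events, X, b)
    for _ in range(max_iter):
        if np.linalg.norm(g) < tol:
            break
        step = np.linalg.solve(H + 1e-12 * np.eye(len(b)), g)
        t = 1.0
        while t > 1e-12:
            bt = b + t * step
            llt, gt, Ht = cox_loglik_grad_hess(times, events, X, bt)
            if llt >= ll:
                break
            t /= 2
        b, ll, g, H = bt, llt, gt, Ht
    return b, ll, H


def pair_auc(scores, times, events, t):
    """Unweighted cumulative/dynamic AUC over all case-control pairs."""
    cases = [i for i in range(len(times)) if times[i] <= t and events[i] == 1]
    controls = [i for i in range(len(times)) if times[i] > t]
    if not cases or not controls:
        return float("nan")
    s = 0.0
    for i in cases:
        for j in controls:
            if scores[i] > scores[j]:
                s += 1.0
            elif scores[i] == scores[j]:
                s += 0.5
    return s / (len(cases) * len(controls))
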