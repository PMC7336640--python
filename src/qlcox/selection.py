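"""Model selection by BIC and predictive evaluation by time-dependent AUC.

BIC here is -2 l(theta_hat) + df * log(number of events): the partial
likelihood accumulates information with events, not subjects (switchable
to n).  df counts the exactly nonzero coefficients of the CLASSO support
plus the K-1 free simplex parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .fitting import FitControl, FitResult, fit_mle
from .classo import adaptive_weights, fit_classo

__all__ = ["bic", "grid_search", "SelectionResult",
           "time_dependent_auc", "bootstrap_auc_interval",
           "DEFAULT_LAMBDA_GRID"]

# lambda_c grid used in the applications: 0, 0.1, ..., 5.0
DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 5.01, 0.1), 10))


def bic(fit: FitResult, data: SurvivalDataset, sample_size: str = "events") -> float:
    """Bayes information criterion of a fitted model.

    df = #nonzero coefficients + (K - 1); the log sample-size term uses
    the event count by default (``sample_size='n'`` switches to subjects).
    """
    n_term = data.n_events if sample_size == "events" else data.n
    if n_term <= 0:
        raise ValueError("BIC undefined with zero events")
    df = fit.params.n_free()
    return -2.0 * fit.loglik + df * np.log(n_term)


@dataclass
class SelectionResult:
    """Grid-search outcome: the full (K, lambda_c) table and the winner."""

    table: pd.DataFrame
    K: int
    lambda_c: float
    fit: FitResult

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def grid_search(data: SurvivalDataset, K_grid, lambda_grid=None,
                control: FitControl = None, groups=None,
                sample_size: str = "events") -> SelectionResult:
    """Fit every (K, lambda_c) pair and pick the BIC minimizer.

    Within each K the penalized path is warm-started along increasing
    lambda_c from the pilot MLE fit.  Failed fits are kept in the table
    (``failed=True``) but excluded from the argmin; ties break toward
    smaller K, then larger lambda_c.
    """
    control = control or FitControl()
    lambda_grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else tuple(lambda_grid)
    K_grid = tuple(K_grid)
    if not K_grid or not lambda_grid:
        raise ValueError("grids must be nonempty")
    rows = []
    fits = {}
    for K in K_grid:
        try:
            pilot = fit_mle(data, K, control, groups=groups)
        except Exception as exc:  # noqa: BLE001 - row-level failure containment
            import warnings
            warnings.warn(f"pilot fit failed for K={K}: {exc}")
            for lam in lambda_grid:
                rows.append({"K": K, "lambda_c": lam, "loglik": np.nan,
                             "df": np.nan, "bic": np.nan, "failed": True})
            continue
        weights = adaptive_weights(pilot)
        init = pilot.params
        for lam in sorted(lambda_grid):
            try:
                fit = fit_classo(data, K, lam, control, pilot=pilot,
                                 groups=groups, weights=weights, init=init)
                init = fit.params  # warm start for the next lambda
                rows.append({"K": K, "lambda_c": lam, "loglik": fit.loglik,
                             "df": fit.params.n_free(),
                             "bic": bic(fit, data, sample_size),
                             "failed": False})
                fits[(K, lam)] = fit
            except Exception as exc:  # noqa: BLE001
                import warnings
                warnings.warn(f"fit failed for K={K}, lambda_c={lam}: {exc}")
                rows.append({"K": K, "lambda_c": lam, "loglik": np.nan,
                             "df": np.nan, "bic": np.nan, "failed": True})
    table = pd.DataFrame(rows)
    ok = table[~table["failed"]]
    if ok.empty:
        raise RuntimeError("every fit in the grid failed")
    order = np.lexsort((-ok["lambda_c"].to_numpy(),
                        ok["K"].to_numpy(),
                        ok["bic"].to_numpy()))
    row = ok.iloc[order[0]]
    K_sel, lam_sel = int(row["K"]), float(row["lambda_c"])
    return SelectionResult(table=table, K=K_sel, lambda_c=lam_sel,
                           fit=fits[(K_sel, lam_sel)])


# ---------------------------------------------------------------------------
# Time-dependent ROC/AUC (cumulative cases / dynamic controls, IPCW).
# ---------------------------------------------------------------------------

def _censoring_survival(data: SurvivalDataset):
    """Kaplan-Meier estimate of the censoring survival G(t)."""
    from lifelines import KaplanMeierFitter
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, event_observed=1 - data.event)
    return kmf


def time_dependent_auc(scores, data: SurvivalDataset, t: float) -> float:
    """AUC at horizon t: cases have the event by t, controls survive past t.

    Weighted concordance with inverse-probability-of-censoring weights
    1/G(t_i-) on the cases; score ties count 1/2.  Returns NaN when there
    is no case or no control at t.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size != data.n:
        raise ValueError("one score per subject required")
    cases = (data.time <= t) & (data.event == 1)
    controls = data.time > t
    if not cases.any() or not controls.any():
        return np.nan
    kmf = _censoring_survival(data)
    # left limit of G at the case's event time
    g = np.atleast_1d(np.asarray(
        kmf.predict(np.maximum(data.time[cases] * (1 - 1e-12), 0.0)),
        dtype=float))
    g = np.clip(g, 1e-12, None)
    w = 1.0 / g
    sc = scores[cases][:, None]
    sn = scores[controls][None, :]
    conc = (sc > sn) + 0.5 * (sc == sn)
    num = float((w[:, None] * conc).sum())
    den = float(w.sum() * controls.sum())
    return num / den


class AUCInterval(NamedTuple):
    lo: float
    hi: float
    n_used: int
    n_skipped: int


def bootstrap_auc_interval(scores, data: SurvivalDataset, t: float,
                           B: int = 200, seed: int = 0) -> AUCInterval:
    """Percentile 95% bootstrap interval for the time-dependent AUC.

    Subject-level resampling; replicates with no case or no control at t
    are skipped and counted.  Deterministic given ``seed``.
    """
    if B < 2:
        raise ValueError("B >= 2 required")
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    values = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, data.n, size=data.n)
        auc = time_dependent_auc(scores[idx], data.subset(idx), t)
        if np.isnan(auc):
            skipped += 1
        else:
            values.append(auc)
    if not values:
        return AUCInterval(np.nan, np.nan, 0, skipped)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return AUCInterval(float(lo), float(hi), len(values), skipped)
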