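"""Model/Results objects wrapping the quasi-linear Cox estimators.

``QuasiLinearCoxModel`` is built from data (arrays, a DataFrame or a CSV
file); ``fit`` runs the MM maximum partial-likelihood estimator and
``fit_regularized`` the CLASSO penalized estimator.  Both return a
``QuasiLinearCoxResults`` carrying the estimates, their standard errors,
the iteration trace and a ``summary()`` table; risk prediction and
time-dependent AUC evaluation hang off the results object.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .params import QuasiLinearParams, groups_to_mask
from .likelihood import (
    quasi_linear_predictor,
    partial_log_likelihood,
    score,
    observed_information,
    information_covariance,
)
from .fitting import FitControl, FitResult, fit_mle
from .classo import fit_classo
from .selection import bic, grid_search, time_dependent_auc, \
    bootstrap_auc_interval, SelectionResult

__all__ = ["QuasiLinearCoxModel", "QuasiLinearCoxResults"]


class QuasiLinearCoxModel:
    """Quasi-linear Cox proportional hazards model.

    Parameters
    ----------
    data : SurvivalDataset
    K : number of mixture components (K = 1 is ordinary Cox regression).
    groups : optional length-K partition of covariate indices for the
        restricted model (component k free only on its block).
    """

    def __init__(self, data: SurvivalDataset, K: int = 1, groups=None):
        if K < 1:
            raise ValueError("K >= 1 required")
        self.data = data
        self.K = K
        self.groups = groups
        self.mask = groups_to_mask(groups, K, data.p) if groups is not None else None

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, K: int = 1, groups=None,
                       time_col: str = "time", event_col: str = "event",
                       covariates=None) -> "QuasiLinearCoxModel":
        data = SurvivalDataset.from_dataframe(df, time_col, event_col, covariates)
        return cls(data, K=K, groups=groups)

    @classmethod
    def from_csv(cls, path, K: int = 1, groups=None, **kwargs):
        return cls.from_dataframe(pd.read_csv(path), K=K, groups=groups, **kwargs)

    # -- likelihood surface ----------------------------------------------
    def loglike(self, params: QuasiLinearParams) -> float:
        return partial_log_likelihood(self.data, params)

    def score(self, params: QuasiLinearParams):
        return score(self.data, params)

    # -- estimation -------------------------------------------------------
    def fit(self, control: FitControl = None,
            compute_covariance: bool = True) -> "QuasiLinearCoxResults":
        res = fit_mle(self.data, self.K, control, groups=self.groups,
                      compute_covariance=compute_covariance)
        return QuasiLinearCoxResults(self, res)

    def fit_regularized(self, lambda_c: float, lambda_2: float = 0.0,
                        control: FitControl = None, pilot=None,
                        **kwargs) -> "QuasiLinearCoxResults":
        if pilot is not None and isinstance(pilot, QuasiLinearCoxResults):
            pilot = pilot._fit
        res = fit_classo(self.data, self.K, lambda_c, control, pilot=pilot,
                         groups=self.groups, lambda_2=lambda_2, **kwargs)
        return QuasiLinearCoxResults(self, res)

    def select(self, K_grid=None, lambda_grid=None,
               control: FitControl = None) -> SelectionResult:
        """BIC grid search over component counts and penalty strengths."""
        K_grid = (self.K,) if K_grid is None else K_grid
        return grid_search(self.data, K_grid, lambda_grid, control,
                           groups=self.groups)


class QuasiLinearCoxResults:
    """Fitted quasi-linear Cox model."""

    def __init__(self, model: QuasiLinearCoxModel, fit: FitResult):
        self.model = model
        self._fit = fit

    # -- pass-through -----------------------------------------------------
    @property
    def params(self) -> QuasiLinearParams:
        return self._fit.params

    @property
    def pi(self) -> np.ndarray:
        return self._fit.params.pi

    @property
    def beta(self) -> np.ndarray:
        return self._fit.params.beta

    @property
    def loglik(self) -> float:
        return self._fit.loglik

    @property
    def trace(self) -> np.ndarray:
        return self._fit.trace

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def n_iter(self) -> int:
        return self._fit.n_iter

    @property
    def covariance(self):
        if self._fit.covariance is None:
            info = observed_information(self.model.data, self.params)
            self._fit.covariance = information_covariance(info)
        return self._fit.covariance

    @property
    def df(self) -> int:
        return self.params.n_free()

    @property
    def bic(self) -> float:
        return bic(self._fit, self.model.data)

    # -- uncertainty -------------------------------------------------------
    def bse(self):
        """Standard errors: (se_pi, se_beta).

        The covariance lives on unconstrained coordinates (log-ratio pi,
        free beta entries); pi standard errors are delta-method
        back-transforms through the softmax.
        """
        cov = np.asarray(self.covariance)
        K = self.params.K
        pi = self.params.pi
        # d pi / d alpha (alpha = log pi_k/pi_K, k < K)
        J = np.diag(pi)[:, :K - 1] - np.outer(pi, pi[:K - 1])
        cov_alpha = cov[:K - 1, :K - 1]
        se_pi = np.sqrt(np.clip(np.diag(J @ cov_alpha @ J.T), 0, None))
        se_beta = np.zeros_like(self.params.beta)
        free = (np.argwhere(self.params.mask) if self.params.mask is not None
                else np.argwhere(np.ones_like(self.params.beta, bool)))
        diag = np.sqrt(np.clip(np.diag(cov)[K - 1:], 0, None))
        for (k, j), se in zip(free, diag):
            se_beta[k, j] = se
        return se_pi, se_beta

    # -- prediction & evaluation ------------------------------------------
    def predict(self, X=None) -> np.ndarray:
        """Quasi-linear risk score f_Q(x) per subject (log relative risk)."""
        if X is None:
            X = self.model.data.covariates
        return np.atleast_1d(quasi_linear_predictor(X, self.params))

    def auc(self, t: float, data: SurvivalDataset = None) -> float:
        data = data or self.model.data
        return time_dependent_auc(self.predict(data.covariates), data, t)

    def auc_interval(self, t: float, data: SurvivalDataset = None,
                     B: int = 200, seed: int = 0):
        data = data or self.model.data
        return bootstrap_auc_interval(self.predict(data.covariates), data,
                                      t, B=B, seed=seed)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        p = self.params
        cols = self.model.data.columns
        try:
            se_pi, se_beta = self.bse()
        except Exception:  # singular information; report point estimates only
            se_pi = np.full(p.K, np.nan)
            se_beta = np.full_like(p.beta, np.nan)
        lines = [
            "Quasi-linear Cox proportional hazards model",
            "=" * 59,
            f"subjects: {self.model.data.n}    events: {self.model.data.n_events}"
            f"    components: {p.K}",
            f"log partial likelihood: {self.loglik:.4f}    "
            f"BIC: {self.bic:.4f}",
            f"converged: {self.converged} in {self.n_iter} sweeps",
            "-" * 59,
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
        ]
        for k in range(p.K):
            lines.append(f"{'pi_' + str(k + 1):<14}{p.pi[k]:>12.4f}"
                         f"{se_pi[k]:>12.4f}")
        for k in range(p.K):
            for j in range(p.p):
                name = f"beta_{k + 1}[{cols[j]}]"
                est = p.beta[k, j]
                tag = "  (zero)" if est == 0.0 else ""
                lines.append(f"{name:<14}{est:>12.4f}{se_beta[k, j]:>12.4f}{tag}")
        lines.append("=" * 59)
        return "\n".join(lines)

    def save(self, path) -> None:
        self._fit.save(path)

    def coefficient_frame(self) -> pd.DataFrame:
        """K rows: mixing proportion plus the coefficient vector."""
        df = pd.DataFrame(self.beta, columns=self.model.data.columns)
        df.insert(0, "pi", self.pi)
        df.index = [f"component_{k + 1}" for k in range(self.params.K)]
        return df

    def __repr__(self):
        return (f"<QuasiLinearCoxResults K={self.params.K} "
                f"loglik={self.loglik:.3f} converged={self.converged}>")
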