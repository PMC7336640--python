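"""Right-censored survival data containers and risk-set machinery.

A subject contributes the triple (x_i, t_i, delta_i): covariate vector,
observed time (event or censoring, whichever came first) and the event
indicator (1 = event observed).  Risk sets are defined as
R(t_i) = { l : t_l >= t_i }; ties are handled Breslow-style, every subject
whose time equals t_i is in R(t_i), and each event contributes its own
likelihood term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "RiskSetIndex", "build_risk_sets"]


@dataclass(frozen=True)
class SurvivalDataset:
    """Immutable container for right-censored survival data.

    Parameters
    ----------
    time : (n,) array of strictly positive observed times.
    event : (n,) array of 0/1 event indicators (1 = event observed).
    covariates : (n, p) covariate matrix with no missing values.
    columns : optional covariate names; defaults to x1..xp.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray
    columns: tuple = field(default=None)

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float).ravel()
        event = np.asarray(self.event).ravel()
        X = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if X.shape[0] != time.size and X.shape[1] == time.size:
            X = X.T
        if time.size < 1:
            raise ValueError("at least one subject is required")
        if event.size != time.size or X.shape[0] != time.size:
            raise ValueError(
                f"inconsistent sizes: {time.size} times, {event.size} events, "
                f"{X.shape[0]} covariate rows"
            )
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("times must be finite and strictly positive")
        ev = event.astype(float)
        if not np.all(np.isin(ev, (0.0, 1.0))):
            raise ValueError("event indicators must be 0 or 1")
        if not np.all(np.isfinite(X)):
            raise ValueError("covariates must be finite (no missing values)")
        cols = self.columns
        if cols is None:
            cols = tuple(f"x{j + 1}" for j in range(X.shape[1]))
        else:
            cols = tuple(cols)
            if len(cols) != X.shape[1]:
                raise ValueError("number of column names must equal p")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", ev.astype(np.int8))
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "columns", cols)

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    # -- interchange -----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time",
                       event_col: str = "event", covariates=None) -> "SurvivalDataset":
        """Build from a tidy DataFrame; non time/event columns are covariates."""
        for col in (time_col, event_col):
            if col not in df.columns:
                raise ValueError(f"required column {col!r} missing")
        if covariates is None:
            covariates = [c for c in df.columns if c not in (time_col, event_col)]
        if len(covariates) == 0:
            raise ValueError("no covariate columns found")
        return cls(
            time=df[time_col].to_numpy(),
            event=df[event_col].to_numpy(),
            covariates=df[covariates].to_numpy(),
            columns=tuple(covariates),
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "SurvivalDataset":
        # round_trip parsing so written datasets re-load bit-identically
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_dataframe(df, **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.time, "event": self.event.astype(int)})
        for j, name in enumerate(self.columns):
            df[name] = self.covariates[:, j]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def subset(self, idx) -> "SurvivalDataset":
        idx = np.asarray(idx)
        return SurvivalDataset(self.time[idx], self.event[idx],
                               self.covariates[idx], self.columns)


@dataclass(frozen=True)
class RiskSetIndex:
    """Time-sorted view of a dataset with per-subject risk sets.

    ``order`` is a stable permutation sorting subjects by increasing time;
    ``start`` maps each sorted position to the first sorted position of its
    tie block, so the risk set of the subject at sorted position i is
    ``order[start[i]:]`` (original indices).
    """

    order: np.ndarray
    sorted_time: np.ndarray
    start: np.ndarray

    def risk_set(self, i_sorted: int) -> np.ndarray:
        """Original indices of R(t) for the subject at sorted position i."""
        return self.order[self.start[i_sorted]:]

    def risk_sets_original(self) -> list:
        """Risk sets indexed by original subject index, sorted index arrays."""
        out = [None] * self.order.size
        for pos in range(self.order.size):
            out[self.order[pos]] = np.sort(self.risk_set(pos))
        return out


def build_risk_sets(data: SurvivalDataset) -> RiskSetIndex:
    """Index the risk sets R(t_i) = { l : t_l >= t_i } of a dataset."""
    order = np.argsort(data.time, kind="stable")
    ts = data.time[order]
    start = np.searchsorted(ts, ts, side="left")
    return RiskSetIndex(order=order, sorted_time=ts, start=start)
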