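"""Parameters of the quasi-linear Cox model.

The parameter is theta = (pi, beta): a mixing vector pi on the K-simplex
and a K x p coefficient matrix whose rows are the component linear
predictors.  A binary mask restricts the model to a prescribed covariate
partition (the restricted quasi-linear model): beta must be zero wherever
the mask is zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["QuasiLinearParams", "apply_restriction"]

_SIMPLEX_TOL = 1e-8


@dataclass(frozen=True)
class QuasiLinearParams:
    pi: np.ndarray
    beta: np.ndarray
    mask: np.ndarray = field(default=None)

    def __post_init__(self):
        pi = np.asarray(self.pi, dtype=float).ravel()
        beta = np.atleast_2d(np.asarray(self.beta, dtype=float))
        if pi.size != beta.shape[0]:
            raise ValueError(
                f"pi has {pi.size} components but beta has {beta.shape[0]} rows"
            )
        if pi.size < 1:
            raise ValueError("K >= 1 required")
        if np.any(pi <= 0):
            raise ValueError("mixing proportions must be strictly positive")
        if abs(pi.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError(f"mixing proportions sum to {pi.sum()!r}, not 1")
        mask = self.mask
        if mask is not None:
            mask = np.atleast_2d(np.asarray(mask)).astype(bool)
            if mask.shape != beta.shape:
                raise ValueError("mask shape must match beta shape")
            if np.any(beta[~mask] != 0.0):
                raise ValueError("beta must be zero where the mask is zero")
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "mask", mask)

    @property
    def K(self) -> int:
        return self.pi.size

    @property
    def p(self) -> int:
        return self.beta.shape[1]

    @property
    def support(self) -> np.ndarray:
        """Boolean K x p matrix of exactly nonzero coefficients."""
        return self.beta != 0.0

    def n_free(self) -> int:
        """Free parameter count: nonzero coefficients plus K-1 simplex dofs."""
        return int(np.count_nonzero(self.beta)) + (self.K - 1)

    def permuted(self, perm) -> "QuasiLinearParams":
        """Relabel components by the permutation ``perm``."""
        perm = np.asarray(perm)
        mask = self.mask[perm] if self.mask is not None else None
        return QuasiLinearParams(self.pi[perm], self.beta[perm], mask)

    def with_beta(self, beta) -> "QuasiLinearParams":
        return replace(self, beta=np.asarray(beta, dtype=float))

    def with_pi(self, pi) -> "QuasiLinearParams":
        return replace(self, pi=np.asarray(pi, dtype=float))

    def to_dict(self) -> dict:
        d = {"pi": self.pi.tolist(), "beta": self.beta.tolist()}
        if self.mask is not None:
            d["mask"] = self.mask.astype(int).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "QuasiLinearParams":
        mask = d.get("mask")
        return cls(np.asarray(d["pi"]), np.asarray(d["beta"]),
                   None if mask is None else np.asarray(mask))


def groups_to_mask(groups, K: int, p: int) -> np.ndarray:
    """Turn a covariate partition into a K x p admissibility mask.

    ``groups`` is a length-K sequence of iterables of 0-based covariate
    indices; blocks must be disjoint (they may cover only a subset of the
    covariates, and a block may be empty).
    """
    if len(groups) != K:
        raise ValueError(f"expected {K} covariate groups, got {len(groups)}")
    mask = np.zeros((K, p), dtype=bool)
    seen = set()
    for k, block in enumerate(groups):
        for j in block:
            j = int(j)
            if j < 0 or j >= p:
                raise ValueError(f"covariate index {j} outside 0..{p - 1}")
            if j in seen:
                raise ValueError(f"covariate index {j} appears in two groups")
            seen.add(j)
            mask[k, j] = True
    return mask


def apply_restriction(params: QuasiLinearParams, groups) -> QuasiLinearParams:
    """Restrict a parameter to disjoint covariate blocks, one per component.

    Component k keeps free coefficients only on its block; everything else
    is forced to zero, yielding the restricted quasi-linear predictor.
    """
    mask = groups_to_mask(groups, params.K, params.p)
    beta = np.where(mask, params.beta, 0.0)
    return QuasiLinearParams(params.pi, beta, mask)
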