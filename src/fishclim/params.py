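"""Parameter container for the inverse almost ideal demand system (IAIDS).

One demand system over ``n`` goods is described by the translog/IAIDS
utility parameters (alpha0, alpha_i, beta0, beta_i, gamma_ij).  The
utility-theoretic restriction set

* adding-up:    sum_i alpha_i = 1, sum_i beta_i = 0, sum_i gamma_ij = 0
* homogeneity:  sum_j gamma_ij = 0
* symmetry:     gamma_ij = gamma_ji

reduces the free-parameter count to ``(n-1) + (n-1) + n(n-1)/2`` (12 when
n = 4).  :class:`IaidsParams` stores the full parameter set, validates the
restrictions, and converts to/from the free-parameter vector used by the
SUR estimator and the delta method.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IaidsParams", "n_free_params"]


def n_free_params(n: int) -> int:
    """Free parameters of an n-good IAIDS under the full restriction set."""
    return (n - 1) + (n - 1) + n * (n - 1) // 2


@dataclass
class IaidsParams:
    """Utility parameters of one inverse almost ideal demand system.

    Parameters
    ----------
    alpha : (n,) array
        Share-equation intercepts; sum to 1.
    beta : (n,) array
        Scale (quantity-index) coefficients; sum to 0.
    gamma : (n, n) array
        Quantity coefficients; symmetric with zero row/column sums.
    alpha0, beta0 : float
        Translog constants. Not identified by the share equations; kept as
        normalizations (0 and 1) for the distance-function welfare stage.
    vcov : (k, k) array, optional
        Covariance of the free-parameter vector after estimation, with
        ``k = n_free_params(n)``.
    labels : list of str, optional
        Good names, in the order of ``alpha``.
    """

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    alpha0: float = 0.0
    beta0: float = 1.0
    vcov: np.ndarray | None = None
    labels: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma.shape != (self.n, self.n):
            raise ValueError(
                f"gamma must be {self.n}x{self.n}, got {self.gamma.shape}"
            )
        if self.beta.shape != (self.n,):
            raise ValueError("alpha and beta must have the same length")
        if self.beta0 <= 0:
            raise ValueError("beta0 must be positive")

    @property
    def n(self) -> int:
        return self.alpha.shape[0]

    @property
    def n_free(self) -> int:
        return n_free_params(self.n)

    def validate(self, atol: float = 1e-8) -> None:
        """Raise ValueError if any utility-theoretic restriction fails."""
        if abs(self.alpha.sum() - 1.0) > atol:
            raise ValueError(f"adding-up violated: sum(alpha) = {self.alpha.sum()}")
        if abs(self.beta.sum()) > atol:
            raise ValueError(f"adding-up violated: sum(beta) = {self.beta.sum()}")
        col = self.gamma.sum(axis=0)
        if np.max(np.abs(col)) > atol:
            raise ValueError(f"adding-up violated: column sums of gamma = {col}")
        row = self.gamma.sum(axis=1)
        if np.max(np.abs(row)) > atol:
            raise ValueError(f"homogeneity violated: row sums of gamma = {row}")
        if np.max(np.abs(self.gamma - self.gamma.T)) > atol:
            raise ValueError("symmetry violated: gamma != gamma'")

    # ---- free-parameter packing ------------------------------------------
    # theta = [alpha_1..alpha_{n-1}, beta_1..beta_{n-1},
    #          gamma_ij for 1 <= i <= j <= n-1]
    # The n-th good's parameters are recovered from adding-up/homogeneity.

    def to_free(self) -> np.ndarray:
        n = self.n
        parts = [self.alpha[: n - 1], self.beta[: n - 1]]
        g = [self.gamma[i, j] for i in range(n - 1) for j in range(i, n - 1)]
        return np.concatenate(parts + [np.asarray(g)])

    @classmethod
    def from_free(
        cls,
        theta: np.ndarray,
        n: int,
        *,
        alpha0: float = 0.0,
        beta0: float = 1.0,
        vcov: np.ndarray | None = None,
        labels: list[str] | None = None,
    ) -> "IaidsParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (n_free_params(n),):
            raise ValueError(
                f"expected {n_free_params(n)} free parameters, got {theta.shape}"
            )
        alpha = np.empty(n)
        beta = np.empty(n)
        alpha[: n - 1] = theta[: n - 1]
        alpha[n - 1] = 1.0 - alpha[: n - 1].sum()
        beta[: n - 1] = theta[n - 1 : 2 * (n - 1)]
        beta[n - 1] = -beta[: n - 1].sum()
        gamma = np.zeros((n, n))
        k = 2 * (n - 1)
        for i in range(n - 1):
            for j in range(i, n - 1):
                gamma[i, j] = gamma[j, i] = theta[k]
                k += 1
        # homogeneity pins the last column; symmetry the last row
        gamma[: n - 1, n - 1] = -gamma[: n - 1, : n - 1].sum(axis=1)
        gamma[n - 1, : n - 1] = gamma[: n - 1, n - 1]
        gamma[n - 1, n - 1] = -gamma[n - 1, : n - 1].sum()
        return cls(
            alpha=alpha, beta=beta, gamma=gamma, alpha0=alpha0, beta0=beta0,
            vcov=vcov, labels=labels,
        )

    def permuted(self, order: np.ndarray) -> "IaidsParams":
        """Return a copy with goods reordered by ``order`` (vcov dropped)."""
        order = np.asarray(order)
        labels = [self.labels[i] for i in order] if self.labels else None
        return IaidsParams(
            alpha=self.alpha[order],
            beta=self.beta[order],
            gamma=self.gamma[np.ix_(order, order)],
            alpha0=self.alpha0,
            beta0=self.beta0,
            labels=labels,
        )
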