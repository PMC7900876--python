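"""Inverse almost ideal demand system (IAIDS): estimation and flexibilities.

The IAIDS models dockside (ex-vessel) prices as responding to exogenous
landings: the expenditure share of good ``i`` is linear in log quantities
and a log quantity index,

    w_i = alpha_i + sum_j gamma_ij ln q_j + beta_i ln Q,

with the Stone (linear-approximate) index ln Q = sum_j w_j ln q_j.  The
system is estimated by iterated feasible GLS on the stacked share
equations (a seemingly unrelated regression), with the adding-up,
homogeneity and symmetry restrictions substituted into the design so they
hold exactly.  The n-th equation is dropped (adding-up makes the error
covariance singular) and its parameters recovered from the restrictions.

Uncompensated quantity flexibilities at mean shares follow
Eales & Unnevehr's linear-approximate form

    f_ij = -delta_ij + (gamma_ij + beta_i wbar_j) / wbar_i,

and the "elasticity" counterparts reported in the output tables are the
entries of the inverse flexibility matrix.
Confidence bands come from the delta method on the free-parameter
covariance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .params import IaidsParams, n_free_params

__all__ = [
    "stone_index",
    "predict_shares",
    "solve_share_fixed_point",
    "InverseAIDS",
    "estimate_sur",
    "flexibilities",
    "FlexibilityTable",
    "delta_method_ci",
]


def stone_index(w: np.ndarray, lnq: np.ndarray) -> np.ndarray | float:
    """Stone log-quantity index ln Q = sum_j w_j ln q_j.

    ``w`` and ``lnq`` may be single observations (1-d) or stacked rows.
    """
    w = np.asarray(w, dtype=float)
    lnq = np.asarray(lnq, dtype=float)
    return (w * lnq).sum(axis=-1)


def predict_shares(p: IaidsParams, lnq: np.ndarray, lnQ) -> np.ndarray:
    """Evaluate the IAIDS share equations at given log quantities and index.

    Under the restriction set the returned shares sum to one identically.
    Accepts a single observation (1-d lnq, scalar lnQ) or stacked rows.
    """
    lnq = np.asarray(lnq, dtype=float)
    lnQ = np.asarray(lnQ, dtype=float)
    return p.alpha + lnq @ p.gamma.T + np.multiply.outer(lnQ, p.beta)


def solve_share_fixed_point(p: IaidsParams, lnq: np.ndarray) -> tuple[np.ndarray, float]:
    """Shares consistent with the Stone index at given log quantities.

    With ln Q = w' ln q substituted into the share equations, the index
    solves in closed form:

        ln Q = (alpha + Gamma ln q)' ln q / (1 - beta' ln q).

    Returns ``(w, lnQ)``.  Raises if the denominator is (near) zero, which
    only happens at extreme quantity configurations.
    """
    lnq = np.asarray(lnq, dtype=float)
    denom = 1.0 - float(p.beta @ lnq)
    if abs(denom) < 1e-10:
        raise ValueError("Stone-index fixed point degenerate: 1 - beta'lnq ~ 0")
    lnQ = float((p.alpha + p.gamma @ lnq) @ lnq) / denom
    return predict_shares(p, lnq, lnQ), lnQ


# ---------------------------------------------------------------------------
# SUR estimation
# ---------------------------------------------------------------------------


class InverseAIDS:
    """Restricted SUR estimator for one inverse almost ideal demand system.

    scikit-learn style: configure, ``fit(lnq, w)``, then read fitted
    attributes (trailing underscore) or ``predict(lnq)``.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the relative parameter change of the
        iterated feasible GLS.
    max_iter : int
        Maximum FGLS iterations.
    drop_equation : int or None
        Index of the share equation dropped during estimation (default:
        the last good). Estimates are equivariant to this choice on
        noise-free data.

    Attributes
    ----------
    params_ : IaidsParams
        Recovered full parameter set (restrictions hold exactly), with
        the free-parameter covariance attached.
    theta_ : ndarray
        Free-parameter vector (length 12 for four goods).
    vcov_ : ndarray
        Covariance of ``theta_``.
    mean_shares_ : ndarray
        Sample mean expenditure shares (used for flexibilities).
    mean_lnq_ : ndarray, mean_lnQ_ : float
        Sample means of the regressors; the fitted system passes through
        them exactly, which anchors out-of-sample forecasting.
    n_iter_ : int
        FGLS iterations used.
    sigma_ : ndarray
        Residual covariance of the kept equations.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100,
                 drop_equation: int | None = None):
        self.tol = tol
        self.max_iter = max_iter
        self.drop_equation = drop_equation

    # -- sklearn plumbing ---------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {"tol": self.tol, "max_iter": self.max_iter,
                "drop_equation": self.drop_equation}

    def set_params(self, **kw) -> "InverseAIDS":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -----------------------------------------------------------------------
    def fit(self, lnq: np.ndarray, w: np.ndarray,
            labels: list[str] | None = None) -> "InverseAIDS":
        """Estimate the system from T observations of n goods.

        Parameters
        ----------
        lnq : (T, n) array of log quantities.
        w : (T, n) array of expenditure shares, each row summing to 1.
        labels : optional good names attached to the result.
        """
        lnq = np.asarray(lnq, dtype=float)
        w = np.asarray(w, dtype=float)
        if lnq.ndim != 2 or w.shape != lnq.shape:
            raise ValueError("lnq and w must be (T, n) arrays of equal shape")
        T, n = lnq.shape
        if n < 2:
            raise ValueError("need at least two goods")
        if np.max(np.abs(w.sum(axis=1) - 1.0)) > 1e-6:
            raise ValueError("share rows must sum to 1")
        k = n_free_params(n)
        if T < 3 * k:
            raise ValueError(
                f"need at least {3 * k} observations for {k} free parameters, got {T}"
            )

        drop = self.drop_equation if self.drop_equation is not None else n - 1
        if not 0 <= drop < n:
            raise ValueError("drop_equation out of range")
        # reorder goods so the dropped equation is last
        order = np.array([i for i in range(n) if i != drop] + [drop])
        inv_order = np.argsort(order)
        lnq_o = lnq[:, order]
        w_o = w[:, order]

        r = lnq_o[:, : n - 1] - lnq_o[:, [n - 1]]  # relative log quantities
        y = w_o[:, : n - 1].T.reshape(-1)  # equation-major stacking

        # Estimate with an iterated Stone index: start from the observed-
        # share index, then rebuild it from fitted fixed-point shares and
        # re-estimate.  The observed-share index carries the same
        # measurement error as the dependent shares (a simultaneity that
        # biases beta); the fitted index is a function of quantities only,
        # so the refit is free of it.  On noise-free data the first pass is
        # already exact and the loop stops immediately.
        lnQ = np.asarray(stone_index(w_o, lnq_o))
        theta = None
        for outer in range(20):
            X = self._design(r, lnQ, n, T, k)
            if np.linalg.matrix_rank(
                    np.column_stack([np.ones(T), r, lnQ])) < n + 1:
                raise ValueError(
                    "degenerate regressors: constant or collinear log "
                    "quantities / quantity index"
                )
            theta_prev = theta
            theta, sigma, vcov, n_iter, exact = self._fgls(X, y, n, T, k)
            if exact:
                break
            p_cur = IaidsParams.from_free(theta, n)
            w_fit = np.vstack([
                solve_share_fixed_point(p_cur, lnq_o[t])[0] for t in range(T)
            ])
            lnQ = np.asarray(stone_index(w_fit, lnq_o))
            if theta_prev is not None and np.max(
                    np.abs(theta - theta_prev)) < self.tol:
                break

        params_o = IaidsParams.from_free(theta, n)
        params = params_o.permuted(inv_order)
        params.vcov = vcov  # covariance in the *estimation* ordering
        params.labels = labels
        params.validate(atol=1e-7)

        self.n_features_in_ = n
        self.order_ = order
        self.theta_ = theta
        self.vcov_ = vcov
        self.sigma_ = sigma
        self.n_iter_ = n_iter
        self.params_ = params
        self.mean_shares_ = w.mean(axis=0)
        self.mean_lnq_ = lnq.mean(axis=0)
        self.mean_lnQ_ = float(np.mean(lnQ))
        return self

    def _fgls(self, X: np.ndarray, y: np.ndarray, n: int, T: int,
              k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, bool]:
        """One iterated-FGLS pass at a fixed quantity index.

        Returns (theta, sigma, vcov, n_iter, exact_fit).
        """
        theta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = (y - X @ theta).reshape(n - 1, T)
        if np.max(np.abs(resid)) < 1e-9:
            # exact fit (noise-free data): OLS solution is the GLS solution
            return theta, np.zeros((n - 1, n - 1)), np.zeros((k, k)), 0, True
        for n_iter in range(1, self.max_iter + 1):
            sigma = resid @ resid.T / T
            if np.linalg.cond(sigma) > 1e12:
                raise np.linalg.LinAlgError(
                    "singular residual covariance; the share equations are "
                    "collinear -- more (or more informative) data needed"
                )
            A = linalg.inv(sigma)
            XtWX, XtWy = self._gls_moments(X, y, A, n, T)
            theta_new = linalg.solve(XtWX, XtWy, assume_a="pos")
            rel = np.max(np.abs(theta_new - theta)) / max(
                1.0, np.max(np.abs(theta))
            )
            theta = theta_new
            resid = (y - X @ theta).reshape(n - 1, T)
            if rel < self.tol:
                break
        else:
            raise RuntimeError(
                f"iterated FGLS did not converge in {self.max_iter} "
                f"iterations (last relative change {rel:.3e})"
            )
        sigma = resid @ resid.T / T
        A = linalg.inv(sigma)
        XtWX, _ = self._gls_moments(X, y, A, n, T)
        return theta, sigma, linalg.inv(XtWX), n_iter, False

    @staticmethod
    def _design(r: np.ndarray, lnQ: np.ndarray, n: int, T: int, k: int) -> np.ndarray:
        """Stacked design matrix mapping free parameters to kept equations.

        theta = [alpha_1..n-1, beta_1..n-1, gamma_ij (i<=j<=n-1)];
        equation i regresses w_i on 1, lnQ and the relative log
        quantities, with symmetry tying gamma_ij across equations.
        """
        m = n - 1
        X = np.zeros((m * T, k))
        for i in range(m):
            rows = slice(i * T, (i + 1) * T)
            X[rows, i] = 1.0          # alpha_i
            X[rows, m + i] = lnQ      # beta_i
        col = 2 * m
        for i in range(m):
            for j in range(i, m):
                X[i * T : (i + 1) * T, col] += r[:, j]
                if i != j:
                    X[j * T : (j + 1) * T, col] += r[:, i]
                col += 1
        return X

    @staticmethod
    def _gls_moments(X: np.ndarray, y: np.ndarray, A: np.ndarray,
                     n: int, T: int) -> tuple[np.ndarray, np.ndarray]:
        """X' (A kron I_T) X and X' (A kron I_T) y without forming the kron."""
        m = n - 1
        k = X.shape[1]
        XtWX = np.zeros((k, k))
        XtWy = np.zeros(k)
        blocks = [X[i * T : (i + 1) * T] for i in range(m)]
        ys = [y[i * T : (i + 1) * T] for i in range(m)]
        for i in range(m):
            for j in range(m):
                if A[i, j] == 0.0:
                    continue
                XtWX += A[i, j] * blocks[i].T @ blocks[j]
                XtWy += A[i, j] * blocks[i].T @ ys[j]
        return XtWX, XtWy

    def predict(self, lnq: np.ndarray) -> np.ndarray:
        """Predicted shares at new log quantities.

        The Stone index is evaluated with the sample-mean shares, anchored
        at the sample means, so prediction at the sample-mean quantities
        returns the sample-mean shares exactly (the GLS normal equations
        zero each equation's mean residual).
        """
        self._check_fitted()
        lnq = np.atleast_2d(np.asarray(lnq, dtype=float))
        lnQ = self.mean_lnQ_ + (lnq - self.mean_lnq_) @ self.mean_shares_
        return predict_shares(self.params_, lnq, lnQ)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("InverseAIDS instance is not fitted yet")


def estimate_sur(lnq: np.ndarray, w: np.ndarray, *,
                 labels: list[str] | None = None, tol: float = 1e-8,
                 max_iter: int = 100) -> IaidsParams:
    """Functional wrapper: fit an :class:`InverseAIDS` and return the params."""
    return InverseAIDS(tol=tol, max_iter=max_iter).fit(lnq, w, labels=labels).params_


# ---------------------------------------------------------------------------
# Flexibilities / elasticities
# ---------------------------------------------------------------------------


@dataclass
class FlexibilityTable:
    """Quantity flexibilities and their inverse-matrix elasticities.

    ``flexibility[i, j]`` is d ln p_i / d ln q_j at mean shares;
    ``elasticity`` is the matrix inverse of ``flexibility`` (NaN if the
    flexibility matrix is singular).  ``*_lo``/``*_hi`` are delta-method
    inner-95th-percentile bounds for the own (diagonal) terms, present
    when a parameter covariance was available.
    """

    flexibility: np.ndarray
    elasticity: np.ndarray
    labels: list[str] | None = None
    own_flex_lo: np.ndarray | None = None
    own_flex_hi: np.ndarray | None = None
    own_elas_lo: np.ndarray | None = None
    own_elas_hi: np.ndarray | None = None


def _flex_matrix(p: IaidsParams, wbar: np.ndarray) -> np.ndarray:
    wbar = np.asarray(wbar, dtype=float)
    n = p.n
    return (-np.eye(n)
            + (p.gamma + np.outer(p.beta, wbar)) / wbar[:, None])


def flexibilities(p: IaidsParams, wbar: np.ndarray, *,
                  compute_ci: bool = True) -> FlexibilityTable:
    """Uncompensated flexibility matrix at mean shares, plus elasticities.

    Raises ValueError on non-positive mean shares.  A singular flexibility
    matrix yields NaN elasticities with a warning (the flexibilities are
    still returned).
    """
    wbar = np.asarray(wbar, dtype=float)
    if np.any(wbar <= 0):
        raise ValueError("mean shares must be strictly positive")
    F = _flex_matrix(p, wbar)
    try:
        E = linalg.inv(F)
    except linalg.LinAlgError:
        warnings.warn("singular flexibility matrix; elasticities set to NaN")
        E = np.full_like(F, np.nan)
    table = FlexibilityTable(flexibility=F, elasticity=E, labels=p.labels)
    if compute_ci and p.vcov is not None:
        n = p.n
        lo_f = np.empty(n); hi_f = np.empty(n)
        lo_e = np.empty(n); hi_e = np.empty(n)
        for i in range(n):
            lo_f[i], hi_f[i] = delta_method_ci(
                p, lambda q, i=i: _flex_matrix(q, wbar)[i, i])
            lo_e[i], hi_e[i] = delta_method_ci(
                p, lambda q, i=i: linalg.inv(_flex_matrix(q, wbar))[i, i])
        table.own_flex_lo, table.own_flex_hi = lo_f, hi_f
        table.own_elas_lo, table.own_elas_hi = lo_e, hi_e
    return table


def delta_method_ci(p: IaidsParams, statistic, *, h: float = 1e-6,
                    z: float = 1.96) -> tuple[float, float]:
    """Delta-method inner-95th-percentile interval for a statistic.

    ``statistic`` maps an :class:`IaidsParams` to a scalar and must be
    differentiable in the free parameters.  The gradient is taken by
    central differences in free-parameter space; the interval is
    point +/- z * sqrt(g' V g).

    Note: ``p.vcov`` is stored in the estimation ordering produced by
    :class:`InverseAIDS` with its default equation drop (last good), which
    matches ``p.to_free()``.
    """
    if p.vcov is None:
        raise ValueError("parameter covariance (vcov) missing; estimate first")
    theta = p.to_free()
    point = float(statistic(p))
    g = np.empty_like(theta)
    for k in range(theta.size):
        step = h * max(1.0, abs(theta[k]))
        tp = theta.copy(); tp[k] += step
        tm = theta.copy(); tm[k] -= step
        pp = IaidsParams.from_free(tp, p.n, alpha0=p.alpha0, beta0=p.beta0)
        pm = IaidsParams.from_free(tm, p.n, alpha0=p.alpha0, beta0=p.beta0)
        g[k] = (float(statistic(pp)) - float(statistic(pm))) / (2 * step)
    se = float(np.sqrt(g @ p.vcov @ g))
    return point - z * se, point + z * se
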