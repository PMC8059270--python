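"""Vermunt's 3-step class-membership regression with classification-error
correction (the maximum-likelihood / modal-assignment variant, as in the
R3STEP procedure).

Step 1 fits the unconditional mixture; step 2 assigns modal classes W_i and
quantifies the classification error Q[s, t] = P(assigned = s | true = t)
from the step-1 posteriors; step 3 regresses true class membership on
covariates by maximising

    L(gamma) = sum_i log sum_t P(C = t | x_i; gamma) * Q[W_i, t]

where P(C = t | x) is a multinomial logit with a chosen reference class.
Treating the modal assignment as error-free (Q = I) attenuates covariate
effects toward the null; fixing Q at its step-2 estimate removes that bias.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from trajmix.gmm_core import assign_modal

logger = logging.getLogger(__name__)

__all__ = ["MisclassMatrix", "ThreeStepResult", "misclassification_matrix", "fit_step3", "naive_step3"]

_Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass(frozen=True)
class MisclassMatrix:
    """K x K conditional probabilities Q[s, t] = P(assigned = s | true = t)."""

    Q: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
            raise ValueError("Q must be square")
        if np.any(Q < 0) or np.any(Q > 1):
            raise ValueError("Q entries must be in [0, 1]")
        if not np.allclose(Q.sum(axis=0), 1.0, atol=1e-8):
            raise ValueError("Q columns must sum to 1")
        object.__setattr__(self, "Q", Q)

    @property
    def K(self) -> int:
        return self.Q.shape[0]

    @classmethod
    def identity(cls, K: int) -> "MisclassMatrix":
        return cls(Q=np.eye(K))


@dataclass(frozen=True)
class ThreeStepResult:
    """Step-3 multinomial coefficients, their covariance and the OR table.

    ``gamma`` has one row per non-reference class and one column per design
    column (intercept first); ``or_table`` lists odds ratios with Wald 95%
    CIs for every class x covariate-level contrast (reference rows have OR 1).
    """

    gamma: np.ndarray
    cov_gamma: np.ndarray
    or_table: pd.DataFrame
    reference_class: int
    reference_level: str
    loglik: float
    converged: bool
    class_labels: tuple[int, ...]
    covariate_levels: tuple[str, ...]


def misclassification_matrix(posteriors: np.ndarray, labels: np.ndarray | None = None) -> MisclassMatrix:
    """Step-2 classification-error matrix from posteriors and modal labels.

    Q[s, t] = sum_i p_it 1[W_i = s] / sum_i p_it.  Zero cells are floored at
    1e-12 and columns renormalised, so downstream logs stay finite.
    """
    p = np.asarray(posteriors, dtype=float)
    n, K = p.shape
    W = assign_modal(p) if labels is None else np.asarray(labels, dtype=int)
    col_tot = p.sum(axis=0)
    empty = np.nonzero(col_tot <= 0)[0]
    if empty.size:
        raise ValueError(f"class {empty[0] + 1} has zero total posterior mass")
    Q = np.zeros((K, K))
    for s in range(K):
        Q[s, :] = p[W == s + 1].sum(axis=0)
    Q /= col_tot[None, :]
    Q = np.maximum(Q, 1e-12)
    Q /= Q.sum(axis=0, keepdims=True)
    return MisclassMatrix(Q=Q)


def _design(covariates, reference_level: str | None):
    """Intercept + dummy design from a categorical Series or a ready matrix."""
    if isinstance(covariates, (pd.Series, list, np.ndarray)) and not (
        isinstance(covariates, np.ndarray) and covariates.ndim == 2
    ):
        s = pd.Series(covariates).astype(str)
        levels = list(pd.unique(s))
        if reference_level is None:
            reference_level = levels[0]
        if reference_level not in levels:
            raise ValueError(f"reference level {reference_level!r} not among {levels}")
        others = [lv for lv in levels if lv != reference_level]
        X = np.column_stack([np.ones(len(s))] + [(s == lv).to_numpy(float) for lv in others])
        return X, reference_level, tuple(others)
    X = np.asarray(covariates, dtype=float)
    names = tuple(f"x{j}" for j in range(1, X.shape[1]))
    return X, (reference_level or "(baseline)"), names


def _loglik_grad(gam_flat, X, Wm1, Q, K, ref0):
    n, P = X.shape
    t_free = [t for t in range(K) if t != ref0]
    gam = gam_flat.reshape(K - 1, P)
    eta = np.zeros((n, K))
    eta[:, t_free] = X @ gam.T
    eta -= eta.max(axis=1, keepdims=True)
    pi = np.exp(eta)
    pi /= pi.sum(axis=1, keepdims=True)
    qi = Q[Wm1, :]  # (n, K)
    num = pi * qi
    den = num.sum(axis=1)
    ll = float(np.log(den).sum())
    w = num / den[:, None]
    diff = (w - pi)[:, t_free]  # (n, K-1)
    grad = diff.T @ X  # (K-1, P)
    return -ll, -grad.ravel()


def _num_hessian(fun, x0, step=1e-5):
    d = x0.size
    H = np.zeros((d, d))
    for a in range(d):
        for b in range(a, d):
            ea = np.eye(1, d, a)[0] * step
            eb = np.eye(1, d, b)[0] * step
            f_pp = fun(x0 + ea + eb)
            f_pm = fun(x0 + ea - eb)
            f_mp = fun(x0 - ea + eb)
            f_mm = fun(x0 - ea - eb)
            H[a, b] = H[b, a] = (f_pp - f_pm - f_mp + f_mm) / (4 * step**2)
    return H


def fit_step3(
    labels: np.ndarray,
    Q: MisclassMatrix,
    covariates,
    reference_class: int = 1,
    reference_level: str | None = None,
) -> ThreeStepResult:
    """Step-3 multinomial regression with fixed classification-error logits.

    ``labels`` are modal class assignments (1-based); ``Q`` the step-2 error
    matrix; ``covariates`` a categorical Series (dummy-coded against
    ``reference_level``) or a ready design matrix with an intercept column.
    Wald 95% CIs come from the inverse observed information (central-
    difference Hessian).
    """
    W = np.asarray(labels, dtype=int)
    K = Q.K
    if W.min() < 1 or W.max() > K:
        raise ValueError("labels must be 1..K")
    if not (1 <= reference_class <= K):
        raise ValueError("reference_class must be 1..K")
    X, ref_level, level_names = _design(covariates, reference_level)
    n, P = X.shape
    ref0 = reference_class - 1
    gam0 = np.zeros((K - 1) * P)
    res = minimize(
        _loglik_grad,
        gam0,
        args=(X, W - 1, Q.Q, K, ref0),
        jac=True,
        method="BFGS",
        options={"maxiter": 500, "gtol": 1e-8},
    )
    gam = res.x.reshape(K - 1, P)
    if np.abs(gam).max() > 15:
        warnings.warn("possible separation: |gamma| > 15", stacklevel=2)

    def nll(v):
        return _loglik_grad(v, X, W - 1, Q.Q, K, ref0)[0]

    H = _num_hessian(nll, res.x)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full_like(H, np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0, None)).reshape(K - 1, P)

    classes_free = [t + 1 for t in range(K) if t != ref0]
    rows = []
    for r, cls in enumerate(classes_free):
        for j, lv in enumerate(level_names, start=1):
            g, s = gam[r, j], se[r, j]
            rows.append((cls, lv, np.exp(g), np.exp(g - _Z95 * s), np.exp(g + _Z95 * s), s))
        rows.append((cls, ref_level, 1.0, 1.0, 1.0, 0.0))
    or_table = pd.DataFrame(
        rows, columns=["class", "covariate_level", "or", "ci_low", "ci_high", "se_logor"]
    ).sort_values(["class", "covariate_level"], kind="stable", ignore_index=True)
    return ThreeStepResult(
        gamma=gam,
        cov_gamma=cov,
        or_table=or_table,
        reference_class=reference_class,
        reference_level=ref_level,
        loglik=-res.fun,
        converged=bool(res.success),
        class_labels=tuple(classes_free),
        covariate_levels=level_names,
    )


def naive_step3(
    labels: np.ndarray,
    covariates,
    reference_class: int = 1,
    reference_level: str | None = None,
) -> ThreeStepResult:
    """Uncorrected comparison: modal class treated as observed (Q = I).

    This is an ordinary multinomial logit of the modal assignment on the
    covariates; with imperfect classification its effects are attenuated
    toward the null relative to :func:`fit_step3`.
    """
    K = int(np.max(labels))
    return fit_step3(labels, MisclassMatrix.identity(K), covariates, reference_class, reference_level)
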