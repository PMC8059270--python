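"""Internal vectorised EM machinery for the growth mixture model.

Subjects are grouped by their observed-sweep pattern so that all linear
algebra runs as batched (G, m, m) operations.  The M-step is an ECM sweep:
mixing proportions and fixed effects have closed forms (mean of posteriors,
posterior-weighted GLS); the covariance parameters (sweep/class residual SDs,
AR(1) correlations, random-effect variances) are updated by L-BFGS on
unconstrained transforms with an analytic gradient of the expected
complete-data log-likelihood.  Each conditional update is non-decreasing in
the EM objective, so the observed-data log-likelihood is monotone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

_LOG2PI = np.log(2.0 * np.pi)
_BIG = 1e12


class StartCollapsed(RuntimeError):
    """A start degenerated (empty class or vanishing residual SD)."""


# ---------------------------------------------------------------------------
# Packing
# ---------------------------------------------------------------------------


@dataclass
class Group:
    idx: np.ndarray  # subject positions, (G,)
    J: np.ndarray  # sweep indices (1-based), (m,)
    T: np.ndarray  # centered ages, (G, m)
    Y: np.ndarray  # BMI, (G, m)
    X: np.ndarray  # fixed-effect design, (G, m, p)
    Z: np.ndarray  # random-effect design, (G, m, q)
    lag: np.ndarray  # |j_a - j_b|, (m, m)


@dataclass
class Packed:
    groups: list[Group]
    ids: tuple[str, ...]
    n: int
    S: int


def design_matrices(t: np.ndarray, degree: int, q: int) -> tuple[np.ndarray, np.ndarray]:
    """Polynomial fixed design (..., degree+1) and RE design (..., q)."""
    t = np.asarray(t, dtype=float)
    X = np.stack([t**d for d in range(degree + 1)], axis=-1)
    if q == 0:
        Z = np.zeros(t.shape + (0,))
    else:
        Z = X[..., :q].copy()
    return X, Z


def pack(ds, degree: int, q: int) -> Packed:
    """Group subjects by observed sweep pattern and build design arrays."""
    buckets: dict[tuple[int, ...], list[int]] = {}
    subs = ds.subjects
    for i, s in enumerate(subs):
        buckets.setdefault(tuple(int(j) for j in s.sweeps()), []).append(i)
    groups = []
    for J, idx in sorted(buckets.items()):
        idx = np.asarray(idx)
        T = np.stack([subs[i].ages() for i in idx])
        Y = np.stack([subs[i].bmis() for i in idx])
        X, Z = design_matrices(T, degree, q)
        Ja = np.asarray(J)
        lag = np.abs(Ja[:, None] - Ja[None, :]).astype(float)
        groups.append(Group(idx=idx, J=Ja, T=T, Y=Y, X=X, Z=Z, lag=lag))
    return Packed(groups=groups, ids=tuple(s.id for s in subs), n=len(subs), S=ds.n_sweeps)


# ---------------------------------------------------------------------------
# Covariance assembly
# ---------------------------------------------------------------------------


def _psi_matrix(pk, q: int) -> np.ndarray | None:
    if q == 0:
        return None
    if q == 1:
        return np.array([[pk.psi[0, 0]]]) if pk.psi.shape[0] > 0 else None
    return pk.psi


def group_cov(g: Group, pk, q: int, ar1: bool) -> np.ndarray:
    """V = Z Psi Z' + R for every subject in a pattern group, (G, m, m)."""
    sig = pk.sigma[g.J - 1]
    if ar1 and pk.rho is not None:
        R = np.outer(sig, sig) * pk.rho**g.lag
    else:
        R = np.diag(sig**2)
    if q > 0:
        V = np.einsum("gmq,qr,gnr->gmn", g.Z, pk.psi[:q, :q], g.Z) + R
    else:
        G = g.T.shape[0]
        V = np.broadcast_to(R, (G, R.shape[0], R.shape[1])).copy()
    return V


def _chol_logdet(V: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(V)  # LinAlgError if any not PD
    return 2.0 * np.log(np.diagonal(L, axis1=-2, axis2=-1)).sum(axis=-1)


def logdens_matrix(packed: Packed, params, spec) -> np.ndarray:
    """Per-subject per-class Gaussian log-density, (n, K)."""
    K = len(params)
    q = spec.n_random_effects
    out = np.empty((packed.n, K))
    for g in packed.groups:
        m = g.J.size
        for k, pk in enumerate(params):
            V = group_cov(g, pk, q, spec.ar1)
            logdet = _chol_logdet(V)
            resid = g.Y - g.X @ pk.beta
            sol = np.linalg.solve(V, resid[..., None])[..., 0]
            quad = np.einsum("gm,gm->g", resid, sol)
            out[g.idx, k] = -0.5 * (m * _LOG2PI + logdet + quad)
    return out


def estep(packed: Packed, params, spec) -> tuple[np.ndarray, float]:
    """Posterior class probabilities and the observed-data log-likelihood."""
    logphi = logdens_matrix(packed, params, spec)
    logpi = np.log(np.array([pk.pi for pk in params]))
    a = logphi + logpi[None, :]
    amax = a.max(axis=1, keepdims=True)
    lse = amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1))
    post = np.exp(a - lse[:, None])
    return post, float(lse.sum())


# ---------------------------------------------------------------------------
# Covariance parameter vector (ties + unconstrained transforms)
# ---------------------------------------------------------------------------


class CovLayout:
    """Maps spec flags to a flat unconstrained covariance parameter vector.

    Blocks, in order: log residual SDs (shape by class-specific /
    heteroskedastic flags), log intercept variance(s), log slope variance,
    intercept-slope covariance (raw), atanh AR correlation(s).
    """

    def __init__(self, spec):
        self.spec = spec
        K, S = spec.K, spec.n_sweeps
        self.cs = spec.class_specific_residuals
        self.het = spec.heteroskedastic_over_sweeps
        self.q = spec.n_random_effects
        self.sigma_shape = (
            (K, S) if (self.cs and self.het) else (1, S) if self.het else (K, 1) if self.cs else (1, 1)
        )
        n_sigma = self.sigma_shape[0] * self.sigma_shape[1]
        self.n_psi0 = (K if spec.class_specific_intercept_var else 1) if self.q >= 1 else 0
        self.n_psi1 = 1 if self.q >= 2 else 0
        self.n_c = 1 if (self.q >= 2 and spec.estimate_intercept_slope_cov) else 0
        self.rho_per_class = spec.ar1 and self.cs and not spec.shared_rho
        self.n_rho = (K if self.rho_per_class else 1) if spec.ar1 else 0
        sizes = [n_sigma, self.n_psi0, self.n_psi1, self.n_c, self.n_rho]
        edges = np.cumsum([0] + sizes)
        names = ["sigma", "psi0", "psi1", "c", "rho"]
        self.sl = {nm: slice(int(a), int(b)) for nm, a, b in zip(names, edges[:-1], edges[1:])}
        self.size = int(edges[-1])

    def to_vector(self, params) -> np.ndarray:
        spec = self.spec
        theta = np.zeros(self.size)
        ks, ss = self.sigma_shape
        sig = np.stack([pk.sigma for pk in params[:ks]])[:, : (ss if ss > 1 else 1)]
        theta[self.sl["sigma"]] = np.log(sig).ravel()
        if self.n_psi0:
            vals = [params[k].psi[0, 0] for k in range(self.n_psi0)]
            theta[self.sl["psi0"]] = np.log(vals)
        if self.n_psi1:
            theta[self.sl["psi1"]] = np.log(params[0].psi[1, 1])
        if self.n_c:
            theta[self.sl["c"]] = params[0].psi[0, 1]
        if self.n_rho:
            vals = [params[k].rho for k in range(self.n_rho)]
            theta[self.sl["rho"]] = np.arctanh(np.clip(vals, -0.999999, 0.999999))
        return theta

    def expand(self, theta: np.ndarray):
        """Per-class (sigma (K,S), psi (K,2,2) or None, rho (K,) or None)."""
        spec = self.spec
        K, S = spec.K, spec.n_sweeps
        ks, ss = self.sigma_shape
        sig = np.exp(theta[self.sl["sigma"]]).reshape(ks, ss)
        sig = np.broadcast_to(sig, (ks, S)) if ss == 1 else sig
        sig = np.broadcast_to(sig, (K, S))
        psi = None
        if self.q >= 1:
            psi0 = np.exp(theta[self.sl["psi0"]])
            psi0 = np.broadcast_to(psi0, (K,)) if self.n_psi0 == 1 else psi0
            psi = np.zeros((K, self.q, self.q))
            psi[:, 0, 0] = psi0
            if self.q >= 2:
                psi[:, 1, 1] = np.exp(theta[self.sl["psi1"]])[0]
                c = theta[self.sl["c"]][0] if self.n_c else 0.0
                psi[:, 0, 1] = psi[:, 1, 0] = c
        rho = None
        if spec.ar1:
            r = np.tanh(theta[self.sl["rho"]])
            rho = np.broadcast_to(r, (K,)) if self.n_rho == 1 else r
        return np.array(sig, dtype=float), psi, rho

    def apply(self, theta: np.ndarray, params) -> list:
        """Return a new params list with covariance blocks from ``theta``."""
        sig, psi, rho = self.expand(theta)
        out = []
        for k, pk in enumerate(params):
            out.append(
                pk.__class__(
                    pi=pk.pi,
                    beta=pk.beta,
                    psi=(psi[k] if psi is not None else pk.psi),
                    sigma=sig[k].copy(),
                    rho=(float(rho[k]) if rho is not None else pk.rho),
                )
            )
        return out

    def reduce_grads(self, theta, g_sigma, g_psi0, g_psi1, g_c, g_rho) -> np.ndarray:
        """Sum raw per-class/per-sweep grads into tied slots, chain-ruled."""
        spec = self.spec
        grad = np.zeros(self.size)
        sig, psi, rho = self.expand(theta)
        ks, ss = self.sigma_shape
        gs = g_sigma * sig  # d/d log sigma, (K, S)
        if ks == 1:
            gs = gs.sum(axis=0, keepdims=True)
        if ss == 1:
            gs = gs.sum(axis=1, keepdims=True)
        grad[self.sl["sigma"]] = gs.ravel()
        if self.n_psi0:
            gp = g_psi0 * psi[:, 0, 0]
            grad[self.sl["psi0"]] = gp.sum() if self.n_psi0 == 1 else gp
        if self.n_psi1:
            grad[self.sl["psi1"]] = g_psi1.sum() * psi[0, 1, 1]
        if self.n_c:
            grad[self.sl["c"]] = g_c.sum()
        if self.n_rho:
            gr = g_rho * (1.0 - rho**2)
            grad[self.sl["rho"]] = gr.sum() if self.n_rho == 1 else gr
        return grad


# ---------------------------------------------------------------------------
# Expected complete-data log-likelihood (covariance part) and gradient
# ---------------------------------------------------------------------------


def _cov_obj_grad(theta, layout: CovLayout, packed: Packed, resid_by_class, post):
    spec = layout.spec
    K, S = spec.K, spec.n_sweeps
    q = layout.q
    sig, psi, rho = layout.expand(theta)
    total = 0.0
    g_sigma = np.zeros((K, S))
    g_psi0 = np.zeros(K)
    g_psi1 = np.zeros(K)
    g_c = np.zeros(K)
    g_rho = np.zeros(K)
    for gi, g in enumerate(packed.groups):
        m = g.J.size
        jm = g.J - 1
        for k in range(K):
            sk = sig[k][jm]
            P = np.outer(sk, sk)
            if spec.ar1:
                R = P * rho[k] ** g.lag
            else:
                R = np.diag(sk**2)
            if q > 0:
                V = np.einsum("gmq,qr,gnr->gmn", g.Z, psi[k], g.Z) + R
            else:
                V = np.broadcast_to(R, (g.T.shape[0], m, m)).copy()
            try:
                logdet = _chol_logdet(V)
            except np.linalg.LinAlgError:
                return _BIG, np.zeros(layout.size)
            A = np.linalg.inv(V)
            r = resid_by_class[k][gi]
            u = np.einsum("gmn,gn->gm", A, r)
            quad = np.einsum("gm,gm->g", r, u)
            ll = -0.5 * (m * _LOG2PI + logdet + quad)
            w = post[g.idx, k]
            total += float(w @ ll)
            # S_mat = sum_i w_i * 0.5 (u u' - A); pairs with dV that is
            # constant across subjects in the group (R and the psi0 block).
            S_mat = 0.5 * (np.einsum("g,gm,gn->mn", w, u, u) - np.einsum("g,gmn->mn", w, A))
            # residual SDs: dR_ab/dsig_j = R_ab (1[j_a=j] + 1[j_b=j]) / sig_j
            DSR = S_mat * R
            row = 2.0 * DSR.sum(axis=1)
            np.add.at(g_sigma[k], jm, row / sk)
            if spec.ar1:
                if abs(rho[k]) < 1e-12:
                    dR = P * (g.lag == 1)
                else:
                    with np.errstate(divide="ignore", invalid="ignore"):
                        dR = np.where(g.lag > 0, P * g.lag * rho[k] ** (g.lag - 1), 0.0)
                g_rho[k] += float((S_mat * dR).sum())
            if q >= 1:
                g_psi0[k] += float(S_mat.sum())  # dV = 1 1'
            if q >= 2:
                ut = np.einsum("gm,gm->g", u, g.T)
                tAt = np.einsum("gm,gmn,gn->g", g.T, A, g.T)
                g_psi1[k] += 0.5 * float(w @ (ut**2 - tAt))
                su = u.sum(axis=1)
                oAt = np.einsum("gmn,gn->g", A, g.T)  # 1' A t
                g_c[k] += float(w @ (su * ut - oAt))
    grad = layout.reduce_grads(theta, g_sigma, g_psi0, g_psi1, g_c, g_rho)
    return -total, -grad


def _cov_obj_only(theta, layout, packed, resid_by_class, post) -> float:
    val, _ = _cov_obj_grad(theta, layout, packed, resid_by_class, post)
    return val


# ---------------------------------------------------------------------------
# M-step
# ---------------------------------------------------------------------------


def _gls_betas(packed: Packed, params, spec, post) -> list[np.ndarray]:
    K = len(params)
    q = spec.n_random_effects
    p = spec.degree + 1
    betas = []
    for k, pk in enumerate(params):
        XtAX = np.zeros((p, p))
        XtAy = np.zeros(p)
        for g in packed.groups:
            V = group_cov(g, pk, q, spec.ar1)
            A = np.linalg.inv(V)
            w = post[g.idx, k]
            XtAX += np.einsum("g,gma,gmn,gnb->ab", w, g.X, A, g.X)
            XtAy += np.einsum("g,gma,gmn,gn->a", w, g.X, A, g.Y)
        betas.append(np.linalg.solve(XtAX, XtAy))
    return betas


def mstep(packed: Packed, spec, params, post, inner_maxiter: int = 12):
    """One ECM sweep: pi (closed form), beta (GLS), covariance (L-BFGS)."""
    pis = post.mean(axis=0)
    params = [
        pk.__class__(pi=float(pis[k]), beta=pk.beta, psi=pk.psi, sigma=pk.sigma, rho=pk.rho)
        for k, pk in enumerate(params)
    ]
    betas = _gls_betas(packed, params, spec, post)
    params = [
        pk.__class__(pi=pk.pi, beta=betas[k], psi=pk.psi, sigma=pk.sigma, rho=pk.rho)
        for k, pk in enumerate(params)
    ]
    layout = CovLayout(spec)
    if layout.size:
        resid_by_class = [
            [g.Y - g.X @ params[k].beta for g in packed.groups] for k in range(spec.K)
        ]
        theta0 = layout.to_vector(params)
        f0, _ = _cov_obj_grad(theta0, layout, packed, resid_by_class, post)
        res = minimize(
            _cov_obj_grad,
            theta0,
            args=(layout, packed, resid_by_class, post),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": inner_maxiter, "maxls": 25},
        )
        # generalized EM: keep the update only if it does not decrease Q
        if np.isfinite(res.fun) and res.fun <= f0:
            params = layout.apply(res.x, params)
    return params


# ---------------------------------------------------------------------------
# EM driver
# ---------------------------------------------------------------------------


def check_collapse(params, post, n: int) -> None:
    for k, pk in enumerate(params):
        if pk.pi < 1.0 / n:
            raise StartCollapsed(f"class {k + 1} collapsed (pi={pk.pi:.3g})")
        if np.min(pk.sigma) < 1e-4:
            raise StartCollapsed(f"class {k + 1} residual SD collapsed")


def run_em(packed: Packed, spec, params, max_iter: int, tol: float, inner_maxiter: int = 12):
    post, ll = estep(packed, params, spec)
    trace = [ll]
    converged = False
    for _ in range(max_iter):
        params = mstep(packed, spec, params, post, inner_maxiter=inner_maxiter)
        post, ll_new = estep(packed, params, spec)
        trace.append(ll_new)
        check_collapse(params, post, packed.n)
        if abs(ll_new - ll) <= tol * (1.0 + abs(ll)):
            converged = True
            ll = ll_new
            break
        ll = ll_new
    return params, post, ll, trace, converged
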