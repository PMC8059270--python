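"""Growth mixture model: specification, maximum-likelihood fitting, scoring.

The model: subject *i* in latent class *k* has

    y_i | k  ~  MVN( X_i beta_k ,  Z_i Psi_k Z_i' + R_ik )

where ``X_i`` is a polynomial design on centered age (degree up to 3), ``Z_i``
carries the random intercept/slope columns, and the residual block is
sweep-heteroskedastic AR(1):

    R_ik[a, b] = sigma[j_a, k] * sigma[j_b, k] * rho_k ** |j_a - j_b|

with ``j_a`` the sweep index of the a-th observation.  Mixing proportions
``pi_k`` complete the marginal likelihood.  Only the latent-intercept
variance is class-specific (when flagged); slope variance and the
intercept-slope covariance are shared across classes, and the variances of
quadratic/cubic growth are structurally zero.  Estimation is EM with
multi-start initialisation; each observed sub-vector contributes through its
own rows/columns (missing sweeps are simply absent, no imputation).

Model comparison uses BIC = -2 loglik + p ln(n); classification sharpness is
summarised by the relative entropy 1 - sum(-p ln p) / (n ln K).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from trajmix import _em
from trajmix.data_model import LongitudinalDataset, StateError

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "ClassParams",
    "FitResult",
    "FitError",
    "ParameterError",
    "build_design",
    "class_covariance",
    "marginal_loglik",
    "e_step",
    "m_step",
    "fit",
    "entropy",
    "bic",
    "n_parameters",
    "assign_modal",
    "order_classes",
]


class ParameterError(ValueError):
    """Parameters violate a structural constraint (e.g. non-PSD Psi)."""


class FitError(RuntimeError):
    """No EM start produced a usable solution."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one mixture variant.

    ``random_effects`` may be empty, ``("intercept",)`` or
    ``("intercept", "slope")``; higher-order growth terms never get random
    effects (their variances are structurally zero, which is what lets cubic
    models converge on serial BMI data).
    """

    K: int
    n_sweeps: int
    degree: int = 3
    random_effects: tuple[str, ...] = ("intercept", "slope")
    class_specific_intercept_var: bool = False
    class_specific_residuals: bool = False
    heteroskedastic_over_sweeps: bool = True
    ar1: bool = False
    shared_rho: bool = False
    estimate_intercept_slope_cov: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.K <= 7):
            raise ValueError(f"K must be in 1..7, got {self.K}")
        if self.degree not in (1, 2, 3):
            raise ValueError(f"degree must be 1, 2 or 3, got {self.degree}")
        re = tuple(self.random_effects)
        if re not in ((), ("intercept",), ("intercept", "slope")):
            raise ValueError(f"unsupported random_effects {re}")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        object.__setattr__(self, "random_effects", re)

    @property
    def n_random_effects(self) -> int:
        return len(self.random_effects)


@dataclass(frozen=True)
class ClassParams:
    """Parameters of one latent class.

    ``sigma`` holds the residual SD (kg/m²) at each sweep (length S even when
    tied); ``psi`` is the random-effect covariance (q x q); ``rho`` the AR(1)
    correlation, or None when the residuals are uncorrelated.
    """

    pi: float
    beta: np.ndarray
    psi: np.ndarray | None
    sigma: np.ndarray
    rho: float | None

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        object.__setattr__(self, "sigma", np.asarray(self.sigma, dtype=float))
        if self.psi is not None:
            object.__setattr__(self, "psi", np.asarray(self.psi, dtype=float))
        if not (0 < self.pi <= 1):
            raise ParameterError(f"pi must be in (0, 1], got {self.pi}")
        if np.any(self.sigma <= 0):
            raise ParameterError("sigma entries must be > 0")
        if self.rho is not None and not (-1 < self.rho < 1):
            raise ParameterError(f"rho must be in (-1, 1), got {self.rho}")


@dataclass(frozen=True)
class FitResult:
    """Fitted mixture: parameters, fit statistics and posterior matrix.

    Classes are ordered by fitted mean BMI at centered age 0, ascending, so
    class 1 is always the lowest trajectory.
    """

    spec: ModelSpec
    params: tuple[ClassParams, ...]
    loglik: float
    n_params: int
    bic: float
    entropy: float
    posteriors: np.ndarray
    converged: bool
    n_starts_used: int
    best_start_seed: int
    ids: tuple[str, ...] = ()
    loglik_trace: tuple[float, ...] = ()
    centering_age: float | None = None

    def to_json(self, path) -> None:
        doc = {
            "spec": {
                "K": self.spec.K,
                "n_sweeps": self.spec.n_sweeps,
                "degree": self.spec.degree,
                "random_effects": list(self.spec.random_effects),
                "class_specific_intercept_var": self.spec.class_specific_intercept_var,
                "class_specific_residuals": self.spec.class_specific_residuals,
                "heteroskedastic_over_sweeps": self.spec.heteroskedastic_over_sweeps,
                "ar1": self.spec.ar1,
                "shared_rho": self.spec.shared_rho,
                "estimate_intercept_slope_cov": self.spec.estimate_intercept_slope_cov,
            },
            "params": [
                {
                    "pi": pk.pi,
                    "beta": pk.beta.tolist(),
                    "psi": None if pk.psi is None else pk.psi.tolist(),
                    "sigma": pk.sigma.tolist(),
                    "rho": pk.rho,
                }
                for pk in self.params
            ],
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "entropy": self.entropy,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "best_start_seed": self.best_start_seed,
            "centering_age": self.centering_age,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            doc = json.load(fh)
        spec = ModelSpec(**{k: tuple(v) if k == "random_effects" else v for k, v in doc["spec"].items()})
        params = tuple(
            ClassParams(
                pi=p["pi"],
                beta=np.array(p["beta"]),
                psi=None if p["psi"] is None else np.array(p["psi"]),
                sigma=np.array(p["sigma"]),
                rho=p["rho"],
            )
            for p in doc["params"]
        )
        return cls(
            spec=spec,
            params=params,
            loglik=doc["loglik"],
            n_params=doc["n_params"],
            bic=doc["bic"],
            entropy=doc["entropy"],
            posteriors=np.zeros((0, spec.K)),
            converged=doc["converged"],
            n_starts_used=doc["n_starts_used"],
            best_start_seed=doc["best_start_seed"],
            centering_age=doc.get("centering_age"),
        )

    def posteriors_to_csv(self, path) -> None:
        K = self.spec.K
        df = pd.DataFrame(self.posteriors, columns=[f"p_{k + 1}" for k in range(K)])
        df.insert(0, "id", list(self.ids))
        df["modal"] = assign_modal(self.posteriors)
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def build_design(ages, degree: int, random_effects: tuple[str, ...] = ("intercept", "slope")):
    """Fixed design X = (1, t, ..., t^degree) and RE design Z = (1[, t])."""
    if degree not in (1, 2, 3):
        raise ValueError(f"degree must be 1, 2 or 3, got {degree}")
    return _em.design_matrices(np.asarray(ages, dtype=float), degree, len(random_effects))


def class_covariance(params: ClassParams, ages, sweeps, ar1: bool = True) -> np.ndarray:
    """Marginal covariance V = Z Psi Z' + R for one subject's observations.

    ``R[a, b] = sigma[j_a] sigma[j_b] rho^|j_a - j_b|`` (diagonal when the
    AR(1) term is off or ``rho`` is None).  Raises :class:`ParameterError`
    when Psi is not positive semi-definite.
    """
    ages = np.asarray(ages, dtype=float)
    sweeps = np.asarray(sweeps, dtype=int)
    if ages.shape != sweeps.shape or ages.ndim != 1 or ages.size < 1:
        raise ValueError("ages and sweeps must be equal-length 1-d arrays")
    if np.any(sweeps < 1) or np.any(sweeps > params.sigma.size):
        raise ValueError("sweep index outside 1..S")
    if params.psi is not None:
        eig = np.linalg.eigvalsh(params.psi)
        if eig.min() < -1e-10:
            raise ParameterError("psi is not positive semi-definite")
    sig = params.sigma[sweeps - 1]
    if ar1 and params.rho is not None:
        lag = np.abs(sweeps[:, None] - sweeps[None, :])
        R = np.outer(sig, sig) * params.rho ** lag
    else:
        R = np.diag(sig**2)
    q = 0 if params.psi is None else params.psi.shape[0]
    if q:
        _, Z = _em.design_matrices(ages, max(q - 1, 1), q)
        R = R + Z @ params.psi @ Z.T
    return R


def _pack(ds: LongitudinalDataset, spec: ModelSpec) -> _em.Packed:
    if ds.centering_age is None:
        raise StateError("dataset must be age-centered before fitting (see center_ages)")
    if ds.n_sweeps > spec.n_sweeps:
        raise ValueError(f"data contain sweep index {ds.n_sweeps} > spec.n_sweeps {spec.n_sweeps}")
    packed = _em.pack(ds, spec.degree, spec.n_random_effects)
    packed.S = spec.n_sweeps
    return packed


def marginal_loglik(ds: LongitudinalDataset, params, spec: ModelSpec) -> float:
    """Observed-data log-likelihood sum_i log sum_k pi_k phi(y_i; X_i b_k, V_ik)."""
    packed = _pack(ds, spec)
    try:
        _, ll = _em.estep(packed, list(params), spec)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular class covariance while scoring: {err}") from err
    return ll


def e_step(ds: LongitudinalDataset, params, spec: ModelSpec) -> np.ndarray:
    """Posterior class probabilities p_ik (rows sum to 1), log-space safe."""
    packed = _pack(ds, spec)
    post, _ = _em.estep(packed, list(params), spec)
    bad = ~np.isfinite(post).all(axis=1)
    if bad.any():
        flagged = [packed.ids[i] for i in np.nonzero(bad)[0]]
        raise FloatingPointError(f"posterior underflow for subjects: {flagged[:10]}")
    return post


def m_step(ds: LongitudinalDataset, posteriors: np.ndarray, spec: ModelSpec, params, inner_maxiter: int = 50):
    """One ECM update of (pi, beta, covariance) given posteriors."""
    packed = _pack(ds, spec)
    return tuple(_em.mstep(packed, spec, list(params), np.asarray(posteriors), inner_maxiter=inner_maxiter))


def entropy(posteriors: np.ndarray) -> float:
    """Relative entropy 1 - sum(-p ln p) / (n ln K), in [0, 1]; 1 = crisp."""
    p = np.asarray(posteriors, dtype=float)
    n, K = p.shape
    if K == 1:
        warnings.warn("entropy is undefined for K=1; returning nan", stacklevel=2)
        return float("nan")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return float(1.0 - terms.sum() / (n * np.log(K)))


def bic(loglik: float, n_params: int, n_subjects: int) -> float:
    """Bayesian Information Criterion -2 loglik + p ln(n); lower is better."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    return -2.0 * loglik + n_params * np.log(n_subjects)


def n_parameters(spec: ModelSpec) -> int:
    """Free-parameter count of a spec (for BIC)."""
    K, S = spec.K, spec.n_sweeps
    p = K * (spec.degree + 1) + (K - 1)
    q = spec.n_random_effects
    if q >= 1:
        p += K if spec.class_specific_intercept_var else 1
    if q >= 2:
        p += 1  # slope variance
        if spec.estimate_intercept_slope_cov:
            p += 1
    cs, het = spec.class_specific_residuals, spec.heteroskedastic_over_sweeps
    p += (K * S if cs else S) if het else (K if cs else 1)
    if spec.ar1:
        p += K if (cs and not spec.shared_rho) else 1
    return p


def assign_modal(posteriors: np.ndarray) -> np.ndarray:
    """Most likely class per subject (1-based); ties go to the lower class."""
    return np.argmax(np.asarray(posteriors), axis=1) + 1


def order_classes(result: FitResult) -> FitResult:
    """Permute classes so the fitted mean at centered age 0 is ascending."""
    means = np.array([pk.beta[0] for pk in result.params])
    perm = np.argsort(means, kind="stable")
    if np.array_equal(perm, np.arange(len(perm))):
        return result
    params = tuple(result.params[j] for j in perm)
    post = result.posteriors[:, perm] if result.posteriors.size else result.posteriors
    return replace(result, params=params, posteriors=post)


# ---------------------------------------------------------------------------
# Initialization and multi-start fitting
# ---------------------------------------------------------------------------


def _subject_growth_features(ds: LongitudinalDataset) -> np.ndarray:
    """Per-subject ridge-stabilised (intercept, slope) at centered age 0."""
    feats = np.zeros((ds.n_subjects, 2))
    scale = 20.0  # ages rescaled so polynomial powers are O(1) under ridge
    for i, s in enumerate(ds.subjects):
        u, y = s.ages() / scale, s.bmis()
        deg = int(min(3, s.n_obs - 1)) if s.n_obs > 1 else 0
        X = np.stack([u**d for d in range(deg + 1)], axis=-1)
        lam = 1e-3 * s.n_obs
        pen = lam * np.eye(X.shape[1])
        pen[0, 0] = 0.0  # never shrink the intercept
        b = np.linalg.solve(X.T @ X + pen, X.T @ y)
        feats[i, 0] = b[0]
        feats[i, 1] = b[1] / scale if deg >= 1 else 0.0
    return feats


def _init_params(ds: LongitudinalDataset, spec: ModelSpec, feats: np.ndarray, rng: np.random.Generator) -> list[ClassParams]:
    from sklearn.cluster import KMeans

    n = ds.n_subjects
    K = spec.K
    if K == 1:
        labels = np.zeros(n, dtype=int)
    else:
        std = feats.std(axis=0)
        std[std == 0] = 1.0
        km = KMeans(n_clusters=K, n_init=5, random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(feats / std)
    # order initial clusters by mean intercept so labels start near final order
    order = np.argsort([feats[labels == k, 0].mean() if (labels == k).any() else np.inf for k in range(K)])
    relabel = np.empty(K, dtype=int)
    relabel[order] = np.arange(K)
    labels = relabel[labels]

    all_t = np.concatenate([s.ages() for s in ds.subjects])
    all_y = np.concatenate([s.bmis() for s in ds.subjects])
    all_j = np.concatenate([s.sweeps() for s in ds.subjects])
    sub_of_obs = np.concatenate([np.full(s.n_obs, i) for i, s in enumerate(ds.subjects)])
    Xall = np.stack([all_t**d for d in range(spec.degree + 1)], axis=-1)

    params = []
    sd_y = float(all_y.std())
    for k in range(K):
        mask = labels[sub_of_obs] == k
        if mask.sum() >= spec.degree + 2:
            Xk, yk = Xall[mask], all_y[mask]
            beta = np.linalg.lstsq(Xk, yk, rcond=None)[0]
            resid = yk - Xk @ beta
        else:
            beta = np.linalg.lstsq(Xall, all_y, rcond=None)[0]
            resid = all_y - Xall @ beta
        sig = np.full(spec.n_sweeps, max(float(resid.std()), 0.5))
        if spec.heteroskedastic_over_sweeps:
            for j in range(1, spec.n_sweeps + 1):
                jm = mask & (all_j == j)
                if jm.sum() >= 5:
                    sig[j - 1] = max(float((all_y[jm] - Xall[jm] @ beta).std()), 0.5)
        q = spec.n_random_effects
        psi = None
        if q >= 1:
            members = labels == k
            v0 = float(np.var(feats[members, 0])) if members.sum() > 2 else 1.0
            psi = np.zeros((q, q))
            psi[0, 0] = max(v0 * 0.5, 0.25)
            if q >= 2:
                v1 = float(np.var(feats[members, 1])) if members.sum() > 2 else 1e-3
                psi[1, 1] = min(max(v1 * 0.5, 1e-4), 0.05)
        pi = max((labels == k).mean(), 0.5 / K)
        params.append(
            ClassParams(pi=pi, beta=beta, psi=psi, sigma=sig, rho=0.3 if spec.ar1 else None)
        )
    tot = sum(pk.pi for pk in params)
    return [replace(pk, pi=pk.pi / tot) for pk in params]


def fit(
    ds: LongitudinalDataset,
    spec: ModelSpec,
    n_starts: int = 50,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    *,
    n_full: int = 10,
    short_iter: int = 20,
    inner_maxiter: int = 12,
    allow_mixed_sex: bool = False,
) -> FitResult:
    """Fit the mixture by multi-start EM; deterministic given ``seed``.

    All ``n_starts`` initialisations get a short EM run (``short_iter``
    iterations); the best ``n_full`` by log-likelihood are run to
    convergence.  Starts whose classes collapse (pi < 1/n or residual SD
    < 1e-4) are discarded with a log message.  The returned classes are
    ordered by fitted mean BMI at the centering age, ascending.
    """
    if len(ds.sexes()) > 1 and not allow_mixed_sex:
        raise ValueError(
            "dataset mixes sexes; trajectory models are sex-specific "
            "(use split_by_sex, or pass allow_mixed_sex=True)"
        )
    n = ds.n_subjects
    if n < spec.K * (spec.degree + 2):
        raise ValueError(f"too few subjects ({n}) for K={spec.K}, degree={spec.degree}")
    packed = _pack(ds, spec)
    feats = _subject_growth_features(ds)
    n_starts = 1 if spec.K == 1 else n_starts
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_starts)

    survivors = []
    sd_y = float(np.concatenate([s.bmis() for s in ds.subjects]).std())
    for s_idx, child in enumerate(children):
        rng = np.random.default_rng(child)
        try:
            params0 = _init_params(ds, spec, feats, rng)
            if s_idx > 0:
                params0 = [
                    replace(pk, beta=pk.beta + np.eye(1, spec.degree + 1, 0)[0] * rng.normal(0.0, 0.5 * sd_y))
                    for pk in params0
                ]
            params, post, ll, trace, _ = _em.run_em(
                packed, spec, params0, max_iter=short_iter, tol=tol, inner_maxiter=inner_maxiter
            )
            survivors.append((ll, s_idx, params))
        except (_em.StartCollapsed, np.linalg.LinAlgError) as err:
            logger.info("fit: start %d discarded (%s)", s_idx, err)
    if not survivors:
        raise FitError(f"all {n_starts} starts failed for K={spec.K} (collapse or singular covariance)")

    survivors.sort(key=lambda r: -r[0])
    best = None
    for ll0, s_idx, params in survivors[: max(1, n_full)]:
        try:
            params, post, ll, trace, conv = _em.run_em(
                packed, spec, params, max_iter=max_iter, tol=tol, inner_maxiter=inner_maxiter
            )
        except (_em.StartCollapsed, np.linalg.LinAlgError) as err:
            logger.info("fit: start %d discarded in full EM (%s)", s_idx, err)
            continue
        if best is None or ll > best[0]:
            best = (ll, s_idx, params, post, trace, conv)
    if best is None:
        raise FitError(f"no start converged for K={spec.K}")

    ll, s_idx, params, post, trace, conv = best
    p = n_parameters(spec)
    result = FitResult(
        spec=spec,
        params=tuple(params),
        loglik=ll,
        n_params=p,
        bic=bic(ll, p, n),
        entropy=entropy(post) if spec.K > 1 else float("nan"),
        posteriors=post,
        converged=conv,
        n_starts_used=len(survivors),
        best_start_seed=s_idx,
        ids=packed.ids,
        loglik_trace=tuple(trace),
        centering_age=ds.centering_age,
    )
    return order_classes(result)
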