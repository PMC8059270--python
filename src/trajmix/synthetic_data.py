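"""Synthetic multi-cohort longitudinal BMI generator with known latent structure.

Emulates three British birth-cohort studies (1946 NSHD, 1958 NCDS, 1970 BCS):
each cohort measures BMI at five target ages between ~10 and ~43 years, with
some sweeps self-reported, cohort-specific latent-class mixes, and per-sweep
dropout.  Subjects belong to one of K latent trajectory classes; within a
class, individual series follow a cubic mean curve plus a random
intercept/slope and a sweep-heteroskedastic AR(1) Gaussian residual process.

The class mean curves shipped in :func:`default_scenario` are synthetic
package defaults chosen so the four classes behave like the archetypes seen
in cohort BMI data (a 'lowest' class staying in the normal range, a 'middle'
class drifting into overweight, a rapidly 'increasing' class, and a 'highest'
class moving from mild overweight into obesity); they are not estimates from
any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from trajmix.data_model import LongitudinalDataset, Observation, Subject

__all__ = [
    "ClassTruth",
    "CohortConfig",
    "GeneratorConfig",
    "TruthRecord",
    "default_scenario",
    "simulate",
    "implied_odds_ratios",
]


@dataclass(frozen=True)
class ClassTruth:
    """Ground-truth parameters of one latent trajectory class.

    ``beta`` are cubic polynomial coefficients on centered age (years);
    ``sigma`` are residual SDs (kg/m²) per sweep; ``rho`` the AR(1)
    correlation between consecutive sweeps' residuals.
    """

    beta: tuple[float, float, float, float]
    intercept_sd: float
    slope_sd: float
    int_slope_corr: float
    sigma: tuple[float, ...]
    rho: float

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma):
            raise ValueError("sigma must be > 0")
        if not (-1 < self.rho < 1):
            raise ValueError("rho must be in (-1, 1)")
        if not (-1 <= self.int_slope_corr <= 1):
            raise ValueError("int_slope_corr must be in [-1, 1]")

    def re_cov(self) -> np.ndarray:
        c = self.int_slope_corr * self.intercept_sd * self.slope_sd
        return np.array([[self.intercept_sd**2, c], [c, self.slope_sd**2]])


@dataclass(frozen=True)
class CohortConfig:
    """One simulated birth cohort: sweep schedule, size, class mix, dropout."""

    label: str
    n_subjects: int
    target_ages: tuple[float, ...]
    class_probabilities: tuple[float, ...]
    retention: tuple[float, ...]  # per-sweep P(observed)
    self_report_sweeps: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if abs(sum(self.class_probabilities) - 1.0) > 1e-8:
            raise ValueError(f"cohort {self.label}: class probabilities must sum to 1")
        if len(self.retention) != len(self.target_ages):
            raise ValueError(f"cohort {self.label}: retention length must match target_ages")
        if any(not (0 < r <= 1) for r in self.retention):
            raise ValueError(f"cohort {self.label}: retention must be in (0, 1]")
        if self.n_subjects < 1:
            raise ValueError(f"cohort {self.label}: n_subjects must be >= 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full scenario: cohorts, latent classes, centering, jitter, sex label."""

    cohorts: tuple[CohortConfig, ...]
    classes: tuple[ClassTruth, ...]
    centering_age: float
    sex: str = "male"
    age_jitter: float = 0.5  # uniform ±jitter years around each target age
    self_report_bias: float = 0.0  # additive kg/m² on self-report sweeps

    def __post_init__(self) -> None:
        K = len(self.classes)
        for c in self.cohorts:
            if len(c.class_probabilities) != K:
                raise ValueError(f"cohort {c.label}: simplex length != number of classes")

    def to_yaml(self, path) -> None:
        doc = {
            "sex": self.sex,
            "centering_age": self.centering_age,
            "age_jitter": self.age_jitter,
            "self_report_bias": self.self_report_bias,
            "classes": [
                {
                    "beta": list(map(float, k.beta)),
                    "intercept_sd": k.intercept_sd,
                    "slope_sd": k.slope_sd,
                    "int_slope_corr": k.int_slope_corr,
                    "sigma": list(map(float, k.sigma)),
                    "rho": k.rho,
                }
                for k in self.classes
            ],
            "cohorts": [
                {
                    "label": c.label,
                    "n_subjects": c.n_subjects,
                    "target_ages": list(map(float, c.target_ages)),
                    "class_probabilities": list(map(float, c.class_probabilities)),
                    "retention": list(map(float, c.retention)),
                    "self_report_sweeps": sorted(c.self_report_sweeps),
                }
                for c in self.cohorts
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        classes = tuple(
            ClassTruth(
                beta=tuple(k["beta"]),
                intercept_sd=k["intercept_sd"],
                slope_sd=k["slope_sd"],
                int_slope_corr=k["int_slope_corr"],
                sigma=tuple(k["sigma"]),
                rho=k["rho"],
            )
            for k in doc["classes"]
        )
        cohorts = tuple(
            CohortConfig(
                label=c["label"],
                n_subjects=c["n_subjects"],
                target_ages=tuple(c["target_ages"]),
                class_probabilities=tuple(c["class_probabilities"]),
                retention=tuple(c["retention"]),
                self_report_sweeps=frozenset(c.get("self_report_sweeps", ())),
            )
            for c in doc["cohorts"]
        )
        return cls(
            cohorts=cohorts,
            classes=classes,
            centering_age=doc["centering_age"],
            sex=doc.get("sex", "male"),
            age_jitter=doc.get("age_jitter", 0.5),
            self_report_bias=doc.get("self_report_bias", 0.0),
        )


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated subject (for recovery tests)."""

    id: str
    true_class: int  # 1-based, ordered by mean BMI at the centering age
    b0: float  # random intercept deviation
    b1: float  # random slope deviation


# ---------------------------------------------------------------------------
# Default three-cohort scenario
# ---------------------------------------------------------------------------

# Sweep target ages and self-report sweeps per cohort (study schedules).
_SCHEDULES = {
    "NSHD1946": ((11.0, 15.0, 26.0, 36.0, 43.0), frozenset({3})),
    "NCDS1958": ((11.0, 16.0, 23.0, 33.0, 42.0), frozenset({3, 5})),
    "BCS1970": ((10.0, 16.0, 26.0, 34.0, 42.0), frozenset({3, 4, 5})),
}

# Modal class counts by cohort (4 classes, lowest..highest), used as the
# cohort-specific latent class mixes.
_CLASS_COUNTS = {
    "male": {
        "NSHD1946": (1188, 296, 328, 60),
        "NCDS1958": (3757, 1093, 1083, 358),
        "BCS1970": (2209, 643, 1150, 300),
    },
    "female": {
        "NSHD1946": (966, 274, 460, 121),
        "NCDS1958": (3036, 1012, 1629, 551),
        "BCS1970": (2248, 656, 1682, 555),
    },
}

_CENTERING = {"male": 23.64, "female": 26.00}

# Per-sweep retention probabilities, chosen so that with 5 sweeps the share of
# subjects with >=4 observations lands near 85% / 81% / 71% by cohort.
_RETENTION = {
    "NSHD1946": (0.855, 0.855, 0.855, 0.855, 0.855),
    "NCDS1958": (0.84, 0.84, 0.84, 0.84, 0.84),
    "BCS1970": (0.79, 0.79, 0.79, 0.79, 0.79),
}

# Anchor (age, BMI) points for each class's mean curve; a cubic is solved
# through the four anchors.  Synthetic defaults, not cohort estimates.
_ANCHOR_AGES = (11.0, 24.0, 33.0, 42.0)
_ANCHOR_BMI = {
    "male": {
        "lowest": (18.5, 22.0, 23.0, 23.5),
        "middle": (21.0, 24.5, 26.0, 27.0),
        "increasing": (19.5, 25.0, 27.5, 29.5),
        "highest": (26.5, 29.0, 30.5, 32.5),
    },
    "female": {
        "lowest": (18.0, 21.5, 22.0, 22.5),
        "middle": (21.0, 23.5, 24.0, 24.5),
        "increasing": (19.0, 24.5, 27.0, 29.5),
        "highest": (26.5, 29.5, 31.5, 33.5),
    },
}

_INTERCEPT_SD = (1.2, 1.5, 1.8, 2.5)
_SIGMA = (1.0, 1.3, 1.7, 2.1, 2.5)  # residual SD rising with sweep/age
_RHO = 0.5
_SLOPE_SD = 0.06
_INT_SLOPE_CORR = 0.2


def _cubic_through(ages, values, center) -> tuple[float, float, float, float]:
    t = np.asarray(ages, dtype=float) - center
    V = np.vander(t, 4, increasing=True)
    return tuple(np.linalg.solve(V, np.asarray(values, dtype=float)))


def default_scenario(scale: float = 0.1, sex: str = "male", n_classes: int = 4) -> GeneratorConfig:
    """Three-cohort scenario at a fraction ``scale`` of full size.

    At ``scale=1`` the male cohorts have (1872, 6291, 4302) subjects and the
    female cohorts (1821, 6228, 5141), with cohort-specific class mixes equal
    to the modal class shares of each cohort.

    ``n_classes=4`` (default) is the full lowest/middle/increasing/highest
    structure, in which the middle and increasing classes overlap strongly
    near the centering age — deliberately, as their real-world counterparts
    do; resolving all four classes then needs samples of order 10^4.
    ``n_classes=3`` merges the middle class into the lowest (summing their
    mix probabilities), giving a scenario whose classes are mutually
    well-resolved at a few hundred subjects — useful for end-to-end
    demonstrations and recovery checks at desk scale.
    """
    if not (0 < scale <= 1):
        raise ValueError("scale must be in (0, 1]")
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    if n_classes not in (3, 4):
        raise ValueError("n_classes must be 3 or 4")
    center = _CENTERING[sex]
    classes = tuple(
        ClassTruth(
            beta=_cubic_through(_ANCHOR_AGES, _ANCHOR_BMI[sex][name], center),
            intercept_sd=_INTERCEPT_SD[i],
            slope_sd=_SLOPE_SD,
            int_slope_corr=_INT_SLOPE_CORR,
            sigma=_SIGMA,
            rho=_RHO,
        )
        for i, name in enumerate(("lowest", "middle", "increasing", "highest"))
    )
    if n_classes == 3:
        classes = (classes[0], classes[2], classes[3])
    cohorts = []
    for label, counts in _CLASS_COUNTS[sex].items():
        total = sum(counts)
        n = round(scale * total)
        if n == 0:
            raise ValueError(f"scale {scale} yields an empty cohort {label}")
        ages, sr = _SCHEDULES[label]
        probs = tuple(c / total for c in counts)
        if n_classes == 3:
            probs = (probs[0] + probs[1], probs[2], probs[3])
        cohorts.append(
            CohortConfig(
                label=label,
                n_subjects=n,
                target_ages=ages,
                class_probabilities=probs,
                retention=_RETENTION[label],
                self_report_sweeps=sr,
            )
        )
    return GeneratorConfig(cohorts=tuple(cohorts), classes=classes, centering_age=center, sex=sex)


def simulate(config: GeneratorConfig, seed: int) -> tuple[LongitudinalDataset, list[TruthRecord]]:
    """Draw a dataset (raw, uncentered ages) and per-subject ground truth.

    Per subject: class ~ cohort simplex; (b0, b1) ~ N(0, Ψ_k); ages are the
    cohort target ages plus uniform jitter; residuals are Gaussian AR(1) over
    sweeps with sweep-specific SDs; each sweep is independently retained with
    the cohort's per-sweep probability.  Subjects with no retained sweeps are
    dropped.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    K = len(config.classes)
    subjects: list[Subject] = []
    truth: list[TruthRecord] = []
    for cohort in config.cohorts:
        S = len(cohort.target_ages)
        lag = np.abs(np.subtract.outer(np.arange(S), np.arange(S)))
        for i in range(cohort.n_subjects):
            sid = f"{cohort.label}-{i:06d}"
            k = int(rng.choice(K, p=cohort.class_probabilities))
            cls = config.classes[k]
            b0, b1 = rng.multivariate_normal([0.0, 0.0], cls.re_cov())
            ages = np.asarray(cohort.target_ages) + rng.uniform(
                -config.age_jitter, config.age_jitter, size=S
            )
            t = ages - config.centering_age
            sig = np.asarray(cls.sigma[:S])
            R = np.outer(sig, sig) * cls.rho**lag
            eps = rng.multivariate_normal(np.zeros(S), R)
            mean = np.polynomial.polynomial.polyval(t, cls.beta)
            y = mean + b0 + b1 * t + eps
            keep = rng.random(S) < np.asarray(cohort.retention)
            obs = []
            for j in np.nonzero(keep)[0]:
                sweep = int(j) + 1
                sr = sweep in cohort.self_report_sweeps
                obs.append(
                    Observation(
                        age=float(ages[j]),
                        bmi=float(y[j] + (config.self_report_bias if sr else 0.0)),
                        sweep_index=sweep,
                        source="self_report" if sr else "measured",
                    )
                )
            if not obs:
                continue
            subjects.append(
                Subject(id=sid, sex=config.sex, cohort=cohort.label, observations=tuple(obs))
            )
            truth.append(TruthRecord(id=sid, true_class=k + 1, b0=float(b0), b1=float(b1)))
    return LongitudinalDataset(subjects=tuple(subjects)), truth


def implied_odds_ratios(config: GeneratorConfig, ref_class: int = 1, ref_cohort: str | None = None) -> dict:
    """True class-membership odds ratios implied by the cohort simplices.

    With class mixes varying only by cohort, the multinomial-logit cohort
    effects are exactly the cross-cohort log-odds contrasts of the simplices:
    OR[c, k] = (p_ck / p_c,ref) / (p_ref_cohort,k / p_ref_cohort,ref).
    """
    if ref_cohort is None:
        ref_cohort = config.cohorts[0].label
    ref = {c.label: c for c in config.cohorts}[ref_cohort]
    out: dict[str, dict[int, float]] = {}
    r = ref_class - 1
    for c in config.cohorts:
        if c.label == ref_cohort:
            continue
        p, q = np.asarray(c.class_probabilities), np.asarray(ref.class_probabilities)
        out[c.label] = {
            k + 1: float((p[k] / p[r]) / (q[k] / q[r]))
            for k in range(len(p))
            if k != r
        }
    return out
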